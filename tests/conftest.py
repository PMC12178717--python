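"""Shared fixtures.

The expensive coalescent-HMM fits are session-scoped and shared between the
property tests and the acceptance tests.  Problem sizes: 10 Mb genomes for
the recovery scenarios, 8 Mb for the repeat-mask comparison.
"""

import numpy as np
import pytest

from psmckit.formats import DiploidConsensus, MaskIntervals, bytes_to_seq, seq_to_bytes
from psmckit.hetstats import apply_mask
from psmckit.pseudodiploid import pseudo_diploid
from psmckit.psmc import PSMC, make_psmcfa
from psmckit.synthetic import (DemographyModel, QuartetModel, drop_mutations,
                               sample_pairwise_tmrca, simulate_quartet_sites,
                               simulate_split_pair)

N_TRUE = 1e4          # diploid Ne of the constant scenario
MU = 1e-8             # per base per generation
R = 1e-8
G_YEARS = 5.0
MU_PER_YEAR = MU / G_YEARS
GENOME = 10_000_000
TAU = 1e5             # split time, generations (= 500 kyr at g = 5)


@pytest.fixture(scope="session")
def constant_consensus():
    model = DemographyModel(epochs=[(0.0, N_TRUE)], mu_per_gen=MU, r_per_gen=R)
    track = sample_pairwise_tmrca(model, GENOME, seed=7)
    return drop_mutations(track, MU, seed=7)


@pytest.fixture(scope="session")
def constant_fit(constant_consensus):
    return PSMC(make_psmcfa(constant_consensus)).fit(n_iter=25)


@pytest.fixture(scope="session")
def bottleneck_fit():
    model = DemographyModel(
        epochs=[(0.0, N_TRUE), (2e4, N_TRUE / 10), (4e4, N_TRUE)],
        mu_per_gen=MU, r_per_gen=R)
    track = sample_pairwise_tmrca(model, GENOME, seed=21)
    cons = drop_mutations(track, MU, seed=21)
    return PSMC(make_psmcfa(cons)).fit(n_iter=25)


@pytest.fixture(scope="session")
def split_case():
    """Clean split at TAU: two singles, their pseudo-diploid, all three fits."""
    model = DemographyModel(epochs=[(0.0, N_TRUE)], mu_per_gen=MU,
                            r_per_gen=R, split_time=TAU)
    a, b, cross = simulate_split_pair(model, GENOME, seed=5)
    pseudo = pseudo_diploid(a, b, seed_x=11, seed_y=12)
    fits = {name: PSMC(make_psmcfa(cons)).fit(n_iter=25)
            for name, cons in (("a", a), ("b", b), ("pseudo", pseudo))}
    trajs = {k: f.trajectory(MU_PER_YEAR, G_YEARS) for k, f in fits.items()}
    return {"a": a, "b": b, "pseudo": pseudo, "cross": cross,
            "fits": fits, "trajs": trajs}


def plant_artifact_regions(cons: DiploidConsensus, seed: int,
                           n_regions: int = 25, region_len: int = 32_000,
                           het_p: float = 0.02):
    """Overwrite regions with artificially dense heterozygosity.

    Emulates the excess apparent heterozygosity that mismapped repetitive
    reads produce; returns (modified consensus, mask covering the regions).
    """
    rng = np.random.default_rng(seed)
    (cname, seq), = cons.contigs
    arr = seq_to_bytes(seq).copy()
    length = len(arr)
    starts = np.sort(rng.choice(length // region_len, n_regions, replace=False)
                     ) * region_len
    het_codes = np.frombuffer(b"RYSWKM", dtype=np.uint8)
    hom_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for s in starts:
        e = min(s + region_len, length)
        block = hom_codes[rng.integers(0, 4, e - s)]
        het = rng.random(e - s) < het_p
        block[het] = het_codes[rng.integers(0, 6, int(het.sum()))]
        arr[s:e] = block
    mask = MaskIntervals(intervals={
        cname: [(int(s), int(min(s + region_len, length))) for s in starts]})
    return DiploidConsensus(name=cons.name + "+artifacts",
                            contigs=[(cname, bytes_to_seq(arr))]), mask


@pytest.fixture(scope="session")
def mask_case():
    """Constant-Ne genome with planted artifact-het regions, fitted with and
    without the mask covering those regions (8 Mb)."""
    model = DemographyModel(epochs=[(0.0, N_TRUE)], mu_per_gen=MU, r_per_gen=R)
    track = sample_pairwise_tmrca(model, 8_000_000, seed=31)
    clean = drop_mutations(track, MU, seed=31)
    dirty, mask = plant_artifact_regions(clean, seed=32)
    fit_masked = PSMC(make_psmcfa(apply_mask(dirty, mask))).fit(n_iter=25)
    fit_unmasked = PSMC(make_psmcfa(dirty)).fit(n_iter=25)
    return {"masked": fit_masked, "unmasked": fit_unmasked, "mask": mask}


QUARTET_NULL = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5, f=0.0)
QUARTET_ADMIXED = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5,
                               f=0.2, t_admix=2e4)


def _quartet_replicates(model, n_rep=10, n_sites=100_000, block=1000,
                        seed0=100):
    from psmckit.dstat import block_jackknife
    out = []
    for rep in range(n_rep):
        q = simulate_quartet_sites(model, n_sites, block, seed=seed0 + rep)
        out.append(block_jackknife(q))
    return out


@pytest.fixture(scope="session")
def quartet_null_results():
    return _quartet_replicates(QUARTET_NULL, seed0=100)


@pytest.fixture(scope="session")
def quartet_admixed_results():
    return _quartet_replicates(QUARTET_ADMIXED, seed0=200)
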