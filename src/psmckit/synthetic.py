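"""Coalescent synthetic-genome generator.

Generates diploid consensus genomes whose heterozygous-site spatial structure
follows a sequentially Markovian coalescent (SMC) under piecewise-constant
effective population size: along the sequence the pairwise TMRCA is piecewise
constant, breakpoints occur at rate 2·T·r per base pair, and at a breakpoint
one lineage is erased at a uniform time u in [0, T] and re-coalesced from u
under the same demography.  Mutations are dropped on the resulting local
genealogies with an infinite-sites emission: a site with TMRCA T (generations)
is heterozygous with probability 1 − exp(−2·T·μ).

SMC (not SMC') resampling is used deliberately: it is the generative model the
discretised coalescent HMM in :mod:`psmckit.psmc` inverts, and it is adequate
for producing recoverable demographies.  Time is internally in generations
throughout; the per-year mutation rate and generation time enter only at the
scaling boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import rng_for
from .dstat import QuartetSiteMatrix
from .formats import DiploidConsensus, BASE_OF_CODE, bytes_to_seq
from .pseudodiploid import _COMBINE

_HET_BYTES = np.frombuffer(b"RYSWKM", dtype=np.uint8)
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DemographyModel:
    """Piecewise-constant Ne demography for one (or a pair of) population(s).

    ``epochs`` is a list of ``(start_time_generations, Ne_diploids)`` with the
    first start at 0 (the present) and times strictly increasing; each epoch
    extends to the next start, the last to infinity.  ``split_time`` (if set)
    is a clean two-population split: no cross-population coalescence more
    recent than it.  ``admixture`` is a ``(donor, recipient, time, f)`` pulse
    used by the quartet generator.
    """

    epochs: list[tuple[float, float]]
    mu_per_gen: float = 1e-8
    r_per_gen: float = 1e-8
    split_time: float | None = None
    admixture: tuple[str, str, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        starts = [t for t, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all Ne must be > 0")
        if self.mu_per_gen < 0 or self.r_per_gen < 0:
            raise ValueError("rates must be non-negative")
        if self.admixture is not None:
            _, _, t_adm, f = self.admixture
            if not 0 <= f <= 1:
                raise ValueError("admixture proportion must be in [0, 1]")
            if self.split_time is not None and t_adm >= self.split_time:
                raise ValueError("admixture time must predate split_time")

    @property
    def _starts(self) -> np.ndarray:
        return np.array([t for t, _ in self.epochs], dtype=float)

    @property
    def _nes(self) -> np.ndarray:
        return np.array([ne for _, ne in self.epochs], dtype=float)

    def coalescent_time(self, rng: np.random.Generator,
                        floor: float = 0.0) -> float:
        """One pairwise coalescence time (generations), conditioned on T >= floor.

        Inverse-CDF sampling: survival P(T > t) = exp(−∫_floor^t du / (2N(u))).
        """
        e = rng.exponential(1.0)
        starts, nes = self._starts, self._nes
        t = floor
        for k in range(len(starts)):
            end = starts[k + 1] if k + 1 < len(starts) else math.inf
            lo = max(starts[k], floor)
            if end <= lo:
                continue
            rate = 1.0 / (2.0 * nes[k])
            capacity = (end - lo) * rate
            if e <= capacity:
                return lo + e / rate
            e -= capacity
            t = end
        return t  # unreachable: last epoch has infinite capacity


@dataclass
class TmrcaTrack:
    """Piecewise-constant TMRCA along one contig: ground truth of the HMM."""

    lengths: np.ndarray  # int, bp per segment
    tmrcas: np.ndarray   # float, generations

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.tmrcas = np.asarray(self.tmrcas, dtype=float)
        if self.lengths.shape != self.tmrcas.shape:
            raise ValueError("lengths and tmrcas must align")
        if (self.lengths <= 0).any():
            raise ValueError("segment lengths must be positive")
        if (self.tmrcas <= 0).any():
            raise ValueError("TMRCA must be positive")

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def per_site(self, dtype=np.float32) -> np.ndarray:
        return np.repeat(self.tmrcas.astype(dtype), self.lengths)


def sample_pairwise_tmrca(model: DemographyModel, length: int, seed: int,
                          floor: float = 0.0,
                          _label: str = "tmrca") -> TmrcaTrack:
    """Sample an SMC TMRCA track of ``length`` bp.

    ``floor`` forbids coalescence more recent than that time (used for
    cross-population pairs under a clean split).  Deterministic given seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = rng_for(seed, _label)
    r = model.r_per_gen
    t = model.coalescent_time(rng, floor=floor)
    if r == 0:
        return TmrcaTrack(lengths=np.array([length]), tmrcas=np.array([t]))

    bounds: list[float] = []   # breakpoint positions (continuous)
    tmrcas: list[float] = []
    pos = 0.0
    while True:
        dist = rng.exponential(1.0 / (2.0 * t * r))
        if pos + dist >= length:
            bounds.append(float(length))
            tmrcas.append(t)
            break
        pos += dist
        bounds.append(pos)
        tmrcas.append(t)
        u = rng.uniform(0.0, t)
        t = model.coalescent_time(rng, floor=max(u, floor))

    edges = np.rint(np.asarray(bounds)).astype(np.int64)
    edges[-1] = length
    lengths = np.diff(np.concatenate([[0], edges]))
    keep = lengths > 0
    return TmrcaTrack(lengths=lengths[keep],
                      tmrcas=np.asarray(tmrcas)[keep])


def drop_mutations(track: TmrcaTrack, mu_per_gen: float, seed: int,
                   name: str = "sim", contig: str = "chr1") -> DiploidConsensus:
    """Emit a diploid consensus from a TMRCA track.

    Each site is heterozygous independently with probability
    1 − exp(−2·T·μ) given its segment's TMRCA; heterozygous sites receive a
    uniformly random two-base IUPAC code, homozygous sites a uniform base.
    """
    rng = rng_for(seed, "mutations")
    L = track.total_length
    p = -np.expm1(-2.0 * track.tmrcas * mu_per_gen)
    p_site = np.repeat(p.astype(np.float32), track.lengths)
    het = rng.random(L, dtype=np.float32) < p_site
    arr = _BASE_BYTES[rng.integers(0, 4, size=L)]
    n_het = int(het.sum())
    if n_het:
        arr[het] = _HET_BYTES[rng.integers(0, 6, size=n_het)]
    return DiploidConsensus(name=name, contigs=[(contig, bytes_to_seq(arr))])


def _mutate_codes(codes: np.ndarray, mask: np.ndarray,
                  rng: np.random.Generator) -> None:
    """Substitute masked positions with a uniformly different base (in place)."""
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n,
                                                  dtype=np.uint8)) % 4


def simulate_split_pair(model: DemographyModel, length: int, seed: int,
                        names: tuple[str, str] = ("A", "B"),
                        contig: str = "chr1",
                        ) -> tuple[DiploidConsensus, DiploidConsensus, TmrcaTrack]:
    """Two individuals from populations that split cleanly at ``split_time``.

    Within-individual TMRCA tracks are drawn unconstrained; the cross-population
    haploid pair's track is floored at the split time (no migration).  The four
    haploids are then built from a shared mutation construction — private
    branches below the within-individual TMRCA plus population "trunk" branches
    up to the cross TMRCA — so that a pseudo-diploid assembled downstream from
    one haploid of each output reproduces the cross-track mismatch probability
    1 − exp(−2·μ·T_cross) in expectation.
    """
    tau = model.split_time
    if tau is None:
        raise ValueError("simulate_split_pair requires model.split_time")
    track_a = sample_pairwise_tmrca(model, length, seed, _label="split:withinA")
    track_b = sample_pairwise_tmrca(model, length, seed, _label="split:withinB")
    track_x = sample_pairwise_tmrca(model, length, seed, floor=tau,
                                    _label="split:cross")

    mu = model.mu_per_gen
    L = length
    Tx = track_x.per_site()
    Ta = np.minimum(track_a.per_site(), Tx)   # within cannot postdate cross
    Tb = np.minimum(track_b.per_site(), Tx)

    rng = rng_for(seed, "split:mutations")

    def bern(branch_len: np.ndarray) -> np.ndarray:
        p = -np.expm1(-mu * branch_len.astype(np.float64))
        return rng.random(L) < p

    anc = rng.integers(0, 4, size=L, dtype=np.uint8)
    lineage_a = anc.copy()
    _mutate_codes(lineage_a, bern(Tx - Ta), rng)   # trunk of population A
    lineage_b = anc.copy()
    _mutate_codes(lineage_b, bern(Tx - Tb), rng)   # trunk of population B

    hap = {}
    for key, lineage, T in (("a1", lineage_a, Ta), ("a2", lineage_a, Ta),
                            ("b1", lineage_b, Tb), ("b2", lineage_b, Tb)):
        h = lineage.copy()
        _mutate_codes(h, bern(T), rng)             # private leaf branch
        hap[key] = h

    def consensus(name: str, h1: np.ndarray, h2: np.ndarray) -> DiploidConsensus:
        merged = _COMBINE[BASE_OF_CODE[h1], BASE_OF_CODE[h2]]
        return DiploidConsensus(name=name, contigs=[(contig, bytes_to_seq(merged))])

    return (consensus(names[0], hap["a1"], hap["a2"]),
            consensus(names[1], hap["b1"], hap["b2"]),
            track_x)


# ---------------------------------------------------------------------------
# Four-taxon site-pattern generator

@dataclass
class QuartetModel:
    """Species tree ((H1,H2),H3),O with an optional admixture pulse H3 -> H2.

    Times are in generations before present; a single constant diploid ``ne``
    applies in every population and ancestor.  With probability ``f`` a site's
    H2 lineage is migrant: it joins the H3 population at ``t_admix``
    (which must predate the H1–H2 split).
    """

    ne: float
    t12: float
    t123: float
    t_out: float
    f: float = 0.0
    t_admix: float | None = None

    def __post_init__(self) -> None:
        if self.f and self.t_admix is None:
            raise ValueError("t_admix required when f > 0")
        if self.t_admix is None:
            self.t_admix = 0.5 * self.t12
        if not (0 < self.t_admix < self.t12 < self.t123 < self.t_out):
            raise ValueError("need 0 < t_admix < t12 < t123 < t_out")
        if not 0 <= self.f <= 1:
            raise ValueError("f must be in [0, 1]")
        if self.ne <= 0:
            raise ValueError("ne must be > 0")


_PAIR_MEMBERS = np.array([[0, 1], [1, 2], [0, 2]])   # (H1,H2) (H2,H3) (H1,H3)
_PAIR_OTHER = np.array([2, 0, 1])


def simulate_quartet_sites(model: QuartetModel, n_sites: int,
                           block_length: int, seed: int,
                           topology: str = "((H1,H2),H3),O",
                           names: tuple[str, str, str, str] =
                           ("H1", "H2", "H3", "OUT")) -> QuartetSiteMatrix:
    """Independent four-taxon site patterns with exactly one mutation per site.

    Per site a coalescent genealogy of one haploid per taxon is drawn under the
    species tree (with the admixture pulse), one mutation is placed uniformly
    on the genealogy, and the resulting biallelic pattern is recorded.  Sites
    carry contiguous coordinates grouped into blocks of ``block_length`` for
    jackknifing.  The outgroup lineage is constrained to coalesce after the
    ingroup root (no ingroup–outgroup lineage sorting), a deliberate
    simplification that leaves the H1/H2 exchange symmetry of the null exact.
    """
    if topology.replace(" ", "") not in {"((H1,H2),H3),O", "(((H1,H2),H3),O)"}:
        raise ValueError(f"unsupported topology string {topology!r}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = rng_for(seed, "quartet")
    n = n_sites
    two_n = 2.0 * model.ne

    admixed = rng.random(n) < model.f
    # first ingroup coalescence: the co-resident pair before t123
    start1 = np.where(admixed, model.t_admix, model.t12)
    t1 = start1 + rng.exponential(two_n, size=n)
    pair1 = np.where(admixed, 1, 0).astype(np.int64)   # (H2,H3) if migrant
    late = t1 >= model.t123
    n_late = int(late.sum())
    if n_late:
        # no coalescence before the ingroup root: three exchangeable lineages
        t1[late] = model.t123 + rng.exponential(two_n / 3.0, size=n_late)
        pair1[late] = rng.integers(0, 3, size=n_late)
    # remaining two ingroup lineages are co-resident from max(t1, t123)
    t2 = np.maximum(t1, model.t123) + rng.exponential(two_n, size=n)
    # outgroup joins after the ingroup root
    t3 = np.maximum(t2, model.t_out) + rng.exponential(two_n, size=n)

    # uniform mutation placement over the six branches of the genealogy
    branch_len = np.column_stack([
        t1,            # leaf: first member of pair1
        t1,            # leaf: second member of pair1
        t2,            # leaf: remaining ingroup taxon
        t2 - t1,       # internal branch (ancestor of pair1)
        t3 - t2,       # ingroup-ancestor branch
        t3,            # outgroup leaf branch
    ])
    cum = np.cumsum(branch_len, axis=1)
    r = rng.random(n) * cum[:, -1]
    branch = (cum < r[:, None]).sum(axis=1)

    derived = np.zeros((n, 4), dtype=bool)
    rows = np.arange(n)
    first = _PAIR_MEMBERS[pair1, 0]
    second = _PAIR_MEMBERS[pair1, 1]
    other = _PAIR_OTHER[pair1]
    m = branch == 0
    derived[rows[m], first[m]] = True
    m = branch == 1
    derived[rows[m], second[m]] = True
    m = branch == 2
    derived[rows[m], other[m]] = True
    m = branch == 3
    derived[rows[m], first[m]] = True
    derived[rows[m], second[m]] = True
    m = branch == 4
    derived[m, 0] = derived[m, 1] = derived[m, 2] = True
    m = branch == 5
    derived[m, 3] = True

    anc = rng.integers(0, 4, size=n, dtype=np.uint8)
    der = (anc + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    alleles = np.where(derived, der[:, None], anc[:, None]).astype(np.uint8)

    pos = np.arange(n, dtype=np.int64)
    return QuartetSiteMatrix(
        names=tuple(names),
        contig_names=["sim"],
        contig_index=np.zeros(n, dtype=np.int32),
        pos=pos,
        alleles=alleles,
        block=(pos // block_length).astype(np.int64),
    )


def write_ground_truth(path: str | Path, model: DemographyModel,
                       seed: int) -> None:
    """Record the generating demography next to simulated FASTA outputs."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for i, (t, ne) in enumerate(model.epochs):
            fh.write(f"epoch{i}_start_gen\t{t}\n")
            fh.write(f"epoch{i}_ne\t{ne}\n")
        fh.write(f"mu_per_gen\t{model.mu_per_gen}\n")
        fh.write(f"r_per_gen\t{model.r_per_gen}\n")
        if model.split_time is not None:
            fh.write(f"split_time_gen\t{model.split_time}\n")
        if model.admixture is not None:
            d, rcp, t, f = model.admixture
            fh.write(f"admixture\t{d}>{rcp}@{t}:f={f}\n")
        fh.write(f"seed\t{seed}\n")
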