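"""Config-driven orchestration of the full analysis.

Every run is governed by a :class:`PipelineConfig` (flat key=value text file;
unknown keys are rejected so typos in rate constants cannot pass silently)
and a master seed.  Each stage draws its randomness from a sub-stream derived
from the master seed and a fixed label, and every output table embeds the
config hash and master seed in its header, so two runs with equal config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .formats import (DiploidConsensus, MaskIntervals, write_tsv,
                      write_consensus_fasta)
from .hetstats import HetSummary, apply_mask, heterozygosity
from .pseudodiploid import combine, haploidize
from .psmc import (PSMC, DemographicTrajectory, DivergenceEstimate,
                   PsmcResults, divergence_readoff, make_psmcfa, parse_pattern)

log = logging.getLogger("psmckit.pipeline")


def _digest(consensus: DiploidConsensus) -> str:
    h = hashlib.sha256()
    for cname, seq in consensus.contigs:
        h.update(cname.encode())
        h.update(seq.encode())
    return h.hexdigest()[:12]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the study-standard defaults."""

    mu_per_year: float = 2e-9        # per base per year
    g_years: float = 5.0             # generation time
    bin_size: int = 100              # bp per psmcfa symbol
    pattern: str = "4+25*2+4+6"      # 64 atomic intervals, 28 free parameters
    t_max: float = 15.0              # oldest boundary, units of 2*N0 gens
    n_iter: int = 25                 # EM iterations
    max_missing_fraction: float = 0.9
    c_threshold: float = 10.0        # "nearly infinity" multiple for read-off
    block_length: int = 5_000_000    # jackknife block, bp
    distance_correction: str = "jc"  # 'jc' or 'poisson'
    exclude_contigs: str = ""        # comma-separated (e.g. the Z chromosome)
    seed: int = 0                    # master seed

    def __post_init__(self) -> None:
        if self.mu_per_year <= 0 or self.g_years <= 0:
            raise ValueError("mu_per_year and g_years must be positive")
        if self.bin_size < 1 or self.n_iter < 1 or self.block_length < 1:
            raise ValueError("bin_size, n_iter and block_length must be >= 1")
        if self.t_max <= 0 or self.c_threshold <= 0:
            raise ValueError("t_max and c_threshold must be positive")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        parse_pattern(self.pattern)

    @property
    def mu_per_gen(self) -> float:
        return self.mu_per_year * self.g_years

    @property
    def excluded(self) -> tuple[str, ...]:
        return tuple(x for x in self.exclude_contigs.split(",") if x)

    def config_hash(self) -> str:
        payload = ";".join(f"{f.name}={getattr(self, f.name)}"
                           for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"config_hash={self.config_hash()}", f"seed={self.seed}"]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key "
                                     f"{key!r}")
                current = getattr(cls(), key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


@dataclass
class IndividualResult:
    het: HetSummary
    fit: PsmcResults
    trajectory: DemographicTrajectory


@dataclass
class PairResult:
    pseudo_het: HetSummary
    pseudo_fit: PsmcResults
    pseudo_trajectory: DemographicTrajectory
    divergence: DivergenceEstimate


def _prepare(consensus: DiploidConsensus, cfg: PipelineConfig,
             mask: MaskIntervals | None) -> DiploidConsensus:
    excluded = cfg.excluded
    if excluded:
        kept = [(c, s) for c, s in consensus.contigs if c not in excluded]
        if not kept:
            raise ValueError("contig exclude list removed every contig")
        consensus = DiploidConsensus(name=consensus.name, contigs=kept)
    if mask is not None:
        consensus = apply_mask(consensus, mask)
    return consensus


def run_individual(consensus: DiploidConsensus, cfg: PipelineConfig,
                   mask: MaskIntervals | None = None,
                   out_dir: str | Path | None = None) -> IndividualResult:
    """mask -> heterozygosity -> psmcfa -> EM fit -> scaled trajectory."""
    prepared = _prepare(consensus, cfg, mask)
    log.info("run_individual %s: config=%s input_digest=%s",
             consensus.name, cfg.config_hash(), _digest(prepared))
    het = heterozygosity(prepared)
    pfa = make_psmcfa(prepared, bin_size=cfg.bin_size,
                      max_missing_fraction=cfg.max_missing_fraction)
    fit = PSMC(pfa, pattern=cfg.pattern, t_max=cfg.t_max).fit(n_iter=cfg.n_iter)
    traj = fit.trajectory(cfg.mu_per_year, cfg.g_years)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_het_table([het], out / f"{consensus.name}.het.tsv", cfg)
        write_trajectory(traj, out / f"{consensus.name}.traj.tsv", cfg, fit)
    return IndividualResult(het=het, fit=fit, trajectory=traj)


def run_pair(a: DiploidConsensus, b: DiploidConsensus, cfg: PipelineConfig,
             mask: MaskIntervals | None = None,
             singles: tuple[IndividualResult, IndividualResult] | None = None,
             out_dir: str | Path | None = None) -> PairResult:
    """haploidize both -> combine -> het -> fit -> divergence read-off.

    One haploid draw per individual per run, with the sub-seed derived from
    the master seed and the individual's name, so the same haploid is reused
    for every pair of a run and the draw is exactly replayable.
    """
    if singles is None:
        singles = (run_individual(a, cfg, mask=mask, out_dir=out_dir),
                   run_individual(b, cfg, mask=mask, out_dir=out_dir))
    prep_a = _prepare(a, cfg, mask)
    prep_b = _prepare(b, cfg, mask)
    seed_a = derive_seed(cfg.seed, f"haploid:{a.name}")
    seed_b = derive_seed(cfg.seed, f"haploid:{b.name}")
    log.info("run_pair %s x %s: config=%s sub-seeds haploid:%s=%d "
             "haploid:%s=%d digests %s/%s", a.name, b.name, cfg.config_hash(),
             a.name, seed_a, b.name, seed_b, _digest(prep_a), _digest(prep_b))
    hap_a = haploidize(prep_a, seed_a)
    hap_b = haploidize(prep_b, seed_b)
    pseudo = combine(hap_a, hap_b, name=f"{a.name}x{b.name}")
    het = heterozygosity(pseudo)
    pfa = make_psmcfa(pseudo, bin_size=cfg.bin_size,
                      max_missing_fraction=cfg.max_missing_fraction)
    fit = PSMC(pfa, pattern=cfg.pattern, t_max=cfg.t_max).fit(n_iter=cfg.n_iter)
    traj = fit.trajectory(cfg.mu_per_year, cfg.g_years)
    est = divergence_readoff(
        traj, (singles[0].trajectory, singles[1].trajectory),
        c=cfg.c_threshold)
    est = replace(est, reference=(a.name, b.name))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_consensus_fasta(pseudo, out / f"{pseudo.name}.fa")
        write_het_table([het], out / f"{pseudo.name}.het.tsv", cfg)
        write_trajectory(traj, out / f"{pseudo.name}.traj.tsv", cfg, fit)
    return PairResult(pseudo_het=het, pseudo_fit=fit, pseudo_trajectory=traj,
                      divergence=est)


def run_mask_sensitivity(consensus: DiploidConsensus, cfg: PipelineConfig,
                         masks: list[MaskIntervals | None],
                         labels: list[str] | None = None) -> pd.DataFrame:
    """Re-run the individual analysis under several mask configurations.

    The report has one row per (mask configuration, atomic interval), with
    per-interval Ne, the Ne ratio against the first configuration, and the
    called/heterozygous site deltas.
    """
    if len(masks) < 2:
        raise ValueError("need at least two mask configurations to compare")
    labels = labels or [f"mask{i}" for i in range(len(masks))]
    results = [run_individual(consensus, cfg, mask=m) for m in masks]
    ref = results[0]
    rows = []
    for label, res in zip(labels, results):
        traj = res.trajectory
        for k, (t0, t1, ne) in enumerate(traj.steps()):
            rows.append({
                "config": label,
                "interval": k,
                "time_years_start": t0,
                "time_years_end": t1,
                "ne": ne,
                "ne_ratio_vs_ref": ne / ref.trajectory.ne[k],
                "called_sites": res.het.called_sites,
                "het_sites": res.het.het_sites,
                "called_delta_vs_ref": res.het.called_sites
                - ref.het.called_sites,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# result tables

def write_het_table(summaries: list[HetSummary], path: str | Path,
                    cfg: PipelineConfig | None = None) -> None:
    write_tsv(path,
              ["individual", "called_sites", "het_sites", "heterozygosity"],
              [[s.name, s.called_sites, s.het_sites, f"{s.rounded(9):.9f}"]
               for s in summaries],
              header_lines=cfg.header_lines() if cfg else ())


def write_trajectory(traj: DemographicTrajectory, path: str | Path,
                     cfg: PipelineConfig | None = None,
                     fit: PsmcResults | None = None) -> None:
    """Trajectory TSV plus a raw-model header block (θ, ρ, λ per interval)."""
    header = list(cfg.header_lines()) if cfg else []
    for key in ("mu_per_year", "g_years", "bin_size", "N0"):
        header.append(f"{key}={traj.provenance[key]}")
    if fit is not None:
        header.append(f"theta={fit.theta!r}")
        header.append(f"rho={fit.rho!r}")
        header.append(f"pattern={fit.pattern.spec}")
        header.append("lambda=" + ",".join(repr(float(x))
                                           for x in fit.lambdas))
    write_tsv(path, ["time_years_start", "time_years_end", "ne"],
              [[f"{t0!r}", f"{t1!r}", f"{ne!r}"] for t0, t1, ne in traj.steps()],
              header_lines=header)


def read_trajectory(path: str | Path) -> DemographicTrajectory:
    """Read a trajectory TSV written by :func:`write_trajectory`."""
    provenance: dict = {}
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, value = body.partition("=")
                    if key in ("mu_per_year", "g_years", "N0", "theta", "rho"):
                        provenance[key] = float(value)
                    elif key == "bin_size":
                        provenance[key] = int(value)
                continue
            if line.startswith("time_years_start"):
                continue
            t0, t1, ne = line.split("\t")
            rows.append((float(t0), float(t1), float(ne)))
    edges = np.array([r[0] for r in rows] + [rows[-1][1]])
    return DemographicTrajectory(edges_years=edges,
                                 ne=np.array([r[2] for r in rows]),
                                 provenance=provenance)
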