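"""ABBA-BABA D-statistics with block-jackknife standard errors.

For a quartet (H1, H2, H3, outgroup) with one sampled allele per taxon per
site, let A be the outgroup allele and B the single alternative allele.  Then

    ABBA: H1 = A, H2 = B, H3 = B        BABA: H1 = B, H2 = A, H3 = B
    D = (nABBA − nBABA) / (nABBA + nBABA)

Under the assumed species tree ((H1,H2),H3) with no gene flow, incomplete
lineage sorting produces ABBA and BABA in equal expectation, so E[D] = 0; an
excess of ABBA (D > 0) indicates H2–H3 allele sharing beyond the tree.
Significance comes from a delete-one block jackknife over contiguous genomic
blocks, which is robust to linkage; |Z| > 3 is the conventional threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._rng import rng_for
from .formats import DiploidConsensus, HET_ALLELES, CODE_OF_BASE, seq_to_bytes


@dataclass
class QuartetSiteMatrix:
    """One sampled allele per taxon per retained site, with block labels.

    ``alleles`` is an (n_sites, 4) array of base codes (A=0 C=1 G=2 T=3) in
    order (H1, H2, H3, outgroup).  Sites where any individual was missing or
    the outgroup heterozygous never enter; retained sites have at most two
    distinct alleles.
    """

    names: tuple[str, str, str, str]
    contig_names: list[str]
    contig_index: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray
    block: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pos)
        if self.alleles.shape != (n, 4):
            raise ValueError("alleles must be (n_sites, 4)")
        if len(self.contig_index) != n or len(self.block) != n:
            raise ValueError("per-site arrays must align")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def swap_h1_h2(self) -> "QuartetSiteMatrix":
        """Relabel H1 <-> H2 (negates D exactly)."""
        return QuartetSiteMatrix(
            names=(self.names[1], self.names[0], self.names[2], self.names[3]),
            contig_names=self.contig_names,
            contig_index=self.contig_index,
            pos=self.pos,
            alleles=self.alleles[:, [1, 0, 2, 3]],
            block=self.block,
        )


@dataclass(frozen=True)
class DStatResult:
    """ABBA/BABA counts, D, block-jackknife SE and Z for one quartet."""

    names: tuple[str, str, str, str]
    n_abba: int
    n_baba: int
    d: float
    se: float
    z: float
    n_blocks: int
    block_length: int | None = None


# ---------------------------------------------------------------------------

_HET_SET = set(HET_ALLELES)


def sample_quartet(consensuses: list[DiploidConsensus], seed: int,
                   block_length: int = 5_000_000) -> QuartetSiteMatrix:
    """Sample one allele per taxon per site from four co-aligned consensuses.

    Sites with any missing call, a heterozygous outgroup call, or more than
    two distinct alleles after sampling are dropped.  At heterozygous sites of
    H1–H3 one of the two alleles is chosen uniformly (seeded).  Blocks are
    assigned by physical coordinate within each contig.
    """
    if len(consensuses) != 4:
        raise ValueError("exactly four consensuses required (H1, H2, H3, outgroup)")
    ref = consensuses[0]
    for other in consensuses[1:]:
        if other.contig_names != ref.contig_names or other.lengths != ref.lengths:
            raise ValueError(
                f"contig mismatch between {ref.name!r} and {other.name!r}")

    rng = rng_for(seed, "sample_quartet")

    # ASCII -> (allele0 code, allele1 code); hom sites repeat their base,
    # missing maps to sentinel 255
    a0 = np.full(256, 255, dtype=np.uint8)
    a1 = np.full(256, 255, dtype=np.uint8)
    for b in "ACGT":
        a0[ord(b)] = a1[ord(b)] = CODE_OF_BASE[ord(b)]
    for code, (x, y) in HET_ALLELES.items():
        a0[ord(code)] = CODE_OF_BASE[ord(x)]
        a1[ord(code)] = CODE_OF_BASE[ord(y)]

    all_contig_idx, all_pos, all_alleles, all_block = [], [], [], []
    block_offset = 0
    for ci, (cname, _) in enumerate(ref.contigs):
        seqs = [seq_to_bytes(c.sequence(cname)) for c in consensuses]
        L = len(seqs[0])
        lo = np.stack([a0[s] for s in seqs])        # (4, L)
        hi = np.stack([a1[s] for s in seqs])
        called = (lo != 255).all(axis=0)
        out_hom = lo[3] == hi[3]                    # outgroup must be homozygous
        keep = called & out_hom
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            block_offset += -(-L // block_length)
            continue
        pick = rng.integers(0, 2, size=(3, idx.size), dtype=np.uint8)
        alleles = np.empty((idx.size, 4), dtype=np.uint8)
        for t in range(3):
            alleles[:, t] = np.where(pick[t] == 0, lo[t, idx], hi[t, idx])
        alleles[:, 3] = lo[3, idx]
        # drop sites with more than two distinct alleles
        counts = np.zeros((idx.size, 4), dtype=np.uint8)
        for t in range(4):
            counts[np.arange(idx.size), alleles[:, t]] = 1
        biallelic = counts.sum(axis=1) <= 2
        idx = idx[biallelic]
        alleles = alleles[biallelic]
        all_contig_idx.append(np.full(idx.size, ci, dtype=np.int32))
        all_pos.append(idx.astype(np.int64))
        all_alleles.append(alleles)
        all_block.append(idx // block_length + block_offset)
        block_offset += -(-L // block_length)

    return QuartetSiteMatrix(
        names=tuple(c.name for c in consensuses),
        contig_names=ref.contig_names,
        contig_index=np.concatenate(all_contig_idx) if all_contig_idx
        else np.empty(0, dtype=np.int32),
        pos=np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64),
        alleles=np.concatenate(all_alleles) if all_alleles
        else np.empty((0, 4), dtype=np.uint8),
        block=np.concatenate(all_block) if all_block
        else np.empty(0, dtype=np.int64),
    )


def _pattern_masks(q: QuartetSiteMatrix) -> tuple[np.ndarray, np.ndarray]:
    al = q.alleles
    distinct = np.zeros((q.n_sites, 4), dtype=np.uint8)
    for t in range(4):
        distinct[np.arange(q.n_sites), al[:, t]] = 1
    if (distinct.sum(axis=1) > 2).any():
        bad = int(np.argmax(distinct.sum(axis=1) > 2))
        raise ValueError(
            f"tri-allelic pattern at site index {bad}: patterns must be "
            "filtered to biallelic before counting")
    h1, h2, h3, out = al[:, 0], al[:, 1], al[:, 2], al[:, 3]
    abba = (h1 == out) & (h2 == h3) & (h2 != out)
    baba = (h2 == out) & (h1 == h3) & (h1 != out)
    return abba, baba


def count_patterns(q: QuartetSiteMatrix) -> tuple[int, int]:
    """Count ABBA and BABA sites; all other patterns are ignored."""
    abba, baba = _pattern_masks(q)
    return int(abba.sum()), int(baba.sum())


def d_statistic(n_abba: int, n_baba: int) -> float:
    """D = (nABBA − nBABA)/(nABBA + nBABA), exact quotient."""
    total = n_abba + n_baba
    if total == 0:
        raise ZeroDivisionError("D undefined: no ABBA or BABA sites")
    return (n_abba - n_baba) / total


def block_jackknife(q: QuartetSiteMatrix,
                    block_length: int | None = None) -> DStatResult:
    """Delete-one-block jackknife over contiguous blocks.

    SE² = ((m−1)/m) · Σ_j (D₍₋ⱼ₎ − D̄)² with D̄ the mean of the leave-one-out
    estimates; blocks with zero informative sites are skipped (m reduced).
    If all leave-one-out estimates coincide, SE = 0 and Z is flagged infinite.
    """
    abba, baba = _pattern_masks(q)
    blocks = q.block
    nb = int(blocks.max()) + 1 if len(blocks) else 0
    a_j = np.bincount(blocks[abba], minlength=nb).astype(np.int64)
    b_j = np.bincount(blocks[baba], minlength=nb).astype(np.int64)
    informative = (a_j + b_j) > 0
    a_j, b_j = a_j[informative], b_j[informative]
    m = len(a_j)
    if m < 2:
        raise ValueError(f"block jackknife needs >= 2 informative blocks, got {m}")
    n_abba, n_baba = int(a_j.sum()), int(b_j.sum())
    d = d_statistic(n_abba, n_baba)
    d_loo = ((n_abba - a_j) - (n_baba - b_j)) / ((n_abba - a_j) + (n_baba - b_j))
    d_bar = d_loo.mean()
    se = math.sqrt((m - 1) / m * float(((d_loo - d_bar) ** 2).sum()))
    z = d / se if se > 0 else math.copysign(math.inf, d) if d != 0 else math.nan
    return DStatResult(names=q.names, n_abba=n_abba, n_baba=n_baba,
                       d=d, se=se, z=z, n_blocks=m, block_length=block_length)


def dstat_rotations(q: QuartetSiteMatrix) -> list[DStatResult]:
    """Run the test under all three rotations of (H1, H2, H3).

    Convenience for exploring which arrangement carries the admixture signal
    when no tree is assumed.
    """
    results = []
    for order in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        rotated = QuartetSiteMatrix(
            names=(q.names[order[0]], q.names[order[1]], q.names[order[2]],
                   q.names[3]),
            contig_names=q.contig_names,
            contig_index=q.contig_index,
            pos=q.pos,
            alleles=q.alleles[:, [order[0], order[1], order[2], 3]],
            block=q.block,
        )
        results.append(block_jackknife(rotated))
    return results
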