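"""Haploidisation and in-silico pseudo-diploid construction.

A pseudo-diploid is a diploid sequence assembled from one haploid of each of
two individuals.  Because the two haploids cannot share ancestry more recently
than the populations' divergence, the pseudo-diploid's heterozygosity is an
inter-individual genetic distance, and its inferred demographic trajectory
explodes at (roughly) the divergence time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import rng_for
from .formats import (DiploidConsensus, FormatError, HET_ALLELES, MISSING,
                      seq_to_bytes, bytes_to_seq)


@dataclass
class HaploidSequence:
    """One randomly resolved haploid of an individual.

    At each heterozygous site one of the two IUPAC-encoded alleles was chosen
    with probability 1/2; ``provenance`` records the source individual and the
    seed so the draw is exactly replayable.
    """

    name: str
    contigs: list[tuple[str, str]]
    provenance: tuple[str, int]

    def __post_init__(self) -> None:
        for cname, seq in self.contigs:
            bad = seq.encode().translate(None, delete=b"ACGTN")
            if bad:
                raise FormatError(
                    f"haploid contig {cname!r} contains non-haploid symbol "
                    f"{chr(bad[0])!r}")


# per-het-code allele pairs as ASCII codes
_HET_PAIR = {ord(k): (ord(v[0]), ord(v[1])) for k, v in HET_ALLELES.items()}


def haploidize(c: DiploidConsensus, seed: int) -> HaploidSequence:
    """Randomly resolve each heterozygous site to one of its two alleles.

    Homozygous sites copy their base, missing sites stay missing; choices are
    independent Bernoulli(1/2) draws, deterministic given ``seed``.
    """
    rng = rng_for(seed, f"haploidize:{c.name}")
    contigs: list[tuple[str, str]] = []
    for cname, seq in c.contigs:
        arr = seq_to_bytes(seq).copy()
        for code, (a0, a1) in _HET_PAIR.items():
            idx = np.flatnonzero(arr == code)
            if idx.size:
                pick = rng.integers(0, 2, size=idx.size)
                arr[idx] = np.where(pick == 0, a0, a1).astype(np.uint8)
        contigs.append((cname, bytes_to_seq(arr)))
    return HaploidSequence(name=f"{c.name}#hap", contigs=contigs,
                           provenance=(c.name, seed))


# 256x256 combination table: equal bases -> base, differing -> IUPAC het,
# any N -> N
_COMBINE = np.full((256, 256), ord(MISSING), dtype=np.uint8)
for _a in "ACGT":
    for _b in "ACGT":
        if _a == _b:
            _COMBINE[ord(_a), ord(_b)] = ord(_a)
        else:
            from .formats import IUPAC_OF_PAIR
            _COMBINE[ord(_a), ord(_b)] = ord(IUPAC_OF_PAIR[frozenset((_a, _b))])


def combine(a: HaploidSequence, b: HaploidSequence,
            name: str | None = None) -> DiploidConsensus:
    """Merge two haploids into a pseudo-diploid consensus.

    A site is called iff both inputs are called; equal bases give a homozygous
    call, differing bases the corresponding IUPAC heterozygote.
    """
    names_a = [c for c, _ in a.contigs]
    names_b = [c for c, _ in b.contigs]
    if names_a != names_b or [len(s) for _, s in a.contigs] != \
            [len(s) for _, s in b.contigs]:
        mism = sorted(set(names_a).symmetric_difference(names_b)) or \
            [c for (c, sa), (_, sb) in zip(a.contigs, b.contigs)
             if len(sa) != len(sb)]
        raise ValueError(f"contig mismatch between {a.name!r} and {b.name!r}: "
                         f"{mism}")
    contigs = []
    for (cname, sa), (_, sb) in zip(a.contigs, b.contigs):
        merged = _COMBINE[seq_to_bytes(sa), seq_to_bytes(sb)]
        contigs.append((cname, bytes_to_seq(merged)))
    label = name or f"{a.provenance[0]}x{b.provenance[0]}"
    return DiploidConsensus(name=label, contigs=contigs)


def pseudo_diploid(x: DiploidConsensus, y: DiploidConsensus,
                   seed_x: int, seed_y: int) -> DiploidConsensus:
    """Convenience: haploidize both individuals and combine."""
    return combine(haploidize(x, seed_x), haploidize(y, seed_y))
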