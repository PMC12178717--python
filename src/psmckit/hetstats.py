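"""Site classification, repeat-mask application and genome-wide heterozygosity.

Heterozygosity here is the plain per-site quantity: the number of heterozygous
calls divided by the number of called (non-missing) sites.  For a pseudo-diploid
built from two haploids it equals the per-site mismatch fraction of the two
haploids over co-called sites, i.e. an uncorrected Jukes–Cantor distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .formats import (DiploidConsensus, MaskIntervals, MISSING, HOM_BASES,
                      HET_CODES, seq_to_bytes, bytes_to_seq)


class SiteClass(Enum):
    HOM = 0
    HET = 1
    MISSING = 2


# ASCII -> site class code (0 hom, 1 het, 2 missing, 255 invalid)
_CLASS_OF = np.full(256, 255, dtype=np.uint8)
for _b in HOM_BASES:
    _CLASS_OF[ord(_b)] = 0
for _b in HET_CODES:
    _CLASS_OF[ord(_b)] = 1
_CLASS_OF[ord(MISSING)] = 2


def classify_site(call: str) -> SiteClass:
    """Classify one normalized call as HOM, HET or MISSING."""
    if len(call) != 1:
        raise ValueError(f"expected a single call, got {call!r}")
    cls = _CLASS_OF[ord(call)]
    if cls == 255:
        raise ValueError(f"unnormalized call {call!r}")
    return SiteClass(cls)


def site_classes(seq: str) -> np.ndarray:
    """Vectorised site classification: uint8 array of 0/1/2 per site."""
    out = _CLASS_OF[seq_to_bytes(seq)]
    if (out == 255).any():
        pos = int(np.argmax(out == 255))
        raise ValueError(f"unnormalized call {seq[pos]!r} at position {pos + 1}")
    return out


@dataclass(frozen=True)
class HetSummary:
    """Called-site and heterozygous-site counts for one (pseudo-)individual."""

    name: str
    called_sites: int
    het_sites: int

    def __post_init__(self) -> None:
        if not 0 <= self.het_sites <= self.called_sites:
            raise ValueError(
                f"het_sites ({self.het_sites}) must lie in [0, called_sites="
                f"{self.called_sites}]")

    @property
    def heterozygosity(self) -> float:
        if self.called_sites == 0:
            raise ZeroDivisionError(
                f"{self.name}: heterozygosity undefined with 0 called sites")
        return self.het_sites / self.called_sites

    def rounded(self, ndigits: int = 9) -> float:
        """Heterozygosity rounded half-even, the precision used for reporting."""
        return round(self.heterozygosity, ndigits)


def apply_mask(c: DiploidConsensus, m: MaskIntervals) -> DiploidConsensus:
    """Set calls inside mask intervals to MISSING; the input is not modified."""
    lengths = c.lengths
    for contig in m.intervals:
        if contig not in lengths:
            raise ValueError(f"mask contig {contig!r} absent from consensus "
                             f"{c.name!r}")
    new_contigs: list[tuple[str, str]] = []
    for cname, seq in c.contigs:
        ivs = m.intervals.get(cname, [])
        if not ivs:
            new_contigs.append((cname, seq))
            continue
        arr = seq_to_bytes(seq).copy()
        n = len(arr)
        for s, e in ivs:
            if e > n:
                raise ValueError(
                    f"mask interval [{s}, {e}) exceeds contig {cname!r} "
                    f"length {n}")
            arr[s:e] = ord(MISSING)
        new_contigs.append((cname, bytes_to_seq(arr)))
    return DiploidConsensus(name=c.name, contigs=new_contigs)


def heterozygosity(c: DiploidConsensus,
                   exclude_contigs: tuple[str, ...] = ()) -> HetSummary:
    """Genome-wide heterozygosity of a diploid consensus.

    ``exclude_contigs`` drops contigs (e.g. a sex chromosome) before counting.
    """
    called = 0
    het = 0
    for cname, seq in c.contigs:
        if cname in exclude_contigs:
            continue
        cls = site_classes(seq)
        counts = np.bincount(cls, minlength=3)
        called += int(counts[0] + counts[1])
        het += int(counts[1])
    return HetSummary(name=c.name, called_sites=called, het_sites=het)
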