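"""Readers and writers for the external representations the pipeline touches.

The universal substrate is a *diploid consensus* genome: one call per site,
where a homozygous site is written as its base (A/C/G/T), a heterozygous site
as the two-base IUPAC ambiguity code (R/Y/S/W/K/M), and anything uncallable as
'N'.  Consensus callers (e.g. ``bcftools mpileup | vcfutils vcf2fq``) emit
exactly this alphabet, so a FASTA of such calls is the interchange format.

Normalisation contract for :func:`read_consensus_fasta`:

========================  ==============
input symbol              normalised to
========================  ==============
A C G T (uppercase)       itself (HOM)
R Y S W K M (uppercase)   itself (HET)
a c g t r y s w k m       N  (soft-masked bases are treated as missing)
n N B D H V, any other    N
========================  ==============

Three- and four-base ambiguity codes (B/D/H/V) indicate low-confidence calls —
a diploid carries at most two alleles — and are therefore dropped to missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

MISSING = "N"
HOM_BASES = "ACGT"
HET_CODES = "RYSWKM"
ALPHABET = HOM_BASES + HET_CODES + MISSING  # the 11-symbol consensus alphabet

#: two-base expansion of each heterozygous IUPAC code
HET_ALLELES: Mapping[str, tuple[str, str]] = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

#: unordered base pair -> heterozygous IUPAC code
IUPAC_OF_PAIR: Mapping[frozenset, str] = {
    frozenset(v): k for k, v in HET_ALLELES.items()
}

_NORMALIZE = bytearray([ord(MISSING)]) * 256
for _c in ALPHABET:
    _NORMALIZE[ord(_c)] = ord(_c)
_NORMALIZE = bytes(_NORMALIZE)

_ALPHABET_BYTES = ALPHABET.encode()


class FormatError(ValueError):
    """Malformed external input; the message locates the offending record."""


def normalize_calls(seq: str) -> str:
    """Map an arbitrary sequence string onto the 11-symbol consensus alphabet."""
    return seq.encode("ascii", errors="replace").translate(_NORMALIZE).decode()


def _check_alphabet(seq: str, alphabet: bytes, where: str) -> None:
    leftover = seq.encode().translate(None, delete=alphabet)
    if leftover:
        bad = chr(leftover[0])
        pos = seq.index(bad)
        raise FormatError(f"{where}: symbol {bad!r} at position {pos + 1} "
                          f"not in alphabet {alphabet.decode()!r}")


@dataclass
class DiploidConsensus:
    """Per-site IUPAC consensus calls for one individual.

    ``contigs`` is an ordered list of ``(name, calls)`` where every call is in
    the 11-symbol alphabet (A/C/G/T hom, R/Y/S/W/K/M het, N missing).
    """

    name: str
    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for cname, seq in self.contigs:
            if cname in seen:
                raise FormatError(f"duplicate contig name {cname!r} in {self.name!r}")
            seen.add(cname)
            if len(seq) == 0:
                raise FormatError(f"contig {cname!r} in {self.name!r} is empty")
            _check_alphabet(seq, _ALPHABET_BYTES, f"contig {cname!r}")

    @property
    def contig_names(self) -> list[str]:
        return [c for c, _ in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs}

    def sequence(self, contig: str) -> str:
        for c, s in self.contigs:
            if c == contig:
                return s
        raise KeyError(contig)

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class MaskIntervals:
    """Per-contig 0-based half-open intervals, sorted and non-overlapping."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {c: merge_intervals(iv) for c, iv in self.intervals.items()}

    def total_masked(self) -> int:
        return sum(e - s for iv in self.intervals.values() for s, e in iv)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class PsmcFasta:
    """Binned genome representation over {K, T, N}.

    One symbol per window of ``bin_size`` bases: 'K' if the window contains a
    heterozygous call, 'T' if it is callable but entirely homozygous, 'N' if
    too much of it is missing.
    """

    contigs: list[tuple[str, str]]
    bin_size: int = 100

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise FormatError("bin_size must be >= 1")
        for cname, seq in self.contigs:
            _check_alphabet(seq, b"KTN", f"psmcfa contig {cname!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PsmcFasta):
            return NotImplemented
        return self.bin_size == other.bin_size and self.contigs == other.contigs


# ---------------------------------------------------------------------------
# FASTA

def read_consensus_fasta(path: str | Path, name: str | None = None) -> DiploidConsensus:
    """Read and normalise an IUPAC consensus FASTA into a DiploidConsensus."""
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        seen.add(rec.id)
        contigs.append((rec.id, normalize_calls(str(rec.seq))))
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return DiploidConsensus(name=name or path.stem, contigs=contigs)


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def write_consensus_fasta(c: DiploidConsensus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cname, seq in c.contigs:
            fh.write(f">{cname}\n{_wrap(seq)}\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> MaskIntervals:
    """Read a 3+ column BED (0-based, half-open) into merged mask intervals."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            contig = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.setdefault(contig, []).append((start, end))
    return MaskIntervals(intervals=intervals)


def write_bed(m: MaskIntervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, ivs in m.intervals.items():
            for s, e in ivs:
                fh.write(f"{contig}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# psmcfa

def write_psmcfa(p: PsmcFasta, path: str | Path) -> None:
    """Write the K/T/N binned genome, 60 symbols per line.

    The bin size is recorded on each header line (``>name s=<bin_size>``) so
    the representation round-trips without external bookkeeping.
    """
    with open(path, "w") as fh:
        for cname, seq in p.contigs:
            fh.write(f">{cname} s={p.bin_size}\n{_wrap(seq)}\n")


_PSMCFA_HEADER = re.compile(r"^>(\S+)(?:\s+s=(\d+))?")


def read_psmcfa(path: str | Path, bin_size: int | None = None) -> PsmcFasta:
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    header_bin: int | None = None
    name: str | None = None
    chunks: list[str] = []
    offset = 0

    def flush() -> None:
        nonlocal chunks, name
        if name is not None:
            contigs.append((name, "".join(chunks)))
        chunks = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                m = _PSMCFA_HEADER.match(line)
                name = m.group(1)
                if m.group(2) is not None:
                    header_bin = int(m.group(2))
                offset = 0
                continue
            bad = line.encode().translate(None, delete=b"KTN")
            if bad:
                col = line.index(chr(bad[0]))
                raise FormatError(
                    f"{path}:{lineno}: symbol {chr(bad[0])!r} at contig position "
                    f"{offset + col + 1} not in psmcfa alphabet 'KTN'")
            chunks.append(line)
            offset += len(line)
    flush()
    if not contigs:
        raise FormatError(f"{path}: no psmcfa records found")
    size = bin_size if bin_size is not None else (header_bin or 100)
    return PsmcFasta(contigs=contigs, bin_size=size)


# ---------------------------------------------------------------------------
# Newick

_PLAIN_LABEL = re.compile(r"^[^\s()\[\]{}:;,\"']+$")


def quote_label(label: str) -> str:
    """Quote a Newick label if it contains whitespace or syntax characters."""
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def format_length(x: float) -> str:
    """Branch length at full (round-trip) precision."""
    return repr(float(x))


def write_newick(tree, path: str | Path) -> None:
    """Serialize an unrooted tree (from :mod:`psmckit.distances`) as Newick.

    The tree is emitted rooted at its trifurcating internal node, the usual
    convention for unrooted Newick.
    """
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# TSV result tables

def write_tsv(path: str | Path, columns: Sequence[str],
              rows: Iterable[Sequence], header_lines: Sequence[str] = ()) -> None:
    """Write a result table as TSV with optional '#'-prefixed header lines."""
    rows = list(rows)
    for r in rows:
        if len(r) != len(columns):
            raise ValueError("column count differs between header and row")
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


# ---------------------------------------------------------------------------
# numeric helpers shared across modules

#: ASCII -> base code (A=0 C=1 G=2 T=3, N=4, anything else 255)
CODE_OF_BASE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    CODE_OF_BASE[ord(_b)] = _i
CODE_OF_BASE[ord(MISSING)] = 4

BASE_OF_CODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def seq_to_bytes(seq: str) -> np.ndarray:
    """View a call string as a uint8 array of ASCII codes (no copy of content)."""
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def bytes_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()
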