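"""Sequence and annotation I/O plus assembly summary statistics.

Scaffold sets are held as lists of :class:`SequenceRecord` (uppercased,
alphabet ``{A,C,G,T,N}``); gene annotation as 1-based inclusive
:class:`GeneInterval` lists.  Coordinates are 1-based inclusive everywhere
in this package; BED input is converted on ingest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COERCE = {c: (c if c in VALID_BASES else "N") for c in
           "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
_COERCE_TABLE = str.maketrans({c.lower(): v for c, v in _COERCE.items()} |
                              _COERCE)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One scaffold: identifier plus uppercase residues."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AssemblySummary:
    n_sequences: int
    total_length: int
    n50: int
    longest: int
    mean_length: float
    gc_fraction: float
    n_ge_2kb: int
    n_ge_10kb: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        d = self.to_dict()
        return ("\t".join(d) + "\n" +
                "\t".join(str(v) for v in d.values()) + "\n")


@dataclass(frozen=True)
class GeneInterval:
    """A gene feature span, 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    feature: str = "gene"

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}")


class FastaError(ValueError):
    """Malformed FASTA input."""


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Residues are uppercased; IUPAC ambiguity codes and any other letters
    outside ``{A,C,G,T,N}`` are coerced to ``N`` with a logged warning.
    Empty files, duplicate ids and malformed headers are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaError(f"{path}: record with empty header (>{rec.description!r})")
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        residues = raw.translate(_COERCE_TABLE)
        bad = sum(1 for a, b in zip(raw.upper(), residues) if a != b)
        if bad:
            logger.warning("%s: %d non-ACGTN residues coerced to N in %s",
                           path, bad, rec.id)
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = rec.residues
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def filter_min_length(records: Sequence[SequenceRecord],
                      min_len: int = 200) -> list[SequenceRecord]:
    """Retain scaffolds of at least ``min_len`` bp (order preserved)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if r.length >= min_len]


def n50(lengths: Sequence[int]) -> int:
    """N50: largest L such that sequences of length >= L cover >= half
    the total assembly length."""
    if not lengths:
        raise ValueError("n50 of an empty length set")
    half = sum(lengths) / 2
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def assembly_summary(records: Sequence[SequenceRecord]) -> AssemblySummary:
    """Scaffold-set summary: counts, N50, mean/longest length and GC.

    GC fraction excludes N from the denominator.
    """
    if not records:
        raise ValueError("assembly_summary of an empty record set")
    lengths = [r.length for r in records]
    gc = at = 0
    for r in records:
        gc += r.residues.count("G") + r.residues.count("C")
        at += r.residues.count("A") + r.residues.count("T")
    return AssemblySummary(
        n_sequences=len(records),
        total_length=sum(lengths),
        n50=n50(lengths),
        longest=max(lengths),
        mean_length=sum(lengths) / len(lengths),
        gc_fraction=(gc / (gc + at)) if (gc + at) else math.nan,
        n_ge_2kb=sum(1 for L in lengths if L >= 2000),
        n_ge_10kb=sum(1 for L in lengths if L >= 10_000),
    )


def read_intervals(path: str | Path, format: str | None = None
                   ) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open, converted to
    1-based inclusive) or GFF3 (used as-is, 1-based inclusive)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"bed": "bed", "gff": "gff3", "gff3": "gff3"}.get(
            suffix.lstrip("."), None)
        if format is None:
            raise ValueError(f"cannot infer interval format from {path.name!r}")
    format = format.lower()
    if format not in ("bed", "gff3"):
        raise ValueError(f"unrecognised interval format {format!r}")
    out: list[GeneInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            try:
                if format == "bed":
                    seq_id, start0, end0 = cols[0], int(cols[1]), int(cols[2])
                    start, end = start0 + 1, end0
                    feature = cols[3] if len(cols) > 3 else "region"
                else:
                    seq_id = cols[0]
                    feature = cols[2]
                    start, end = int(cols[3]), int(cols[4])
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed {format} line: {line!r}"
                ) from exc
            if end < start or start < 1:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"{seq_id}:{start}-{end}")
            out.append(GeneInterval(seq_id=seq_id, start=start, end=end,
                                    feature=feature))
    return out
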