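"""Core domain types and small primitives shared across the pipeline.

All internal coordinates are 0-based half-open on the forward strand of the
named sequence; converters to/from 1-based formats live at the I/O boundary
only (see :mod:`asmcurate.seqio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .errors import ValidationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Python's built-in ``round`` is banker's rounding; printed tables in
    genome reports use conventional half-up rounding, so percentages like
    44.885 must become 44.89, not 44.88.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def div_round_half_up(num: int, den: int) -> int:
    """Integer division rounded half-up, exact (no float)."""
    if den <= 0:
        raise ValidationError(f"denominator must be positive, got {den}")
    return int((Decimal(num) / Decimal(den)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass
class SeqRecord:
    """A named DNA sequence with optional Phred qualities.

    The sequence is uppercased on construction. Bases outside {A,C,G,T}
    are tolerated and treated like N by windowed operations (k-mers, SSRs).
    """

    id: str
    sequence: str
    quality: Optional[Sequence[int]] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r} has empty sequence")
        if self.quality is not None:
            self.quality = list(self.quality)
            if len(self.quality) != len(self.sequence):
                raise ValidationError(
                    f"record {self.id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on one sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"bad interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) half-open spans."""
    spans = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_union_length(intervals: Sequence[Interval]) -> int:
    """Total length of the set-theoretic union of intervals on one sequence.

    Input order is irrelevant; duplicates do not change the result. Abutting
    half-open intervals ([0,10) and [10,20)) merge into a single 20-bp span.
    """
    if not intervals:
        return 0
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) > 1:
        raise ValidationError(f"intervals span multiple sequences: {sorted(seq_ids)}")
    return sum(e - s for s, e in merge_intervals((iv.start, iv.end) for iv in intervals))


ALIGNMENT_SOURCES = ("internal", "paf", "coords", "blast6")


@dataclass
class AlignmentBlock:
    """One local match between two sequences.

    Coordinates are 0-based half-open on the forward strand of each
    sequence; ``strand`` is the orientation of the query relative to the
    target. For ``source == "internal"`` blocks (exact anchor runs) the
    identity invariant ``identity == matched_bases / max(spans)`` holds by
    construction.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matched_bases: int
    identity: float
    score: float
    evalue: Optional[float] = None
    source: str = "internal"

    def __post_init__(self):
        if self.q_end <= self.q_start or self.t_end <= self.t_start:
            raise ValidationError(
                f"degenerate block {self.query_id}/{self.target_id}: "
                f"q[{self.q_start},{self.q_end}) t[{self.t_start},{self.t_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.matched_bases < 0:
            raise ValidationError("matched_bases must be >= 0")
        if self.matched_bases > min(self.q_span, self.t_span):
            raise ValidationError(
                f"matched_bases {self.matched_bases} exceeds min span "
                f"{min(self.q_span, self.t_span)}"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity {self.identity} outside [0,1]")
        if self.source not in ALIGNMENT_SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start

    def swapped(self) -> "AlignmentBlock":
        """The same match with query and target roles exchanged."""
        return AlignmentBlock(
            query_id=self.target_id,
            target_id=self.query_id,
            q_start=self.t_start,
            q_end=self.t_end,
            t_start=self.q_start,
            t_end=self.q_end,
            strand=self.strand,
            matched_bases=self.matched_bases,
            identity=self.identity,
            score=self.score,
            evalue=self.evalue,
            source=self.source,
        )


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T (N and other ambiguity codes excluded)."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    total = gc + at
    return gc / total if total else 0.0
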