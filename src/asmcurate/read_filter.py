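"""Short-read cleaning: the five-rule Illumina filter.

Rules, applied per read in this order: (adapter) discard reads containing
an adapter as an exact substring; (trim) cut a fixed 2 bp at the 5' end and
3 bp at the 3' end; (n_fraction) discard if N bases exceed 10% of the
trimmed read; (duplicate) discard PCR duplicates, defined on the pair's
sequences only; (low_quality) discard if more than 50% of trimmed bases
have Phred quality <= 5. Fractions use strict inequality ("more than") and
are evaluated on the post-trim sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import SeqRecord
from .errors import ValidationError

RULES = ("adapter", "too_short", "n_fraction", "low_quality", "duplicate")


@dataclass
class ReadPair:
    r1: SeqRecord
    r2: Optional[SeqRecord] = None


@dataclass
class FilterReport:
    """Bookkeeping for one cleaning run; counts are in read pairs."""

    input_reads: int = 0
    kept_reads: int = 0
    discarded_by_rule: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in RULES}
    )
    bases_trimmed: int = 0

    def check(self) -> None:
        if self.input_reads != self.kept_reads + sum(self.discarded_by_rule.values()):
            raise ValidationError("filter report does not conserve read count")


def clean_read(
    read: SeqRecord,
    adapters: Sequence[str] = (),
    n_fraction_max: float = 0.10,
    lowq_phred_max: int = 5,
    lowq_fraction_max: float = 0.50,
    trim5: int = 2,
    trim3: int = 3,
) -> tuple[Optional[SeqRecord], Optional[str]]:
    """Clean one read; returns (cleaned record, None) or (None, rule name)."""
    if read.quality is None:
        raise ValidationError(f"read {read.id!r} has no quality scores")
    seq = read.sequence
    for adapter in adapters:
        if adapter.upper() in seq:
            return None, "adapter"
    if len(seq) < trim5 + trim3 + 1:
        return None, "too_short"
    end = len(seq) - trim3 if trim3 else len(seq)
    seq = seq[trim5:end]
    qual = list(read.quality[trim5:end])
    n = len(seq)
    if seq.count("N") / n > n_fraction_max:
        return None, "n_fraction"
    if sum(1 for q in qual if q <= lowq_phred_max) / n > lowq_fraction_max:
        return None, "low_quality"
    return SeqRecord(read.id, seq, qual), None


def remove_duplicates(pairs: Sequence[ReadPair]) -> tuple[list[ReadPair], int]:
    """Drop PCR duplicates: a pair is a duplicate iff its (r1, r2) sequence
    tuple is byte-identical to an earlier pair's; first occurrence kept,
    order stable. Qualities and ids are ignored."""
    seen: set[tuple[str, Optional[str]]] = set()
    kept: list[ReadPair] = []
    n_dup = 0
    for pair in pairs:
        key = (pair.r1.sequence, pair.r2.sequence if pair.r2 else None)
        if key in seen:
            n_dup += 1
        else:
            seen.add(key)
            kept.append(pair)
    return kept, n_dup


def filter_read_pairs(
    pairs: Sequence[ReadPair],
    adapters: Sequence[str] = (),
    **clean_kwargs,
) -> tuple[list[ReadPair], FilterReport]:
    """Full cleaning pass: per-mate rules, then pair-level deduplication.

    A pair is discarded if either mate fails, attributed to the first
    failing mate's rule.
    """
    report = FilterReport(input_reads=len(pairs))
    trim5 = clean_kwargs.get("trim5", 2)
    trim3 = clean_kwargs.get("trim3", 3)
    cleaned: list[ReadPair] = []
    for pair in pairs:
        r1, rule = clean_read(pair.r1, adapters, **clean_kwargs)
        if rule is not None:
            report.discarded_by_rule[rule] += 1
            continue
        r2 = None
        if pair.r2 is not None:
            r2, rule = clean_read(pair.r2, adapters, **clean_kwargs)
            if rule is not None:
                report.discarded_by_rule[rule] += 1
                continue
        report.bases_trimmed += trim5 + trim3
        if r2 is not None:
            report.bases_trimmed += trim5 + trim3
        cleaned.append(ReadPair(r1, r2))
    kept, n_dup = remove_duplicates(cleaned)
    report.discarded_by_rule["duplicate"] = n_dup
    report.kept_reads = len(kept)
    report.check()
    return kept, report
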