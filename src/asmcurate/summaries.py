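"""Assembly statistics and report arithmetic.

N50/N90 with their ranks, GC content, repeat-class occupancy percentages,
functional-annotation percentages, consensus quality value (QV) from the
homozygous-variant rate, and assembly-vs-estimate genome-size concordance.
Percentages are rounded half-up at each report's printed precision:
2 decimals for table figures, 1 decimal for concordance, 0 for Mb.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .core import Interval, SeqRecord, interval_union_length, merge_intervals, round_half_up
from .errors import ValidationError
from .kmer import GenomeSizeEstimate

TE_CLASSES = ("DNA", "LINE", "SINE", "LTR")


@dataclass
class AssemblyStats:
    n_contigs: int
    total_len: int
    mean_len: float
    n50_len: int
    n50_count: int
    n90_len: int
    n90_count: int
    longest: int
    gc_percent: float


def assembly_stats(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    """Contiguity and composition statistics of an assembly.

    N50 length is the length of the contig at which the cumulative length
    (contigs sorted descending) first reaches 50% of the total; its count
    is that contig's 1-based rank. N90 analogous at 90%. GC excludes N.
    """
    if not contigs:
        raise ValidationError("assembly_stats needs at least one contig")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    n50_len = n50_count = n90_len = n90_count = 0
    cum = 0
    for rank, length in enumerate(lengths, 1):
        cum += length
        if not n50_len and 2 * cum >= total:
            n50_len, n50_count = length, rank
        if not n90_len and 10 * cum >= 9 * total:
            n90_len, n90_count = length, rank
            break
    gc = sum(c.sequence.count("G") + c.sequence.count("C") for c in contigs)
    at = sum(c.sequence.count("A") + c.sequence.count("T") for c in contigs)
    gc_percent = round_half_up(100.0 * gc / (gc + at), 2) if gc + at else 0.0
    return AssemblyStats(
        n_contigs=len(lengths), total_len=total, mean_len=total / len(lengths),
        n50_len=n50_len, n50_count=n50_count,
        n90_len=n90_len, n90_count=n90_count,
        longest=lengths[0], gc_percent=gc_percent,
    )


@dataclass
class RepeatClassRow:
    element_count: int
    occupied_bp: int
    percent_of_genome: float


@dataclass
class RepeatSummary:
    per_class: dict[str, RepeatClassRow]
    total_elements: int
    total_occupied_bp: int
    total_percent: float
    te_fraction_of_repeats: float  # percent of repeat bp in TE classes


def repeat_summary(
    mask_by_class: dict[str, Sequence[Interval]], assembly_len: int
) -> RepeatSummary:
    """Repeat occupancy per class against the assembly length.

    Classes are trusted as disjoint (masker precedence applied upstream);
    inter-class overlap triggers a warning, not an error. Within a class,
    occupancy is the interval union.
    """
    occupied: dict[str, int] = {}
    counts: dict[str, int] = {}
    all_spans: dict[str, list[tuple[int, int]]] = {}
    for cls, intervals in mask_by_class.items():
        by_seq: dict[str, list[Interval]] = {}
        for iv in intervals:
            if iv.end > assembly_len:
                raise ValidationError(
                    f"interval end {iv.end} beyond assembly length {assembly_len}"
                )
            by_seq.setdefault(iv.seq_id, []).append(iv)
            all_spans.setdefault(iv.seq_id, []).append((iv.start, iv.end))
        occupied[cls] = sum(interval_union_length(ivs) for ivs in by_seq.values())
        counts[cls] = len(intervals)
    total_occupied = sum(occupied.values())
    union_all = sum(
        sum(e - s for s, e in merge_intervals(spans)) for spans in all_spans.values()
    )
    if union_all < total_occupied:
        warnings.warn(
            f"repeat classes overlap by {total_occupied - union_all} bp; "
            "totals assume disjoint classes", stacklevel=2,
        )
    return summarize_repeat_occupancy(occupied, assembly_len, counts)


def summarize_repeat_occupancy(
    occupied_by_class: dict[str, int],
    assembly_len: int,
    element_counts: Optional[dict[str, int]] = None,
    total_occupied_bp: Optional[int] = None,
) -> RepeatSummary:
    """Repeat summary from pre-tallied occupied lengths (e.g. a published
    masker report).

    Masker reports often print a deduplicated total that is smaller than
    the sum of the class rows (classes can overlap before precedence is
    applied); pass it as ``total_occupied_bp`` to use it as the repeat
    total, otherwise the class sum is used.
    """
    if assembly_len <= 0:
        raise ValidationError("assembly_len must be positive")
    element_counts = element_counts or {}
    per_class = {
        cls: RepeatClassRow(
            element_counts.get(cls, 0), bp,
            round_half_up(100.0 * bp / assembly_len, 2),
        )
        for cls, bp in occupied_by_class.items()
    }
    class_sum = sum(occupied_by_class.values())
    total_occupied = total_occupied_bp if total_occupied_bp is not None else class_sum
    if total_occupied > class_sum:
        raise ValidationError("total occupied exceeds the sum of class rows")
    te_bp = sum(occupied_by_class.get(c, 0) for c in TE_CLASSES)
    return RepeatSummary(
        per_class=per_class,
        total_elements=sum(element_counts.values()),
        total_occupied_bp=total_occupied,
        total_percent=round_half_up(100.0 * total_occupied / assembly_len, 2),
        te_fraction_of_repeats=(
            round_half_up(100.0 * te_bp / total_occupied, 2) if total_occupied else 0.0
        ),
    )


@dataclass
class AnnotationSummary:
    per_source: dict[str, tuple[int, float]]  # source -> (gene_count, percent)
    total_genes: int


def annotation_summary(
    counts: dict[str, int], total_genes: int
) -> AnnotationSummary:
    """Percent of genes annotated per source, to two decimals half-up."""
    if total_genes <= 0:
        raise ValidationError("total_genes must be positive")
    per_source = {}
    for source, count in counts.items():
        if count > total_genes:
            raise ValidationError(
                f"{source} count {count} exceeds total genes {total_genes}"
            )
        per_source[source] = (count, round_half_up(100.0 * count / total_genes, 2))
    per_source.setdefault("Total", (total_genes, 100.0))
    return AnnotationSummary(per_source, total_genes)


@dataclass
class QVEstimate:
    rate: float  # homozygous variant sites per assembly base
    qv: int
    capped: bool


def consensus_qv(
    homozygous_variant_sites: int, assembly_len: int, qv_cap: int = 60
) -> QVEstimate:
    """Consensus quality value from the homozygous-variant rate.

    QV = floor(-10 log10 rate), floored (not rounded) because QV is
    reported as an integer class; capped at qv_cap, and zero variant
    sites yields the cap with a flag.
    """
    if assembly_len <= 0:
        raise ValidationError("assembly_len must be positive")
    if homozygous_variant_sites < 0:
        raise ValidationError("variant site count must be >= 0")
    rate = homozygous_variant_sites / assembly_len
    if homozygous_variant_sites == 0:
        return QVEstimate(0.0, qv_cap, True)
    qv = math.floor(-10.0 * math.log10(rate))
    return QVEstimate(rate, min(qv_cap, qv), qv >= qv_cap)


def genome_size_concordance(
    assembly_len: int, estimate: Union[GenomeSizeEstimate, int]
) -> float:
    """Assembly length as a percent of the estimated genome size, one
    decimal half-up, not clamped at 100."""
    G = estimate.G if isinstance(estimate, GenomeSizeEstimate) else int(estimate)
    if G <= 0:
        raise ValidationError("estimated genome size must be positive")
    return round_half_up(100.0 * assembly_len / G, 1)
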