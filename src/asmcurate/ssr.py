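"""Microsatellite (SSR) detection and genetic-marker selection.

Detection is MISA-style: maximal perfect tandem runs of 1-7 bp units, with
minimum unit counts of 10 (mono), 6 (di) and 5 (tri- through hepta-).
Runs whose unit is itself periodic (ATAT = 2xAT) are reported at the
smallest period only. Consecutive SSRs separated by at most a short
interruption fuse into compound loci. Marker selection applies four
criteria: perfect di/tri/tetra repeats at their minimum unit counts, an
SSR-free +/-2 kb neighbourhood, location outside the repeat mask, and
200-bp flanks that occur exactly once in the assembly (both strands).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_SSR_MIN_UNITS, PipelineConfig
from .core import Interval, SeqRecord, revcomp
from .errors import ValidationError


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the motif or of its reverse
    complement, pooling e.g. AT/TA and AAT/ATT/TAT... under one label."""
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def _minimal_period(motif: str) -> int:
    p = len(motif)
    for q in range(1, p):
        if all(motif[i] == motif[i - q] for i in range(q, p)):
            return q
    return p


@dataclass
class SSRLocus:
    """One microsatellite locus, perfect or compound (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    motif: str  # repeat unit as it occurs; joined with '+' for compounds
    canonical_motif: str
    unit_len: int  # 0 for compound loci
    n_units: int  # summed over members for compounds
    kind: str = "perfect"  # perfect | compound
    members: tuple = ()

    def __post_init__(self):
        if self.kind == "perfect":
            if self.end - self.start != self.unit_len * self.n_units:
                raise ValidationError(
                    f"perfect SSR span {self.end - self.start} != "
                    f"{self.unit_len} x {self.n_units}"
                )
        elif self.kind != "compound":
            raise ValidationError(f"unknown SSR kind {self.kind!r}")


def find_ssrs(
    contigs: Sequence[SeqRecord],
    min_units: Optional[dict[int, int]] = None,
    max_unit_len: int = 7,
) -> list[SSRLocus]:
    """All maximal perfect SSRs meeting the per-unit-length minima.

    A locus spans whole units only (a trailing partial unit does not extend
    the reported coordinates). Windows containing N (or any non-ACGT base)
    terminate runs. Output sorted by (contig, start, unit_len).
    """
    min_units = dict(min_units or DEFAULT_SSR_MIN_UNITS)
    loci: list[SSRLocus] = []
    for rec in contigs:
        seq = rec.sequence
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        acgt = (
            (arr == ord("A")) | (arr == ord("C"))
            | (arr == ord("G")) | (arr == ord("T"))
        )
        for p in range(1, max_unit_len + 1):
            need = min_units.get(p)
            if need is None or len(arr) < p * 2:
                continue
            eq = (arr[:-p] == arr[p:]) & acgt[:-p] & acgt[p:]
            if not eq.any():
                continue
            # maximal runs of True in eq
            diff = np.diff(eq.astype(np.int8))
            starts = np.nonzero(diff == 1)[0] + 1
            ends = np.nonzero(diff == -1)[0] + 1
            if eq[0]:
                starts = np.concatenate(([0], starts))
            if eq[-1]:
                ends = np.concatenate((ends, [eq.size]))
            for i, j in zip(starts, ends):
                region_len = (j - i) + p
                n = region_len // p
                if n < need:
                    continue
                motif = seq[i : i + p]
                if _minimal_period(motif) != p:
                    continue  # reported at the smaller period instead
                loci.append(SSRLocus(
                    rec.id, int(i), int(i) + n * p, motif,
                    canonical_motif(motif), p, int(n),
                ))
    loci.sort(key=lambda L: (L.contig_id, L.start, L.unit_len))
    return loci


def find_compound_ssrs(
    perfect: Sequence[SSRLocus], max_interruption: int = 100
) -> tuple[list[SSRLocus], list[SSRLocus]]:
    """Fuse neighbouring perfect SSRs into compound loci.

    Consecutive loci on one contig separated by at most ``max_interruption``
    bp (fusion is transitive) become one compound locus spanning the first
    start to the last end; its members leave the perfect list. Returns
    (compound loci, surviving perfect loci).
    """
    by_contig: dict[str, list[SSRLocus]] = defaultdict(list)
    for L in sorted(perfect, key=lambda L: (L.contig_id, L.start, L.end)):
        by_contig[L.contig_id].append(L)
    compounds: list[SSRLocus] = []
    surviving: list[SSRLocus] = []
    for cid in sorted(by_contig):
        group: list[SSRLocus] = []
        for L in by_contig[cid]:
            if group and L.start - group[-1].end <= max_interruption:
                group.append(L)
            else:
                _flush_group(group, compounds, surviving)
                group = [L]
        _flush_group(group, compounds, surviving)
    compounds.sort(key=lambda L: (L.contig_id, L.start))
    surviving.sort(key=lambda L: (L.contig_id, L.start, L.unit_len))
    return compounds, surviving


def _flush_group(group, compounds, surviving):
    if not group:
        return
    if len(group) == 1:
        surviving.append(group[0])
        return
    compounds.append(SSRLocus(
        group[0].contig_id, group[0].start, group[-1].end,
        "+".join(L.motif for L in group),
        "+".join(L.canonical_motif for L in group),
        0, sum(L.n_units for L in group), "compound", tuple(group),
    ))


# ---------------------------------------------------------------------------
# marker selection

#: criterion i: perfect repeats only, unit length -> minimum unit count
MARKER_MIN_UNITS = {2: 6, 3: 5, 4: 5}

CRITERIA = ("perfect_min_units", "flank_ssr_free", "outside_repeat", "flanks_unique")


@dataclass
class MarkerCandidate:
    locus: SSRLocus
    flank5: str
    flank3: str
    criteria: dict[str, bool]
    selected: bool = field(init=False)

    def __post_init__(self):
        self.selected = all(self.criteria.values())


def _count_occurrences(haystack: str, needle: str) -> int:
    """Occurrences of needle in haystack, overlapping counted."""
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def select_markers(
    loci: Sequence[SSRLocus],
    contigs: Sequence[SeqRecord],
    repeat_mask: Sequence[Interval] = (),
    cfg: Optional[PipelineConfig] = None,
) -> list[MarkerCandidate]:
    """Score every locus against the four marker criteria.

    i.   perfect repeat with unit length 2/3/4 and at least 6/5/5 units
         (mono- and penta-plus excluded);
    ii.  no OTHER SSR locus overlaps the +/-2 kb windows adjoining the
         locus (the locus itself trivially sits in its own window);
    iii. the locus does not intersect the repeat mask;
    iv.  each 200-bp flank occurs exactly once in the assembly as an exact
         match counting both strands — a flank truncated by a contig end
         fails.
    """
    cfg = cfg or PipelineConfig()
    seqs = {c.id: c.sequence for c in contigs}
    mask_by_contig: dict[str, list[Interval]] = defaultdict(list)
    for iv in repeat_mask:
        mask_by_contig[iv.seq_id].append(iv)
    loci_by_contig: dict[str, list[SSRLocus]] = defaultdict(list)
    for L in loci:
        loci_by_contig[L.contig_id].append(L)

    flank_len = cfg.marker_flank_len
    window = cfg.marker_flank_exclusion
    out: list[MarkerCandidate] = []
    for L in loci:
        seq = seqs.get(L.contig_id)
        if seq is None:
            raise ValidationError(f"locus on unknown contig {L.contig_id!r}")
        crit_i = (
            L.kind == "perfect"
            and L.unit_len in MARKER_MIN_UNITS
            and L.n_units >= MARKER_MIN_UNITS[L.unit_len]
        )
        crit_ii = not any(
            other is not L
            and other.end > L.start - window
            and other.start < L.end + window
            for other in loci_by_contig[L.contig_id]
        )
        crit_iii = not any(
            iv.start < L.end and L.start < iv.end
            for iv in mask_by_contig[L.contig_id]
        )
        flank5 = seq[max(0, L.start - flank_len) : L.start]
        flank3 = seq[L.end : L.end + flank_len]
        if len(flank5) < flank_len or len(flank3) < flank_len:
            crit_iv = False
        else:
            crit_iv = all(
                sum(
                    _count_occurrences(s, f) + _count_occurrences(s, revcomp(f))
                    for s in seqs.values()
                ) == 1
                for f in (flank5, flank3)
            )
        out.append(MarkerCandidate(
            L, flank5, flank3,
            {"perfect_min_units": crit_i, "flank_ssr_free": crit_ii,
             "outside_repeat": crit_iii, "flanks_unique": crit_iv},
        ))
    return out


def motif_frequency_table(
    loci: Sequence[SSRLocus],
) -> tuple[dict[str, int], Optional[tuple[str, int]]]:
    """Counts of canonical motifs, and the most frequent SSR type
    (motif, n_units) among perfect loci with unit length >= 2.

    Ties break lexicographically (smaller motif, then smaller unit count).
    """
    motif_counts: dict[str, int] = dict(
        Counter(L.canonical_motif for L in loci)
    )
    types = Counter(
        (L.canonical_motif, L.n_units)
        for L in loci
        if L.kind == "perfect" and L.unit_len >= 2
    )
    if not types:
        return motif_counts, None
    best = min(types.items(), key=lambda kv: (-kv[1], kv[0]))
    return motif_counts, best[0]


def write_ssr_table(loci: Sequence[SSRLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tstart\tend\tkind\tmotif\tcanonical_motif\tunit_len\tn_units\n")
        for L in loci:
            fh.write(
                f"{L.contig_id}\t{L.start}\t{L.end}\t{L.kind}\t{L.motif}\t"
                f"{L.canonical_motif}\t{L.unit_len}\t{L.n_units}\n"
            )


def write_marker_table(markers: Sequence[MarkerCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig_id\tstart\tend\tmotif\tn_units\t"
            + "\t".join(CRITERIA) + "\tselected\tflank5\tflank3\n"
        )
        for m in markers:
            L = m.locus
            flags = "\t".join(str(int(m.criteria[c])) for c in CRITERIA)
            fh.write(
                f"{L.contig_id}\t{L.start}\t{L.end}\t{L.motif}\t{L.n_units}\t"
                f"{flags}\t{int(m.selected)}\t{m.flank5}\t{m.flank3}\n"
            )
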