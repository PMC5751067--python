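"""Whole-assembly self-alignment by exact canonical anchors.

A built-in substitute for external whole-genome aligners, emitting the same
AlignmentBlock atoms their outputs parse into. Shared canonical k-mers
(anchors) between contigs are grouped by diagonal; maximal runs of
co-diagonal anchors whose starts are at most k apart delimit spans that
match base-for-base, and each run becomes one exact block. Heterozygous
divergence therefore appears as breaks between blocks — exactly what the
downstream LIS chaining and merge stage is designed to bridge. Canonical
anchors give reverse-strand detection without a second pass; a per-anchor
occurrence cap keeps repeats from blowing up the pair list.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AlignmentBlock, SeqRecord
from .errors import ValidationError
from .kmer import encode_bases, kmer_codes, revcomp_codes


@dataclass
class AnchorParams:
    anchor_k: int = 21
    max_anchor_occurrence: int = 10
    min_block_len: int = 100

    def __post_init__(self):
        if self.anchor_k < 11:
            raise ValidationError("anchor_k must be >= 11")
        if self.anchor_k % 2 == 0:
            raise ValidationError("anchor_k must be odd (no palindromic anchors)")
        if self.max_anchor_occurrence < 1 or self.min_block_len < 1:
            raise ValidationError("occurrence cap and min_block_len must be positive")


@dataclass
class AnchorIndex:
    """Opaque index: canonical anchor code -> occurrences (contig, pos, strand).

    ``strand`` is '+' when the canonical representative equals the forward
    k-mer at that position, '-' when it is the reverse complement. Anchors
    occurring more often than the cap are dropped as repeats.
    """

    params: AnchorParams
    contig_ids: list[str]
    occurrences: dict[int, list[tuple[int, int, str]]]

    def lookup(self, code: int) -> list[tuple[str, int, str]]:
        return [
            (self.contig_ids[ci], pos, strand)
            for ci, pos, strand in self.occurrences.get(code, [])
        ]

    def __len__(self) -> int:
        return len(self.occurrences)


def _anchor_arrays(contigs: Sequence[SeqRecord], k: int):
    """Per-assembly arrays of (canonical code, contig index, position, fwd flag)."""
    codes_l, ci_l, pos_l, fwd_l = [], [], [], []
    for ci, rec in enumerate(contigs):
        fw, valid = kmer_codes(encode_bases(rec.sequence), k)
        if fw.size == 0:
            continue
        rc = revcomp_codes(fw, k)
        canon = np.minimum(fw, rc)
        fwd = fw <= rc
        idx = np.nonzero(valid)[0]
        codes_l.append(canon[idx])
        ci_l.append(np.full(idx.size, ci, dtype=np.int32))
        pos_l.append(idx.astype(np.int64))
        fwd_l.append(fwd[idx])
    if not codes_l:
        return (np.empty(0, np.uint64), np.empty(0, np.int32),
                np.empty(0, np.int64), np.empty(0, bool))
    return (np.concatenate(codes_l), np.concatenate(ci_l),
            np.concatenate(pos_l), np.concatenate(fwd_l))


def build_anchor_index(
    contigs: Sequence[SeqRecord], params: AnchorParams | None = None
) -> AnchorIndex:
    """Index every canonical anchor occurring at most max_anchor_occurrence
    times across the assembly."""
    if not contigs:
        raise ValidationError("contig list is empty")
    params = params or AnchorParams()
    codes, cis, poss, fwds = _anchor_arrays(contigs, params.anchor_k)
    occ: dict[int, list[tuple[int, int, str]]] = {}
    if codes.size:
        order = np.argsort(codes, kind="stable")
        sc = codes[order]
        starts = np.concatenate(([0], np.nonzero(sc[1:] != sc[:-1])[0] + 1, [sc.size]))
        for gi in range(starts.size - 1):
            lo, hi = starts[gi], starts[gi + 1]
            if hi - lo > params.max_anchor_occurrence:
                continue
            rows = order[lo:hi]
            occ[int(sc[lo])] = [
                (int(cis[r]), int(poss[r]), "+" if fwds[r] else "-") for r in rows
            ]
    return AnchorIndex(params, [c.id for c in contigs], occ)


def anchor_matches(
    contigs: Sequence[SeqRecord], params: AnchorParams | None = None
) -> list[AlignmentBlock]:
    """Exact match blocks between all contig pairs (and within contigs).

    For every unordered pair of anchor occurrences (excluding each contig's
    trivial self-match on its own diagonal), anchors are grouped by
    (query contig, target contig, relative strand, diagonal); maximal runs
    with successive starts at most k apart are emitted as blocks. Because
    consecutive anchors overlap or abut, every base in a run's span matches
    exactly, so matched_bases equals the span and identity is 1.0. Blocks
    shorter than min_block_len are dropped. The query of each block is the
    contig appearing earlier in the input (or the lower coordinate for
    intra-contig matches).
    """
    params = params or AnchorParams()
    if not contigs:
        return []
    k = params.anchor_k
    index = build_anchor_index(contigs, params)
    ids = index.contig_ids

    # (q_ci, t_ci, strand, diag) -> list of query anchor starts
    groups: dict[tuple[int, int, str, int], list[int]] = defaultdict(list)
    for occs in index.occurrences.values():
        if len(occs) < 2:
            continue
        for i in range(len(occs)):
            ci_a, p_a, s_a = occs[i]
            for j in range(i + 1, len(occs)):
                ci_b, p_b, s_b = occs[j]
                if ci_a == ci_b and p_a == p_b:
                    continue  # cannot happen (distinct positions) but cheap guard
                if ci_a < ci_b or (ci_a == ci_b and p_a <= p_b):
                    qc, qp, qs, tc, tp, ts = ci_a, p_a, s_a, ci_b, p_b, s_b
                else:
                    qc, qp, qs, tc, tp, ts = ci_b, p_b, s_b, ci_a, p_a, s_a
                strand = "+" if qs == ts else "-"
                if qc == tc and strand == "+" and qp == tp:
                    continue  # trivial full-length self diagonal
                diag = tp - qp if strand == "+" else tp + qp
                groups[(qc, tc, strand, diag)].append(qp)

    blocks: list[AlignmentBlock] = []
    for (qc, tc, strand, diag), qps in sorted(groups.items()):
        qa = np.unique(np.asarray(qps, dtype=np.int64))
        # split into maximal runs with start-to-start gaps <= k
        cut = np.nonzero(np.diff(qa) > k)[0] + 1
        for run in np.split(qa, cut):
            q_start = int(run[0])
            q_end = int(run[-1]) + k
            span = q_end - q_start
            if span < params.min_block_len:
                continue
            if strand == "+":
                t_start, t_end = q_start + diag, q_end + diag
            else:
                t_start = diag - (q_end - k)
                t_end = diag - q_start + k
            blocks.append(
                AlignmentBlock(
                    query_id=ids[qc], target_id=ids[tc],
                    q_start=q_start, q_end=q_end,
                    t_start=t_start, t_end=t_end,
                    strand=strand, matched_bases=span,
                    identity=1.0, score=float(span), source="internal",
                )
            )
    blocks.sort(key=lambda b: (b.query_id, b.target_id, b.strand, b.q_start, b.t_start))
    return blocks
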