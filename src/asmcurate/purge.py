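"""Haplotig purging and foreign-contig filters.

The core procedure: whole-assembly self-alignment blocks for a contig pair
are chained with a maximum-weight longest-increasing-subset (LIS) dynamic
program, adjacent chained blocks separated by short gaps on both sequences
are merged, per-pair overlap coverage is computed on the shorter contig,
and the shorter contig is discarded when at least 80% of its length is
covered by the longer one. Removals whose alignment identity falls below a
floor are automatically restored (the mechanised form of a manual dot-plot
review), and an operator-supplied restore list can re-add contigs by id.
Mitochondrial and taxon-annotated GC/coverage (blobplot-style)
contamination filters follow the same per-contig coverage logic.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import PipelineConfig
from .core import AlignmentBlock, Interval, SeqRecord, interval_union_length, merge_intervals
from .errors import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# chaining


@dataclass
class Chain:
    """A co-linear chain of alignment blocks for one contig pair and strand.

    Blocks are strictly increasing in the query coordinate and in the
    target coordinate (decreasing target for '-'). ``span_identity`` is
    total matched bases over the summed per-block spans — the alignment's
    identity, fixed when the chain is built and deliberately carried
    through merging unchanged (merging only widens block spans across
    unaligned gaps; it adds no evidence about identity).
    """

    query_id: str
    target_id: str
    strand: str
    blocks: list[AlignmentBlock]
    total_matched: int = 0
    span_identity: float = 0.0

    @classmethod
    def from_blocks(cls, blocks: list[AlignmentBlock]) -> "Chain":
        total = sum(b.matched_bases for b in blocks)
        denom = sum(max(b.q_span, b.t_span) for b in blocks)
        b0 = blocks[0]
        return cls(b0.query_id, b0.target_id, b0.strand, blocks,
                   total, total / denom if denom else 0.0)


def _check_same_pair(blocks: Sequence[AlignmentBlock]) -> None:
    keys = {(b.query_id, b.target_id, b.strand) for b in blocks}
    if len(keys) > 1:
        raise ValidationError(f"blocks mix contig pairs/strands: {sorted(keys)}")


def _compatible(a: AlignmentBlock, b: AlignmentBlock) -> bool:
    """b may follow a: strictly increasing in both coordinates."""
    if b.q_start < a.q_end:
        return False
    if a.strand == "+":
        return b.t_start >= a.t_end
    return b.t_end <= a.t_start  # target runs backwards on '-'


def chain_lis(
    blocks: Sequence[AlignmentBlock], min_chain_weight: int = 100
) -> list[Chain]:
    """Maximum-weight co-linear chaining of one pair's blocks.

    A dynamic program selects the subset of blocks strictly increasing in
    both query and target coordinates that maximises total matched bases;
    that subset is the primary chain. Remaining blocks are re-chained
    iteratively until none remain or the best chain's weight drops below
    ``min_chain_weight``. Ties break toward the chain whose first block
    has the smaller q_start.
    """
    if not blocks:
        return []
    _check_same_pair(blocks)
    pool = sorted(blocks, key=lambda b: (b.q_start, b.q_end, b.t_start))
    chains: list[Chain] = []
    while pool:
        selected = _best_chain(pool)
        chain = Chain.from_blocks(selected)
        # the primary chain is always emitted; re-chaining of leftovers
        # stops once the best remaining chain drops below the weight floor
        if chains and chain.total_matched < min_chain_weight:
            break
        chains.append(chain)
        chosen = set(map(id, selected))
        pool = [b for b in pool if id(b) not in chosen]
    return chains


def _gap(a: AlignmentBlock, b: AlignmentBlock) -> int:
    t_gap = (a.t_start - b.t_end) if a.strand == "-" else (b.t_start - a.t_end)
    return (b.q_start - a.q_end) + t_gap


def _best_chain(pool: list[AlignmentBlock]) -> list[AlignmentBlock]:
    # maximise chain weight; ties break toward the smaller first-block
    # q_start, then toward the chain with less total gap (tighter diagonal)
    n = len(pool)
    weight = [b.matched_bases for b in pool]
    best = list(weight)  # best chain weight ending at i
    first_q = [b.q_start for b in pool]  # first-block q_start of that chain
    gap_cost = [0] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if _compatible(pool[j], pool[i]):
                cand = (
                    -(best[j] + weight[i]),
                    first_q[j],
                    gap_cost[j] + _gap(pool[j], pool[i]),
                )
                if cand < (-best[i], first_q[i], gap_cost[i]):
                    best[i] = -cand[0]
                    first_q[i] = cand[1]
                    gap_cost[i] = cand[2]
                    prev[i] = j
    end = 0
    for i in range(1, n):
        if (-best[i], first_q[i], gap_cost[i]) < (-best[end], first_q[end], gap_cost[end]):
            end = i
    out: list[AlignmentBlock] = []
    while end != -1:
        out.append(pool[end])
        end = prev[end]
    out.reverse()
    return out


def merge_adjacent_blocks(chain: Chain, max_gap: int = 500) -> Chain:
    """Fuse consecutive blocks whose gaps on BOTH sequences are <= max_gap.

    Where two input blocks overlap on the query, only the higher-score
    block contributes before merging (repeat alignments filtered by score).
    Gap bases are not matched: matched_bases of a fused block is the sum of
    its parts, and the fused block's identity is recomputed over its span.
    The chain-level ``span_identity`` is carried over unchanged.
    """
    if not chain.blocks:
        return chain
    minus = chain.strand == "-"
    blocks = sorted(chain.blocks, key=lambda b: (b.q_start, -b.score))
    # score-filter query-overlapping blocks
    kept: list[AlignmentBlock] = []
    for b in blocks:
        if kept and b.q_start < kept[-1].q_end:
            if b.score > kept[-1].score:
                kept[-1] = b
            continue
        kept.append(b)

    merged: list[AlignmentBlock] = [kept[0]]
    for b in kept[1:]:
        a = merged[-1]
        q_gap = b.q_start - a.q_end
        t_gap = (a.t_start - b.t_end) if minus else (b.t_start - a.t_end)
        if 0 <= q_gap <= max_gap and 0 <= t_gap <= max_gap:
            matched = a.matched_bases + b.matched_bases
            q_start, q_end = a.q_start, b.q_end
            t_start = min(a.t_start, b.t_start)
            t_end = max(a.t_end, b.t_end)
            span = max(q_end - q_start, t_end - t_start)
            merged[-1] = AlignmentBlock(
                a.query_id, a.target_id, q_start, q_end, t_start, t_end,
                a.strand, matched, matched / span, a.score + b.score,
                a.evalue, a.source,
            )
        else:
            merged.append(b)
    out = Chain(chain.query_id, chain.target_id, chain.strand, merged,
                sum(b.matched_bases for b in merged), chain.span_identity)
    return out


# ---------------------------------------------------------------------------
# pair coverage


@dataclass
class ContigPairSummary:
    """Coverage of the shorter contig of a pair by the longer one."""

    short_id: str
    long_id: str
    short_len: int
    long_len: int
    covered_bp: int
    coverage_fraction: float
    identity: float
    chains: list[Chain] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.short_len > self.long_len:
            raise ValidationError("short_len exceeds long_len")
        if not 0.0 <= self.coverage_fraction <= 1.0 + 1e-12:
            raise ValidationError(f"coverage fraction {self.coverage_fraction} outside [0,1]")


def pair_coverage(
    chains: Sequence[Chain],
    short_id: str,
    long_id: str,
    short_len: int,
    long_len: int,
) -> ContigPairSummary:
    """Union coverage of the short contig by all (merged) chains of a pair.

    covered_bp is the union of block spans projected on the shorter contig;
    identity is the matched-bases-weighted mean of the chain identities.
    """
    spans: list[tuple[int, int]] = []
    total_matched = 0
    id_weighted = 0.0
    for chain in chains:
        if {chain.query_id, chain.target_id} != {short_id, long_id} and short_id != long_id:
            raise ValidationError(
                f"chain {chain.query_id}/{chain.target_id} does not belong to "
                f"pair {short_id}/{long_id}"
            )
        on_query = chain.query_id == short_id
        for b in chain.blocks:
            s, e = (b.q_start, b.q_end) if on_query else (b.t_start, b.t_end)
            if e > short_len:
                raise ValidationError(
                    f"block end {e} beyond short contig length {short_len}"
                )
            spans.append((s, e))
        total_matched += chain.total_matched
        id_weighted += chain.span_identity * chain.total_matched
    covered = sum(e - s for s, e in merge_intervals(spans)) if spans else 0
    identity = id_weighted / total_matched if total_matched else 0.0
    return ContigPairSummary(
        short_id, long_id, short_len, long_len,
        covered, covered / short_len if short_len else 0.0, identity,
        chains=list(chains),
    )


def summarize_pair(
    blocks: Sequence[AlignmentBlock],
    short_id: str,
    long_id: str,
    short_len: int,
    long_len: int,
    cfg: Optional[PipelineConfig] = None,
) -> ContigPairSummary:
    """Chain, merge and summarise one pair's raw blocks (both strands).

    Blocks from any aligner/source are pooled by union before chaining.
    Blocks whose roles are reversed (query == long contig) are swapped so
    the chains all run short-vs-long.
    """
    cfg = cfg or PipelineConfig()
    oriented = [b if b.query_id == short_id else b.swapped() for b in blocks]
    by_strand: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for b in oriented:
        by_strand[b.strand].append(b)
    merged_chains: list[Chain] = []
    for strand_blocks in by_strand.values():
        for chain in chain_lis(strand_blocks):
            merged_chains.append(merge_adjacent_blocks(chain, cfg.max_chain_gap))
    return pair_coverage(merged_chains, short_id, long_id, short_len, long_len)


# ---------------------------------------------------------------------------
# assembly purge


@dataclass
class PurgeDecision:
    removed_id: str
    kept_id: str
    coverage_fraction: float
    identity: float
    restored: bool
    reason: str  # heterozygous_duplicate | restored_low_identity


def purge_assembly(
    contigs: Sequence[SeqRecord],
    summaries: Sequence[ContigPairSummary],
    cfg: Optional[PipelineConfig] = None,
    restore_ids: Sequence[str] = (),
    dotplot_dir: Optional[str] = None,
) -> tuple[list[SeqRecord], list[PurgeDecision]]:
    """Remove redundant heterozygous (haplotig) contigs.

    Pairs are processed in decreasing order of long-contig length. A
    removal fires iff coverage_fraction >= the removal threshold AND the
    long contig has not itself been removed earlier in the pass (so a
    removed contig can never cascade into removing both haplotypes).
    Removals with identity below min_restore_identity are auto-restored:
    the decision is recorded with the restored flag and the contig stays
    in the output. Every removal exports a TSV dot plot (block endpoints)
    for manual review when ``dotplot_dir`` is given. ``restore_ids``
    re-adds contigs by id; naming an id that was never removed only warns.
    """
    cfg = cfg or PipelineConfig()
    order = sorted(
        summaries, key=lambda s: (-s.long_len, s.long_id, s.short_id)
    )
    removed: set[str] = set()
    decisions: list[PurgeDecision] = []
    for s in order:
        if s.long_id in removed or s.short_id in removed:
            continue
        if s.coverage_fraction < cfg.coverage_removal_threshold:
            continue
        if s.identity < cfg.min_restore_identity:
            decisions.append(PurgeDecision(
                s.short_id, s.long_id, s.coverage_fraction, s.identity,
                restored=True, reason="restored_low_identity",
            ))
        else:
            removed.add(s.short_id)
            decisions.append(PurgeDecision(
                s.short_id, s.long_id, s.coverage_fraction, s.identity,
                restored=False, reason="heterozygous_duplicate",
            ))
        if dotplot_dir is not None:
            export_dotplot(s, dotplot_dir)
    for rid in restore_ids:
        if rid in removed:
            removed.discard(rid)
            logger.info("operator restore: %s re-added to the assembly", rid)
        else:
            logger.warning("restore list names %s, which was never removed", rid)
    kept = [c for c in contigs if c.id not in removed]
    return kept, decisions


def export_dotplot(summary: ContigPairSummary, out_dir: str) -> str:
    """Write block endpoints of a pair as TSV for dot-plot review."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"{summary.short_id}__{summary.long_id}.tsv")
    with open(path, "w") as fh:
        fh.write("query_id\ttarget_id\tstrand\tq_start\tq_end\tt_start\tt_end\tmatched\tidentity\n")
        for chain in summary.chains:
            for b in chain.blocks:
                fh.write(
                    f"{b.query_id}\t{b.target_id}\t{b.strand}\t{b.q_start}\t"
                    f"{b.q_end}\t{b.t_start}\t{b.t_end}\t{b.matched_bases}\t"
                    f"{b.identity:.4f}\n"
                )
    return path


def run_purge(
    contigs: Sequence[SeqRecord],
    blocks: Sequence[AlignmentBlock],
    cfg: Optional[PipelineConfig] = None,
    restore_ids: Sequence[str] = (),
    dotplot_dir: Optional[str] = None,
) -> tuple[list[SeqRecord], list[PurgeDecision], list[ContigPairSummary]]:
    """Blocks-to-decisions driver: group blocks by contig pair, summarise
    each pair, then purge. Intra-contig matches are ignored here (they are
    repeats, not haplotigs)."""
    cfg = cfg or PipelineConfig()
    lengths = {c.id: len(c) for c in contigs}
    by_pair: dict[tuple[str, str], list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        if b.query_id == b.target_id:
            continue
        a, bb = sorted(
            (b.query_id, b.target_id), key=lambda cid: (lengths.get(cid, 0), cid)
        )
        by_pair[(a, bb)].append(b)  # (short, long)
    summaries = [
        summarize_pair(pair_blocks, short, long_,
                       lengths[short], lengths[long_], cfg)
        for (short, long_), pair_blocks in sorted(by_pair.items())
    ]
    kept, decisions = purge_assembly(contigs, summaries, cfg, restore_ids, dotplot_dir)
    return kept, decisions, summaries


def purge_pipeline(
    contigs: Sequence[SeqRecord],
    cfg: Optional[PipelineConfig] = None,
    extra_blocks: Sequence[AlignmentBlock] = (),
    restore_ids: Sequence[str] = (),
    dotplot_dir: Optional[str] = None,
) -> tuple[list[SeqRecord], list[PurgeDecision], list[ContigPairSummary]]:
    """The full haplotig-purge procedure from contigs alone.

    Runs the built-in self-alignment in sensitive mode (every anchor run
    is kept, down to a single anchor) and pools those blocks with any
    externally supplied alignment tables before chaining. Fractured
    matches at heterozygous loci are then fused by LIS chaining, where the
    100-bp weight floor applies at the chain level — the same division of
    labour as pooling a strict aligner with a sensitive one and clustering
    their union into larger matches.
    """
    from .self_align import AnchorParams, anchor_matches  # local: avoid cycle

    cfg = cfg or PipelineConfig()
    params = AnchorParams(anchor_k=cfg.anchor_k, min_block_len=cfg.anchor_k)
    blocks = list(anchor_matches(contigs, params)) + list(extra_blocks)
    return run_purge(contigs, blocks, cfg, restore_ids, dotplot_dir)


# ---------------------------------------------------------------------------
# mitochondrial & contamination filters


def filter_mitochondrial(
    contig_hits: Sequence[AlignmentBlock],
    contig_lengths: dict[str, int],
    cfg: Optional[PipelineConfig] = None,
) -> list[str]:
    """Contig ids whose length is >=80% covered by mitochondrial-reference
    hits with E-value below the threshold."""
    cfg = cfg or PipelineConfig()
    spans: dict[str, list[Interval]] = defaultdict(list)
    for b in contig_hits:
        if b.evalue is None:
            raise ValidationError(
                f"hit {b.query_id}->{b.target_id} at q[{b.q_start},{b.q_end}) "
                "has no E-value (mitochondrial rule needs blast6-style hits)"
            )
        if b.evalue < cfg.mito_evalue_max:
            spans[b.query_id].append(Interval(b.query_id, b.q_start, b.q_end))
    flagged = []
    for cid, ivs in spans.items():
        if cid not in contig_lengths:
            raise ValidationError(f"no length known for contig {cid}")
        if interval_union_length(ivs) / contig_lengths[cid] >= cfg.mito_coverage_threshold:
            flagged.append(cid)
    return sorted(flagged)


@dataclass
class ContigAnnotation:
    """Per-contig blobplot-style annotation: GC, read coverage, best-hit
    taxon, and rescue evidence (transcript reads, single-copy orthologs)."""

    contig_id: str
    length: int
    gc: float
    read_coverage: float
    best_hit_taxon: Optional[str] = None
    target_clade: str = "Arthropoda"
    has_transcript_evidence: bool = False
    has_busco_gene: bool = False

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError(f"gc {self.gc} outside [0,1]")
        if self.read_coverage < 0:
            raise ValidationError("read_coverage must be >= 0")


@dataclass
class ContaminantVerdict:
    contig_id: str
    keep: bool
    rule: Optional[str]  # low_coverage | foreign_no_evidence | None when kept


def filter_contaminants(
    annotations: Sequence[ContigAnnotation],
    cfg: Optional[PipelineConfig] = None,
) -> list[ContaminantVerdict]:
    """Blobplot rule: discard a contig iff its read coverage is below the
    floor, OR its best hit is outside the target clade AND it has neither
    transcript evidence nor a single-copy-ortholog gene. Contigs with no
    best hit are treated as in-clade."""
    cfg = cfg or PipelineConfig()
    verdicts = []
    for a in annotations:
        if a.read_coverage < cfg.blob_coverage_min:
            verdicts.append(ContaminantVerdict(a.contig_id, False, "low_coverage"))
        elif (
            a.best_hit_taxon is not None
            and a.best_hit_taxon != a.target_clade
            and not a.has_transcript_evidence
            and not a.has_busco_gene
        ):
            verdicts.append(ContaminantVerdict(a.contig_id, False, "foreign_no_evidence"))
        else:
            verdicts.append(ContaminantVerdict(a.contig_id, True, None))
    return verdicts


def read_annotations(path, target_clade: str = "Arthropoda") -> list[ContigAnnotation]:
    """Read a per-contig annotation TSV: contig_id, length, gc, read_coverage,
    best_hit_taxon ('.' for none), has_transcript_evidence, has_busco_gene."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("contig_id"):
                continue
            cid, length, gc, cov, taxon, tr, bu = line.split("\t")
            out.append(ContigAnnotation(
                cid, int(length), float(gc), float(cov),
                None if taxon == "." else taxon, target_clade,
                tr in ("1", "True", "true"), bu in ("1", "True", "true"),
            ))
    return out


def write_annotations(annotations: Sequence[ContigAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlength\tgc\tread_coverage\tbest_hit_taxon\t"
                 "has_transcript_evidence\thas_busco_gene\n")
        for a in annotations:
            fh.write(
                f"{a.contig_id}\t{a.length}\t{a.gc:.4f}\t{a.read_coverage:.2f}\t"
                f"{a.best_hit_taxon or '.'}\t{int(a.has_transcript_evidence)}\t"
                f"{int(a.has_busco_gene)}\n"
            )
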