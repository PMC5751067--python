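"""Chaining, merging, pair coverage and the purge/contamination rules."""

from itertools import combinations

import numpy as np
import pytest

from asmcurate.config import PipelineConfig
from asmcurate.core import AlignmentBlock, SeqRecord
from asmcurate.errors import ValidationError
from asmcurate.purge import (
    Chain,
    ContigAnnotation,
    ContigPairSummary,
    chain_lis,
    filter_contaminants,
    filter_mitochondrial,
    merge_adjacent_blocks,
    pair_coverage,
    purge_assembly,
)


def blk(qs, qe, ts, te, matched=None, strand="+", score=None, ident=None):
    matched = matched if matched is not None else min(qe - qs, te - ts)
    span = max(qe - qs, te - ts)
    return AlignmentBlock(
        "S", "L", qs, qe, ts, te, strand, matched,
        ident if ident is not None else matched / span,
        score if score is not None else float(matched), None, "internal",
    )


def brute_force_best_weight(blocks):
    """Exhaustive maximum-weight increasing subset (the oracle)."""

    def increasing(subset):
        s = sorted(subset, key=lambda b: b.q_start)
        for a, b in zip(s, s[1:]):
            if b.q_start < a.q_end:
                return False
            if a.strand == "+" and b.t_start < a.t_end:
                return False
            if a.strand == "-" and b.t_end > a.t_start:
                return False
        return True

    best = 0
    for r in range(1, len(blocks) + 1):
        for subset in combinations(blocks, r):
            if increasing(subset):
                best = max(best, sum(b.matched_bases for b in subset))
    return best


class TestChainLis:
    def test_non_colinear_block_excluded(self):
        a = blk(0, 100, 0, 100)
        b = blk(200, 300, 200, 300)
        c = blk(150, 250, 900, 1000)
        chains = chain_lis([a, b, c])
        assert chains[0].blocks == [a, b]

    def test_single_block(self):
        a = blk(0, 150, 0, 150)
        (chain,) = chain_lis([a])
        assert chain.blocks == [a] and chain.total_matched == 150

    def test_minus_strand_needs_decreasing_target(self):
        a = blk(0, 100, 900, 1000, strand="-")
        b = blk(200, 300, 600, 700, strand="-")
        c = blk(400, 500, 750, 850, strand="-")  # target rises again: breaks
        chains = chain_lis([a, b, c])
        assert chains[0].blocks == [a, b]

    def test_mixed_pairs_rejected(self):
        a = blk(0, 100, 0, 100)
        b = AlignmentBlock("X", "L", 0, 100, 0, 100, "+", 100, 1.0, 100.0)
        with pytest.raises(ValidationError):
            chain_lis([a, b])

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 11))
        blocks = []
        for _ in range(n):
            qs = int(rng.integers(0, 900))
            qe = qs + int(rng.integers(20, 120))
            ts = int(rng.integers(0, 900))
            te = ts + int(rng.integers(20, 120))
            blocks.append(blk(qs, qe, ts, te, matched=min(qe - qs, te - ts)))
        chains = chain_lis(blocks, min_chain_weight=1)
        assert chains[0].total_matched == brute_force_best_weight(blocks)

    def test_rechaining_consumes_leftovers(self):
        # two disjoint co-linear groups that cannot share a chain
        g1 = [blk(0, 200, 0, 200), blk(300, 500, 300, 500)]
        g2 = [blk(50, 250, 700, 900)]
        chains = chain_lis(g1 + g2, min_chain_weight=50)
        assert len(chains) == 2
        assert chains[0].total_matched == 400
        assert chains[1].total_matched == 200


class TestMergeAdjacentBlocks:
    def test_small_gaps_fused(self):
        chain = Chain.from_blocks([blk(0, 100, 0, 100), blk(110, 200, 112, 202)])
        merged = merge_adjacent_blocks(chain, max_gap=500)
        assert len(merged.blocks) == 1
        b = merged.blocks[0]
        assert (b.q_start, b.q_end, b.t_start, b.t_end) == (0, 200, 0, 202)
        assert b.matched_bases == 190

    def test_large_gap_not_fused(self):
        chain = Chain.from_blocks([blk(0, 100, 0, 100), blk(700, 800, 700, 800)])
        merged = merge_adjacent_blocks(chain, max_gap=500)
        assert len(merged.blocks) == 2

    def test_query_overlap_resolved_by_score(self):
        lo = blk(0, 100, 0, 100, score=50.0)
        hi = blk(0, 100, 500, 600, score=90.0)
        chain = Chain("S", "L", "+", [lo, hi], 200, 1.0)
        merged = merge_adjacent_blocks(chain, max_gap=500)
        assert merged.blocks == [hi]

    def test_chain_identity_carried_through_merge(self):
        chain = Chain.from_blocks([blk(0, 100, 0, 100), blk(110, 200, 112, 202)])
        assert chain.span_identity == 1.0  # exact blocks
        merged = merge_adjacent_blocks(chain, max_gap=500)
        assert merged.span_identity == 1.0  # merging adds no mismatch evidence

    def test_minus_strand_gap_arithmetic(self):
        a = blk(0, 100, 900, 1000, strand="-")
        b = blk(150, 250, 700, 800, strand="-")
        chain = Chain.from_blocks([a, b])
        merged = merge_adjacent_blocks(chain, max_gap=500)
        assert len(merged.blocks) == 1
        assert (merged.blocks[0].t_start, merged.blocks[0].t_end) == (700, 1000)


class TestPairCoverage:
    def test_union_projection_on_short(self):
        c1 = Chain.from_blocks([blk(0, 400, 0, 400)])
        c2 = Chain.from_blocks([blk(300, 600, 300, 600)])
        s = pair_coverage([c1, c2], "S", "L", 1000, 5000)
        assert s.covered_bp == 600
        assert s.coverage_fraction == pytest.approx(0.60)

    def test_no_chains_zero_coverage(self):
        s = pair_coverage([], "S", "L", 1000, 5000)
        assert s.coverage_fraction == 0.0

    def test_identity_weighted_by_matched(self):
        a = Chain.from_blocks([blk(0, 100, 0, 100, matched=90, ident=0.9)])
        b = Chain.from_blocks([blk(200, 500, 200, 500, matched=300, ident=1.0)])
        a = Chain("S", "L", "+", a.blocks, 90, 0.9)
        b = Chain("S", "L", "+", b.blocks, 300, 1.0)
        s = pair_coverage([a, b], "S", "L", 1000, 5000)
        assert s.identity == pytest.approx((0.9 * 90 + 1.0 * 300) / 390)


def summary(short, long_, cov, ident, short_len=1000, long_len=2000):
    return ContigPairSummary(short, long_, short_len, long_len,
                             int(cov * short_len), cov, ident)


class TestPurgeAssembly:
    def contigs(self, ids_lens):
        return [SeqRecord(i, "A" * n) for i, n in ids_lens]

    def test_demonstration_pair_decision(self):
        contigs = self.contigs([("tigL", 2_140_267), ("tigS", 865_792)])
        s = summary("tigS", "tigL", 0.8349, 0.94,
                    short_len=865_792, long_len=2_140_267)
        kept, decisions = purge_assembly(contigs, [s])
        assert [c.id for c in kept] == ["tigL"]
        (d,) = decisions
        assert d.removed_id == "tigS" and not d.restored
        assert d.reason == "heterozygous_duplicate"

    def test_below_threshold_untouched(self):
        contigs = self.contigs([("L", 2000), ("S", 1000)])
        kept, decisions = purge_assembly(contigs, [summary("S", "L", 0.79, 0.95)])
        assert len(kept) == 2 and decisions == []

    def test_low_identity_auto_restored(self):
        contigs = self.contigs([("L", 2000), ("S", 1000)])
        kept, decisions = purge_assembly(contigs, [summary("S", "L", 0.85, 0.70)])
        assert len(kept) == 2
        (d,) = decisions
        assert d.restored and d.reason == "restored_low_identity"

    def test_no_cascade_through_removed_contig(self):
        # A covers 85% of B; B covers 85% of C; A longest. B falls to A;
        # C survives because its only coverer B was already removed.
        contigs = self.contigs([("A", 3000), ("B", 2000), ("C", 1000)])
        summaries = [
            summary("B", "A", 0.85, 0.95, short_len=2000, long_len=3000),
            summary("C", "B", 0.85, 0.95, short_len=1000, long_len=2000),
        ]
        kept, decisions = purge_assembly(contigs, summaries)
        assert [c.id for c in kept] == ["A", "C"]
        assert [d.removed_id for d in decisions if not d.restored] == ["B"]

    def test_never_removes_both_members(self):
        contigs = self.contigs([("L", 2000), ("S", 1900)])
        summaries = [
            summary("S", "L", 0.9, 0.95, short_len=1900, long_len=2000),
            summary("S", "L", 0.95, 0.95, short_len=1900, long_len=2000),
        ]
        kept, decisions = purge_assembly(contigs, summaries)
        removed = {d.removed_id for d in decisions if not d.restored}
        assert removed == {"S"} and [c.id for c in kept] == ["L"]

    def test_length_conservation(self):
        contigs = self.contigs([("A", 3000), ("B", 2000), ("C", 1000)])
        summaries = [summary("B", "A", 0.9, 0.95, short_len=2000, long_len=3000)]
        kept, decisions = purge_assembly(contigs, summaries)
        removed_len = sum(
            2000 for d in decisions if not d.restored
        )
        assert sum(len(c) for c in kept) + removed_len == 6000

    def test_operator_restore_list(self):
        contigs = self.contigs([("L", 2000), ("S", 1000)])
        kept, _ = purge_assembly(contigs, [summary("S", "L", 0.9, 0.95)],
                                 restore_ids=["S"])
        assert {c.id for c in kept} == {"L", "S"}

    def test_unknown_restore_id_warns_not_errors(self, caplog):
        contigs = self.contigs([("L", 2000)])
        with caplog.at_level("WARNING"):
            purge_assembly(contigs, [], restore_ids=["ghost"])
        assert "never removed" in caplog.text

    def test_dotplot_export(self, tmp_path):
        contigs = self.contigs([("L", 2000), ("S", 1000)])
        s = summary("S", "L", 0.9, 0.95)
        s.chains = [Chain.from_blocks([blk(0, 900, 0, 900)])]
        purge_assembly(contigs, [s], dotplot_dir=str(tmp_path))
        out = tmp_path / "S__L.tsv"
        assert out.exists() and "q_start" in out.read_text()


class TestFilterMitochondrial:
    def hit(self, qs, qe, evalue, cid="c1"):
        return AlignmentBlock(cid, "mito_ref", qs, qe, qs, qe, "+",
                              qe - qs, 1.0, float(qe - qs), evalue, "blast6")

    def test_covered_and_significant_flagged(self):
        flagged = filter_mitochondrial([self.hit(0, 850, 1e-10)], {"c1": 1000})
        assert flagged == ["c1"]

    def test_coverage_below_threshold(self):
        assert filter_mitochondrial([self.hit(0, 700, 1e-10)], {"c1": 1000}) == []

    def test_weak_evalue_ignored(self):
        assert filter_mitochondrial([self.hit(0, 850, 1e-3)], {"c1": 1000}) == []

    def test_missing_evalue_rejected(self):
        b = AlignmentBlock("c1", "m", 0, 850, 0, 850, "+", 850, 1.0, 850.0, None)
        with pytest.raises(ValidationError, match="E-value"):
            filter_mitochondrial([b], {"c1": 1000})


class TestFilterContaminants:
    def ann(self, cid="c", cov=50.0, taxon="Arthropoda", tr=False, bu=False):
        return ContigAnnotation(cid, 1000, 0.35, cov, taxon,
                                has_transcript_evidence=tr, has_busco_gene=bu)

    def test_low_coverage_discarded(self):
        (v,) = filter_contaminants([self.ann(cov=5)])
        assert not v.keep and v.rule == "low_coverage"

    def test_foreign_without_evidence_discarded(self):
        (v,) = filter_contaminants([self.ann(taxon="Bacteria")])
        assert not v.keep and v.rule == "foreign_no_evidence"

    def test_busco_evidence_rescues(self):
        (v,) = filter_contaminants([self.ann(taxon="Bacteria", bu=True)])
        assert v.keep

    def test_transcript_evidence_rescues(self):
        (v,) = filter_contaminants([self.ann(taxon="Bacteria", tr=True)])
        assert v.keep

    def test_no_hit_treated_as_in_clade(self):
        (v,) = filter_contaminants([self.ann(taxon=None)])
        assert v.keep
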