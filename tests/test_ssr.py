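"""SSR detection vs a regex oracle, compound fusion, marker criteria."""

import re

import numpy as np
import pytest

from asmcurate.config import DEFAULT_SSR_MIN_UNITS, PipelineConfig
from asmcurate.core import Interval, SeqRecord, revcomp
from asmcurate.ssr import (
    canonical_motif,
    find_compound_ssrs,
    find_ssrs,
    motif_frequency_table,
    select_markers,
)
from conftest import random_dna


def regex_ssr_oracle(seq, min_units=DEFAULT_SSR_MIN_UNITS, max_unit_len=7):
    """Independent SSR finder: lookahead regex per unit length (finds
    overlapping runs too), left-maximality and periodicity filtered."""
    found = []
    for p in range(1, max_unit_len + 1):
        for m in re.finditer(rf"(?=(([ACGT]{{{p}}})\2+))", seq):
            i, rep, motif = m.start(), m.group(1), m.group(2)
            if i >= 1 and seq[i - 1] in "ACGT" and seq[i - 1] == seq[i - 1 + p]:
                continue  # not left-maximal: part of an earlier run
            n = len(rep) // p
            if n < min_units[p]:
                continue
            if any(motif == motif[:q] * (p // q) + motif[: p % q]
                   for q in range(1, p)):
                continue  # motif itself periodic: belongs to a smaller unit
            found.append((i, i + n * p, motif, n))
    return sorted(found)


class TestFindSsrs:
    def test_mono_threshold(self):
        loci = find_ssrs([SeqRecord("c", "GC" + "A" * 10 + "GC")])
        (L,) = loci
        assert (L.start, L.end, L.motif, L.n_units) == (2, 12, "A", 10)

    def test_di_below_threshold_absent(self):
        assert find_ssrs([SeqRecord("c", "G" + "AC" * 5 + "G")]) == []

    def test_tri_at_threshold(self):
        loci = find_ssrs([SeqRecord("c", "CC" + "AGT" * 5 + "CC")])
        (L,) = loci
        assert (L.motif, L.n_units, L.unit_len) == ("AGT", 5, 3)
        assert L.canonical_motif == canonical_motif("AGT")

    def test_periodic_motif_reported_at_smallest_period(self):
        # (AT)x8 must not also be reported as (ATAT)x4
        loci = find_ssrs([SeqRecord("c", "GG" + "AT" * 8 + "GG")])
        assert [(L.unit_len, L.n_units) for L in loci] == [(2, 8)]

    def test_n_terminates_runs(self):
        loci = find_ssrs([SeqRecord("c", "A" * 6 + "N" + "A" * 6)])
        assert loci == []  # neither side reaches 10 units

    def test_partial_unit_not_counted(self):
        # (AC)x6 plus a trailing A: locus ends at the last whole unit
        loci = find_ssrs([SeqRecord("c", "GG" + "AC" * 6 + "A" + "GG")])
        (L,) = loci
        assert (L.start, L.end, L.n_units) == (2, 14, 6)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_regex_oracle_on_random_sequence(self, trial):
        rng = np.random.default_rng(7000 + trial)
        # low-entropy alphabet mix makes repeats common enough to exercise
        seq = "".join(
            random_dna(rng, 50, gc=0.2) + "AT" * int(rng.integers(0, 9))
            + random_dna(rng, 30) + "AAT" * int(rng.integers(0, 7))
            + "A" * int(rng.integers(0, 14))
            for _ in range(10)
        )
        got = sorted(
            (L.start, L.end, L.motif, L.n_units)
            for L in find_ssrs([SeqRecord("c", seq)])
        )
        assert got == regex_ssr_oracle(seq)


class TestCompoundSsrs:
    def ssr(self, start, motif, n, cid="c"):
        p = len(motif)
        from asmcurate.ssr import SSRLocus

        return SSRLocus(cid, start, start + p * n, motif, canonical_motif(motif), p, n)

    def test_nearby_ssrs_fused(self):
        a, b = self.ssr(0, "AC", 6), self.ssr(22, "AG", 6)
        compounds, surviving = find_compound_ssrs([a, b], max_interruption=100)
        assert surviving == []
        (comp,) = compounds
        assert (comp.start, comp.end) == (0, 34)
        assert comp.kind == "compound" and len(comp.members) == 2

    def test_distant_ssrs_stay_perfect(self):
        a, b = self.ssr(0, "AC", 6), self.ssr(200, "AG", 6)
        compounds, surviving = find_compound_ssrs([a, b], max_interruption=100)
        assert compounds == [] and len(surviving) == 2

    def test_transitive_fusion(self):
        loci = [self.ssr(0, "AC", 6), self.ssr(50, "AG", 6), self.ssr(110, "AAT", 5)]
        compounds, surviving = find_compound_ssrs(loci, max_interruption=100)
        (comp,) = compounds
        assert len(comp.members) == 3 and surviving == []


class TestSelectMarkers:
    def build_assembly(self, rng, motif="AC", n=6, mask=(), duplicate_flank=False):
        flank5 = random_dna(rng, 3000)
        flank3 = random_dna(rng, 3000)
        seq = flank5 + motif * n + flank3
        contigs = [SeqRecord("c1", seq), SeqRecord("c2", random_dna(rng, 2000))]
        if duplicate_flank:
            dup = seq[3000 - 200 : 3000]  # the 5' flank, copied elsewhere
            contigs[1] = SeqRecord("c2", random_dna(rng, 1000) + dup + random_dna(rng, 800))
        return contigs

    def markers(self, contigs, mask=()):
        loci = find_ssrs(contigs)
        return select_markers(loci, contigs, mask)

    def test_clean_locus_selected(self, rng):
        contigs = self.build_assembly(rng)
        (m,) = self.markers(contigs)
        assert m.selected and all(m.criteria.values())
        assert len(m.flank5) == len(m.flank3) == 200

    def test_mono_repeat_fails_criterion_i(self, rng):
        contigs = self.build_assembly(rng, motif="A", n=12)
        (m,) = self.markers(contigs)
        assert not m.criteria["perfect_min_units"] and not m.selected

    def test_nearby_ssr_fails_flank_window(self, rng):
        flank = random_dna(rng, 2500)
        seq = flank + "AC" * 6 + random_dna(rng, 1000) + "AG" * 6 + random_dna(rng, 2500)
        contigs = [SeqRecord("c1", seq)]
        ms = self.markers(contigs)
        assert len(ms) == 2
        assert all(not m.criteria["flank_ssr_free"] for m in ms)

    def test_repeat_mask_fails_criterion_iii(self, rng):
        contigs = self.build_assembly(rng)
        (L,) = find_ssrs(contigs)
        mask = [Interval("c1", L.start - 5, L.start + 5)]
        (m,) = select_markers([L], contigs, mask)
        assert not m.criteria["outside_repeat"] and not m.selected

    def test_mask_removal_is_monotone(self, rng):
        contigs = self.build_assembly(rng)
        (L,) = find_ssrs(contigs)
        with_mask = select_markers([L], contigs, [Interval("c1", L.start, L.end)])
        without = select_markers([L], contigs, [])
        assert sum(m.selected for m in without) >= sum(m.selected for m in with_mask)

    def test_duplicated_flank_fails_uniqueness(self, rng):
        contigs = self.build_assembly(rng, duplicate_flank=True)
        ms = [m for m in self.markers(contigs) if m.locus.contig_id == "c1"]
        (m,) = ms
        assert not m.criteria["flanks_unique"] and not m.selected

    def test_contig_edge_truncated_flank_fails(self, rng):
        seq = "AC" * 6 + random_dna(rng, 3000)  # no 5' flank at all
        (m,) = self.markers([SeqRecord("c1", seq)])
        assert not m.criteria["flanks_unique"]


class TestMotifFrequency:
    def ssr(self, motif, n, start=0):
        from asmcurate.ssr import SSRLocus

        p = len(motif)
        return SSRLocus("c", start, start + p * n, motif, canonical_motif(motif), p, n)

    def test_most_frequent_type(self):
        loci = [self.ssr("AAT", 5), self.ssr("AAT", 5, 100), self.ssr("AC", 6, 200)]
        counts, best = motif_frequency_table(loci)
        assert best == (canonical_motif("AAT"), 5)
        assert counts[canonical_motif("AAT")] == 2

    def test_empty(self):
        counts, best = motif_frequency_table([])
        assert counts == {} and best is None

    def test_rotation_and_revcomp_pooling(self):
        loci = [self.ssr("AT", 6), self.ssr("TA", 6, 100)]
        counts, _ = motif_frequency_table(loci)
        assert counts == {canonical_motif("AT"): 2}

    def test_canonical_motif_examples(self):
        assert canonical_motif("AT") == canonical_motif("TA")
        assert canonical_motif("AAT") == canonical_motif("TAT") == canonical_motif("ATT")
        assert canonical_motif("AGT") == min(
            "AGT", "GTA", "TAG", revcomp("AGT"),
            revcomp("AGT")[1:] + revcomp("AGT")[:1],
            revcomp("AGT")[2:] + revcomp("AGT")[:2],
        )
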