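"""Five-way allele classification, editing metrics and founder triage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abequant.align import orient_and_align
from abequant.classify import (
    AlleleClassCounts,
    EditingMetrics,
    QuantTable,
    TriageThresholds,
    classify_read,
    compute_metrics,
    founder_triage,
    tally,
    to_quant_table,
)

from conftest import perfect_read, read_with_deletion


def classify(locus, edits=None, **kw):
    return classify_read(orient_and_align(perfect_read(locus, edits, **kw), locus), locus)


class TestClassifyRead:
    def test_wild_type(self, toy_locus):
        assert classify(toy_locus) == "wt"

    def test_desired_only(self, toy_locus):
        a5 = toy_locus.spacer_start + 4
        assert classify(toy_locus, {a5: "G"}) == "desired_only"

    def test_desired_plus_bystander(self, toy_locus):
        s = toy_locus.spacer_start
        assert classify(toy_locus, {s + 4: "G", s + 3: "G"}) == "desired_bystander"

    def test_bystander_only(self, toy_locus):
        s = toy_locus.spacer_start
        assert classify(toy_locus, {s + 3: "G"}) == "bystander_only"

    def test_partial_desired_set_is_bystander_only(self, two_target_locus):
        # editing one of two targeted adenines gives a different missense
        # change than intended, so a partially-desired read is NOT perfect
        s = two_target_locus.spacer_start
        assert classify(two_target_locus, {s + 4: "G"}) == "bystander_only"
        assert classify(two_target_locus, {s + 4: "G", s + 5: "G"}) == "desired_only"

    def test_indel_overrides_desired(self, toy_locus):
        read = read_with_deletion(toy_locus, toy_locus.spacer_start + 8, 2)
        read.seq = (
            read.seq[: toy_locus.spacer_start + 4] + "G" + read.seq[toy_locus.spacer_start + 5 :]
        )
        assert classify_read(orient_and_align(read, toy_locus), toy_locus) == "indel"

    def test_short_read_excluded(self, toy_locus):
        assert classify(toy_locus, trim=35) == "short_read"

    def test_substitution_outside_window_ignored(self, toy_locus):
        win_start, _ = toy_locus.quant_window()
        assert win_start > 2
        assert classify(toy_locus, {1: "G" if toy_locus.reference[1] != "G" else "C"}) == "wt"


class TestClassifierOracle:
    def test_all_patterns_match_literal_rules(self, toy_locus):
        """Exhaustive: every substitution pattern over the 5 variable adenines
        × every non-empty desired-set choice matches the rule-by-rule oracle."""
        from itertools import chain, combinations

        from abequant.loci import AmpliconLocus
        from oracles import classify_literal

        var_proto = [4, 5, 6, 9, 12]  # adenines in the fixture spacer
        ref = toy_locus.reference
        start = toy_locus.spacer_start
        subsets = list(
            chain.from_iterable(combinations(var_proto, r) for r in range(len(var_proto) + 1))
        )
        for desired in subsets[1:]:  # non-empty desired sets
            locus = AmpliconLocus(
                "o", ref, toy_locus.spacer, start, "TGG",
                frozenset((p, "A", "G") for p in desired),
            )
            desired_ref = frozenset((start + p - 1, "G") for p in desired)
            for pattern in subsets:
                edits = {start + p - 1: "G" for p in pattern}
                got = classify_read(orient_and_align(perfect_read(locus, edits), locus), locus)
                subs = frozenset((start + p - 1, "G") for p in pattern)
                expected = classify_literal(subs, desired_ref, True, False)
                assert got == expected, (desired, pattern)


class TestTallyAndTable:
    def make_counts(self):
        return AlleleClassCounts(
            total_aligned=1000, wt=530, desired_only=300, desired_bystander=100,
            bystander_only=50, indel=20, short_reads_excluded=0,
        )

    def test_tally_bookkeeping(self, toy_locus):
        s = toy_locus.spacer_start
        reads = (
            [perfect_read(toy_locus)] * 5
            + [perfect_read(toy_locus, {s + 4: "G"})] * 3
            + [perfect_read(toy_locus, {s + 4: "G", s + 3: "G"})] * 2
            + [read_with_deletion(toy_locus, s + 8, 1)]
        )
        counts = tally([orient_and_align(r, toy_locus) for r in reads], toy_locus)
        assert counts.total_aligned == 11
        assert (counts.wt, counts.desired_only, counts.desired_bystander, counts.indel) == (5, 3, 2, 1)

    def test_empty_and_all_wt(self, toy_locus):
        empty = tally([], toy_locus)
        assert empty.total_aligned == 0
        allwt = tally([orient_and_align(perfect_read(toy_locus), toy_locus)] * 4, toy_locus)
        assert allwt.wt == allwt.total_aligned == 4

    def test_conservation_enforced(self):
        with pytest.raises(ValueError):
            AlleleClassCounts(total_aligned=10, wt=5)

    def test_quant_table_mapping(self):
        qt = to_quant_table(self.make_counts())
        assert qt == QuantTable(
            Reads_aligned_all_amplicons=1000, Reads_aligned=400,
            Unmodified=300, Modified=100, Discarded=20,
        )

    def test_zero_and_no_bystander_cases(self):
        zero = to_quant_table(AlleleClassCounts())
        assert zero.Reads_aligned_all_amplicons == 0
        nobys = to_quant_table(
            AlleleClassCounts(total_aligned=10, wt=5, desired_only=5)
        )
        assert nobys.Modified == 0 and nobys.Reads_aligned == nobys.Unmodified


class TestMetrics:
    def test_reference_arithmetic(self):
        qt = QuantTable(1000, 400, 300, 100, 20)
        m = compute_metrics(qt)
        assert m.specified_incl_bystanders_pct == pytest.approx(40.0)
        assert m.specified_without_bystanders_pct == pytest.approx(30.0)
        assert m.purity_pct == pytest.approx(75.0)
        assert m.indels_pct == pytest.approx(2.0)

    def test_no_edited_reads_purity_unavailable(self):
        m = compute_metrics(QuantTable(100, 0, 0, 0, 0))
        assert m.specified_incl_bystanders_pct == 0.0
        assert m.purity_pct is None

    def test_no_bystanders_purity_100(self):
        m = compute_metrics(QuantTable(100, 40, 40, 0, 0))
        assert m.purity_pct == pytest.approx(100.0)

    def test_total_zero_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics(QuantTable(0, 0, 0, 0, 0))

    def test_purity_identity_on_random_tallies(self):
        """purity ≡ 100·(without bystanders)/(incl. bystanders) over random tallies."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            unmod, mod, disc, wt = (int(x) for x in rng.integers(0, 500, 4))
            if unmod + mod == 0:
                continue
            total = unmod + mod + disc + wt
            qt = QuantTable(total, unmod + mod, unmod, mod, disc)
            m = compute_metrics(qt)
            assert m.purity_pct == pytest.approx(
                100.0 * m.specified_without_bystanders_pct / m.specified_incl_bystanders_pct
            )
            # exact integer identity before rounding
            assert m.purity_pct * qt.Reads_aligned == pytest.approx(100.0 * qt.Unmodified)
            assert m.specified_incl_bystanders_pct - m.specified_without_bystanders_pct == (
                pytest.approx(100.0 * qt.Modified / total)
            )


class TestTriage:
    def counts(self, total, desired_only, desired_bystander=0, bystander_only=0, indel=0):
        wt = total - desired_only - desired_bystander - bystander_only - indel
        return AlleleClassCounts(
            total_aligned=total, wt=wt, desired_only=desired_only,
            desired_bystander=desired_bystander, bystander_only=bystander_only, indel=indel,
        )

    def call(self, counts, **kw):
        m = compute_metrics(to_quant_table(counts))
        return founder_triage(m, counts, TriageThresholds(**kw))

    def test_clean_founder_high_confidence(self):
        assert self.call(self.counts(1000, 261, indel=10)) == "high_confidence"

    def test_below_desired_threshold(self):
        assert self.call(self.counts(1000, 199)) == "not_high_confidence"

    def test_unwanted_above_threshold(self):
        assert self.call(self.counts(1000, 500, bystander_only=26)) == "not_high_confidence"

    def test_unwanted_at_threshold_inclusive_vs_strict(self):
        c = self.counts(1000, 500, bystander_only=25)  # exactly 2.5%
        assert self.call(c) == "high_confidence"
        assert self.call(c, unwanted_inclusive=False) == "not_high_confidence"

    @given(
        desired=st.integers(min_value=0, max_value=900),
        unwanted=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_desired_only(self, desired, unwanted):
        """More desired-only reads at fixed unwanted reads never flips a
        high-confidence call to not-high-confidence."""
        total = 1000
        if desired + unwanted > total - 10:
            return
        c1 = self.counts(total, desired, bystander_only=unwanted)
        c2 = self.counts(total, desired + 10, bystander_only=unwanted)
        if self.call(c1) == "high_confidence":
            assert self.call(c2) == "high_confidence"
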