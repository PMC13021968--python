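"""Gated two-group tests, replication, intersection, rescue and epistasis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from danscreen.errors import InsufficientDataError, ValidationError
from danscreen.examples import (
    REPLICATED_GENES,
    SA_KD_DOWN_GENES,
    SMC1_KD_DOWN_GENES,
)
from danscreen.triage import (
    STAGE_FLAGS,
    GroupComparison,
    StageLedger,
    classify_epistasis,
    classify_rescue,
    intersect_candidates,
    replication_gate,
    two_group_test,
)


class TestTwoGroupTest:
    def test_identical_samples_maximally_nonsignificant(self):
        res = two_group_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0
        assert res.direction == 0

    def test_clear_shift_selects_t_and_rejects(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = rng.normal(3, 1, 10)
        res = two_group_test(a, b)
        assert res.test_used == "students_t"
        assert res.p_value < 1e-3
        assert res.direction == 1

    def test_outliers_switch_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 12)
        b = np.concatenate([rng.normal(0, 1, 10), [40.0, 55.0]])  # fails Shapiro
        res = two_group_test(a, b)
        assert res.test_used == "mann_whitney"

    def test_force_overrides_gating(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 10)
        b = np.concatenate([rng.normal(0, 1, 8), [30.0, 50.0]])
        assert two_group_test(a, b, force="students_t").test_used == "students_t"

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_group_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_unknown_force_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1, 2, 3], [1, 2, 3], force="anova")


class TestReplicationGate:
    def _cmp(self, p, direction):
        return GroupComparison("students_t", p, direction, 10, 10, 0.0)

    def test_both_significant_correct_direction_passes(self):
        assert replication_gate(self._cmp(0.01, 1), self._cmp(0.02, 1), 1)

    def test_one_nonsignificant_fails(self):
        assert not replication_gate(self._cmp(0.01, 1), self._cmp(0.3, 1), 1)

    def test_wrong_direction_fails(self):
        assert not replication_gate(self._cmp(0.01, -1), self._cmp(0.01, 1), 1)

    def test_expected_direction_validated(self):
        with pytest.raises(ValueError):
            replication_gate(self._cmp(0.01, 1), self._cmp(0.01, 1), 0)


class TestIntersectCandidates:
    def test_any_empty_set_gives_empty(self):
        assert intersect_candidates([], ["a"], ["a"]) == set()
        assert intersect_candidates(["a"], [], ["a"]) == set()

    def test_published_sets_single_out_nep1(self):
        final = intersect_candidates(
            REPLICATED_GENES, SA_KD_DOWN_GENES, SMC1_KD_DOWN_GENES
        )
        assert final == {"Nep1"}

    @given(
        st.sets(st.sampled_from("abcdefgh")),
        st.sets(st.sampled_from("abcdefgh")),
        st.sets(st.sampled_from("abcdefgh")),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_membership_scan(self, r, s, m):
        got = intersect_candidates(r, s, m)
        brute = {g for g in r | s | m if g in r and g in s and g in m}
        assert got == brute
        # commutative in its set arguments
        assert got == intersect_candidates(s, m, r) == intersect_candidates(m, r, s)


class TestClassifiers:
    def _groups(self, means, n=10, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        return [rng.normal(m, sd, n) for m in means]

    def test_full_rescue(self):
        # rescue genotype drawn from the control distribution; kd shifted +2 SD
        control, kd, oe, kd_oe = self._groups([0.0, 2.0, 0.0, 0.0], seed=1)
        assert classify_rescue(control, kd, oe, kd_oe) == "full_rescue"

    def test_partial_rescue(self):
        control, kd, oe, kd_oe = self._groups([0.0, 4.0, 0.0, 2.0], n=20, seed=2)
        assert classify_rescue(control, kd, oe, kd_oe) == "partial_rescue"

    def test_no_rescue_when_rescue_equals_kd(self):
        control, kd, oe, _ = self._groups([0.0, 3.0, 0.0, 3.0], seed=3)
        assert classify_rescue(control, kd, oe, kd) == "no_rescue"

    def test_same_pathway_epistasis(self):
        control, a, b, double = self._groups([0.0, 2.5, 2.5, 2.5], seed=4)
        assert classify_epistasis(control, a, b, double) == "same_pathway"

    def test_additive_epistasis(self):
        control, a, b, double = self._groups([0.0, 2.0, 2.0, 4.0], n=20, seed=5)
        assert classify_epistasis(control, a, b, double) == "additive"

    def test_all_identical_is_other(self):
        g = self._groups([0.0], seed=6)[0]
        assert classify_epistasis(g, g, g, g) == "other"

    def test_kruskal_dunn_backend_agrees_on_strong_effects(self):
        control, kd, oe, kd_oe = self._groups([0.0, 3.0, 0.0, 0.0], n=15, seed=7)
        assert classify_rescue(control, kd, oe, kd_oe, method="kruskal_dunn") == "full_rescue"

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_rescue([1.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestStageLedger:
    def test_monotone_chain_enforced(self):
        led = StageLedger(["g1"])
        led.set_flag("g1", "replicated")
        with pytest.raises(ValidationError, match="prerequisite"):
            led.validate()

    def test_finalize_requires_all_three_inputs(self):
        led = StageLedger(["g1", "g2"])
        for g in ("g1", "g2"):
            for f in STAGE_FLAGS[:7]:
                led.set_flag(g, f)
        led.set_flag("g1", "sa_kd_downregulated")
        led.set_flag("g1", "smc1_kd_downregulated")
        led.finalize()
        assert led.genes_with("final_candidate") == {"g1"}

    def test_unknown_gene_or_flag_rejected(self):
        led = StageLedger(["g1"])
        with pytest.raises(ValidationError):
            led.set_flag("gx", "in_catalog")
        with pytest.raises(ValidationError):
            led.set_flag("g1", "not_a_flag")

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotonicity_on_random_prefix_flags(self, data):
        # setting any prefix of the chain is always valid; finalize keeps it so
        led = StageLedger(["g1", "g2", "g3"])
        for g in led.gene_ids:
            k = data.draw(st.integers(0, 7))
            for f in STAGE_FLAGS[:k]:
                led.set_flag(g, f)
            if data.draw(st.booleans()) and k >= 4:
                led.set_flag(g, "sa_kd_downregulated")
            if data.draw(st.booleans()) and k >= 4:
                led.set_flag(g, "smc1_kd_downregulated")
        led.finalize()  # must not raise
        counts = led.stage_counts()
        assert counts["final_candidate"] <= counts["replicated"]
        assert counts["replicated"] <= counts["secondary_concordant"]
        assert counts["secondary_concordant"] <= counts["primary_concordant"]
        assert counts["primary_concordant"] <= counts["tested_primary"] <= counts["in_catalog"]

    def test_tsv_round_trip(self, tmp_path):
        led = StageLedger(["g1"])
        led.set_flag("g1", "in_catalog")
        p = tmp_path / "ledger.tsv"
        led.to_tsv(p)
        import pandas as pd

        back = pd.read_csv(p, sep="\t")
        assert bool(back.loc[0, "in_catalog"]) is True
        assert bool(back.loc[0, "final_candidate"]) is False
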