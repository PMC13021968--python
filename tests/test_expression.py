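"""Housekeeping normalization, expression ratios, and ΔΔCt fold changes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from danscreen.errors import MissingReferenceError, NormalizationError, ValidationError
from danscreen.expression import (
    CountPanel,
    QPCRRecord,
    ddct_fold,
    expression_ratio_and_test,
    housekeeping_normalize,
)

HK = ("hk1", "hk2")


def make_panel(counts, n_control=None, genes=("hk1", "hk2", "tgt")):
    counts = np.asarray(counts, dtype=float)
    n_samples = counts.shape[1]
    n_control = n_control if n_control is not None else n_samples // 2
    samples = [(f"s{j}", "control" if j < n_control else "kd") for j in range(n_samples)]
    return CountPanel(list(genes), samples, counts, HK)


class TestHousekeepingNormalize:
    def test_identical_samples_are_unchanged(self):
        col = [100.0, 400.0, 50.0]
        panel = make_panel(np.column_stack([col, col, col, col]))
        out = housekeeping_normalize(panel)
        assert np.allclose(out, panel.counts)

    def test_factor_two_sample_closed_form(self):
        # sample B = 2 x sample A: scale factors are sqrt(2) and 1/sqrt(2),
        # and the normalized columns coincide
        a = np.array([100.0, 400.0, 50.0])
        panel = make_panel(np.column_stack([a, 2 * a]), n_control=1)
        out = housekeeping_normalize(panel)
        assert np.allclose(out[:, 0], a * np.sqrt(2.0))
        assert np.allclose(out[:, 0], out[:, 1])

    def test_zero_housekeeping_count_names_gene_and_sample(self):
        panel = make_panel([[100.0, 0.0], [400.0, 400.0], [50.0, 50.0]], n_control=1)
        with pytest.raises(NormalizationError, match="hk1.*s1"):
            housekeeping_normalize(panel)

    def test_housekeeping_geometric_means_equalized(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.uniform(10, 1000, size=(3, 6)))
        out = housekeeping_normalize(panel)
        gms = np.exp(np.mean(np.log(out[:2, :]), axis=0))
        assert np.allclose(gms, gms[0])

    @given(st.floats(0.1, 10.0), st.integers(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_gain_invariance_per_sample(self, gain, which):
        # rescaling one raw sample is absorbed: relative expression is
        # exactly invariant (the grand-mean anchor shifts by gain**(1/n),
        # a common factor on the whole matrix)
        rng = np.random.default_rng(7)
        counts = rng.uniform(10, 1000, size=(3, 4))
        base = housekeeping_normalize(make_panel(counts))
        scaled = counts.copy()
        scaled[:, which] *= gain
        out = housekeeping_normalize(make_panel(scaled))
        assert np.allclose(out / out[0, 0], base / base[0, 0])
        assert np.allclose(out, base * gain ** (1.0 / 4.0))


class TestExpressionRatio:
    def test_identical_groups_ratio_one_not_significant(self):
        col = [100.0, 400.0, 50.0]
        panel = make_panel(np.column_stack([col] * 6))
        res = expression_ratio_and_test(panel, "tgt", rnaseq_log2fc=-1.0)
        assert res.expression_ratio == pytest.approx(1.0)
        assert not res.significant

    def test_planted_twofold_reduction_recovered(self):
        rng = np.random.default_rng(11)
        hk = np.array([1000.0, 2000.0])
        rows = []
        for mean_tgt in [(400.0, 200.0)]:  # control mean, kd mean
            ctrl = [np.append(hk, mean_tgt[0]) * rng.normal(1, 0.05, 3) for _ in range(3)]
            kd = [np.append(hk, mean_tgt[1]) * rng.normal(1, 0.05, 3) for _ in range(3)]
        panel = make_panel(np.column_stack(ctrl + kd), n_control=3)
        res = expression_ratio_and_test(panel, "tgt", rnaseq_log2fc=-1.2)
        assert res.expression_ratio == pytest.approx(0.5, rel=0.15)
        assert res.significant
        assert res.concordant_with_rnaseq

    def test_missing_gene_rejected(self):
        panel = make_panel(np.ones((3, 4)) * 10)
        with pytest.raises(ValidationError):
            expression_ratio_and_test(panel, "nope")

    def test_library_size_absorbed_by_normalization(self):
        # doubling an entire kd sample (genes + housekeeping) leaves the
        # ratio unchanged
        col = np.array([100.0, 400.0, 50.0])
        counts = np.column_stack([col, col, col * 0.5, col * 0.5])
        panel = make_panel(counts)
        r0 = expression_ratio_and_test(panel, "tgt").expression_ratio
        counts2 = counts.copy()
        counts2[:, 3] *= 2.0
        r1 = expression_ratio_and_test(make_panel(counts2), "tgt").expression_ratio
        assert r1 == pytest.approx(r0)


class TestDdctFold:
    def _rec(self, sid, group, ct_t, ct_h):
        return QPCRRecord(sid, group, (ct_t,) * 3, (ct_h,) * 3)

    def test_equal_delta_ct_gives_fold_one(self):
        recs = [self._rec("c", "control", 20.0, 15.0), self._rec("k", "kd", 22.0, 17.0)]
        out = ddct_fold(recs)
        assert out.loc[out["group"] == "kd", "fold"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_doubling_law(self):
        recs = [self._rec("c", "control", 20.0, 15.0), self._rec("k", "kd", 21.0, 15.0)]
        out = ddct_fold(recs)
        assert out.loc[out["group"] == "kd", "fold"].iloc[0] == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        recs = [self._rec("c", "control", 20.0, 15.0), self._rec("k", "kd", 22.0, 15.5)]
        out = ddct_fold(recs)
        # ddCt = (22 - 15.5) - (20 - 15) = 1.5 -> 2^-1.5
        assert out.loc[out["group"] == "kd", "fold"].iloc[0] == pytest.approx(2 ** -1.5)

    def test_single_control_sample_has_fold_exactly_one(self):
        recs = [self._rec("c", "control", 20.0, 15.0), self._rec("k", "kd", 25.0, 15.0)]
        out = ddct_fold(recs)
        assert out.loc[out["group"] == "control", "fold"].iloc[0] == pytest.approx(1.0)

    def test_no_control_is_a_reference_error(self):
        with pytest.raises(MissingReferenceError):
            ddct_fold([self._rec("k", "kd", 22.0, 15.0)])

    @given(st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_law(self, ddct):
        # folds at +ddct and -ddct multiply to 1
        assert 2.0 ** (-ddct) * 2.0 ** (ddct) == pytest.approx(1.0)
        recs_plus = [
            self._rec("c", "control", 20.0, 15.0),
            self._rec("k", "kd", 20.0 + ddct, 15.0),
        ]
        recs_minus = [
            self._rec("c", "control", 20.0, 15.0),
            self._rec("k", "kd", 20.0 - ddct, 15.0),
        ]
        f_plus = ddct_fold(recs_plus).query("group == 'kd'")["fold"].iloc[0]
        f_minus = ddct_fold(recs_minus).query("group == 'kd'")["fold"].iloc[0]
        assert f_plus * f_minus == pytest.approx(1.0)


def test_ratio_parameter_recovery_at_low_cv():
    """Median estimated ratio within 10% of truth: n = 4/group, CV 10%."""
    rng = np.random.default_rng(2024)
    hk = np.array([1000.0, 2000.0])
    for true_ratio in (0.25, 0.5, 1.0, 2.0):
        est = []
        for _ in range(100):
            cols = []
            for grp, scale in (("control", 1.0), ("kd", true_ratio)):
                for _ in range(4):
                    size = rng.lognormal(0, 0.2)
                    noise = rng.normal(1, 0.1, 3)
                    cols.append(np.append(hk, 500.0 * scale) * size * noise)
            panel = make_panel(np.column_stack(cols), n_control=4)
            est.append(expression_ratio_and_test(panel, "tgt").expression_ratio)
        assert abs(np.median(est) - true_ratio) <= 0.1 * true_ratio
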