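"""Agreement statistics: ICC, observer SD, Bland-Altman, Wilcoxon, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mpsquant as mq
from mpsquant.agreement import _two_way_mean_squares


class TestColumnSummary:
    def test_basic_statistics(self):
        s = mq.column_summary([1.0, 2.0, 3.0, 4.0])
        assert s.mean == 2.5 and s.median == 2.5
        assert s.min == 1.0 and s.max == 4.0
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_odd_median_is_middle_order_statistic(self):
        assert mq.column_summary([5, 1, 9]).median == 5.0

    def test_single_value_degenerate(self):
        s = mq.column_summary([7.0])
        assert s.mean == 7.0 and s.median == 7.0 and s.sd == 0.0
        assert s.degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mq.column_summary([])


def _anova_oracle(v):
    """Hand mean-squares ICC(2,1) oracle, written out long-form."""
    n, k = v.shape
    gm = v.mean()
    msr = k * sum((v[i].mean() - gm) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((v[:, j].mean() - gm) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (v[i, j] - v[i].mean() - v[:, j].mean() + gm) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_observers_gives_one(self):
        v = np.tile(np.array([[10.0], [20.0], [35.0], [5.0]]), (1, 3))
        res = mq.icc_two_way_random(mq.RaterPanel(values=v))
        assert res.icc == pytest.approx(1.0)
        assert res.var_observer == 0.0 and res.var_error == 0.0

    def test_constant_panel_flagged_degenerate(self):
        res = mq.icc_two_way_random(mq.RaterPanel(values=np.full((4, 3), 9.0)))
        assert res.icc == 1.0 and res.degenerate
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_hand_matrix_matches_mean_squares_oracle(self):
        v = np.array([
            [9.0, 2.0, 5.0],
            [6.0, 1.0, 3.0],
            [8.0, 4.0, 6.0],
            [7.0, 1.0, 2.0],
        ])
        res = mq.icc_two_way_random(mq.RaterPanel(values=v))
        assert res.icc == pytest.approx(_anova_oracle(v), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_pingouin_icc2_with_ci(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(6, 15)), int(rng.integers(3, 6))
        # real patient and rater signal keeps every variance component
        # positive, away from the truncation edge handled elsewhere (our
        # estimator clips negative components; pingouin does not)
        v = (rng.normal(0, 8, (n, 1)) + rng.normal(0, 5, (1, k))
             + rng.normal(0, 3, (n, k)) + 20.0)
        res = mq.icc_two_way_random(mq.RaterPanel(values=v))
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "scores": v.ravel(),
        })
        table = pg.intraclass_corr(long, targets="targets", raters="raters",
                                   ratings="scores").set_index("Type")
        # two-way random, absolute agreement, single rater
        icc2 = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
        assert res.icc == pytest.approx(icc2["ICC"], abs=1e-9)
        lo, hi = icc2["CI95"]  # pingouin prints the CI rounded to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=0.006)
        assert res.ci_high == pytest.approx(hi, abs=0.006)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_invariance_to_affine_rescaling(self, shift, scale):
        rng = np.random.default_rng(42)
        v = rng.normal(30, 10, (8, 4))
        base = mq.icc_two_way_random(mq.RaterPanel(values=v)).icc
        moved = mq.icc_two_way_random(mq.RaterPanel(values=scale * v + shift)).icc
        assert moved == pytest.approx(base, abs=1e-9)

    def test_added_noise_lowers_icc_in_expectation(self):
        spec = mq.RaterPanelSpec(60, 6, 15.0, 3.0, 3.0, grand_mean=50.0)
        deltas = []
        for seed in range(50):
            panel, _ = mq.simulate_rater_panel(spec, seed)
            clean = mq.icc_two_way_random(panel).icc
            rng = np.random.default_rng(10_000 + seed)
            noisy = mq.RaterPanel(values=panel.values
                                  + rng.normal(0, 6, panel.values.shape))
            deltas.append(mq.icc_two_way_random(noisy).icc - clean)
        assert np.mean(deltas) < 0

    def test_negative_components_truncated(self):
        # column-constant rows -> observer variance dominates, patient
        # component estimate can go negative and must be clipped to 0
        v = np.array([[1.0, 5.0, 9.0], [1.1, 5.2, 8.8], [0.9, 4.9, 9.1]])
        res = mq.icc_two_way_random(mq.RaterPanel(values=v))
        assert res.var_patient >= 0.0
        assert 0.0 <= res.icc <= 1.0


class TestBetweenObserverSD:
    def test_identical_observers_zero(self):
        v = np.tile(np.array([[10.0], [30.0], [20.0]]), (1, 4))
        assert mq.between_observer_sd(mq.RaterPanel(values=v)) == 0.0

    def test_pure_offsets_recovered_exactly(self):
        # observers offset by (-5, 0, +5), no residual error: the observer
        # variance component is 25 (population convention), so SD = 5
        patients = np.array([10.0, 22.0, 35.0, 18.0, 27.0])
        v = patients[:, None] + np.array([-5.0, 0.0, 5.0])[None, :]
        assert mq.between_observer_sd(mq.RaterPanel(values=v)) == pytest.approx(5.0)

    def test_observer_mean_sd_alternative_exposed(self):
        patients = np.array([10.0, 22.0, 35.0, 18.0, 27.0])
        v = patients[:, None] + np.array([-5.0, 0.0, 5.0])[None, :]
        assert mq.observer_mean_sd(mq.RaterPanel(values=v)) == pytest.approx(5.0)


class TestBlandAltman:
    def test_identical_methods(self):
        x = [5.0, 10.0, 20.0]
        res = mq.bland_altman(x, x)
        assert res.bias == 0.0 and res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([5.0, 10.0, 20.0, 40.0])
        res = mq.bland_altman(x, x + 3.0)
        assert res.bias == pytest.approx(3.0) and res.sd == 0.0

    def test_limits_arithmetic(self):
        res = mq.bland_altman([10.0, 10.0, 10.0], [8.0, 10.0, 12.0])
        assert res.bias == 0.0
        assert res.loa_high == pytest.approx(1.96 * 2.0)
        assert res.loa_low == pytest.approx(-1.96 * 2.0)

    def test_max_difference_boundary(self):
        res = mq.bland_altman([10.0, 90.0], [10.0, 90.0])
        # at mean 10 the difference cannot fall below -20; at mean 90,
        # below -(200 - 180) = -20
        np.testing.assert_allclose(res.max_diff_boundary, [-20.0, -20.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mq.bland_altman([1.0, 2.0], [1.0])

    @given(c=st.floats(-30, 30))
    def test_offset_property(self, c):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 60, 12)
        res = mq.bland_altman(x, x + c)
        assert res.bias == pytest.approx(c, abs=1e-9)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-7)


def _enumeration_oracle(d):
    """Brute-force two-sided exact p over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_samples_no_test(self):
        res = mq.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.mode == "no-test" and res.p_value == 1.0

    def test_five_positive_differences_exact(self):
        res = mq.wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1],
                                      mode="exact")
        assert res.p_value == pytest.approx(2 / 32)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.integers(0, 8, n).astype(float)
        y = rng.integers(0, 8, n).astype(float)
        if np.all(x == y):
            x[0] += 1
        res = mq.wilcoxon_signed_rank(x, y, mode="exact")
        assert res.p_value == pytest.approx(_enumeration_oracle(x - y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.permutation(np.arange(1, 13)) * rng.choice([-1, 1], 12)
        x = d.astype(float)
        y = np.zeros(12)
        res = mq.wilcoxon_signed_rank(x, y, mode="exact")
        ref = stats.wilcoxon(x, y, mode="exact", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_close_to_approx_at_n15(self, seed):
        rng = np.random.default_rng(200 + seed)
        x = rng.normal(0.3, 1.0, 15)
        y = np.zeros(15)
        p_exact = mq.wilcoxon_signed_rank(x, y, mode="exact").p_value
        p_approx = mq.wilcoxon_signed_rank(x, y, mode="approx").p_value
        assert abs(p_exact - p_approx) <= 0.02


class TestMethodContrast:
    @staticmethod
    def _long(values_by_method):
        rows = []
        for method, vals in values_by_method.items():
            for i, v in enumerate(vals):
                rows.append({"patient": i, "method": method, "value": v})
        return pd.DataFrame(rows)

    def test_constant_offset_contrast(self):
        a = np.array([10.0, 20.0, 30.0, 15.0, 25.0, 12.0])
        df = self._long({"A": a, "B": a + 5.0})
        (c,) = mq.method_contrast(df)
        assert c.mean_difference == pytest.approx(-5.0)
        assert c.p_value < 1e-6

    def test_permuted_deviations_zero_contrast(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        b = np.array([40.0, 10.0, 30.0, 20.0])  # same mean
        (c,) = mq.method_contrast(self._long({"A": a, "B": b}))
        assert c.mean_difference == pytest.approx(0.0)

    def test_contrast_equals_difference_of_means(self):
        rng = np.random.default_rng(9)
        a, b, c3 = rng.normal(20, 6, (3, 15))
        df = self._long({"A": a, "B": b, "C": c3})
        for con in mq.method_contrast(df):
            means = {"A": a.mean(), "B": b.mean(), "C": c3.mean()}
            assert con.mean_difference == pytest.approx(
                means[con.method_a] - means[con.method_b], abs=1e-12
            )

    def test_unbalanced_design_rejected(self):
        df = self._long({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        df = df.drop(index=4)  # remove one (patient, method) cell
        with pytest.raises(ValueError, match="balanced"):
            mq.method_contrast(df)


class TestMeanSquaresInternals:
    def test_decomposition_reconstructs_total_ss(self):
        rng = np.random.default_rng(5)
        v = rng.normal(15, 5, (7, 4))
        msr, msc, mse = _two_way_mean_squares(v)
        n, k = v.shape
        total = ((v - v.mean()) ** 2).sum()
        recon = msr * (n - 1) + msc * (k - 1) + mse * (n - 1) * (k - 1)
        assert recon == pytest.approx(total)
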