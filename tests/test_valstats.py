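"""Equivalence testing, agreement, DiD, error bands, and the design sample size."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dietval import (
    DesignParams,
    bland_altman,
    diff_in_differences,
    error_band_table,
    foodgroup_comparison,
    sample_size_correlation,
    tost_equivalence,
)

THETA = math.log(1.1)


def pairs_from_logdiffs(d: np.ndarray):
    """WFR = 1, R24 = exp(d): paired values with exactly these log differences."""
    return np.ones_like(d), np.exp(d)


def logdiffs(mean: float, sd: float, n: int) -> np.ndarray:
    """An n-vector with exactly this sample mean and sample SD (ddof=1)."""
    d = np.linspace(-1, 1, n)
    d = (d - d.mean()) / d.std(ddof=1)
    return mean + sd * d


def tost_oracle(d: np.ndarray) -> float:
    """Closed-form TOST p: max of the two one-sided t CDF tails."""
    n, dbar, sd = len(d), d.mean(), d.std(ddof=1)
    se = sd / math.sqrt(n)
    return max(
        stats.t.sf((dbar + THETA) / se, n - 1),
        stats.t.cdf((dbar - THETA) / se, n - 1),
    )


class TestTOST:
    def test_matches_closed_form_oracle(self):
        d = logdiffs(0.0, 0.20, 100)
        wfr, r24 = pairs_from_logdiffs(d)
        result = tost_equivalence(wfr, r24)
        # t = theta / (sd / sqrt(n)) = 4.77 -> clearly equivalent
        assert result.p_value < 1e-5
        assert result.equivalent
        assert result.p_value == pytest.approx(tost_oracle(d), abs=1e-9)

    @pytest.mark.parametrize("mean,sd,n", [
        (0.0, 0.2, 100), (0.05, 0.3, 50), (-0.08, 0.15, 20), (0.2, 0.5, 111),
    ])
    def test_oracle_agreement_grid(self, mean, sd, n):
        d = logdiffs(mean, sd, n)
        wfr, r24 = pairs_from_logdiffs(d)
        assert tost_equivalence(wfr, r24).p_value == pytest.approx(
            tost_oracle(d), abs=1e-9
        )

    def test_bias_beyond_bound_cannot_reject(self):
        for sd in (0.05, 0.2, 1.0):
            d = logdiffs(0.15, sd, 60)
            wfr, r24 = pairs_from_logdiffs(d)
            result = tost_equivalence(wfr, r24)
            assert result.p_value > 0.5
            assert not result.equivalent

    def test_identical_pairs_degenerate_equivalent(self):
        wfr = np.array([100.0, 200.0, 300.0])
        result = tost_equivalence(wfr, wfr.copy())
        assert result.p_value == 0.0
        assert result.equivalent
        assert result.sd_log_diff == 0.0

    def test_zero_pairs_excluded_and_tallied(self):
        wfr = np.array([100.0, 0.0, 200.0, 300.0])
        r24 = np.array([100.0, 50.0, 200.0, 0.0])
        result = tost_equivalence(wfr, r24)
        assert result.n_pairs == 2
        assert result.n_zero_excluded == 2

    def test_symmetry_under_ratio_inversion(self):
        d = logdiffs(0.04, 0.3, 40)
        w1, r1 = pairs_from_logdiffs(d)
        w2, r2 = pairs_from_logdiffs(-d)
        assert tost_equivalence(w1, r1).p_value == pytest.approx(
            tost_equivalence(w2, r2).p_value, abs=1e-12
        )

    def test_p_decreases_with_n(self):
        ps = []
        for n in (10, 30, 100, 300):
            wfr, r24 = pairs_from_logdiffs(logdiffs(0.0, 0.3, n))
            ps.append(tost_equivalence(wfr, r24).p_value)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_p_minimised_at_zero_mean(self):
        p0 = tost_equivalence(*pairs_from_logdiffs(logdiffs(0.0, 0.3, 50))).p_value
        for mean in (-0.08, -0.04, 0.04, 0.08):
            p = tost_equivalence(*pairs_from_logdiffs(logdiffs(mean, 0.3, 50))).p_value
            assert p >= p0


class TestBlandAltman:
    def test_hand_arithmetic(self):
        wfr = np.array([10.0, 10.0, 10.0])
        r24 = wfr + np.array([-2.0, 0.0, 2.0])
        result = bland_altman(wfr, r24)
        assert result.bias == pytest.approx(0.0)
        assert result.sd_diff == pytest.approx(2.0)
        assert result.loa_lower == pytest.approx(-3.92)
        assert result.loa_upper == pytest.approx(3.92)

    def test_zero_differences(self):
        wfr = np.array([5.0, 7.0])
        result = bland_altman(wfr, wfr.copy())
        assert (result.bias, result.loa_lower, result.loa_upper) == (0.0, 0.0, 0.0)

    def test_translation_equivariance(self, rng):
        wfr = rng.uniform(50, 150, 30)
        r24 = wfr + rng.normal(0, 5, 30)
        base = bland_altman(wfr, r24)
        shifted = bland_altman(wfr, r24 + 7.5)
        assert shifted.bias == pytest.approx(base.bias + 7.5)
        assert shifted.sd_diff == pytest.approx(base.sd_diff)


def did_frame(diffs_capi, diffs_papi, rng=None, wfr_level=2000.0, wfr_sd=400.0):
    """Stacked long frame with given per-respondent (WFR - R24) differences.

    Respondent intake levels vary far more than the within-pair differences,
    as in real dietary data, so the random-intercept variance is well away
    from its zero boundary and the mixed model's closed-form equivalence
    with the pooled t test holds.
    """
    rows = []
    rng = rng or np.random.default_rng(0)
    for arm, diffs in (("CAPI", diffs_capi), ("PAPI", diffs_papi)):
        for i, d in enumerate(diffs):
            rid = f"{arm}{i}"
            wfr = wfr_level + rng.normal(0, wfr_sd)
            rows.append((rid, arm, "WFR", wfr))
            rows.append((rid, arm, "R24", wfr - d))
    return pd.DataFrame(rows, columns=["respondent_id", "arm", "source", "value"])


class TestDiD:
    def test_small_fixture_matches_pooled_t(self):
        long = did_frame([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        result = diff_in_differences(long)
        assert result.estimate == pytest.approx(-1.0, abs=1e-8)
        oracle = stats.ttest_ind([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert result.p_value == pytest.approx(oracle.pvalue, abs=1e-6)
        assert result.p_value == pytest.approx(0.2879, abs=1e-3)

    def test_identical_arms_estimate_zero(self):
        long = did_frame([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert diff_in_differences(long).estimate == pytest.approx(0.0, abs=1e-7)

    def test_translation_linearity(self, rng):
        d_capi = list(rng.normal(50, 30, 8))
        d_papi = list(rng.normal(80, 30, 9))
        base = diff_in_differences(did_frame(d_capi, d_papi))
        # +100 to every CAPI R24 value lowers the (WFR - R24) diff by 100
        shifted_frame = did_frame(d_capi, d_papi)
        mask = (shifted_frame["arm"] == "CAPI") & (shifted_frame["source"] == "R24")
        shifted_frame.loc[mask, "value"] += 100.0
        shifted = diff_in_differences(shifted_frame)
        assert shifted.estimate == pytest.approx(base.estimate - 100.0, abs=1e-6)

    def test_mixed_model_matches_t_oracle_random_fixtures(self, rng):
        for _ in range(5):
            n_capi, n_papi = rng.integers(5, 30, size=2)
            d_capi = list(rng.normal(100, 150, n_capi))
            d_papi = list(rng.normal(-50, 150, n_papi))
            result = diff_in_differences(did_frame(d_capi, d_papi, rng))
            oracle = stats.ttest_ind(d_capi, d_papi)
            assert result.p_value == pytest.approx(oracle.pvalue, abs=1e-6)
            assert result.estimate == pytest.approx(
                np.mean(d_capi) - np.mean(d_papi), abs=1e-6
            )

    def test_respondent_in_both_arms_rejected(self):
        long = did_frame([1.0, 2.0], [3.0, 4.0])
        long.loc[long["respondent_id"] == "PAPI0", "respondent_id"] = "CAPI0"
        with pytest.raises(ValueError, match="both arms"):
            diff_in_differences(long)


class TestErrorBands:
    def test_hand_count(self):
        wfr = np.full(4, 100.0)
        r24 = np.array([105.0, 115.0, 150.0, 300.0])
        row = error_band_table(wfr, r24)
        assert row.within[10.0] == 25.0
        assert row.within[20.0] == 50.0
        assert row.within[50.0] == 75.0
        assert row.over_pct == 25.0
        assert row.under_pct == 0.0

    def test_identity_all_within_narrowest(self):
        wfr = np.array([90.0, 110.0, 130.0])
        row = error_band_table(wfr, wfr.copy())
        assert row.within[10.0] == 100.0

    def test_boundary_inclusive(self):
        wfr = np.array([100.0, 100.0])
        row = error_band_table(wfr, 1.2 * wfr)
        assert row.within[10.0] == 0.0
        assert row.within[20.0] == 100.0

    def test_zero_wfr_names_respondent(self):
        with pytest.raises(ValueError, match="R7"):
            error_band_table(
                np.array([100.0, 0.0]), np.array([100.0, 50.0]), ids=["R1", "R7"]
            )

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1.0, max_value=1e4),
                st.floats(min_value=0.0, max_value=3e4),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_nesting_and_partition(self, pairs):
        wfr = np.array([p[0] for p in pairs])
        r24 = np.array([p[1] for p in pairs])
        row = error_band_table(wfr, r24)
        widths = sorted(row.within)
        percents = [row.within[w] for w in widths]
        assert all(a <= b for a, b in zip(percents, percents[1:]))
        assert row.within[widths[-1]] + row.over_pct + row.under_pct == pytest.approx(
            100.0, abs=1e-9
        )


def signed_rank_exact_oracle(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean_w = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2**n


class TestFoodgroupComparison:
    def shares(self, wfr_rows, r24_rows, groups=("CE", "VE")):
        index = [f"R{i}" for i in range(len(wfr_rows))]
        return (
            pd.DataFrame(wfr_rows, index=index, columns=list(groups)),
            pd.DataFrame(r24_rows, index=index, columns=list(groups)),
        )

    def test_exact_enumeration_example(self):
        w, r = self.shares([[10, 90], [10, 90], [10, 90]],
                           [[20, 80], [30, 70], [40, 60]])
        out = foodgroup_comparison(w, r)
        # three positive differences: exact two-sided p = 2/8
        assert out.loc["CE", "p_value"] == pytest.approx(0.25)

    def test_matches_enumeration_oracle_random(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 10))
            w = rng.uniform(10, 60, n)
            r = w + rng.normal(0, 8, n)
            frame_w = pd.DataFrame({"CE": w, "VE": 100 - w})
            frame_r = pd.DataFrame({"CE": r, "VE": 100 - r})
            out = foodgroup_comparison(frame_w, frame_r)
            assert out.loc["CE", "p_value"] == pytest.approx(
                signed_rank_exact_oracle(r - w), abs=1e-9
            )

    def test_rare_group_not_reported(self):
        wfr = [[0.0, 100.0]] * 19 + [[5.0, 95.0]]
        r24 = [[0.0, 98.0]] * 19 + [[7.0, 93.0]]
        w, r = self.shares(wfr, r24)
        out = foodgroup_comparison(w, r)
        assert out.loc["CE", "consumer_frac_wfr"] == pytest.approx(0.05)
        assert not out.loc["CE", "reported"]
        assert np.isfinite(out.loc["CE", "median_wfr"])  # medians still emitted

    def test_all_zero_differences_undefined(self):
        w, r = self.shares([[30, 70]] * 4, [[30, 70]] * 4)
        out = foodgroup_comparison(w, r)
        assert np.isnan(out.loc["CE", "p_value"])
        assert "zero" in out.loc["CE", "note"]


class TestSampleSize:
    def test_study_design_value(self):
        result = sample_size_correlation(DesignParams())
        assert result.n_per_arm == 104
        assert result.n_inflated == 117

    def test_higher_power(self):
        result = sample_size_correlation(DesignParams(power=0.90))
        assert result.n_per_arm == 138

    def test_equal_correlations_rejected(self):
        with pytest.raises(ValueError):
            DesignParams(rho0=0.6, rho1=0.6)
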