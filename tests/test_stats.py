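"""Outlier rule against a direct mean/SD oracle; ANOVA/Dunnett layer properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize
from scipy import stats as sps

from gammassr import anova_dunnett, build_report, remove_outliers
from gammassr.errors import ConfigurationError, DegenerateInputError
from gammassr.stats import significance_stars


def _table(groups: dict) -> pd.DataFrame:
    rows = [{"subject": f"{a}{i}", "arm": a, "value": v}
            for a, vals in groups.items() for i, v in enumerate(vals)]
    return pd.DataFrame(rows)


class TestRemoveOutliers:
    def test_clear_outlier_removed(self):
        vals = [0.0] * 9 + [10.0]
        gt = _table({"a": vals})
        clean, removed = remove_outliers(gt)
        # oracle: mean 1, sample SD ~3.162 -> |10-1|/3.162 ≈ 2.85 SD > 2
        v = np.array(vals)
        assert abs(10.0 - v.mean()) / v.std(ddof=1) > 2
        assert removed["value"].tolist() == [10.0]
        assert len(clean) == 9

    def test_small_n_masking_retains_extreme(self):
        vals = [1.0, 1.0, 1.0, 1.0, 100.0]
        gt = _table({"a": vals})
        clean, removed = remove_outliers(gt)
        # oracle: mean 20.8, SD ~44.27 -> 100 is only ~1.79 SD away
        v = np.array(vals)
        assert abs(100.0 - v.mean()) / v.std(ddof=1) < 2
        assert removed.empty and len(clean) == 5

    def test_all_equal_arm_unchanged(self):
        gt = _table({"a": [5.0] * 6})
        clean, removed = remove_outliers(gt)
        assert removed.empty and len(clean) == 6

    def test_single_pass_not_iterative(self):
        # after removing 50, the remaining {0,...,0,8} would flag 8 on a second
        # pass; single-pass must keep it
        vals = [0.0] * 10 + [8.0, 50.0]
        clean, removed = remove_outliers(_table({"a": vals}))
        assert removed["value"].tolist() == [50.0]
        assert 8.0 in clean["value"].tolist()

    def test_tiny_arm_skipped(self):
        gt = _table({"a": [0.0, 100.0]})
        clean, removed = remove_outliers(gt)
        assert removed.empty

    def test_oracle_on_random_arms(self, rng):
        vals = rng.normal(10, 3, size=40)
        gt = _table({"a": vals.tolist()})
        clean, removed = remove_outliers(gt, k=2.0)
        flag = np.abs(vals - vals.mean()) > 2.0 * vals.std(ddof=1)
        assert sorted(removed["value"]) == sorted(vals[flag])


def dunnett_critical_value(k: int, df: int, alpha: float = 0.05) -> float:
    """Independent oracle: two-sided Dunnett quantile via numerical integration.

    With a balanced design, T_i = (X_i - X_0) / (S * sqrt(2)) for iid standard
    normal X and S^2 ~ chi2_df/df, so conditional on (S, X_0) the events
    |T_i| <= c are independent normal-tail probabilities.
    """

    def coverage(c):
        def inner(s):
            def over_z(z):
                p = sps.norm.cdf(z + np.sqrt(2) * c * s) - sps.norm.cdf(z - np.sqrt(2) * c * s)
                return sps.norm.pdf(z) * p**k

            val, _ = integrate.quad(over_z, -8, 8, limit=100)
            return val

        # density of S = sqrt(chi2_df / df)
        def s_density(s):
            return sps.chi2.pdf(s**2 * df, df) * 2 * s * df

        val, _ = integrate.quad(lambda s: s_density(s) * inner(s), 1e-6, 4, limit=100)
        return val

    return float(optimize.brentq(lambda c: coverage(c) - (1 - alpha), 1.5, 5.0, xtol=1e-4))


class TestAnovaDunnett:
    def test_zero_variance_everywhere_is_degenerate(self):
        gt = _table({"a": [1.0] * 4, "b": [1.0] * 4})
        with pytest.raises(DegenerateInputError):
            anova_dunnett(gt, reference_arm="a")

    def test_missing_reference_arm_rejected(self):
        gt = _table({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        with pytest.raises(ConfigurationError):
            anova_dunnett(gt, reference_arm="zzz")

    def test_dunnett_critical_value_matches_published_table(self):
        """k=3 comparisons, df=20, two-sided alpha 0.05 -> critical value ≈ 2.54."""
        assert dunnett_critical_value(3, 20) == pytest.approx(2.54, abs=0.01)

    def test_adjusted_p_not_below_pairwise_t(self, rng):
        groups = {a: rng.normal(loc, 1.0, size=8).tolist()
                  for a, loc in [("veh", 0.0), ("d1", 0.6), ("d2", 1.0), ("d3", 0.2)]}
        res = anova_dunnett(_table(groups), reference_arm="veh", k_sd=None)
        for _, row in res.comparisons.iterrows():
            t_p = sps.ttest_ind(groups[row["arm"]], groups["veh"]).pvalue
            assert row["p_dunnett"] >= t_p - 1e-9

    def test_anova_f_invariant_under_affine_rescaling(self, rng):
        groups = {a: rng.normal(mu, 2.0, size=7).tolist() for a, mu in [("veh", 5), ("d", 7)]}
        gt = _table(groups)
        gt2 = gt.assign(value=gt["value"] * 3.7 - 11.0)
        r1 = anova_dunnett(gt, "veh", k_sd=None)
        r2 = anova_dunnett(gt2, "veh", k_sd=None)
        assert r1.f_stat == pytest.approx(r2.f_stat)

    def test_deterministic_p_values(self, rng):
        gt = _table({"veh": rng.normal(0, 1, 8).tolist(), "d": rng.normal(1, 1, 8).tolist()})
        p1 = anova_dunnett(gt, "veh").comparisons["p_dunnett"].iloc[0]
        p2 = anova_dunnett(gt, "veh").comparisons["p_dunnett"].iloc[0]
        assert p1 == p2

    def test_stars_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.0099) == "**"
        assert significance_stars(0.0001) == "****"
        assert significance_stars(0.2) == "ns"


class TestBuildReport:
    def test_reference_row_is_100_percent(self, rng):
        gt = _table({"veh": rng.normal(10, 1, 6).tolist(), "d": rng.normal(5, 1, 6).tolist()})
        res = anova_dunnett(gt, "veh", endpoint="plf")
        rep = build_report({"plf": res})
        ref_row = rep[rep["arm"] == "veh"].iloc[0]
        assert ref_row["percent_of_reference"] == pytest.approx(100.0)
        assert ref_row["stars"] == ""

    def test_strong_attenuation_flagged(self, rng):
        veh = rng.normal(0.20, 0.03, 8)
        drug = rng.normal(0.10, 0.03, 8)
        res = anova_dunnett(_table({"veh": veh.tolist(), "mk801": drug.tolist()}), "veh",
                            endpoint="plf")
        rep = build_report({"plf": res})
        row = rep[rep["arm"] == "mk801"].iloc[0]
        assert row["percent_of_reference"] == pytest.approx(50.0, abs=15.0)
        assert row["p_dunnett"] < 0.05

    def test_empty_endpoint_omitted(self, rng):
        gt = _table({"veh": rng.normal(1, 0.1, 5).tolist(), "d": rng.normal(1, 0.1, 5).tolist()})
        res = anova_dunnett(gt, "veh", endpoint="ok")
        rep = build_report({"ok": res, "empty": None})
        assert set(rep["endpoint"]) == {"ok"}
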