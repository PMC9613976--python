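import numpy as np
import pytest
from scipy import stats as sps

from speechdx.exceptions import ValidationError
from speechdx.stats import (
    CONTRASTS,
    comparison_table,
    correlate,
    group_comparison,
    normality_p,
)


class TestNormality:
    def test_preconditions(self):
        with pytest.raises(ValidationError):
            normality_p(np.arange(5.0))
        with pytest.raises(ValidationError):
            normality_p(np.full(20, 3.0))
        with pytest.raises(ValidationError):
            normality_p(np.arange(20.0), mode="bogus")

    def test_naive_matches_scipy(self, rng):
        x = rng.standard_normal(50)
        z = (x - x.mean()) / x.std(ddof=1)
        assert normality_p(x, mode="naive") == pytest.approx(
            sps.kstest(z, "norm").pvalue, abs=1e-15
        )

    def test_detects_exponential(self, rng):
        rejections = sum(
            normality_p(np.random.default_rng(s).exponential(size=200)) < 0.05
            for s in range(20)
        )
        assert rejections >= 19

    def test_accepts_normal_mostly(self):
        rejections = sum(
            normality_p(np.random.default_rng(s).standard_normal(200)) < 0.05
            for s in range(20)
        )
        assert rejections <= 4


class TestGroupComparison:
    def sample(self, rng, shift=0.0, skew=False):
        draw = (lambda n: rng.exponential(size=n)) if skew else (
            lambda n: rng.standard_normal(n))
        return {
            "HC": draw(60),
            "PD": draw(20),
            "PSP": draw(20),
            "MSA": draw(25) + shift,
        }

    def test_routes_normal_to_anova(self, rng):
        cmp = group_comparison(self.sample(rng))
        assert cmp.normal
        assert cmp.omnibus_method == "anova"
        assert set(cmp.pairwise_p) == set(CONTRASTS)

    def test_routes_skewed_to_kruskal(self, rng):
        cmp = group_comparison(self.sample(rng, skew=True))
        assert not cmp.normal
        assert cmp.omnibus_method == "kruskal"

    def test_detects_planted_shift(self, rng):
        cmp = group_comparison(self.sample(rng, shift=2.0))
        assert cmp.omnibus_p < 1e-4
        assert cmp.pairwise_p[("PSP", "MSA")] < 1e-3
        assert cmp.pairwise_p[("HC", "PD")] > 0.05

    def test_anova_omnibus_matches_scipy(self, rng):
        vals = self.sample(rng)
        cmp = group_comparison(vals)
        expected = sps.f_oneway(*(vals[g] for g in ("HC", "PD", "PSP", "MSA")))
        assert cmp.omnibus_p == pytest.approx(expected.pvalue, abs=1e-15)

    def test_missing_group_rejected(self, rng):
        vals = self.sample(rng)
        del vals["PD"]
        with pytest.raises(ValidationError, match="PD"):
            group_comparison(vals)


class TestComparisonTable:
    def test_layout(self, small_cohort):
        table, _ = small_cohort
        out = comparison_table(table, columns=["stdF0_a", "DUS_m"])
        assert list(out["feature"]) == ["stdF0_a", "DUS_m"]
        for col in ("HC_mean", "MSA_sd", "PSP_lo", "PD_hi", "omnibus_p",
                    "p_PSP_MSA", "p_HC_MSA"):
            assert col in out.columns
        row = out.iloc[0]
        hc = table.loc[table["group"] == "HC", "stdF0_a"]
        assert row["HC_mean"] == pytest.approx(hc.mean())
        assert row["HC_sd"] == pytest.approx(hc.std(ddof=1))


class TestCorrelate:
    def test_pearson_for_normal_pair(self, rng):
        x = rng.standard_normal(100)
        y = 0.6 * x + 0.8 * rng.standard_normal(100)
        r, p, method = correlate(x, y)
        assert method == "pearson"
        expected_r, expected_p = sps.pearsonr(x, y)
        assert r == pytest.approx(expected_r, abs=1e-15)
        assert p == pytest.approx(expected_p, abs=1e-15)

    def test_spearman_for_skewed_margin(self, rng):
        x = rng.exponential(size=100)
        y = x + rng.exponential(size=100)
        r, p, method = correlate(x, y)
        assert method == "spearman"
        expected_r, _ = sps.spearmanr(x, y)
        assert r == pytest.approx(expected_r, abs=1e-15)

    def test_preconditions(self, rng):
        with pytest.raises(ValidationError):
            correlate(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValidationError):
            correlate(np.arange(10.0), np.arange(9.0))
        with pytest.raises(ValidationError):
            correlate(np.full(10, 1.0), np.arange(10.0))

    def test_nan_pairs_dropped(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.5 * rng.standard_normal(30)
        x2, y2 = x.copy(), y.copy()
        x2[0] = np.nan
        r_full, _, _ = correlate(x[1:], y[1:])
        r_drop, _, _ = correlate(x2, y2)
        assert r_drop == pytest.approx(r_full, abs=1e-15)
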