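from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from speechdx.exceptions import ValidationError
from speechdx.search import pairwise_p, search_subsystem


def z_frame(rng, features, n_psp=10, n_msa=10, shift=None):
    """PSP/MSA z-table with optional per-feature PSP shifts."""
    n = n_psp + n_msa
    data = rng.standard_normal((n, len(features)))
    if shift:
        for f, d in shift.items():
            data[:n_psp, features.index(f)] += d
    out = pd.DataFrame(data, columns=features)
    out["group"] = ["PSP"] * n_psp + ["MSA"] * n_msa
    return out


def oracle_search(z, features, alpha=0.05):
    """Independent brute-force reimplementation of the staged search."""
    a = (z["group"] == "PSP").to_numpy()
    b = (z["group"] == "MSA").to_numpy()

    def pval(v):
        p = float(sps.ttest_ind(v[a], v[b], equal_var=False).pvalue)
        return 1.0 if np.isnan(p) else p

    entries = []
    for r in range(1, len(features) + 1):
        for s in combinations(sorted(features), r):
            entries.append((pval(z[list(s)].mean(axis=1).to_numpy()), r, s))
    entries.sort()
    p_best, _, s_best = entries[0]
    if p_best < alpha:
        return "single-significant", (s_best,), p_best
    for p2, _, s2 in entries[1:]:
        if not set(s_best) & set(s2):
            combo = (2 * z[list(s_best)].mean(axis=1)
                     + z[list(s2)].mean(axis=1)) / 2
            pc = pval(combo.to_numpy())
            if pc < alpha:
                return "weighted-pair", (s_best, s2), pc
            break
    return "best-nonsignificant", (s_best,), p_best


class TestPairwiseP:
    def test_welch_matches_scipy(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 1
        p = pairwise_p({"x": a, "y": b}, "x", "y")
        expected = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert p == pytest.approx(expected, abs=1e-15)

    def test_mannwhitney_matches_scipy(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 1
        p = pairwise_p({"x": a, "y": b}, "x", "y", test="mannwhitney")
        expected = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(expected, abs=1e-15)

    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pairwise_p({"x": a, "y": a.copy()}, "x", "y") == 1.0

    def test_degenerate_constant_samples_give_p_one(self):
        a = np.array([1.0, 1.0, 1.0])
        assert pairwise_p({"x": a, "y": a.copy()}, "x", "y") == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_p({"x": np.array([1.0]), "y": np.array([1.0, 2.0])},
                       "x", "y")

    def test_unknown_test_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_p({"x": np.zeros(3), "y": np.ones(3)}, "x", "y",
                       test="bogus")


class TestSearchAgainstOracle:
    def test_matches_oracle_on_random_instances(self):
        feats = [f"f{i}" for i in range(4)]
        for seed in range(25):
            rng = np.random.default_rng(seed)
            shift = {"f0": rng.uniform(0, 1.5)} if seed % 2 else None
            z = z_frame(rng, feats, shift=shift)
            res = search_subsystem(z, feats, alpha=0.05)
            stage, subsets, p = oracle_search(z, feats, alpha=0.05)
            assert res.stage == stage
            assert res.subsets == subsets
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_ranking_enumerates_all_subsets(self, rng):
        feats = [f"f{i}" for i in range(5)]
        res = search_subsystem(z_frame(rng, feats), feats)
        assert len(res.ranking) == 2**5 - 1
        assert res.ranking["p"].is_monotonic_increasing

    def test_input_order_invariance(self, rng):
        feats = [f"f{i}" for i in range(4)]
        z = z_frame(rng, feats, shift={"f2": 2.0})
        res1 = search_subsystem(z, feats)
        res2 = search_subsystem(z, feats[::-1])
        assert res1.subsets == res2.subsets
        assert res1.stage == res2.stage
        assert res1.p_value == res2.p_value


class TestStages:
    def test_planted_strong_singleton(self, rng):
        feats = [f"f{i}" for i in range(5)]
        z = z_frame(rng, feats, n_psp=20, n_msa=25, shift={"f3": 3.0})
        res = search_subsystem(z, feats)
        assert res.stage == "single-significant"
        assert res.subsets == (("f3",),)
        assert res.weights == (1,)

    def test_identical_groups_fall_to_best_nonsignificant(self):
        feats = ["f0", "f1", "f2"]
        block = np.arange(15, dtype=float).reshape(5, 3)
        z = pd.DataFrame(np.vstack([block, block]), columns=feats)
        z["group"] = ["PSP"] * 5 + ["MSA"] * 5
        res = search_subsystem(z, feats)
        assert res.stage == "best-nonsignificant"
        assert res.p_value == 1.0
        assert len(res.subsets) == 1

    def test_weighted_pair_combination_semantics(self, rng):
        feats = [f"f{i}" for i in range(4)]
        z = z_frame(rng, feats)
        res = search_subsystem(z, feats)
        vals = res.combination_values(z)
        if len(res.subsets) == 2:
            (s1, s2), (w1, w2) = res.subsets, res.weights
            expected = (w1 * z[list(s1)].mean(axis=1)
                        + w2 * z[list(s2)].mean(axis=1)) / 2
        else:
            expected = z[list(res.subsets[0])].mean(axis=1)
        assert np.allclose(vals, expected, atol=1e-12)

    def test_to_dict_is_json_ready(self, rng):
        import json

        feats = ["f0", "f1"]
        res = search_subsystem(z_frame(rng, feats), feats)
        payload = json.loads(json.dumps(res.to_dict()))
        assert payload["stage"] == res.stage


class TestValidation:
    def test_feature_count_limits(self, rng):
        z = z_frame(rng, ["f0"])
        with pytest.raises(ValidationError):
            search_subsystem(z, [])
        feats = [f"f{i}" for i in range(13)]
        with pytest.raises(ValidationError):
            search_subsystem(z_frame(rng, feats), feats)

    def test_missing_column_rejected(self, rng):
        z = z_frame(rng, ["f0"])
        with pytest.raises(ValidationError, match="f9"):
            search_subsystem(z, ["f0", "f9"])

    def test_small_contrast_group_rejected(self, rng):
        z = z_frame(rng, ["f0", "f1"], n_psp=1, n_msa=10)
        with pytest.raises(ValidationError, match=">= 2"):
            search_subsystem(z, ["f0", "f1"])
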