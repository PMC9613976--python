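import numpy as np
import pandas as pd
import pytest

from speechdx.classify import (
    POSITIVE_LABELS,
    fit_boundary,
    loso_logistic,
    plot_boundary,
)
from speechdx.exceptions import ValidationError


def separable_data(n=10, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n, 2)),
                   rng.standard_normal((n, 2)) + gap])
    y = np.array(["MSA"] * n + ["PSP"] * n)
    return X, y


def test_separable_perfect_scores():
    X, y = separable_data()
    rep = loso_logistic(X, y, positive_label="PSP")
    assert rep.accuracy == 100.0
    assert rep.sensitivity == 100.0
    assert rep.specificity == 100.0
    assert rep.auc == 1.0
    assert rep.auc_full_fit == 1.0
    assert rep.confusion == {"tp": 10, "tn": 10, "fp": 0, "fn": 0}


def test_metrics_consistent_with_probabilities():
    X, y = separable_data(gap=1.0, seed=3)
    rep = loso_logistic(X, y, positive_label="PSP")
    pred = rep.probabilities >= 0.5
    acc = 100.0 * (pred == rep.y_true.astype(bool)).mean()
    assert rep.accuracy == pytest.approx(acc)
    c = rep.confusion
    assert c["tp"] + c["tn"] + c["fp"] + c["fn"] == len(y)
    assert rep.sensitivity == pytest.approx(100.0 * c["tp"] / (c["tp"] + c["fn"]))
    assert rep.specificity == pytest.approx(100.0 * c["tn"] / (c["tn"] + c["fp"]))


def test_auc_invariant_to_monotone_feature_transform():
    X, y = separable_data(gap=1.5, seed=5)
    rep1 = loso_logistic(X[:, :1], y, positive_label="PSP")
    rep2 = loso_logistic(np.exp(X[:, :1]), y, positive_label="PSP")
    # the full-fit probabilities are monotone in a single predictor, so the
    # full-fit AUC depends only on the predictor ordering
    assert rep1.auc_full_fit == pytest.approx(rep2.auc_full_fit, abs=1e-12)


def test_youden_point_bounds():
    X, y = separable_data(gap=1.0, seed=7)
    rep = loso_logistic(X, y, positive_label="PSP")
    assert 0.0 <= rep.youden_sensitivity <= 100.0
    assert 0.0 <= rep.youden_specificity <= 100.0
    j = rep.youden_sensitivity + rep.youden_specificity - 100.0
    j_fixed = rep.sensitivity + rep.specificity - 100.0
    assert j >= j_fixed - 1e-9  # the Youden point is ROC-optimal


def test_dataframe_input_and_subjects():
    X, y = separable_data()
    df = pd.DataFrame(X, columns=["DTI1", "DTI2"])
    subjects = [f"S{i}" for i in range(len(y))]
    rep = loso_logistic(df, y, positive_label="PSP", subjects=subjects)
    assert rep.predictors == ("DTI1", "DTI2")
    frame = rep.per_subject_frame()
    assert list(frame["subject"]) == subjects
    assert frame["probability"].between(0, 1).all()


def test_validation_errors():
    X, y = separable_data()
    with pytest.raises(ValidationError, match="finite"):
        bad = X.copy()
        bad[0, 0] = np.nan
        loso_logistic(bad, y, positive_label="PSP")
    with pytest.raises(ValidationError, match="two classes"):
        loso_logistic(X, np.array(["PSP"] * len(y)), positive_label="PSP")
    with pytest.raises(ValidationError, match="positive label"):
        loso_logistic(X, y, positive_label="PD")
    with pytest.raises(ValidationError, match=">= 3"):
        loso_logistic(X[8:], y[8:], positive_label="PSP")


def test_positive_label_conventions():
    assert POSITIVE_LABELS[("PSP", "MSA")] == "PSP"
    assert POSITIVE_LABELS[("PD", "MSA")] == "MSA"
    assert POSITIVE_LABELS[("PD", "PSP")] == "PSP"


class TestBoundary:
    def test_midpoint_on_symmetric_data(self):
        # symmetric 1-D classes around 0: the boundary crosses x = 0
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1])
        b = fit_boundary(x, y, predictors=["x"])
        crossing = -b["intercept"] / b["x"]
        assert abs(crossing) < 1e-3

    def test_label_swap_flips_signs(self, rng):
        X = rng.standard_normal((30, 2))
        y = (X[:, 0] + 0.5 * rng.standard_normal(30) > 0).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        b1 = fit_boundary(X, y, predictors=["a", "b"])
        b2 = fit_boundary(X, 1 - y, predictors=["a", "b"])
        assert b1["a"] == pytest.approx(-b2["a"], rel=1e-3, abs=1e-6)
        assert b1["intercept"] == pytest.approx(-b2["intercept"], rel=1e-3,
                                                abs=1e-6)

    def test_duplicate_column_ridge_fallback(self):
        X, y = separable_data(gap=1.0)
        dup = np.column_stack([X[:, 0], X[:, 0]])
        b = fit_boundary(dup, (np.arange(len(y)) % 2), predictors=["a", "b"])
        assert np.isfinite(list(b.values())).all()


def test_plot_boundary_writes_file(tmp_path):
    X, y = separable_data()
    rep = loso_logistic(X, y, positive_label="PSP", predictors=("DTI1", "DTI2"))
    out = tmp_path / "boundary.png"
    plot_boundary(rep, X, y, out)
    assert out.stat().st_size > 0


def test_to_dict_is_json_ready():
    import json

    X, y = separable_data()
    rep = loso_logistic(X, y, positive_label="PSP")
    payload = json.loads(json.dumps(rep.to_dict()))
    assert payload["positive_label"] == "PSP"
    assert payload["accuracy"] == 100.0
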