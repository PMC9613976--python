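"""Group statistics: normality screening, omnibus tests, post hocs, correlations.

The analysis routes every feature or index through a normality screen
(one-sample Kolmogorov-Smirnov with the Lilliefors correction for
estimated parameters, since the reference mean and SD are estimated from
the sample).  Normally distributed variables go through one-way ANOVA
with Tukey's HSD post hoc; non-normal ones through Kruskal-Wallis with
Tukey's HSD on rank-transformed values.  Only the four clinically
relevant pairwise contrasts are reported: HC-PD, HC-PSP, HC-MSA and
PSP-MSA.  Correlations between indices and clinical severity use Pearson
when both variables pass the normality screen and Spearman otherwise.

No multiple-testing correction is applied across features; the tables
report raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import ValidationError

CONTRASTS = (("HC", "PD"), ("HC", "PSP"), ("HC", "MSA"), ("PSP", "MSA"))
GROUP_ORDER = ("HC", "PD", "PSP", "MSA")


def normality_p(values: np.ndarray, mode: str = "lilliefors") -> float:
    """P-value of the KS normality test on a sample.

    ``mode="lilliefors"`` (default) corrects for the mean and SD being
    estimated from the data; ``mode="naive"`` compares the standardized
    sample against the standard normal without correction.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        raise ValidationError(f"normality test needs n >= 8, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("normality test undefined for constant input")
    if mode == "lilliefors":
        # the Dallal-Wilkinson approximation is accurate in the rejection
        # region (p < 0.1) at large n, where the interpolation table is
        # conservative; only the alpha = 0.05 boundary matters for routing
        _, p = lilliefors(x, dist="norm", pvalmethod="approx")
    elif mode == "naive":
        z = (x - x.mean()) / x.std(ddof=1)
        _, p = sps.kstest(z, "norm")
    else:
        raise ValidationError(f"unknown normality mode {mode!r}")
    return float(p)


@dataclass(frozen=True)
class GroupComparison:
    """One row of the group-comparison table."""

    normality_p: dict[str, float]
    normal: bool
    omnibus_method: str  # "anova" | "kruskal"
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]


def group_comparison(
    values_by_group: dict[str, np.ndarray],
    alpha: float = 0.05,
    normality_mode: str = "lilliefors",
) -> GroupComparison:
    """Omnibus + post hoc comparison of one variable across the four groups.

    The omnibus test is ANOVA when every group passes the normality
    screen at *alpha* (Kruskal-Wallis otherwise); the post hoc is Tukey's
    HSD on raw values after ANOVA and on pooled ranks after
    Kruskal-Wallis.  Routing is a pure function of the normality
    p-values.
    """
    for g in GROUP_ORDER:
        if g not in values_by_group:
            raise ValidationError(f"missing group {g!r}")
        if len(np.asarray(values_by_group[g])) < 2:
            raise ValidationError(f"group {g!r} needs >= 2 values")
    samples = {g: np.asarray(values_by_group[g], dtype=float) for g in GROUP_ORDER}
    samples = {g: v[np.isfinite(v)] for g, v in samples.items()}

    norm_p = {g: normality_p(v, mode=normality_mode) for g, v in samples.items()}
    normal = all(p >= alpha for p in norm_p.values())

    arrays = [samples[g] for g in GROUP_ORDER]
    if normal:
        omnibus_method = "anova"
        omnibus_p = float(sps.f_oneway(*arrays).pvalue)
        posthoc_arrays = arrays
    else:
        omnibus_method = "kruskal"
        omnibus_p = float(sps.kruskal(*arrays).pvalue)
        pooled = np.concatenate(arrays)
        ranks = sps.rankdata(pooled)
        splits = np.cumsum([len(a) for a in arrays])[:-1]
        posthoc_arrays = np.split(ranks, splits)

    hsd = sps.tukey_hsd(*posthoc_arrays)
    idx = {g: i for i, g in enumerate(GROUP_ORDER)}
    pairwise = {
        (a, b): float(hsd.pvalue[idx[a], idx[b]]) for a, b in CONTRASTS
    }
    return GroupComparison(
        normality_p=norm_p,
        normal=normal,
        omnibus_method=omnibus_method,
        omnibus_p=omnibus_p,
        pairwise_p=pairwise,
    )


def comparison_table(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    alpha: float = 0.05,
    normality_mode: str = "lilliefors",
) -> pd.DataFrame:
    """Group-comparison table for many variables of a feature/index table.

    Mirrors the layout of a published per-feature summary: per group the
    mean/SD/(range) of the raw values, then the omnibus method and the
    four pairwise p-values.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in ("subject", "group", "run")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for col in columns:
        by_group = {
            g: table.loc[table["group"] == g, col].dropna().to_numpy()
            for g in GROUP_ORDER
        }
        cmp = group_comparison(by_group, alpha=alpha, normality_mode=normality_mode)
        row: dict[str, object] = {"feature": col, "method": cmp.omnibus_method,
                                  "omnibus_p": cmp.omnibus_p}
        for g in GROUP_ORDER:
            v = by_group[g]
            row[f"{g}_mean"] = v.mean()
            row[f"{g}_sd"] = v.std(ddof=1)
            row[f"{g}_lo"] = v.min()
            row[f"{g}_hi"] = v.max()
        for a, b in CONTRASTS:
            row[f"p_{a}_{b}"] = cmp.pairwise_p[(a, b)]
        rows.append(row)
    return pd.DataFrame(rows)


def correlate(
    index_values: np.ndarray,
    clinical_values: np.ndarray,
    alpha: float = 0.05,
    normality_mode: str = "lilliefors",
) -> tuple[float, float, str]:
    """Correlation between an index and a clinical score with normality routing.

    Pearson when both variables pass the normality screen at *alpha*,
    Spearman otherwise.  Returns ``(r, two-sided p, method)``.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(clinical_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 8:
        raise ValidationError(f"correlation needs n >= 8 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")

    def _is_normal(v: np.ndarray) -> bool:
        # a perfectly linear pair duplicates the scale; screen each margin
        return normality_p(v, mode=normality_mode) >= alpha

    if _is_normal(x) and _is_normal(y):
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return float(r), float(p), method
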