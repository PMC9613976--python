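"""Semi-supervised exhaustive search for subset-average feature composites.

The composite design restricts feature combinations to plain averages of
z-scored features.  For a given speech subsystem, every non-empty subset
of its features is enumerated, each subject receives the subset average
of their z-scores, and subsets are ranked by the two-group separation
p-value (PSP vs MSA by default).  Three stages produce the returned
combination:

1. **single-significant** — if the best subset is already significant at
   ``alpha``, it is returned alone.
2. **weighted-pair** — otherwise the best subset (weight 2) is combined
   with the lowest-p subset disjoint from it (weight 1) as
   ``(2 * avg_best + avg_second) / 2``; if that combination is
   significant it is returned.
3. **best-nonsignificant** — otherwise the best subset is returned alone,
   flagged as non-significant.

Ties on p-value are broken by smaller subset size, then lexicographic
feature order, which makes the search invariant to input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

log = logging.getLogger(__name__)

MAX_FEATURES = 12


def pairwise_p(
    values_by_group: dict[str, np.ndarray],
    group_a: str,
    group_b: str,
    test: str = "welch",
) -> float:
    """Two-sided two-group separation p-value on composite values.

    ``test`` is ``"welch"`` (default, unequal-variance t-test) or
    ``"mannwhitney"``.  Each group needs at least two values.
    """
    a = np.asarray(values_by_group[group_a], dtype=float)
    b = np.asarray(values_by_group[group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values for a two-group test")
    if test == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValidationError(f"unknown test {test!r}")
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance degenerate case: no detectable difference
        p = 1.0
    return p


@dataclass(frozen=True)
class SearchResult:
    """Outcome of the subset-average search for one subsystem."""

    subsystem: str
    stage: str  # single-significant | weighted-pair | best-nonsignificant
    subsets: tuple[tuple[str, ...], ...]
    weights: tuple[int, ...]
    p_value: float
    ranking: pd.DataFrame = field(repr=False)  # subset, size, p columns

    def combination_values(self, z: pd.DataFrame) -> pd.Series:
        """Evaluate the returned combination on a z-table (reproducibility)."""
        return _combination(z, self.subsets, self.weights)

    def to_dict(self) -> dict:
        return {
            "subsystem": self.subsystem,
            "stage": self.stage,
            "subsets": [list(s) for s in self.subsets],
            "weights": list(self.weights),
            "p_value": self.p_value,
        }


def _combination(z: pd.DataFrame, subsets, weights) -> pd.Series:
    """(sum_j w_j * avg_j) / 2 for the weighted pair, avg for a single subset."""
    if len(subsets) == 1:
        return z[list(subsets[0])].mean(axis=1)
    acc = 0.0
    for subset, w in zip(subsets, weights):
        acc = acc + w * z[list(subset)].mean(axis=1)
    return acc / 2.0


def search_subsystem(
    z: pd.DataFrame,
    features: Sequence[str],
    groups: pd.Series | None = None,
    alpha: float = 0.05,
    contrast: tuple[str, str] = ("PSP", "MSA"),
    test: str = "welch",
    subsystem: str = "",
) -> SearchResult:
    """Run the three-stage exhaustive subset-average search.

    *z* is a z-table containing the *features* columns; group labels come
    from *groups* (or a ``group`` column of *z*).  Only the two *contrast*
    groups enter the p-values.
    """
    features = sorted(set(features))
    if not 1 <= len(features) <= MAX_FEATURES:
        raise ValidationError(
            f"search handles 1..{MAX_FEATURES} features, got {len(features)}"
        )
    missing = [f for f in features if f not in z.columns]
    if missing:
        raise ValidationError(f"z-table lacks columns {missing}")
    labels = groups if groups is not None else z["group"]
    mask_a = (labels == contrast[0]).to_numpy()
    mask_b = (labels == contrast[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("each contrast group needs >= 2 subjects")

    def p_of(series: pd.Series) -> float:
        return pairwise_p(
            {"a": series.to_numpy()[mask_a], "b": series.to_numpy()[mask_b]},
            "a",
            "b",
            test=test,
        )

    rows = []
    for r in range(1, len(features) + 1):
        for subset in combinations(features, r):
            rows.append(
                {"subset": subset, "size": r, "p": p_of(z[list(subset)].mean(axis=1))}
            )
    ranking = pd.DataFrame(rows)
    order = sorted(range(len(rows)), key=lambda i: (rows[i]["p"], rows[i]["size"], rows[i]["subset"]))
    ranking = ranking.iloc[order].reset_index(drop=True)

    best = ranking.iloc[0]
    if best["p"] < alpha:
        return SearchResult(
            subsystem=subsystem,
            stage="single-significant",
            subsets=(tuple(best["subset"]),),
            weights=(1,),
            p_value=float(best["p"]),
            ranking=ranking,
        )

    best_set = set(best["subset"])
    second = None
    for _, row in ranking.iloc[1:].iterrows():
        if not best_set & set(row["subset"]):
            second = row
            break
    if second is not None:
        subsets = (tuple(best["subset"]), tuple(second["subset"]))
        combo = _combination(z, subsets, (2, 1))
        p_combo = p_of(combo)
        if p_combo < alpha:
            return SearchResult(
                subsystem=subsystem,
                stage="weighted-pair",
                subsets=subsets,
                weights=(2, 1),
                p_value=float(p_combo),
                ranking=ranking,
            )
    else:
        log.warning(
            "no subset disjoint from the best one exists; falling back to the "
            "best single average"
        )

    return SearchResult(
        subsystem=subsystem,
        stage="best-nonsignificant",
        subsets=(tuple(best["subset"]),),
        weights=(1,),
        p_value=float(best["p"]),
        ranking=ranking,
    )
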