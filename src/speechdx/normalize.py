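"""HC-referenced, impairment-oriented z-scoring of raw features.

Raw features are converted to z-scores using the healthy-control (HC)
sample mean and standard deviation of each feature.  Features for which a
*lower* raw value signals worse speech have their z-score sign reversed,
so that after normalization a higher z-score always means more speech
impairment.  The default reversal list comes from the feature registry
and can be overridden per feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateFeatureError, ValidationError
from .io import feature_columns, validate_feature_table
from .registry import direction_map


def default_directions() -> dict[str, int]:
    """Default impairment orientation (+1/-1) per canonical feature."""
    return direction_map()


@dataclass(frozen=True)
class ZNormalizer:
    """Frozen HC reference: per-feature mean, SD and impairment direction.

    ``z = direction * (x - hc_mean) / hc_sd``; the sample SD uses the
    n - 1 denominator.
    """

    hc_mean: Mapping[str, float]
    hc_sd: Mapping[str, float]
    direction: Mapping[str, int]

    @property
    def features(self) -> list[str]:
        return list(self.hc_mean)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "hc_mean": dict(self.hc_mean),
                "hc_sd": dict(self.hc_sd),
                "direction": dict(self.direction),
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ZNormalizer":
        path = Path(source)
        text = path.read_text(encoding="utf-8") if path.exists() else str(source)
        raw = json.loads(text)
        return cls(
            hc_mean={k: float(v) for k, v in raw["hc_mean"].items()},
            hc_sd={k: float(v) for k, v in raw["hc_sd"].items()},
            direction={k: int(v) for k, v in raw["direction"].items()},
        )


def fit_normalizer(
    table: pd.DataFrame,
    directions: Mapping[str, int] | None = None,
    features: Iterable[str] | None = None,
) -> ZNormalizer:
    """Fit the HC reference statistics from a feature table.

    Uses only the HC rows; requires at least two non-missing HC values per
    feature and a non-degenerate (non-constant) HC column.  *directions*
    overrides the registry defaults per feature; features absent from both
    raise :class:`ValidationError`.
    """
    validate_feature_table(table)
    feats = list(features) if features is not None else feature_columns(table)
    hc = table[table["group"] == "HC"]
    if hc.empty:
        raise ValidationError("no HC rows to fit the normalizer on")

    defaults = default_directions()
    overrides = dict(directions) if directions else {}
    mean, sd, dirs = {}, {}, {}
    for f in feats:
        values = hc[f].dropna().to_numpy(dtype=float)
        if len(values) < 2:
            raise ValidationError(
                f"need >= 2 non-missing HC values for feature {f!r}, got {len(values)}"
            )
        s = float(np.std(values, ddof=1))
        if s == 0:
            raise DegenerateFeatureError(f"HC column {f!r} is constant")
        mean[f] = float(np.mean(values))
        sd[f] = s
        if f in overrides:
            d = int(overrides[f])
        elif f in defaults:
            d = defaults[f]
        else:
            raise ValidationError(
                f"no impairment direction known for feature {f!r}; pass it explicitly"
            )
        if d not in (-1, 1):
            raise ValidationError(f"direction for {f!r} must be +1 or -1")
        dirs[f] = d
    return ZNormalizer(hc_mean=mean, hc_sd=sd, direction=dirs)


def apply_normalizer(
    norm: ZNormalizer,
    table: pd.DataFrame,
    impute_missing: bool = False,
) -> pd.DataFrame:
    """Convert a feature table to an impairment-oriented z-score table.

    Metadata columns (subject, group, run) are carried through.  Missing
    cells stay missing unless *impute_missing*, in which case they are set
    to z = 0, i.e. the HC mean.  Feature columns unknown to the normalizer
    raise :class:`ValidationError`.
    """
    validate_feature_table(table)
    feats = feature_columns(table)
    unknown = [f for f in feats if f not in norm.hc_mean]
    if unknown:
        raise ValidationError(f"features unknown to the normalizer: {unknown}")

    out = table[["subject", "group", "run"]].copy()
    for f in feats:
        z = norm.direction[f] * (table[f] - norm.hc_mean[f]) / norm.hc_sd[f]
        if impute_missing:
            z = z.fillna(0.0)
        out[f] = z
    return out
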