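"""Reading, writing and validation of feature tables and calibration data.

A *feature table* is a :class:`pandas.DataFrame` with the reserved columns
``subject`` (str), ``group`` (one of HC/PD/PSP/MSA) and ``run`` (int, the
repetition index of the recording session), followed by canonical feature
columns named per :mod:`speechdx.registry`.  Values are raw feature units;
missing cells are allowed and stay missing (imputation, where wanted,
happens in the normalization step).

*Clinical scores* are a per-patient table of NNIPPS severity scores
(total plus bradykinesia/rigidity, bulbar and cerebellar subscores),
present only for PSP and MSA subjects.

*Group statistics* are the per-group, per-feature mean/SD/range summaries
used to calibrate the synthetic cohort generator; a packaged transcription
of the published cohort statistics is available as ``load_group_stats("builtin")``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError
from .registry import GROUPS, is_canonical

log = logging.getLogger(__name__)

META_COLUMNS = ("subject", "group", "run")

CLINICAL_COLUMNS = (
    "subject",
    "group",
    "nnipps_total",
    "nnipps_bradyrigidity",
    "nnipps_bulbar",
    "nnipps_cerebellar",
)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatEntry:
    """Mean/SD/range of one feature in one group, raw units."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.mean, self.sd, self.lo, self.hi]).all():
            raise ValidationError("group statistics must be finite")
        if self.sd <= 0:
            raise ValidationError(f"sd must be positive, got {self.sd}")
        if self.lo >= self.hi:
            raise ValidationError(f"range lo={self.lo} must be below hi={self.hi}")
        if not (self.lo <= self.mean <= self.hi):
            raise ValidationError(
                f"mean {self.mean} outside printed range [{self.lo}, {self.hi}]"
            )


class GroupStats:
    """Per-group marginal statistics for a set of features.

    Thin mapping ``(group, feature) -> StatEntry`` with validation of the
    structural invariants (positive SD, ordered range, mean inside range).
    """

    def __init__(self, entries: Mapping[str, Mapping[str, StatEntry]]):
        # entries: feature -> group -> StatEntry
        self._entries = {f: dict(g) for f, g in entries.items()}
        for feature, per_group in self._entries.items():
            for group in per_group:
                if group not in GROUPS:
                    raise ValidationError(
                        f"unknown group {group!r} for feature {feature!r}"
                    )

    @property
    def features(self) -> list[str]:
        return list(self._entries)

    def groups_for(self, feature: str) -> list[str]:
        return list(self._entries[feature])

    def has(self, group: str, feature: str) -> bool:
        return feature in self._entries and group in self._entries[feature]

    def get(self, group: str, feature: str) -> StatEntry:
        try:
            return self._entries[feature][group]
        except KeyError:
            raise KeyError(f"no statistics for feature {feature!r}, group {group!r}")

    def subset(self, features: Iterable[str]) -> "GroupStats":
        return GroupStats({f: self._entries[f] for f in features})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "group": g, "mean": e.mean, "sd": e.sd, "lo": e.lo, "hi": e.hi}
            for f, per_group in self._entries.items()
            for g, e in per_group.items()
        ]
        return pd.DataFrame(rows)


def load_group_stats(source: str | Path = "builtin") -> GroupStats:
    """Load group statistics from a JSON/YAML file or the packaged table.

    The file layout is ``{"stats": {feature: {group: {mean, sd, lo, hi}}}}``;
    non-group keys (such as ``note``) inside a feature block are ignored.
    """
    if source == "builtin":
        text = resources.files("speechdx.data").joinpath("group_stats.json").read_text()
        raw = json.loads(text)
    else:
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    entries: dict[str, dict[str, StatEntry]] = {}
    for feature, per_group in raw["stats"].items():
        entries[feature] = {}
        for group, stats in per_group.items():
            if group not in GROUPS:
                continue  # descriptive keys such as "note"
            entries[feature][group] = StatEntry(
                mean=float(stats["mean"]),
                sd=float(stats["sd"]),
                lo=float(stats["lo"]),
                hi=float(stats["hi"]),
            )
    return GroupStats(entries)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of *table* that are not reserved metadata columns."""
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_feature_table(table: pd.DataFrame) -> list[str]:
    """Validate feature-table invariants; return non-canonical column names.

    Raises :class:`FormatError` on structural problems (missing metadata
    columns, unknown group labels, duplicate (subject, run) keys, a group
    label that varies across a subject's runs, or non-finite values).
    Unknown feature columns are tolerated but returned so callers can log
    them.
    """
    for col in ("subject", "group"):
        if col not in table.columns:
            raise FormatError(f"feature table lacks required column {col!r}")
    if "run" not in table.columns:
        raise FormatError("feature table lacks required column 'run'")

    bad_groups = set(table["group"]) - set(GROUPS)
    if bad_groups:
        raise FormatError(f"unknown group labels: {sorted(bad_groups)}")

    dup = table.duplicated(subset=["subject", "run"])
    if dup.any():
        key = table.loc[dup, ["subject", "run"]].iloc[0]
        raise FormatError(
            f"duplicate (subject, run) key: ({key['subject']!r}, {key['run']!r})"
        )

    varying = table.groupby("subject")["group"].nunique()
    if (varying > 1).any():
        subj = varying[varying > 1].index[0]
        raise FormatError(f"group label varies across runs of subject {subj!r}")

    unknown = []
    for col in feature_columns(table):
        values = table[col]
        if not pd.api.types.is_numeric_dtype(values):
            bad = values[~values.map(lambda v: pd.isna(v) or isinstance(v, (int, float)))]
            row = bad.index[0] if len(bad) else values.index[0]
            raise FormatError(f"non-numeric value in column {col!r}, row {row}")
        finite = np.isfinite(values.to_numpy(dtype=float))
        missing = values.isna().to_numpy()
        if not (finite | missing).all():
            row = values.index[(~finite & ~missing)][0]
            raise FormatError(f"non-finite value in column {col!r}, row {row}")
        if not is_canonical(col):
            unknown.append(col)
    return unknown


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 comma-separated feature table and validate it.

    A missing ``run`` column is filled with 1 (single-run table).
    """
    try:
        table = pd.read_csv(path, encoding="utf-8")
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if "run" not in table.columns:
        table["run"] = 1
    table["subject"] = table["subject"].astype(str)
    for col in feature_columns(table):
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {col!r}: {exc}") from exc
    unknown = validate_feature_table(table)
    if unknown:
        log.warning("non-canonical feature columns preserved: %s", unknown)
    return table


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as UTF-8 comma-separated CSV ('.' decimal)."""
    validate_feature_table(table)
    table.to_csv(path, index=False, encoding="utf-8")


def average_runs(table: pd.DataFrame) -> pd.DataFrame:
    """Average repeated runs per subject into a single row.

    Each feature becomes the mean of its non-missing run values; a cell is
    missing only if it is missing in every run.  The returned table has a
    constant ``run`` of 1.  The operation is idempotent.
    """
    validate_feature_table(table)
    feats = feature_columns(table)
    grouped = table.groupby("subject", sort=False)
    out = grouped[feats].mean() if feats else pd.DataFrame(index=grouped.size().index)
    out.insert(0, "group", grouped["group"].first())
    out = out.reset_index()
    out.insert(2, "run", 1)
    return out


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def validate_clinical_scores(scores: pd.DataFrame) -> None:
    for col in CLINICAL_COLUMNS:
        if col not in scores.columns:
            raise FormatError(f"clinical score table lacks column {col!r}")
    bad = set(scores["group"]) - {"PSP", "MSA"}
    if bad:
        raise FormatError(
            f"clinical scores are defined for PSP/MSA only, got groups {sorted(bad)}"
        )
    numeric = scores[list(CLINICAL_COLUMNS[2:])].to_numpy(dtype=float)
    if not np.isfinite(numeric).all():
        raise FormatError("clinical scores must be finite")


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    try:
        scores = pd.read_csv(path, encoding="utf-8")
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    scores["subject"] = scores["subject"].astype(str)
    validate_clinical_scores(scores)
    return scores


def write_clinical_csv(scores: pd.DataFrame, path: str | Path) -> None:
    validate_clinical_scores(scores)
    scores.to_csv(path, index=False, encoding="utf-8")
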