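"""Canonical registry of acoustic features.

Every feature is identified by a canonical id ``"<base>_<task>"`` where the
task subscript is one of

* ``a`` — sustained phonation of the vowel /a/,
* ``s`` — fast /pa/-/ta/-/ka/ syllable repetition,
* ``m`` — monologue,
* ``t`` — reading passage.

The registry carries, per feature, its measurement unit, the speech
subsystem it probes (respiration, phonation, articulation, prosody,
timing), the dysarthria subtype whose perceptual correlate it targets
(hypokinetic, ataxic, spastic) and the *direction* of impairment: ``+1``
when larger raw values mean worse speech and ``-1`` when smaller raw
values mean worse speech.  All modules resolve feature columns through
this registry so that a table column is either canonical or explicitly
flagged as foreign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

TASKS = ("a", "s", "m", "t")
GROUPS = ("HC", "PD", "PSP", "MSA")
SUBSYSTEMS = ("respiration", "phonation", "articulation", "prosody", "timing")
DYSARTHRIA_TYPES = ("hypokinetic", "ataxic", "spastic")


@dataclass(frozen=True)
class FeatureSpec:
    """Registry entry for one canonical feature."""

    feature_id: str
    base: str
    task: str
    unit: str
    direction: int
    subsystem: str
    dysarthria_type: str
    description: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task subscript {self.task!r}")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.subsystem not in SUBSYSTEMS:
            raise ValueError(f"unknown subsystem {self.subsystem!r}")
        if self.dysarthria_type not in DYSARTHRIA_TYPES:
            raise ValueError(f"unknown dysarthria type {self.dysarthria_type!r}")


def _load_registry() -> dict[str, FeatureSpec]:
    text = resources.files("speechdx.data").joinpath("feature_registry.json").read_text()
    raw = json.loads(text)
    registry = {}
    for fid, entry in raw["features"].items():
        registry[fid] = FeatureSpec(
            feature_id=fid,
            base=entry["base"],
            task=entry["task"],
            unit=entry["unit"],
            direction=int(entry["direction"]),
            subsystem=entry["subsystem"],
            dysarthria_type=entry["dysarthria_type"],
            description=entry["description"],
        )
    return registry


@lru_cache(maxsize=1)
def registry() -> dict[str, FeatureSpec]:
    """Return the canonical feature registry (id -> :class:`FeatureSpec`)."""
    return _load_registry()


def canonical_features() -> list[str]:
    """All canonical feature ids, in registry order."""
    return list(registry())


def direction_map() -> dict[str, int]:
    """Default impairment orientation per canonical feature id."""
    return {fid: spec.direction for fid, spec in registry().items()}


def subsystem_of(feature_id: str) -> str:
    return registry()[feature_id].subsystem


def is_canonical(feature_id: str) -> bool:
    return feature_id in registry()


# Columns required to evaluate the subsystem features and both families of
# composite indices from a z-score table.
SUBSYSTEM_FEATURE_COLUMNS: dict[str, tuple[str, ...]] = {
    "F_resp": ("RLR_m", "RLR_t", "PIR_m", "PIR_t", "RSR_m", "RSR_t"),
    "F_phon": ("jitter_a", "GVI_m", "GVI_t", "stdF0_a"),
    "F_art": ("RFA_m", "RFA_t", "stdPSD_a"),
    "F_pros": ("stdF0_m", "stdF0_t"),
    "F_time": ("EST_m", "RST_m", "AST_t"),
}

SSI_EXTRA_COLUMNS: tuple[str, ...] = ("DUS_m",)

DTI_EXTRA_COLUMNS: tuple[str, ...] = ("VD_s", "DDKI_s", "NSR_t", "DDKR_s", "PSI_a")

INDEX_COLUMNS: tuple[str, ...] = tuple(
    dict.fromkeys(
        c
        for cols in SUBSYSTEM_FEATURE_COLUMNS.values()
        for c in cols
    )
) + SSI_EXTRA_COLUMNS + DTI_EXTRA_COLUMNS
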