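"""Composite speech indices built from impairment-oriented z-scores.

Two families of linear composites summarise the z-scored acoustic
features of each subject:

* **Subsystem features and indices** — one composite per speech
  subsystem (respiration, phonation, articulation, prosody, timing),
  combined into two subsystem indices.  SSI1 aggregates the dimensions
  that are more affected in PSP (respiratory dysfunction, imprecise stop
  consonants, monopitch); SSI2 aggregates the dimensions more affected in
  MSA (articulatory decay, phonatory instability, timing abnormalities).
  The pair (SSI1, SSI2) is the composite subsystem index CSSI.

* **Dysarthria-type indices** — hypokinetic (H1, H2), ataxic (A1, A2)
  and spastic (S1) composites, combined into DTI1 = H1 + (A1 + S1)/2 and
  DTI2 = H2 + A2.  The pair (DTI1, DTI2) is the composite dysarthria-type
  index CDTI.

All weights are fixed by design and are not refit; the point of this
module is an exact, reproducible transcription of the published
composites.  Inside composites, within-group averages carry weight 1 and
the emphasised term carries weight 2 (e.g. the speech-respiration rate
inside the respiration feature, or pitch fluctuation inside the phonation
feature).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .exceptions import ValidationError
from .registry import (
    DTI_EXTRA_COLUMNS,
    SSI_EXTRA_COLUMNS,
    SUBSYSTEM_FEATURE_COLUMNS,
)

SUBSYSTEM_FEATURES = ("F_resp", "F_phon", "F_art", "F_pros", "F_time")
SUBSYSTEM_INDICES = ("SSI1", "SSI2")
TYPE_FEATURES = ("H1", "H2", "H_art", "H_phon", "H_time", "A1", "A2", "S1")
TYPE_INDICES = ("DTI1", "DTI2")
ALL_INDEX_COLUMNS = SUBSYSTEM_FEATURES + SUBSYSTEM_INDICES + TYPE_FEATURES + TYPE_INDICES


def _require(z: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in z.columns]
    if missing:
        raise ValidationError(f"z-table lacks required columns: {missing}")


def subsystem_features(z: pd.DataFrame) -> pd.DataFrame:
    """Per-subject subsystem composites F_resp, F_phon, F_art, F_pros, F_time.

    *z* is a z-score table (rows = subjects, columns = canonical feature
    ids).  Returns a frame with one column per composite, aligned on the
    input index.
    """
    needed = [c for cols in SUBSYSTEM_FEATURE_COLUMNS.values() for c in cols]
    _require(z, needed)
    out = pd.DataFrame(index=z.index)
    out["F_resp"] = 0.5 * (
        (z["RLR_m"] + z["RLR_t"] + z["PIR_m"] + z["PIR_t"]) / 4
        + z["RSR_m"]
        + z["RSR_t"]
    )
    out["F_phon"] = 0.5 * (
        (z["jitter_a"] + z["GVI_m"] + z["GVI_t"]) / 3 + 2 * z["stdF0_a"]
    )
    out["F_art"] = (z["RFA_m"] + z["RFA_t"] + z["stdPSD_a"]) / 3
    out["F_pros"] = (z["stdF0_m"] + z["stdF0_t"]) / 2
    out["F_time"] = (z["EST_m"] + z["RST_m"] + z["AST_t"]) / 3
    return out


def subsystem_indices(z: pd.DataFrame) -> pd.DataFrame:
    """Subsystem indices SSI1 and SSI2 (the CSSI pair) per subject."""
    _require(z, SSI_EXTRA_COLUMNS)
    f = subsystem_features(z)
    out = pd.DataFrame(index=z.index)
    out["SSI1"] = f["F_resp"] + z["DUS_m"] / 2 + f["F_pros"] / 2
    out["SSI2"] = f["F_art"] + f["F_phon"] / 2 + f["F_time"] / 2
    return out


def dysarthria_type_indices(z: pd.DataFrame) -> pd.DataFrame:
    """Dysarthria-type composites and the indices DTI1, DTI2 (the CDTI pair).

    H1 coincides with SSI1 by construction; H2 rebuilds the hypokinetic
    part of SSI2 from its articulation, phonation and timing constituents,
    while A2 isolates the sustained-phonation ataxic part.  A1 (syllable
    timing) and S1 (spastic rate/subharmonics) extend the assessment with
    the syllable-repetition task.
    """
    _require(z, DTI_EXTRA_COLUMNS)
    ssi = subsystem_indices(z)
    out = pd.DataFrame(index=z.index)
    out["H1"] = ssi["SSI1"]
    out["H_art"] = (z["RFA_m"] + z["RFA_t"]) / 2
    out["H_phon"] = (z["jitter_a"] + z["GVI_m"] + z["GVI_t"]) / 3
    out["H_time"] = (z["EST_m"] + z["RST_m"] + z["AST_t"]) / 3
    out["H2"] = out["H_art"] + out["H_phon"] / 2 + out["H_time"] / 2
    out["A1"] = (z["VD_s"] + z["DDKI_s"]) / 2
    out["A2"] = (z["stdF0_a"] + z["stdPSD_a"]) / 2
    out["S1"] = 0.5 * ((z["NSR_t"] + z["DDKR_s"]) / 2 + z["PSI_a"])
    out["DTI1"] = out["H1"] + (out["A1"] + out["S1"]) / 2
    out["DTI2"] = out["H2"] + out["A2"]
    return out


def compute_indices(z: pd.DataFrame) -> pd.DataFrame:
    """All subsystem features and indices plus dysarthria-type indices.

    Accepts either a bare z-matrix or a full z-table with subject/group/run
    metadata columns, which are carried through to the output.
    """
    meta = [c for c in ("subject", "group", "run") if c in z.columns]
    zz = z.drop(columns=meta)
    out = pd.concat(
        [z[meta], subsystem_features(zz), subsystem_indices(zz),
         dysarthria_type_indices(zz)],
        axis=1,
    )
    return out
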