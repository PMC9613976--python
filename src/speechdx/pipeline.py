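"""End-to-end analysis pipeline: cohort -> z-scores -> indices -> stats -> LOSO.

The pipeline mirrors the analysis order of the underlying study design:
feature acquisition (synthetic cohort or a user-supplied feature table),
averaging of repeated runs, HC-referenced z-scoring, composite index
computation (optionally preceded by the subset-average search), group
statistics, index/severity correlations and LOSO logistic-regression
classification for the three pairwise contrasts.  All outputs are
plain CSV/JSON plus a markdown report; a MANIFEST file lists every
output with its SHA-256 content hash.  Given a fixed configuration and
seed the bundle is byte-identical across runs (no timestamps are
written).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import classify as clf
from . import indices as idx
from . import normalize, search, stats, synthesis
from .exceptions import FormatError, SpeechDxError, ValidationError
from .io import (
    average_runs,
    read_clinical_csv,
    read_feature_csv,
    write_clinical_csv,
    write_feature_csv,
)
from .registry import SUBSYSTEM_FEATURE_COLUMNS

log = logging.getLogger(__name__)

STAGE_EXIT_CODES = {
    "config": 9,
    "simulate": 10,
    "ingest": 11,
    "normalize": 12,
    "indices": 13,
    "search": 14,
    "stats": 15,
    "classify": 16,
    "report": 17,
}

CONTRAST_SPECS = {
    "PSP_vs_MSA": ("PSP", "MSA"),
    "PD_vs_MSA": ("PD", "MSA"),
    "PD_vs_PSP": ("PD", "PSP"),
}

PREDICTOR_SETS = {
    "SSI1": ("SSI1",),
    "SSI2": ("SSI2",),
    "CSSI": ("SSI1", "SSI2"),
    "DTI1": ("DTI1",),
    "DTI2": ("DTI2",),
    "CDTI": ("DTI1", "DTI2"),
}


class StageError(SpeechDxError):
    """Pipeline failure tagged with the stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    input_table: str | None = None  # CSV path; None -> simulate
    input_clinical: str | None = None
    input_audio_manifest: str | None = None  # CSV: subject,group,task,wav
    stop_after: str | None = None  # stage name; None = run everything
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(synthesis.DEFAULT_N_PER_GROUP)
    )
    effect_scale: float = 1.0
    severity_coupling: float | None = None
    correlation_rho: float = 0.0
    direction_overrides: Mapping[str, int] = field(default_factory=dict)
    search_alpha: float = 0.05
    run_search: bool = True
    contrasts: Sequence[str] = ("PSP_vs_MSA", "PD_vs_MSA", "PD_vs_PSP")
    predictor_sets: Sequence[str] = tuple(PREDICTOR_SETS)

    def __post_init__(self) -> None:
        self.contrasts = tuple(self.contrasts)
        self.predictor_sets = tuple(self.predictor_sets)
        if self.stop_after is not None and self.stop_after not in STAGE_EXIT_CODES:
            raise ValidationError(f"unknown stage {self.stop_after!r}")
        unknown = set(self.contrasts) - set(CONTRAST_SPECS)
        if unknown:
            raise ValidationError(f"unknown contrasts: {sorted(unknown)}")
        unknown = set(self.predictor_sets) - set(PREDICTOR_SETS)
        if unknown:
            raise ValidationError(f"unknown predictor sets: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        try:
            return cls(**raw)
        except (TypeError, ValidationError) as exc:
            raise StageError("config", exc) from exc

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "input_table": self.input_table,
            "input_clinical": self.input_clinical,
            "input_audio_manifest": self.input_audio_manifest,
            "stop_after": self.stop_after,
            "n_per_group": dict(self.n_per_group),
            "effect_scale": self.effect_scale,
            "severity_coupling": self.severity_coupling,
            "correlation_rho": self.correlation_rho,
            "direction_overrides": dict(self.direction_overrides),
            "search_alpha": self.search_alpha,
            "run_search": self.run_search,
            "contrasts": list(self.contrasts),
            "predictor_sets": list(self.predictor_sets),
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, complete: bool) -> None:
    lines = [f"complete: {str(complete).lower()}"]
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "MANIFEST":
            lines.append(f"{_sha256(p)}  {p.relative_to(out_dir)}")
    (out_dir / "MANIFEST").write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; write the report bundle; return a summary.

    On a stage failure, partial outputs are retained and the MANIFEST
    marks the bundle incomplete; the raised :class:`StageError` carries a
    stage-specific exit code.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}
    try:
        _run(config, out, summary)
    except StageError:
        _write_manifest(out, complete=False)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        _write_manifest(out, complete=False)
        raise StageError("report", exc) from exc
    _write_manifest(out, complete=True)
    return summary


@contextmanager
def _stage(name: str):
    """Time a pipeline stage and tag its failures with the stage name."""
    t0 = time.perf_counter()
    try:
        yield
    except StageError:
        raise
    except SpeechDxError as exc:
        raise StageError(name, exc) from exc
    log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)


def extract_audio_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Extract front-end features for the recordings listed in a manifest.

    The manifest is a CSV with columns ``subject``, ``group``, ``task``
    (a or s) and ``wav``.  Every referenced file must exist; a missing
    file aborts naming it.  Returns a feature table with one row per
    subject carrying the extracted columns.
    """
    from . import audio as aud
    from . import frontend as fe

    manifest = pd.read_csv(manifest_path)
    required = {"subject", "group", "task", "wav"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"audio manifest lacks columns {sorted(missing)}")
    base = Path(manifest_path).parent
    rows: dict[str, dict] = {}
    for rec in manifest.itertuples(index=False):
        wav = Path(rec.wav)
        if not wav.is_absolute():
            wav = base / wav
        if not wav.exists():
            raise ValidationError(f"audio manifest references missing file: {wav}")
        if rec.task not in ("a", "s"):
            raise ValidationError(
                f"audio manifest task must be 'a' or 's', got {rec.task!r}"
            )
        x, fs = aud.read_wav(wav)
        pitch = fe.track_pitch(x, fs)
        row = rows.setdefault(str(rec.subject),
                              {"subject": str(rec.subject), "group": rec.group})
        if rec.task == "a":
            feats = fe.phonation_features(pitch, x, fs)
            row.update({"stdF0_a": feats["stdF0_a"], "jitter_a": feats["jitter"],
                        "PSI_a": feats["PSI"], "stdPSD_a": feats["stdPSD"]})
        else:
            seg = fe.segment_speech(x, fs, pitch)
            feats = fe.syllable_features(x, fs, seg)
            row.update({"VD_s": feats["VD"], "DDKI_s": feats["DDKI"],
                        "DDKR_s": feats["DDKR"]})
    table = pd.DataFrame(list(rows.values()))
    table.insert(2, "run", 1)
    return table


def _run(config: PipelineConfig, out: Path, summary: dict) -> None:
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    def done(stage: str) -> bool:
        return config.stop_after == stage

    # --- acquire -----------------------------------------------------------
    if config.input_table is None and config.input_audio_manifest is None:
        with _stage("simulate"):
            spec = synthesis.CohortSpec(
                n_per_group=dict(config.n_per_group),
                effect_scale=config.effect_scale,
                severity_coupling=config.severity_coupling,
                correlation_rho=config.correlation_rho,
                seed=config.seed,
            )
            table, clinical = synthesis.simulate_feature_cohort(spec)
    else:
        with _stage("ingest"):
            if config.input_audio_manifest is not None:
                extracted = extract_audio_manifest(config.input_audio_manifest)
                if config.input_table is not None:
                    table = read_feature_csv(config.input_table)
                    table = table.merge(
                        extracted.drop(columns=["group", "run"]),
                        on="subject", how="left",
                    )
                else:
                    table = extracted
            else:
                table = read_feature_csv(config.input_table)
            clinical = (
                read_clinical_csv(config.input_clinical)
                if config.input_clinical
                else None
            )

    table = average_runs(table)
    write_feature_csv(table, out / "features.csv")
    if clinical is not None and not clinical.empty:
        write_clinical_csv(clinical, out / "clinical.csv")
    if done("simulate") or done("ingest"):
        return

    # --- normalise ---------------------------------------------------------
    with _stage("normalize"):
        norm = normalize.fit_normalizer(table, directions=config.direction_overrides)
        ztable = normalize.apply_normalizer(norm, table)
        norm.to_json(out / "normalizer.json")
        ztable.to_csv(out / "zscores.csv", index=False)
    if done("normalize"):
        return

    # --- search (audit of the composite design) ----------------------------
    if config.run_search:
        with _stage("search"):
            results = {}
            for name, cols in SUBSYSTEM_FEATURE_COLUMNS.items():
                cols = [c for c in cols if c in ztable.columns]
                if len(cols) < 1:
                    continue
                res = search.search_subsystem(
                    ztable,
                    cols,
                    alpha=config.search_alpha,
                    subsystem=name,
                )
                results[name] = res.to_dict()
            (out / "search.json").write_text(
                json.dumps(results, indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            summary["search"] = results
    if done("search"):
        return

    # --- indices -----------------------------------------------------------
    with _stage("indices"):
        index_table = idx.compute_indices(ztable)
        index_table.to_csv(out / "indices.csv", index=False)
    if done("indices"):
        return

    # --- group statistics and correlations ---------------------------------
    with _stage("stats"):
        cmp_tab = stats.comparison_table(
            index_table, columns=list(idx.SUBSYSTEM_FEATURES + idx.SUBSYSTEM_INDICES
                                      + idx.TYPE_INDICES)
        )
        cmp_tab.to_csv(out / "group_comparisons.csv", index=False)
        corr_rows = []
        if clinical is not None and not clinical.empty:
            merged = index_table.merge(clinical, on=["subject", "group"])
            for index_name in ("SSI1", "SSI2", "DTI1", "DTI2"):
                for score in (
                    "nnipps_bradyrigidity",
                    "nnipps_bulbar",
                    "nnipps_cerebellar",
                    "nnipps_total",
                ):
                    r, p, method = stats.correlate(
                        merged[index_name].to_numpy(), merged[score].to_numpy()
                    )
                    corr_rows.append(
                        {"index": index_name, "score": score, "r": r, "p": p,
                         "method": method}
                    )
            pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
        summary["correlations"] = corr_rows
    if done("stats"):
        return

    # --- classification -----------------------------------------------------
    with _stage("classify"):
        class_rows = []
        reports = {}
        for contrast_name in config.contrasts:
            a, b = CONTRAST_SPECS[contrast_name]
            positive = clf.POSITIVE_LABELS[(a, b)]
            sub = index_table[index_table["group"].isin((a, b))]
            for set_name in config.predictor_sets:
                cols = PREDICTOR_SETS[set_name]
                report = clf.loso_logistic(
                    sub[list(cols)],
                    sub["group"].to_numpy(),
                    positive_label=positive,
                    subjects=sub["subject"].tolist(),
                )
                reports[f"{contrast_name}:{set_name}"] = report
                class_rows.append(
                    {
                        "contrast": contrast_name,
                        "predictors": set_name,
                        "auc": report.auc,
                        "accuracy": report.accuracy,
                        "sensitivity": report.sensitivity,
                        "specificity": report.specificity,
                    }
                )
                report.per_subject_frame().to_csv(
                    out / f"loso_{contrast_name}_{set_name}.csv", index=False
                )
        class_tab = pd.DataFrame(class_rows)
        class_tab.to_csv(out / "classification.csv", index=False)
        (out / "boundaries.json").write_text(
            json.dumps(
                {k: r.boundary for k, r in reports.items()}, indent=2, sort_keys=True
            )
            + "\n",
            encoding="utf-8",
        )
        summary["classification"] = class_rows
    if done("classify"):
        return

    # --- report -------------------------------------------------------------
    try:
        with _stage("report"):
            _write_report(out, cmp_tab, class_tab, corr_rows)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("report", exc) from exc


def _write_report(out: Path, cmp_tab: pd.DataFrame, class_tab: pd.DataFrame,
                  corr_rows: list[dict]) -> None:
    lines = ["# Speech-index analysis report", ""]
    lines += ["## Group comparisons (indices)", "",
              cmp_tab.to_markdown(index=False, floatfmt=".3f"), ""]
    lines += ["## LOSO classification", "",
              class_tab.to_markdown(index=False, floatfmt=".3f"), ""]
    if corr_rows:
        lines += ["## Index / NNIPPS correlations", "",
                  pd.DataFrame(corr_rows).to_markdown(index=False, floatfmt=".3f"), ""]
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
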