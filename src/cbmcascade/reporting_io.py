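"""Shared I/O, overlap accounting and end-to-end orchestration.

Feature tables travel as wide CSV: the first five columns are
``sample_id, matrix, species, group, role``; every remaining column is one
feature's intensity. The format is deliberately post-peak-picking — raw
spectra and vendor formats are out of scope. Optional per-feature m/z and
retention-time metadata can ride along in a sidecar CSV when
tolerance-based matching is needed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import chemometrics
from .cascade import CascadeConfig, CascadeResult, run_cascade
from .classifier_eval import evaluate_panel
from .feature_filtering import define_features
from .synthetic_data import (
    FeatureUniverses,
    GeneratedStudy,
    PlantedEffect,
    StudyConfig,
    VennConfig,
    build_feature_universes,
    generate_study,
    plan_effects,
)
from .tables import SAMPLE_META_COLUMNS, FeatureTable, FeatureTableError

log = logging.getLogger(__name__)

META_COLUMNS = ("sample_id",) + SAMPLE_META_COLUMNS


# ---------------------------------------------------------------------------
# feature-table CSV round trip
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a table as wide CSV (metadata columns first, then features)."""
    path = Path(path)
    out = table.sample_meta[list(SAMPLE_META_COLUMNS)].copy()
    out.insert(0, "sample_id", table.intensities.index)
    frame = pd.concat(
        [out.reset_index(drop=True),
         table.intensities.reset_index(drop=True)], axis=1
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a wide-CSV feature table, validating the header contract."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise FeatureTableError(f"{path.name}: missing metadata column(s) {missing}")
    feature_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if not feature_cols:
        raise FeatureTableError(f"{path.name}: no feature columns found")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise FeatureTableError(f"{path.name}: duplicate sample_id(s) {dup}")
    intensities = frame[feature_cols].copy()
    for col in feature_cols:
        converted = pd.to_numeric(intensities[col], errors="coerce")
        if converted.isna().any() and not intensities[col].isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise FeatureTableError(
                f"{path.name}: non-numeric intensity at row {row + 2}, column {col!r}"
            )
        intensities[col] = converted
    intensities.index = pd.Index(frame["sample_id"].astype(str))
    intensities.index.name = None
    sample_meta = frame[list(SAMPLE_META_COLUMNS)].copy()
    sample_meta.index = intensities.index
    return FeatureTable(intensities=intensities, sample_meta=sample_meta)


def save_study(study: GeneratedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the four cohort tables as CSV and the planted truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("muscle1", "muscle2", "serum", "human"):
        paths[name] = write_feature_table(getattr(study, name), outdir / f"{name}.csv")
    truth = [dataclasses.asdict(e) for e in study.truth]
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    return paths


def load_truth(path: str | Path) -> list[PlantedEffect]:
    return [PlantedEffect(**d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# overlap accounting
# ---------------------------------------------------------------------------

REGION_NAMES = (
    "unique_muscle",
    "unique_mouse_plasma",
    "unique_human_plasma",
    "pair_muscle_mouse_plasma",
    "pair_mouse_human_plasma",
    "pair_muscle_human_plasma",
    "triple",
)


def compute_overlap(
    muscle, mouse_plasma, human_plasma
) -> dict[str, int]:
    """Seven Venn region counts over three feature universes by set algebra.

    Accepts :class:`FeatureTable` objects or plain feature-ID iterables.
    Pairwise totals (region + triple) are included under ``total_*`` keys.
    """
    def ids(x) -> set[str]:
        return set(x.feature_ids) if isinstance(x, FeatureTable) else set(x)

    mu, mp, hp = ids(muscle), ids(mouse_plasma), ids(human_plasma)
    counts = {
        "unique_muscle": len(mu - mp - hp),
        "unique_mouse_plasma": len(mp - mu - hp),
        "unique_human_plasma": len(hp - mu - mp),
        "pair_muscle_mouse_plasma": len((mu & mp) - hp),
        "pair_mouse_human_plasma": len((mp & hp) - mu),
        "pair_muscle_human_plasma": len((mu & hp) - mp),
        "triple": len(mu & mp & hp),
    }
    counts["total_muscle_mouse_plasma"] = len(mu & mp)
    counts["total_mouse_human_plasma"] = len(mp & hp)
    counts["total_muscle_human_plasma"] = len(mu & hp)
    return counts


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One end-to-end run: simulate (or load), filter, model, cascade, classify."""

    study: StudyConfig | None = None
    table_paths: Mapping[str, str] | None = None  # muscle1/muscle2/serum/human
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    blank_ratio: float = 5.0
    run_chemometrics: bool = True
    run_classifier: bool = True
    n_train_cases: int = 14
    n_trees: int = 500
    seed: int = 0
    outdir: str = "results/run"


def default_study_config(seed: int = 0, n_true_cbm: int = 9) -> StudyConfig:
    """Study conditions used when no explicit recipe is given: default
    cohort sizes and overlap structure, with a planted signature of
    ``n_true_cbm`` genuine candidate biomarkers among muscle-only,
    serum-discordant (legal) and human-discordant (must-reject) decoys."""
    venn = VennConfig()
    universes = build_feature_universes(venn, seed=seed)
    effects = plan_effects(
        universes,
        n_true_cbm=n_true_cbm,
        n_muscle_only=10,
        n_discordant_serum=2,
        n_discordant_human=5,
        seed=seed + 101,
    )
    return StudyConfig(venn=venn, effects=tuple(effects), seed=seed)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline and write every artifact under ``outdir``.

    Returns a summary dict (also written as JSON plus a markdown digest).
    Any stage failure aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    truth = None

    stage = "simulate/load"
    try:
        if config.study is not None:
            study = generate_study(config.study)
            save_study(study, outdir / "study")
            tables = {
                "muscle1": study.muscle1, "muscle2": study.muscle2,
                "serum": study.serum, "human": study.human,
            }
            truth = study.truth
        elif config.table_paths:
            tables = {k: read_feature_table(v) for k, v in config.table_paths.items()}
        else:
            raise ValueError("RunConfig needs a study recipe or table paths")

        stage = "filter"
        filtered = {}
        counts = {}
        for name, tbl in tables.items():
            counts[name] = {"raw": tbl.n_features}
            filtered[name] = define_features(tbl, blank_ratio=config.blank_ratio)
            counts[name]["filtered"] = filtered[name].n_features
        summary["feature_counts"] = counts
        summary["overlap"] = compute_overlap(
            filtered["muscle1"], filtered["serum"], filtered["human"]
        )

        stage = "chemometrics"
        if config.run_chemometrics:
            cc = config.cascade
            models = {}
            for name, (case, ctrl) in {
                "muscle1": (cc.case_label_mouse, cc.control_label_mouse),
                "serum": (cc.case_label_mouse, cc.control_label_mouse),
                "human": (cc.case_label_human, cc.control_label_human),
            }.items():
                s = chemometrics.plsda_summary(
                    filtered[name], case, ctrl, seed=config.seed
                )
                models[name] = s.to_dict()
            summary["plsda"] = models

        stage = "cascade"
        result: CascadeResult = run_cascade(
            muscle1=filtered["muscle1"], muscle2=filtered["muscle2"],
            serum=filtered["serum"], human=filtered["human"], cfg=config.cascade,
        )
        summary["stage_counts"] = result.stage_counts
        summary["panel"] = result.panel_features
        result.panel_table().to_csv(outdir / "panel.csv")
        _json_dump(
            {
                "stage_counts": result.stage_counts,
                "stages": {
                    s.stage: {"surviving": sorted(s.surviving), "n_tested": s.n_tested,
                              "n_unmatched": s.n_unmatched}
                    for s in result.stages
                },
                "panel": result.panel_features,
            },
            outdir / "cascade.json",
        )
        if truth is not None:
            from .cascade import score_recovery

            summary["recovery"] = score_recovery(result, truth)

        stage = "classify"
        if config.run_classifier and result.panel_features:
            report, split = evaluate_panel(
                filtered["human"], result.panel_features,
                case_label=config.cascade.case_label_human,
                control_label=config.cascade.control_label_human,
                n_train_cases=config.n_train_cases,
                n_trees=config.n_trees, seed=config.seed,
            )
            summary["classifier"] = report.to_dict()
            summary["classifier"]["n_train"] = len(split.train_ids)
            report.roc_points.to_csv(outdir / "roc.csv", index=False)
        elif config.run_classifier:
            summary["classifier"] = None
            log.warning("empty panel: classifier stage skipped")
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _json_dump(summary, outdir / "summary.json")
    (outdir / "summary.md").write_text(_markdown_summary(summary))
    return summary


def _markdown_summary(summary: dict) -> str:
    lines = ["# Pipeline run summary", ""]
    lines.append(f"- seed: {summary['seed']}")
    if "stage_counts" in summary:
        lines.append(
            "- cascade stage counts (discovery -> validation -> serum -> human): "
            + " -> ".join(map(str, summary["stage_counts"]))
        )
        lines.append(f"- candidate-biomarker panel ({len(summary['panel'])}): "
                     + ", ".join(summary["panel"]))
    if summary.get("plsda"):
        lines.append("")
        lines.append("## PLS-DA diagnostics")
        for name, d in summary["plsda"].items():
            lines.append(
                f"- {name}: A={d['n_components']} R2X={d['r2x_cum']} "
                f"R2Y={d['r2y_cum']} Q2={d['q2_cum']} CV-ANOVA p={d['cv_anova_p']:.3g}"
            )
    if summary.get("classifier"):
        c = summary["classifier"]
        lines.append("")
        lines.append("## Random-forest panel evaluation")
        lines.append(
            f"- sensitivity {c['sensitivity']:.3f}, specificity "
            f"{c['specificity']:.3f}, OOB error {c['oob_error']:.3f}, AUC {c['auc']:.3f}"
        )
        lines.append(f"- caveat: {c['caveat']}")
    if "recovery" in summary:
        r = summary["recovery"]
        lines.append("")
        lines.append(
            f"## Planted-truth recovery\n- recovered {r['n_recovered']}/{r['n_true']} "
            f"true candidate biomarkers; {r['n_discordant_leaked']} discordant leaked"
        )
    return "\n".join(lines) + "\n"
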