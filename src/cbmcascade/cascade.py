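"""The staged cross-species biomarker translation cascade.

A disease signature discovered in model-organism tissue is carried step by
step toward the human circulation:

1. **discover** — features significantly different (p < 0.05) between case
   and control in the discovery muscle cohort;
2. **validate** — of those, features replicating in an independent muscle
   cohort (p < 0.05 with the same direction of change);
3. **translate_to_serum** — of those, features also dysregulated in paired
   serum at a deliberately looser p < 0.1 (the serum metabolome is noisier
   and the serum stage re-tests an already validated signature). No
   direction agreement with muscle is demanded: a metabolite may
   legitimately move opposite ways in tissue and circulation;
4. **translate_to_human** — of those, features significant in human plasma
   (p < 0.05) whose fold change lies on the same side of 1 as in mouse
   serum. Serum-to-human direction concordance is the specificity guard of
   the whole design: a blood marker must behave consistently across species.

All thresholds are strict inequalities on raw (uncorrected) p-values.
Features are matched across tables by shared identifier by default; an
m/z + retention-time tolerance mode exists for data where identifiers do
not carry across matrices.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

from .synthetic_data import GeneratedStudy
from .tables import FeatureTable
from .univariate_stats import FeatureStat, test_all

log = logging.getLogger(__name__)

Stage = Literal["discovery", "validation", "serum", "human"]


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and rules of the four-stage translation cascade."""

    p_discovery: float = 0.05
    p_validation: float = 0.05
    require_validation_direction: bool = True
    p_serum: float = 0.1
    p_human: float = 0.05
    require_serum_human_direction: bool = True
    translate_from: Literal["validated", "discovery"] = "validated"
    matching: Literal["identifier", "mz_rt"] = "identifier"
    mz_tol_ppm: float = 10.0
    rt_tol_min: float = 0.5
    case_label_mouse: str = "A17.1"
    control_label_mouse: str = "FvB"
    case_label_human: str = "OPMD"
    control_label_human: str = "Control"
    normality_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_discovery", "p_validation", "p_serum", "p_human"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def replace(self, **kw) -> "CascadeConfig":
        return replace(self, **kw)


@dataclass
class StageResult:
    """Survivors and bookkeeping of one cascade stage."""

    stage: Stage
    surviving: list[str]
    stats: dict[str, FeatureStat]
    n_tested: int
    n_unmatched: int = 0

    @property
    def surviving_set(self) -> frozenset[str]:
        return frozenset(self.surviving)


@dataclass
class CascadeResult:
    """Ordered stage results plus the final candidate-biomarker panel."""

    stages: list[StageResult]
    panel: dict[str, dict[str, FeatureStat]]  # feature -> stage name -> stat
    config: CascadeConfig

    @property
    def stage_counts(self) -> list[int]:
        return [len(s.surviving) for s in self.stages]

    @property
    def panel_features(self) -> list[str]:
        return list(self.panel)

    def counts_line(self) -> str:
        return " -> ".join(str(c) for c in self.stage_counts)

    def panel_table(self):
        """Panel as a wide per-matrix p/FC table (candidate-panel layout)."""
        import pandas as pd

        rows = {}
        for fid, per_stage in self.panel.items():
            row = {}
            for stage, stat in per_stage.items():
                if stat is None:
                    continue
                row[f"{stage}_p"] = stat.p_value
                row[f"{stage}_fc"] = stat.fold_change
            rows[fid] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def concordant(fc_a: float, fc_b: float) -> bool:
    """Same side of 1 in both matrices; a flat fold change (FC = 1) fails."""
    la, lb = math.log(fc_a), math.log(fc_b)
    return la * lb > 0


def _as_stats_map(stats: Iterable[FeatureStat] | Mapping[str, FeatureStat]) -> dict[str, FeatureStat]:
    if isinstance(stats, Mapping):
        return dict(stats)
    return {s.feature_id: s for s in stats}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def discover(
    muscle1_stats: Iterable[FeatureStat] | Mapping[str, FeatureStat],
    cfg: CascadeConfig = CascadeConfig(),
) -> StageResult:
    """Stage 1: tissue signature — features with discovery p below threshold."""
    stats = _as_stats_map(muscle1_stats)
    if not stats:
        warnings.warn("discovery received no feature statistics", UserWarning)
    surviving = [f for f, s in stats.items() if s.p_value < cfg.p_discovery]
    log.info("discovery: %d / %d features significant", len(surviving), len(stats))
    return StageResult("discovery", surviving, stats, n_tested=len(stats))


def validate(
    discovery: StageResult,
    muscle2_stats: Iterable[FeatureStat] | Mapping[str, FeatureStat],
    cfg: CascadeConfig = CascadeConfig(),
) -> StageResult:
    """Stage 2: replication in an independent tissue cohort."""
    stats = _as_stats_map(muscle2_stats)
    surviving: list[str] = []
    unmatched = 0
    for f in discovery.surviving:
        s2 = stats.get(f)
        if s2 is None:
            unmatched += 1
            continue
        if s2.p_value >= cfg.p_validation:
            continue
        if cfg.require_validation_direction:
            s1 = discovery.stats[f]
            if not concordant(s1.fold_change, s2.fold_change):
                continue
        surviving.append(f)
    if unmatched:
        log.info("validation: %d discovery features absent from cohort 2", unmatched)
    return StageResult("validation", surviving, stats, n_tested=len(stats), n_unmatched=unmatched)


def match_features(
    source_table: FeatureTable,
    target_table: FeatureTable,
    cfg: CascadeConfig = CascadeConfig(),
) -> dict[str, str]:
    """Map source features onto target features.

    Identifier mode matches by exact ID equality. The mz_rt mode matches
    each source feature to the nearest target feature within the m/z (ppm)
    and retention-time tolerances; the assignment is injective, resolved
    greedily by smallest m/z distance, then smallest RT distance, then
    feature ID for full determinism.
    """
    if cfg.matching == "identifier":
        target = set(target_table.feature_ids)
        return {f: f for f in source_table.feature_ids if f in target}
    for tbl, name in ((source_table, "source"), (target_table, "target")):
        for col in ("mz", "rt"):
            if col not in tbl.feature_meta.columns:
                raise ValueError(f"mz_rt matching needs {col!r} in {name} feature_meta")
    candidates: list[tuple[float, float, str, str]] = []
    src = source_table.feature_meta
    tgt = target_table.feature_meta
    for sf in source_table.feature_ids:
        smz, srt = float(src.at[sf, "mz"]), float(src.at[sf, "rt"])
        for tf in target_table.feature_ids:
            tmz, trt = float(tgt.at[tf, "mz"]), float(tgt.at[tf, "rt"])
            dmz_ppm = abs(tmz - smz) / smz * 1e6
            drt = abs(trt - srt)
            if dmz_ppm <= cfg.mz_tol_ppm and drt <= cfg.rt_tol_min:
                candidates.append((dmz_ppm, drt, sf, tf))
    mapping: dict[str, str] = {}
    used_targets: set[str] = set()
    for _dmz, _drt, sf, tf in sorted(candidates):
        if sf in mapping or tf in used_targets:
            continue
        mapping[sf] = tf
        used_targets.add(tf)
    return mapping


def translate_to_serum(
    validated: StageResult,
    serum_stats: Iterable[FeatureStat] | Mapping[str, FeatureStat],
    cfg: CascadeConfig = CascadeConfig(),
    mapping: Mapping[str, str] | None = None,
) -> StageResult:
    """Stage 3: translation into the paired circulation at the looser p.

    Direction agreement with muscle is deliberately not required here.
    """
    stats = _as_stats_map(serum_stats)
    surviving: list[str] = []
    unmatched = 0
    for f in validated.surviving:
        serum_id = mapping.get(f, f) if mapping is not None else f
        s = stats.get(serum_id)
        if s is None:
            unmatched += 1
            continue
        if s.p_value < cfg.p_serum:
            surviving.append(serum_id)
    return StageResult("serum", surviving, stats, n_tested=len(stats), n_unmatched=unmatched)


def translate_to_human(
    serum_stage: StageResult,
    human_stats: Iterable[FeatureStat] | Mapping[str, FeatureStat],
    cfg: CascadeConfig = CascadeConfig(),
    mapping: Mapping[str, str] | None = None,
) -> StageResult:
    """Stage 4: human plasma significance plus serum/human direction
    concordance — the cross-species specificity rule."""
    stats = _as_stats_map(human_stats)
    surviving: list[str] = []
    unmatched = 0
    for f in serum_stage.surviving:
        human_id = mapping.get(f, f) if mapping is not None else f
        s = stats.get(human_id)
        if s is None:
            unmatched += 1
            continue
        if s.p_value >= cfg.p_human:
            continue
        if cfg.require_serum_human_direction:
            s_serum = serum_stage.stats[f]
            if not concordant(s_serum.fold_change, s.fold_change):
                continue
        surviving.append(human_id)
    return StageResult("human", surviving, stats, n_tested=len(stats), n_unmatched=unmatched)


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


def run_cascade_from_stats(
    muscle1_stats,
    muscle2_stats,
    serum_stats,
    human_stats,
    cfg: CascadeConfig = CascadeConfig(),
    serum_mapping: Mapping[str, str] | None = None,
    human_mapping: Mapping[str, str] | None = None,
) -> CascadeResult:
    """Run all four stages over pre-computed per-feature statistics."""
    d = discover(muscle1_stats, cfg)
    v = validate(d, muscle2_stats, cfg)
    source = v if cfg.translate_from == "validated" else StageResult(
        "validation", list(d.surviving), _as_stats_map(muscle2_stats),
        n_tested=v.n_tested,
    )
    s = translate_to_serum(source, serum_stats, cfg, mapping=serum_mapping)
    h = translate_to_human(s, human_stats, cfg, mapping=human_mapping)

    m1 = _as_stats_map(muscle1_stats)
    m2 = _as_stats_map(muscle2_stats)
    se = _as_stats_map(serum_stats)
    hu = _as_stats_map(human_stats)
    inv_h = {v_: k for k, v_ in (human_mapping or {}).items()}
    inv_s = {v_: k for k, v_ in (serum_mapping or {}).items()}
    panel: dict[str, dict[str, FeatureStat]] = {}
    for f in h.surviving:
        serum_id = inv_h.get(f, f)
        muscle_id = inv_s.get(serum_id, serum_id)
        panel[f] = {
            "muscle1": m1.get(muscle_id),
            "muscle2": m2.get(muscle_id),
            "serum": se.get(serum_id),
            "human": hu.get(f),
        }
    result = CascadeResult(stages=[d, v, s, h], panel=panel, config=cfg)
    log.info("cascade stage counts: %s", result.counts_line())
    return result


def run_cascade(
    study: GeneratedStudy | None = None,
    *,
    muscle1: FeatureTable | None = None,
    muscle2: FeatureTable | None = None,
    serum: FeatureTable | None = None,
    human: FeatureTable | None = None,
    cfg: CascadeConfig = CascadeConfig(),
) -> CascadeResult:
    """Run the cascade from four (already filtered) feature tables.

    Per-feature statistics are computed with the normality-routed test;
    feature matching across tables follows ``cfg.matching``.
    """
    if study is not None:
        muscle1, muscle2, serum, human = study.muscle1, study.muscle2, study.serum, study.human
    if any(t is None for t in (muscle1, muscle2, serum, human)):
        raise ValueError("run_cascade needs a study or all four tables")
    kw = dict(normality_alpha=cfg.normality_alpha)
    m1 = test_all(muscle1, cfg.case_label_mouse, cfg.control_label_mouse, **kw)
    m2 = test_all(muscle2, cfg.case_label_mouse, cfg.control_label_mouse, **kw)
    se = test_all(serum, cfg.case_label_mouse, cfg.control_label_mouse, **kw)
    hu = test_all(human, cfg.case_label_human, cfg.control_label_human, **kw)
    serum_mapping = human_mapping = None
    if cfg.matching == "mz_rt":
        serum_mapping = match_features(muscle1, serum, cfg)
        human_mapping = match_features(serum, human, cfg)
    return run_cascade_from_stats(
        m1, m2, se, hu, cfg, serum_mapping=serum_mapping, human_mapping=human_mapping
    )


def score_recovery(
    result: CascadeResult, truth: Sequence, roles: tuple[str, ...] = ("true_cbm",)
) -> dict[str, float]:
    """Score a cascade run against planted ground truth.

    Returns the recovered fraction of features whose planted role is in
    ``roles`` plus the count of planted serum/human-discordant features that
    leaked into the panel (should be zero when the concordance rule is on).
    """
    panel = set(result.panel_features)
    want = [e.feature_id for e in truth if e.role in roles]
    discordant = [e.feature_id for e in truth if e.role == "discordant_human"]
    return {
        "n_true": len(want),
        "n_recovered": sum(f in panel for f in want),
        "recovery": (sum(f in panel for f in want) / len(want)) if want else float("nan"),
        "n_discordant_leaked": sum(f in panel for f in discordant),
        "panel_size": len(panel),
    }
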