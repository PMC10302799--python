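"""Linked multi-matrix, multi-species synthetic metabolomics studies.

Real OPMD cohorts are not publicly available, so the pipeline is exercised on
generated studies that mimic the structure of the original design: two mouse
muscle case-control cohorts (discovery and validation), mouse serum paired
1:1 with the discovery animals, and a human plasma cohort, with the three
feature universes overlapping per a configurable Venn structure and disease
effects planted as per-matrix fold changes.

Noise model: each feature gets one log-normal baseline ``10**N(mu, sd)``;
each sample observes ``baseline * FC(feature, group) * (1 + eps)`` with
``eps ~ N(0, cv)``, truncated at zero. Extraction blanks sit at a small
fraction of baseline; pooled-QC rows carry the mean analytical intensity.
Multiplicative log-normal intensities with Gaussian relative error are the
standard first-order picture of untargeted LC-MS peak areas; batch effects,
missingness and adduct structure are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .tables import FeatureTable

EffectRole = Literal[
    "true_cbm", "muscle_only", "discordant_serum", "discordant_human", "null"
]


class ConfigurationError(ValueError):
    """Invalid generator configuration (negative counts, dangling effects...)."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VennConfig:
    """Seven-region overlap structure of the three feature universes.

    Region counts refer to the classic three-set Venn diagram over the mouse
    muscle, mouse plasma and human plasma feature universes. Defaults follow
    the observed overlap of the OPMD study cohorts; the muscle/human-plasma
    pair region was not reported there and defaults to 0.
    """

    unique_muscle: int = 327
    unique_mouse_plasma: int = 365
    unique_human_plasma: int = 1556
    pair_muscle_mouse_plasma: int = 231
    pair_mouse_human_plasma: int = 1182
    pair_muscle_human_plasma: int = 0
    triple: int = 1549

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ConfigurationError(f"VennConfig.{name} must be >= 0, got {value}")

    @property
    def muscle_size(self) -> int:
        return (
            self.unique_muscle
            + self.pair_muscle_mouse_plasma
            + self.pair_muscle_human_plasma
            + self.triple
        )

    @property
    def mouse_plasma_size(self) -> int:
        return (
            self.unique_mouse_plasma
            + self.pair_muscle_mouse_plasma
            + self.pair_mouse_human_plasma
            + self.triple
        )

    @property
    def human_plasma_size(self) -> int:
        return (
            self.unique_human_plasma
            + self.pair_mouse_human_plasma
            + self.pair_muscle_human_plasma
            + self.triple
        )

    @property
    def total(self) -> int:
        return (
            self.unique_muscle
            + self.unique_mouse_plasma
            + self.unique_human_plasma
            + self.pair_muscle_mouse_plasma
            + self.pair_mouse_human_plasma
            + self.pair_muscle_human_plasma
            + self.triple
        )


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth disease effect of one feature, as per-matrix fold changes.

    Fold changes are case-group mean over control-group mean; 1 means no
    effect. ``role`` records the intent so recovery tests can score the
    cascade: a ``true_cbm`` is perturbed everywhere with serum and human on
    the same side of 1; a ``discordant_human`` flips sign between serum and
    human and must be rejected by the concordance rule.
    """

    feature_id: str
    fc_muscle1: float = 1.0
    fc_muscle2: float = 1.0
    fc_serum: float = 1.0
    fc_human: float = 1.0
    role: EffectRole = "null"

    def __post_init__(self) -> None:
        fcs = (self.fc_muscle1, self.fc_muscle2, self.fc_serum, self.fc_human)
        if any(fc <= 0 for fc in fcs):
            raise ConfigurationError(f"{self.feature_id}: fold changes must be > 0")
        if self.role == "null" and any(fc != 1.0 for fc in fcs):
            raise ConfigurationError(f"{self.feature_id}: null effect must have all FC = 1")
        if self.role == "true_cbm":
            if any(fc == 1.0 for fc in fcs):
                raise ConfigurationError(
                    f"{self.feature_id}: true_cbm needs all four FC != 1"
                )
            if (self.fc_serum > 1) != (self.fc_human > 1):
                raise ConfigurationError(
                    f"{self.feature_id}: true_cbm needs serum/human FC on the same side of 1"
                )
        if self.role == "discordant_human" and (self.fc_serum > 1) == (self.fc_human > 1):
            raise ConfigurationError(
                f"{self.feature_id}: discordant_human needs serum/human FC on opposite sides"
            )


@dataclass(frozen=True)
class StudyConfig:
    """Full study recipe: cohort sizes, noise, overlap structure and effects.

    Cohort defaults mirror the original design: 9 A17.1 vs 8 FvB mice in the
    discovery muscle and paired serum cohorts, 8 vs 8 in the validation
    muscle cohort (size unreported in the source study), and 51 OPMD patients
    vs 14 controls in human plasma. Identical seed + config gives
    bit-identical output.
    """

    venn: VennConfig = field(default_factory=VennConfig)
    n_fvb_muscle1: int = 8
    n_a17_muscle1: int = 9
    n_fvb_muscle2: int = 8
    n_a17_muscle2: int = 8
    n_fvb_serum: int = 8
    n_a17_serum: int = 9
    n_ctrl_human: int = 14
    n_opmd_human: int = 51
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 0.5
    cv_analytical: float = 0.2
    blank_fraction: float = 0.02
    n_blanks: int = 3
    n_qc: int = 4
    effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        for name in (
            "n_fvb_muscle1", "n_a17_muscle1", "n_fvb_muscle2", "n_a17_muscle2",
            "n_fvb_serum", "n_a17_serum", "n_ctrl_human", "n_opmd_human",
        ):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2 (tests undefined below)")

    def with_effects(self, effects: Sequence[PlantedEffect]) -> "StudyConfig":
        return replace(self, effects=tuple(effects))


class FeatureUniverses(NamedTuple):
    muscle: frozenset[str]
    mouse_plasma: frozenset[str]
    human_plasma: frozenset[str]


@dataclass
class GeneratedStudy:
    """Four linked feature tables plus the planted ground truth."""

    muscle1: FeatureTable
    muscle2: FeatureTable
    serum: FeatureTable
    human: FeatureTable
    truth: tuple[PlantedEffect, ...]
    universes: FeatureUniverses
    config: StudyConfig


# ---------------------------------------------------------------------------
# feature universes
# ---------------------------------------------------------------------------

_REGION_MEMBERSHIP = {
    # region -> (in muscle, in mouse plasma, in human plasma)
    "unique_muscle": (True, False, False),
    "unique_mouse_plasma": (False, True, False),
    "unique_human_plasma": (False, False, True),
    "pair_muscle_mouse_plasma": (True, True, False),
    "pair_mouse_human_plasma": (False, True, True),
    "pair_muscle_human_plasma": (True, False, True),
    "triple": (True, True, True),
}


def _id_sort_key(feature_id: str) -> tuple[str, int]:
    method, _, num = feature_id.partition("_")
    return (method, int(num))


def build_feature_universes(venn: VennConfig, seed: int = 0) -> FeatureUniverses:
    """Materialise the three feature-ID universes from a Venn structure.

    Identifiers are stable strings ``HILIC_<n>`` / ``RP_<n>`` (the two
    chromatographic methods); the split between methods is random under
    ``seed`` but region membership and cardinalities are exact for any seed.
    """
    rng = np.random.default_rng(seed)
    total = venn.total
    is_hilic = rng.random(total) < 0.5
    ids: list[str] = []
    n_h = n_r = 0
    for h in is_hilic:
        if h:
            n_h += 1
            ids.append(f"HILIC_{n_h}")
        else:
            n_r += 1
            ids.append(f"RP_{n_r}")

    muscle: list[str] = []
    mouse_plasma: list[str] = []
    human_plasma: list[str] = []
    cursor = 0
    for region, (in_mu, in_mp, in_hp) in _REGION_MEMBERSHIP.items():
        count = getattr(venn, region)
        block = ids[cursor : cursor + count]
        cursor += count
        if in_mu:
            muscle.extend(block)
        if in_mp:
            mouse_plasma.extend(block)
        if in_hp:
            human_plasma.extend(block)
    return FeatureUniverses(
        muscle=frozenset(muscle),
        mouse_plasma=frozenset(mouse_plasma),
        human_plasma=frozenset(human_plasma),
    )


# ---------------------------------------------------------------------------
# table generation
# ---------------------------------------------------------------------------


def generate_feature_table(
    universe: Iterable[str],
    *,
    matrix: str,
    species: str,
    groups: Mapping[str, int],
    case_group: str | None = None,
    effects: Mapping[str, float] | None = None,
    baseline_log_mean: float = 5.0,
    baseline_log_sd: float = 0.5,
    cv: float = 0.2,
    blank_fraction: float = 0.02,
    n_blanks: int = 3,
    n_qc: int = 4,
    sample_ids: Mapping[str, Sequence[str]] | None = None,
    seed: int | np.random.Generator = 0,
) -> FeatureTable:
    """Simulate one feature table for a two-group (or k-group) cohort.

    ``effects`` maps feature_id -> fold change applied to ``case_group``
    only; every mapped feature must be in ``universe``. Intensities are
    ``10**N(baseline_log_mean, baseline_log_sd) * FC * (1 + eps)`` with
    ``eps ~ N(0, cv)``, truncated at zero; the baseline is drawn once per
    feature so a noiseless (cv=0) table realises fold changes exactly.
    """
    features = sorted(universe, key=_id_sort_key)
    if not features:
        raise ConfigurationError("empty feature universe")
    effects = dict(effects or {})
    unknown = set(effects) - set(features)
    if unknown:
        raise ConfigurationError(
            f"effect feature(s) absent from the {matrix} universe: {sorted(unknown)[:5]}"
        )
    for label, n in groups.items():
        if n < 2:
            raise ConfigurationError(f"group {label!r} has n={n}; need >= 2")
    if case_group is None and effects:
        raise ConfigurationError("effects given but no case_group")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = len(features)
    baseline = 10.0 ** rng.normal(baseline_log_mean, baseline_log_sd, size=p)

    fc = {g: np.ones(p) for g in groups}
    if case_group is not None:
        if case_group not in groups:
            raise ConfigurationError(f"case_group {case_group!r} not among groups")
        col_index = {f: i for i, f in enumerate(features)}
        for f, ratio in effects.items():
            fc[case_group][col_index[f]] = ratio

    rows: list[np.ndarray] = []
    ids: list[str] = []
    meta: list[tuple[str, str, str, str]] = []
    for label, n in groups.items():
        given = list(sample_ids[label]) if sample_ids else None
        if given is not None and len(given) != n:
            raise ConfigurationError(
                f"group {label!r}: {len(given)} sample_ids for n={n}"
            )
        eps = rng.normal(0.0, cv, size=(n, p)) if cv > 0 else np.zeros((n, p))
        block = baseline * fc[label] * (1.0 + eps)
        for i in range(n):
            rows.append(block[i])
            ids.append(given[i] if given else f"{matrix}_{label}_{i + 1}")
            meta.append((matrix, species, label, "analytical"))

    analytical_mean = np.mean(rows, axis=0)
    for b in range(n_blanks):
        eps = rng.normal(0.0, cv, size=p) if cv > 0 else np.zeros(p)
        rows.append(blank_fraction * baseline * (1.0 + eps))
        ids.append(f"{matrix}_blank_{b + 1}")
        meta.append((matrix, species, "blank", "blank"))
    for q in range(n_qc):
        eps = rng.normal(0.0, cv, size=p) if cv > 0 else np.zeros(p)
        rows.append(analytical_mean * (1.0 + eps))
        ids.append(f"{matrix}_QC_{q + 1}")
        meta.append((matrix, species, "QC", "QC"))

    intensities = pd.DataFrame(
        np.clip(np.vstack(rows), 0.0, None), index=ids, columns=features
    )
    sample_meta = pd.DataFrame(
        meta, index=ids, columns=["matrix", "species", "group", "role"]
    )
    return FeatureTable(intensities=intensities, sample_meta=sample_meta)


def _effect_maps(
    effects: Sequence[PlantedEffect], universes: FeatureUniverses
) -> dict[str, dict[str, float]]:
    """Per-matrix feature -> FC maps; error on effects the matrices cannot host."""
    maps: dict[str, dict[str, float]] = {
        "muscle1": {}, "muscle2": {}, "serum": {}, "human": {}
    }
    required = {
        "muscle1": ("fc_muscle1", universes.muscle),
        "muscle2": ("fc_muscle2", universes.muscle),
        "serum": ("fc_serum", universes.mouse_plasma),
        "human": ("fc_human", universes.human_plasma),
    }
    for eff in effects:
        for table, (attr, universe) in required.items():
            ratio = getattr(eff, attr)
            if ratio == 1.0:
                continue
            if eff.feature_id not in universe:
                raise ConfigurationError(
                    f"effect {eff.feature_id!r} ({eff.role}) sets {attr}={ratio} "
                    f"but the feature is absent from that matrix's universe"
                )
            maps[table][eff.feature_id] = ratio
    return maps


def generate_study(config: StudyConfig) -> GeneratedStudy:
    """Generate the four linked cohorts of one synthetic translation study.

    The serum table reuses the discovery-muscle animal identifiers, giving
    the paired design; all randomness descends from ``config.seed``.
    """
    universes = build_feature_universes(config.venn, seed=config.seed)
    fc_maps = _effect_maps(config.effects, universes)

    ss = np.random.SeedSequence(config.seed)
    rng_m1, rng_m2, rng_se, rng_hu = (np.random.default_rng(c) for c in ss.spawn(4))

    animals = {
        "FvB": [f"FvB_{i + 1}" for i in range(config.n_fvb_muscle1)],
        "A17.1": [f"A17.1_{i + 1}" for i in range(config.n_a17_muscle1)],
    }
    shared = dict(
        baseline_log_mean=config.baseline_log_mean,
        baseline_log_sd=config.baseline_log_sd,
        cv=config.cv_analytical,
        blank_fraction=config.blank_fraction,
        n_blanks=config.n_blanks,
        n_qc=config.n_qc,
    )
    muscle1 = generate_feature_table(
        universes.muscle, matrix="muscle", species="mouse",
        groups={"FvB": config.n_fvb_muscle1, "A17.1": config.n_a17_muscle1},
        case_group="A17.1", effects=fc_maps["muscle1"],
        sample_ids=animals, seed=rng_m1, **shared,
    )
    muscle2 = generate_feature_table(
        universes.muscle, matrix="muscle", species="mouse",
        groups={"FvB": config.n_fvb_muscle2, "A17.1": config.n_a17_muscle2},
        case_group="A17.1", effects=fc_maps["muscle2"], seed=rng_m2, **shared,
    )
    if (
        config.n_fvb_serum != config.n_fvb_muscle1
        or config.n_a17_serum != config.n_a17_muscle1
    ):
        raise ConfigurationError(
            "paired design: serum cohort sizes must equal discovery muscle sizes"
        )
    serum = generate_feature_table(
        universes.mouse_plasma, matrix="serum", species="mouse",
        groups={"FvB": config.n_fvb_serum, "A17.1": config.n_a17_serum},
        case_group="A17.1", effects=fc_maps["serum"],
        sample_ids=animals, seed=rng_se, **shared,
    )
    human = generate_feature_table(
        universes.human_plasma, matrix="plasma", species="human",
        groups={"Control": config.n_ctrl_human, "OPMD": config.n_opmd_human},
        case_group="OPMD", effects=fc_maps["human"], seed=rng_hu, **shared,
    )
    return GeneratedStudy(
        muscle1=muscle1, muscle2=muscle2, serum=serum, human=human,
        truth=tuple(config.effects), universes=universes, config=config,
    )


# ---------------------------------------------------------------------------
# effect planning
# ---------------------------------------------------------------------------


def plan_effects(
    universes: FeatureUniverses,
    *,
    n_true_cbm: int = 0,
    n_muscle_only: int = 0,
    n_discordant_serum: int = 0,
    n_discordant_human: int = 0,
    fc_up: float = 1.5625,
    fc_down: float = 0.64,
    seed: int = 0,
) -> list[PlantedEffect]:
    """Assign planted roles to concrete features of a universe set.

    Roles needing all four matrices draw from the triple-overlap region;
    muscle_only draws from muscle-exclusive features. The default magnitudes
    (0.64 down / 1.5625 up, i.e. |log2 FC| ~ 0.64) sit inside the fold-change
    range of the observed nine-candidate panel. Direction is randomised per
    effect under ``seed``.
    """
    rng = np.random.default_rng(seed)
    triple = sorted(
        universes.muscle & universes.mouse_plasma & universes.human_plasma,
        key=_id_sort_key,
    )
    muscle_excl = sorted(
        universes.muscle - universes.mouse_plasma - universes.human_plasma,
        key=_id_sort_key,
    )
    n_shared = n_true_cbm + n_discordant_serum + n_discordant_human
    if n_shared > len(triple):
        raise ConfigurationError(
            f"need {n_shared} triple-region features, universe has {len(triple)}"
        )
    if n_muscle_only > len(muscle_excl):
        raise ConfigurationError(
            f"need {n_muscle_only} muscle-exclusive features, universe has {len(muscle_excl)}"
        )
    shared_pick = list(rng.choice(triple, size=n_shared, replace=False))
    muscle_pick = list(rng.choice(muscle_excl, size=n_muscle_only, replace=False))

    def fc_pair() -> tuple[float, float]:
        up = bool(rng.random() < 0.5)
        return (fc_up, fc_down) if up else (fc_down, fc_up)

    effects: list[PlantedEffect] = []
    for _ in range(n_true_cbm):
        fc, _other = fc_pair()
        effects.append(
            PlantedEffect(shared_pick.pop(), fc, fc, fc, fc, role="true_cbm")
        )
    for _ in range(n_discordant_serum):
        fc, other = fc_pair()
        effects.append(
            PlantedEffect(
                shared_pick.pop(), fc, fc, other, other, role="discordant_serum"
            )
        )
    for _ in range(n_discordant_human):
        fc, other = fc_pair()
        effects.append(
            PlantedEffect(
                shared_pick.pop(), fc, fc, fc, other, role="discordant_human"
            )
        )
    for _ in range(n_muscle_only):
        fc, _other = fc_pair()
        effects.append(
            PlantedEffect(muscle_pick.pop(), fc, fc, 1.0, 1.0, role="muscle_only")
        )
    return effects
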