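"""Per-feature two-group statistics: p-values, fold changes and directions.

Each feature is compared between the case and control group with a
normality-routed test: Welch's unequal-variance t-test when both groups look
Gaussian under Shapiro-Wilk, the Mann-Whitney U-test otherwise. Fold change
is the ratio of raw (pre-log) arithmetic group means, case over control, so
FC < 1 means the feature is lower in disease. No multiple-testing
correction is applied anywhere in the pipeline: every downstream threshold
is a raw p-value by design, which callers should keep in mind when
interpreting survivor counts.

A two-group Gaussian linear model on log10 intensities (equivalent to a
pooled-variance t-test) is available as an alternative testing mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .tables import FeatureTable, FeatureTableError

Direction = Literal["up", "down", "flat"]
TestName = Literal["welch", "mann_whitney", "glm_log10", "reported"]

#: largest combined sample size for which the U-test p is computed exactly
EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class FeatureStat:
    """Univariate result of one feature's case-vs-control comparison."""

    feature_id: str
    p_value: float
    fold_change: float
    direction: Direction
    test_used: TestName
    statistic: float = float("nan")
    normality_p_case: float | None = None
    normality_p_control: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.feature_id}: p_value {self.p_value} outside [0,1]")
        expected = (
            "up" if self.fold_change > 1 else "down" if self.fold_change < 1 else "flat"
        )
        if self.direction != expected:
            raise ValueError(
                f"{self.feature_id}: direction {self.direction!r} inconsistent "
                f"with fold change {self.fold_change}"
            )


def direction_of(fold_change: float) -> Direction:
    return "up" if fold_change > 1 else "down" if fold_change < 1 else "flat"


def _check_groups(case: np.ndarray, control: np.ndarray) -> None:
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 values")


def welch_t(case: Sequence[float], control: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t-test.

    Degenerate inputs (both variances zero) follow the convention p = 1 for
    equal means and p = 0 otherwise.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    _check_groups(case, control)
    if case.var(ddof=1) == 0.0 and control.var(ddof=1) == 0.0:
        if case.mean() == control.mean():
            return 0.0, 1.0
        return float("inf") if case.mean() > control.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(case, control, equal_var=False)
    return float(t), float(p)


def mann_whitney_u(case: Sequence[float], control: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test (U reported for the case sample).

    Exact null distribution when the combined sample size is at most
    :data:`EXACT_MWU_MAX_N` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    _check_groups(case, control)
    pooled = np.concatenate([case, control])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_MWU_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        case, control, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def fold_change(
    case: Sequence[float],
    control: Sequence[float],
    scale: Literal["arithmetic", "geometric"] = "arithmetic",
) -> float:
    """Case-over-control ratio of group means on raw intensities.

    ``scale="geometric"`` uses geometric means instead (requires strictly
    positive values); the default arithmetic ratio matches how fold changes
    are conventionally reported for untargeted peak intensities.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if scale == "geometric":
        if (case <= 0).any() or (control <= 0).any():
            raise ValueError("geometric fold change needs strictly positive values")
        return float(np.exp(np.log(case).mean() - np.log(control).mean()))
    denom = control.mean()
    if denom == 0:
        raise ZeroDivisionError("fold change undefined: control mean is 0")
    return float(case.mean() / denom)


def _normality_p(values: np.ndarray) -> float:
    """Shapiro-Wilk p; groups too small to test (< 3) are not rejected."""
    if len(values) < 3 or np.ptp(values) == 0:
        return 1.0
    return float(stats.shapiro(values).pvalue)


def test_feature(
    case: Sequence[float],
    control: Sequence[float],
    feature_id: str = "",
    normality_alpha: float = 0.05,
    fc_scale: Literal["arithmetic", "geometric"] = "arithmetic",
) -> FeatureStat:
    """Normality-routed comparison of one feature.

    Welch's t-test is used iff both groups pass Shapiro-Wilk at
    ``normality_alpha`` (p strictly above the threshold, so an alpha of 0
    always routes to Welch); otherwise Mann-Whitney.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    _check_groups(case, control)
    p_norm_case = _normality_p(case)
    p_norm_control = _normality_p(control)
    if p_norm_case > normality_alpha and p_norm_control > normality_alpha:
        test_used: TestName = "welch"
        statistic, p = welch_t(case, control)
    else:
        test_used = "mann_whitney"
        statistic, p = mann_whitney_u(case, control)
    fc = fold_change(case, control, scale=fc_scale)
    return FeatureStat(
        feature_id=feature_id,
        p_value=p,
        fold_change=fc,
        direction=direction_of(fc),
        test_used=test_used,
        statistic=statistic,
        normality_p_case=p_norm_case,
        normality_p_control=p_norm_control,
    )


def _glm_log10(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    # two-group Gaussian linear model on log10 intensities == pooled t-test
    if (case <= 0).any() or (control <= 0).any():
        raise ValueError("log10 model needs strictly positive intensities")
    t, p = stats.ttest_ind(np.log10(case), np.log10(control), equal_var=True)
    return float(t), float(p)


def test_all(
    table: FeatureTable,
    case_label: str,
    control_label: str,
    normality_alpha: float = 0.05,
    method: Literal["routed", "glm_log10"] = "routed",
    fc_scale: Literal["arithmetic", "geometric"] = "arithmetic",
) -> list[FeatureStat]:
    """Run the per-feature comparison over every feature of a table.

    Returns one :class:`FeatureStat` per feature in the table's column
    order. ``method="glm_log10"`` replaces the routed test with the Gaussian
    log10 linear model; fold changes stay on the raw scale either way.
    """
    groups = set(table.groups)
    for label in (case_label, control_label):
        if label not in groups:
            raise FeatureTableError(
                f"group {label!r} not among analytical groups {sorted(groups)}"
            )
    case_block = table.group_intensities(case_label).to_numpy()
    control_block = table.group_intensities(control_label).to_numpy()
    out: list[FeatureStat] = []
    for j, fid in enumerate(table.feature_ids):
        case = case_block[:, j]
        control = control_block[:, j]
        if method == "glm_log10":
            statistic, p = _glm_log10(case, control)
            fc = fold_change(case, control, scale=fc_scale)
            out.append(
                FeatureStat(
                    feature_id=fid, p_value=p, fold_change=fc,
                    direction=direction_of(fc), test_used="glm_log10",
                    statistic=statistic,
                )
            )
        else:
            out.append(
                test_feature(
                    case, control, feature_id=fid,
                    normality_alpha=normality_alpha, fc_scale=fc_scale,
                )
            )
    return out
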