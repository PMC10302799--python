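"""Built-in worked-example dataset: the published OPMD nine-candidate panel.

The OPMD case study that motivates this pipeline reported, for each of nine
candidate biomarker features, the univariate p-value and fold change in four
cohorts: discovery mouse muscle (A17.1 vs FvB, fold change relative to FvB),
an independent validation muscle cohort, paired mouse serum, and human
plasma (OPMD vs healthy controls, fold change relative to controls). Those
printed per-matrix statistics are self-contained inputs to the translation
rules, so they serve as the pipeline's canonical worked example: running the
cascade thresholds over them must return the full nine-feature panel.

One reversed-phase feature ID appears twice in the published panel with
distinct statistics (a presumed typographical duplicate); the two rows are
encoded as RP_1362a and RP_1362b to keep identifiers unique.
"""

from __future__ import annotations

from .univariate_stats import FeatureStat, direction_of

STAGE_NAMES = ("muscle1", "muscle2", "serum", "human")

# feature_id -> (p, FC) x (muscle1, muscle2, serum, human)
_PANEL_ROWS: dict[str, tuple[float, float, float, float, float, float, float, float]] = {
    "HILIC_4":    (0.035,   0.81, 0.033,  0.78,  0.018, 0.64, 0.0041,  0.62),
    "HILIC_14":   (8.22e-5, 0.76, 0.022,  0.38,  0.021, 0.76, 1.56e-5, 0.71),
    "HILIC_55":   (8.22e-5, 1.43, 0.0006, 2.07,  0.040, 0.82, 0.0055,  0.89),
    "HILIC_186":  (0.0079,  0.79, 0.037,  0.71,  0.094, 0.76, 0.027,   0.79),
    "HILIC_201":  (0.0079,  0.88, 0.026,  0.70,  0.034, 0.84, 0.0073,  0.84),
    "RP_1362a":   (0.015,   0.79, 0.0029, 0.65,  0.079, 0.80, 0.0023,  0.72),
    "HILIC_687":  (0.029,   0.63, 0.020,  0.513, 0.027, 1.26, 0.013,   5.88),
    "HILIC_2523": (0.020,   0.83, 0.031,  0.49,  0.028, 1.30, 0.038,   1.39),
    "RP_1362b":   (0.0005,  0.44, 0.0024, 0.49,  0.069, 1.32, 0.0073,  1.74),
}


def reference_panel_stats() -> dict[str, dict[str, FeatureStat]]:
    """Per-stage feature statistics of the nine-candidate reference panel.

    Returns a mapping ``stage -> {feature_id -> FeatureStat}`` with stages
    ``muscle1`` (discovery muscle), ``muscle2`` (validation muscle),
    ``serum`` (paired mouse serum) and ``human`` (human plasma).
    """
    out: dict[str, dict[str, FeatureStat]] = {s: {} for s in STAGE_NAMES}
    for fid, row in _PANEL_ROWS.items():
        for k, stage in enumerate(STAGE_NAMES):
            p, fc = row[2 * k], row[2 * k + 1]
            out[stage][fid] = FeatureStat(
                feature_id=fid,
                p_value=p,
                fold_change=fc,
                direction=direction_of(fc),
                test_used="reported",
            )
    return out


def reference_panel_feature_ids() -> list[str]:
    return list(_PANEL_ROWS)
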