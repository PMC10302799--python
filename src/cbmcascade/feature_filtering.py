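"""Feature-definition filters applied to a raw feature table before statistics.

Two rules decide what counts as a real metabolite feature: the blank-ratio
rule (mean analytical intensity at least ``ratio`` times the mean
extraction-blank intensity, default 5x) and the group-presence rule (the
feature must be detected, i.e. intensity strictly above zero, in every
analytical sample of at least one group). Both rules look only at
``role == "analytical"`` rows (plus blanks for the ratio); QC injections are
ignored. The blank rule is applied first, then presence.
"""

from __future__ import annotations

import logging

import numpy as np

from .tables import FeatureTable, FeatureTableError

log = logging.getLogger(__name__)


def blank_filter(table: FeatureTable, ratio: float = 5.0) -> FeatureTable:
    """Keep features whose mean analytical intensity is >= ratio x blank mean.

    The comparison is inclusive ("at least" ``ratio`` times) and uses the
    mean over *all* analytical samples against the mean over all blank rows.
    A feature never seen in blanks (blank mean 0) is kept whenever it has any
    analytical signal. Feature order is preserved.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    blanks = table.blanks
    if blanks.empty:
        raise FeatureTableError(
            "blank_filter needs at least one blank row (role='blank'); none found"
        )
    analytical_mean = table.analytical.mean(axis=0).to_numpy()
    blank_mean = blanks.mean(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = analytical_mean >= ratio * blank_mean
    # blank mean 0: retain iff any analytical signal
    zero_blank = blank_mean == 0
    keep[zero_blank] = analytical_mean[zero_blank] > 0
    survivors = [f for f, k in zip(table.feature_ids, keep) if k]
    log.info(
        "blank_filter (ratio=%g): %d -> %d features",
        ratio, table.n_features, len(survivors),
    )
    return table.select_features(survivors)


def presence_filter(table: FeatureTable) -> FeatureTable:
    """Keep features present (> 0) in every analytical sample of some group."""
    groups = table.groups
    if not groups:
        raise FeatureTableError("presence_filter needs at least one analytical group")
    keep = np.zeros(table.n_features, dtype=bool)
    for g in groups:
        block = table.group_intensities(g).to_numpy()
        keep |= (block > 0).all(axis=0)
    survivors = [f for f, k in zip(table.feature_ids, keep) if k]
    log.info("presence_filter: %d -> %d features", table.n_features, len(survivors))
    return table.select_features(survivors)


def define_features(table: FeatureTable, blank_ratio: float = 5.0) -> FeatureTable:
    """Apply both feature-definition filters in order: blank ratio, presence."""
    return presence_filter(blank_filter(table, ratio=blank_ratio))
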