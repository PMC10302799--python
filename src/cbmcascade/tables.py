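"""Sample-by-feature intensity tables, the currency of every pipeline stage.

A :class:`FeatureTable` holds one LC-MS feature-intensity matrix (rows =
samples, columns = anonymous metabolite features) together with per-sample
metadata (matrix, species, group, role) and per-feature metadata (separation
method, optionally m/z and retention time). Features are anonymous IDs such
as ``HILIC_186`` or ``RP_1362``; chemical annotation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATRICES = frozenset({"muscle", "serum", "plasma"})
SPECIES = frozenset({"mouse", "human"})
ROLES = frozenset({"analytical", "blank", "QC"})

#: columns every sample_meta frame must carry (sample_id is the index)
SAMPLE_META_COLUMNS = ("matrix", "species", "group", "role")


class FeatureTableError(ValueError):
    """Raised when a table violates the header/metadata contract."""


@dataclass
class FeatureTable:
    """Intensity matrix plus sample and feature metadata.

    Parameters
    ----------
    intensities
        Non-negative matrix indexed by sample_id with feature_id columns.
    sample_meta
        Indexed by sample_id; columns ``matrix``, ``species``, ``group``,
        ``role`` (role in {analytical, blank, QC}).
    feature_meta
        Indexed by feature_id; column ``method`` in {HILIC, RP}; optional
        ``mz`` and ``rt`` columns enable tolerance-based cross-table matching.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            method = [
                "HILIC" if str(f).startswith("HILIC") else "RP"
                for f in self.intensities.columns
            ]
            self.feature_meta = pd.DataFrame(
                {"method": method}, index=self.intensities.columns
            )
        self._validate()

    def _validate(self) -> None:
        ix = self.intensities
        if ix.index.duplicated().any():
            dup = ix.index[ix.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate sample_ids: {dup}")
        if ix.columns.duplicated().any():
            dup = ix.columns[ix.columns.duplicated()].tolist()
            raise FeatureTableError(f"duplicate feature_ids: {dup}")
        missing = [c for c in SAMPLE_META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise FeatureTableError(f"sample_meta missing column(s): {missing}")
        if not ix.index.equals(self.sample_meta.index):
            raise FeatureTableError("intensities and sample_meta sample_ids differ")
        if not ix.columns.equals(self.feature_meta.index):
            raise FeatureTableError("intensities and feature_meta feature_ids differ")
        bad_role = set(self.sample_meta["role"]) - ROLES
        if bad_role:
            raise FeatureTableError(f"unknown sample role(s): {sorted(bad_role)}")
        vals = ix.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = [
                (str(ix.index[i]), str(ix.columns[j]))
                for i, j in zip(*np.where(~np.vectorize(np.isreal)(vals)))
            ][:5]
            raise FeatureTableError(f"non-numeric intensities at {bad}")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise FeatureTableError(
                f"negative intensity at sample {ix.index[i]!r}, "
                f"feature {ix.columns[j]!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def role_mask(self, role: str) -> pd.Series:
        return self.sample_meta["role"] == role

    @property
    def analytical(self) -> pd.DataFrame:
        """Intensity rows of analytical samples only (QC and blanks excluded)."""
        return self.intensities.loc[self.role_mask("analytical")]

    @property
    def blanks(self) -> pd.DataFrame:
        return self.intensities.loc[self.role_mask("blank")]

    @property
    def groups(self) -> list[str]:
        """Group labels present among analytical samples."""
        return sorted(self.sample_meta.loc[self.role_mask("analytical"), "group"].unique())

    def group_intensities(self, group: str) -> pd.DataFrame:
        """Analytical intensity rows for one group label."""
        mask = self.role_mask("analytical") & (self.sample_meta["group"] == group)
        if not mask.any():
            raise FeatureTableError(f"no analytical samples with group {group!r}")
        return self.intensities.loc[mask]

    def select_features(self, feature_ids) -> "FeatureTable":
        """Sub-table restricted to ``feature_ids`` (original column order kept)."""
        keep = [f for f in self.intensities.columns if f in set(feature_ids)]
        return FeatureTable(
            intensities=self.intensities[keep],
            sample_meta=self.sample_meta,
            feature_meta=self.feature_meta.loc[keep],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.intensities.equals(other.intensities)
            and self.sample_meta.equals(other.sample_meta)
            and self.feature_meta.equals(other.feature_meta)
        )
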