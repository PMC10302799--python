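import numpy as np
import pandas as pd
import pytest

from cbmcascade import FeatureTable, StudyConfig, VennConfig, generate_study, plan_effects
from cbmcascade.synthetic_data import build_feature_universes


def make_table(
    values,
    groups,
    feature_ids=None,
    roles=None,
    matrix="muscle",
    species="mouse",
    sample_ids=None,
):
    """Build a FeatureTable from a raw array and per-row group labels.

    Rows whose group is ``blank`` or ``QC`` get the matching role unless
    ``roles`` overrides.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_ids = feature_ids or [f"HILIC_{j + 1}" for j in range(p)]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    if roles is None:
        roles = [g if g in ("blank", "QC") else "analytical" for g in groups]
    meta = pd.DataFrame(
        {
            "matrix": matrix,
            "species": species,
            "group": list(groups),
            "role": list(roles),
        },
        index=sample_ids,
    )
    return FeatureTable(
        intensities=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        sample_meta=meta,
    )


#: compact overlap structure used by the heavier multi-seed suites
#: (2000 features total; cohort sizes stay at the study defaults)
SMALL_VENN = VennConfig(
    unique_muscle=150,
    unique_mouse_plasma=100,
    unique_human_plasma=250,
    pair_muscle_mouse_plasma=100,
    pair_mouse_human_plasma=300,
    pair_muscle_human_plasma=0,
    triple=1100,
)

TINY_VENN = VennConfig(
    unique_muscle=5,
    unique_mouse_plasma=4,
    unique_human_plasma=6,
    pair_muscle_mouse_plasma=3,
    pair_mouse_human_plasma=4,
    pair_muscle_human_plasma=2,
    triple=12,
)


def null_study(seed, venn=SMALL_VENN, **overrides):
    """All-null synthetic study at default cohort sizes."""
    return generate_study(StudyConfig(venn=venn, seed=seed, **overrides))


def planted_study(
    seed,
    venn=SMALL_VENN,
    n_true_cbm=10,
    n_muscle_only=5,
    n_discordant_serum=2,
    n_discordant_human=5,
    cv=0.2,
    **plan_kw,
):
    """Synthetic study with planted effects at reference-panel magnitudes."""
    universes = build_feature_universes(venn, seed=seed)
    effects = plan_effects(
        universes,
        n_true_cbm=n_true_cbm,
        n_muscle_only=n_muscle_only,
        n_discordant_serum=n_discordant_serum,
        n_discordant_human=n_discordant_human,
        seed=seed + 10_000,
        **plan_kw,
    )
    cfg = StudyConfig(venn=venn, effects=tuple(effects), cv_analytical=cv, seed=seed)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def tiny_study():
    return planted_study(
        7, venn=TINY_VENN, n_true_cbm=3, n_muscle_only=1,
        n_discordant_serum=1, n_discordant_human=2,
    )
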