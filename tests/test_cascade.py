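import numpy as np
import pandas as pd
import pytest

from cbmcascade import (
    CascadeConfig,
    FeatureTable,
    discover,
    match_features,
    reference_panel_stats,
    run_cascade,
    run_cascade_from_stats,
    translate_to_human,
    translate_to_serum,
    validate,
)
from cbmcascade.cascade import StageResult, concordant, score_recovery
from cbmcascade.univariate_stats import FeatureStat, direction_of

from conftest import planted_study


def fs(fid, p, fc):
    return FeatureStat(fid, p, fc, direction_of(fc), "reported")


def random_stage_stats(rng, feature_ids):
    return {
        f: fs(f, float(rng.random()), float(np.exp(rng.normal(0, 0.7))))
        for f in feature_ids
    }


def brute_force_cascade(m1, m2, se, hu, cfg):
    """The whole cascade as plain set comprehensions (oracle)."""
    d = {f for f, s in m1.items() if s.p_value < cfg.p_discovery}
    v = {
        f
        for f in d
        if f in m2
        and m2[f].p_value < cfg.p_validation
        and (
            not cfg.require_validation_direction
            or np.log(m1[f].fold_change) * np.log(m2[f].fold_change) > 0
        )
    }
    src = v if cfg.translate_from == "validated" else d
    s = {f for f in src if f in se and se[f].p_value < cfg.p_serum}
    h = {
        f
        for f in s
        if f in hu
        and hu[f].p_value < cfg.p_human
        and (
            not cfg.require_serum_human_direction
            or np.log(se[f].fold_change) * np.log(hu[f].fold_change) > 0
        )
    }
    return d, v, s, h


class TestReferencePanel:
    """The printed nine-candidate panel is a self-contained worked example."""

    def test_full_panel_survives(self):
        ref = reference_panel_stats()
        res = run_cascade_from_stats(
            ref["muscle1"], ref["muscle2"], ref["serum"], ref["human"]
        )
        assert res.stage_counts == [9, 9, 9, 9]
        assert len(res.panel_features) == 9

    def test_serum_stage_at_stricter_threshold(self):
        # tightening serum p to 0.05 drops the three features near 0.1
        ref = reference_panel_stats()
        cfg = CascadeConfig(p_serum=0.05)
        res = run_cascade_from_stats(
            ref["muscle1"], ref["muscle2"], ref["serum"], ref["human"], cfg
        )
        assert res.stage_counts[2] == 6

    def test_translate_from_discovery_equivalent_here(self):
        ref = reference_panel_stats()
        cfg = CascadeConfig(translate_from="discovery")
        res = run_cascade_from_stats(
            ref["muscle1"], ref["muscle2"], ref["serum"], ref["human"], cfg
        )
        assert len(res.panel_features) == 9

    def test_muscle_serum_direction_flip_is_legal(self):
        # one panel member flips direction between muscle and serum yet survives
        ref = reference_panel_stats()
        flipped = [
            f
            for f in ref["muscle1"]
            if not concordant(
                ref["muscle1"][f].fold_change, ref["serum"][f].fold_change
            )
        ]
        assert "HILIC_687" in flipped
        res = run_cascade_from_stats(
            ref["muscle1"], ref["muscle2"], ref["serum"], ref["human"]
        )
        assert "HILIC_687" in res.panel_features


class TestStages:
    def test_discovery_strict_threshold(self):
        stats = [fs("a", 0.04, 2.0), fs("b", 0.05, 2.0), fs("c", 0.06, 2.0)]
        assert discover(stats).surviving == ["a"]

    def test_discovery_all_null(self):
        stats = [fs(f, 1.0, 2.0) for f in "abc"]
        assert discover(stats).surviving == []

    def test_discovery_empty_warns(self):
        with pytest.warns(UserWarning):
            assert discover([]).surviving == []

    def test_validation_requires_direction(self):
        d = discover([fs("a", 0.01, 2.0)])
        res = validate(d, [fs("a", 0.01, 0.5)])
        assert res.surviving == []
        res2 = validate(d, [fs("a", 0.01, 0.5)], CascadeConfig(require_validation_direction=False))
        assert res2.surviving == ["a"]

    def test_validation_empty_input(self):
        d = discover([fs("a", 0.9, 2.0)])
        assert validate(d, [fs("a", 0.001, 2.0)]).surviving == []

    def test_validation_counts_unmatched(self):
        d = discover([fs("a", 0.01, 2.0), fs("b", 0.01, 2.0)])
        res = validate(d, [fs("a", 0.01, 2.0)])
        assert res.n_unmatched == 1

    def test_serum_no_direction_requirement(self):
        stage = StageResult("validation", ["a"], {"a": fs("a", 0.01, 2.0)}, 1)
        res = translate_to_serum(stage, [fs("a", 0.09, 0.5)])
        assert res.surviving == ["a"]  # p<0.1; muscle->serum flip allowed

    def test_human_discordance_rejected(self):
        serum_stage = StageResult("serum", ["a"], {"a": fs("a", 0.05, 1.3)}, 1)
        res = translate_to_human(serum_stage, [fs("a", 0.001, 0.7)])
        assert res.surviving == []

    def test_human_flat_fold_change_fails_concordance(self):
        serum_stage = StageResult("serum", ["a"], {"a": fs("a", 0.05, 1.3)}, 1)
        res = translate_to_human(serum_stage, [fs("a", 0.001, 1.0)])
        assert res.surviving == []


class TestMatching:
    def _table(self, ids, mz=None, rt=None):
        vals = np.ones((2, len(ids))) * 10
        meta = pd.DataFrame(
            {"matrix": "serum", "species": "mouse", "group": "g", "role": "analytical"},
            index=["s1", "s2"],
        )
        fm = pd.DataFrame({"method": "HILIC"}, index=ids)
        if mz is not None:
            fm["mz"] = mz
            fm["rt"] = rt
        return FeatureTable(
            intensities=pd.DataFrame(vals, index=["s1", "s2"], columns=ids),
            sample_meta=meta,
            feature_meta=fm,
        )

    def test_identifier_mode_identity(self):
        t = self._table(["HILIC_1", "HILIC_2"])
        assert match_features(t, t) == {"HILIC_1": "HILIC_1", "HILIC_2": "HILIC_2"}

    def test_identifier_mode_disjoint(self):
        a = self._table(["HILIC_1"])
        b = self._table(["HILIC_2"])
        assert match_features(a, b) == {}

    def test_mz_rt_jittered_matching_vs_brute_force(self):
        rng = np.random.default_rng(0)
        n = 60
        mz = np.sort(rng.uniform(100, 900, n))
        rt = rng.uniform(0.5, 15, n)
        src = self._table([f"HILIC_{i}" for i in range(n)], mz=mz, rt=rt)
        jit = mz * (1 + rng.uniform(-3e-6, 3e-6, n))
        tgt = self._table([f"RP_{i}" for i in range(n)], mz=jit, rt=rt)
        cfg = CascadeConfig(matching="mz_rt", mz_tol_ppm=10, rt_tol_min=0.5)
        mapping = match_features(src, tgt, cfg)
        correct = sum(mapping.get(f"HILIC_{i}") == f"RP_{i}" for i in range(n))
        assert correct >= 0.99 * n
        # brute-force all-pairs nearest-in-tolerance oracle
        for i in range(n):
            d = np.abs(jit - mz[i]) / mz[i] * 1e6
            ok = np.flatnonzero((d <= 10) & (np.abs(rt - rt[i]) <= 0.5))
            if len(ok) == 1:
                assert mapping[f"HILIC_{i}"] == f"RP_{ok[0]}"


class TestFullCascade:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        ids = [f"HILIC_{j}" for j in range(n)]
        m1, m2 = random_stage_stats(rng, ids), random_stage_stats(rng, ids)
        se, hu = random_stage_stats(rng, ids), random_stage_stats(rng, ids)
        cfg = CascadeConfig(
            p_discovery=float(rng.uniform(0.05, 0.5)),
            p_validation=float(rng.uniform(0.05, 0.5)),
            p_serum=float(rng.uniform(0.1, 0.6)),
            p_human=float(rng.uniform(0.05, 0.5)),
            translate_from=("validated", "discovery")[seed % 2],
        )
        res = run_cascade_from_stats(m1, m2, se, hu, cfg)
        d, v, s, h = brute_force_cascade(m1, m2, se, hu, cfg)
        assert set(res.stages[0].surviving) == d
        assert set(res.stages[1].surviving) == v
        assert set(res.stages[2].surviving) == s
        assert set(res.stages[3].surviving) == h
        assert set(res.panel_features) == h

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_attrition(self, seed):
        rng = np.random.default_rng(100 + seed)
        ids = [f"RP_{j}" for j in range(40)]
        res = run_cascade_from_stats(
            random_stage_stats(rng, ids), random_stage_stats(rng, ids),
            random_stage_stats(rng, ids), random_stage_stats(rng, ids),
        )
        c = res.stage_counts
        assert c[0] >= c[1] >= c[2] >= c[3]

    def test_threshold_loosening_never_shrinks_panel(self):
        rng = np.random.default_rng(77)
        ids = [f"RP_{j}" for j in range(60)]
        args = tuple(random_stage_stats(rng, ids) for _ in range(4))
        base_cfg = CascadeConfig(p_discovery=0.2, p_validation=0.2, p_serum=0.3, p_human=0.2)
        base = set(run_cascade_from_stats(*args, base_cfg).panel_features)
        for name in ("p_discovery", "p_validation", "p_serum", "p_human"):
            loose = base_cfg.replace(**{name: min(1.0, getattr(base_cfg, name) * 2)})
            panel = set(run_cascade_from_stats(*args, loose).panel_features)
            assert base <= panel, name

    def test_recovery_and_discordant_rejection_on_tables(self, tiny_study):
        res = run_cascade(tiny_study)
        score = score_recovery(res, tiny_study.truth)
        assert score["n_discordant_leaked"] == 0

    def test_planted_recovery_small_study(self):
        recovered = total = leaked = 0
        for seed in range(3):
            study = planted_study(seed, n_true_cbm=5, n_discordant_human=3)
            res = run_cascade(study)
            s = score_recovery(res, study.truth)
            recovered += s["n_recovered"]
            total += s["n_true"]
            leaked += s["n_discordant_leaked"]
        assert leaked == 0
        assert recovered / total >= 0.8
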