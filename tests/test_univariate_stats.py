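import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cbmcascade import fold_change, generate_feature_table, mann_whitney_u, welch_t
from cbmcascade.univariate_stats import test_all as univariate_all
from cbmcascade.univariate_stats import test_feature as univariate_one
from cbmcascade.tables import FeatureTableError

from conftest import make_table


def enumerate_mwu_p(case, control):
    """Exact two-sided p by enumerating every label assignment (oracle).

    The U null distribution is symmetric about n1*n2/2; the two-sided p is
    the probability of a U at least as far from the centre as observed.
    """
    pooled = list(case) + list(control)
    n1 = len(case)
    centre = n1 * len(control) / 2

    def u_of(case_idx):
        u = 0
        case_vals = [pooled[i] for i in case_idx]
        ctrl_vals = [pooled[i] for i in range(len(pooled)) if i not in case_idx]
        for cv in case_vals:
            for kv in ctrl_vals:
                u += (cv > kv) + 0.5 * (cv == kv)
        return u

    observed = abs(u_of(tuple(range(n1))) - centre)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(comb) - centre) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestWelch:
    def test_hand_computed_formula(self):
        case, control = (10.0, 11.0, 12.0), (1.0, 2.0, 3.0)
        t, p = welch_t(case, control)
        # textbook Welch: t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2), WS df
        v1, v2 = np.var(case, ddof=1) / 3, np.var(control, ddof=1) / 3
        t_ref = (np.mean(case) - np.mean(control)) / math.sqrt(v1 + v2)
        df_ref = (v1 + v2) ** 2 / (v1**2 / 2 + v2**2 / 2)
        p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_samples(self):
        assert welch_t((1, 2, 3), (1, 2, 3))[1] == pytest.approx(1.0)

    def test_symmetry(self):
        t1, p1 = welch_t((5, 6, 9), (1, 2, 3))
        t2, p2 = welch_t((1, 2, 3), (5, 6, 9))
        assert p1 == pytest.approx(p2)
        assert t1 == pytest.approx(-t2)

    def test_degenerate_zero_variance(self):
        assert welch_t((5, 5), (5, 5)) == (0.0, 1.0)
        assert welch_t((6, 6), (5, 5))[1] == 0.0


class TestMannWhitney:
    def test_tiny_exact_case(self):
        u, p = mann_whitney_u((3, 4), (1, 2))
        assert u == 4  # U of the case sample; control-side U is 0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets(self):
        _, p = mann_whitney_u((1, 2, 3), (1, 2, 3))
        assert p == pytest.approx(1.0)

    @given(
        case=st.lists(st.integers(0, 1000), min_size=2, max_size=5),
        control=st.lists(st.integers(0, 1000), min_size=2, max_size=5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_matches_enumeration(self, case, control):
        pooled = case + control
        if len(set(pooled)) != len(pooled):  # oracle covers tie-free inputs
            return
        _, p = mann_whitney_u(case, control)
        assert p == pytest.approx(enumerate_mwu_p(case, control), abs=1e-12)

    def test_approximation_close_to_exact(self):
        # n=6+6 exact vs the same data pushed through the large-n path
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(20):
            case, control = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
            _, p_exact = mann_whitney_u(case, control)
            p_asym = sps.mannwhitneyu(
                case, control, alternative="two-sided", method="asymptotic"
            ).pvalue
            worst = max(worst, abs(p_exact - p_asym))
        assert worst < 0.05


class TestFoldChange:
    def test_basic_ratio(self):
        assert fold_change((8, 8), (10, 10)) == pytest.approx(0.8)

    def test_identity(self):
        assert fold_change((3, 4), (3, 4)) == pytest.approx(1.0)

    def test_reciprocal_property(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.lognormal(1, 1, 5), rng.lognormal(1, 1, 5)
            assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_zero_control_mean_signalled(self):
        with pytest.raises(ZeroDivisionError):
            fold_change((1, 2), (0, 0))

    def test_geometric_mode(self):
        assert fold_change((2, 8), (1, 1), scale="geometric") == pytest.approx(4.0)

    def test_planted_estimate_distribution(self):
        # FC 0.64 planted at cohort sizes 9 vs 8, cv 0.1: median estimate close
        fcs = []
        for seed in range(50):
            t = generate_feature_table(
                ["HILIC_1"], matrix="serum", species="mouse",
                groups={"FvB": 8, "A17.1": 9}, case_group="A17.1",
                effects={"HILIC_1": 0.64}, cv=0.1, seed=seed,
            )
            fcs.append(
                fold_change(
                    t.group_intensities("A17.1").iloc[:, 0],
                    t.group_intensities("FvB").iloc[:, 0],
                )
            )
        assert 0.55 <= np.median(fcs) <= 0.73


class TestRouting:
    def test_gaussian_groups_use_welch(self):
        rng = np.random.default_rng(0)
        case, control = rng.normal(10, 1, 8), rng.normal(12, 1, 8)
        assert sps.shapiro(case).pvalue > 0.05 and sps.shapiro(control).pvalue > 0.05
        s = univariate_one(case, control)
        assert s.test_used == "welch"

    def test_heavy_tailed_group_uses_mann_whitney(self):
        rng = np.random.default_rng(5)
        control = rng.normal(10, 1, 8)
        case = np.array([10.0, 10.1, 9.9, 10.0, 10.2, 9.8, 150.0, 180.0])
        assert sps.shapiro(case).pvalue < 0.05
        s = univariate_one(case, control)
        assert s.test_used == "mann_whitney"

    def test_zero_alpha_always_welch(self):
        case = np.array([10.0, 10.1, 9.9, 10.0, 10.2, 9.8, 150.0, 180.0])
        control = np.array([1.0, 1.1, 0.9, 1.0, 1.2, 0.8, 15.0, 18.0])
        s = univariate_one(case, control, normality_alpha=0.0)
        assert s.test_used == "welch"

    def test_direction_consistent(self):
        s = univariate_one((1.0, 2.0, 3.0), (4.0, 5.0, 6.0))
        assert s.direction == "down" and s.fold_change < 1


class TestTestAll:
    def test_single_feature_table(self):
        t = make_table([[1.0], [2.0], [3.0], [4.0]], ["a", "a", "b", "b"])
        out = univariate_all(t, "b", "a")
        assert len(out) == 1 and out[0].feature_id == "HILIC_1"

    def test_unknown_label(self):
        t = make_table([[1.0], [2.0], [3.0], [4.0]], ["a", "a", "b", "b"])
        with pytest.raises(FeatureTableError, match="nope"):
            univariate_all(t, "nope", "a")

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        ids = [f"RP_{j}" for j in (9, 2, 7, 1)]
        t = make_table(rng.lognormal(3, 1, (6, 4)), ["a"] * 3 + ["b"] * 3, feature_ids=ids)
        assert [s.feature_id for s in univariate_all(t, "b", "a")] == ids

    def test_null_p_values_uniform(self):
        t = generate_feature_table(
            [f"HILIC_{j}" for j in range(1, 1001)], matrix="muscle", species="mouse",
            groups={"FvB": 8, "A17.1": 9}, cv=0.2, seed=123,
        )
        p = [s.p_value for s in univariate_all(t, "A17.1", "FvB")]
        assert sps.kstest(p, "uniform").pvalue > 0.01
        frac = np.mean(np.array(p) < 0.05)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(p))

    def test_reference_magnitudes_all_significant_at_low_noise(self):
        # the nine panel fold changes planted in discovery muscle, low noise
        ref_fcs = [0.81, 0.76, 1.43, 0.79, 0.88, 0.79, 0.63, 0.83, 0.44]
        ids = [f"HILIC_{j + 1}" for j in range(9)]
        t = generate_feature_table(
            ids, matrix="muscle", species="mouse",
            groups={"FvB": 8, "A17.1": 9}, case_group="A17.1",
            effects=dict(zip(ids, ref_fcs)), cv=0.05, seed=11,
        )
        out = univariate_all(t, "A17.1", "FvB")
        assert all(s.p_value < 0.05 for s in out)

    def test_glm_log10_mode_matches_pooled_t(self):
        rng = np.random.default_rng(8)
        t = make_table(rng.lognormal(3, 0.5, (8, 3)), ["a"] * 4 + ["b"] * 4)
        out = univariate_all(t, "b", "a", method="glm_log10")
        for j, s in enumerate(out):
            a = np.log10(t.group_intensities("b").iloc[:, j])
            b = np.log10(t.group_intensities("a").iloc[:, j])
            assert s.p_value == pytest.approx(sps.ttest_ind(a, b).pvalue)
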