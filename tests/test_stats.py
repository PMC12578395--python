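"""Densities, cohort contrasts, correlation, damage scores, and OLS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from renimap.compartments import build_compartment_masks, assign_compartment
from renimap.errors import ConfigError
from renimap.stack import ChannelStack
from renimap.stats import (class_density_matrix, compare_cohorts,
                           compute_density_table, damage_scores, ols_fit,
                           spearman_blocks)


def mwu_enumeration_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of arrangements."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def ustat(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0
                   for a in xs for b in ys)

    u_obs = ustat(x, y)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = ustat(xs, ys)
        mid = len(x) * len(y) / 2
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up in closed form."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def _simple_comps(shape=(100, 100)):
    tub = np.zeros(shape, dtype=int)
    tub[10:30, 10:30] = 1
    glom = np.zeros(shape, dtype=int)
    glom[60:80, 60:80] = 1
    return build_compartment_masks(tub, glom, 10, 1.0)


class TestDensityTable:
    def test_density_is_count_over_area_in_mm2(self):
        # 10 cells on a 1 mm^2 interstitium-only field at 10 um/px
        comps = build_compartment_masks(np.zeros((100, 100), int),
                                        np.zeros((100, 100), int),
                                        ring_width_um=20, pixel_size=10.0)
        cells = pd.DataFrame({"x": np.linspace(5, 95, 10), "y": np.full(10, 50.0),
                              "class_label": ["A"] * 10})
        cells = assign_compartment(cells, comps)
        table = compute_density_table(cells, comps)
        assert table.loc["A", "interstitial"] == pytest.approx(10.0)
        assert table.loc["A", "total"] == pytest.approx(10.0)

    def test_empty_class_in_compartment_is_zero_density(self):
        comps = _simple_comps()
        cells = pd.DataFrame({"x": [50.0], "y": [50.0], "class_label": ["A"]})
        cells = assign_compartment(cells, comps)
        table = compute_density_table(cells, comps)
        assert table.loc["A", "glomerular"] == 0.0

    def test_proportions_sum_to_one_over_classified(self):
        comps = _simple_comps()
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({
            "x": rng.uniform(0, 99, 50), "y": rng.uniform(0, 99, 50),
            "class_label": rng.choice(["A", "B", "non-classified"], 50),
        })
        cells = assign_compartment(cells, comps)
        table = compute_density_table(cells, comps)
        assert table["proportion"].dropna().sum() == pytest.approx(1.0)
        assert np.isnan(table.loc["non-classified", "proportion"])

    def test_unknown_compartment_label_rejected(self):
        comps = _simple_comps()
        cells = pd.DataFrame({"x": [1.0], "y": [1.0], "class_label": ["A"],
                              "compartment": ["cortex"]})
        with pytest.raises(ConfigError):
            compute_density_table(cells, comps)


class TestCompareCohorts:
    def _matrix(self, groups):
        rows, cohorts = {}, {}
        for cohort, arrays in groups.items():
            for i, vals in enumerate(arrays):
                bid = f"{cohort}{i}"
                rows[bid] = vals
                cohorts[bid] = cohort
        dens = pd.DataFrame(rows, index=["c1"]).T
        return dens, pd.Series(cohorts)

    def test_identical_groups_give_p_one(self):
        dens, cohorts = self._matrix({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        out = compare_cohorts(dens, cohorts, pairs=[("A", "B")])
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_small_groups_exact_p(self):
        # {1,2,3} vs {4,5,6}: U = 0, two-sided exact p = 2/20 = 0.1
        dens, cohorts = self._matrix({"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0]})
        out = compare_cohorts(dens, cohorts, pairs=[("A", "B")])
        assert out["U"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 7))
        y = rng.normal(size=rng.integers(3, 7))
        p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
        assert p == pytest.approx(mwu_enumeration_oracle(x, y))

    def test_bh_correction_matches_step_up_closed_form(self):
        dens = pd.DataFrame(np.random.default_rng(1).random((8, 6)),
                            columns=[f"c{i}" for i in range(6)])
        cohorts = pd.Series(["A"] * 4 + ["B"] * 4, index=dens.index)
        out = compare_cohorts(dens, cohorts, pairs=[("A", "B")])
        assert np.allclose(out["q"], bh_oracle(out["p"]))
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_bh_known_vector(self):
        assert np.allclose(bh_oracle([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_missing_cohort_rejected(self):
        dens, cohorts = self._matrix({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigError):
            compare_cohorts(dens, cohorts, pairs=[("A", "Z")])


class TestSpearman:
    def test_monotone_relation_is_one(self):
        mat = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 8, 16, 32]})
        cm = spearman_blocks(mat)
        assert cm.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_rank_formula(self):
        # x=(1,2,3), y=(3,1,2): rho = 1 - 6*6/(3*8) = -0.5
        mat = pd.DataFrame({"a": [1, 2, 3], "b": [3, 1, 2]})
        cm = spearman_blocks(mat)
        assert cm.rho.loc["a", "b"] == pytest.approx(-0.5)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        cm = spearman_blocks(mat)
        assert np.allclose(cm.rho, cm.rho.T)
        assert np.allclose(np.diag(cm.rho), 1.0)
        assert (cm.rho.abs().to_numpy() <= 1 + 1e-12).all()

    def test_constant_column_reported_missing(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        cm = spearman_blocks(mat)
        assert np.isnan(cm.rho.loc["a", "b"])

    def test_small_n_exact_p_matches_permutation_null(self):
        # for n=4 and a perfect ranking, the exact two-sided p is 2/4! = 1/12
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 3.0, 5.0, 9.0]})
        cm = spearman_blocks(mat)
        assert cm.p.loc["a", "b"] == pytest.approx(2 / math.factorial(4))


class TestDamageScores:
    def _setup(self):
        shape = (40, 40)
        tub = np.zeros(shape, dtype=int)
        tub[0:20, 0:20] = 1
        comps = build_compartment_masks(tub, np.zeros(shape, int), 5, 1.0)
        chans = {}
        for name in ("MXA", "Claudin1", "COLIII"):
            c = np.zeros(shape)
            c[0:20, 0:20] = 1.0  # 25% of the field positive
            chans[name] = c
        stack = ChannelStack(channels=chans, pixel_size=1.0)
        return stack, comps

    def test_marker_mask_area_percentage(self):
        stack, comps = self._setup()
        cells = pd.DataFrame({"x": [], "y": [], "class_label": [],
                              "compartment": [], "mfi_MXA": [], "mfi_Claudin1": []})
        out = damage_scores(stack, cells, comps,
                            mask_thresholds={"MXA": 0.5, "Claudin1": 0.5,
                                             "COLIII": 0.5})
        assert out["coliii_area_pct"] == pytest.approx(25.0)
        assert out["mxa_area_pct"] == pytest.approx(25.0)

    def test_inflamed_tubule_density_unit_arithmetic(self):
        stack, comps = self._setup()
        # 5 double-positive cells inside the tubule; tubular area = 400 um^2
        cells = pd.DataFrame({
            "x": [5.0, 6.0, 7.0, 8.0, 9.0, 30.0],
            "y": [5.0] * 5 + [30.0],
            "class_label": ["A"] * 6,
            "compartment": ["tubular"] * 5 + ["interstitial"],
            "mfi_MXA": [1.0] * 6,
            "mfi_Claudin1": [1.0] * 5 + [0.0],
        })
        out = damage_scores(stack, cells, comps,
                            mask_thresholds={"MXA": 0.5, "Claudin1": 0.5,
                                             "COLIII": 0.5})
        tub_mm2 = 400 * 1e-6
        assert out["inflamed_tubule_density"] == pytest.approx(5 / tub_mm2)

    def test_missing_channel_rejected(self):
        stack, comps = self._setup()
        del stack.channels["MXA"]
        with pytest.raises(ConfigError):
            damage_scores(stack, pd.DataFrame(), comps)


class TestOls:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        out = ols_fit(x, 2 * x + 1)
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_hand_computed_normal_equations(self):
        out = ols_fit([0.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert out["slope"] == pytest.approx(0.5)
        assert out["intercept"] == pytest.approx(1 / 6)

    def test_constant_response_flat_fit(self):
        out = ols_fit([0.0, 1.0, 2.0], [3.0, 3.0, 3.0])
        assert out["slope"] == pytest.approx(0.0)
        assert out["r2"] == pytest.approx(0.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ConfigError):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_class_density_matrix_stacks_biopsies():
    t1 = pd.DataFrame({"total": [1.0, 2.0]}, index=["A", "B"])
    t2 = pd.DataFrame({"total": [3.0]}, index=["A"])
    mat = class_density_matrix({"b1": t1, "b2": t2})
    assert mat.loc["b2", "B"] == 0.0
    assert mat.loc["b1", "A"] == 1.0
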