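"""Deterministic cross predictions vs. hand calculations and the MC oracle."""

import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gencross.crosspred import (
    SelectionParams,
    crosses_to_frame,
    mc_predict_cross,
    pair_weight,
    pair_weight_matrices,
    predict_all_crosses,
    predict_cross,
    selection_intensity,
)
from gencross.effects import MarkerEffects
from gencross.genome import GeneticMap, GenotypeMatrix, map_distance_to_recomb


def _eff(vec, mu=0.0, trait="t"):
    return MarkerEffects(trait, mu, np.asarray(vec, dtype=float), "true")


class TestSelectionIntensity:
    def test_top_five_percent(self):
        assert selection_intensity(0.05) == pytest.approx(2.0627, abs=1e-4)
        assert round(selection_intensity(0.05), 2) == 2.06

    def test_half_and_limit(self):
        assert selection_intensity(0.5) == pytest.approx(0.798, abs=1e-3)
        assert selection_intensity(0.9999) < 1e-3

    def test_domain(self):
        for p in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                selection_intensity(p)

    def test_params_object(self):
        assert SelectionParams(0.05).ksp == selection_intensity(0.05)


class TestPairWeight:
    def test_anchor_values(self):
        assert pair_weight(0.5) == 0.0
        assert pair_weight(0.0) == 1.0
        assert pair_weight(0.25) == pytest.approx(1 / 3)

    @given(st.floats(0.0, 0.5))
    def test_bounded_and_monotone(self, c):
        w = pair_weight(c)
        assert 0.0 <= w <= 1.0


class TestTwoLocusClosedForms:
    def test_coupling_variance(self, two_locus_map_c01):
        p = predict_cross(np.array([1.0, 1.0]), np.array([-1.0, -1.0]),
                          _eff([1, 1]), _eff([1, 1]), two_locus_map_c01)
        assert p.variance1 == pytest.approx(1 + 1 + 2 * (0.8 / 1.2))

    def test_repulsion_variance(self, two_locus_map_c01):
        p = predict_cross(np.array([1.0, -1.0]), np.array([-1.0, 1.0]),
                          _eff([1, 1]), _eff([1, 1]), two_locus_map_c01)
        assert p.variance1 == pytest.approx(2 - 4 / 3)

    def test_two_trait_covariance_and_correlation(self, two_locus_map_c01):
        p = predict_cross(np.array([1.0, 1.0]), np.array([-1.0, -1.0]),
                          _eff([1, 0]), _eff([0, 0.5]), two_locus_map_c01)
        assert p.covariance == pytest.approx(1 / 3)
        assert (p.variance1, p.variance2) == (pytest.approx(1.0),
                                              pytest.approx(0.25))
        assert p.correlation == pytest.approx(2 / 3)

    def test_identical_traits_give_unit_correlation(self, two_locus_map_c01):
        p = predict_cross(np.array([1.0, 1.0]), np.array([-1.0, -1.0]),
                          _eff([1, 1]), _eff([1, 1]), two_locus_map_c01)
        assert p.covariance == pytest.approx(p.variance1)
        assert p.correlation == pytest.approx(1.0)

    def test_superior_and_correlated_progeny_means(self, two_locus_map_c01):
        sel = SelectionParams(0.05)
        p = predict_cross(np.array([1.0, 1.0]), np.array([-1.0, -1.0]),
                          _eff([1, 0], mu=1.0), _eff([0, 0.5], mu=-1.0),
                          two_locus_map_c01, sel=sel)
        assert p.mean1 == pytest.approx(1.0) and p.mean2 == pytest.approx(-1.0)
        assert p.musp1 == pytest.approx(1.0 + sel.ksp * 1.0)
        assert p.musp2C == pytest.approx(-1.0 + sel.ksp * (2 / 3) * 0.5)
        assert p.musp1 >= p.mean1


class TestAgainstMonteCarloOracle:
    def test_worked_cases_within_3se(self, two_locus_map_c01):
        n = 100_000
        mc = mc_predict_cross(np.array([1.0, 1.0]), np.array([-1.0, -1.0]),
                              _eff([1, 1]), _eff([1, 1]), two_locus_map_c01,
                              n_progeny=n, seed=5)
        # progeny values are bounded; 3*SE of the variance via moment bound
        assert mc.variance1 == pytest.approx(10 / 3, abs=0.1)
        mc2 = mc_predict_cross(np.array([1.0, 1.0]), np.array([-1.0, -1.0]),
                               _eff([1, 0]), _eff([0, 0.5]),
                               two_locus_map_c01, n_progeny=n, seed=6)
        assert mc2.correlation == pytest.approx(2 / 3, abs=0.02)

    def test_identical_parents_zero_variance(self, two_locus_map_c01):
        mc = mc_predict_cross(np.array([1.0, 1.0]), np.array([1.0, 1.0]),
                              _eff([1, 1]), _eff([1, 1]), two_locus_map_c01,
                              n_progeny=500, seed=7)
        assert mc.variance1 == 0.0


class TestPredictCross:
    def test_identical_parents_warn(self, two_locus_map_c01):
        with pytest.warns(UserWarning, match="identical parents"):
            p = predict_cross(np.array([1.0, 1.0]), np.array([1.0, 1.0]),
                              _eff([1, 1]), _eff([1, 1]), two_locus_map_c01)
        assert p.variance1 == 0.0 and np.isnan(p.correlation)
        assert p.musp1 == p.mean1 and p.musp2C == p.mean2

    def test_non_inbred_parent_rejected(self, two_locus_map_c01):
        with pytest.raises(ValueError, match="not fully inbred"):
            predict_cross(np.array([1.0, 0.0]), np.array([-1.0, -1.0]),
                          _eff([1, 1]), _eff([1, 1]), two_locus_map_c01)

    def test_parent_swap_invariance(self, tiny_panel):
        geno, gmap = tiny_panel
        rng = np.random.default_rng(0)
        u1 = rng.normal(0, 0.1, gmap.n_markers)
        u2 = rng.normal(0, 0.1, gmap.n_markers)
        w = pair_weight_matrices(gmap)
        for i, j in [(0, 1), (4, 9), (20, 77)]:
            a = predict_cross(geno.calls[i], geno.calls[j], _eff(u1), _eff(u2),
                              gmap, weights=w)
            b = predict_cross(geno.calls[j], geno.calls[i], _eff(u1), _eff(u2),
                              gmap, weights=w)
            assert a.variance1 == pytest.approx(b.variance1)
            assert a.covariance == pytest.approx(b.covariance)
            assert a.mean1 == pytest.approx(b.mean1)

    def test_progeny_covariance_matrix_psd(self, tiny_panel):
        geno, gmap = tiny_panel
        rng = np.random.default_rng(1)
        w = pair_weight_matrices(gmap)
        for k in range(10):
            u1 = rng.normal(0, 0.1, gmap.n_markers)
            u2 = rng.normal(0, 0.1, gmap.n_markers)
            i, j = rng.choice(geno.n_individuals, 2, replace=False)
            p = predict_cross(geno.calls[i], geno.calls[j], _eff(u1), _eff(u2),
                              gmap, weights=w)
            cov = np.array([[p.variance1, p.covariance],
                            [p.covariance, p.variance2]])
            assert np.linalg.eigvalsh(cov).min() > -1e-9


def _naive_cross_stats(p1, p2, u1, u2, gmap):
    """Independent oracle: full genomewide double sum over the recombination
    matrix, no chromosome blocking."""
    d = (p1 - p2) / 2.0
    g1, g2 = d * u1, d * u2
    W = (1 - 2 * gmap.recomb_matrix()) / (1 + 2 * gmap.recomb_matrix())
    W[gmap.chrom[:, None] != gmap.chrom[None, :]] = 0.0
    np.fill_diagonal(W, 1.0)
    return g1 @ W @ g1, g2 @ W @ g2, g1 @ W @ g2


class TestPredictAllCrosses:
    def test_counts_and_order(self, tiny_panel):
        geno, gmap = tiny_panel
        u = np.zeros(gmap.n_markers)
        u[0] = 1.0
        for n, expected in [(30, 435), (50, 1225)]:
            preds = predict_all_crosses(geno.subset_individuals(range(n)),
                                        _eff(u), _eff(u), gmap)
            assert len(preds) == expected
        pairs = [(p.parent1, p.parent2) for p in preds]
        idx = {pid: k for k, pid in enumerate(geno.ids[:50])}
        assert pairs == sorted(pairs, key=lambda t: (idx[t[0]], idx[t[1]]))

    def test_blocked_equals_naive_double_sum(self, tiny_panel):
        geno, gmap = tiny_panel
        rng = np.random.default_rng(2)
        u1 = rng.normal(0, 0.2, gmap.n_markers)
        u2 = rng.normal(0, 0.2, gmap.n_markers)
        w = pair_weight_matrices(gmap)
        for _ in range(5):
            i, j = rng.choice(geno.n_individuals, 2, replace=False)
            p = predict_cross(geno.calls[i], geno.calls[j], _eff(u1), _eff(u2),
                              gmap, weights=w)
            v1, v2, cov = _naive_cross_stats(geno.calls[i], geno.calls[j],
                                             u1, u2, gmap)
            assert abs(p.variance1 - v1) < 1e-10
            assert abs(p.variance2 - v2) < 1e-10
            assert abs(p.covariance - cov) < 1e-10

    def test_frame_column_order(self, tiny_panel):
        geno, gmap = tiny_panel
        u = np.zeros(gmap.n_markers)
        u[:3] = 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = crosses_to_frame(
                predict_all_crosses(geno.subset_individuals(range(4)),
                                    _eff(u), _eff(u), gmap))
        assert list(df.columns[:4]) == ["parent1", "parent2", "mean1", "mean2"]
        assert len(df) == 6
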