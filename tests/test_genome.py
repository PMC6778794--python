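"""Genetic maps, founder hygiene and the synthetic panel generator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gencross.genome import (
    GeneticMap,
    GenotypeMatrix,
    clean_founders,
    generate_synthetic_founders,
    jitter_map,
    kosambi_distance_to_recomb,
    map_distance_to_recomb,
    read_genetic_map,
    read_genotype_matrix,
    write_genetic_map,
    write_genotype_matrix,
)


class TestMappingFunction:
    def test_known_values(self):
        assert map_distance_to_recomb(0.0) == 0.0
        assert map_distance_to_recomb(10.0) == pytest.approx(0.090635, abs=1e-6)
        assert map_distance_to_recomb(1e9) == pytest.approx(0.5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            map_distance_to_recomb(-1.0)
        with pytest.raises(ValueError):
            kosambi_distance_to_recomb(-0.1)

    @given(st.floats(0.0, 500.0), st.floats(0.0, 500.0))
    def test_monotone_and_bounded(self, d1, d2):
        c1, c2 = map_distance_to_recomb(d1), map_distance_to_recomb(d2)
        assert 0.0 <= c1 <= 0.5
        if d1 < d2:
            assert c1 <= c2


class TestJitter:
    def test_coincident_positions_spread(self):
        m = GeneticMap(np.array(["a", "b", "c"], dtype=object),
                       np.array([1, 1, 1]), np.array([5.0, 5.0, 5.0]))
        j = jitter_map(m)
        assert np.allclose(j.pos_cM, [5.0, 5.000001, 5.000002])
        assert list(j.marker) == ["a", "b", "c"]

    def test_strict_map_unchanged(self):
        m = GeneticMap(np.array(["a", "b"], dtype=object),
                       np.array([1, 1]), np.array([1.0, 2.0]))
        assert np.array_equal(jitter_map(m).pos_cM, m.pos_cM)

    @given(st.lists(st.sampled_from([0.0, 1.0, 1.0, 2.5, 2.5, 7.0]),
                    min_size=2, max_size=12))
    def test_jitter_always_strictly_increasing(self, pos):
        pos = sorted(pos)
        n = len(pos)
        chrom = np.array([1] * (n // 2) + [2] * (n - n // 2))
        m = GeneticMap(np.array([f"m{i}" for i in range(n)], dtype=object),
                       chrom, np.array(pos)[np.argsort(chrom, kind="stable")])
        assert jitter_map(m).is_strictly_increasing()


class TestRecombinationModel:
    def test_matrix_invariants(self):
        rng = np.random.default_rng(0)
        m = jitter_map(GeneticMap(
            np.array([f"m{i}" for i in range(30)], dtype=object),
            np.repeat([1, 2, 3], 10),
            np.concatenate([np.sort(rng.uniform(0, 100, 10)) for _ in range(3)]),
        ))
        C = m.recomb_matrix()
        assert np.allclose(C, C.T)
        assert np.all(np.diag(C) == 0.0)
        cross = m.chrom[:, None] != m.chrom[None, :]
        assert np.all(C[cross] == 0.5)
        assert np.all((C >= 0) & (C <= 0.5))


def _as_geno(calls):
    calls = np.asarray(calls, dtype=float)
    return GenotypeMatrix([f"L{i}" for i in range(calls.shape[0])], calls)


def _line_map(n, pos=None):
    return GeneticMap(np.array([f"m{i}" for i in range(n)], dtype=object),
                      np.ones(n, dtype=int),
                      np.arange(n, dtype=float) if pos is None else np.array(pos))


class TestCleanFounders:
    def test_monomorphic_removed(self):
        g = _as_geno([[1, 1], [1, -1], [1, 1]])
        out, omap = clean_founders(g, _line_map(2))
        assert out.n_markers == 1 and list(omap.marker) == ["m1"]

    def test_redundant_same_calls_and_position_deduped(self):
        calls = [[1, 1, -1], [-1, -1, 1], [1, 1, -1]]
        gmap = _line_map(3, pos=[1.0, 1.0, 2.0])
        out, omap = clean_founders(_as_geno(calls), gmap)
        assert out.n_markers == 2  # m0/m1 identical calls at identical position

    def test_mode_imputation_and_het_to_missing(self):
        calls = np.array([[1, 1], [1, 0], [np.nan, -1], [-1, 1]])
        out, _ = clean_founders(_as_geno(calls), _line_map(2), max_missing=0.6)
        assert out.calls[2, 0] == 1  # mode of (1, 1, -1)
        assert out.calls[1, 1] == 1  # het set missing, imputed to mode
        assert not out.has_missing() and out.is_inbred()

    def test_missing_filters_lines_then_markers(self):
        calls = np.array([
            [1, -1, 1, -1],
            [np.nan, np.nan, np.nan, 1],  # 75% missing line: dropped
            [1, 1, -1, -1],
            [-1, 1, np.nan, 1],
        ])
        out, _ = clean_founders(_as_geno(calls), _line_map(4), max_missing=0.30)
        assert out.n_individuals == 3
        assert out.n_markers == 3  # m2 still 1/3 missing: dropped

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([-1.0, 0.0, 1.0], size=(40, 60),
                           p=[0.45, 0.05, 0.5])
        calls[rng.random(calls.shape) < 0.05] = np.nan
        gmap = _line_map(60)
        g1, m1 = clean_founders(_as_geno(calls), gmap)
        g2, m2 = clean_founders(g1, m1)
        assert np.array_equal(g1.calls, g2.calls)
        assert list(m1.marker) == list(m2.marker)

    def test_everything_removed_raises(self):
        g = _as_geno([[1, 1], [1, 1]])
        with pytest.raises(ValueError):
            clean_founders(g, _line_map(2))


class TestSyntheticFounders:
    def test_deterministic_under_seed(self):
        a = generate_synthetic_founders(50, 60, 3, 100.0, 10, 1, seed=9)
        b = generate_synthetic_founders(50, 60, 3, 100.0, 10, 1, seed=9)
        assert np.array_equal(a[0].calls, b[0].calls)
        assert np.array_equal(a[1].pos_cM, b[1].pos_cM)

    def test_no_mixing_returns_base_haplotypes(self):
        g, _ = generate_synthetic_founders(60, 50, 2, 80.0, 5, 0, seed=2)
        assert len(np.unique(g.calls, axis=0)) <= 5

    def test_panel_is_inbred_and_polymorphic(self, desk_panel):
        geno, _ = desk_panel
        assert geno.is_inbred()
        poly = np.mean([len(np.unique(c)) > 1 for c in geno.calls.T])
        assert poly >= 0.95

    def test_ld_decays_with_distance(self):
        # the spec-sheet panel configuration: many mixing generations
        geno, gmap = generate_synthetic_founders(300, 350, 7, 150.0, 30, 20,
                                                 seed=4)
        X = geno.calls - geno.calls.mean(axis=0)
        sd = X.std(axis=0)
        bins = [(0, 10), (10, 30), (30, 60), (60, 120)]
        means = []
        rng = np.random.default_rng(0)
        for lo, hi in bins:
            r2 = []
            for _ in range(4000):
                sl = gmap.chrom_slices()[int(rng.choice(gmap.chromosomes))]
                i, j = rng.integers(sl.start, sl.stop, 2)
                d = abs(gmap.pos_cM[i] - gmap.pos_cM[j])
                if lo <= d < hi and sd[i] > 0 and sd[j] > 0:
                    r2.append(((X[:, i] * X[:, j]).mean() / (sd[i] * sd[j])) ** 2)
            means.append(np.mean(r2))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_survives_hygiene_mostly_unchanged(self, tiny_panel):
        geno, gmap = tiny_panel
        out, omap = clean_founders(geno, gmap)
        assert out.n_individuals == geno.n_individuals
        assert out.n_markers >= 0.9 * geno.n_markers

    def test_too_few_base_haplotypes(self):
        with pytest.raises(ValueError):
            generate_synthetic_founders(10, 10, 1, 50.0, 1, 0, seed=0)


class TestFileFormats:
    def test_round_trip(self, tmp_path, tiny_panel):
        geno, gmap = tiny_panel
        write_genetic_map(gmap, tmp_path / "m.tsv")
        write_genotype_matrix(geno, gmap, tmp_path / "g.tsv")
        gmap2 = read_genetic_map(tmp_path / "m.tsv")
        geno2 = read_genotype_matrix(tmp_path / "g.tsv", gmap2)
        assert list(gmap2.marker) == list(gmap.marker)
        assert np.allclose(gmap2.pos_cM, gmap.pos_cM)
        assert np.array_equal(geno2.calls, geno.calls)
        assert geno2.ids == geno.ids

    def test_na_sentinel(self, tmp_path):
        gmap = _line_map(2)
        g = _as_geno(np.array([[1.0, np.nan], [-1.0, 1.0]]))
        write_genotype_matrix(g, gmap, tmp_path / "g.tsv")
        text = (tmp_path / "g.tsv").read_text()
        assert "NA" in text
        back = read_genotype_matrix(tmp_path / "g.tsv", gmap)
        assert np.isnan(back.calls[0, 1])

    def test_marker_set_mismatch_reports_diff(self, tmp_path, tiny_panel):
        geno, gmap = tiny_panel
        write_genotype_matrix(geno, gmap, tmp_path / "g.tsv")
        other = gmap.subset(np.arange(gmap.n_markers - 1))
        with pytest.raises(ValueError, match="only in genotypes"):
            read_genotype_matrix(tmp_path / "g.tsv", other)
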