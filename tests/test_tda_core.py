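"""Filtration construction, GF(2) reduction, representatives, Betti curves."""

import math

import numpy as np
import pytest

from connectoloop import (
    betti_curve,
    build_filtration,
    reduce_filtration,
    representative_cycle,
    tighten_cycle,
)
from gf2_oracle import betti_numbers, random_distance_matrix

SQRT2 = math.sqrt(2.0)
SIN60 = abs(math.sin(2 * math.pi / 6))  # ≈ 0.8660254


def equilateral(n: int, dist: float = 1.0) -> np.ndarray:
    d = np.full((n, n), dist)
    np.fill_diagonal(d, 0.0)
    return d


class TestBuildFiltration:
    def test_three_points_counts(self):
        f = build_filtration(equilateral(3))
        assert len(f) == 7
        dims = [s.dim for s in f.simplices]
        assert dims.count(0) == 3 and dims.count(1) == 3 and dims.count(2) == 1
        tri = f.simplices[-1]
        assert tri.vertices == (0, 1, 2) and tri.value == 1.0

    def test_square_max_edge_rule(self, square_distance):
        f = build_filtration(square_distance)
        assert len(f) == 4 + 6 + 4
        tris = [s for s in f.simplices if s.dim == 2]
        assert all(s.value == SQRT2 for s in tris)

    def test_eps_max_cutoff_drops_triangles(self, square_distance):
        # between the side length and the diagonal: 4 sides, no triangles
        f = build_filtration(square_distance, eps_max=1.2)
        assert all(s.dim < 2 for s in f.simplices)
        assert sum(s.dim == 1 for s in f.simplices) == 4

    def test_order_is_value_dim_lex(self, square_distance):
        f = build_filtration(square_distance)
        keys = [s.sort_key() for s in f.simplices]
        assert keys == sorted(keys)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_filtration(np.zeros((0, 0)))

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            build_filtration(d)


class TestReduce:
    def test_square_single_h1_bar(self, square_distance):
        bars, _ = reduce_filtration(build_filtration(square_distance))
        h1 = [b for b in bars if b.dim == 1]
        assert len(h1) == 1
        assert h1[0].birth == 1.0
        assert h1[0].death == pytest.approx(SQRT2, abs=1e-15)

    def test_square_representative_all_corners(self, square_distance):
        bars, state = reduce_filtration(build_filtration(square_distance))
        bar = next(b for b in bars if b.dim == 1)
        assert representative_cycle(bar, state) == (0, 1, 2, 3)

    def test_h0_structure(self, square_distance):
        bars, _ = reduce_filtration(build_filtration(square_distance),
                                    keep_zero_bars=True)
        h0 = [b for b in bars if b.dim == 0]
        assert len(h0) == 4
        assert all(b.birth == 0.0 for b in h0)
        assert sum(b.essential for b in h0) == 1

    def test_triangle_has_no_visible_h1(self):
        # cycle and filling triangle co-occur at eps=1: zero-longitude bar
        bars, _ = reduce_filtration(build_filtration(equilateral(3)))
        assert not any(b.dim == 1 for b in bars)
        bars_all, _ = reduce_filtration(build_filtration(equilateral(3)),
                                        keep_zero_bars=True)
        zero = [b for b in bars_all if b.dim == 1]
        assert len(zero) == 1 and zero[0].birth == zero[0].death == 1.0

    def test_hexagon_phase_fixture(self, hexagon_distance):
        bars, state = reduce_filtration(build_filtration(hexagon_distance))
        h1 = [b for b in bars if b.dim == 1]
        assert len(h1) == 1
        bar = h1[0]
        assert bar.birth == pytest.approx(0.5, abs=1e-12)
        assert bar.death == pytest.approx(SIN60, abs=1e-12)
        assert representative_cycle(bar, state) == (0, 1, 2, 3, 4, 5)

    def test_hexagon_representative_is_closed_walk(self, hexagon_distance):
        bars, state = reduce_filtration(build_filtration(hexagon_distance))
        bar = next(b for b in bars if b.dim == 1)
        degree: dict[int, int] = {}
        for i, j in bar.representative_edges:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        assert all(v == 2 for v in degree.values())  # a single closed walk
        assert bar.birth_simplex.vertices in bar.representative_edges

    def test_no_essential_h1_on_full_filtration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            d = random_distance_matrix(rng, 7)
            bars, _ = reduce_filtration(build_filtration(d))
            assert not any(b.dim == 1 and b.essential for b in bars)

    def test_representative_even_degree_with_birth_edge(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = random_distance_matrix(rng, 8)
            bars, state = reduce_filtration(build_filtration(d))
            for bar in bars:
                if bar.dim != 1 or bar.essential:
                    continue
                assert bar.birth_simplex.vertices in bar.representative_edges
                degree: dict[int, int] = {}
                for i, j in bar.representative_edges:
                    degree[i] = degree.get(i, 0) + 1
                    degree[j] = degree.get(j, 0) + 1
                assert all(v % 2 == 0 for v in degree.values())

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        d = random_distance_matrix(rng, 7)
        perm = rng.permutation(7)
        dp = d[np.ix_(perm, perm)]
        bars, _ = reduce_filtration(build_filtration(d))
        bars_p, _ = reduce_filtration(build_filtration(dp))
        pairs = sorted((b.dim, b.birth, b.death) for b in bars)
        pairs_p = sorted((b.dim, b.birth, b.death) for b in bars_p)
        assert pairs == pytest.approx(pairs_p)

    def test_eps_max_can_leave_essential_h1(self, square_distance):
        # cut the filtration before the diagonals: the loop never dies
        f = build_filtration(square_distance, eps_max=1.1)
        bars, _ = reduce_filtration(f)
        h1 = [b for b in bars if b.dim == 1]
        assert len(h1) == 1 and h1[0].essential


class TestBettiCurve:
    @pytest.mark.parametrize("dim,eps,expected", [(1, 1.2, 1), (0, 1.2, 1),
                                                  (0, 0.5, 4), (1, 1.5, 0)])
    def test_square_betti(self, square_distance, dim, eps, expected):
        bars, _ = reduce_filtration(build_filtration(square_distance),
                                    keep_zero_bars=True)
        assert betti_curve(bars, dim, eps) == expected

    def test_negative_eps_counts_nothing(self, square_distance):
        bars, _ = reduce_filtration(build_filtration(square_distance),
                                    keep_zero_bars=True)
        assert betti_curve(bars, 0, -0.1) == 0

    def test_matches_oracle_small_suite(self):
        rng = np.random.default_rng(23)
        for _ in range(8):
            n = int(rng.integers(4, 8))
            d = random_distance_matrix(rng, n)
            bars, _ = reduce_filtration(build_filtration(d),
                                        keep_zero_bars=True)
            for eps in rng.uniform(0.0, 1.05, size=5):
                b0, b1 = betti_numbers(d, eps)
                assert betti_curve(bars, 0, eps) == b0
                assert betti_curve(bars, 1, eps) == b1


class TestTighten:
    def test_tighten_returns_cycle_no_longer_than_original(self):
        rng = np.random.default_rng(31)
        d = random_distance_matrix(rng, 8)
        bars, state = reduce_filtration(build_filtration(d))
        for bar in bars:
            if bar.dim != 1 or bar.essential:
                continue
            tightened = tighten_cycle(bar, d, state)
            assert len(tightened) <= len(bar.representative_edges)
            degree: dict[int, int] = {}
            for i, j in tightened:
                degree[i] = degree.get(i, 0) + 1
                degree[j] = degree.get(j, 0) + 1
            assert all(v % 2 == 0 for v in degree.values())

    def test_usage_errors(self, square_distance):
        bars, state = reduce_filtration(build_filtration(square_distance))
        h0 = next(b for b in bars if b.dim == 0)
        with pytest.raises(ValueError, match="dimension-1"):
            representative_cycle(h0, state)
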