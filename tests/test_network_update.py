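"""Bond inheritance at division: triangle criterion, tetrahedron prune, locality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamella import (
    ModelParams,
    TriangleOutcome,
    reassign_bonds,
    segment_min_distance,
    tetrahedron_prune,
    triangle_rule,
)

from conftest import make_tissue


class TestTriangleRule:
    @pytest.mark.parametrize(
        "d1j, d2j, eps, expected",
        [
            (1.0, 1.0, 0.85, TriangleOutcome.BOTH),  # ratio 1 is always inside
            (0.5, 1.0, 0.85, TriangleOutcome.NEAREST_ONLY),
            (0.9, 1.0, 0.85, TriangleOutcome.BOTH),  # 0.85 < 0.9 < 1.176
            (1.0, 0.9, 0.85, TriangleOutcome.BOTH),  # symmetric counterpart
            (2.0, 1.0, 0.85, TriangleOutcome.NEAREST_ONLY),
            (0.85, 1.0, 0.85, TriangleOutcome.NEAREST_ONLY),  # strict: tie fails
            (1.0, 0.85, 0.85, TriangleOutcome.NEAREST_ONLY),
        ],
    )
    def test_ratio_band(self, d1j, d2j, eps, expected):
        assert triangle_rule(d1j, d2j, eps) is expected

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            triangle_rule(0.0, 1.0, 0.85)

    def test_symmetric_in_daughters(self, rng):
        for _ in range(100):
            d1j, d2j = rng.uniform(0.2, 3.0, 2)
            assert triangle_rule(d1j, d2j, 0.85) is triangle_rule(d2j, d1j, 0.85)


def _grid_oracle(a0, a1, b0, b1):
    """Brute-force segment distance: coarse grid plus two local refinements."""
    a0, a1, b0, b1 = map(np.asarray, (a0, a1, b0, b1))

    def dist(s, t):
        pa = a0[None, None] + s[:, None, None] * (a1 - a0)[None, None]
        pb = b0[None, None] + t[None, :, None] * (b1 - b0)[None, None]
        return np.linalg.norm(pa - pb, axis=-1)

    lo_s, hi_s, lo_t, hi_t = 0.0, 1.0, 0.0, 1.0
    for n in (401, 101, 101):
        s = np.linspace(lo_s, hi_s, n)
        t = np.linspace(lo_t, hi_t, n)
        d = dist(s, t)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        ds, dt = (hi_s - lo_s) / (n - 1), (hi_t - lo_t) / (n - 1)
        lo_s, hi_s = max(0.0, s[i] - ds), min(1.0, s[i] + ds)
        lo_t, hi_t = max(0.0, t[j] - dt), min(1.0, t[j] + dt)
    return float(d[i, j])


class TestSegmentDistance:
    def test_regular_tetrahedron_opposite_edges(self):
        a0, a1 = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        b0 = np.array([0.5, np.sqrt(3) / 2, 0.0])
        b1 = np.array([0.5, np.sqrt(3) / 6, np.sqrt(6) / 3])
        assert segment_min_distance(a0, a1, b0, b1) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_intersecting_segments(self):
        assert segment_min_distance([-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_parallel_offset_segments(self):
        assert segment_min_distance([0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]) == pytest.approx(
            1.0
        )

    def test_degenerate_segments_are_points(self):
        assert segment_min_distance([0, 0, 0], [0, 0, 0], [3, 4, 0], [3, 4, 0]) == pytest.approx(
            5.0
        )

    def test_symmetry(self, rng):
        for _ in range(50):
            a0, a1, b0, b1 = rng.uniform(-1, 1, (4, 3))
            assert segment_min_distance(a0, a1, b0, b1) == pytest.approx(
                segment_min_distance(b0, b1, a0, a1), abs=1e-12
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False),
            min_size=12,
            max_size=12,
        )
    )
    def test_metric_properties(self, coords):
        """Non-negative, symmetric, endpoint-order invariant, and never
        above the closest endpoint-to-endpoint distance."""
        a0, a1, b0, b1 = np.asarray(coords).reshape(4, 3)
        d = segment_min_distance(a0, a1, b0, b1)
        assert d >= 0.0
        assert d == pytest.approx(segment_min_distance(b0, b1, a0, a1), abs=1e-12)
        assert d == pytest.approx(segment_min_distance(a1, a0, b1, b0), abs=1e-9)
        endpoint_min = min(
            np.linalg.norm(p - q) for p in (a0, a1) for q in (b0, b1)
        )
        assert d <= endpoint_min + 1e-12

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(40):
            a0, a1, b0, b1 = rng.uniform(-1, 1, (4, 3))
            exact = segment_min_distance(a0, a1, b0, b1)
            assert exact == pytest.approx(_grid_oracle(a0, a1, b0, b1), abs=1e-4)
            # the oracle minimises over a subset, so it can never be below
            assert exact <= _grid_oracle(a0, a1, b0, b1) + 1e-12


def _four_clique(nA_pos, nB_pos, d1_pos=(0.5, 0.0, 0.0), d2_pos=(-0.5, 0.0, 0.0)):
    """Daughter pair + two neighbours with all six bonds (a full 4-clique)."""
    t, ids = make_tissue(
        [(d1_pos, 0.8), (d2_pos, 0.8), (nA_pos, 0.8), (nB_pos, 0.8)],
        bonds=[(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
    )
    return t, ids


class TestTetrahedronPrune:
    def test_coplanar_clique_loses_neighbour_diagonal(self):
        t, ids = _four_clique((0, 1, 0), (0, -1, 0))
        removed = tetrahedron_prune(t, ids[0], ids[1], tau=0.4)
        assert removed == [(ids[2], ids[3])]
        assert not t.has_bond(ids[2], ids[3])
        assert t.has_bond(ids[0], ids[1])  # daughter wall survives

    def test_regular_tetrahedron_survives_default_tau(self):
        d1 = (0.0, 0.0, 0.0)
        d2 = (1.0, 0.0, 0.0)
        nA = (0.5, np.sqrt(3) / 2, 0.0)
        nB = (0.5, np.sqrt(3) / 6, np.sqrt(6) / 3)
        t, ids = _four_clique(nA, nB, d1, d2)
        assert tetrahedron_prune(t, ids[0], ids[1], tau=0.4) == []
        assert len(t.bonds) == 6

    @pytest.mark.parametrize("z, pruned", [(0.39, True), (0.41, False)])
    def test_thickness_boundary(self, z, pruned):
        # thickness of this clique is exactly z; daughter separation is 1
        t, ids = _four_clique((0, 1, z), (0, -1, z))
        removed = tetrahedron_prune(t, ids[0], ids[1], tau=0.4)
        assert bool(removed) is pruned

    def test_daughter_bond_protected_even_when_longer(self):
        # neighbour diagonal (length 0.6) is shorter than d1-d2 (length 1):
        # the "remove the longer" rule would pick d1-d2, but the daughter
        # wall is unconditional, so nA-nB goes instead
        t, ids = _four_clique((0, 0.3, 0.1), (0, -0.3, 0.1))
        removed = tetrahedron_prune(t, ids[0], ids[1], tau=0.4)
        assert removed == [(ids[2], ids[3])]
        assert t.has_bond(ids[0], ids[1])

    def test_incomplete_clique_untouched(self):
        t, ids = _four_clique((0, 1, 0), (0, -1, 0))
        t.remove_bond(ids[1], ids[3])  # d2-nB missing: not a 4-clique
        assert tetrahedron_prune(t, ids[0], ids[1], tau=0.4) == []


class TestReassignBonds:
    def _divided(self, neighbours, bonds_among=(), epsilon=0.85):
        """Place daughters at (+-0.5, 0, 0) plus neighbours; reassign."""
        cells = [((0.5, 0.0, 0.0), 0.8), ((-0.5, 0.0, 0.0), 0.8)]
        cells += [(pos, 0.8) for pos in neighbours]
        t, ids = make_tissue(cells)
        for a, b in bonds_among:
            t.add_bond(ids[2 + a], ids[2 + b])
        res = reassign_bonds(
            t, set(ids[2:]), ids[0], ids[1], ModelParams(epsilon=epsilon)
        )
        return t, ids, res

    def test_no_neighbours_gives_single_daughter_bond(self):
        t, ids, res = self._divided([])
        assert t.bonds == {(ids[0], ids[1])}
        assert res.added == [(ids[0], ids[1])]

    def test_equidistant_neighbour_bonds_both(self):
        t, ids, _ = self._divided([(0.0, 2.0, 0.0)])
        assert t.has_bond(ids[0], ids[2]) and t.has_bond(ids[1], ids[2])

    def test_lopsided_neighbour_bonds_nearest_only(self):
        t, ids, _ = self._divided([(1.5, 0.0, 0.0)])  # d1j=1, d2j=2
        assert t.has_bond(ids[0], ids[2])
        assert not t.has_bond(ids[1], ids[2])

    def test_every_neighbour_keeps_a_daughter(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 7))
            nbrs = [tuple(v) for v in rng.uniform(-2, 2, (n, 3))]
            t, ids, _ = self._divided(nbrs)
            for j in ids[2:]:
                assert t.has_bond(ids[0], j) or t.has_bond(ids[1], j)

    def test_unrelated_bonds_untouched(self):
        t, ids, _ = self._divided(
            [(0.0, 2.0, 0.0), (0.0, 5.0, 0.0)], bonds_among=[(0, 1)]
        )
        # the neighbour-neighbour bond is outside any flat 4-clique here
        assert t.has_bond(ids[2], ids[3])

    def test_work_depends_on_degree_not_tissue_size(self, rng):
        """Same mother degree, wildly different sample size: equal effort."""
        counts = []
        for extra in (0, 400):
            cells = [((0.5, 0.0, 0.0), 0.8), ((-0.5, 0.0, 0.0), 0.8)]
            nbrs = [(0.0, 1.8, 0.0), (0.0, -1.8, 0.0), (1.8, 1.0, 0.0)]
            cells += [(p, 0.8) for p in nbrs]
            cells += [((100 + 3 * i, 0.0, 0.0), 0.8) for i in range(extra)]
            t, ids = make_tissue(cells)
            for i in range(extra - 1):
                t.add_bond(ids[5 + i], ids[5 + i + 1])
            res = reassign_bonds(t, set(ids[2:5]), ids[0], ids[1], ModelParams())
            counts.append(res.distance_evaluations)
        assert counts[0] == counts[1]
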