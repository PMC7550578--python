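"""Order parameters: psi6/psi6*, neighbour counts, rows, S(q), events."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corti_vertex.analysis import (
    CentroidSet,
    area_ratio,
    classify_rows,
    count_events,
    displacement_profiles,
    hc_neighbor_graph,
    psi6,
    psi6_star,
    sc_neighbor_count,
    sc_neighbor_counts,
    straighten_centroids,
    structure_factor,
)
from corti_vertex.fixtures import (
    checkerboard_strip,
    spiral_arc,
    stretched_hexagon,
)
from corti_vertex.topology import TopologyEvent

from conftest import strip_state


def hexagon(center=(0.0, 0.0), r=1.0, phase=0.0):
    ang = np.arange(6) * math.pi / 3 + phase
    return np.asarray(center) + r * np.column_stack([np.cos(ang), np.sin(ang)])


class TestPsi6:
    def test_regular_hexagon_is_one(self):
        assert psi6(np.zeros(2), hexagon()) == pytest.approx(1.0)

    @pytest.mark.parametrize("phase", [0.1, 0.7, 2.0])
    def test_rotation_invariant(self, phase):
        assert psi6(np.zeros(2), hexagon(phase=phase)) == pytest.approx(1.0)

    def test_hand_computed_defective_hexagon(self):
        # angles 0..240 in 60-degree steps plus one neighbour at 330:
        # sum of exp(6 i theta) = 5 + exp(i*1980 deg) = 5 - 1
        ang = np.radians([0, 60, 120, 180, 240, 330])
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        assert psi6(np.zeros(2), pts) == pytest.approx(4.0 / 6.0)

    def test_coincident_neighbor_rejected(self):
        with pytest.raises(ValueError):
            psi6(np.zeros(2), np.array([[0.0, 0.0], [1.0, 0.0]]))

    @given(st.integers(1, 12), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_bounded_on_random_points(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0.5, 2.0, (n, 1)) * \
            np.column_stack([np.cos(a := rng.uniform(0, 2 * np.pi, n)),
                             np.sin(a)])
        v = psi6(np.zeros(2), pts)
        assert 0.0 <= v <= 1.0 + 1e-12


class TestPsi6Star:
    FULL_GRAPH = ({0: {1, 2, 3, 4, 5, 6}}, set())

    def test_stretched_hexagon_recovered(self):
        # at stretch 1.8 the same-row points leave the Voronoi neighbour
        # set, so the inverse construction is checked on the full ring
        pts = stretched_hexagon(r=1.8)
        res = psi6_star(0, pts, graph=self.FULL_GRAPH)
        assert res is not None
        assert res.psi6 == pytest.approx(1.0, abs=1e-6)
        assert res.r_e == pytest.approx(1.8, rel=1e-3)

    def test_moderately_stretched_hexagon_via_voronoi(self):
        pts = stretched_hexagon(r=1.5)
        res = psi6_star(0, pts)
        assert res is not None
        assert len(res.neighbors) == 6
        assert res.psi6 == pytest.approx(1.0, abs=1e-6)
        assert res.r_e == pytest.approx(1.5, rel=1e-3)

    def test_unstretched_hexagon_identity(self):
        pts = stretched_hexagon(r=1.0)
        res = psi6_star(0, pts)
        assert res.r_e == pytest.approx(1.0, abs=1e-6)
        assert res.psi6 == pytest.approx(res.psi6_raw, abs=1e-9)
        assert res.psi6 == pytest.approx(1.0, abs=1e-6)

    def test_rescaling_beats_raw_under_jitter(self):
        """On jittered stretched hexagons the corrected order parameter is
        systematically higher than the raw one."""
        rng = np.random.default_rng(12)
        stars, raws = [], []
        for _ in range(300):
            pts = stretched_hexagon(r=1.5, jitter=0.02, rng=rng)
            res = psi6_star(0, pts, graph=self.FULL_GRAPH)
            if res is None:
                continue
            stars.append(res.psi6)
            raws.append(res.psi6_raw)
        assert np.mean(stars) > np.mean(raws)

    def test_too_few_neighbors_excluded(self):
        pts = CentroidSet(ids=np.arange(3),
                          cls=np.array(["HC"] * 3, dtype=object),
                          xy=np.array([[0, 0], [1, 0], [0, 1.0]]))
        # all three points lie on the hull: boundary cells are excluded
        assert psi6_star(0, pts) is None


class TestNeighborGraph:
    def test_triangle_complete(self):
        pts = CentroidSet(ids=np.arange(3),
                          cls=np.array(["HC"] * 3, dtype=object),
                          xy=np.array([[0, 0], [2, 0], [1, 1.5]]))
        adj, boundary = hc_neighbor_graph(pts)
        assert adj == {0: {1, 2}, 1: {0, 2}, 2: {0, 1}}
        assert boundary == {0, 1, 2}

    def test_square_grid_interior_has_four(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        xy = np.column_stack([xs.ravel(), ys.ravel()])
        pts = CentroidSet(ids=np.arange(25),
                          cls=np.array(["HC"] * 25, dtype=object), xy=xy)
        adj, boundary = hc_neighbor_graph(pts)
        center = 12  # (2, 2)
        assert center not in boundary
        assert adj[center] == {7, 11, 13, 17}

    def test_collinear_rejected(self):
        pts = CentroidSet(ids=np.arange(4),
                          cls=np.array(["HC"] * 4, dtype=object),
                          xy=np.column_stack([np.arange(4.0), np.zeros(4)]))
        with pytest.raises(ValueError):
            hc_neighbor_graph(pts)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        pts = CentroidSet(ids=np.arange(30),
                          cls=np.array(["HC"] * 30, dtype=object),
                          xy=rng.uniform(0, 10, (30, 2)))
        adj, _ = hc_neighbor_graph(pts)
        for a, nbs in adj.items():
            for b in nbs:
                assert a in adj[b]


class TestCountsAndRatios:
    def test_checkerboard_middle_row_has_four_sc(self):
        st = checkerboard_strip()
        counts = sc_neighbor_counts(st)
        assert counts  # middle-row HCs are analysed
        assert set(counts.values()) == {4}

    def test_neighbor_partition(self, disordered_state):
        from corti_vertex.initial import lateral_inhibition

        lateral_inhibition(disordered_state, np.random.default_rng(0))
        adj = disordered_state.adjacency()
        for cid, cd in disordered_state.alive_cells().items():
            if cd.cls != "HC":
                continue
            n_sc = sc_neighbor_count(disordered_state, cid)
            n_hc = sum(disordered_state.cells[n].cls == "HC"
                       for n in adj[cid])
            assert n_sc + n_hc <= len(adj[cid])
            assert n_sc == sum(disordered_state.cells[n].cls == "SC"
                               for n in adj[cid])

    def test_area_ratio_equal_areas(self):
        st = checkerboard_strip()
        assert area_ratio(st) == pytest.approx(1.0)

    def test_area_ratio_hand_fixture(self):
        # HC of area 2 flanked by SCs of area 1 and 4: mean{2/1, 2/4} = 1.25
        # (the pad column keeps every strip below half the box width)
        st = strip_state([1.0, 2.0, 4.0, 4.0], ["SC", "HC", "SC", "SC"])
        assert area_ratio(st) == pytest.approx(1.25)

    def test_area_ratio_homogeneous_in_hc_area(self):
        st = strip_state([1.0, 2.0, 4.0, 4.0], ["SC", "HC", "SC", "SC"])
        r1 = area_ratio(st)
        st2 = strip_state([1.0, 4.0, 4.0, 4.0], ["SC", "HC", "SC", "SC"])
        assert area_ratio(st2) == pytest.approx(2 * r1)


class TestRows:
    def test_perfect_strip(self):
        st = checkerboard_strip(cols=8)
        pts = CentroidSet.from_state(st)
        labels, n = classify_rows(pts, st)
        assert n == 3
        per_row = {"OHC1": 0, "OHC2": 0, "OHC3": 0}
        for lab in labels.values():
            per_row[lab] += 1
        assert per_row == {"OHC1": 4, "OHC2": 4, "OHC3": 4}

    def test_single_row(self):
        st = checkerboard_strip(cols=8)
        # drop the two upper HC rows
        for cid, cd in st.alive_cells().items():
            if cd.cls == "HC" and st.cell_centroid(cid)[1] > 2.0:
                cd.cls = "SC"
        pts = CentroidSet.from_state(st)
        labels, n = classify_rows(pts, st)
        assert n == 1
        assert set(labels.values()) == {"OHC1"}

    def test_middle_row_touches_only_sc(self):
        st = checkerboard_strip()
        pts = CentroidSet.from_state(st)
        labels, _ = classify_rows(pts, st)
        adj = st.adjacency()
        for cid, lab in labels.items():
            if lab == "OHC2":
                assert all(st.cells[n].cls == "SC" for n in adj[cid])


class TestStraightening:
    def test_straight_row_is_identity(self):
        xy = np.column_stack([np.arange(10.0), np.zeros(10)])
        pts = CentroidSet(ids=np.arange(10),
                          cls=np.array(["HC"] * 10, dtype=object), xy=xy,
                          row=np.array(["OHC2"] * 10, dtype=object))
        out = straighten_centroids(pts)
        assert np.allclose(out.xy, xy, atol=1e-10)

    def test_arc_unrolled_to_axis(self):
        pts = spiral_arc(n=40, radius=40.0)
        out = straighten_centroids(pts)
        total = 40 * 1.0
        assert np.abs(out.xy[:, 1]).max() < 0.01 * total

    def test_consecutive_distances_preserved(self):
        pts = spiral_arc(n=30, radius=30.0)
        d_in = np.linalg.norm(np.diff(pts.xy, axis=0), axis=1)
        out = straighten_centroids(pts)
        d_out = np.linalg.norm(np.diff(out.xy, axis=0), axis=1)
        assert np.allclose(d_in, d_out, atol=1e-9)


class TestStructureFactor:
    def test_s0_equals_n(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 10, (50, 2))
        pts = CentroidSet(ids=np.arange(50),
                          cls=np.array(["HC"] * 50, dtype=object), xy=xy)
        sf = structure_factor(pts, qx=np.array([0.0]), qy=np.array([0.0]))
        assert sf.S[0, 0] == pytest.approx(50.0)

    def test_bragg_peak_of_rectangular_lattice(self):
        xs, ys = np.meshgrid(np.arange(8.0), 2.0 * np.arange(6.0))
        xy = np.column_stack([xs.ravel(), ys.ravel()])
        n = len(xy)
        pts = CentroidSet(ids=np.arange(n),
                          cls=np.array(["HC"] * n, dtype=object), xy=xy)
        q1 = 2 * math.pi  # first reciprocal vector of unit x-spacing
        sf = structure_factor(pts, qx=np.array([q1]), qy=np.array([0.0]))
        assert sf.S[0, 0] == pytest.approx(n, rel=1e-9)

    def test_poisson_mean_near_one(self):
        rng = np.random.default_rng(4)
        n = 200
        xy = rng.uniform(0, 30, (n, 2))
        pts = CentroidSet(ids=np.arange(n),
                          cls=np.array(["HC"] * n, dtype=object), xy=xy)
        qs = np.linspace(1.0, 4.0, 24)
        sf = structure_factor(pts, qx=qs, qy=qs)
        m = sf.S.mean()
        # S has mean 1 and variance ~1 for an ideal gas of points
        assert abs(m - 1.0) < 3.0 / math.sqrt(sf.S.size / 4)


def _ev(kind, step, y=1.0):
    return TopologyEvent(kind=kind, step=step, cells=(), junction=None,
                        cell=None, location=(0.0, y))


class TestEventRates:
    def test_empty_log(self):
        assert count_events([], "T1", n_cells=10, duration=5.0) == 0.0

    def test_hand_arithmetic(self):
        evs = [_ev("T1", s) for s in range(6)] + [_ev("T2", 1)]
        assert count_events(evs, "T1", n_cells=30, duration=2.0) == \
            pytest.approx(0.1)

    def test_region_filter(self):
        evs = [_ev("T1", 0, y=1.0), _ev("T1", 1, y=9.0)]
        assert count_events(evs, "T1", 10, 1.0, region=(0, 5)) == \
            pytest.approx(0.1)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            count_events([], "T1", 0, 1.0)


class TestDisplacementProfiles:
    def _traj(self, states):
        class T:
            pass

        t = T()
        t.snapshots = [(k, s) for k, s in enumerate(states)]
        return t

    def test_static_tissue_zero(self, regioned_state):
        traj = self._traj([regioned_state, regioned_state.copy()])
        df = displacement_profiles(traj)
        assert np.allclose(df[["mean_dx", "mean_dy"]].to_numpy(), 0.0)

    def test_rigid_drift_removed_by_pillar_frame(self, regioned_state):
        shifted = regioned_state.copy()
        for v in shifted.vertices:
            shifted.vertices[v] = shifted.domain.wrap(
                shifted.vertices[v] + np.array([0.8, 0.3]))
        df = displacement_profiles(self._traj([regioned_state, shifted]))
        last = df[df.step == 1]
        assert np.allclose(last[["mean_dx", "mean_dy"]].to_numpy(), 0.0,
                           atol=1e-9)
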