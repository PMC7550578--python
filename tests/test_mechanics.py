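"""Energy terms, analytic gradient, external and noise forces."""

import math

import numpy as np
import pytest

from corti_vertex.mechanics import (
    MeshArrays,
    SingularityError,
    energy_gradient,
    external_force,
    noise_force,
    repulsion_energy,
    total_energy,
)
from corti_vertex.mesh import Cell, Domain, TissueState
from corti_vertex.params import HEX_AREA, ModelParams

from conftest import single_cell_state, strip_state


def zeroed(params: ModelParams) -> ModelParams:
    """All mechanical couplings off: E must vanish identically."""
    p = params.model_copy(deep=True)
    for cp in p.cells.values():
        cp.alpha = 0.0
        cp.Gamma = 0.0
    p.tensions = {"default": 0.0}
    p.repulsion.sigma = 0.0
    p.shear.eta = p.shear.zeta = 0.0
    p.noise.amplitude = 0.0
    return p


def dict_energy_oracle(state: TissueState, params: ModelParams) -> float:
    """Independent per-cell evaluation of every energy term (no arrays)."""
    e = 0.0
    juncs = state.junctions()
    for cid, cell in state.alive_cells().items():
        cp = params.cell_params(cell.cls)
        A = state.cell_area(cid)
        A0 = state.a0_overrides.get(cid, cp.A0)
        L = state.cell_perimeter(cid)
        Gamma = state.contractility_overrides.get(cid, cp.Gamma)
        e += 0.5 * cp.alpha * (A - A0) ** 2 + 0.5 * Gamma * L ** 2
        vs = cell.vertices
        for a, b in zip(vs, vs[1:] + vs[:1]):
            key = (min(a, b), max(a, b))
            if key in state.gamma_overrides:
                g = state.gamma_overrides[key]
            else:
                owners = juncs[key]
                other = owners[0] if owners[1] == cid else owners[1]
                g = params.gamma_for(cell.cls, state.cells[other].cls)
            e += g * state.junction_length(key)
    hcs = [c for c, cd in state.alive_cells().items() if cd.cls == "HC"]
    rp = params.repulsion
    for n in hcs:
        for m in hcs:
            if n == m:
                continue
            d = state.domain.min_image(
                state.cell_centroid(n) - state.cell_centroid(m))
            e += rp.sigma * (rp.D / float(np.hypot(*d))) ** rp.kappa
    return e


class TestTotalEnergy:
    def test_zero_couplings_vanish(self, params):
        st = single_cell_state([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert total_energy(st, zeroed(params)) == 0.0

    def test_area_term_closed_form(self, params):
        # square of side 2: A=4, A0=1, alpha=2 -> E = 0.5*2*3^2 = 9
        st = single_cell_state([(0, 0), (2, 0), (2, 2), (0, 2)])
        p = zeroed(params)
        p.cells["SC"].alpha = 2.0
        p.cells["SC"].A0 = 1.0
        assert total_energy(st, p) == pytest.approx(9.0)

    def test_mixed_lattice_matches_term_by_term_oracle(self, disordered_state, params):
        st = disordered_state
        for cid, cell in list(st.alive_cells().items()):
            if cell.region == "OHC" and cid % 3 == 0:
                cell.cls = "HC"
        assert total_energy(st, params) == pytest.approx(
            dict_energy_oracle(st, params), rel=1e-10)

    def test_junction_term_counts_each_junction_twice(self, params):
        # abutting cells on a torus: shared junctions appear once per owner
        st = strip_state([1.0, 1.0, 1.0], ["SC", "SC", "SC"])
        p = zeroed(params)
        p.tensions = {"default": 0.25}
        total_len = sum(st.junction_length(k) for k in st.junctions())
        assert total_energy(st, p) == pytest.approx(2 * 0.25 * total_len)


class TestRepulsion:
    def test_single_hc_no_pair(self, regioned_state, params):
        cells = [c for c, cd in regioned_state.alive_cells().items()
                 if cd.region == "OHC"]
        regioned_state.cells[cells[0]].cls = "HC"
        assert repulsion_energy(regioned_state, params) == 0.0

    def test_two_hcs_at_contact_distance(self, params):
        # centroids 0.5 and 7.5 in a box of 8: minimum-image distance 1
        sq = lambda x: [(x, 0), (x + 1, 0), (x + 1, 1), (x, 1)]
        pts = sq(0.0) + sq(7.0)
        st = TissueState(
            vertices={i: np.asarray(q, float) for i, q in enumerate(pts)},
            cells={0: Cell(vertices=[0, 1, 2, 3], cls="HC"),
                   1: Cell(vertices=[4, 5, 6, 7], cls="HC")},
            domain=Domain(8.0, 8.0))
        p = params.model_copy(deep=True)
        p.repulsion.sigma = 0.7
        p.repulsion.D = 1.0  # exactly the ordered-pair separation
        assert repulsion_energy(st, p) == pytest.approx(2 * 0.7)

    def test_three_hcs_match_brute_force(self, disordered_state, params):
        st = disordered_state
        hcs = [c for c, cd in st.alive_cells().items()
               if cd.region == "OHC"][:3]
        for c in hcs:
            st.cells[c].cls = "HC"
        rp = params.repulsion
        brute = 0.0
        for n in hcs:
            for m in hcs:
                if n == m:
                    continue
                d = st.domain.min_image(st.cell_centroid(n) - st.cell_centroid(m))
                brute += rp.sigma * (rp.D / float(np.hypot(*d))) ** rp.kappa
        assert repulsion_energy(st, params) == pytest.approx(brute, rel=1e-12)

    def test_coincident_centroids_raise(self, params):
        st = single_cell_state([(0, 0), (1, 0), (1, 1), (0, 1)], cls="HC")
        st.cells[1] = Cell(vertices=[0, 1, 2, 3], cls="HC")
        with pytest.raises(SingularityError):
            repulsion_energy(st, params)

    def test_locality_power_law_decay(self, params):
        """Doubling a far pair's separation shrinks its term by 2^-kappa."""
        p = params.model_copy(deep=True)
        p.repulsion.minimum_image = False
        box = 1000.0
        sq = lambda x: [(x, 0), (x + 1, 0), (x + 1, 1), (x, 1)]
        for x2 in (10.0, 20.0):
            st = TissueState(
                vertices={}, cells={}, domain=Domain(box, box))
            pts = sq(0.0) + sq(x2)
            st.vertices = {i: np.asarray(q, float) for i, q in enumerate(pts)}
            st.cells = {0: Cell(vertices=[0, 1, 2, 3], cls="HC"),
                        1: Cell(vertices=[4, 5, 6, 7], cls="HC")}
            if x2 == 10.0:
                e_near = repulsion_energy(st, p)
            else:
                e_far = repulsion_energy(st, p)
        assert e_far == pytest.approx(e_near * 0.5 ** p.repulsion.kappa, rel=1e-9)


class TestExternalForce:
    def test_zero_at_pillar_line(self, params):
        st = single_cell_state([(0, 0), (1, 0), (1, 1), (0, 1)], cls="HC")
        st.pillar_y = 0.5  # centroid sits exactly on the origin line
        F = external_force(st, params)
        assert np.allclose(F.F, 0.0)

    def test_sc_only_tissue_zero_everywhere(self, hex_state, params):
        F = external_force(hex_state, params)
        assert np.allclose(F.F, 0.0)

    def test_single_hc_square_hand_value(self, params):
        # unit square HC with centroid at y_cm = 2 above the pillar line
        st = single_cell_state([(0, 1.5), (1, 1.5), (1, 2.5), (0, 2.5)], cls="HC")
        st.pillar_y = 0.0
        p = params.model_copy(deep=True)
        p.shear.eta, p.shear.zeta = 0.1, -0.05
        F = external_force(st, p)
        # per vertex: (eta*y_cm, zeta*y_cm*1/4)
        assert np.allclose(F.F, [[0.2, -0.025]] * 4)


class TestGradient:
    def test_zero_at_exact_minimum(self, hex_state, params):
        p = zeroed(params)
        for cp in p.cells.values():
            cp.alpha = 1.0
            cp.A0 = HEX_AREA
        g = energy_gradient(hex_state, p)
        assert np.abs(g.F).max() < 1e-8

    def test_matches_finite_differences(self, disordered_state, params):
        st = disordered_state
        for cid, cell in list(st.alive_cells().items()):
            if cell.region == "OHC" and cid % 3 == 0:
                cell.cls = "HC"
        m = MeshArrays(st, params)
        g = m.gradient()
        rng = np.random.default_rng(3)
        h = 1e-6
        for i in rng.integers(0, len(m.pos), 8):
            for k in (0, 1):
                pp, pm = m.pos.copy(), m.pos.copy()
                pp[i, k] += h
                pm[i, k] -= h
                fd = (m.energy(pp) - m.energy(pm)) / (2 * h)
                assert g[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_area_term_shoelace_derivative(self, params):
        pts = np.array([(0.0, 0.0), (2.0, 0.0), (2.5, 1.5), (0.5, 2.0)]) + 5
        st = single_cell_state(pts)
        p = zeroed(params)
        p.cells["SC"].alpha = 1.3
        p.cells["SC"].A0 = 1.0
        m = MeshArrays(st, p)
        g = m.gradient()
        A = st.cell_area(0)
        n = len(pts)
        for i in range(n):
            prv, nxt = pts[(i - 1) % n], pts[(i + 1) % n]
            dA = 0.5 * np.array([nxt[1] - prv[1], prv[0] - nxt[0]])
            assert np.allclose(g[i], 1.3 * (A - 1.0) * dA, atol=1e-12)

    def test_translation_invariance(self, disordered_state, params):
        e0 = total_energy(disordered_state, params)
        shift = np.array([1.3, -2.7])
        st = disordered_state.copy()
        for v in st.vertices:
            st.vertices[v] = st.domain.wrap(st.vertices[v] + shift)
        assert total_energy(st, params) == pytest.approx(e0, abs=1e-10)


class TestNoise:
    def test_zero_amplitude(self, hex_state, params):
        p = params.model_copy(deep=True)
        p.noise.amplitude = 0.0
        F = noise_force(np.random.default_rng(0), hex_state, p)
        assert np.all(F.F == 0.0)

    def test_deterministic_replay(self, hex_state, params):
        a = noise_force(np.random.default_rng(11), hex_state, params)
        b = noise_force(np.random.default_rng(11), hex_state, params)
        assert np.array_equal(a.F, b.F)

    def test_mean_near_zero(self, hex_state, params):
        draws = noise_force(np.random.default_rng(5), hex_state, params)
        a = params.noise.amplitude
        n = draws.F.size
        se = a / math.sqrt(3 * n)  # uniform variance a^2/3
        assert abs(draws.F.mean()) < 3 * se + 1e-12

    def test_field_cardinality(self, disordered_state, params):
        F = noise_force(np.random.default_rng(0), disordered_state, params)
        assert len(F.ids) == len(disordered_state.vertices)
        assert np.all(np.isfinite(F.F))
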