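import numpy as np
import pytest

from corti_vertex.initial import assign_regions, disorder_lattice, hexagonal_lattice
from corti_vertex.mesh import Cell, Domain, TissueState
from corti_vertex.params import ModelParams, ProtocolConfig, RegionSpec


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def small_spec() -> RegionSpec:
    return RegionSpec(rows=8, cols=6, outside_bottom=1, ihc_rows=1,
                      pillar_rows=1, ohc_rows=3)


@pytest.fixture
def hex_state(small_spec) -> TissueState:
    return hexagonal_lattice(small_spec)


@pytest.fixture
def regioned_state(small_spec):
    state = hexagonal_lattice(small_spec)
    return assign_regions(state, small_spec)


@pytest.fixture
def disordered_state(small_spec, params):
    """A small melted lattice with heterogeneous polygon classes."""
    state = hexagonal_lattice(small_spec)
    assign_regions(state, small_spec)
    rng = np.random.default_rng(7)
    disorder_lattice(state, params, rng, n_cycles=8, redraw_every=60,
                     gamma_range=(0.1, 3.0), a0_range=(0.3, 1.7))
    return state


def single_cell_state(points, cls="SC", box=100.0) -> TissueState:
    """One free polygon in a huge box (toy state; no periodic closure)."""
    vertices = {i: np.asarray(p, dtype=float) for i, p in enumerate(points)}
    return TissueState(
        vertices=vertices,
        cells={0: Cell(vertices=list(range(len(points))), cls=cls)},
        domain=Domain(box, box))


def strip_state(widths, classes, height=1.0, rows=3) -> TissueState:
    """Vertical strips on a torus, duplicated over ``rows`` rows.

    Cell (r, k) spans widths[k] in x and ``height`` in y; at least three
    rows and three columns keep every junction's vertex pair distinct.
    """
    xs = np.concatenate([[0.0], np.cumsum(widths)])
    Lx, Ly = float(xs[-1]), height * rows
    ncol = len(widths)
    vid = {}
    vertices = {}

    def v(i, r):
        key = (i % ncol, r % rows)
        if key not in vid:
            vid[key] = len(vid)
            vertices[vid[key]] = np.array([xs[key[0]], height * key[1]])
        return vid[key]

    cells = {}
    for r in range(rows):
        for k in range(ncol):
            cyc = [v(k, r), v(k + 1, r), v(k + 1, r + 1), v(k, r + 1)]
            cells[r * ncol + k] = Cell(vertices=cyc, cls=classes[k])
    state = TissueState(vertices=vertices, cells=cells, domain=Domain(Lx, Ly))
    state.audit()
    return state
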