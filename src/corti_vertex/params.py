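"""Model, region and protocol parameter sets.

All quantities are dimensionless; lengths are measured in units of the
initial hexagon side, so the undeformed cell area is 3*sqrt(3)/2.

Parameter names map onto the vertex-model energy

    E = sum_n [ alpha_n/2 (A_n - A0_n)^2  +  sum_ij gamma_n^ij l_n^ij
                + Gamma_n/2 L_n^2  +  sum_m sigma_nm (D_nm / R_nm)^kappa ]

plus external shear/compression forces on hair cells,

    F_i = eta * y_cm * x_hat + zeta * y_cm * grad_i(y_cm),

with y_cm the distance of the HC centroid from the pillar-cell row.  The
junction-tension sum runs per cell, so each physical junction is counted
once for each of its two owners; the default gammas are chosen with that
factor of two folded in.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, Field, model_validator

HEX_AREA = 3.0 * math.sqrt(3.0) / 2.0  # area of a unit-side regular hexagon


class _Strict(BaseModel):
    model_config = {"extra": "forbid"}


class CellClassParams(_Strict):
    alpha: float = Field(ge=0.0, description="area stiffness")
    A0: float = Field(gt=0.0, description="preferred area")
    Gamma: float = Field(ge=0.0, description="perimeter contractility")


class RepulsionParams(_Strict):
    sigma: float = Field(default=1.5, ge=0.0)
    D: float = Field(default=2.2, ge=0.0)
    kappa: float = Field(default=8.0, ge=2.0)
    minimum_image: bool = True  # use periodic minimum-image distances


class ShearParams(_Strict):
    eta: float = 0.15    # horizontal shear per unit distance from pillar row
    zeta: float = -0.33  # signed; negative compresses toward the pillar row


class NoiseParams(_Strict):
    amplitude: float = Field(default=0.08, ge=0.0)
    refresh_every: int = Field(default=10, ge=1)


class ThresholdParams(_Strict):
    l_min: float = Field(default=0.32, ge=0.0, description="T1 junction length")
    A_min: float = Field(default=0.45, ge=0.0, description="T2 cell area")
    t1_lockout: int = Field(default=50, ge=0, description="steps a junction is T1-immune")
    l_new_factor: float = Field(default=1.5, gt=1.0, description="post-T1 length / l_min")
    hc_t2_allowed: bool = False


def _default_cells() -> dict[str, CellClassParams]:
    # HCs are less compressible (higher alpha) and more contractile (higher
    # Gamma) than SCs, and grow a larger apex; SCs tolerate compression to
    # a small preferred area.  Pillar cells are stiff to hold the boundary.
    return {
        "HC": CellClassParams(alpha=4.0, A0=3.4, Gamma=0.20),
        "SC": CellClassParams(alpha=1.0, A0=1.6, Gamma=0.04),
        "IHC": CellClassParams(alpha=3.0, A0=HEX_AREA, Gamma=0.15),
        "pillar": CellClassParams(alpha=5.0, A0=HEX_AREA, Gamma=0.10),
        "top_boundary": CellClassParams(alpha=1.0, A0=HEX_AREA, Gamma=0.08),
        "outside": CellClassParams(alpha=1.0, A0=HEX_AREA, Gamma=0.08),
    }


def _default_tensions() -> dict[str, float]:
    # per-cell sums count each junction twice; values include that factor.
    # A moderate interfacial tension on junctions facing the outside
    # region keeps the sensory band cohesive during compaction.
    return {
        "default": 0.12,
        "pillar_boundary": 1.2,
        "HC:outside": 0.2,
        "SC:outside": 0.2,
        "HC:top_boundary": 0.2,
        "SC:top_boundary": 0.2,
    }


class ModelParams(_Strict):
    """Every mechanical parameter, keyed by cell/junction class."""

    cells: dict[str, CellClassParams] = Field(default_factory=_default_cells)
    tensions: dict[str, float] = Field(default_factory=_default_tensions)
    repulsion: RepulsionParams = Field(default_factory=RepulsionParams)
    shear: ShearParams = Field(default_factory=ShearParams)
    noise: NoiseParams = Field(default_factory=NoiseParams)
    thresholds: ThresholdParams = Field(default_factory=ThresholdParams)
    epsilon: float = Field(default=0.02, ge=0.0, description="gradient-descent step")

    @model_validator(mode="after")
    def _check_tensions(self):
        if "default" not in self.tensions:
            raise ValueError("tensions must define a 'default' entry")
        return self

    # ------------------------------------------------------------------
    def cell_params(self, cls: str) -> CellClassParams:
        try:
            return self.cells[cls]
        except KeyError:
            raise KeyError(f"no mechanical parameters for cell class {cls!r}") from None

    def gamma_for(self, cls_a: str, cls_b: str) -> float:
        """Line tension for a junction between cells of the given classes."""
        t = self.tensions
        pair = {cls_a, cls_b}
        if ("pillar" in pair) and (cls_a != cls_b):
            if "pillar_boundary" in t:
                return t["pillar_boundary"]
        if ("top_boundary" in pair) and (pair & {"HC", "SC"}):
            # stage-2 constriction applies to OHC-facing border junctions only
            if "top_boundary" in t:
                return t["top_boundary"]
        key = ":".join(sorted(pair)) if len(pair) == 2 else f"{cls_a}:{cls_a}"
        if key in t:
            return t[key]
        return t["default"]

    def with_tensions(self, **updates: float) -> "ModelParams":
        new = self.model_copy(deep=True)
        new.tensions.update(updates)
        return new


class RegionSpec(_Strict):
    """Stripe layout of the initial lattice along y (in cell rows).

    Stripes stack bottom-to-top: outside_bottom | IHC | pillar | OHC zone |
    outside_top; they must tile the full lattice height.  The pillar stripe
    is a single row.
    """

    rows: int = Field(default=12, ge=4)
    cols: int = Field(default=12, ge=4)
    side: float = Field(default=1.0, gt=0.0)
    outside_bottom: int = Field(default=2, ge=1)
    ihc_rows: int = Field(default=1, ge=1)
    pillar_rows: int = Field(default=1, ge=1)
    ohc_rows: int = Field(default=5, ge=2)
    hc_cap_override: int | None = Field(
        default=None, description="override the three-row HC budget")

    @model_validator(mode="after")
    def _check(self):
        if self.pillar_rows != 1:
            raise ValueError("the pillar stripe must be exactly one cell row")
        if self.outside_top < 1:
            raise ValueError("stripes exceed the lattice height")
        if self.rows % 2 != 0:
            raise ValueError("rows must be even for periodic hexagonal tiling")
        return self

    @property
    def outside_top(self) -> int:
        return self.rows - (self.outside_bottom + self.ihc_rows
                            + self.pillar_rows + self.ohc_rows)

    @property
    def row_height(self) -> float:
        return 1.5 * self.side

    def stripe_bounds(self) -> dict[str, tuple[float, float]]:
        """y-interval of each stripe; cell row r is centred at 1.5*side*r."""
        h = self.row_height
        edges = [-0.5 * h]
        counts = [self.outside_bottom, self.ihc_rows, self.pillar_rows,
                  self.ohc_rows, self.outside_top]
        for n in counts:
            edges.append(edges[-1] + n * h)
        names = ["outside_bottom", "IHC", "pillar", "OHC", "outside_top"]
        return {name: (edges[i], edges[i + 1]) for i, name in enumerate(names)}

    @property
    def pillar_interface_y(self) -> float:
        """The pillar-row/OHC-zone interface: y-origin of the shear force."""
        return self.stripe_bounds()["pillar"][1]

    @property
    def hc_cap(self) -> int:
        """HCs that fit exactly three checkerboard rows on the periodic
        strip: no two HCs may share a junction, so at most every other
        cell of a row carries HC fate."""
        if self.hc_cap_override is not None:
            return self.hc_cap_override
        return 3 * math.ceil(self.cols / 2)


class DisorderSpec(_Strict):
    """Randomised-relaxation schedule that melts the regular lattice."""

    cycles: int = Field(default=15, ge=0)
    redraw_every: int = Field(default=80, ge=1)
    gamma_range: tuple[float, float] = (0.1, 3.0)
    a0_range: tuple[float, float] = (0.3, 1.7)


class StageOverrides(_Strict):
    tensions: dict[str, float] = Field(default_factory=dict)
    eta: float | None = None
    zeta: float | None = None
    sigma: float | None = None
    equalize_tensions: bool = False            # collapse all gammas to default
    gamma_factor: float | None = None          # scales every tension entry
    contractility_factor: float | None = None  # scales every Gamma
    equalize_cells: bool = False               # alpha/Gamma of HC := SC values
    noise_amplitude: float | None = None


class ProtocolConfig(_Strict):
    """Schedules and per-stage overrides for the staged experiments."""

    steps_stage1: int = Field(default=8000, ge=0)
    steps_stage2: int = Field(default=8000, ge=0)
    steps_blebbistatin: int = Field(default=1500, ge=0)
    steps_ablation: int = Field(default=1500, ge=0)
    ablation_measure_step: int = Field(default=400, ge=1)
    ablation_gamma_factor: float = Field(default=100.0, gt=1.0)
    blebbistatin: StageOverrides = Field(default_factory=lambda: StageOverrides(
        equalize_tensions=True, gamma_factor=0.5, contractility_factor=0.5,
        eta=0.0, zeta=0.0))
    stage2_tensions: dict[str, float] = Field(
        default_factory=lambda: {"SC:SC": 1.6, "top_boundary": 0.8})
    stage2_overrides: StageOverrides = Field(default_factory=StageOverrides)
    snapshot_every: int = Field(default=200, ge=1)
    differentiate_every: int = Field(default=5, ge=1)
    relax_steps: int = Field(default=300, ge=0)
    disorder: DisorderSpec = Field(default_factory=DisorderSpec)


def default_params() -> ModelParams:
    return ModelParams()
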