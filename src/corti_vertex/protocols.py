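"""Staged simulation experiments.

Stage 1 (compaction): shear and compression on HCs plus HC-HC repulsion
drive the disordered mosaic toward compact, ordered HC rows; lateral
inhibition keeps differentiating SCs that lose HC contact.  Stage 2
(refinement): SC:SC junction tension rises above HC:SC tension and the
top border constricts, producing the confined checkerboard and the
increase of the HC/SC area ratio.  Perturbation protocols start from a
stage-2 endpoint: the myosin-inhibition (blebbistatin) override reduces
and equates all junction tensions, reduces contractility and suppresses
shear; ablation spikes one cell's contractility so it shrinks through
forced T1s and delaminates.  The alternative, adhesion-only model runs
with differential tension but no shear/compression and no HC/SC
stiffness difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import state_metrics
from .dynamics import Simulation
from .initial import init_tissue, label_top_boundary
from .mesh import TissueState
from .params import ModelParams, ProtocolConfig, RegionSpec, StageOverrides
from .topology import TopologyEvent


@dataclass
class Trajectory:
    """Snapshots, event log and metric series of one protocol run."""

    snapshots: list[tuple[int, TissueState]] = field(default_factory=list)
    events: list[TopologyEvent] = field(default_factory=list)
    metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    params_log: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def final_state(self) -> TissueState:
        return self.snapshots[-1][1]

    @property
    def start_step(self) -> int:
        return self.snapshots[0][0]

    @property
    def end_step(self) -> int:
        return self.snapshots[-1][0]


def apply_overrides(params: ModelParams, ov: StageOverrides) -> ModelParams:
    """Derive a stage parameter set from ``params`` (pure)."""
    p = params.model_copy(deep=True)
    if ov.equalize_tensions:
        p.tensions = {"default": p.tensions["default"]}
    if ov.gamma_factor is not None:
        p.tensions = {k: v * ov.gamma_factor for k, v in p.tensions.items()}
    p.tensions.update(ov.tensions)
    if ov.eta is not None:
        p.shear.eta = ov.eta
    if ov.zeta is not None:
        p.shear.zeta = ov.zeta
    if ov.sigma is not None:
        p.repulsion.sigma = ov.sigma
    if ov.contractility_factor is not None:
        for cp in p.cells.values():
            cp.Gamma *= ov.contractility_factor
    if ov.equalize_cells:
        sc = p.cells["SC"]
        hc = p.cells["HC"]
        hc.alpha, hc.Gamma = sc.alpha, sc.Gamma
    if ov.noise_amplitude is not None:
        p.noise.amplitude = ov.noise_amplitude
    return p


def _record_run(sim: Simulation, n_steps: int, every: int,
                traj: Trajectory, metrics: bool = True) -> None:
    seen = set()

    def cb(s: Simulation) -> None:
        if s.step_index in seen:
            return
        seen.add(s.step_index)
        traj.snapshots.append((s.step_index, s.state.copy()))
        if metrics:
            row = state_metrics(s.state)
            row["step"] = s.step_index
            traj.metrics = pd.concat(
                [traj.metrics, pd.DataFrame([row])], ignore_index=True)

    sim.run(n_steps, callback=cb, callback_every=every)


# ----------------------------------------------------------------------
# the two main stages
# ----------------------------------------------------------------------
def run_stage1(spec: RegionSpec, params: ModelParams, cfg: ProtocolConfig,
               rng: np.random.Generator,
               state: TissueState | None = None) -> Trajectory:
    """Compaction stage from a fresh (or supplied) initial tissue.

    Shear/compression and repulsion are active; T1/T2 and the ongoing
    differentiation rule run every step.  The top border is labelled at
    completion, before any statistics are taken from the endpoint.
    """
    r_init, r_run = rng.spawn(2)
    if state is None:
        state = init_tissue(spec, params, cfg, r_init)
    traj = Trajectory(params_log=[{"stage": "stage1",
                                   "params": params.model_dump()}])
    sim = Simulation(state, params, r_run, differentiation=True,
                     hc_cap=spec.hc_cap,
                     differentiate_every=cfg.differentiate_every,
                     events=traj.events)
    _record_run(sim, cfg.steps_stage1, cfg.snapshot_every, traj)
    label_top_boundary(state)
    traj.snapshots[-1] = (sim.step_index, state.copy())
    return traj


def run_stage2(state: TissueState, params: ModelParams, cfg: ProtocolConfig,
               rng: np.random.Generator, start_step: int = 0,
               hc_cap: int | None = None) -> Trajectory:
    """Refinement stage: elevated SC:SC and top-border tension."""
    p2 = apply_overrides(params, cfg.stage2_overrides)
    p2 = p2.with_tensions(**cfg.stage2_tensions)
    traj = Trajectory(params_log=[{"stage": "stage2",
                                   "params": p2.model_dump()}])
    sim = Simulation(state, p2, rng, differentiation=True,
                     hc_cap=hc_cap,
                     differentiate_every=cfg.differentiate_every,
                     start_step=start_step, events=traj.events)
    _record_run(sim, cfg.steps_stage2, cfg.snapshot_every, traj)
    return traj


def run_full(spec: RegionSpec, params: ModelParams, cfg: ProtocolConfig,
             seed: int) -> tuple[Trajectory, Trajectory]:
    """Initialise and run both stages; returns (stage1, stage2)."""
    rng = np.random.default_rng(seed)
    r1, r2 = rng.spawn(2)
    t1 = run_stage1(spec, params, cfg, r1)
    t2 = run_stage2(t1.final_state.copy(), params, cfg, r2,
                    start_step=t1.end_step, hc_cap=spec.hc_cap)
    return t1, t2


# ----------------------------------------------------------------------
# perturbations from a stage-2 endpoint
# ----------------------------------------------------------------------
def run_blebbistatin(state: TissueState, params: ModelParams,
                     cfg: ProtocolConfig, rng: np.random.Generator,
                     control: bool = False) -> Trajectory:
    """Myosin-inhibition protocol: reduce and equate all junction
    tensions, reduce contractility, suppress shear/compression.

    With ``control=True`` the run continues with unmodified stage-2
    parameters (the no-drug control arm)."""
    p2 = apply_overrides(params, cfg.stage2_overrides)
    p2 = p2.with_tensions(**cfg.stage2_tensions)
    pb = p2 if control else apply_overrides(p2, cfg.blebbistatin)
    traj = Trajectory(params_log=[{
        "stage": "blebbistatin" if not control else "blebbistatin_control",
        "params": pb.model_dump()}])
    sim = Simulation(state, pb, rng, events=traj.events)
    _record_run(sim, cfg.steps_blebbistatin, cfg.snapshot_every, traj)
    return traj


def run_ablation(state: TissueState, target: int, params: ModelParams,
                 cfg: ProtocolConfig, rng: np.random.Generator) -> Trajectory:
    """Single-cell ablation: spike the target's contractility so it
    shrinks through forced T1s and delaminates (T2).

    The first-ring neighbour identities are frozen at ablation time;
    their relative area changes at the fixed measurement step are stored
    in ``extras['neighbor_response']``."""
    cd = state.cells[target]
    if not cd.alive:
        raise ValueError(f"ablation target {target} is not alive")
    p2 = apply_overrides(params, cfg.stage2_overrides)
    p2 = p2.with_tensions(**cfg.stage2_tensions)
    if cd.cls == "HC":
        p2.thresholds.hc_t2_allowed = True
    base_gamma = state.contractility_overrides.get(
        target, p2.cell_params(cd.cls).Gamma)
    state.contractility_overrides[target] = base_gamma * cfg.ablation_gamma_factor

    ring = sorted(state.neighbors(target))
    ring_cls = {c: state.cells[c].cls for c in ring}
    area0 = {c: state.cell_area(c) for c in ring}

    traj = Trajectory(params_log=[{"stage": "ablation",
                                   "params": p2.model_dump(),
                                   "target": target}])
    sim = Simulation(state, p2, rng, events=traj.events)
    measured = None
    steps = max(cfg.steps_ablation, cfg.ablation_measure_step)
    for _ in range(steps):
        sim.step_once()
        if sim.step_index == cfg.ablation_measure_step:
            sim.sync()
            measured = {
                c: (state.cell_area(c) - area0[c]) / area0[c]
                for c in ring if state.cells[c].alive}
    sim.sync()
    traj.snapshots.append((sim.step_index, state.copy()))
    traj.extras["neighbor_response"] = pd.DataFrame(
        [{"cell": c, "class": ring_cls[c], "rel_area_change": v}
         for c, v in (measured or {}).items()])
    traj.extras["target_removed"] = any(
        ev.kind == "T2" and ev.cell == target for ev in traj.events)
    return traj


def run_alternative(spec: RegionSpec, params: ModelParams,
                    cfg: ProtocolConfig, rng: np.random.Generator,
                    state: TissueState | None = None) -> Trajectory:
    """Adhesion-only alternative model: differential junction tension from
    the start; no shear/compression, no HC/SC stiffness difference, and
    no nuclear repulsion — the ordering, if any, must come from the
    tensile differences alone."""
    r_init, r_run = rng.spawn(2)
    if state is None:
        state = init_tissue(spec, params, cfg, r_init)
    pa = apply_overrides(params, StageOverrides(
        eta=0.0, zeta=0.0, sigma=0.0, equalize_cells=True,
        tensions=dict(cfg.stage2_tensions)))
    traj = Trajectory(params_log=[{"stage": "alternative",
                                   "params": pa.model_dump()}])
    sim = Simulation(state, pa, r_run, differentiation=True,
                     hc_cap=spec.hc_cap,
                     differentiate_every=cfg.differentiate_every,
                     events=traj.events)
    _record_run(sim, cfg.steps_stage1 + cfg.steps_stage2,
                cfg.snapshot_every, traj)
    label_top_boundary(state)
    traj.snapshots[-1] = (sim.step_index, state.copy())
    return traj


# ----------------------------------------------------------------------
# robustness sweep
# ----------------------------------------------------------------------
SWEEP_PARAMETERS = (
    "repulsion.sigma", "repulsion.D", "shear.eta", "shear.zeta",
    "tensions.default", "cells.HC.alpha", "cells.HC.Gamma", "cells.SC.alpha",
)


def _scale_param(params: ModelParams, name: str, factor: float) -> ModelParams:
    p = params.model_copy(deep=True)
    obj: object = p
    parts = name.split(".")
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = obj[last] * factor
    else:
        setattr(obj, last, getattr(obj, last) * factor)
    return p


def parameter_sweep(spec: RegionSpec, params: ModelParams, cfg: ProtocolConfig,
                    seed: int,
                    parameters: tuple[str, ...] = SWEEP_PARAMETERS,
                    factors: tuple[float, ...] = (0.5, 1.0, 1.5)) -> pd.DataFrame:
    """Re-run both stages with each parameter scaled by each factor.

    Returns one row per (parameter, factor) with the end-state order
    parameters; the factor-1.0 rows all reproduce the default run."""
    rows = []
    default_row = None
    for pname in parameters:
        for f in factors:
            if f == 1.0 and default_row is not None:
                row = dict(default_row)
                row.update(parameter=pname, factor=f)
                rows.append(row)
                continue
            ps = _scale_param(params, pname, f)
            _, t2 = run_full(spec, ps, cfg, seed)
            row = dict(t2.metrics.iloc[-1])
            row.update(parameter=pname, factor=f)
            rows.append(row)
            if f == 1.0 and default_row is None:
                default_row = dict(t2.metrics.iloc[-1])
    return pd.DataFrame(rows)
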