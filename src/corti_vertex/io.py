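"""Configuration, snapshot and log serialization.

YAML config with three optional sections (``model``, ``regions``,
``protocol``); unknown keys anywhere are rejected with the offending key
path.  Tissue snapshots are JSON (floats round-trip exactly through
Python's shortest-repr encoding); event logs and metric series are TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from pydantic import ValidationError

from .mesh import TissueState
from .params import ModelParams, ProtocolConfig, RegionSpec
from .topology import TopologyEvent


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


_SECTIONS = {"model": ModelParams, "regions": RegionSpec,
             "protocol": ProtocolConfig}


def _format_validation_error(section: str, e: ValidationError) -> str:
    lines = []
    for err in e.errors():
        path = ".".join(str(p) for p in (section, *err["loc"]))
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def parse_config(raw: dict) -> tuple[ModelParams, RegionSpec, ProtocolConfig]:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        try:
            out[name] = cls.model_validate(raw.get(name, {}))
        except ValidationError as e:
            raise ConfigError(_format_validation_error(name, e)) from e
    return out["model"], out["regions"], out["protocol"]


def load_config(path: str | Path) -> tuple[ModelParams, RegionSpec, ProtocolConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def dump_config(params: ModelParams, spec: RegionSpec, cfg: ProtocolConfig,
                path: str | Path | None = None) -> str:
    doc = {"model": params.model_dump(), "regions": spec.model_dump(),
           "protocol": cfg.model_dump()}
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(params: ModelParams, spec: RegionSpec,
                cfg: ProtocolConfig) -> str:
    return hashlib.sha256(dump_config(params, spec, cfg).encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# snapshots
# ----------------------------------------------------------------------
def save_snapshot(state: TissueState, path: str | Path) -> None:
    Path(path).write_text(json.dumps(state.to_dict(), indent=1))


def load_snapshot(path: str | Path) -> TissueState:
    state = TissueState.from_dict(json.loads(Path(path).read_text()))
    state.audit()
    return state


def cell_table(state: TissueState) -> pd.DataFrame:
    """Flat per-cell export: id, class, centroid, area, perimeter, degree."""
    adj = state.adjacency()
    rows = []
    for cid in sorted(state.alive_cells()):
        c = state.cell_centroid(cid)
        rows.append({
            "id": cid, "class": state.cells[cid].cls,
            "region": state.cells[cid].region,
            "x": float(c[0]), "y": float(c[1]),
            "area": state.cell_area(cid),
            "perimeter": state.cell_perimeter(cid),
            "n_neighbors": len(adj[cid]),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# event and metric logs
# ----------------------------------------------------------------------
def save_events_tsv(events: list[TopologyEvent], path: str | Path) -> None:
    rows = [{"step": ev.step, "kind": ev.kind,
             "cells": ",".join(map(str, ev.cells)),
             "junction": "" if ev.junction is None
             else f"{ev.junction[0]}-{ev.junction[1]}",
             "cell": "" if ev.cell is None else ev.cell,
             "x": ev.location[0], "y": ev.location[1]}
            for ev in events]
    pd.DataFrame(rows, columns=["step", "kind", "cells", "junction",
                                "cell", "x", "y"]).to_csv(
        path, sep="\t", index=False)


def load_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_metrics_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class RunManifest:
    """Everything needed to replay a run bit-for-bit."""

    config_hash: str
    seed: int
    version: str
    protocol: str
    stages: list[dict]
    outputs: dict[str, str]
    steps: int

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))
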