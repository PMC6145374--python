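"""Serialization of targets, parameter sets and ensembles, plus the run
configuration schema consumed by the command-line interface.

Formats are deliberately plain: YAML for configuration and target bands,
JSON for parameter sets and reports, JSON-lines for ensembles, CSV for
tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import ParameterSet
from .observables import FeedSpec, ObservationBands, ObservationSet
from .search import AdmissibleMember, AdmissibilityVerdict
from .steady_state import CompartmentStates
from .topology import Topology, build_brachypodium_topology

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_observations",
    "load_observations",
    "save_bands",
    "load_bands",
    "parameter_set_to_dict",
    "parameter_set_from_dict",
    "save_parameter_set",
    "load_parameter_set",
    "save_ensemble",
    "load_ensemble",
]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    include_c3h: bool = True
    r: float = 0.9
    seed: int = 0
    lignin_tol: float = 0.25
    wall_tol: float = 0.50
    n_static: int = 20
    static_attempts: int = 40000
    budget: int = 2000
    epsilon: float = 0.2
    stall_restart: int = 500
    validation_n: int = 20000
    influx_bounds: tuple[float, float] = (0.5, 1.0)
    scenario: str = "control"
    horizon: float = 500.0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ConfigError("r must be in (0, 1)")
        if self.budget < 0 or self.n_static < 1:
            raise ConfigError("budget must be >= 0 and n_static >= 1")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError("epsilon must be in [0, 1]")

    def topology(self) -> Topology:
        return build_brachypodium_topology(include_c3h=self.include_c3h)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "influx_bounds" in raw:
        raw["influx_bounds"] = tuple(raw["influx_bounds"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# observations & bands
# ---------------------------------------------------------------------------
_OBS_FIELDS = (
    "h_total",
    "g_total",
    "s_total",
    "inc_h",
    "inc_g",
    "inc_s",
    "inc_wall_pca",
    "inc_wall_fa",
)


def save_observations(obs: dict[str, ObservationSet], path: str | Path) -> None:
    payload = {
        scen: {k: float(getattr(o, k)) for k in _OBS_FIELDS} for scen, o in obs.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_observations(path: str | Path) -> dict[str, ObservationSet]:
    raw = yaml.safe_load(Path(path).read_text())
    return {scen: ObservationSet(**vals) for scen, vals in raw.items()}


def save_bands(bands: ObservationBands, path: str | Path) -> None:
    payload = {
        scen: {k: [float(lo), float(hi)] for k, (lo, hi) in kb.items()}
        for scen, kb in bands.bands.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_bands(path: str | Path) -> ObservationBands:
    raw = yaml.safe_load(Path(path).read_text())
    return ObservationBands(
        bands={
            scen: {k: (float(v[0]), float(v[1])) for k, v in kb.items()}
            for scen, kb in raw.items()
        }
    )


# ---------------------------------------------------------------------------
# parameter sets & ensembles
# ---------------------------------------------------------------------------
def parameter_set_to_dict(p: ParameterSet) -> dict:
    ss = p.steady_state
    return {
        "r": p.r,
        "a": {k: float(v) for k, v in p.a.items()},
        "g": {k: float(v) for k, v in p.g.items()},
        "d": {str(k): float(v) for k, v in p.d.items()},
        "steady_state": None
        if ss is None
        else {
            "X": [float(v) for v in ss.X],
            "Y": [None if np.isnan(v) else float(v) for v in ss.Y],
            "d": [None if np.isnan(v) else float(v) for v in ss.d],
            "sampled": {str(k): [float(x) for x in v] for k, v in ss.sampled.items()},
            "unidentifiable": list(ss.unidentifiable),
        },
        "degenerate_ss": {str(k): [float(x) for x in v] for k, v in p.degenerate_ss.items()},
    }


def parameter_set_from_dict(raw: dict, t: Topology) -> ParameterSet:
    ss = None
    if raw.get("steady_state") is not None:
        s = raw["steady_state"]
        ss = CompartmentStates(
            X=np.array([float(v) for v in s["X"]]),
            Y=np.array([np.nan if v is None else float(v) for v in s["Y"]]),
            d=np.array([np.nan if v is None else float(v) for v in s["d"]]),
            sampled={int(k): tuple(v) for k, v in s.get("sampled", {}).items()},
            unidentifiable=list(s.get("unidentifiable", [])),
        )
    return ParameterSet(
        topology=t,
        a={k: float(v) for k, v in raw["a"].items()},
        g={k: float(v) for k, v in raw["g"].items()},
        d={int(k): float(v) for k, v in raw["d"].items()},
        r=float(raw["r"]),
        steady_state=ss,
        degenerate_ss={int(k): tuple(v) for k, v in raw.get("degenerate_ss", {}).items()},
    )


def save_parameter_set(p: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(parameter_set_to_dict(p), indent=1))


def load_parameter_set(path: str | Path, t: Topology) -> ParameterSet:
    return parameter_set_from_dict(json.loads(Path(path).read_text()), t)


def _member_to_dict(m: AdmissibleMember) -> dict:
    return {
        "params": parameter_set_to_dict(m.params),
        "feed": asdict(m.feed),
        "dilution_rates": {k: float(v) for k, v in m.dilution_rates.items()},
        "score": float(m.verdict.score),
        "provenance": m.provenance,
    }


def save_ensemble(members, path: str | Path) -> None:
    """One admissible parameter set per JSON line."""
    with open(path, "w") as fh:
        for m in members:
            fh.write(json.dumps(_member_to_dict(m)) + "\n")


def load_ensemble(path: str | Path, t: Topology) -> list[AdmissibleMember]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        raw = json.loads(line)
        out.append(
            AdmissibleMember(
                params=parameter_set_from_dict(raw["params"], t),
                feed=FeedSpec(**raw["feed"]),
                dilution_rates=raw["dilution_rates"],
                verdict=AdmissibilityVerdict(passed=True, margins={}, score=raw["score"]),
                provenance=raw.get("provenance", {}),
            )
        )
    return out
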