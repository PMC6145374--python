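"""Measurable surface of the model: feeds, readouts and admissibility bands.

All concentrations and fluxes are on the normalized wild-type scale (pool
totals = 100); monomer totals are steady-state sink mass rates and label
incorporations are fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SCENARIO_KINDS",
    "FeedSpec",
    "ObservationSet",
    "ObservationBands",
    "make_bands",
]

#: the seven experimental scenarios used for admissibility plus the knockdown
SCENARIO_KINDS = (
    "control",
    "phe_label",
    "tyr_label",
    "ca_dilution_phe",
    "ca_dilution_tyr",
    "pca_dilution_phe",
    "pca_dilution_tyr",
    "knockdown",
)

#: observables treated as lignin readouts (tight band) vs wall phenolics
LIGNIN_KEYS = ("h_total", "g_total", "s_total", "total_lignin", "s_over_g",
               "inc_h", "inc_g", "inc_s", "inc_total")
WALL_KEYS = ("inc_wall_pca", "inc_wall_fa")


@dataclass(frozen=True)
class FeedSpec:
    """Constant zero-order influxes into the cytosolic source pools.

    Rates are in normalized mass units per time; label fractions in [0, 1].
    Medium additions of cinnamic acid / p-coumaric acid are always unlabeled.
    """

    phe_rate: float = 50.0
    tyr_rate: float = 50.0
    phe_label: float = 0.0
    tyr_label: float = 0.0
    ca_rate: float = 0.0
    pca_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("phe_rate", "tyr_rate", "ca_rate", "pca_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("phe_label", "tyr_label"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def total_influx(self) -> float:
        return self.phe_rate + self.tyr_rate + self.ca_rate + self.pca_rate

    def with_labels(self, phe: float = 0.0, tyr: float = 0.0) -> "FeedSpec":
        return replace(self, phe_label=phe, tyr_label=tyr)


@dataclass
class ObservationSet:
    """Per-scenario readouts: monomer totals and label incorporations."""

    h_total: float
    g_total: float
    s_total: float
    inc_h: float = 0.0
    inc_g: float = 0.0
    inc_s: float = 0.0
    inc_wall_pca: float = 0.0
    inc_wall_fa: float = 0.0
    undefined: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for k in ("h_total", "g_total", "s_total"):
            if getattr(self, k) < -1e-12:
                raise ValueError(f"{k} must be >= 0")
        for k in ("inc_h", "inc_g", "inc_s", "inc_wall_pca", "inc_wall_fa"):
            v = getattr(self, k)
            if np.isfinite(v) and not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{k}={v} outside [0, 1]")

    @property
    def total_lignin(self) -> float:
        return self.h_total + self.g_total + self.s_total

    @property
    def s_over_g(self) -> float:
        return self.s_total / self.g_total if self.g_total > 0 else float("nan")

    @property
    def inc_total(self) -> float:
        """Mass-weighted label incorporation over the three monomers."""
        tot = self.total_lignin
        if tot <= 0:
            return float("nan")
        return (
            self.h_total * self.inc_h
            + self.g_total * self.inc_g
            + self.s_total * self.inc_s
        ) / tot

    def as_dict(self) -> dict[str, float]:
        return {
            "h_total": self.h_total,
            "g_total": self.g_total,
            "s_total": self.s_total,
            "total_lignin": self.total_lignin,
            "s_over_g": self.s_over_g,
            "inc_h": self.inc_h,
            "inc_g": self.inc_g,
            "inc_s": self.inc_s,
            "inc_total": self.inc_total,
            "inc_wall_pca": self.inc_wall_pca,
            "inc_wall_fa": self.inc_wall_fa,
        }


@dataclass
class ObservationBands:
    """Admissibility bands per scenario: ``{scenario: {key: (lo, hi)}}``."""

    bands: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def scenarios(self) -> list[str]:
        return list(self.bands)

    def contains(self, scenario: str, obs: ObservationSet) -> bool:
        return all(v == 0.0 for v in self.margins(scenario, obs).values())

    def margins(self, scenario: str, obs: ObservationSet) -> dict[str, float]:
        """Signed fractional band violation per observable (0 = inside)."""
        out: dict[str, float] = {}
        values = obs.as_dict()
        for key, (lo, hi) in self.bands[scenario].items():
            v = values[key]
            if not np.isfinite(v):
                out[key] = float("inf")
            elif v < lo:
                out[key] = (v - lo) / max(abs(lo), 1e-12)
            elif v > hi:
                out[key] = (v - hi) / max(abs(hi), 1e-12)
            else:
                out[key] = 0.0
        return out


def make_bands(
    observations: dict[str, ObservationSet],
    lignin_tol: float = 0.25,
    wall_tol: float = 0.50,
    keys: dict[str, tuple[str, ...]] | None = None,
) -> ObservationBands:
    """Mean +/- 25% bands for lignin observables, relaxed for wall phenolics.

    ``keys`` maps scenario name to the observable keys that are constrained
    there; by default the control scenario constrains amounts/composition and
    every labeling scenario constrains the five sink incorporations.
    """
    default_label_keys = ("inc_h", "inc_g", "inc_s", "inc_total", "inc_wall_pca", "inc_wall_fa")
    bands: dict[str, dict[str, tuple[float, float]]] = {}
    for scen, obs in observations.items():
        if keys is not None and scen in keys:
            use = keys[scen]
        elif scen == "control":
            use = ("h_total", "g_total", "s_total", "total_lignin", "s_over_g")
        else:
            use = default_label_keys
        values = obs.as_dict()
        scen_bands: dict[str, tuple[float, float]] = {}
        for k in use:
            v = values[k]
            if not np.isfinite(v):
                continue
            tol = wall_tol if k in WALL_KEYS else lignin_tol
            lo, hi = v * (1 - tol), v * (1 + tol)
            if lo > hi:  # negative value, not expected but keep ordered
                lo, hi = hi, lo
            scen_bands[k] = (lo, hi)
        bands[scen] = scen_bands
    return ObservationBands(bands=bands)
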