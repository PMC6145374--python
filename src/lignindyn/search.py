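"""Monte Carlo parameterization: kinetic-order sampling in fixed ranges,
algebraic rate-constant back-calculation at the steady state, admissibility
scoring against per-scenario bands, and the explore-and-exploit ensemble
search."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import EnzymeActivityProfile, ParameterSet, assemble_rhs, rate_flux_ids
from .experiments import evaluate_all_scenarios
from .observables import SCENARIO_KINDS, FeedSpec, ObservationBands, ObservationSet
from .steady_state import (
    CompartmentStates,
    FluxDistribution,
    compute_compartment_steady_states,
    propagate_label_fractions,
)
from .topology import CYTOSOL, ER, Topology

__all__ = [
    "SamplingRanges",
    "AdmissibilityCriteria",
    "AdmissibilityVerdict",
    "AdmissibleMember",
    "AdmissibleEnsemble",
    "sample_kinetic_orders",
    "back_calculate_rate_constants",
    "build_parameter_set",
    "evaluate_admissibility",
    "explore_exploit_search",
]

ADMISSIBILITY_SCENARIOS = SCENARIO_KINDS[:7]


@dataclass(frozen=True)
class SamplingRanges:
    """Sampling intervals for kinetic orders."""

    substrate: tuple[float, float] = (0.0, 1.0)
    efflux: tuple[float, float] = (0.0, 4.0)
    inhibitor: tuple[float, float] = (-4.0, 0.0)


@dataclass
class AdmissibilityCriteria:
    """Per-scenario target bands; all seven scenarios must be present."""

    bands: ObservationBands

    def __post_init__(self) -> None:
        missing = [s for s in ADMISSIBILITY_SCENARIOS if s not in self.bands.bands]
        if missing:
            raise ValueError(f"criteria missing scenarios: {missing}")
        for scen, kb in self.bands.bands.items():
            for key, (lo, hi) in kb.items():
                if hi < lo:
                    raise ValueError(f"empty band for {scen}/{key}")


@dataclass
class AdmissibilityVerdict:
    passed: bool
    margins: dict[str, dict[str, float]]
    score: float


@dataclass
class AdmissibleMember:
    params: ParameterSet
    feed: FeedSpec
    dilution_rates: dict[str, float]
    verdict: AdmissibilityVerdict
    provenance: dict = field(default_factory=dict)


@dataclass
class AdmissibleEnsemble:
    members: list[AdmissibleMember]
    evaluations: int
    best_score: float
    best_margins: dict | None = None

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        return self.members[i]


# ---------------------------------------------------------------------------
# kinetic orders & rate constants
# ---------------------------------------------------------------------------
def sample_kinetic_orders(
    t: Topology,
    ranges: SamplingRanges | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Uniform kinetic-order draw per GMA flux.

    Substrate orders (enzymatic reactions and monolignol transports) come
    from the substrate interval, the four wall-phenolic effluxes from the
    efflux interval; modifier orders, when a topology declares them, use the
    substrate interval for activators and the inhibitor interval otherwise.
    """
    ranges = ranges or SamplingRanges()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g: dict[str, float] = {}
    for r in t.reactions:
        g[r.id] = float(rng.uniform(*ranges.substrate))
    for s in t.sinks:
        interval = ranges.efflux if s.kind == "wall_phenolic" else ranges.substrate
        g[s.id] = float(rng.uniform(*interval))
    return g


def back_calculate_rate_constants(
    t: Topology,
    f: FluxDistribution,
    ss: CompartmentStates,
    g: dict[str, float],
    e: EnzymeActivityProfile | None = None,
    r: float = 0.9,
) -> dict[str, float]:
    """Invert the GMA rate law at the steady state: ``a_j = V_j / (C^g E^h)``.

    Flux values are converted from mass units to the concentration scale of
    their compartment before inversion, so the reconstructed model has the
    given flux distribution as an exact steady state.
    """
    e = e or EnzymeActivityProfile()
    a: dict[str, float] = {}

    def conc(met: int, comp: str) -> float:
        c = ss.X[met - 1] if comp == CYTOSOL else ss.Y[met - 1]
        return float(c)

    for rxn in t.reactions:
        c = conc(rxn.substrate, rxn.compartment)
        if c <= 0 or not np.isfinite(c):
            if g[rxn.id] != 0:
                raise ValueError(
                    f"zero/undefined steady state of pool ({rxn.substrate}, {rxn.compartment}) "
                    f"with nonzero kinetic order on {rxn.id}"
                )
            c = 1.0
        scale = r if rxn.compartment == CYTOSOL else 1.0 - r
        v_conc = f.values[rxn.id] / scale
        a[rxn.id] = v_conc / (c ** g[rxn.id] * e.activity(rxn.enzyme))
    for s in t.sinks:
        met, comp = s.source
        c = conc(met, comp)
        if c <= 0 or not np.isfinite(c):
            if g[s.id] != 0:
                raise ValueError(f"zero steady state of pool {s.source} feeding sink {s.id}")
            c = 1.0
        scale = r if comp == CYTOSOL else 1.0 - r
        a[s.id] = (f.values[s.id] / scale) / c ** g[s.id]
    return a


def build_parameter_set(
    t: Topology,
    f: FluxDistribution,
    ss: CompartmentStates,
    g: dict[str, float],
    r: float = 0.9,
    e: EnzymeActivityProfile | None = None,
) -> ParameterSet:
    """Assemble a full ParameterSet whose exact steady state is ``(f, ss)``."""
    a = back_calculate_rate_constants(t, f, ss, g, e, r)
    d = {m.id: (ss.d[m.id - 1] if m.has_er_pool else float("nan")) for m in t.metabolites}
    return ParameterSet(
        topology=t, a=a, g=dict(g), d=d, r=r, steady_state=ss, degenerate_ss=dict(ss.sampled)
    )


# ---------------------------------------------------------------------------
# admissibility
# ---------------------------------------------------------------------------
def evaluate_admissibility(
    obs: dict[str, ObservationSet],
    c: AdmissibilityCriteria,
) -> AdmissibilityVerdict:
    """Pass iff every observable of every scenario lies inside its band."""
    missing = [s for s in ADMISSIBILITY_SCENARIOS if s not in obs]
    if missing:
        raise ValueError(f"missing simulated scenarios: {missing}")
    margins: dict[str, dict[str, float]] = {}
    score = 0.0
    for scen in c.bands.scenarios():
        if scen not in obs:
            continue
        m = c.bands.margins(scen, obs[scen])
        margins[scen] = m
        score += sum(v * v for v in m.values() if np.isfinite(v))
        score += sum(1e6 for v in m.values() if not np.isfinite(v))
    return AdmissibilityVerdict(passed=score == 0.0, margins=margins, score=score)


# ---------------------------------------------------------------------------
# explore-and-exploit search
# ---------------------------------------------------------------------------
@dataclass
class _Candidate:
    member_idx: int
    g: dict[str, float]
    degenerate_seed: int
    dilution_rates: dict[str, float]


def _stable(t: Topology, p: ParameterSet, feed: FeedSpec, tol: float = 1e-6) -> bool:
    rhs = assemble_rhs(t, p, None, feed)
    pooled = p.wild_type_pooled()
    jac = rhs.pooled_jacobian(pooled)
    return bool(np.max(np.real(np.linalg.eigvals(jac))) < tol)


def _evaluate_candidate(
    t: Topology,
    static_ens: list[FluxDistribution],
    cand: _Candidate,
    c: AdmissibilityCriteria,
    r: float,
    check_stability: bool,
) -> tuple[AdmissibilityVerdict | None, ParameterSet | None, FeedSpec | None]:
    fd = static_ens[cand.member_idx]
    lf = propagate_label_fractions(t, fd, fd.feed.with_labels(1.0, 0.0), "phe_label")
    ss = compute_compartment_steady_states(t, fd, lf, r, seed=cand.degenerate_seed)
    try:
        p = build_parameter_set(t, fd, ss, cand.g, r)
    except ValueError:
        return None, None, None
    if check_stability and not _stable(t, p, fd.feed):
        return None, None, None
    try:
        obs = evaluate_all_scenarios(t, p, fd.feed, cand.dilution_rates)
    except Exception:
        return None, None, None
    verdict = evaluate_admissibility(obs, c)
    return verdict, p, fd.feed


def explore_exploit_search(
    t: Topology,
    static_ens: list[FluxDistribution],
    c: AdmissibilityCriteria,
    budget: int,
    seed: int | np.random.Generator = 0,
    r: float = 0.9,
    ranges: SamplingRanges | None = None,
    epsilon: float = 0.2,
    stall_restart: int = 500,
    initial_radius: float = 0.25,
    dilution_rate_bounds: tuple[float, float] = (1.0, 30.0),
    check_stability: bool = True,
    max_members: int | None = None,
) -> AdmissibleEnsemble:
    """Explore-and-exploit search for admissible parameter sets.

    Global exploration draws fresh kinetic orders, degenerate-pool steady
    states, medium-uptake rates and a static-ensemble member; exploitation
    perturbs the incumbent (best-scoring) candidate inside a neighborhood
    whose radius halves after each improvement.  A stall of
    ``stall_restart`` consecutive non-improving evaluations triggers a
    restart from a fresh random candidate.  Every admissible set found is
    returned with full provenance; candidates are re-scored from scratch so
    returned members re-pass admissibility when re-simulated.
    """
    if budget < 1:
        return AdmissibleEnsemble(members=[], evaluations=0, best_score=np.inf)
    if not static_ens:
        raise ValueError("empty static ensemble")
    ranges = ranges or SamplingRanges()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def fresh() -> _Candidate:
        return _Candidate(
            member_idx=int(rng.integers(len(static_ens))),
            g=sample_kinetic_orders(t, ranges, rng),
            degenerate_seed=int(rng.integers(2**31 - 1)),
            dilution_rates={
                "ca": float(np.exp(rng.uniform(*np.log(dilution_rate_bounds)))),
                "pca": float(np.exp(rng.uniform(*np.log(dilution_rate_bounds)))),
            },
        )

    def jitter(base: _Candidate, radius: float) -> _Candidate:
        g = {}
        for fid, val in base.g.items():
            interval = ranges.efflux if fid.startswith("E") else ranges.substrate
            width = interval[1] - interval[0]
            g[fid] = float(np.clip(val + rng.normal(0.0, radius * width), *interval))
        dil = {
            k: float(np.clip(v * np.exp(rng.normal(0.0, radius)), *dilution_rate_bounds))
            for k, v in base.dilution_rates.items()
        }
        deg = base.degenerate_seed if rng.random() < 0.7 else int(rng.integers(2**31 - 1))
        return _Candidate(base.member_idx, g, deg, dil)

    members: list[AdmissibleMember] = []
    incumbent: _Candidate | None = None
    best_score = np.inf
    best_margins: dict | None = None
    radius = initial_radius
    stall = 0

    for it in range(budget):
        explore = incumbent is None or rng.random() < epsilon
        cand = fresh() if explore else jitter(incumbent, radius)
        verdict, p, feed = _evaluate_candidate(t, static_ens, cand, c, r, check_stability)
        if verdict is None:
            stall += 1
            continue
        if verdict.passed:
            members.append(
                AdmissibleMember(
                    params=p,
                    feed=feed,
                    dilution_rates=dict(cand.dilution_rates),
                    verdict=verdict,
                    provenance={
                        "iteration": it,
                        "mode": "explore" if explore else "exploit",
                        "member_idx": cand.member_idx,
                        "degenerate_seed": cand.degenerate_seed,
                    },
                )
            )
            incumbent = cand
            best_score = 0.0
            best_margins = verdict.margins
            radius = max(radius / 2.0, 0.02)
            stall = 0
            if max_members is not None and len(members) >= max_members:
                return AdmissibleEnsemble(members, it + 1, best_score, best_margins)
            continue
        if verdict.score < best_score:
            best_score = verdict.score
            best_margins = verdict.margins
            incumbent = cand
            radius = max(radius / 2.0, 0.02)
            stall = 0
        else:
            stall += 1
            if stall >= stall_restart:
                incumbent = None
                radius = initial_radius
                stall = 0

    return AdmissibleEnsemble(members, budget, best_score, best_margins)
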