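"""Two-compartment monolignol pathway topology for Brachypodium distachyon.

The pathway is a fixed reaction network over 18 metabolites.  The two amino
acid sources (Phe, Tyr) live in the cytosol only; every other metabolite is
present as a pair of well-mixed pools, one in the cytosol (``X_i``) and one
at the outer ER surface (``Y_i``), giving 18 + 16 = 34 metabolite pools.
Three enzymes (C4H, C3'H, F5H) are membrane bound and only act on ER pools;
other enzymes may act in either compartment.  Paired pools exchange material
through linear diffusion links, and terminal sinks (three lignin monomer
transports plus four wall-bound phenolic effluxes) absorb mass irreversibly.

With labeled and unlabeled species tracked separately the 34 pools yield the
68-equation dynamic system assembled in :mod:`lignindyn.dynamics`.

Flux numbering is canonical for this package; the anchored indices are
``V25`` (ER 4CL), ``V26``/``V31`` (the two ER consumers of p-coumaroyl-CoA)
and diffusion link ``D9`` (p-coumaroyl-CoA), recorded in ``Topology.aliases``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "CYTOSOL",
    "ER",
    "N_METABOLITES",
    "N_POOLS",
    "Metabolite",
    "EnzymaticReaction",
    "DiffusionLink",
    "Sink",
    "Topology",
    "ValidationReport",
    "build_brachypodium_topology",
    "stoichiometric_matrix",
    "validate_topology",
]

CYTOSOL = "cytosol"
ER = "er"

N_METABOLITES = 18
N_POOLS = 34

#: enzymes anchored to the outer ER surface; reactions they catalyse can only
#: be instantiated on the ER pools.
ER_BOUND_ENZYMES = frozenset({"C4H", "C3'H", "F5H"})


@dataclass(frozen=True)
class Metabolite:
    id: int
    name: str
    has_er_pool: bool = True
    is_source: bool = False
    is_degenerate_candidate: bool = False


@dataclass(frozen=True)
class EnzymaticReaction:
    """A single GMA flux ``V_j`` converting one substrate pool to products."""

    id: str
    substrate: int
    products: tuple[int, ...]
    enzyme: str
    compartment: str
    modifiers: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.compartment not in (CYTOSOL, ER):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.enzyme in ER_BOUND_ENZYMES and self.compartment != ER:
            raise ValueError(f"{self.enzyme} is ER bound; cannot act in {self.compartment}")


@dataclass(frozen=True)
class DiffusionLink:
    """Net diffusion flux ``D_j = d_j (X_i - Y_i)`` between paired pools."""

    id: str
    metabolite: int


@dataclass(frozen=True)
class Sink:
    """Absorbing efflux: lignin monomer transport or wall-phenolic efflux."""

    id: str
    source: tuple[int, str]  # (metabolite id, compartment)
    kind: str  # "lignin_monomer" | "wall_phenolic"


@dataclass
class ValidationReport:
    unreachable_pools: list[tuple[int, str]] = field(default_factory=list)
    dead_end_pools: list[tuple[int, str]] = field(default_factory=list)
    duplicate_flux_ids: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unreachable_pools or self.dead_end_pools or self.duplicate_flux_ids)


@dataclass
class Topology:
    metabolites: list[Metabolite]
    reactions: list[EnzymaticReaction]
    diffusion_links: list[DiffusionLink]
    sinks: list[Sink]
    channel_annotations: list[tuple[tuple[str, ...], str]] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)

    # ---- lookups -------------------------------------------------------
    def metabolite(self, key: int | str) -> Metabolite:
        if isinstance(key, int):
            for m in self.metabolites:
                if m.id == key:
                    return m
        else:
            for m in self.metabolites:
                if m.name == key:
                    return m
        raise KeyError(key)

    @property
    def enzymes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.enzyme, None)
        return list(seen)

    @property
    def source_ids(self) -> list[int]:
        return [m.id for m in self.metabolites if m.is_source]

    @property
    def dual_ids(self) -> list[int]:
        return [m.id for m in self.metabolites if m.has_er_pool]

    @property
    def n_pools(self) -> int:
        return len(self.metabolites) + len(self.dual_ids)

    def pool_index(self, metabolite: int, compartment: str) -> int:
        if compartment == CYTOSOL:
            return metabolite - 1
        if compartment == ER:
            duals = self.dual_ids
            try:
                return len(self.metabolites) + duals.index(metabolite)
            except ValueError:
                raise KeyError(f"metabolite {metabolite} has no ER pool") from None
        raise ValueError(compartment)

    def pool_label(self, index: int) -> str:
        n = len(self.metabolites)
        if index < n:
            return f"X{index + 1}"
        return f"Y{self.dual_ids[index - n]}"

    def pools(self) -> list[tuple[int, str]]:
        """Pools in flat-index order: all X pools, then the ER (Y) pools."""
        return [(m.id, CYTOSOL) for m in self.metabolites] + [
            (i, ER) for i in self.dual_ids
        ]

    @property
    def flux_ids(self) -> list[str]:
        """Column order of the stoichiometric matrix: V*, D*, sinks."""
        return (
            [r.id for r in self.reactions]
            + [d.id for d in self.diffusion_links]
            + [s.id for s in self.sinks]
        )

    def reaction(self, rid: str) -> EnzymaticReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def diffusion_link_for(self, metabolite: int) -> DiffusionLink:
        for d in self.diffusion_links:
            if d.metabolite == metabolite:
                return d
        raise KeyError(metabolite)

    def consumers(self, metabolite: int, compartment: str) -> list[EnzymaticReaction]:
        return [
            r
            for r in self.reactions
            if r.substrate == metabolite and r.compartment == compartment
        ]

    def producers(self, metabolite: int, compartment: str) -> list[EnzymaticReaction]:
        return [
            r
            for r in self.reactions
            if metabolite in r.products and r.compartment == compartment
        ]

    def sinks_from(self, metabolite: int, compartment: str) -> list[Sink]:
        return [s for s in self.sinks if s.source == (metabolite, compartment)]

    # ---- graph view ----------------------------------------------------
    def graph(self, include_diffusion: bool = True) -> nx.DiGraph:
        """Directed pool-level graph (diffusion edges both ways)."""
        g = nx.DiGraph()
        for met, comp in self.pools():
            g.add_node((met, comp))
        for r in self.reactions:
            for p in r.products:
                g.add_edge((r.substrate, r.compartment), (p, r.compartment), flux=r.id)
        if include_diffusion:
            for d in self.diffusion_links:
                g.add_edge((d.metabolite, CYTOSOL), (d.metabolite, ER), flux=d.id)
                g.add_edge((d.metabolite, ER), (d.metabolite, CYTOSOL), flux=d.id)
        for s in self.sinks:
            g.add_edge(s.source, ("sink", s.id), flux=s.id)
        return g


# ---------------------------------------------------------------------------
# canonical metabolite numbering (indices 2, 4, 5, 9, 16, 17 are fixed by the
# published equation set; the rest follow pathway order)
# ---------------------------------------------------------------------------
_METABOLITE_NAMES = {
    1: "phenylalanine",
    2: "cinnamic acid",
    3: "tyrosine",
    4: "p-coumaric acid",
    5: "p-coumaroyl-CoA",
    6: "caffeic acid",
    7: "p-coumaraldehyde",
    8: "p-coumaroyl shikimate",
    9: "caffeoyl shikimate",
    10: "caffeoyl-CoA",
    11: "feruloyl-CoA",
    12: "coniferaldehyde",
    13: "coniferyl alcohol",
    14: "p-coumaryl alcohol",
    15: "sinapyl alcohol",
    16: "5-OH-coniferaldehyde",
    17: "5-OH-coniferyl alcohol",
    18: "sinapaldehyde",
}

_SOURCES = {1, 3}
_DEGENERATE_CANDIDATES = {2, 9, 16, 17}

# diffusion-link numbering over the 16 dual metabolites; the only anchored
# assignment is d9 <-> metabolite 5 (p-coumaroyl-CoA).
_DIFFUSION_ORDER = [2, 4, 6, 8, 9, 10, 11, 12, 5, 7, 13, 14, 16, 17, 18, 15]

# (substrate, product, enzyme) in canonical V order
_CYTOSOL_REACTIONS = [
    (1, 2, "PAL"),  # V1
    (3, 4, "PTAL"),  # V2
    (1, 2, "PTAL"),  # V3: PTAL is bifunctional and also deaminates Phe
    (4, 6, "C3H"),  # V4
    (4, 5, "4CL"),  # V5
    (6, 10, "4CL"),  # V6
    (5, 8, "HCT"),  # V7
    (9, 10, "HCT"),  # V8
    (10, 11, "CCoAOMT"),  # V9
    (11, 12, "CCR"),  # V10
    (5, 7, "CCR"),  # V11
    (7, 14, "CAD"),  # V12
    (12, 13, "CAD"),  # V13
    (16, 18, "COMT"),  # V14
    (18, 15, "CAD"),  # V15
    (16, 17, "CAD"),  # V16
    (17, 15, "COMT"),  # V17
]

# ER side, ordered so that the published anchors hold: V25 = 4CL on Y4 -> Y5,
# V26 and V31 are the two consumers of Y5.  The S branch past F5H returns to
# the cytosol by diffusion (no ER COMT/CAD on pools 18 and 15), which is what
# confines the label-degenerate pools to {2, 9, 16, 17}.
_ER_REACTIONS = [
    (2, 4, "C4H"),  # V18
    (4, 6, "C3H"),  # V19
    (6, 10, "4CL"),  # V20
    (9, 10, "HCT"),  # V21
    (10, 11, "CCoAOMT"),  # V22
    (11, 12, "CCR"),  # V23
    (12, 13, "CAD"),  # V24
    (4, 5, "4CL"),  # V25  (anchored)
    (5, 8, "HCT"),  # V26  (anchored)
    (8, 9, "C3'H"),  # V27
    (12, 16, "F5H"),  # V28
    (16, 17, "CAD"),  # V29
    (7, 14, "CAD"),  # V30
    (5, 7, "CCR"),  # V31  (anchored)
]


def build_brachypodium_topology(include_c3h: bool = True) -> Topology:
    """Construct the fixed two-compartment Brachypodium pathway.

    Parameters
    ----------
    include_c3h:
        Keep the direct 3-hydroxylation route (p-coumaric acid -> caffeic
        acid -> caffeoyl-CoA).  It is required for the published label
        degeneracy pattern (exactly four degenerate pools) to emerge, so it
        is on by default; ``False`` removes fluxes V4, V6, V19 and V20 along
        with the caffeic acid branch.
    """
    metabolites = [
        Metabolite(
            id=i,
            name=_METABOLITE_NAMES[i],
            has_er_pool=i not in _SOURCES,
            is_source=i in _SOURCES,
            is_degenerate_candidate=i in _DEGENERATE_CANDIDATES,
        )
        for i in range(1, N_METABOLITES + 1)
    ]

    reactions: list[EnzymaticReaction] = []
    j = 0
    for sub, prod, enz in _CYTOSOL_REACTIONS:
        j += 1
        reactions.append(
            EnzymaticReaction(id=f"V{j}", substrate=sub, products=(prod,), enzyme=enz, compartment=CYTOSOL)
        )
    for sub, prod, enz in _ER_REACTIONS:
        j += 1
        reactions.append(
            EnzymaticReaction(id=f"V{j}", substrate=sub, products=(prod,), enzyme=enz, compartment=ER)
        )

    if not include_c3h:
        c3h_route = {"V4", "V6", "V19", "V20"}
        reactions = [r for r in reactions if r.id not in c3h_route]

    diffusion_links = [
        DiffusionLink(id=f"D{k + 1}", metabolite=met) for k, met in enumerate(_DIFFUSION_ORDER)
    ]

    sinks = [
        Sink(id="H", source=(14, CYTOSOL), kind="lignin_monomer"),
        Sink(id="G", source=(13, CYTOSOL), kind="lignin_monomer"),
        Sink(id="S", source=(15, CYTOSOL), kind="lignin_monomer"),
        Sink(id="E1", source=(4, CYTOSOL), kind="wall_phenolic"),  # wall-bound pCA
        Sink(id="E2", source=(4, ER), kind="wall_phenolic"),  # wall-bound pCA
        Sink(id="E3", source=(11, CYTOSOL), kind="wall_phenolic"),  # wall-bound FA
        Sink(id="E4", source=(11, ER), kind="wall_phenolic"),  # wall-bound FA
    ]

    channels = [
        # C4H output funnelled along the ER surface to caffeoyl shikimate
        (("V18", "V25", "V26", "V27"), ER),
        # the coniferaldehyde branch point at the ER: F5H route toward S
        (("V28", "V29"), ER),
        # channeled ER CAD route toward G
        (("V24",), ER),
    ]

    aliases = {
        "V25": "er 4CL: Y4 -> Y5",
        "V26": "er HCT: Y5 -> Y8",
        "V31": "er CCR: Y5 -> Y7",
        "d9": "diffusion link of p-coumaroyl-CoA (metabolite 5)",
    }

    return Topology(
        metabolites=metabolites,
        reactions=reactions,
        diffusion_links=diffusion_links,
        sinks=sinks,
        channel_annotations=channels,
        aliases=aliases,
    )


def stoichiometric_matrix(t: Topology) -> np.ndarray:
    """Integer stoichiometric matrix, pools x fluxes.

    Diffusion columns carry -1 on the cytosolic row and +1 on the ER row
    (positive flux = net cytosol -> ER); the ER volume-ratio multiplier R is
    applied at ODE assembly time, not here, so every column is in mass units.
    """
    n = t.n_pools
    cols = t.flux_ids
    mat = np.zeros((n, len(cols)), dtype=int)
    for c, r in enumerate(t.reactions):
        mat[t.pool_index(r.substrate, r.compartment), c] -= 1
        for p in r.products:
            mat[t.pool_index(p, r.compartment), c] += 1
    off = len(t.reactions)
    for c, d in enumerate(t.diffusion_links):
        mat[t.pool_index(d.metabolite, CYTOSOL), off + c] = -1
        mat[t.pool_index(d.metabolite, ER), off + c] = 1
    off += len(t.diffusion_links)
    for c, s in enumerate(t.sinks):
        mat[t.pool_index(*s.source), off + c] = -1
    return mat


def validate_topology(t: Topology) -> ValidationReport:
    """Structural checks: reachability, dead ends, duplicate flux ids."""
    report = ValidationReport()

    ids = t.flux_ids
    seen: set[str] = set()
    for fid in ids:
        if fid in seen:
            report.duplicate_flux_ids.append(fid)
        seen.add(fid)

    g = t.graph()
    reachable: set = set()
    for src in t.source_ids:
        reachable |= nx.descendants(g, (src, CYTOSOL))
        reachable.add((src, CYTOSOL))
    for met, comp in t.pools():
        if (met, comp) not in reachable:
            report.unreachable_pools.append((met, comp))

    # a pool is a dead end if no absorbing sink is reachable from it: mass
    # arriving there (directly or via diffusion) would accumulate forever
    sink_nodes = {("sink", s.id) for s in t.sinks}
    for met, comp in t.pools():
        if not (nx.descendants(g, (met, comp)) & sink_nodes):
            report.dead_end_pools.append((met, comp))

    return report
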