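"""Minimal SBML Level 3 export/import for model exchange.

Written with the standard library XML tools (no libsbml dependency): species
are the 34 metabolite pools plus one boundary species per sink, reactions
carry GMA kinetic laws as MathML power products when a parameter set is
supplied, and diffusion links are reversible reactions between the paired
pools.  The reader rebuilds the stoichiometry so exports round-trip.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import ParameterSet
from .topology import CYTOSOL, ER, Topology

__all__ = ["export_sbml", "read_sbml", "check_sbml_consistency", "SbmlModel"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _species_id(t: Topology, met: int, comp: str) -> str:
    return f"X{met}" if comp == CYTOSOL else f"Y{met}"


def _mathml_power_product(a: float, species: str, g: float, enzyme: float | None) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    times = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    ET.SubElement(times, f"{{{MATHML_NS}}}times")
    cn = ET.SubElement(times, f"{{{MATHML_NS}}}cn")
    cn.text = repr(float(a))
    power = ET.SubElement(times, f"{{{MATHML_NS}}}apply")
    ET.SubElement(power, f"{{{MATHML_NS}}}power")
    ci = ET.SubElement(power, f"{{{MATHML_NS}}}ci")
    ci.text = species
    gcn = ET.SubElement(power, f"{{{MATHML_NS}}}cn")
    gcn.text = repr(float(g))
    if enzyme is not None:
        ecn = ET.SubElement(times, f"{{{MATHML_NS}}}cn")
        ecn.text = repr(float(enzyme))
    return math


def export_sbml(
    t: Topology,
    p: ParameterSet | None = None,
    path: str | Path | None = None,
) -> str:
    """Serialize the topology (and optional kinetics) to SBML L3; returns the
    document text and optionally writes it to ``path``."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": "brachypodium_lignin_2c"})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cid, size in ((CYTOSOL, p.r if p else 0.9), (ER, 1 - (p.r if p else 0.9)), ("wall", 1.0)):
        ET.SubElement(
            comps,
            f"{{{SBML_NS}}}compartment",
            {"id": cid, "size": repr(float(size)), "constant": "true"},
        )

    species = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for met, comp in t.pools():
        ET.SubElement(
            species,
            f"{{{SBML_NS}}}species",
            {
                "id": _species_id(t, met, comp),
                "name": t.metabolite(met).name,
                "compartment": comp,
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    for s in t.sinks:
        ET.SubElement(
            species,
            f"{{{SBML_NS}}}species",
            {
                "id": f"sink_{s.id}",
                "compartment": "wall",
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "true",
                "constant": "false",
            },
        )

    reactions = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")

    def add_reaction(rid: str, reactants: list[str], products: list[str], reversible: bool,
                     kinetics: ET.Element | None = None) -> None:
        rxn = ET.SubElement(
            reactions,
            f"{{{SBML_NS}}}reaction",
            {"id": rid, "reversible": "true" if reversible else "false"},
        )
        lor = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfReactants")
        for sp in reactants:
            ET.SubElement(
                lor, f"{{{SBML_NS}}}speciesReference",
                {"species": sp, "stoichiometry": "1", "constant": "true"},
            )
        lop = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfProducts")
        for sp in products:
            ET.SubElement(
                lop, f"{{{SBML_NS}}}speciesReference",
                {"species": sp, "stoichiometry": "1", "constant": "true"},
            )
        if kinetics is not None:
            kl = ET.SubElement(rxn, f"{{{SBML_NS}}}kineticLaw")
            kl.append(kinetics)

    for r in t.reactions:
        sub = _species_id(t, r.substrate, r.compartment)
        prods = [_species_id(t, pr, r.compartment) for pr in r.products]
        kin = None
        if p is not None:
            kin = _mathml_power_product(p.a[r.id], sub, p.g[r.id], 100.0)
        add_reaction(r.id, [sub], prods, reversible=False, kinetics=kin)
    for dl in t.diffusion_links:
        kin = None
        if p is not None and np.isfinite(p.d.get(dl.metabolite, np.nan)):
            kin = _mathml_power_product(p.d[dl.metabolite], _species_id(t, dl.metabolite, CYTOSOL), 1.0, None)
        add_reaction(
            dl.id,
            [_species_id(t, dl.metabolite, CYTOSOL)],
            [_species_id(t, dl.metabolite, ER)],
            reversible=True,
            kinetics=kin,
        )
    for s in t.sinks:
        kin = None
        if p is not None:
            kin = _mathml_power_product(p.a[s.id], _species_id(t, *s.source), p.g[s.id], None)
        add_reaction(s.id, [_species_id(t, *s.source)], [f"sink_{s.id}"], reversible=False, kinetics=kin)

    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class SbmlModel:
    species: list[str]
    compartments: dict[str, str]  # species id -> compartment
    reactions: list[tuple[str, list[str], list[str], bool]]  # id, reactants, products, reversible

    def stoichiometric_matrix(self, species_order: list[str] | None = None,
                              reaction_order: list[str] | None = None) -> np.ndarray:
        sp = species_order or self.species
        rids = reaction_order or [r[0] for r in self.reactions]
        idx = {s: i for i, s in enumerate(sp)}
        by_id = {r[0]: r for r in self.reactions}
        mat = np.zeros((len(sp), len(rids)), dtype=int)
        for c, rid in enumerate(rids):
            _id, reactants, products, _rev = by_id[rid]
            for s in reactants:
                if s in idx:
                    mat[idx[s], c] -= 1
            for s in products:
                if s in idx:
                    mat[idx[s], c] += 1
        return mat


def read_sbml(source: str | Path) -> SbmlModel:
    """Parse an SBML document (path or text) back into a structural model."""
    text = source if isinstance(source, str) and source.lstrip().startswith("<") else Path(source).read_text()
    root = ET.fromstring(text)
    ns = {"s": SBML_NS}
    species, compartments = [], {}
    for sp in root.findall(".//s:listOfSpecies/s:species", ns):
        species.append(sp.attrib["id"])
        compartments[sp.attrib["id"]] = sp.attrib["compartment"]
    reactions = []
    for rx in root.findall(".//s:listOfReactions/s:reaction", ns):
        reactants = [
            ref.attrib["species"]
            for ref in rx.findall("s:listOfReactants/s:speciesReference", ns)
        ]
        products = [
            ref.attrib["species"]
            for ref in rx.findall("s:listOfProducts/s:speciesReference", ns)
        ]
        reactions.append(
            (rx.attrib["id"], reactants, products, rx.attrib.get("reversible") == "true")
        )
    return SbmlModel(species=species, compartments=compartments, reactions=reactions)


def check_sbml_consistency(model: SbmlModel) -> list[str]:
    """Structural consistency checks; returns a list of problems (empty = ok)."""
    problems = []
    if len(set(model.species)) != len(model.species):
        problems.append("duplicate species ids")
    rids = [r[0] for r in model.reactions]
    if len(set(rids)) != len(rids):
        problems.append("duplicate reaction ids")
    known = set(model.species)
    for rid, reactants, products, _rev in model.reactions:
        for s in reactants + products:
            if s not in known:
                problems.append(f"reaction {rid} references unknown species {s}")
        if not reactants and not products:
            problems.append(f"reaction {rid} has no participants")
    for s, c in model.compartments.items():
        if c not in (CYTOSOL, ER, "wall"):
            problems.append(f"species {s} in undeclared compartment {c}")
    return problems
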