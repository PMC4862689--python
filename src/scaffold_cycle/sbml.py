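"""SBML Level 3 export of the motif (and a reader for round-trip checks).

A purpose-built serializer for this one mass-action network: 9 species
with initial amounts, 10 global parameters, 10 irreversible reactions
whose kinetic laws are plain mass-action products rendered as MathML.
The reader reconstructs a rate function directly from the document so the
exported model can be verified against the native right-hand side.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from scaffold_cycle.motif_model import (
    ConcentrationTotals,
    MotifModel,
    SPECIES,
    initial_state,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

#: reaction table: (id, rate-constant name, reactants, products)
REACTIONS = (
    ("assoc_SK", "k1", ("S", "K"), ("SK",)),
    ("dissoc_SK", "k2", ("SK",), ("S", "K")),
    ("phosphorylation", "k3", ("SK",), ("Sp", "K")),
    ("assoc_SpP", "k4", ("Sp", "P"), ("SpP",)),
    ("dissoc_SpP", "k5", ("SpP",), ("Sp", "P")),
    ("dephosphorylation", "k6", ("SpP",), ("S", "P")),
    ("assoc_KT", "k7", ("K", "T"), ("KT",)),
    ("dissoc_KT", "k8", ("KT",), ("K", "T")),
    ("assoc_PT", "k9", ("P", "T"), ("PT",)),
    ("dissoc_PT", "k10", ("PT",), ("P", "T")),
)


def export_sbml(model: MotifModel, totals: ConcentrationTotals, path) -> str:
    """Write the motif as an SBML L3V2 document; returns the XML text.

    Initial amounts put each moiety entirely in its free form (the
    all-free convention); the four conserved totals are therefore the
    free-species initial amounts.
    """
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml",
                      attrib={"level": "3", "version": "2"})
    mdl = ET.SubElement(sbml, f"{{{SBML_NS}}}model",
                        attrib={"id": "scaffold_cycle_motif",
                                "substanceUnits": "micromole",
                                "timeUnits": "second"})
    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  attrib={"id": "cell", "size": "1", "constant": "true",
                          "spatialDimensions": "3"})
    init = initial_state(totals)
    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for name in SPECIES:
        ET.SubElement(sps, f"{{{SBML_NS}}}species", attrib={
            "id": name, "compartment": "cell",
            "initialConcentration": format(float(getattr(init, name)), ".17g"),
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false", "constant": "false",
        })
    pars = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for name in model.rate_names:
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", attrib={
            "id": name, "value": format(float(getattr(model.rates, name)), ".17g"),
            "constant": "true",
        })
    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rid, kname, reactants, products in REACTIONS:
        rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction",
                           attrib={"id": rid, "reversible": "false"})
        lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
        for sp in reactants:
            ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference",
                          attrib={"species": sp, "stoichiometry": "1",
                                  "constant": "true"})
        lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
        for sp in products:
            ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference",
                          attrib={"species": sp, "stoichiometry": "1",
                                  "constant": "true"})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        apply_ = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply_, f"{{{MATHML_NS}}}times")
        for token in (kname, *reactants):
            ci = ET.SubElement(apply_, f"{{{MATHML_NS}}}ci")
            ci.text = token
    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    Path(path).write_text(text)
    return text


class SBMLModel:
    """A mass-action model reconstructed from an exported document."""

    def __init__(self, species, initial, parameters, reactions):
        self.species = species            # ordered ids
        self.initial = initial            # {id: concentration}
        self.parameters = parameters      # {id: value}
        self.reactions = reactions        # list of (k_name, reactants, products)

    def rhs(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        idx = {s: i for i, s in enumerate(self.species)}
        dy = np.zeros(len(self.species))
        for kname, reactants, products in self.reactions:
            flux = self.parameters[kname]
            for sp in reactants:
                flux *= y[idx[sp]]
            for sp in reactants:
                dy[idx[sp]] -= flux
            for sp in products:
                dy[idx[sp]] += flux
        return dy


def read_sbml(path) -> SBMLModel:
    """Parse an exported document back into a rate-evaluable model."""
    root = ET.parse(path).getroot()
    mdl = root.find(f"{{{SBML_NS}}}model")
    species = []
    initial = {}
    for sp in mdl.iter(f"{{{SBML_NS}}}species"):
        species.append(sp.get("id"))
        initial[sp.get("id")] = float(sp.get("initialConcentration"))
    parameters = {p.get("id"): float(p.get("value"))
                  for p in mdl.iter(f"{{{SBML_NS}}}parameter")}
    reactions = []
    for rx in mdl.iter(f"{{{SBML_NS}}}reaction"):
        reactants = [r.get("species")
                     for lor in rx.iter(f"{{{SBML_NS}}}listOfReactants")
                     for r in lor.iter(f"{{{SBML_NS}}}speciesReference")]
        products = [r.get("species")
                    for lop in rx.iter(f"{{{SBML_NS}}}listOfProducts")
                    for r in lop.iter(f"{{{SBML_NS}}}speciesReference")]
        cis = [ci.text.strip() for ci in rx.iter(f"{{{MATHML_NS}}}ci")]
        kname = next(t for t in cis if t in parameters)
        reactions.append((kname, reactants, products))
    return SBMLModel(species, initial, parameters, reactions)
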