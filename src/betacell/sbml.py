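"""Minimal SBML Level 3 Version 2 export.

Writes compartments, species (with boundaryCondition flags), global
parameters and reactions.  Kinetic laws are exported as MathML only for
templates with a closed algebraic form that maps cleanly onto MathML
(mass action); the other templates are annotated by name so that the
structural model remains interoperable.  Import is intentionally not
supported.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .network import NetworkModel

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(raw: str) -> str:
    """SBML identifiers must match [A-Za-z_][A-Za-z0-9_]*."""
    out = raw.replace("-", "_")
    if out and out[0].isdigit():
        out = "_" + out
    return out


def _mass_action_math(reaction, pm) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    apply_times = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    ET.SubElement(apply_times, f"{{{MATHML_NS}}}times")
    ci = ET.SubElement(apply_times, f"{{{MATHML_NS}}}ci")
    ci.text = _sid(pm["kf"])
    for sid, coeff in reaction.substrates.items():
        for _ in range(coeff):
            ci = ET.SubElement(apply_times, f"{{{MATHML_NS}}}ci")
            ci.text = _sid(sid)
    return math


def export_sbml(model: NetworkModel, path: str | Path) -> None:
    """Write the network as an SBML Level 3 document."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", attrib={"level": "3", "version": "2"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", attrib={"id": _sid(model.name)})

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for c in model.compartments:
        ET.SubElement(comps, f"{{{SBML_NS}}}compartment", attrib={
            "id": _sid(c.id), "size": str(c.relative_volume),
            "constant": "true", "spatialDimensions": "3",
        })

    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in model.species:
        init = s.initial_concentration
        ET.SubElement(sps, f"{{{SBML_NS}}}species", attrib={
            "id": _sid(s.id), "name": s.name, "compartment": _sid(s.compartment),
            "initialConcentration": str(init if not isinstance(init, str) else 0.0),
            "boundaryCondition": "true" if s.boundary else "false",
            "hasOnlySubstanceUnits": "false", "constant": "false",
        })

    if model.parameters is not None:
        pars = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
        for name, value in model.parameters.values.items():
            ET.SubElement(pars, f"{{{SBML_NS}}}parameter", attrib={
                "id": _sid(name), "value": str(value), "constant": "true",
            })

    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", attrib={
            "id": _sid(r.id), "reversible": "true" if r.reversible else "false",
            "name": f"{r.pathway}:{r.rate_law.template}",
        })
        if r.substrates:
            lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sid, coeff in r.substrates.items():
                ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference", attrib={
                    "species": _sid(sid), "stoichiometry": str(coeff), "constant": "true",
                })
        if r.products:
            lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sid, coeff in r.products.items():
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference", attrib={
                    "species": _sid(sid), "stoichiometry": str(coeff), "constant": "true",
                })
        if r.modifiers:
            lom = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for m in r.modifiers:
                ET.SubElement(lom, f"{{{SBML_NS}}}modifierSpeciesReference",
                              attrib={"species": _sid(m["species"])})
        if r.rate_law.template == "mass_action" and "kf" in r.rate_law.parameter_names:
            kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
            kl.append(_mass_action_math(r, r.rate_law.parameter_names))

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")
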