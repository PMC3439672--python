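"""Model serialization (YAML), SBML Level 3 export/import, and TSV writers.

The native model document is a YAML mapping with sections ``species``,
``reactions``, ``initial_concentrations`` and ``rates``; round-trips are
structurally exact (species order preserved, floats rendered at full repr
precision).  SBML export targets Level 3 Version 1 with explicit mass-action
kinetic laws; moiety composition and species roles ride along in a package
annotation namespace so that re-importing one of our own exports restores
the full :class:`~ssnm.network.NetworkModel`.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from typing import Dict, List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np
import yaml

from . import __version__
from .network import (
    NetworkModel,
    RateSet,
    Reaction,
    Species,
    Violation,
    rates_from_model,
    validate_model,
)

__all__ = [
    "ModelValidationError",
    "write_model",
    "read_model",
    "model_to_dict",
    "model_from_dict",
    "export_sbml",
    "import_sbml",
    "check_sbml",
    "write_table",
    "config_hash",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:ssnm:moieties"


class ModelValidationError(ValueError):
    """Raised when a parsed document violates model invariants."""

    def __init__(self, violations: List[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


def model_to_dict(model: NetworkModel, rates: Optional[RateSet] = None) -> dict:
    rates = rates if rates is not None else rates_from_model(model)
    return {
        "name": model.name,
        "readout_moiety": model.readout_moiety,
        "species": [
            {"name": s.name, "role": s.role, "moieties": dict(s.moieties)} for s in model.species
        ],
        "reactions": [
            {
                "label": r.label,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
            }
            for r in model.reactions
        ],
        "initial_concentrations": {
            s.name: float(model.initial_concentrations.get(s.name, 0.0)) for s in model.species
        },
        "rates": {lab: {"kf": float(kf), "kr": float(kr)} for lab, (kf, kr) in rates.items()},
    }


def model_from_dict(doc: dict) -> NetworkModel:
    try:
        rates = doc.get("rates", {})
        species = [
            Species(d["name"], {k: int(v) for k, v in d["moieties"].items()}, d.get("role", "monomer"))
            for d in doc["species"]
        ]
        reactions = []
        for d in doc["reactions"]:
            kf, kr = 0.0, 0.0
            if d["label"] in rates:
                kf = float(rates[d["label"]].get("kf", 0.0))
                kr = float(rates[d["label"]].get("kr", 0.0))
            reactions.append(
                Reaction(
                    d["label"],
                    {k: int(v) for k, v in d["reactants"].items()},
                    {k: int(v) for k, v in d["products"].items()},
                    kf,
                    kr,
                )
            )
        model = NetworkModel(
            name=doc.get("name", "model"),
            species=species,
            reactions=reactions,
            initial_concentrations={k: float(v) for k, v in doc["initial_concentrations"].items()},
            readout_moiety=doc["readout_moiety"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed model document: {exc!r}") from exc
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


def write_model(model: NetworkModel, path: str, rates: Optional[RateSet] = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model, rates), fh, sort_keys=False)


def read_model(path: str) -> NetworkModel:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return model_from_dict(doc)


# --- SBML -------------------------------------------------------------------


def _mathml_mass_action(reaction: Reaction, kf_id: str, kr_id: str) -> ET.Element:
    """<math> for kf·∏reactants − kr·∏products (in concentration units)."""

    def product(k_id: str, side: Dict[str, int]) -> ET.Element:
        times = ET.Element(f"{{{MATHML_NS}}}apply")
        ET.SubElement(times, f"{{{MATHML_NS}}}times")
        ci = ET.SubElement(times, f"{{{MATHML_NS}}}ci")
        ci.text = k_id
        for name, coeff in side.items():
            for _ in range(int(coeff)):
                ci = ET.SubElement(times, f"{{{MATHML_NS}}}ci")
                ci.text = name
        return times

    math = ET.Element(f"{{{MATHML_NS}}}math")
    if reaction.kr > 0:
        minus = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(minus, f"{{{MATHML_NS}}}minus")
        minus.append(product(kf_id, dict(reaction.reactants)))
        minus.append(product(kr_id, dict(reaction.products)))
    else:
        math.append(product(kf_id, dict(reaction.reactants)))
    return math


def export_sbml(model: NetworkModel, path: str, rates: Optional[RateSet] = None) -> None:
    """Write an SBML Level 3 Version 1 document with mass-action kinetics."""
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    rates = rates if rates is not None else rates_from_model(model)
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("ssnm", ANNOT_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": model.name or "model"})
    annot = ET.SubElement(mdl, f"{{{SBML_NS}}}annotation")
    meta = ET.SubElement(annot, f"{{{ANNOT_NS}}}ssnm")
    meta.set("readout_moiety", model.readout_moiety)
    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "size": "1", "spatialDimensions": "3", "constant": "true"},
    )
    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in model.species:
        el = ET.SubElement(
            sps,
            f"{{{SBML_NS}}}species",
            {
                "id": s.name,
                "compartment": "cell",
                "initialConcentration": repr(float(model.initial_concentrations.get(s.name, 0.0))),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
        sannot = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        smeta = ET.SubElement(sannot, f"{{{ANNOT_NS}}}ssnm")
        smeta.set("role", s.role)
        smeta.set("moieties", json.dumps(dict(s.moieties)))
    params = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for r in model.reactions:
        kf, kr = rates[r.label]
        ET.SubElement(
            params, f"{{{SBML_NS}}}parameter", {"id": f"kf_{r.label}", "value": repr(float(kf)), "constant": "true"}
        )
        ET.SubElement(
            params, f"{{{SBML_NS}}}parameter", {"id": f"kr_{r.label}", "value": repr(float(kr)), "constant": "true"}
        )
    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        el = ET.SubElement(
            rxns,
            f"{{{SBML_NS}}}reaction",
            {"id": r.label, "reversible": "true" if r.kr > 0 else "false", "fast": "false"},
        )
        lor = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
        for name, coeff in r.reactants.items():
            ET.SubElement(
                lor,
                f"{{{SBML_NS}}}speciesReference",
                {"species": name, "stoichiometry": str(int(coeff)), "constant": "true"},
            )
        lop = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
        for name, coeff in r.products.items():
            ET.SubElement(
                lop,
                f"{{{SBML_NS}}}speciesReference",
                {"species": name, "stoichiometry": str(int(coeff)), "constant": "true"},
            )
        kl = ET.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_mathml_mass_action(r, f"kf_{r.label}", f"kr_{r.label}"))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")


def import_sbml(path: str) -> NetworkModel:
    """Re-import one of this package's own SBML exports."""
    tree = ET.parse(path)
    mdl = tree.getroot().find(f"{{{SBML_NS}}}model")
    if mdl is None:
        raise ValueError(f"{path}: no <model> element")
    meta = mdl.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}ssnm")
    readout = meta.get("readout_moiety") if meta is not None else ""
    species, initials = [], {}
    for el in mdl.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        smeta = el.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}ssnm")
        moieties = json.loads(smeta.get("moieties")) if smeta is not None else {el.get("id"): 1}
        role = smeta.get("role") if smeta is not None else "monomer"
        species.append(Species(el.get("id"), {k: int(v) for k, v in moieties.items()}, role))
        initials[el.get("id")] = float(el.get("initialConcentration", "0"))
    pvals = {
        el.get("id"): float(el.get("value", "0"))
        for el in mdl.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")
    }
    reactions = []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        label = el.get("id")
        reactants: Dict[str, int] = {}
        products: Dict[str, int] = {}
        for sr in el.findall(f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"):
            reactants[sr.get("species")] = reactants.get(sr.get("species"), 0) + int(
                float(sr.get("stoichiometry", "1"))
            )
        for sr in el.findall(f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"):
            products[sr.get("species")] = products.get(sr.get("species"), 0) + int(
                float(sr.get("stoichiometry", "1"))
            )
        reactions.append(
            Reaction(label, reactants, products, pvals.get(f"kf_{label}", 0.0), pvals.get(f"kr_{label}", 0.0))
        )
    model = NetworkModel(
        name=mdl.get("id", "model"),
        species=species,
        reactions=reactions,
        initial_concentrations=initials,
        readout_moiety=readout,
    )
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


def check_sbml(path: str) -> List[str]:
    """Structural consistency check of an SBML document; empty list = clean.

    Verifies well-formed XML, unique species/reaction/parameter ids, that
    every species reference resolves, that every kinetic law only references
    declared ids, and that numeric attributes parse.
    """
    problems: List[str] = []
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        return [f"XML parse error: {exc}"]
    mdl = tree.getroot().find(f"{{{SBML_NS}}}model")
    if mdl is None:
        return ["no <model> element in SBML namespace"]
    sp_ids = [el.get("id") for el in mdl.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")]
    if len(sp_ids) != len(set(sp_ids)):
        problems.append("duplicate species ids")
    for el in mdl.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        try:
            float(el.get("initialConcentration", "0"))
        except ValueError:
            problems.append(f"species {el.get('id')}: bad initialConcentration")
    p_ids = [el.get("id") for el in mdl.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")]
    if len(p_ids) != len(set(p_ids)):
        problems.append("duplicate parameter ids")
    known = set(sp_ids) | set(p_ids)
    rx_ids = []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rx_ids.append(el.get("id"))
        for sr in el.iter(f"{{{SBML_NS}}}speciesReference"):
            if sr.get("species") not in sp_ids:
                problems.append(f"reaction {el.get('id')}: unresolved species {sr.get('species')!r}")
        for ci in el.iter(f"{{{MATHML_NS}}}ci"):
            if ci.text.strip() not in known:
                problems.append(f"reaction {el.get('id')}: kinetic law references unknown id {ci.text!r}")
    if len(rx_ids) != len(set(rx_ids)):
        problems.append("duplicate reaction ids")
    return problems


# --- tabular output ---------------------------------------------------------


def config_hash(config: dict) -> str:
    """Short stable hash of a run configuration for provenance lines."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df, path: str, config: Optional[dict] = None, seed: Optional[int] = None) -> None:
    """Write a TSV table with '#'-prefixed provenance comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# ssnm {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
            for k in sorted(config):
                fh.write(f"# config {k} = {config[k]}\n")
        if seed is not None:
            fh.write(f"# seed {seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
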