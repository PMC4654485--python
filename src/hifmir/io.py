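"""Model serialization: YAML (primary structured-text format) and SBML
Level 3 export/import.

The YAML document is a faithful dump of the registry tables (compartments,
species with initial uM, reactions with rate-law kinds and parameter ids,
parameter values/units/provenance) and round-trips losslessly.

The SBML writer emits Level 3 Version 2 core with kinetic laws as MathML;
since SBML has no notion of named rate-law kinds, each kineticLaw carries a
tool annotation (namespace ``https://hifmir.dev/sbml``) recording the kind
and the role->parameter mapping, which the importer reads back, making the
SBML round trip lossless as well.
"""

from __future__ import annotations

import yaml
from lxml import etree

from .errors import ModelDefinitionError
from .network import (
    Compartment,
    ModelDefinition,
    Parameter,
    ParameterSet,
    RATE_LAW_KINDS,
    RateLaw,
    Reaction,
    SpeciesDef,
)

__all__ = ["to_yaml", "from_yaml", "to_sbml", "from_sbml"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_ANN_NS = "https://hifmir.dev/sbml"


# ---------------------------------------------------------------------------
# YAML

def to_yaml(model: ModelDefinition) -> str:
    doc = {
        "compartments": [{"id": c.id, "label": c.label}
                         for c in model.compartments],
        "species": [{
            "id": s.id, "compartment": s.compartment, "role": s.role,
            "initial_uM": s.initial_concentration, "boundary": s.boundary,
            "label": s.label,
        } for s in model.species],
        "parameters": {
            pid: {"value": model.parameters[pid],
                  "units": model.parameters.info(pid).units,
                  "provenance": model.parameters.info(pid).provenance}
            for pid in model.parameters
        },
        "reactions": [_reaction_doc(r) for r in model.reactions],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _reaction_doc(r: Reaction) -> dict:
    doc = {
        "id": r.id,
        "group": r.group,
        "reactants": [[s, c] for s, c in r.reactants],
        "products": [[s, c] for s, c in r.products],
        "modifiers": list(r.modifiers),
        "rate_law": {"kind": r.rate_law.kind,
                     "parameters": dict(r.rate_law.parameters)},
        "description": r.description,
    }
    if r.reverse_rate_law is not None:
        doc["reverse_rate_law"] = {
            "kind": r.reverse_rate_law.kind,
            "parameters": dict(r.reverse_rate_law.parameters)}
    return doc


def from_yaml(text: str) -> ModelDefinition:
    doc = yaml.safe_load(text)
    compartments = tuple(Compartment(c["id"], c.get("label", ""))
                         for c in doc["compartments"])
    species = tuple(SpeciesDef(
        id=s["id"], compartment=s["compartment"], role=s["role"],
        initial_concentration=float(s["initial_uM"]),
        boundary=bool(s.get("boundary", False)), label=s.get("label", ""),
    ) for s in doc["species"])
    params = ParameterSet({
        pid: Parameter(value=float(p["value"]), units=p["units"],
                       provenance=p.get("provenance", "user"))
        for pid, p in doc["parameters"].items()
    })
    reactions = []
    for r in doc["reactions"]:
        rev = r.get("reverse_rate_law")
        reactions.append(Reaction(
            id=r["id"],
            reactants=tuple((s, int(c)) for s, c in r["reactants"]),
            products=tuple((s, int(c)) for s, c in r["products"]),
            modifiers=tuple(r.get("modifiers", ())),
            rate_law=RateLaw(r["rate_law"]["kind"],
                             dict(r["rate_law"]["parameters"])),
            reverse_rate_law=(RateLaw(rev["kind"], dict(rev["parameters"]))
                              if rev else None),
            group=r.get("group", "other"),
            description=r.get("description", ""),
        ))
    return ModelDefinition(compartments=compartments, species=species,
                           reactions=tuple(reactions), parameters=params)


# ---------------------------------------------------------------------------
# SBML L3

def _m(tag: str) -> str:
    return f"{{{_MATHML_NS}}}{tag}"


def _mathml_flux(kind: str, pmap: dict[str, str], species: list[str]) -> etree._Element:
    """MathML expression for one rate law (species = reactants then modifiers)."""
    def ci(name):
        el = etree.Element(_m("ci"))
        el.text = f" {name} "
        return el

    def apply(op, *args):
        el = etree.Element(_m("apply"))
        el.append(etree.Element(_m(op)))
        for a in args:
            el.append(a)
        return el

    def cn(v):
        el = etree.Element(_m("cn"))
        el.text = f" {v} "
        return el

    s = species
    if kind == "constant":
        return ci(pmap["k"])
    if kind == "mass_action_1":
        return apply("times", ci(pmap["k"]), ci(s[0]))
    if kind == "mass_action_2":
        return apply("times", ci(pmap["k"]), ci(s[0]), ci(s[1]))
    if kind == "michaelis_menten":
        return apply("divide",
                     apply("times", ci(pmap["vmax"]), ci(s[0])),
                     apply("plus", ci(pmap["km"]), ci(s[0])))
    if kind == "michaelis_menten_catalyzed":
        return apply("divide",
                     apply("times", ci(pmap["kcat"]), ci(s[-1]), ci(s[0])),
                     apply("plus", ci(pmap["km"]), ci(s[0])))
    if kind in ("hill_activation", "hill_activation_basal"):
        hill = apply("divide",
                     apply("times", ci(pmap["vmax"]),
                           apply("power", ci(s[0]), ci(pmap["n"]))),
                     apply("plus",
                           apply("power", ci(pmap["k"]), ci(pmap["n"])),
                           apply("power", ci(s[0]), ci(pmap["n"]))))
        if kind == "hill_activation_basal":
            return apply("plus", hill, ci(pmap["basal"]))
        return hill
    if kind == "hill_inhibition":
        return apply("divide",
                     apply("times", ci(pmap["vmax"]),
                           apply("power", ci(pmap["k"]), ci(pmap["n"]))),
                     apply("plus",
                           apply("power", ci(pmap["k"]), ci(pmap["n"])),
                           apply("power", ci(s[0]), ci(pmap["n"]))))
    if kind == "ma1_modulated":
        return apply("times", ci(pmap["k"]), ci(s[0]),
                     apply("plus", cn(1), apply("times", ci(pmap["a"]), ci(s[1]))))
    if kind == "ma1_saturating_activation":
        return apply("times", ci(pmap["k"]), ci(s[0]),
                     apply("plus", cn(1),
                           apply("divide",
                                 apply("times", ci(pmap["a"]), ci(s[1])),
                                 apply("plus", ci(pmap["ka"]), ci(s[1])))))
    if kind == "kd_dissociation":
        return apply("times", ci(pmap["kf"]), ci(pmap["kd"]), ci(s[0]))
    raise ModelDefinitionError(f"no MathML template for {kind!r}")


def to_sbml(model: ModelDefinition) -> str:
    nsmap = {None: _SBML_NS}
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap=nsmap,
                         attrib={"level": "3", "version": "2"})
    mdl = etree.SubElement(sbml, f"{{{_SBML_NS}}}model",
                           attrib={"id": "hif_let7_ago1_vegf",
                                   "timeUnits": "minute"})
    loc = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfCompartments")
    for c in model.compartments:
        etree.SubElement(loc, f"{{{_SBML_NS}}}compartment",
                         attrib={"id": c.id, "name": c.label or c.id,
                                 "constant": "true", "spatialDimensions": "3",
                                 "size": "1"})
    los = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfSpecies")
    for s in model.species:
        etree.SubElement(los, f"{{{_SBML_NS}}}species", attrib={
            "id": s.id, "name": s.label or s.id, "compartment": s.compartment,
            "initialConcentration": repr(s.initial_concentration),
            "boundaryCondition": "true" if s.boundary else "false",
            "hasOnlySubstanceUnits": "false", "constant": "false",
            "sboTerm": _ROLE_SBO.get(s.role, "SBO:0000240"),
        })
    lop = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfParameters")
    for pid in model.parameters:
        info = model.parameters.info(pid)
        etree.SubElement(lop, f"{{{_SBML_NS}}}parameter", attrib={
            "id": pid, "value": repr(info.value), "constant": "true",
            "name": f"{pid} [{info.units}] ({info.provenance})"})
    lor = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfReactions")
    for r in model.reactions:
        rx = etree.SubElement(lor, f"{{{_SBML_NS}}}reaction", attrib={
            "id": r.id, "reversible": "true" if r.reversible else "false",
            "name": r.description[:80]})
        if r.reactants:
            lo = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for sid, c in r.reactants:
                etree.SubElement(lo, f"{{{_SBML_NS}}}speciesReference",
                                 attrib={"species": sid, "stoichiometry": str(c),
                                         "constant": "true"})
        if r.products:
            lo = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for sid, c in r.products:
                etree.SubElement(lo, f"{{{_SBML_NS}}}speciesReference",
                                 attrib={"species": sid, "stoichiometry": str(c),
                                         "constant": "true"})
        if r.modifiers:
            lo = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfModifiers")
            for sid in r.modifiers:
                etree.SubElement(lo, f"{{{_SBML_NS}}}modifierSpeciesReference",
                                 attrib={"species": sid})
        kl = etree.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        ann = etree.SubElement(kl, f"{{{_SBML_NS}}}annotation")
        rl = etree.SubElement(ann, f"{{{_ANN_NS}}}rateLaw",
                              nsmap={"hifmir": _ANN_NS})
        rl.set("kind", r.rate_law.kind)
        rl.set("group", r.group)
        rl.set("description", r.description)
        for role, pid in r.rate_law.parameters.items():
            rl.set(f"p_{role}", pid)
        if r.reverse_rate_law is not None:
            rl.set("reverse_kind", r.reverse_rate_law.kind)
            for role, pid in r.reverse_rate_law.parameters.items():
                rl.set(f"rp_{role}", pid)
        math = etree.SubElement(kl, f"{{{_MATHML_NS}}}math",
                                nsmap={None: _MATHML_NS})
        fwd = _mathml_flux(r.rate_law.kind, dict(r.rate_law.parameters),
                           list(r.forward_rate_species()))
        if r.reverse_rate_law is None:
            math.append(fwd)
        else:
            rev = _mathml_flux(r.reverse_rate_law.kind,
                               dict(r.reverse_rate_law.parameters),
                               list(r.reverse_rate_species()))
            minus = etree.SubElement(math, _m("apply"))
            etree.SubElement(minus, _m("minus"))
            minus.append(fwd)
            minus.append(rev)
    return etree.tostring(sbml, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


_ROLE_SBO = {
    "mRNA": "SBO:0000278",
    "miR_precursor": "SBO:0000250",
    "miR_mature": "SBO:0000316",
    "protein": "SBO:0000252",
    "complex": "SBO:0000253",
    "small_molecule": "SBO:0000247",
    "perturbant": "SBO:0000247",
}
_SBO_ROLE = {v: k for k, v in _ROLE_SBO.items()}
_SBO_ROLE["SBO:0000247"] = "small_molecule"


def from_sbml(text: str) -> ModelDefinition:
    root = etree.fromstring(text.encode())
    mdl = root.find(f"{{{_SBML_NS}}}model")
    compartments = tuple(
        Compartment(c.get("id"), c.get("name", ""))
        for c in mdl.findall(f"{{{_SBML_NS}}}listOfCompartments/"
                             f"{{{_SBML_NS}}}compartment"))
    species = []
    for s in mdl.findall(f"{{{_SBML_NS}}}listOfSpecies/{{{_SBML_NS}}}species"):
        role = _SBO_ROLE.get(s.get("sboTerm", ""), "small_molecule")
        name = s.get("name", "")
        if role == "small_molecule" and s.get("id", "").startswith(
                ("CoCl2", "siRNA", "anti")) and ":" not in name:
            role = "perturbant"
        species.append(SpeciesDef(
            id=s.get("id"), compartment=s.get("compartment"), role=role,
            initial_concentration=float(s.get("initialConcentration", "0")),
            boundary=s.get("boundaryCondition") == "true",
            label=name))
    params = {}
    for p in mdl.findall(f"{{{_SBML_NS}}}listOfParameters/"
                         f"{{{_SBML_NS}}}parameter"):
        name = p.get("name", "")
        units, prov = "dimensionless", "user"
        if "[" in name and "]" in name:
            units = name.split("[", 1)[1].split("]", 1)[0]
        if "(" in name and ")" in name:
            prov = name.rsplit("(", 1)[1].rstrip(")")
        params[p.get("id")] = Parameter(float(p.get("value")), units, prov)
    reactions = []
    for rx in mdl.findall(f"{{{_SBML_NS}}}listOfReactions/"
                          f"{{{_SBML_NS}}}reaction"):
        def refs(tag):
            return tuple(
                (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
                for sr in rx.findall(f"{{{_SBML_NS}}}{tag}/"
                                     f"{{{_SBML_NS}}}speciesReference"))
        mods = tuple(
            sr.get("species")
            for sr in rx.findall(f"{{{_SBML_NS}}}listOfModifiers/"
                                 f"{{{_SBML_NS}}}modifierSpeciesReference"))
        ann = rx.find(f"{{{_SBML_NS}}}kineticLaw/{{{_SBML_NS}}}annotation/"
                      f"{{{_ANN_NS}}}rateLaw")
        if ann is None:
            raise ModelDefinitionError(
                f"reaction {rx.get('id')}: missing rate-law annotation; "
                "only hifmir-exported SBML can be imported losslessly")
        kind = ann.get("kind")
        pmap = {k[2:]: v for k, v in ann.attrib.items() if k.startswith("p_")}
        rkind = ann.get("reverse_kind")
        rpmap = {k[3:]: v for k, v in ann.attrib.items() if k.startswith("rp_")}
        reactions.append(Reaction(
            id=rx.get("id"), reactants=refs("listOfReactants"),
            products=refs("listOfProducts"), modifiers=mods,
            rate_law=RateLaw(kind, pmap),
            reverse_rate_law=RateLaw(rkind, rpmap) if rkind else None,
            group=ann.get("group", "other"),
            description=ann.get("description", "")))
    return ModelDefinition(compartments=compartments, species=tuple(species),
                           reactions=tuple(reactions),
                           parameters=ParameterSet(params))
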