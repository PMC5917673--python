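"""Read, write and merge metabolic network models.

Two dialects are supported: a minimal SBML Level 3 Version 2 core subset
(species, reactions, modifiers) and an internal JSON dialect that mirrors the
in-memory types one-to-one.  Enzyme/inhibitor roles of SBML modifiers are
resolved through SBO terms: SBO:0000460 ("enzymatic catalyst") maps to the
reaction's enzyme, SBO:0000020 ("inhibitor") to its inhibitor list, and an
unannotated modifier defaults to enzyme (BRENDA-style exports rarely carry
inhibitor annotations, and the default maximises mineable gates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .errors import IntegrityError, MergeConflictError, NetworkParseError

SPECIES_ROLES = ("metabolite", "enzyme", "reporter")

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
ANNOT_NS = "urn:protoforge:network"
SBO_CATALYST = "SBO:0000460"
SBO_INHIBITOR = "SBO:0000020"


@dataclass
class Species:
    """A molecular species: metabolite, enzyme or optical reporter."""

    id: str
    name: str = ""
    role: str = "metabolite"
    context_tag: str | None = None
    initial_concentration: float | None = None  # mol/L

    def __post_init__(self):
        if self.role not in SPECIES_ROLES:
            raise IntegrityError(
                f"species {self.id!r}: role {self.role!r} not in {SPECIES_ROLES}")
        if self.initial_concentration is not None and self.initial_concentration < 0:
            raise IntegrityError(
                f"species {self.id!r}: negative initial concentration")


@dataclass
class Reaction:
    """An (optionally enzyme-catalysed) irreversible reaction.

    ``substrates`` and ``products`` are lists of ``(species_id, stoich)`` with
    positive integer stoichiometric coefficients.  ``rate_law`` is an opaque
    reference resolved by the kinetics module and may be None at parse time.
    """

    id: str
    substrates: list[tuple[str, int]]
    products: list[tuple[str, int]]
    enzyme: str | None = None
    inhibitors: list[str] = field(default_factory=list)
    rate_law: object | None = None

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise IntegrityError(
                f"reaction {self.id!r}: substrates and products must be non-empty")
        for sid, coeff in [*self.substrates, *self.products]:
            if not (isinstance(coeff, int) and coeff >= 1):
                raise IntegrityError(
                    f"reaction {self.id!r}: stoichiometry of {sid!r} must be a "
                    f"positive integer, got {coeff!r}")

    def signature(self) -> tuple:
        """Deduplication key: (sorted substrates, sorted products, enzyme)."""
        return (tuple(sorted(self.substrates)),
                tuple(sorted(self.products)),
                self.enzyme)

    def participant_ids(self) -> set[str]:
        ids = {sid for sid, _ in self.substrates} | {sid for sid, _ in self.products}
        ids |= set(self.inhibitors)
        if self.enzyme is not None:
            ids.add(self.enzyme)
        return ids


@dataclass
class NetworkModel:
    """Species + reactions; the substrate mined for logic gates."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def validate(self) -> None:
        seen = set()
        for s in self.species:
            if s.id in seen:
                raise IntegrityError(f"duplicate species id {s.id!r}")
            seen.add(s.id)
        rseen = set()
        dangling = []
        for r in self.reactions:
            if r.id in rseen:
                raise IntegrityError(f"duplicate reaction id {r.id!r}")
            rseen.add(r.id)
            for sid in sorted(r.participant_ids()):
                if sid not in seen:
                    dangling.append((r.id, sid))
        if dangling:
            detail = ", ".join(f"{rid}->{sid}" for rid, sid in dangling)
            raise IntegrityError(f"dangling species references: {detail}")

    def canonical(self) -> dict:
        """Order-insensitive plain representation used for structural equality."""
        return {
            "species": sorted(
                ({"id": s.id, "name": s.name, "role": s.role,
                  "context_tag": s.context_tag,
                  "initial_concentration": s.initial_concentration}
                 for s in self.species), key=lambda d: d["id"]),
            "reactions": sorted(
                ({"id": r.id,
                  "substrates": sorted(map(list, r.substrates)),
                  "products": sorted(map(list, r.products)),
                  "enzyme": r.enzyme,
                  "inhibitors": sorted(r.inhibitors)}
                 for r in self.reactions), key=lambda d: d["id"]),
        }


def structurally_equal(a: NetworkModel, b: NetworkModel) -> bool:
    """Equality up to list ordering; metadata (provenance) is not compared."""
    return a.canonical() == b.canonical()


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_json_obj(model: NetworkModel) -> dict:
    return {
        "species": [
            {"id": s.id, "name": s.name, "role": s.role,
             "context_tag": s.context_tag,
             "initial_concentration": s.initial_concentration}
            for s in model.species],
        "reactions": [
            {"id": r.id, "substrates": [list(t) for t in r.substrates],
             "products": [list(t) for t in r.products],
             "enzyme": r.enzyme, "inhibitors": list(r.inhibitors)}
            for r in model.reactions],
        "metadata": model.metadata,
    }


def _model_from_json_obj(obj: dict) -> NetworkModel:
    try:
        species = [Species(id=d["id"], name=d.get("name", ""),
                           role=d.get("role", "metabolite"),
                           context_tag=d.get("context_tag"),
                           initial_concentration=d.get("initial_concentration"))
                   for d in obj.get("species", [])]
        reactions = [Reaction(id=d["id"],
                              substrates=[(s, int(c)) for s, c in d["substrates"]],
                              products=[(s, int(c)) for s, c in d["products"]],
                              enzyme=d.get("enzyme"),
                              inhibitors=list(d.get("inhibitors", [])))
                     for d in obj.get("reactions", [])]
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkParseError(f"malformed JSON network: {exc}") from exc
    return NetworkModel(species=species, reactions=reactions,
                        metadata=dict(obj.get("metadata", {})))


# ---------------------------------------------------------------------------
# SBML dialect (minimal L3V2 core subset)
# ---------------------------------------------------------------------------

def _q(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _model_to_sbml(model: NetworkModel) -> etree._ElementTree:
    nsmap = {None: SBML_NS, "pf": ANNOT_NS}
    sbml = etree.Element(_q("sbml"), nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(sbml, _q("model"), id="protoforge_model")

    comps = etree.SubElement(mdl, _q("listOfCompartments"))
    etree.SubElement(comps, _q("compartment"), id="interior", constant="true")

    if model.species:
        los = etree.SubElement(mdl, _q("listOfSpecies"))
        for s in model.species:
            attrs = {"id": s.id, "compartment": "interior",
                     "hasOnlySubstanceUnits": "false",
                     "boundaryCondition": "false", "constant": "false"}
            if s.name:
                attrs["name"] = s.name
            if s.initial_concentration is not None:
                attrs["initialConcentration"] = repr(s.initial_concentration)
            el = etree.SubElement(los, _q("species"), **attrs)
            annot = etree.SubElement(el, _q("annotation"))
            info = etree.SubElement(annot, f"{{{ANNOT_NS}}}speciesInfo")
            info.set("role", s.role)
            if s.context_tag is not None:
                info.set("contextTag", s.context_tag)

    if model.reactions:
        lor = etree.SubElement(mdl, _q("listOfReactions"))
        for r in model.reactions:
            rel = etree.SubElement(lor, _q("reaction"), id=r.id,
                                   reversible="false")
            lreac = etree.SubElement(rel, _q("listOfReactants"))
            for sid, coeff in r.substrates:
                etree.SubElement(lreac, _q("speciesReference"), species=sid,
                                 stoichiometry=str(coeff), constant="true")
            lprod = etree.SubElement(rel, _q("listOfProducts"))
            for sid, coeff in r.products:
                etree.SubElement(lprod, _q("speciesReference"), species=sid,
                                 stoichiometry=str(coeff), constant="true")
            if r.enzyme is not None or r.inhibitors:
                lmod = etree.SubElement(rel, _q("listOfModifiers"))
                if r.enzyme is not None:
                    etree.SubElement(lmod, _q("modifierSpeciesReference"),
                                     species=r.enzyme, sboTerm=SBO_CATALYST)
                for sid in r.inhibitors:
                    etree.SubElement(lmod, _q("modifierSpeciesReference"),
                                     species=sid, sboTerm=SBO_INHIBITOR)
    return etree.ElementTree(sbml)


def _parse_float(text, what, line):
    try:
        return float(text)
    except ValueError:
        raise NetworkParseError(f"line {line}: bad {what}: {text!r}")


def _model_from_sbml(tree: etree._ElementTree) -> NetworkModel:
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise NetworkParseError(
            f"line {root.sourceline}: root element is "
            f"{etree.QName(root).localname!r}, expected 'sbml'")
    ns = etree.QName(root).namespace
    mdl = root.find(f"{{{ns}}}model")
    if mdl is None:
        raise NetworkParseError("no <model> element found")

    species = []
    for el in mdl.findall(f"{{{ns}}}listOfSpecies/{{{ns}}}species"):
        sid = el.get("id")
        if sid is None:
            raise NetworkParseError(f"line {el.sourceline}: species without id")
        role, tag = "metabolite", None
        info = el.find(f"{{{ns}}}annotation/{{{ANNOT_NS}}}speciesInfo")
        if info is not None:
            role = info.get("role", "metabolite")
            tag = info.get("contextTag")
        conc = el.get("initialConcentration")
        species.append(Species(
            id=sid, name=el.get("name", ""), role=role, context_tag=tag,
            initial_concentration=None if conc is None
            else _parse_float(conc, "initialConcentration", el.sourceline)))

    reactions = []
    for el in mdl.findall(f"{{{ns}}}listOfReactions/{{{ns}}}reaction"):
        rid = el.get("id")
        if rid is None:
            raise NetworkParseError(f"line {el.sourceline}: reaction without id")

        def refs(kind):
            out = []
            for ref in el.findall(f"{{{ns}}}{kind}/{{{ns}}}speciesReference"):
                coeff = _parse_float(ref.get("stoichiometry", "1"),
                                     "stoichiometry", ref.sourceline)
                out.append((ref.get("species"), int(round(coeff))))
            return out

        enzyme, inhibitors = None, []
        for ref in el.findall(
                f"{{{ns}}}listOfModifiers/{{{ns}}}modifierSpeciesReference"):
            if ref.get("sboTerm") == SBO_INHIBITOR:
                inhibitors.append(ref.get("species"))
            else:  # catalyst SBO term or unannotated modifier
                enzyme = ref.get("species")
        try:
            reactions.append(Reaction(id=rid, substrates=refs("listOfReactants"),
                                      products=refs("listOfProducts"),
                                      enzyme=enzyme, inhibitors=inhibitors))
        except IntegrityError as exc:
            raise NetworkParseError(f"line {el.sourceline}: {exc}") from exc

    return NetworkModel(species=species, reactions=reactions, metadata={})


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def read_network(path: str | Path, dialect: str = "json") -> NetworkModel:
    """Load a network file and validate referential integrity."""
    path = Path(path)
    if dialect == "json":
        try:
            obj = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise NetworkParseError(
                f"{path}: line {exc.lineno}: {exc.msg}") from exc
        model = _model_from_json_obj(obj)
    elif dialect == "sbml":
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise NetworkParseError(f"{path}: {exc}") from exc
        model = _model_from_sbml(tree)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    model.metadata.setdefault("source", str(path))
    model.validate()
    return model


def write_network(model: NetworkModel, path: str | Path,
                  dialect: str = "json") -> None:
    """Serialize a model; the emitted file re-reads to a structurally equal model."""
    model.validate()
    path = Path(path)
    if dialect == "json":
        path.write_text(json.dumps(_model_to_json_obj(model), indent=1),
                        encoding="utf-8")
    elif dialect == "sbml":
        _model_to_sbml(model).write(str(path), pretty_print=True,
                                    xml_declaration=True, encoding="UTF-8")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def merge_networks(models: list[NetworkModel]) -> NetworkModel:
    """Union species by id and deduplicate reactions by signature.

    Species identity is by id string only (no name-based fuzzy matching);
    conflicting role declarations for the same id raise MergeConflictError.
    """
    if not models:
        raise ValueError("merge_networks requires at least one model")
    species: dict[str, Species] = {}
    conflicts = []
    for m in models:
        for s in m.species:
            prev = species.get(s.id)
            if prev is None:
                species[s.id] = s
            elif prev.role != s.role:
                conflicts.append(s.id)
    if conflicts:
        raise MergeConflictError(
            f"conflicting roles for species: {sorted(set(conflicts))}")

    reactions: dict[tuple, Reaction] = {}
    rids = set()
    for m in models:
        for r in m.reactions:
            sig = r.signature()
            if sig in reactions:
                continue
            rid = r.id
            k = 1
            while rid in rids:  # disambiguate colliding ids of distinct reactions
                rid = f"{r.id}__{k}"
                k += 1
            rids.add(rid)
            reactions[sig] = Reaction(id=rid, substrates=list(r.substrates),
                                      products=list(r.products), enzyme=r.enzyme,
                                      inhibitors=list(r.inhibitors),
                                      rate_law=r.rate_law)

    merged = NetworkModel(
        species=sorted(species.values(), key=lambda s: s.id),
        reactions=sorted(reactions.values(), key=lambda r: r.id),
        metadata={"merged_from": [m.metadata.get("source", f"model_{i}")
                                  for i, m in enumerate(models)]})
    merged.validate()
    return merged
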