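"""Machine-readable CG and PC type systems and document validation.

The Cancer Genetics (CG) task annotates 18 entity types spanning molecular
to organism-level anatomy, and ~40 event types grouped into anatomical,
pathological, molecular, general, regulation and planned categories, with
Gene Ontology as the main reference. The Pathway Curation (PC) task
annotates 4 molecular entity types and an SBO-aligned event inventory
(simple / general / regulation categories).

Each event type licenses a set of roles. *Core* roles are the ones that
define the event for matching purposes; *additional* roles (Site, location
roles, ...) refine it. Role multiplicity follows the task tables' notation:
bare = exactly one, ``?`` = optional, ``+`` = one or more, ``*`` = zero or
more. Unmarked additional roles are read as optional (a mandatory
"additional" argument would contradict the category's definition).

Filler categories (which entity types may fill a role, e.g. "Molecule" or
"Anatomy") are not exhaustively enumerated by the task description; the
tables shipped here are a documented best effort, exportable to YAML and
overridable without code changes. Category-membership findings are
therefore reported as warnings, structural findings as errors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import yaml

from .standoff import Document, Violation

MULTIPLICITIES = ("one", "optional", "one_or_more", "zero_or_more")
_MARKER = {"": "one", "?": "optional", "+": "one_or_more", "*": "zero_or_more"}
ROLES = (
    "Theme", "Cause", "Participant", "Product", "Instrument",
    "Site", "AtLoc", "FromLoc", "ToLoc",
)
MODIFICATION_TYPES = ("Negation", "Speculation")


def role_base(role_label: str) -> str:
    """Strip the numeric slot suffix from a role label ('Theme2' -> 'Theme')."""
    if not role_label:
        raise ValueError("empty role label")
    base = role_label.rstrip("0123456789")
    if not base:
        raise ValueError(f"role label {role_label!r} is all digits")
    return base


@dataclass(frozen=True)
class FillerCategory:
    name: str
    entity_types: frozenset[str]
    allows_events: bool = False

    def admits_entity(self, entity_type: str) -> bool:
        return entity_type in self.entity_types


@dataclass(frozen=True)
class RoleSpec:
    role: str
    filler: str  # FillerCategory name
    multiplicity: str  # one of MULTIPLICITIES
    core: bool

    @property
    def required(self) -> bool:
        return self.multiplicity in ("one", "one_or_more")

    @property
    def repeatable(self) -> bool:
        return self.multiplicity in ("one_or_more", "zero_or_more")


@dataclass(frozen=True)
class EventTypeSpec:
    name: str
    category: str
    roles: tuple[RoleSpec, ...]

    def role_spec(self, role: str) -> RoleSpec | None:
        for spec in self.roles:
            if spec.role == role:
                return spec
        return None

    @property
    def core_roles(self) -> frozenset[str]:
        return frozenset(r.role for r in self.roles if r.core)


@dataclass(frozen=True)
class TaskSchema:
    task: str  # "CG" | "PC"
    entity_types: frozenset[str]
    categories: Mapping[str, FillerCategory]
    event_types: Mapping[str, EventTypeSpec]
    modification_types: tuple[str, ...] = MODIFICATION_TYPES

    def is_event_type(self, name: str) -> bool:
        return name in self.event_types

    def core_roles(self, event_type: str) -> frozenset[str]:
        return self.event_types[event_type].core_roles

    def event_categories(self) -> list[str]:
        seen: list[str] = []
        for spec in self.event_types.values():
            if spec.category not in seen:
                seen.append(spec.category)
        return seen


# ---------------------------------------------------------------------------
# built-in type systems

_ROLE_RE = re.compile(r"^([A-Za-z]+)([?+*]?)\(([^)]+)\)$")


def _roles(core: str, additional: str = "") -> tuple[RoleSpec, ...]:
    out = []
    for part, is_core in [(core, True), (additional, False)]:
        for token in filter(None, (t.strip() for t in part.split(","))):
            m = _ROLE_RE.match(token)
            if not m:  # pragma: no cover - table definitions are static
                raise ValueError(f"bad role token {token!r}")
            role, marker, filler = m.groups()
            mult = _MARKER[marker]
            if not is_core and marker == "":
                mult = "optional"
            out.append(RoleSpec(role, filler, mult, is_core))
    return tuple(out)


_CG_ANATOMICAL_ENTITIES = (
    "Organism subdivision", "Anatomical system", "Organ",
    "Multi-tissue structure", "Tissue", "Developing anatomical structure",
    "Cell", "Cellular component", "Organism substance",
    "Immaterial anatomical entity", "Pathological formation", "Cancer",
)
_CG_ENTITY_TYPES = ("Organism",) + _CG_ANATOMICAL_ENTITIES + (
    "Gene or gene product", "Protein domain or region", "DNA domain or region",
    "Simple chemical", "Amino acid",
)
_CG_MOLECULE = (
    "Gene or gene product", "Simple chemical", "Amino acid",
    "Protein domain or region", "DNA domain or region",
)
_CG_SITE = ("Protein domain or region", "DNA domain or region", "Amino acid")

# CG chemical-modification family, defined like Phosphorylation
_CG_CHEMMOD = (
    "Phosphorylation", "Dephosphorylation", "Acetylation", "Glycosylation",
    "Ubiquitination", "DNA methylation", "DNA demethylation",
)

_CG_EVENTS: list[tuple[str, str, str, str]] = [
    # (name, category, core roles, additional roles)
    ("Development", "anatomical", "Theme(Anatomy)", ""),
    ("Blood vessel development", "anatomical", "Theme?(Anatomy)", "AtLoc?(Location)"),
    ("Growth", "anatomical", "Theme(Anatomy)", ""),
    ("Death", "anatomical", "Theme(Anatomy)", ""),
    ("Cell death", "anatomical", "Theme?(Cell)", ""),
    ("Breakdown", "anatomical", "Theme(Anatomy)", ""),
    ("Cell proliferation", "anatomical", "Theme(Cell)", ""),
    ("Cell division", "anatomical", "Theme(Cell)", ""),
    ("Cell differentiation", "anatomical", "Theme(Cell)", "AtLoc?(Location)"),
    ("Remodeling", "anatomical", "Theme(Tissue)", ""),
    ("Reproduction", "anatomical", "Theme(Organism)", ""),
    ("Mutation", "pathological", "Theme(GGP)", "AtLoc?(Location), Site?(Site region)"),
    ("Carcinogenesis", "pathological", "Theme?(Anatomy)", "AtLoc?(Location)"),
    ("Cell transformation", "pathological", "Theme(Cell)", "AtLoc?(Location)"),
    ("Metastasis", "pathological", "Theme?(Anatomy)", "ToLoc(Location)"),
    ("Infection", "pathological", "Theme?(Anatomy), Participant?(Organism)", ""),
    ("Metabolism", "molecular", "Theme(Molecule)", ""),
    ("Synthesis", "molecular", "Theme(Simple chemical)", ""),
    ("Catabolism", "molecular", "Theme(Molecule)", ""),
    ("Amino acid catabolism", "molecular", "Theme?(Molecule)", ""),
    ("Glycolysis", "molecular", "Theme?(Molecule)", ""),
    ("Gene expression", "molecular", "Theme+(GGP)", ""),
    ("Transcription", "molecular", "Theme(GGP)", ""),
    ("Translation", "molecular", "Theme(GGP)", ""),
    ("Protein processing", "molecular", "Theme(GGP)", ""),
    *[(name, "molecular", "Theme(Molecule)", "Site?(Site region)") for name in _CG_CHEMMOD],
    ("Pathway", "molecular", "Participant(Molecule)", ""),
    ("Binding", "general", "Theme+(Molecule)", "Site?(Site region)"),
    ("Dissociation", "general", "Theme(Molecule)", "Site?(Site region)"),
    ("Localization", "general", "Theme+(Molecule)",
     "AtLoc?(Location), FromLoc?(Location), ToLoc?(Location)"),
    ("Regulation", "regulation", "Theme(Any), Cause?(Any)", ""),
    ("Positive regulation", "regulation", "Theme(Any), Cause?(Any)", ""),
    ("Negative regulation", "regulation", "Theme(Any), Cause?(Any)", ""),
    ("Planned process", "planned", "Theme*(Any), Instrument*(Entity)", ""),
]

_PC_ENTITY_TYPES = (
    "Simple chemical", "Gene or gene product", "Complex", "Cellular component",
)
_PC_MOLECULE = ("Simple chemical", "Gene or gene product", "Complex")

# PC covalent-modification family, defined like Phosphorylation
_PC_CHEMMOD = (
    "Phosphorylation", "Dephosphorylation", "Acetylation", "Deacetylation",
    "Methylation", "Demethylation", "Ubiquitination", "Deubiquitination",
)

_PC_EVENTS: list[tuple[str, str, str, str]] = [
    ("Conversion", "simple", "Theme(Molecule), Product(Molecule)", ""),
    *[(name, "simple", "Theme(Molecule), Cause(Molecule)", "Site?(Simple chemical cat)")
      for name in _PC_CHEMMOD],
    ("Localization", "simple", "Theme(Molecule)",
     "AtLoc?(Cellular component cat), FromLoc?(Cellular component cat), "
     "ToLoc?(Cellular component cat)"),
    ("Transport", "simple", "Theme(Molecule)",
     "FromLoc?(Cellular component cat), ToLoc?(Cellular component cat)"),
    ("Gene expression", "simple", "Theme(GGP)", ""),
    ("Transcription", "simple", "Theme(GGP)", ""),
    ("Translation", "simple", "Theme(GGP)", ""),
    ("Degradation", "general", "Theme(Molecule)", ""),
    ("Binding", "general", "Theme(Molecule), Product(Complex cat)", ""),
    ("Dissociation", "general", "Theme(Complex cat), Product(Molecule)", ""),
    ("Activation", "general", "Theme(Molecule), Cause(Any)", ""),
    ("Inactivation", "general", "Theme(Molecule), Cause(Any)", ""),
    ("Pathway", "general", "Participant(Molecule)", ""),
    ("Regulation", "regulation", "Theme(Any), Cause(Any)", ""),
    ("Positive regulation", "regulation", "Theme(Any), Cause(Any)", ""),
    ("Negative regulation", "regulation", "Theme(Any), Cause(Any)", ""),
]


def _categories(defs: dict[str, tuple[Iterable[str], bool]]) -> dict[str, FillerCategory]:
    return {
        name: FillerCategory(name, frozenset(types), allows_events)
        for name, (types, allows_events) in defs.items()
    }


def _build(task: str, entity_types: tuple[str, ...],
           categories: dict[str, FillerCategory],
           events: list[tuple[str, str, str, str]]) -> TaskSchema:
    event_types = {
        name: EventTypeSpec(name, category, _roles(core, extra))
        for name, category, core, extra in events
    }
    return TaskSchema(
        task=task,
        entity_types=frozenset(entity_types),
        categories=categories,
        event_types=event_types,
    )


def builtin_schema(task: str) -> TaskSchema:
    """Return the complete built-in CG or PC type system."""
    task = task.upper()
    if task == "CG":
        cats = _categories({
            "Anatomy": (_CG_ANATOMICAL_ENTITIES, False),
            "Cell": (("Cell",), False),
            "Tissue": (("Tissue",), False),
            "Organism": (("Organism",), False),
            "GGP": (("Gene or gene product",), False),
            "Molecule": (_CG_MOLECULE, False),
            "Simple chemical": (("Simple chemical",), False),
            "Site region": (_CG_SITE, False),
            "Location": (_CG_ANATOMICAL_ENTITIES, False),
            "Entity": (_CG_ENTITY_TYPES, False),
            "Any": (_CG_ENTITY_TYPES, True),
        })
        return _build("CG", _CG_ENTITY_TYPES, cats, _CG_EVENTS)
    if task == "PC":
        cats = _categories({
            "Molecule": (_PC_MOLECULE, False),
            "GGP": (("Gene or gene product",), False),
            "Simple chemical cat": (("Simple chemical",), False),
            "Complex cat": (("Complex",), False),
            "Cellular component cat": (("Cellular component",), False),
            "Entity": (_PC_ENTITY_TYPES, False),
            "Any": (_PC_ENTITY_TYPES, True),
        })
        return _build("PC", _PC_ENTITY_TYPES, cats, _PC_EVENTS)
    raise ValueError(f"unknown task {task!r}: expected CG or PC")


# ---------------------------------------------------------------------------
# validation


def validate(doc: Document, schema: TaskSchema) -> list[Violation]:
    """Check a (reference-consistent) document against the type system.

    Structural problems (unknown types, unlicensed roles, multiplicity,
    event fillers where only entities are allowed, Equiv over events) are
    errors; filler-category membership findings are warnings because the
    category tables are a documented approximation.
    """
    out: list[Violation] = []
    entities = doc.entity_map()
    events = doc.event_map()
    triggers = doc.trigger_map()

    for ent in doc.entities:
        if ent.type not in schema.entity_types:
            out.append(Violation("unknown-entity-type", ent.id,
                                 f"entity type {ent.type!r} not in {schema.task} schema"))

    for trig in doc.triggers:
        if not schema.is_event_type(trig.type):
            out.append(Violation("trigger-not-event-type", trig.id,
                                 f"trigger type {trig.type!r} is not a {schema.task} event type"))

    for ev in doc.events:
        spec = schema.event_types.get(ev.type)
        if spec is None:
            out.append(Violation("unknown-event-type", ev.id,
                                 f"event type {ev.type!r} not in {schema.task} schema"))
            continue
        trig = triggers.get(ev.trigger_id)
        if trig is not None and trig.type != ev.type:
            out.append(Violation("trigger-type-mismatch", ev.id,
                                 f"event type {ev.type!r} != trigger type {trig.type!r}"))
        counts: dict[str, int] = {}
        for arg in ev.args:
            base = role_base(arg.role_label)
            counts[base] = counts.get(base, 0) + 1
            rspec = spec.role_spec(base)
            if rspec is None:
                out.append(Violation("unlicensed-role", ev.id,
                                     f"role {base} not licensed for {ev.type}"))
                continue
            category = schema.categories[rspec.filler]
            if arg.filler_id in events:
                if not category.allows_events:
                    out.append(Violation("entity-filler-required", ev.id,
                                         f"{base} of {ev.type} must be an entity, "
                                         f"got event {arg.filler_id}"))
            elif arg.filler_id in entities:
                etype = entities[arg.filler_id].type
                if not category.admits_entity(etype):
                    out.append(Violation(
                        "filler-category", ev.id,
                        f"{base} filler {arg.filler_id} has type {etype!r}, outside "
                        f"category {category.name}", severity="warning"))
        for rspec in spec.roles:
            n = counts.get(rspec.role, 0)
            if rspec.required and n == 0:
                out.append(Violation("missing-required-role", ev.id,
                                     f"{ev.type} requires a {rspec.role} argument"))
            if n > 1 and not rspec.repeatable:
                out.append(Violation("repeated-role", ev.id,
                                     f"role {rspec.role} of {ev.type} filled {n} times"))

    for mod in doc.modifications:
        if mod.type not in schema.modification_types:
            out.append(Violation("unknown-modification-type", mod.id,
                                 f"modification type {mod.type!r} unknown"))

    for group in doc.equivs:
        for member in group.member_ids:
            if member in events:
                out.append(Violation("equiv-contains-event", member,
                                     "Equiv groups may contain only entity mentions"))
    return out


# ---------------------------------------------------------------------------
# YAML round-trip (category tables are meant to be user-adjustable)


def schema_to_yaml(schema: TaskSchema) -> str:
    data = {
        "task": schema.task,
        "entity_types": sorted(schema.entity_types),
        "categories": {
            c.name: {"entity_types": sorted(c.entity_types),
                     "allows_events": c.allows_events}
            for c in schema.categories.values()
        },
        "event_types": {
            spec.name: {
                "category": spec.category,
                "roles": [
                    {"role": r.role, "filler": r.filler,
                     "multiplicity": r.multiplicity, "core": r.core}
                    for r in spec.roles
                ],
            }
            for spec in schema.event_types.values()
        },
        "modification_types": list(schema.modification_types),
    }
    return yaml.safe_dump(data, sort_keys=False)


def schema_from_yaml(text: str) -> TaskSchema:
    data = yaml.safe_load(text)
    categories = {
        name: FillerCategory(name, frozenset(info["entity_types"]),
                             bool(info.get("allows_events", False)))
        for name, info in data["categories"].items()
    }
    event_types = {}
    for name, info in data["event_types"].items():
        roles = tuple(
            RoleSpec(r["role"], r["filler"], r["multiplicity"], bool(r["core"]))
            for r in info["roles"]
        )
        for r in roles:
            if r.multiplicity not in MULTIPLICITIES:
                raise ValueError(f"bad multiplicity {r.multiplicity!r} in {name}")
            if r.filler not in categories:
                raise ValueError(f"unknown filler category {r.filler!r} in {name}")
        event_types[name] = EventTypeSpec(name, info["category"], roles)
    return TaskSchema(
        task=data["task"],
        entity_types=frozenset(data["entity_types"]),
        categories=categories,
        event_types=event_types,
        modification_types=tuple(data.get("modification_types", MODIFICATION_TYPES)),
    )
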