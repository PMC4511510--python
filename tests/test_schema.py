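"""Built-in CG/PC type systems and schema validation."""

import pytest

from bionlpeval.schema import (
    builtin_schema,
    role_base,
    schema_from_yaml,
    schema_to_yaml,
    validate,
)
from bionlpeval.reported import PC_PRIMARY_BY_TYPE
from bionlpeval.synthetic import GeneratorConfig, generate

# every event type appearing in the published per-type CG result breakdown
CG_RESULT_TYPES = [
    "Development", "Blood vessel development", "Growth", "Death", "Cell death",
    "Cell proliferation", "Cell division", "Cell differentiation", "Remodeling",
    "Reproduction", "Mutation", "Carcinogenesis", "Cell transformation",
    "Breakdown", "Metastasis", "Infection", "Metabolism", "Synthesis",
    "Catabolism", "Glycolysis", "Amino acid catabolism", "Gene expression",
    "Transcription", "Translation", "Protein processing", "Acetylation",
    "Glycosylation", "Phosphorylation", "Ubiquitination", "Dephosphorylation",
    "DNA methylation", "DNA demethylation", "Pathway", "Binding",
    "Dissociation", "Localization", "Regulation", "Positive regulation",
    "Negative regulation", "Planned process",
]


def test_pc_has_exactly_four_entity_types(pc_schema):
    assert pc_schema.entity_types == {
        "Simple chemical", "Gene or gene product", "Complex", "Cellular component",
    }


def test_cg_has_eighteen_entity_types(cg_schema):
    assert len(cg_schema.entity_types) == 18
    assert "Cancer" in cg_schema.entity_types
    assert "Complex" not in cg_schema.entity_types  # PC-only type


def test_pc_binding_takes_theme_molecule_and_product_complex(pc_schema):
    roles = pc_schema.event_types["Binding"].roles
    themes = [r for r in roles if r.role == "Theme"]
    products = [r for r in roles if r.role == "Product"]
    assert themes[0].filler == "Molecule" and themes[0].core
    assert products[0].core
    assert pc_schema.categories[products[0].filler].entity_types == {"Complex"}


def test_cg_never_uses_product_and_pc_never_uses_instrument(cg_schema, pc_schema):
    cg_roles = {r.role for s in cg_schema.event_types.values() for r in s.roles}
    pc_roles = {r.role for s in pc_schema.event_types.values() for r in s.roles}
    assert "Product" not in cg_roles
    assert "Instrument" in cg_roles
    assert "Instrument" not in pc_roles
    assert "Product" in pc_roles


def test_every_published_cg_event_type_resolves(cg_schema):
    missing = [t for t in CG_RESULT_TYPES if t not in cg_schema.event_types]
    assert missing == []


def test_every_published_pc_event_type_resolves(pc_schema):
    subtotals = {"Simple total", "General total", "Regulation total", "Sub-total",
                 "Modification total", "TOTAL", "Negation", "Speculation"}
    type_labels = {e.label for e in PC_PRIMARY_BY_TYPE} - subtotals
    missing = [t for t in sorted(type_labels) if t not in pc_schema.event_types]
    assert missing == []


def test_builtin_schema_deterministic():
    assert builtin_schema("CG") == builtin_schema("CG")
    assert builtin_schema("PC") == builtin_schema("PC")
    with pytest.raises(ValueError, match="unknown task"):
        builtin_schema("GE")


@pytest.mark.parametrize("label,expected", [
    ("Theme2", "Theme"),
    ("Theme", "Theme"),
    ("AtLoc", "AtLoc"),
    ("Theme12", "Theme"),
])
def test_role_base_strips_numeric_suffix(label, expected):
    assert role_base(label) == expected


def test_role_base_rejects_degenerate_labels():
    with pytest.raises(ValueError):
        role_base("123")
    with pytest.raises(ValueError):
        role_base("")


# --- validation ------------------------------------------------------------


def test_generated_documents_validate_clean(cg_schema, pc_schema):
    for task, schema in (("CG", cg_schema), ("PC", pc_schema)):
        for doc in generate(GeneratorConfig(task=task, n_docs=5, seed=42)):
            errors = [v for v in validate(doc, schema) if v.severity == "error"]
            assert errors == [], (task, doc.doc_id, errors[:3])


def test_instrument_not_licensed_in_pc(builder, pc_schema):
    ent = builder.entity("Gene or gene product", "TAK1")
    ins = builder.entity("Simple chemical", "drug")
    trig = builder.trigger("Gene expression", "expressed")
    builder.event("Gene expression", trig, ("Theme", ent), ("Instrument", ins))
    codes = {v.code for v in validate(builder.build(), pc_schema)}
    assert "unlicensed-role" in codes


def test_repeated_theme_allowed_for_cg_binding(builder, cg_schema):
    a = builder.entity("Gene or gene product", "IL2")
    b = builder.entity("Gene or gene product", "IL2R")
    trig = builder.trigger("Binding", "binds")
    builder.event("Binding", trig, ("Theme", a), ("Theme2", b))
    assert validate(builder.build(), cg_schema) == []


def test_optional_theme_may_be_absent(builder, cg_schema):
    trig = builder.trigger("Cell death", "apoptosis")
    builder.event("Cell death", trig)
    assert validate(builder.build(), cg_schema) == []


def test_missing_required_theme_flagged(builder, cg_schema):
    trig = builder.trigger("Development", "develops")
    builder.event("Development", trig)
    codes = {v.code for v in validate(builder.build(), cg_schema)}
    assert "missing-required-role" in codes


def test_repeated_single_valued_role_flagged(builder, cg_schema):
    a = builder.entity("Gene or gene product", "p53")
    b = builder.entity("Gene or gene product", "mdm2")
    trig = builder.trigger("Transcription", "transcription")
    builder.event("Transcription", trig, ("Theme", a), ("Theme2", b))
    codes = {v.code for v in validate(builder.build(), cg_schema)}
    assert "repeated-role" in codes


def test_unknown_types_flagged(builder, cg_schema):
    builder.entity("Protein", "p53")  # GE-style type, not CG
    trig = builder.trigger("Methylation", "methylated")  # PC-only type
    builder.event("Methylation", trig)
    codes = {v.code for v in validate(builder.build(), cg_schema)}
    assert {"unknown-entity-type", "trigger-not-event-type", "unknown-event-type"} <= codes


def test_event_filler_rejected_where_entity_required(builder, cg_schema):
    ent = builder.entity("Gene or gene product", "p53")
    t1 = builder.trigger("Gene expression", "expressed")
    e1 = builder.event("Gene expression", t1, ("Theme", ent))
    t2 = builder.trigger("Transcription", "transcribed")
    builder.event("Transcription", t2, ("Theme", e1))  # GGP role, event filler
    codes = {v.code for v in validate(builder.build(), cg_schema)}
    assert "entity-filler-required" in codes


def test_filler_category_mismatch_is_warning(builder, cg_schema):
    ent = builder.entity("Organism", "mice")
    trig = builder.trigger("Gene expression", "expressed")
    builder.event("Gene expression", trig, ("Theme", ent))
    findings = validate(builder.build(), cg_schema)
    assert [v.code for v in findings] == ["filler-category"]
    assert findings[0].severity == "warning"


def test_equiv_over_events_flagged(builder, cg_schema):
    ent = builder.entity("Gene or gene product", "p53")
    trig = builder.trigger("Gene expression", "expressed")
    ev = builder.event("Gene expression", trig, ("Theme", ent))
    builder.equiv(ent, ev)
    codes = {v.code for v in validate(builder.build(), cg_schema)}
    assert "equiv-contains-event" in codes


def test_planned_process_with_zero_arguments_is_legal(builder, cg_schema):
    trig = builder.trigger("Planned process", "treatment")
    builder.event("Planned process", trig)
    assert validate(builder.build(), cg_schema) == []


@pytest.mark.parametrize("task", ["CG", "PC"])
def test_yaml_roundtrip_preserves_schema(task):
    schema = builtin_schema(task)
    assert schema_from_yaml(schema_to_yaml(schema)) == schema
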