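"""Parse a standoff document triple, validate it, and round-trip it.

The document says that MDM2 negatively regulates p53 expression: a nested
event structure in which a Negative regulation event takes the Gene
expression event as its Theme. The annotations reference the text purely by
character offsets (0-based, end-exclusive).
"""

from bionlpeval import builtin_schema, parse_document, serialize_target_layer, validate

TEXT = "MDM2 blocks p53 expression"
GIVEN = (
    "T1\tGene_or_gene_product 0 4\tMDM2\n"
    "T2\tGene_or_gene_product 12 15\tp53\n"
)
TARGET = (
    "T3\tGene_expression 16 26\texpression\n"
    "T4\tNegative_regulation 5 11\tblocks\n"
    "E1\tGene_expression:T3 Theme:T2\n"
    "E2\tNegative_regulation:T4 Theme:E1 Cause:T1\n"
)

doc = parse_document("PMID0", TEXT, GIVEN, TARGET)
outer = doc.event_map()["E2"]
print(f"{outer.id} is a {outer.type!r} event with arguments:")
for arg in outer.args:
    print(f"  {arg.role_label} -> {arg.filler_id}")

findings = validate(doc, builtin_schema("CG"))
print(f"validation findings: {len(findings)}")

print("round-tripped target layer:")
print(serialize_target_layer(doc), end="")
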