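"""Score a perturbed system output against a synthetic gold standard.

Generates a small Cancer Genetics corpus, derives a "system output" from it
by deleting some events and dropping some arguments, and prints the
micro-averaged evaluation under the primary criteria and the single-partial-
penalty relaxation. Recall counts matched gold events, precision counts
matched predicted events; SPP can only raise both, because it waives one of
the two penalties a partially correct event otherwise pays.
"""

from bionlpeval import (
    GeneratorConfig,
    PerturbationPlan,
    PRIMARY,
    PRIMARY_SPP,
    builtin_schema,
    evaluate,
    generate,
    perturb,
    prf,
    report_to_tsv,
)

gold = generate(GeneratorConfig(task="CG", n_docs=10, events_per_doc=8, seed=42))
pred, _ = perturb(gold, PerturbationPlan(delete_event=0.15, drop_argument=0.2, seed=7))
schema = builtin_schema("CG")

report = evaluate(gold, pred, schema, PRIMARY)
print(report_to_tsv(report))

for criteria in (PRIMARY, PRIMARY_SPP):
    m = prf(evaluate(gold, pred, schema, criteria).total)
    print(f"{criteria.name:>12}: R={m.recall:.2f} P={m.precision:.2f} F={m.fscore:.2f}")
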