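"""Evaluation reports: P/R/F arithmetic, core reduction, SPP, invariances."""

import random

import pytest

from bionlpeval.scoring import (
    ALL_CRITERIA,
    CORE,
    PRIMARY,
    PRIMARY_SPP,
    CountRow,
    CriteriaConfig,
    evaluate,
    prf,
    report_to_json,
    report_to_tsv,
    round2,
    strip_to_core,
)
from bionlpeval.standoff import Argument, EventAnnotation
from bionlpeval.synthetic import GeneratorConfig, generate

from conftest import DocBuilder, simple_gene_expression_corpus


def _row(gm, gt, pm, pt):
    return CountRow("x", "type", gold_total=gt, gold_matched=gm,
                    pred_total=pt, pred_matched=pm)


@pytest.mark.parametrize("gm,gt,pm,pt,expected", [
    (4, 4, 4, 4, (100.00, 100.00, 100.00)),
    (0, 5, 0, 0, (0.00, 0.00, 0.00)),
    (7, 10, 7, 7, (70.00, 100.00, 82.35)),
    # counts chosen to reproduce a published summary row's arithmetic
    (4876, 10000, 6417, 10000, (48.76, 64.17, 55.41)),
])
def test_prf_arithmetic(gm, gt, pm, pt, expected):
    m = prf(_row(gm, gt, pm, pt))
    assert (m.recall, m.precision, m.fscore) == expected


def test_rounding_is_half_away_from_zero():
    assert round2(55.405) == 55.41
    assert round2(55.404999) == 55.40
    assert round2(0.005) == 0.01


@pytest.mark.parametrize("criteria", ALL_CRITERIA, ids=lambda c: c.name)
@pytest.mark.parametrize("task", ["CG", "PC"])
def test_self_evaluation_is_perfect(task, criteria):
    schema_docs = generate(GeneratorConfig(task=task, n_docs=6, seed=13))
    from bionlpeval.schema import builtin_schema
    report = evaluate(schema_docs, schema_docs, builtin_schema(task), criteria)
    for row in report.rows:
        m = prf(row)
        assert (m.recall, m.precision, m.fscore) == (100.0, 100.0, 100.0), row.label


def test_deleting_three_of_ten_events(cg_schema):
    gold = simple_gene_expression_corpus(10)
    pred = gold.copy()
    pred.events = pred.events[:7]
    report = evaluate([gold], [pred], cg_schema, PRIMARY)
    m = prf(report.total)
    assert (m.recall, m.precision, m.fscore) == (70.00, 100.00, 82.35)


def test_strip_to_core_removes_site_and_keeps_theme(cg_schema):
    b = DocBuilder()
    theme = b.entity("Gene or gene product", "p53")
    site = b.entity("Protein domain or region", "serine")
    trig = b.trigger("Phosphorylation", "phosphorylated")
    b.event("Phosphorylation", trig, ("Theme", theme), ("Site", site))
    b.modification("Negation", "E1")
    doc = strip_to_core(b.build(), cg_schema)
    assert [(a.role_label, a.filler_id) for a in doc.events[0].args] == [("Theme", theme)]
    assert doc.modifications == []


def test_strip_to_core_merges_duplicates_and_remaps_references(cg_schema):
    b = DocBuilder()
    mol = b.entity("Gene or gene product", "VEGF")
    loc = b.entity("Cellular component", "nucleus")
    trig = b.trigger("Localization", "localization")
    e1 = b.event("Localization", trig, ("Theme", mol), ("AtLoc", loc))
    e2 = b.event("Localization", trig, ("Theme", mol))
    rtrig = b.trigger("Regulation", "regulates")
    b.event("Regulation", rtrig, ("Theme", e2))
    doc = strip_to_core(b.build(), cg_schema)
    locs = [e for e in doc.events if e.type == "Localization"]
    assert len(locs) == 1 and locs[0].id == e1  # smallest id survives
    reg = next(e for e in doc.events if e.type == "Regulation")
    assert reg.args[0].filler_id == e1  # reference remapped to survivor


def test_duplicate_predictions_do_not_inflate_precision(cg_schema):
    gold = simple_gene_expression_corpus(5)
    pred = gold.copy()
    pred.events = list(pred.events) + [
        EventAnnotation("E99", ev.type, ev.trigger_id, ev.args) for ev in gold.events[:1]
    ]
    report = evaluate([gold], [pred], cg_schema, PRIMARY)
    m = prf(report.total)
    assert (m.recall, m.precision) == (100.00, 100.00)


def _spp_fixture(extra=False, missing=False, retype=False):
    b = DocBuilder()
    theme = b.entity("Gene or gene product", "p53")
    cause = b.entity("Gene or gene product", "MDM2")
    trig = b.trigger("Regulation", "regulates")
    b.event("Regulation", trig, ("Theme", theme), ("Cause", cause))
    gold = b.build()
    pred = gold.copy()
    ev = pred.events[0]
    if missing:
        pred.events = [EventAnnotation(ev.id, ev.type, ev.trigger_id,
                                       (Argument("Theme", theme),))]
    if extra:
        gold.events = [EventAnnotation(ev.id, ev.type, ev.trigger_id,
                                       (Argument("Theme", theme),))]
    if retype:
        from dataclasses import replace
        pred.events = [replace(ev, type="Positive regulation")]
        pred.triggers = [replace(pred.triggers[0], type="Positive regulation")]
    return gold, pred


def test_spp_waives_false_negative_for_extra_arguments(cg_schema):
    gold, pred = _spp_fixture(extra=True)  # prediction has a spurious Cause
    base = evaluate([gold], [pred], cg_schema, PRIMARY).total
    spp = evaluate([gold], [pred], cg_schema, PRIMARY_SPP).total
    assert (base.gold_matched, base.pred_matched) == (0, 0)
    assert (spp.gold_matched, spp.pred_matched) == (1, 0)  # FP stands, FN waived


def test_spp_waives_false_positive_for_missing_arguments(cg_schema):
    gold, pred = _spp_fixture(missing=True)  # prediction lacks the Cause
    spp = evaluate([gold], [pred], cg_schema, PRIMARY_SPP).total
    assert (spp.gold_matched, spp.pred_matched) == (0, 1)  # FN stands, FP waived


def test_spp_requires_equal_event_types(cg_schema):
    gold, pred = _spp_fixture(retype=True)
    spp = evaluate([gold], [pred], cg_schema, PRIMARY_SPP).total
    assert (spp.gold_matched, spp.pred_matched) == (0, 0)


def test_modifications_scored_through_their_target_events(cg_schema):
    gold = simple_gene_expression_corpus(3)
    from bionlpeval.standoff import EventModification
    gold.modifications = [EventModification("M1", "Negation", "E1"),
                          EventModification("M2", "Speculation", "E2")]
    pred = gold.copy()
    pred.modifications = [EventModification("M1", "Negation", "E1")]
    pred.events = list(pred.events)[:2]  # E3 deleted; its absence is an event miss
    report = evaluate([gold], [pred], cg_schema, PRIMARY)
    neg = report.row("Negation")
    spec = report.row("Speculation")
    assert (neg.gold_matched, neg.gold_total) == (1, 1)
    assert (spec.gold_matched, spec.gold_total) == (0, 1)
    assert (spec.pred_total) == 0
    # grand total mixes events and modifications
    assert report.total.gold_total == 5


def test_report_permutation_invariance(cg_schema):
    docs = generate(GeneratorConfig(n_docs=6, events_per_doc=6, seed=21))
    from bionlpeval.synthetic import PerturbationPlan, perturb
    preds, _ = perturb(docs, PerturbationPlan(delete_event=0.2, drop_argument=0.2, seed=3))
    baseline = report_to_tsv(evaluate(docs, preds, cg_schema, PRIMARY))

    rng = random.Random(0)
    docs2 = [d.copy() for d in docs]
    preds2 = [d.copy() for d in preds]
    rng.shuffle(docs2)
    rng.shuffle(preds2)
    for d in docs2 + preds2:
        rng.shuffle(d.events)
        rng.shuffle(d.entities)
        rng.shuffle(d.triggers)
    assert report_to_tsv(evaluate(docs2, preds2, cg_schema, PRIMARY)) == baseline


def test_count_conservation(cg_schema):
    docs = generate(GeneratorConfig(n_docs=5, events_per_doc=7, seed=8))
    from bionlpeval.synthetic import PerturbationPlan, perturb
    preds, _ = perturb(docs, PerturbationPlan(delete_event=0.2, retype_event=0.2, seed=4))
    report = evaluate(docs, preds, cg_schema, PRIMARY)
    for row in report.rows:
        assert 0 <= row.gold_matched <= row.gold_total
        assert 0 <= row.pred_matched <= row.pred_total
    total = report.total
    subtotal = report.row("Sub-total")
    mods = [r for r in report.rows if r.kind == "modification"]
    assert total.gold_total == subtotal.gold_total + sum(r.gold_total for r in mods)


def test_unknown_prediction_document_is_an_error(cg_schema):
    gold = simple_gene_expression_corpus(2, doc_id="A")
    stray = simple_gene_expression_corpus(2, doc_id="B")
    with pytest.raises(ValueError, match="B"):
        evaluate([gold], [stray], cg_schema, PRIMARY)


def test_missing_prediction_document_counts_as_empty(cg_schema):
    gold = simple_gene_expression_corpus(4, doc_id="A")
    report = evaluate([gold], [], cg_schema, PRIMARY)
    m = prf(report.total)
    assert (m.recall, m.precision, m.fscore) == (0.0, 0.0, 0.0)
    assert report.total.gold_total == 4


def test_report_writers_are_stable(cg_schema):
    gold = simple_gene_expression_corpus(2)
    tsv = report_to_tsv(evaluate([gold], [gold], cg_schema, PRIMARY))
    assert "Gene expression\t2\t2\t2\t2\t100.00\t100.00\t100.00" in tsv
    js = report_to_json(evaluate([gold], [gold], cg_schema, CORE))
    import json
    payload = json.loads(js)
    assert payload["criteria"]["core_targets"] is True
    assert payload["rows"][-1]["label"] == "TOTAL"
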