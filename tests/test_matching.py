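"""Span relaxation, Equiv closure, and recursive event matching."""

import itertools

import pytest

from bionlpeval.matching import (
    approx_span_match,
    core_match_relation,
    equiv_closure,
    full_match,
    tokenize,
)
from bionlpeval.standoff import EquivGroup, Span

from conftest import DocBuilder


@pytest.mark.parametrize("text,n", [
    ("p53 is not affected", 4),
    ("NF-kappa B", 3),
    ("", 0),
    ("  ...  ", 0),
    ("IL-2R alpha", 3),
])
def test_tokenize_counts_alphanumeric_runs(text, n):
    assert len(tokenize(text).tokens) == n


TEXT = "aa bb cc dd ee ff gg hh"  # token i covers [3i, 3i+2)


def _tok_span(first, last):
    return Span(3 * first, 3 * last + 2)


def test_identical_spans_always_match():
    idx = tokenize(TEXT)
    for rule in ("approximate", "strict", "containment"):
        assert approx_span_match(_tok_span(2, 3), _tok_span(2, 3), idx, rule)


def test_one_word_shift_matches_two_does_not():
    idx = tokenize(TEXT)
    gold = _tok_span(5, 6)
    assert approx_span_match(gold, _tok_span(4, 6), idx)       # one word left
    assert approx_span_match(gold, _tok_span(5, 7), idx)       # one word right
    assert approx_span_match(gold, _tok_span(4, 7), idx)       # one each side
    assert not approx_span_match(gold, _tok_span(3, 6), idx)   # two words left
    assert not approx_span_match(gold, _tok_span(5, 5), idx, "strict")


def test_span_rule_is_symmetric_over_all_small_spans():
    idx = tokenize(TEXT)
    spans = [_tok_span(i, j) for i in range(8) for j in range(i, 8)]
    for a, b in itertools.combinations(spans, 2):
        assert approx_span_match(a, b, idx) == approx_span_match(b, a, idx)


def test_containment_rule_requires_pred_inside_extended_gold():
    idx = tokenize(TEXT)
    gold = _tok_span(5, 5)
    assert approx_span_match(gold, _tok_span(4, 6), idx, "containment")
    assert not approx_span_match(gold, _tok_span(3, 5), idx, "containment")
    # asymmetric by design: wide gold accepts narrow pred, not vice versa
    assert approx_span_match(_tok_span(3, 6), _tok_span(4, 5), idx, "containment")
    assert not approx_span_match(_tok_span(4, 5), _tok_span(2, 6), idx, "containment")


def test_span_over_no_token_warns_and_fails():
    idx = tokenize(TEXT)
    with pytest.warns(UserWarning):
        assert not approx_span_match(Span(2, 3), _tok_span(1, 1), idx)


def test_equiv_closure_is_transitive_and_idempotent():
    closure = equiv_closure([
        EquivGroup(frozenset({"T1", "T2"})),
        EquivGroup(frozenset({"T2", "T3"})),
    ])
    assert closure.same("T1", "T3")
    assert not closure.same("T1", "T9")
    for x in ("T1", "T2", "T3", "T9"):
        assert closure.find(closure.find(x)) == closure.find(x)


def test_equiv_closure_rejects_event_members():
    with pytest.raises(ValueError, match="E1"):
        equiv_closure([EquivGroup(frozenset({"T1", "E1"}))], event_ids={"E1"})


# --- recursive event matching ----------------------------------------------


def _nested_pair(shift_inner=False, wrong_inner_theme=False):
    """Gold: E1 = Gene expression(Theme:T_gene), E2 = Positive regulation(Theme:E1).
    Prediction is identical modulo the requested corruption."""
    gold = DocBuilder("D1")
    g_ent = gold.entity("Gene or gene product", "p53")
    gold.entity("Gene or gene product", "other")
    g_t1 = gold.trigger("Gene expression", "expression")
    g_e1 = gold.event("Gene expression", g_t1, ("Theme", g_ent))
    g_t2 = gold.trigger("Positive regulation", "induces")
    gold.event("Positive regulation", g_t2, ("Theme", g_e1))
    gold_doc = gold.build()

    pred_doc = gold_doc.copy()
    if shift_inner:
        # move the inner trigger's start one token left
        idx = tokenize(gold_doc.text)
        trig = pred_doc.triggers[0]
        tok = [t for t in idx.tokens if t.end <= trig.span.start][-1]
        from dataclasses import replace
        new_span = Span(tok.start, trig.span.end)
        pred_doc.triggers = [
            replace(trig, span=new_span,
                    surface=gold_doc.text[new_span.start:new_span.end]),
            pred_doc.triggers[1],
        ]
    if wrong_inner_theme:
        from bionlpeval.standoff import Argument, EventAnnotation
        inner = pred_doc.events[0]
        pred_doc.events = [
            EventAnnotation(inner.id, inner.type, inner.trigger_id,
                            (Argument("Theme", "T2"),)),  # not Equiv-linked
            pred_doc.events[1],
        ]
    return gold_doc, pred_doc


def _relation(gold_doc, pred_doc, schema, span_rule="approximate"):
    idx = tokenize(gold_doc.text)
    closure = equiv_closure(gold_doc.equivs)
    return core_match_relation(
        gold_doc.events, pred_doc.events, closure, schema, idx,
        {t.id: t.span for t in gold_doc.triggers},
        {t.id: t.span for t in pred_doc.triggers},
        span_rule,
    ), idx, closure


def test_identity_prediction_yields_identity_relation(cg_schema):
    gold, pred = _nested_pair()
    rel, _, _ = _relation(gold, pred, cg_schema)
    assert rel.pairs == {("E1", "E1"), ("E2", "E2")}


def test_shifted_inner_trigger_still_matches_both_levels(cg_schema):
    gold, pred = _nested_pair(shift_inner=True)
    rel, _, _ = _relation(gold, pred, cg_schema)
    assert rel.pairs == {("E1", "E1"), ("E2", "E2")}
    # under the strict span rule the inner pair fails and the outer cascades
    strict_rel, _, _ = _relation(gold, pred, cg_schema, "strict")
    assert strict_rel.pairs == set()


def test_inner_failure_cascades_to_outer(cg_schema):
    gold, pred = _nested_pair(wrong_inner_theme=True)
    rel, _, _ = _relation(gold, pred, cg_schema)
    assert rel.pairs == set()


def test_strict_relation_is_subset_of_approximate(cg_schema):
    from bionlpeval.synthetic import GeneratorConfig, PerturbationPlan, generate, perturb

    docs = generate(GeneratorConfig(n_docs=8, events_per_doc=6, seed=5))
    preds, _ = perturb(docs, PerturbationPlan(shift_trigger_one_token=0.4, seed=6))
    for gold, pred in zip(docs, preds):
        approx, _, _ = _relation(gold, pred, cg_schema)
        strict, _, _ = _relation(gold, pred, cg_schema, "strict")
        assert strict.pairs <= approx.pairs


def test_full_match_requires_additional_arguments_too(cg_schema):
    b = DocBuilder("D1")
    theme = b.entity("Gene or gene product", "p53")
    site = b.entity("Protein domain or region", "serine")
    trig = b.trigger("Phosphorylation", "phosphorylation")
    b.event("Phosphorylation", trig, ("Theme", theme), ("Site", site))
    gold = b.build()

    pred = gold.copy()
    from bionlpeval.standoff import Argument, EventAnnotation
    ev = pred.events[0]
    pred.events = [EventAnnotation(ev.id, ev.type, ev.trigger_id,
                                   (Argument("Theme", theme),))]  # Site omitted

    rel, idx, closure = _relation(gold, pred, cg_schema)
    assert rel.pairs == {("E1", "E1")}  # core-level match survives
    gold_ids, pred_ids = {"E1"}, {"E1"}
    assert not full_match(
        gold.events[0], pred.events[0], rel, closure, gold_ids, pred_ids, idx,
        {t.id: t.span for t in gold.triggers}, {t.id: t.span for t in pred.triggers},
    )


def test_equiv_connected_fillers_are_interchangeable(cg_schema):
    b = DocBuilder("D1")
    a = b.entity("Gene or gene product", "p53")
    alias = b.entity("Gene or gene product", "TP53")
    b.equiv(a, alias)
    trig = b.trigger("Gene expression", "expressed")
    b.event("Gene expression", trig, ("Theme", a))
    gold = b.build()

    pred = gold.copy()
    from bionlpeval.standoff import Argument, EventAnnotation
    ev = pred.events[0]
    pred.events = [EventAnnotation(ev.id, ev.type, ev.trigger_id,
                                   (Argument("Theme", alias),))]
    rel, idx, closure = _relation(gold, pred, cg_schema)
    assert rel.pairs == {("E1", "E1")}
    assert full_match(
        gold.events[0], pred.events[0], rel, closure, {"E1"}, {"E1"}, idx,
        {t.id: t.span for t in gold.triggers}, {t.id: t.span for t in pred.triggers},
    )
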