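"""Micro-averaged precision/recall/F reporting under the task criteria.

Four published evaluation settings are supported, all instance-based:

===================  ==========================================================
primary              full argument structures, approximate trigger spans,
                     nested events compared on core arguments
core                 all non-core arguments and modifications stripped from
                     gold and predictions alike, duplicates merged
primary + SPP        single partial penalty: a prediction differing from a
                     gold event only by extra arguments costs one false
                     positive (the gold false negative is waived), one
                     differing only by missing arguments costs one false
                     negative (the false positive is waived)
core + SPP           both relaxations combined
===================  ==========================================================

A gold event counts as matched if at least one predicted event matches it,
and vice versa (set-based, not an assignment); SPP is the only stage that
uses an explicit maximum matching, with ascending-id tie-breaking for
determinism. Counts are pooled over documents and types (micro-averaging);
modification rows contribute to the grand total.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .matching import (
    EquivClosure,
    MatchRelation,
    approx_span_match,
    args_align,  # noqa: F401 - re-exported for matching-level callers
    core_match_relation,
    equiv_closure,
    full_match,
    tokenize,
)
from .schema import TaskSchema, role_base
from .standoff import Argument, Document, EventAnnotation, EventModification


@dataclass(frozen=True)
class CriteriaConfig:
    core_targets: bool = False
    single_partial_penalty: bool = False
    span_rule: str = "approximate"

    @property
    def name(self) -> str:
        bits = ["core" if self.core_targets else "primary"]
        if self.single_partial_penalty:
            bits.append("spp")
        if self.span_rule != "approximate":
            bits.append(self.span_rule)
        return "+".join(bits)


#: The four published criteria settings.
PRIMARY = CriteriaConfig()
CORE = CriteriaConfig(core_targets=True)
PRIMARY_SPP = CriteriaConfig(single_partial_penalty=True)
CORE_SPP = CriteriaConfig(core_targets=True, single_partial_penalty=True)
ALL_CRITERIA = (PRIMARY, CORE, PRIMARY_SPP, CORE_SPP)


def round2(x: float) -> float:
    """Round to two decimals, half away from zero (table formatting)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fscore(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision given as percentages."""
    if recall + precision == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class CountRow:
    label: str
    kind: str  # type | modification | category | subtotal | modification_total | total
    gold_total: int = 0
    gold_matched: int = 0
    pred_total: int = 0
    pred_matched: int = 0

    def add(self, other: "CountRow") -> None:
        self.gold_total += other.gold_total
        self.gold_matched += other.gold_matched
        self.pred_total += other.pred_total
        self.pred_matched += other.pred_matched


@dataclass(frozen=True)
class PRF:
    recall: float
    precision: float
    fscore: float


def prf(row: CountRow) -> PRF:
    """Percentages to two decimals; zero-denominator cases are 0 by convention."""
    recall = 100.0 * row.gold_matched / row.gold_total if row.gold_total else 0.0
    precision = 100.0 * row.pred_matched / row.pred_total if row.pred_total else 0.0
    return PRF(round2(recall), round2(precision), round2(fscore(recall, precision)))


@dataclass
class EvalReport:
    task: str
    criteria: CriteriaConfig
    rows: list[CountRow]

    def row(self, label: str) -> CountRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def total(self) -> CountRow:
        return self.row("TOTAL")


# ---------------------------------------------------------------------------
# structural normalization


_ID_RE = re.compile(r"([A-Za-z]*)(\d+)")


def id_key(ann_id: str) -> tuple[str, int]:
    m = _ID_RE.fullmatch(ann_id)
    return (m.group(1), int(m.group(2))) if m else (ann_id, 0)


def _dedup_events(doc: Document) -> Document:
    """Merge structurally identical events (type, trigger span, argument
    multiset, with event fillers compared through the merge itself); inbound
    references and modifications are remapped to the surviving event."""
    triggers = doc.trigger_map()
    rep = {ev.id: ev.id for ev in doc.events}
    while True:
        groups: dict[tuple, str] = {}
        changed = False
        for ev in sorted(doc.events, key=lambda e: id_key(e.id)):
            trig = triggers[ev.trigger_id]
            args_key = tuple(sorted(
                (role_base(a.role_label), rep.get(a.filler_id, a.filler_id))
                for a in ev.args
            ))
            key = (ev.type, trig.span, args_key)
            if key in groups:
                if rep[ev.id] != groups[key]:
                    rep[ev.id] = groups[key]
                    changed = True
            else:
                groups[key] = rep[ev.id]
        if not changed:
            break

    out = doc.copy()
    out.events = [
        EventAnnotation(
            ev.id, ev.type, ev.trigger_id,
            tuple(Argument(a.role_label, rep.get(a.filler_id, a.filler_id))
                  for a in ev.args),
        )
        for ev in doc.events if rep[ev.id] == ev.id
    ]
    seen: set[tuple[str, str]] = set()
    mods = []
    for mod in doc.modifications:
        key = (mod.type, rep.get(mod.target_id, mod.target_id))
        if key not in seen:
            seen.add(key)
            mods.append(EventModification(mod.id, key[0], key[1]))
    out.modifications = mods
    return out


def strip_to_core(doc: Document, schema: TaskSchema) -> Document:
    """Reduce to core extraction targets: drop all non-core arguments and all
    modifications, then merge duplicate events arising from the reduction."""
    out = doc.copy()
    out.events = [
        EventAnnotation(
            ev.id, ev.type, ev.trigger_id,
            tuple(a for a in ev.args
                  if role_base(a.role_label) in schema.core_roles(ev.type)),
        )
        for ev in doc.events
    ]
    out.modifications = []
    return _dedup_events(out)


# ---------------------------------------------------------------------------
# SPP partial matching


def _injection_exists(small: Sequence[str], large: Sequence[str], ok) -> bool:
    """Can every element of *small* be matched to a distinct element of
    *large*? (Kuhn's augmenting paths; slot counts are tiny.)"""
    match: dict[int, int] = {}  # large index -> small index

    def try_assign(si: int, visited: set[int]) -> bool:
        for li in range(len(large)):
            if li in visited or not ok(small[si], large[li]):
                continue
            visited.add(li)
            if li not in match or try_assign(match[li], visited):
                match[li] = si
                return True
        return False

    return all(try_assign(si, set()) for si in range(len(small)))


def _partial_direction(
    g: EventAnnotation, p: EventAnnotation,
    relation: set[tuple[str, str]], closure: EquivClosure,
    gold_events: set[str], pred_events: set[str],
) -> str | None:
    """'extra' if p's arguments strictly contain g's (pred has extra args),
    'missing' if strictly contained, None otherwise."""
    from .matching import _fillers_match, _group_by_role  # shared internals

    g_args = _group_by_role(g, None)
    p_args = _group_by_role(p, None)

    def ok(gf: str, pf: str) -> bool:
        return _fillers_match(gf, pf, gold_events, pred_events, closure, relation)

    def contained(inner: dict, outer: dict, inner_first: bool) -> bool:
        # every inner slot injects into outer slots of the same role
        for role, fillers in inner.items():
            other = outer.get(role, [])
            if len(fillers) > len(other):
                return False
            pair_ok = ok if inner_first else (lambda a, b: ok(b, a))
            if not _injection_exists(fillers, other, pair_ok):
                return False
        return True

    n_g = sum(len(v) for v in g_args.values())
    n_p = sum(len(v) for v in p_args.values())
    if n_p > n_g and contained(g_args, p_args, inner_first=True):
        return "extra"
    if n_g > n_p and contained(p_args, g_args, inner_first=False):
        return "missing"
    return None


def spp_adjust(
    unmatched_gold: Sequence[EventAnnotation],
    unmatched_pred: Sequence[EventAnnotation],
    core_rel: MatchRelation,
    closure: EquivClosure,
    schema: TaskSchema,
    idx,
    gold_triggers: dict,
    pred_triggers: dict,
    gold_events: set[str],
    pred_events: set[str],
    span_rule: str = "approximate",
) -> tuple[set[str], set[str]]:
    """Single-partial-penalty stage over the unmatched residue.

    Returns (gold event ids newly counted matched, pred event ids newly
    counted matched): one id per selected partial pair, on the side whose
    penalty the criterion waives. The selected pairing is the canonical
    maximum bipartite matching: lexicographically smallest in ascending
    (gold id, pred id) order among all maximum matchings.
    """
    directions: dict[tuple[str, str], str] = {}
    for g in unmatched_gold:
        for p in unmatched_pred:
            if g.type != p.type:
                continue
            if not approx_span_match(
                gold_triggers[g.trigger_id], pred_triggers[p.trigger_id], idx, span_rule
            ):
                continue
            direction = _partial_direction(
                g, p, core_rel.pairs, closure, gold_events, pred_events
            )
            if direction is not None:
                directions[(g.id, p.id)] = direction

    chosen = _lex_min_maximum_matching(set(directions))
    extra_gold: set[str] = set()
    extra_pred: set[str] = set()
    for gid, pid in chosen:
        if directions[(gid, pid)] == "extra":
            extra_gold.add(gid)  # prediction keeps its false positive
        else:
            extra_pred.add(pid)  # gold keeps its false negative
    return extra_gold, extra_pred


def _max_matching_size(edges: set[tuple[str, str]]) -> int:
    adj: dict[str, list[str]] = {}
    for g, p in sorted(edges, key=lambda e: (id_key(e[0]), id_key(e[1]))):
        adj.setdefault(g, []).append(p)
    match_p: dict[str, str] = {}

    def augment(gid: str, visited: set[str]) -> bool:
        for pid in adj.get(gid, []):
            if pid in visited:
                continue
            visited.add(pid)
            if pid not in match_p or augment(match_p[pid], visited):
                match_p[pid] = gid
                return True
        return False

    return sum(augment(g, set()) for g in adj)


def _lex_min_maximum_matching(edges: set[tuple[str, str]]) -> list[tuple[str, str]]:
    """Greedy-with-feasibility-check construction of the lexicographically
    smallest maximum matching (pairs considered in ascending id order)."""
    total = _max_matching_size(edges)
    chosen: list[tuple[str, str]] = []
    used_g: set[str] = set()
    used_p: set[str] = set()
    for g, p in sorted(edges, key=lambda e: (id_key(e[0]), id_key(e[1]))):
        if g in used_g or p in used_p:
            continue
        rest = {
            (gg, pp) for gg, pp in edges
            if gg not in used_g | {g} and pp not in used_p | {p}
        }
        if len(chosen) + 1 + _max_matching_size(rest) == total:
            chosen.append((g, p))
            used_g.add(g)
            used_p.add(p)
    return chosen


# ---------------------------------------------------------------------------
# document-level scoring


@dataclass
class DocumentScore:
    """Per-(kind, label) counts for one document."""

    counts: dict[tuple[str, str], CountRow] = field(default_factory=dict)

    def row(self, kind: str, label: str) -> CountRow:
        key = (kind, label)
        if key not in self.counts:
            self.counts[key] = CountRow(label, kind)
        return self.counts[key]

    def totals(self) -> tuple[int, int, int, int]:
        gm = gt = pm = pt = 0
        for row in self.counts.values():
            gm += row.gold_matched
            gt += row.gold_total
            pm += row.pred_matched
            pt += row.pred_total
        return gm, gt, pm, pt


def score_document(
    gold: Document, pred: Document, schema: TaskSchema, criteria: CriteriaConfig
) -> DocumentScore:
    """Count matched/total gold and predicted instances in one document."""
    if criteria.core_targets:
        gold = strip_to_core(gold, schema)
        pred = strip_to_core(pred, schema)
    else:
        gold = _dedup_events(gold)
        pred = _dedup_events(pred)

    idx = tokenize(gold.text)
    closure = equiv_closure(gold.equivs)
    gold_trigger_spans = {t.id: t.span for t in gold.triggers}
    pred_trigger_spans = {t.id: t.span for t in pred.triggers}
    gold_ids = {e.id for e in gold.events}
    pred_ids = {e.id for e in pred.events}

    core_rel = core_match_relation(
        gold.events, pred.events, closure, schema, idx,
        gold_trigger_spans, pred_trigger_spans, criteria.span_rule,
    )

    matched_pairs: set[tuple[str, str]] = set()
    for g in gold.events:
        for p in pred.events:
            if full_match(g, p, core_rel, closure, gold_ids, pred_ids, idx,
                          gold_trigger_spans, pred_trigger_spans, criteria.span_rule):
                matched_pairs.add((g.id, p.id))
    gold_matched = {g for g, _ in matched_pairs}
    pred_matched = {p for _, p in matched_pairs}

    if criteria.single_partial_penalty:
        extra_gold, extra_pred = spp_adjust(
            [e for e in gold.events if e.id not in gold_matched],
            [e for e in pred.events if e.id not in pred_matched],
            core_rel, closure, schema, idx,
            gold_trigger_spans, pred_trigger_spans,
            gold_ids, pred_ids, criteria.span_rule,
        )
        gold_matched |= extra_gold
        pred_matched |= extra_pred

    score = DocumentScore()
    for ev in gold.events:
        row = score.row("event", ev.type)
        row.gold_total += 1
        if ev.id in gold_matched:
            row.gold_matched += 1
    for ev in pred.events:
        row = score.row("event", ev.type)
        row.pred_total += 1
        if ev.id in pred_matched:
            row.pred_matched += 1

    # modifications: scored by type equality plus top-level match of targets
    for mod in gold.modifications:
        row = score.row("modification", mod.type)
        row.gold_total += 1
        if any(
            pm.type == mod.type and (mod.target_id, pm.target_id) in matched_pairs
            for pm in pred.modifications
        ):
            row.gold_matched += 1
    for mod in pred.modifications:
        row = score.row("modification", mod.type)
        row.pred_total += 1
        if any(
            gm.type == mod.type and (gm.target_id, mod.target_id) in matched_pairs
            for gm in gold.modifications
        ):
            row.pred_matched += 1
    return score


# ---------------------------------------------------------------------------
# corpus-level evaluation


def align_documents(
    gold_docs: Sequence[Document], pred_docs: Sequence[Document]
) -> list[tuple[Document, Document]]:
    """Pair documents by doc_id. A gold document without a prediction gets an
    empty target layer; a prediction without a gold document is an error."""
    gold_by_id = {d.doc_id: d for d in gold_docs}
    pred_by_id = {d.doc_id: d for d in pred_docs}
    orphans = sorted(set(pred_by_id) - set(gold_by_id))
    if orphans:
        raise ValueError(f"predictions for unknown documents: {', '.join(orphans)}")
    pairs = []
    for doc_id in sorted(gold_by_id):
        gold = gold_by_id[doc_id]
        pred = pred_by_id.get(doc_id)
        if pred is None:
            pred = Document(doc_id=doc_id, text=gold.text,
                            entities=list(gold.entities), equivs=list(gold.equivs))
        pairs.append((gold, pred))
    return pairs


def evaluate(
    gold_docs: Sequence[Document],
    pred_docs: Sequence[Document],
    schema: TaskSchema,
    criteria: CriteriaConfig = PRIMARY,
) -> EvalReport:
    """Micro-averaged per-type, per-category and total scores."""
    pooled: dict[tuple[str, str], CountRow] = {}
    for gold, pred in align_documents(gold_docs, pred_docs):
        doc_score = score_document(gold, pred, schema, criteria)
        for key, row in doc_score.counts.items():
            pooled.setdefault(key, CountRow(row.label, row.kind)).add(row)
    return _build_report(pooled, schema, criteria)


def _build_report(
    pooled: dict[tuple[str, str], CountRow],
    schema: TaskSchema,
    criteria: CriteriaConfig,
) -> EvalReport:
    rows: list[CountRow] = []
    subtotal = CountRow("Sub-total", "subtotal")
    for category in schema.event_categories():
        cat_row = CountRow(f"{category} total", "category")
        member_rows = []
        for name, spec in schema.event_types.items():
            if spec.category != category:
                continue
            row = pooled.get(("event", name))
            if row is None or (row.gold_total == 0 and row.pred_total == 0):
                continue
            member_rows.append(row)
            cat_row.add(row)
        if member_rows:
            rows.extend(member_rows)
            rows.append(cat_row)
            subtotal.add(cat_row)
    rows.append(subtotal)

    total = CountRow("TOTAL", "total")
    total.add(subtotal)
    if not criteria.core_targets:
        mod_total = CountRow("Modification total", "modification_total")
        mod_rows = []
        for mtype in schema.modification_types:
            row = pooled.get(("modification", mtype))
            if row is not None and (row.gold_total or row.pred_total):
                mod_rows.append(row)
                mod_total.add(row)
        if mod_rows:
            rows.extend(mod_rows)
            rows.append(mod_total)
            total.add(mod_total)
    rows.append(total)
    return EvalReport(task=schema.task, criteria=criteria, rows=rows)


# ---------------------------------------------------------------------------
# report writers


def report_to_tsv(report: EvalReport) -> str:
    lines = ["label\tgold\tgold_matched\tpred\tpred_matched\trecall\tprecision\tfscore"]
    for row in report.rows:
        m = prf(row)
        lines.append(
            f"{row.label}\t{row.gold_total}\t{row.gold_matched}"
            f"\t{row.pred_total}\t{row.pred_matched}"
            f"\t{m.recall:.2f}\t{m.precision:.2f}\t{m.fscore:.2f}"
        )
    return "\n".join(lines) + "\n"


def report_to_json(report: EvalReport) -> str:
    def row_obj(row: CountRow) -> dict:
        m = prf(row)
        return {
            "label": row.label,
            "kind": row.kind,
            "gold_total": row.gold_total,
            "gold_matched": row.gold_matched,
            "pred_total": row.pred_total,
            "pred_matched": row.pred_matched,
            "recall": m.recall,
            "precision": m.precision,
            "fscore": m.fscore,
        }

    payload = {
        "task": report.task,
        "criteria": {
            "core_targets": report.criteria.core_targets,
            "single_partial_penalty": report.criteria.single_partial_penalty,
            "span_rule": report.criteria.span_rule,
        },
        "rows": [row_obj(r) for r in report.rows],
    }
    return json.dumps(payload, indent=2) + "\n"
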