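"""Synthetic schema-conformant corpora, controlled perturbations, and a
naive reference scorer.

The generator emits "token soup" documents: whitespace-separated synthetic
words, entity mentions and event triggers each covering one word, events
drawn from the CG or PC type system with role fillers satisfying the role
constraints, regulation-family events nesting to a configurable depth, and
Equiv groups / Negation-Speculation modifications / non-core arguments
sampled at configurable rates. The evaluation criteria depend only on
spans, types and structure, so linguistic realism is deliberately absent.

Default rates loosely track the published corpus statistics (roughly one
modification per 13 events and one Equiv group per 19 events in the CG
data; about 6% of events carrying non-core arguments).

:func:`perturb` produces a "system output" from a gold corpus by seeded
edits with analytically known effects where those are unambiguous;
:func:`oracle_evaluate` recomputes the full evaluation by direct memoized
recursion and exhaustive search, as an independent check on the scorer.
"""

from __future__ import annotations

import itertools
import random
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

from .schema import TaskSchema, builtin_schema, role_base
from .standoff import (
    Argument,
    Document,
    EntityMention,
    EquivGroup,
    EventAnnotation,
    EventModification,
    EventTrigger,
    Span,
    check_references,
)
from .scoring import (
    CountRow,
    CriteriaConfig,
    EvalReport,
    align_documents,
    id_key,
)

# ---------------------------------------------------------------------------
# generation


@dataclass(frozen=True)
class GeneratorConfig:
    task: str = "CG"
    n_docs: int = 20
    events_per_doc: float = 10.0  # Poisson mean
    max_nesting_depth: int = 3
    p_regulation: float = 0.3
    p_equiv: float = 0.05
    p_modification: float = 0.075
    p_noncore: float = 0.06
    vocabulary_size: int = 200
    seed: int = 0


def _poisson(rng: random.Random, mean: float) -> int:
    # Knuth's method; means here are small
    import math

    L = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


class _DocBuilder:
    """Accumulates words and mentions, assigning offsets as it goes."""

    def __init__(self, doc_id: str, rng: random.Random, config: GeneratorConfig,
                 schema: TaskSchema):
        self.rng = rng
        self.config = config
        self.schema = schema
        self.words: list[str] = []
        self.offset = 0
        self.doc = Document(doc_id=doc_id, text="")
        self.t_counter = 0
        self.e_counter = 0
        self.m_counter = 0
        self.entities_by_type: dict[str, list[EntityMention]] = {}
        self._pad()  # leading pad so a left trigger shift always has a token

    def _word(self) -> str:
        return f"w{self.rng.randrange(self.config.vocabulary_size):03d}"

    def _append_word(self, word: str) -> Span:
        if self.words:
            self.offset += 1  # separating space
        start = self.offset
        self.words.append(word)
        self.offset += len(word)
        return Span(start, self.offset)

    def _pad(self) -> None:
        self._append_word(self._word())

    def new_entity(self, entity_type: str) -> EntityMention:
        word = self._word()
        span = self._append_word(word)
        self._pad()
        self.t_counter += 1
        ent = EntityMention(f"T{self.t_counter}", entity_type, span, word)
        self.doc.entities.append(ent)
        self.entities_by_type.setdefault(entity_type, []).append(ent)
        if self.rng.random() < self.config.p_equiv:
            alias_word = self._word()
            alias_span = self._append_word(alias_word)
            self._pad()
            self.t_counter += 1
            alias = EntityMention(f"T{self.t_counter}", entity_type, alias_span, alias_word)
            self.doc.entities.append(alias)
            self.entities_by_type[entity_type].append(alias)
            self.doc.equivs.append(EquivGroup(frozenset({ent.id, alias.id})))
        return ent

    def entity_for(self, category_name: str) -> EntityMention:
        category = self.schema.categories[category_name]
        pool = [
            e for t in sorted(category.entity_types)
            for e in self.entities_by_type.get(t, [])
        ]
        if pool and self.rng.random() < 0.5:
            return self.rng.choice(pool)
        entity_type = self.rng.choice(sorted(category.entity_types))
        return self.new_entity(entity_type)

    def new_trigger(self, event_type: str) -> EventTrigger:
        word = self._word()
        span = self._append_word(word)
        self._pad()
        self.t_counter += 1
        trig = EventTrigger(f"T{self.t_counter}", event_type, span, word)
        self.doc.triggers.append(trig)
        return trig

    def gen_event(self, budget: int) -> tuple[EventAnnotation, int]:
        """Generate one event (plus nested ones); returns (event, n produced).

        *budget* caps how many events this call may produce in total, so a
        corpus-level event count can be hit exactly.
        """
        rng = self.rng
        reg_types = sorted(
            n for n, s in self.schema.event_types.items() if s.category == "regulation"
        )
        other_types = sorted(
            n for n, s in self.schema.event_types.items() if s.category != "regulation"
        )
        depth_room = min(self.config.max_nesting_depth, budget - 1)
        nest = depth_room >= 1 and rng.random() < self.config.p_regulation
        event_type = rng.choice(reg_types if nest else other_types)
        spec = self.schema.event_types[event_type]

        produced = 1
        nested_theme: EventAnnotation | None = None
        if nest:
            nested_theme, n_sub = self.gen_event(budget - 1)
            produced += n_sub

        trig = self.new_trigger(event_type)
        args: list[Argument] = []
        role_counts: dict[str, int] = {}

        def add_arg(role: str, filler_id: str) -> None:
            # canonical presentation: later same-role slots carry suffixes
            role_counts[role] = role_counts.get(role, 0) + 1
            label = role if role_counts[role] == 1 else f"{role}{role_counts[role]}"
            args.append(Argument(label, filler_id))

        for rspec in spec.roles:
            if not rspec.core:
                continue
            if rspec.multiplicity == "one":
                n = 1
            elif rspec.multiplicity == "optional":
                n = 1 if rng.random() < 0.5 else 0
            elif rspec.multiplicity == "one_or_more":
                n = 1 + (1 if rng.random() < 0.3 else 0)
            else:  # zero_or_more
                n = rng.choice([0, 1, 1, 2])
            for i in range(n):
                if rspec.role == "Theme" and nested_theme is not None and i == 0:
                    add_arg("Theme", nested_theme.id)
                    continue
                filler = self.entity_for(rspec.filler)
                add_arg(rspec.role, filler.id)
        noncore = [r for r in spec.roles if not r.core]
        if noncore and rng.random() < self.config.p_noncore:
            rspec = rng.choice(noncore)
            if not any(role_base(a.role_label) == rspec.role for a in args):
                filler = self.entity_for(rspec.filler)
                add_arg(rspec.role, filler.id)

        self.e_counter += 1
        ev = EventAnnotation(f"E{self.e_counter}", event_type, trig.id, tuple(args))
        self.doc.events.append(ev)
        if rng.random() < self.config.p_modification:
            self.m_counter += 1
            mtype = rng.choice(self.schema.modification_types)
            self.doc.modifications.append(
                EventModification(f"M{self.m_counter}", mtype, ev.id)
            )
        return ev, produced

    def finish(self) -> Document:
        self.doc.text = " ".join(self.words)
        return self.doc


def generate(config: GeneratorConfig) -> list[Document]:
    """Deterministically generate a schema-conformant corpus."""
    if config.max_nesting_depth < 1:
        raise ValueError("max_nesting_depth must be >= 1")
    if not (0 <= config.p_regulation <= 1):
        raise ValueError("p_regulation must be a probability")
    schema = builtin_schema(config.task)
    master = random.Random(config.seed)
    docs = []
    for i in range(config.n_docs):
        rng = random.Random(master.randrange(2**31))
        builder = _DocBuilder(f"SYN{i:04d}", rng, config, schema)
        n_events = _poisson(rng, config.events_per_doc)
        produced = 0
        while produced < n_events:
            _, n = builder.gen_event(n_events - produced)
            produced += n
        docs.append(builder.finish())
    return docs


# ---------------------------------------------------------------------------
# perturbation


@dataclass(frozen=True)
class PerturbationPlan:
    delete_event: float = 0.0
    duplicate_event: float = 0.0
    retype_event: float = 0.0
    shift_trigger_one_token: float = 0.0
    drop_argument: float = 0.0
    add_spurious_argument: float = 0.0
    swap_theme_entity_within_equiv: float = 0.0
    flip_modification: float = 0.0
    seed: int = 0


@dataclass
class OpEffect:
    op: str
    n_applied: int = 0
    exact: bool = True  # expected score effect analytically determined


@dataclass
class ExpectedDelta:
    """Expected grand-total confusion counts under the primary criteria.

    ``gold_total`` counts gold instances (events + modifications). When
    every applied operation has an analytically exact effect (``exact``),
    the expected matched/total counts are filled in; context-dependent
    operations leave them None and clear the flag.
    """

    gold_total: int
    effects: list[OpEffect] = field(default_factory=list)
    expected_gold_matched: int | None = None
    expected_pred_total: int | None = None
    expected_pred_matched: int | None = None

    @property
    def exact(self) -> bool:
        return all(e.exact for e in self.effects if e.n_applied)


_EXACT_OPS = {
    "delete_event", "duplicate_event", "shift_trigger_one_token",
    "swap_theme_entity_within_equiv",
}


def perturb(
    gold: Sequence[Document], plan: PerturbationPlan, task: str = "CG"
) -> tuple[list[Document], ExpectedDelta]:
    """Apply the plan's edits (in field order) to fresh copies of *gold*."""
    schema = builtin_schema(task)
    rng = random.Random(plan.seed)
    effects = {
        op: OpEffect(op, exact=op in _EXACT_OPS)
        for op in (
            "delete_event", "duplicate_event", "retype_event",
            "shift_trigger_one_token", "drop_argument", "add_spurious_argument",
            "swap_theme_entity_within_equiv", "flip_modification",
        )
    }
    n_gold = sum(len(d.events) + len(d.modifications) for d in gold)
    deleted_instances = 0  # events + their modifications removed from pred

    out_docs = []
    for doc in gold:
        pred = doc.copy()
        deleted_instances += _apply_delete(pred, plan.delete_event, rng, effects)
        _apply_duplicate(pred, plan.duplicate_event, rng, effects)
        _apply_retype(pred, schema, plan.retype_event, rng, effects)
        _apply_shift(pred, plan.shift_trigger_one_token, rng, effects)
        _apply_drop_arg(pred, schema, plan.drop_argument, rng, effects)
        _apply_add_arg(pred, schema, plan.add_spurious_argument, rng, effects)
        _apply_equiv_swap(pred, plan.swap_theme_entity_within_equiv, rng, effects)
        _apply_flip_mod(pred, plan.flip_modification, rng, effects)
        bad = [v for v in check_references(pred) if v.severity == "error"]
        if bad:  # cascade bookkeeping bug, must never happen
            raise RuntimeError(f"perturbation left {doc.doc_id} inconsistent: {bad[0]}")
        out_docs.append(pred)

    expected = ExpectedDelta(gold_total=n_gold, effects=list(effects.values()))
    if expected.exact:
        expected.expected_gold_matched = n_gold - deleted_instances
        expected.expected_pred_total = n_gold - deleted_instances
        expected.expected_pred_matched = n_gold - deleted_instances
    return out_docs, expected


def _apply_delete(doc: Document, rate: float, rng: random.Random,
                  effects: dict[str, OpEffect]) -> int:
    if rate <= 0:
        return 0
    doomed = {
        ev.id for ev in sorted(doc.events, key=lambda e: id_key(e.id))
        if rng.random() < rate
    }
    # cascade: events referring to a deleted event go too, transitively
    changed = True
    while changed:
        changed = False
        for ev in doc.events:
            if ev.id in doomed:
                continue
            if any(a.filler_id in doomed for a in ev.args):
                doomed.add(ev.id)
                changed = True
    if not doomed:
        return 0
    n_mods = sum(1 for m in doc.modifications if m.target_id in doomed)
    used_triggers = {e.trigger_id for e in doc.events if e.id not in doomed}
    doc.events = [e for e in doc.events if e.id not in doomed]
    doc.modifications = [m for m in doc.modifications if m.target_id not in doomed]
    doc.triggers = [t for t in doc.triggers if t.id in used_triggers]
    effects["delete_event"].n_applied += len(doomed)
    return len(doomed) + n_mods


def _apply_duplicate(doc: Document, rate: float, rng: random.Random,
                     effects: dict[str, OpEffect]) -> None:
    if rate <= 0:
        return
    max_e = max((id_key(e.id)[1] for e in doc.events), default=0)
    copies = []
    for ev in sorted(doc.events, key=lambda e: id_key(e.id)):
        if rng.random() < rate:
            max_e += 1
            copies.append(replace(ev, id=f"E{max_e}"))
            effects["duplicate_event"].n_applied += 1
    doc.events.extend(copies)


def _signature(spec) -> tuple:
    return tuple(sorted((r.role, r.filler, r.multiplicity, r.core) for r in spec.roles))


def _apply_retype(doc: Document, schema: TaskSchema, rate: float,
                  rng: random.Random, effects: dict[str, OpEffect]) -> None:
    if rate <= 0:
        return
    triggers = doc.trigger_map()
    for i, ev in enumerate(list(doc.events)):
        if rng.random() >= rate:
            continue
        spec = schema.event_types[ev.type]
        alternatives = sorted(
            name for name, other in schema.event_types.items()
            if name != ev.type and _signature(other) == _signature(spec)
        )
        if not alternatives:
            continue
        new_type = rng.choice(alternatives)
        old_trig = triggers[ev.trigger_id]
        new_trig = replace(old_trig, type=new_type)
        doc.triggers[doc.triggers.index(old_trig)] = new_trig
        triggers[new_trig.id] = new_trig
        doc.events[i] = replace(ev, type=new_type)
        effects["retype_event"].n_applied += 1


def _apply_shift(doc: Document, rate: float, rng: random.Random,
                 effects: dict[str, OpEffect]) -> None:
    if rate <= 0:
        return
    token_spans = [Span(m.start(), m.end())
                   for m in re.finditer(r"[0-9A-Za-z]+", doc.text)]
    shifted_ids = set()
    for j, trig in enumerate(list(doc.triggers)):
        if rng.random() >= rate:
            continue
        prev = [t for t in token_spans if t.end <= trig.span.start]
        if not prev:
            continue
        new_span = Span(prev[-1].start, trig.span.end)
        new_trig = replace(trig, span=new_span,
                           surface=doc.text[new_span.start:new_span.end])
        doc.triggers[j] = new_trig
        shifted_ids.add(trig.id)
    effects["shift_trigger_one_token"].n_applied += len(shifted_ids)


def _apply_drop_arg(doc: Document, schema: TaskSchema, rate: float,
                    rng: random.Random, effects: dict[str, OpEffect]) -> None:
    if rate <= 0:
        return
    for i, ev in enumerate(list(doc.events)):
        if not ev.args or rng.random() >= rate:
            continue
        spec = schema.event_types.get(ev.type)
        core = spec.core_roles if spec else frozenset()
        optional = [a for a in ev.args if role_base(a.role_label) not in core]
        victim = rng.choice(optional if optional else list(ev.args))
        new_args = list(ev.args)
        new_args.remove(victim)
        doc.events[i] = replace(ev, args=tuple(new_args))
        effects["drop_argument"].n_applied += 1
        effects["drop_argument"].exact = False


def _apply_add_arg(doc: Document, schema: TaskSchema, rate: float,
                   rng: random.Random, effects: dict[str, OpEffect]) -> None:
    if rate <= 0:
        return
    for i, ev in enumerate(list(doc.events)):
        if rng.random() >= rate:
            continue
        spec = schema.event_types.get(ev.type)
        if spec is None:
            continue
        filled = {role_base(a.role_label) for a in ev.args}
        options = [r for r in spec.roles if r.role not in filled or r.repeatable]
        added = False
        for rspec in options:
            category = schema.categories[rspec.filler]
            pool = sorted(
                (e for e in doc.entities if category.admits_entity(e.type)),
                key=lambda e: id_key(e.id),
            )
            pool = [e for e in pool
                    if not any(a.filler_id == e.id and role_base(a.role_label) == rspec.role
                               for a in ev.args)]
            if pool:
                filler = rng.choice(pool)
                doc.events[i] = replace(
                    ev, args=ev.args + (Argument(rspec.role, filler.id),)
                )
                added = True
                break
        if added:
            effects["add_spurious_argument"].n_applied += 1
            effects["add_spurious_argument"].exact = False


def _apply_equiv_swap(doc: Document, rate: float, rng: random.Random,
                      effects: dict[str, OpEffect]) -> None:
    if rate <= 0:
        return
    classes: dict[str, frozenset[str]] = {}
    for group in doc.equivs:
        for member in group.member_ids:
            classes[member] = group.member_ids
    for i, ev in enumerate(list(doc.events)):
        new_args = list(ev.args)
        changed = False
        for j, arg in enumerate(new_args):
            siblings = sorted(classes.get(arg.filler_id, frozenset()) - {arg.filler_id})
            if siblings and rng.random() < rate:
                new_args[j] = replace(arg, filler_id=rng.choice(siblings))
                changed = True
                effects["swap_theme_entity_within_equiv"].n_applied += 1
        if changed:
            doc.events[i] = replace(ev, args=tuple(new_args))


def _apply_flip_mod(doc: Document, rate: float, rng: random.Random,
                    effects: dict[str, OpEffect]) -> None:
    if rate <= 0:
        return
    max_m = max((id_key(m.id)[1] for m in doc.modifications), default=0)
    modded = {m.target_id for m in doc.modifications}
    for ev in sorted(doc.events, key=lambda e: id_key(e.id)):
        if rng.random() >= rate:
            continue
        if ev.id in modded:
            doc.modifications = [m for m in doc.modifications if m.target_id != ev.id]
        else:
            max_m += 1
            doc.modifications.append(EventModification(f"M{max_m}", "Negation", ev.id))
        effects["flip_modification"].n_applied += 1
        effects["flip_modification"].exact = False


# ---------------------------------------------------------------------------
# naive reference scorer
#
# An independent re-derivation of the evaluation: direct memoized recursion
# over the acyclic event graph instead of the fixed-point pruning, explicit
# permutation search for argument alignment, and exhaustive enumeration for
# the SPP pairing. Deliberately slow and simple; refuses large inputs.

_ORACLE_EVENT_LIMIT = 15
_WORD = re.compile(r"[0-9A-Za-z]+")


class OracleSizeError(ValueError):
    pass


def _o_tokens(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _WORD.finditer(text)]


def _o_snap(tokens: list[tuple[int, int]], span: Span) -> tuple[int, int] | None:
    hits = [i for i, (s, e) in enumerate(tokens) if s < span.end and span.start < e]
    if not hits:
        return None
    return hits[0], hits[-1]


def _o_span_match(tokens, gold: Span, pred: Span, rule: str) -> bool:
    if gold == pred:
        return True
    if rule == "strict":
        return False
    g, p = _o_snap(tokens, gold), _o_snap(tokens, pred)
    if g is None or p is None:
        return False
    if rule == "approximate":
        return abs(p[0] - g[0]) <= 1 and abs(p[1] - g[1]) <= 1
    lo = tokens[max(g[0] - 1, 0)][0]
    hi = tokens[min(g[1] + 1, len(tokens) - 1)][1]
    return lo <= pred.start and pred.end <= hi


def _o_equiv_classes(doc: Document) -> dict[str, frozenset[str]]:
    classes: list[set[str]] = [set(g.member_ids) for g in doc.equivs]
    merged = True
    while merged:
        merged = False
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                if classes[i] & classes[j]:
                    classes[i] |= classes.pop(j)
                    merged = True
                    break
            if merged:
                break
    return {m: frozenset(c) for c in classes for m in c}


def _o_group(ev: EventAnnotation, roles: frozenset[str] | None) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for a in ev.args:
        base = role_base(a.role_label)
        if roles is None or base in roles:
            out.setdefault(base, []).append(a.filler_id)
    return out


def _o_structurally_identical(doc: Document) -> dict[str, str]:
    """Map each event id to the smallest id of a structurally identical event."""
    triggers = {t.id: t.span for t in doc.triggers}
    events = doc.event_map()
    memo: dict[tuple[str, str], bool] = {}

    def same(a_id: str, b_id: str) -> bool:
        if a_id == b_id:
            return True
        key = (min(a_id, b_id), max(a_id, b_id))
        if key in memo:
            return memo[key]
        memo[key] = False
        a, b = events.get(a_id), events.get(b_id)
        if a is None or b is None:  # entity ids: identity only
            result = False
        elif a.type != b.type or triggers[a.trigger_id] != triggers[b.trigger_id]:
            result = False
        else:
            ga, gb = _o_group(a, None), _o_group(b, None)
            result = set(ga) == set(gb) and all(
                len(ga[r]) == len(gb[r]) and any(
                    all(
                        (x == y) or same(x, y)
                        for x, y in zip(ga[r], perm)
                    )
                    for perm in itertools.permutations(gb[r])
                )
                for r in ga
            )
        memo[key] = result
        return result

    rep: dict[str, str] = {}
    ordered = sorted(events, key=id_key)
    for eid in ordered:
        for other in ordered:
            if same(other, eid):
                rep[eid] = other
                break
    return rep


def _o_normalize(doc: Document, schema: TaskSchema, core_only: bool) -> Document:
    out = doc.copy()
    if core_only:
        out.events = [
            replace(ev, args=tuple(
                a for a in ev.args
                if role_base(a.role_label) in schema.core_roles(ev.type)
            ))
            for ev in out.events
        ]
        out.modifications = []
    rep = _o_structurally_identical(out)
    out.events = [
        replace(ev, args=tuple(
            replace(a, filler_id=rep.get(a.filler_id, a.filler_id)) for a in ev.args
        ))
        for ev in out.events if rep[ev.id] == ev.id
    ]
    seen = set()
    mods = []
    for m in out.modifications:
        key = (m.type, rep.get(m.target_id, m.target_id))
        if key not in seen:
            seen.add(key)
            mods.append(EventModification(m.id, key[0], key[1]))
    out.modifications = mods
    return out


def _oracle_score_document(
    gold: Document, pred: Document, schema: TaskSchema, criteria: CriteriaConfig
) -> dict[tuple[str, str], CountRow]:
    gold = _o_normalize(gold, schema, criteria.core_targets)
    pred = _o_normalize(pred, schema, criteria.core_targets)
    tokens = _o_tokens(gold.text)
    classes = _o_equiv_classes(gold)
    gtrig = {t.id: t.span for t in gold.triggers}
    ptrig = {t.id: t.span for t in pred.triggers}
    gev, pev = gold.event_map(), pred.event_map()
    memo: dict[tuple[str, str, bool], bool] = {}

    def ent_same(a: str, b: str) -> bool:
        return a == b or b in classes.get(a, frozenset())

    def filler_ok(gf: str, pf: str) -> bool:
        g_is_ev, p_is_ev = gf in gev, pf in pev
        if g_is_ev != p_is_ev:
            return False
        if g_is_ev:
            return ev_match(gf, pf, True)
        return ent_same(gf, pf)

    def args_ok(g: EventAnnotation, p: EventAnnotation,
                roles: frozenset[str] | None) -> bool:
        ga, pa = _o_group(g, roles), _o_group(p, roles)
        if set(ga) != set(pa):
            return False
        for role in ga:
            if len(ga[role]) != len(pa[role]):
                return False
            if not any(
                all(filler_ok(x, y) for x, y in zip(ga[role], perm))
                for perm in itertools.permutations(pa[role])
            ):
                return False
        return True

    def ev_match(gid: str, pid: str, core_only: bool) -> bool:
        key = (gid, pid, core_only)
        if key not in memo:
            g, p = gev[gid], pev[pid]
            memo[key] = (
                g.type == p.type
                and _o_span_match(tokens, gtrig[g.trigger_id], ptrig[p.trigger_id],
                                  criteria.span_rule)
                and args_ok(g, p, schema.core_roles(g.type) if core_only else None)
            )
        return memo[key]

    matched_pairs = {
        (g.id, p.id)
        for g in gold.events for p in pred.events
        if ev_match(g.id, p.id, False)
    }
    gold_matched = {g for g, _ in matched_pairs}
    pred_matched = {p for _, p in matched_pairs}

    if criteria.single_partial_penalty:
        directions: dict[tuple[str, str], str] = {}
        for g in gold.events:
            if g.id in gold_matched:
                continue
            for p in pred.events:
                if p.id in pred_matched:
                    continue
                if g.type != p.type or not _o_span_match(
                    tokens, gtrig[g.trigger_id], ptrig[p.trigger_id], criteria.span_rule
                ):
                    continue
                ga, pa = _o_group(g, None), _o_group(p, None)
                n_g = sum(len(v) for v in ga.values())
                n_p = sum(len(v) for v in pa.values())

                def sub(inner, outer, gold_side_inner):
                    for role, fillers in inner.items():
                        others = outer.get(role, [])
                        if len(fillers) > len(others):
                            return False
                        hit = False
                        for combo in itertools.permutations(others, len(fillers)):
                            if all(
                                filler_ok(x, y) if gold_side_inner else filler_ok(y, x)
                                for x, y in zip(fillers, combo)
                            ):
                                hit = True
                                break
                        if not hit:
                            return False
                    return True

                if n_p > n_g and sub(ga, pa, True):
                    directions[(g.id, p.id)] = "extra"
                elif n_g > n_p and sub(pa, ga, False):
                    directions[(g.id, p.id)] = "missing"

        chosen = _o_lex_min_max_matching(sorted(
            directions, key=lambda e: (id_key(e[0]), id_key(e[1]))
        ))
        for gid, pid in chosen:
            if directions[(gid, pid)] == "extra":
                gold_matched.add(gid)
            else:
                pred_matched.add(pid)

    counts: dict[tuple[str, str], CountRow] = {}

    def row(kind: str, label: str) -> CountRow:
        return counts.setdefault((kind, label), CountRow(label, kind))

    for ev in gold.events:
        r = row("event", ev.type)
        r.gold_total += 1
        r.gold_matched += ev.id in gold_matched
    for ev in pred.events:
        r = row("event", ev.type)
        r.pred_total += 1
        r.pred_matched += ev.id in pred_matched
    for m in gold.modifications:
        r = row("modification", m.type)
        r.gold_total += 1
        r.gold_matched += any(
            pm.type == m.type and (m.target_id, pm.target_id) in matched_pairs
            for pm in pred.modifications
        )
    for m in pred.modifications:
        r = row("modification", m.type)
        r.pred_total += 1
        r.pred_matched += any(
            gm.type == m.type and (gm.target_id, m.target_id) in matched_pairs
            for gm in gold.modifications
        )
    return counts


def _o_lex_min_max_matching(
    edges: list[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Exhaustive search for the lexicographically smallest maximum matching."""
    golds = sorted({g for g, _ in edges}, key=id_key)
    best: list[list[tuple[str, str]]] = [[]]

    def better(a: list, b: list) -> bool:
        ka = (-len(a), [(id_key(g), id_key(p)) for g, p in a])
        kb = (-len(b), [(id_key(g), id_key(p)) for g, p in b])
        return ka < kb

    def recurse(i: int, used_p: set[str], acc: list[tuple[str, str]]) -> None:
        if len(acc) + (len(golds) - i) < len(best[0]):
            return  # cannot beat current best size
        if i == len(golds):
            if better(acc, best[0]):
                best[0] = list(acc)
            return
        g = golds[i]
        options = sorted((p for gg, p in edges if gg == g and p not in used_p),
                         key=id_key)
        for p in options:
            acc.append((g, p))
            used_p.add(p)
            recurse(i + 1, used_p, acc)
            used_p.discard(p)
            acc.pop()
        recurse(i + 1, used_p, acc)  # leave g unmatched

    recurse(0, set(), [])
    return best[0]


def oracle_evaluate(
    gold_docs: Sequence[Document],
    pred_docs: Sequence[Document],
    schema: TaskSchema,
    criteria: CriteriaConfig,
) -> EvalReport:
    """Reference evaluation by direct recursion; same report shape as
    :func:`bionlpeval.scoring.evaluate`. Refuses documents with more than
    15 events (the oracle is deliberately naive)."""
    from .scoring import _build_report

    pooled: dict[tuple[str, str], CountRow] = {}
    for gold, pred in align_documents(gold_docs, pred_docs):
        if max(len(gold.events), len(pred.events)) > _ORACLE_EVENT_LIMIT:
            raise OracleSizeError(
                f"{gold.doc_id}: more than {_ORACLE_EVENT_LIMIT} events; "
                "the reference scorer only handles fixture-scale documents"
            )
        for key, r in _oracle_score_document(gold, pred, schema, criteria).items():
            pooled.setdefault(key, CountRow(r.label, r.kind)).add(r)
    return _build_report(pooled, schema, criteria)
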