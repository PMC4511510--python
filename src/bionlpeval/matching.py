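"""Matching of predicted against gold event structures.

The official criteria relax exact identity in two ways: a predicted trigger
span may differ from the gold one by up to one word on each side, and an
event referred to *as an argument* of another event is compared on its core
arguments only. Entity mentions connected by Equiv relations are
interchangeable as argument fillers.

The span rule needs a notion of "word": here a token is a maximal run of
alphanumeric characters, and spans are snapped outward to the tokens they
overlap. Three span rules are supported:

``approximate``
    |first-token difference| <= 1 and |last-token difference| <= 1,
    applied symmetrically (the default).
``containment``
    the predicted span must lie within the gold span extended by one token
    on each side (the behaviour of the historical official tool).
``strict``
    exact character offsets.

Recursive event matching is computed as the greatest fixed point of a
pruning iteration: start from all same-type pairs with matching triggers
and repeatedly drop pairs whose core arguments cannot be aligned under the
current relation. On acyclic event graphs this coincides with direct
recursion (tested against a memoized recursive oracle).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

from .schema import TaskSchema, role_base
from .standoff import EquivGroup, EventAnnotation, Span

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")

SPAN_RULES = ("approximate", "strict", "containment")


@dataclass(frozen=True)
class TokenIndex:
    """Token spans of a text, ordered, non-overlapping."""

    tokens: tuple[Span, ...]

    def covering(self, span: Span) -> tuple[int, int] | None:
        """Indices of the first and last token overlapping *span*, or None."""
        first = last = None
        for i, tok in enumerate(self.tokens):
            if tok.start < span.end and span.start < tok.end:
                if first is None:
                    first = i
                last = i
            elif tok.start >= span.end:
                break
        if first is None:
            return None
        return first, last


def tokenize(text: str) -> TokenIndex:
    return TokenIndex(tuple(Span(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)))


def approx_span_match(
    gold: Span, pred: Span, idx: TokenIndex, rule: str = "approximate"
) -> bool:
    """Span comparison under the configured word-level relaxation."""
    if gold == pred:
        return True
    if rule == "strict":
        return False
    g = idx.covering(gold)
    p = idx.covering(pred)
    if g is None or p is None:
        warnings.warn(f"span overlapping no token: gold={gold} pred={pred}", stacklevel=2)
        return False
    if rule == "approximate":
        return abs(p[0] - g[0]) <= 1 and abs(p[1] - g[1]) <= 1
    if rule == "containment":
        lo = idx.tokens[max(g[0] - 1, 0)].start
        hi = idx.tokens[min(g[1] + 1, len(idx.tokens) - 1)].end
        return lo <= pred.start and pred.end <= hi
    raise ValueError(f"unknown span rule {rule!r}")


# ---------------------------------------------------------------------------
# Equiv closure (union-find)


class EquivClosure:
    """Partition of entity ids into interchangeability classes."""

    def __init__(self) -> None:
        self._parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self._parent
        if x not in parent:
            return x
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the representative
            lo, hi = sorted((ra, rb))
            self._parent[hi] = lo
            self._parent.setdefault(lo, lo)

    def same(self, a: str, b: str) -> bool:
        return self.find(a) == self.find(b)


def equiv_closure(groups: Iterable[EquivGroup], event_ids: Iterable[str] = ()) -> EquivClosure:
    closure = EquivClosure()
    events = set(event_ids)
    for group in groups:
        members = sorted(group.member_ids)
        for m in members:
            if m in events:
                raise ValueError(f"Equiv group contains event {m}")
        for other in members[1:]:
            closure.union(members[0], other)
    return closure


# ---------------------------------------------------------------------------
# argument alignment


def _group_by_role(ev: EventAnnotation, roles: frozenset[str] | None) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for arg in ev.args:
        base = role_base(arg.role_label)
        if roles is None or base in roles:
            out.setdefault(base, []).append(arg.filler_id)
    return out


def _fillers_match(
    g_filler: str, p_filler: str,
    gold_events: set[str], pred_events: set[str],
    closure: EquivClosure, relation: set[tuple[str, str]],
) -> bool:
    g_is_event = g_filler in gold_events
    p_is_event = p_filler in pred_events
    if g_is_event != p_is_event:
        return False
    if g_is_event:
        return (g_filler, p_filler) in relation
    return closure.same(g_filler, p_filler)


def _bijection_exists(gold: Sequence[str], pred: Sequence[str], ok) -> bool:
    """Perfect one-to-one correspondence between two filler multisets."""
    if len(gold) != len(pred):
        return False
    if len(gold) <= 1:
        return all(ok(g, p) for g, p in zip(gold, pred))
    # same-role slots are few (<= a handful); brute force is fine
    return any(
        all(ok(g, p) for g, p in zip(gold, perm)) for perm in permutations(pred)
    )


def args_align(
    g: EventAnnotation, p: EventAnnotation,
    relation: set[tuple[str, str]],
    closure: EquivClosure,
    gold_events: set[str], pred_events: set[str],
    roles: frozenset[str] | None,
) -> bool:
    """Whether g's and p's argument multisets correspond one-to-one.

    *roles* restricts comparison to a role set (core roles for nested
    matching); ``None`` compares every role. Role labels are normalized
    before grouping, so Theme/Theme2 are slots of one role.
    """
    g_args = _group_by_role(g, roles)
    p_args = _group_by_role(p, roles)
    if set(g_args) != set(p_args):
        return False

    def ok(gf: str, pf: str) -> bool:
        return _fillers_match(gf, pf, gold_events, pred_events, closure, relation)

    return all(
        _bijection_exists(g_args[role], p_args[role], ok) for role in g_args
    )


# ---------------------------------------------------------------------------
# the match relation


@dataclass
class MatchRelation:
    pairs: set[tuple[str, str]]
    mode: str = "core"

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


def core_match_relation(
    gold_events: Sequence[EventAnnotation],
    pred_events: Sequence[EventAnnotation],
    closure: EquivClosure,
    schema: TaskSchema,
    idx: TokenIndex,
    gold_triggers: dict[str, Span],
    pred_triggers: dict[str, Span],
    span_rule: str = "approximate",
) -> MatchRelation:
    """Greatest fixed point of core-argument matching.

    Start from every (gold, pred) pair with equal type and matching trigger
    spans; repeatedly remove pairs whose core arguments fail to align under
    the current relation, until stable.
    """
    gold_ids = {e.id for e in gold_events}
    pred_ids = {e.id for e in pred_events}
    by_gold = {e.id: e for e in gold_events}
    by_pred = {e.id: e for e in pred_events}

    pairs: set[tuple[str, str]] = set()
    for g in gold_events:
        if g.type not in schema.event_types:
            raise ValueError(f"unknown event type {g.type!r} ({g.id})")
        for p in pred_events:
            if p.type not in schema.event_types:
                raise ValueError(f"unknown event type {p.type!r} ({p.id})")
            if g.type != p.type:
                continue
            if approx_span_match(
                gold_triggers[g.trigger_id], pred_triggers[p.trigger_id], idx, span_rule
            ):
                pairs.add((g.id, p.id))

    changed = True
    while changed:
        changed = False
        for gid, pid in sorted(pairs):
            g, p = by_gold[gid], by_pred[pid]
            roles = schema.core_roles(g.type)
            if not args_align(g, p, pairs, closure, gold_ids, pred_ids, roles):
                pairs.discard((gid, pid))
                changed = True
    return MatchRelation(pairs=pairs, mode="core")


def full_match(
    g: EventAnnotation, p: EventAnnotation,
    core_rel: MatchRelation,
    closure: EquivClosure,
    gold_events: set[str], pred_events: set[str],
    idx: TokenIndex,
    gold_triggers: dict[str, Span],
    pred_triggers: dict[str, Span],
    span_rule: str = "approximate",
) -> bool:
    """Top-level primary-criteria match: equal types, triggers matching under
    the span rule, and ALL arguments (core and additional) aligned, with
    event-valued fillers compared through *core_rel*."""
    if g.type != p.type:
        return False
    if not approx_span_match(
        gold_triggers[g.trigger_id], pred_triggers[p.trigger_id], idx, span_rule
    ):
        return False
    return args_align(g, p, core_rel.pairs, closure, gold_events, pred_events, None)
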