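"""Reader/writer for the BioNLP-ST three-file standoff representation.

Each document is a triple ``<id>.txt`` (plain text), ``<id>.a1`` (the *given*
layer: entity mentions and Equiv relations) and ``<id>.a2`` (the *target*
layer: event triggers, events, and Negation/Speculation modifications).
Annotations reference the text by 0-based, end-exclusive character offsets
over Unicode code points.

Line format (tab-separated fields)::

    T1<TAB>Gene_or_gene_product 0 3<TAB>IL2          # entity or trigger
    E1<TAB>Gene_expression:T2 Theme:T1               # event
    M1<TAB>Negation E1                               # modification
    *<TAB>Equiv T1 T3                                # equivalence

Type names containing spaces are serialized with underscores, since the
format is whitespace-delimited within fields.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence


class StandoffError(ValueError):
    """Base class for errors raised while reading standoff data."""


class ParseError(StandoffError):
    """Malformed annotation line (wrong field count, bad offsets...)."""


class IntegrityError(StandoffError):
    """Annotation surface string disagrees with the document text."""


class ReferenceError_(StandoffError):
    """An identifier reference does not resolve within the document."""


class CycleError(StandoffError):
    """The event-argument graph contains a cycle."""


def type_to_wire(name: str) -> str:
    return name.replace(" ", "_")


def type_from_wire(name: str) -> str:
    return name.replace("_", " ")


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)``, 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class EntityMention:
    id: str
    type: str
    span: Span
    surface: str


@dataclass(frozen=True)
class EventTrigger:
    id: str
    type: str
    span: Span
    surface: str


@dataclass(frozen=True)
class Argument:
    """One event participant: a (possibly suffixed) role label and a filler id.

    Role labels may carry a numeric suffix distinguishing repeated slots of
    the same role (Theme, Theme2, ...); the suffix is presentation only.
    """

    role_label: str
    filler_id: str


@dataclass(frozen=True)
class EventAnnotation:
    id: str
    type: str
    trigger_id: str
    args: tuple[Argument, ...]


@dataclass(frozen=True)
class EventModification:
    id: str
    type: str  # Negation | Speculation
    target_id: str


@dataclass(frozen=True)
class EquivGroup:
    member_ids: frozenset[str]


@dataclass(frozen=True)
class Violation:
    """A single validation finding; ``severity`` is 'error' or 'warning'."""

    code: str
    annotation_id: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code} ({self.annotation_id}): {self.message}"


@dataclass
class Document:
    """A text with its given (entity) layer and target (event) layer."""

    doc_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    equivs: list[EquivGroup] = field(default_factory=list)
    triggers: list[EventTrigger] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)
    modifications: list[EventModification] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------

    def entity_map(self) -> dict[str, EntityMention]:
        return {e.id: e for e in self.entities}

    def trigger_map(self) -> dict[str, EventTrigger]:
        return {t.id: t for t in self.triggers}

    def event_map(self) -> dict[str, EventAnnotation]:
        return {e.id: e for e in self.events}

    def copy(self) -> "Document":
        return Document(
            doc_id=self.doc_id,
            text=self.text,
            entities=list(self.entities),
            equivs=list(self.equivs),
            triggers=list(self.triggers),
            events=list(self.events),
            modifications=list(self.modifications),
        )


# ---------------------------------------------------------------------------
# parsing


def _split_line(line: str, lineno: int, expected_fields: int | None = None) -> list[str]:
    fields = line.rstrip("\n").rstrip("\r").split("\t")
    if expected_fields is not None and len(fields) != expected_fields:
        raise ParseError(
            f"line {lineno}: expected {expected_fields} tab-separated fields, got {len(fields)}: {line!r}"
        )
    return fields


def _parse_textbound(fields: list[str], lineno: int) -> tuple[str, str, Span, str]:
    ann_id = fields[0]
    head = fields[1].split(" ")
    if len(head) != 3:
        raise ParseError(
            f"line {lineno}: expected 'Type start end' in second field, got {fields[1]!r}"
        )
    wire_type, s, e = head
    try:
        start, end = int(s), int(e)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer offsets in {fields[1]!r}") from None
    if not (0 <= start < end):
        raise ParseError(f"line {lineno}: invalid offsets {start} {end}")
    surface = fields[2] if len(fields) > 2 else ""
    return ann_id, type_from_wire(wire_type), Span(start, end), surface


def _check_surface(
    ann_id: str, span: Span, surface: str, text: str, lineno: int, lenient: bool
) -> None:
    if span.end > len(text):
        raise IntegrityError(
            f"line {lineno}: {ann_id} span [{span.start},{span.end}) exceeds text length {len(text)}"
        )
    actual = text[span.start : span.end]
    if actual != surface:
        msg = (
            f"line {lineno}: {ann_id} surface mismatch: annotation says {surface!r}, "
            f"text has {actual!r}"
        )
        if lenient:
            warnings.warn(msg, stacklevel=3)
        else:
            raise IntegrityError(msg)


def parse_document(
    doc_id: str,
    text_content: str,
    given_content: str,
    target_content: str,
    lenient: bool = False,
) -> Document:
    """Parse one document from its three file contents.

    The given layer holds entity ("T") and Equiv ("*") lines; the target
    layer holds trigger ("T"), event ("E") and modification ("M") lines.
    Equiv lines are tolerated in either file and always land in the given
    layer. With ``lenient=True`` a surface/offset mismatch is downgraded to
    a warning (tolerates normalization differences in third-party data).

    Raises :class:`ParseError`, :class:`IntegrityError`,
    :class:`ReferenceError_` or :class:`CycleError` on inconsistent input.
    """
    doc = Document(doc_id=doc_id, text=text_content)
    text = text_content

    # given layer: entities + equivs
    for lineno, line in _iter_lines(given_content):
        if line.startswith("T"):
            fields = _split_line(line, lineno)
            if len(fields) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2-3 fields, got {len(fields)}")
            ann_id, tname, span, surface = _parse_textbound(fields, lineno)
            _check_surface(ann_id, span, surface, text, lineno, lenient)
            doc.entities.append(EntityMention(ann_id, tname, span, surface))
        elif line.startswith("*"):
            doc.equivs.append(_parse_equiv(line, lineno))
        else:
            raise ParseError(
                f"line {lineno}: unexpected line in given layer (only T/* allowed): {line!r}"
            )

    # target layer: triggers + events + modifications (+ stray equivs)
    for lineno, line in _iter_lines(target_content):
        if line.startswith("T"):
            fields = _split_line(line, lineno)
            if len(fields) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2-3 fields, got {len(fields)}")
            ann_id, tname, span, surface = _parse_textbound(fields, lineno)
            _check_surface(ann_id, span, surface, text, lineno, lenient)
            doc.triggers.append(EventTrigger(ann_id, tname, span, surface))
        elif line.startswith("E"):
            doc.events.append(_parse_event(line, lineno))
        elif line.startswith("M"):
            doc.modifications.append(_parse_modification(line, lineno))
        elif line.startswith("*"):
            doc.equivs.append(_parse_equiv(line, lineno))
        else:
            raise ParseError(
                f"line {lineno}: unexpected line in target layer (T/E/M/* allowed): {line!r}"
            )

    violations = check_references(doc)
    errors = [
        v for v in violations
        if v.severity == "error" and not (lenient and v.code == "surface-mismatch")
    ]
    if errors:
        first = errors[0]
        exc = {
            "dangling-reference": ReferenceError_,
            "event-cycle": CycleError,
        }.get(first.code, ReferenceError_)
        raise exc("; ".join(str(v) for v in errors))
    return doc


def _iter_lines(content: str) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.strip("\r")
        if line.strip():
            yield lineno, line


def _parse_event(line: str, lineno: int) -> EventAnnotation:
    fields = _split_line(line, lineno, 2)
    ann_id = fields[0]
    parts = fields[1].split(" ")
    head = parts[0]
    if ":" not in head:
        raise ParseError(f"line {lineno}: event head must be Type:TriggerId, got {head!r}")
    wire_type, trigger_id = head.split(":", 1)
    args = []
    for part in parts[1:]:
        if not part:
            continue
        if ":" not in part:
            raise ParseError(f"line {lineno}: argument must be Role:Id, got {part!r}")
        role, filler = part.split(":", 1)
        if not role or not filler:
            raise ParseError(f"line {lineno}: empty role or filler in {part!r}")
        args.append(Argument(role, filler))
    return EventAnnotation(ann_id, type_from_wire(wire_type), trigger_id, tuple(args))


def _parse_modification(line: str, lineno: int) -> EventModification:
    fields = _split_line(line, lineno, 2)
    parts = fields[1].split(" ")
    if len(parts) != 2:
        raise ParseError(f"line {lineno}: modification must be 'Type EventId', got {fields[1]!r}")
    return EventModification(fields[0], parts[0], parts[1])


def _parse_equiv(line: str, lineno: int) -> EquivGroup:
    fields = _split_line(line, lineno, 2)
    parts = fields[1].split(" ")
    if parts[0] != "Equiv":
        raise ParseError(f"line {lineno}: '*' line must be an Equiv relation, got {parts[0]!r}")
    members = [p for p in parts[1:] if p]
    if len(members) < 2:
        raise ParseError(f"line {lineno}: Equiv needs at least two members")
    return EquivGroup(frozenset(members))


# ---------------------------------------------------------------------------
# reference checking


def check_references(doc: Document) -> list[Violation]:
    """Return every dangling-reference, duplicate-id, surface-mismatch and
    event-cycle finding; the empty list iff the document invariants hold."""
    out: list[Violation] = []

    seen_tb: set[str] = set()
    for mention in [*doc.entities, *doc.triggers]:
        if mention.id in seen_tb:
            out.append(
                Violation("duplicate-id", mention.id, f"text-bound id {mention.id} reused")
            )
        seen_tb.add(mention.id)
        if mention.span.end > len(doc.text):
            out.append(
                Violation(
                    "surface-mismatch",
                    mention.id,
                    f"span [{mention.span.start},{mention.span.end}) exceeds text length",
                )
            )
        elif doc.text[mention.span.start : mention.span.end] != mention.surface:
            out.append(
                Violation(
                    "surface-mismatch",
                    mention.id,
                    f"surface {mention.surface!r} != text "
                    f"{doc.text[mention.span.start:mention.span.end]!r}",
                )
            )

    entity_ids = {e.id for e in doc.entities}
    trigger_ids = {t.id for t in doc.triggers}
    event_ids: set[str] = set()
    for ev in doc.events:
        if ev.id in event_ids:
            out.append(Violation("duplicate-id", ev.id, f"event id {ev.id} reused"))
        event_ids.add(ev.id)

    for ev in doc.events:
        if ev.trigger_id not in trigger_ids:
            out.append(
                Violation(
                    "dangling-reference", ev.id, f"trigger {ev.trigger_id} not found"
                )
            )
        for arg in ev.args:
            if arg.filler_id not in entity_ids and arg.filler_id not in event_ids:
                out.append(
                    Violation(
                        "dangling-reference",
                        ev.id,
                        f"argument {arg.role_label}:{arg.filler_id} does not resolve",
                    )
                )

    mod_seen: set[tuple[str, str]] = set()
    mod_ids: set[str] = set()
    for mod in doc.modifications:
        if mod.id in mod_ids:
            out.append(Violation("duplicate-id", mod.id, f"modification id {mod.id} reused"))
        mod_ids.add(mod.id)
        if mod.target_id not in event_ids:
            out.append(
                Violation(
                    "dangling-reference", mod.id, f"target event {mod.target_id} not found"
                )
            )
        key = (mod.type, mod.target_id)
        if key in mod_seen:
            out.append(
                Violation(
                    "duplicate-modification",
                    mod.id,
                    f"duplicate {mod.type} on {mod.target_id}",
                )
            )
        mod_seen.add(key)

    for group in doc.equivs:
        for member in group.member_ids:
            if member not in entity_ids:
                out.append(
                    Violation(
                        "dangling-reference",
                        member,
                        f"Equiv member {member} is not an entity mention",
                    )
                )

    out.extend(_find_cycles(doc, event_ids))
    return out


def _find_cycles(doc: Document, event_ids: set[str]) -> list[Violation]:
    # iterative three-color DFS over the event->event argument graph
    graph: dict[str, list[str]] = {
        ev.id: [a.filler_id for a in ev.args if a.filler_id in event_ids]
        for ev in doc.events
    }
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {eid: WHITE for eid in graph}
    out: list[Violation] = []
    for root in sorted(graph):
        if color[root] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [(root, iter(graph[root]))]
        color[root] = GRAY
        path = [root]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    start = path.index(nxt)
                    members = path[start:]
                    out.append(
                        Violation(
                            "event-cycle",
                            members[0],
                            "event argument cycle: " + " -> ".join(members + [nxt]),
                        )
                    )
                elif color[nxt] == WHITE:
                    color[nxt] = GRAY
                    path.append(nxt)
                    stack.append((nxt, iter(graph[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                path.pop()
                stack.pop()
    return out


# ---------------------------------------------------------------------------
# serialization


def _role_labels_with_suffixes(args: Sequence[Argument]) -> list[str]:
    """Re-derive presentation labels: first slot bare, later slots suffixed."""
    from .schema import role_base  # local import to avoid a cycle

    counts: dict[str, int] = {}
    labels = []
    for arg in args:
        base = role_base(arg.role_label)
        counts[base] = counts.get(base, 0) + 1
        labels.append(base if counts[base] == 1 else f"{base}{counts[base]}")
    return labels


def serialize_textbound(tb: EntityMention | EventTrigger) -> str:
    return f"{tb.id}\t{type_to_wire(tb.type)} {tb.span.start} {tb.span.end}\t{tb.surface}"


def serialize_target_layer(doc: Document) -> str:
    """Render the target layer (.a2) back to its line-oriented form.

    Round-trips: parsing the output yields a structurally identical target
    layer. Repeated same-role arguments get numeric suffixes (Theme, Theme2).
    """
    known = {e.id for e in doc.entities} | {e.id for e in doc.events} | {
        t.id for t in doc.triggers
    }
    lines = []
    for trig in doc.triggers:
        lines.append(serialize_textbound(trig))
    for ev in doc.events:
        if ev.trigger_id not in known:
            raise ReferenceError_(f"{ev.id}: unresolvable trigger {ev.trigger_id}")
        labels = _role_labels_with_suffixes(ev.args)
        parts = [f"{type_to_wire(ev.type)}:{ev.trigger_id}"]
        for label, arg in zip(labels, ev.args):
            if arg.filler_id not in known:
                raise ReferenceError_(f"{ev.id}: unresolvable filler {arg.filler_id}")
            parts.append(f"{label}:{arg.filler_id}")
        lines.append(f"{ev.id}\t{' '.join(parts)}")
    for mod in doc.modifications:
        lines.append(f"{mod.id}\t{mod.type} {mod.target_id}")
    return "".join(line + "\n" for line in lines)


def serialize_given_layer(doc: Document) -> str:
    lines = [serialize_textbound(e) for e in doc.entities]
    for group in doc.equivs:
        lines.append("*\tEquiv " + " ".join(sorted(group.member_ids)))
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# directory-level I/O


def read_document(
    directory: str,
    doc_id: str,
    pred_dir: str | None = None,
    lenient: bool = False,
    missing_target_ok: bool = False,
) -> Document:
    """Read ``<doc_id>.txt/.a1`` from *directory* and ``.a2`` from
    *pred_dir* (defaults to the same directory). A missing .a2 is an empty
    target layer when ``missing_target_ok`` is set."""
    txt = _read(os.path.join(directory, doc_id + ".txt"))
    a1_path = os.path.join(directory, doc_id + ".a1")
    a1 = _read(a1_path) if os.path.exists(a1_path) else ""
    a2_path = os.path.join(pred_dir or directory, doc_id + ".a2")
    if os.path.exists(a2_path):
        a2 = _read(a2_path)
    elif missing_target_ok:
        a2 = ""
    else:
        raise FileNotFoundError(a2_path)
    return parse_document(doc_id, txt, a1, a2, lenient=lenient)


def read_corpus(
    directory: str, pred_dir: str | None = None, lenient: bool = False,
    missing_target_ok: bool = False,
) -> list[Document]:
    """Read every ``*.txt`` document triple under *directory*, sorted by id."""
    doc_ids = sorted(
        fn[:-4] for fn in os.listdir(directory) if fn.endswith(".txt")
    )
    return [
        read_document(directory, d, pred_dir, lenient, missing_target_ok)
        for d in doc_ids
    ]


def write_document(doc: Document, directory: str, target_only: bool = False) -> None:
    os.makedirs(directory, exist_ok=True)
    if not target_only:
        _write(os.path.join(directory, doc.doc_id + ".txt"), doc.text)
        _write(os.path.join(directory, doc.doc_id + ".a1"), serialize_given_layer(doc))
    _write(os.path.join(directory, doc.doc_id + ".a2"), serialize_target_layer(doc))


def write_corpus(docs: Iterable[Document], directory: str, target_only: bool = False) -> None:
    for doc in docs:
        write_document(doc, directory, target_only=target_only)


def _read(path: str) -> str:
    with open(path, encoding="utf-8", newline="") as fh:
        return fh.read()


def _write(path: str, content: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(content)
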