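"""Shared fixtures: schemas and a small builder for hand-made documents."""

from __future__ import annotations

import pytest

from bionlpeval.schema import builtin_schema
from bionlpeval.standoff import (
    Argument,
    Document,
    EntityMention,
    EquivGroup,
    EventAnnotation,
    EventModification,
    EventTrigger,
    Span,
)


class DocBuilder:
    """Builds a document word by word so offsets are always right."""

    def __init__(self, doc_id: str = "D1"):
        self.doc_id = doc_id
        self.words: list[str] = []
        self.offset = 0
        self.entities: list[EntityMention] = []
        self.triggers: list[EventTrigger] = []
        self.events: list[EventAnnotation] = []
        self.modifications: list[EventModification] = []
        self.equivs: list[EquivGroup] = []
        self._t = 0
        self._e = 0
        self._m = 0

    def _place(self, word: str) -> Span:
        if self.words:
            self.offset += 1
        start = self.offset
        self.words.append(word)
        self.offset += len(word)
        return Span(start, self.offset)

    def word(self, word: str) -> "DocBuilder":
        self._place(word)
        return self

    def entity(self, etype: str, word: str) -> str:
        span = self._place(word)
        self._t += 1
        self.entities.append(EntityMention(f"T{self._t}", etype, span, word))
        return f"T{self._t}"

    def trigger(self, etype: str, word: str) -> str:
        span = self._place(word)
        self._t += 1
        self.triggers.append(EventTrigger(f"T{self._t}", etype, span, word))
        return f"T{self._t}"

    def event(self, etype: str, trigger_id: str, *args: tuple[str, str]) -> str:
        self._e += 1
        self.events.append(EventAnnotation(
            f"E{self._e}", etype, trigger_id,
            tuple(Argument(role, filler) for role, filler in args),
        ))
        return f"E{self._e}"

    def modification(self, mtype: str, target: str) -> str:
        self._m += 1
        self.modifications.append(EventModification(f"M{self._m}", mtype, target))
        return f"M{self._m}"

    def equiv(self, *members: str) -> None:
        self.equivs.append(EquivGroup(frozenset(members)))

    def build(self) -> Document:
        return Document(
            doc_id=self.doc_id,
            text=" ".join(self.words),
            entities=list(self.entities),
            equivs=list(self.equivs),
            triggers=list(self.triggers),
            events=list(self.events),
            modifications=list(self.modifications),
        )


@pytest.fixture(scope="session")
def cg_schema():
    return builtin_schema("CG")


@pytest.fixture(scope="session")
def pc_schema():
    return builtin_schema("PC")


@pytest.fixture
def builder():
    return DocBuilder()


def simple_gene_expression_corpus(n_events: int = 10, doc_id: str = "D1") -> Document:
    """One document with *n_events* independent Gene expression events."""
    b = DocBuilder(doc_id)
    for i in range(n_events):
        ent = b.entity("Gene or gene product", f"gene{i}")
        trig = b.trigger("Gene expression", f"expr{i}")
        b.event("Gene expression", trig, ("Theme", ent))
    return b.build()
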