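"""Approximate randomization test for corpus-level F-score differences.

Two systems' outputs against one gold standard are compared on the
grand-total micro-averaged F-score. Because scoring is document-local and
only pooled at the end, each document contributes a fixed count tuple
(gold matched, gold total, predicted matched, predicted total) per system;
a permutation simply swaps the two systems' tuples on a random subset of
documents. Each repetition swaps every document independently with
probability 1/2 (the stratified shuffle standard for corpus-level F), and
the p-value uses the add-one estimator (r+1)/(R+1), valid at finite R.

The default repetition count is 9,999.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .schema import TaskSchema
from .scoring import CriteriaConfig, PRIMARY, align_documents, fscore, score_document
from .standoff import Document

DEFAULT_REPETITIONS = 9999


@dataclass(frozen=True)
class SignificanceResult:
    observed_delta: float  # |F_a - F_b| in percentage points
    repetitions: int
    exceed_count: int
    p_value: float
    seed: int
    f_a: float
    f_b: float

    def to_dict(self) -> dict:
        return {
            "observed_delta": self.observed_delta,
            "repetitions": self.repetitions,
            "exceed_count": self.exceed_count,
            "p_value": self.p_value,
            "seed": self.seed,
            "f_a": self.f_a,
            "f_b": self.f_b,
        }


def _per_document_totals(
    gold_docs: Sequence[Document],
    pred_docs: Sequence[Document],
    schema: TaskSchema,
    criteria: CriteriaConfig,
) -> dict[str, tuple[int, int, int, int]]:
    out = {}
    for gold, pred in align_documents(gold_docs, pred_docs):
        out[gold.doc_id] = score_document(gold, pred, schema, criteria).totals()
    return out


def _micro_f(counts: np.ndarray) -> float:
    gm, gt, pm, pt = counts.sum(axis=0)
    recall = 100.0 * gm / gt if gt else 0.0
    precision = 100.0 * pm / pt if pt else 0.0
    return fscore(recall, precision)


def approximate_randomization(
    gold_docs: Sequence[Document],
    pred_a: Sequence[Document],
    pred_b: Sequence[Document],
    schema: TaskSchema,
    criteria: CriteriaConfig = PRIMARY,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int = 0,
) -> SignificanceResult:
    """Stratified approximate randomization over documents.

    Both prediction sets must align to the gold documents by doc_id.
    Reproducible for a given *seed*: documents are processed in doc_id-sorted
    order and swap decisions come from a single named generator.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    totals_a = _per_document_totals(gold_docs, pred_a, schema, criteria)
    totals_b = _per_document_totals(gold_docs, pred_b, schema, criteria)

    doc_ids = sorted(totals_a)
    a = np.array([totals_a[d] for d in doc_ids], dtype=np.int64).reshape(-1, 4)
    b = np.array([totals_b[d] for d in doc_ids], dtype=np.int64).reshape(-1, 4)

    observed = abs(_micro_f(a) - _micro_f(b))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(repetitions):
        swap = rng.random(len(doc_ids)) < 0.5
        pa = np.where(swap[:, None], b, a)
        pb = np.where(swap[:, None], a, b)
        delta = abs(_micro_f(pa) - _micro_f(pb))
        if delta >= observed - 1e-12:
            exceed += 1

    return SignificanceResult(
        observed_delta=observed,
        repetitions=repetitions,
        exceed_count=exceed,
        p_value=(exceed + 1) / (repetitions + 1),
        seed=seed,
        f_a=_micro_f(a),
        f_b=_micro_f(b),
    )


def exact_randomization_p(
    gold_docs: Sequence[Document],
    pred_a: Sequence[Document],
    pred_b: Sequence[Document],
    schema: TaskSchema,
    criteria: CriteriaConfig = PRIMARY,
) -> float:
    """Exhaustive enumeration of all 2^n document-swap assignments (small
    corpora only); reference point for the Monte-Carlo estimate."""
    totals_a = _per_document_totals(gold_docs, pred_a, schema, criteria)
    totals_b = _per_document_totals(gold_docs, pred_b, schema, criteria)
    doc_ids = sorted(totals_a)
    n = len(doc_ids)
    if n > 16:
        raise ValueError(f"{n} documents: exhaustive enumeration limited to 16")
    a = np.array([totals_a[d] for d in doc_ids], dtype=np.int64).reshape(-1, 4)
    b = np.array([totals_b[d] for d in doc_ids], dtype=np.int64).reshape(-1, 4)
    observed = abs(_micro_f(a) - _micro_f(b))
    exceed = 0
    for mask in range(2**n):
        swap = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        pa = np.where(swap[:, None], b, a)
        pb = np.where(swap[:, None], a, b)
        if abs(_micro_f(pa) - _micro_f(pb)) >= observed - 1e-12:
            exceed += 1
    return exceed / 2**n
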