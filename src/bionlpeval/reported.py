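"""Officially reported CG/PC shared-task results, as reference data.

These are the published recall/precision/F percentages of the participating
systems (summary tables for both tasks, the PC per-type breakdown, and the
PC core-target summary). They ship here for metric-arithmetic consistency
checking: the F-score column of each table must be the harmonic mean of its
recall and precision columns.

Because the printed recall and precision are themselves rounded to two
decimals, the F recomputed from them can differ from the printed F by one
unit in the last place. :func:`check_entry` therefore tests the exact
consequence of that precision: the printed F must lie in the interval of
harmonic means over recall ± 0.005 and precision ± 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scoring import fscore, round2


@dataclass(frozen=True)
class ReportedScore:
    task: str       # CG | PC
    setting: str    # primary | core
    system: str
    label: str      # TOTAL or an event/modification type or subtotal label
    recall: float
    precision: float
    fscore: float


def _rows(task, setting, label, triples):
    return tuple(
        ReportedScore(task, setting, system, label, r, p, f)
        for system, r, p, f in triples
    )


# CG task, primary criteria, grand totals
CG_PRIMARY_SUMMARY = _rows("CG", "primary", "TOTAL", [
    ("TEES-2.1", 48.76, 64.17, 55.41),
    ("NaCTeM", 48.83, 55.82, 52.09),
    ("NCBI", 38.28, 58.84, 46.38),
    ("RelAgent", 41.73, 49.58, 45.32),
    ("UET-NII", 19.66, 62.73, 29.94),
    ("ISI", 16.44, 47.83, 24.47),
])

# PC task, primary criteria, grand totals
PC_PRIMARY_SUMMARY = _rows("PC", "primary", "TOTAL", [
    ("NaCTeM", 52.23, 53.48, 52.84),
    ("TEES-2.1", 47.15, 55.78, 51.10),
])

# PC task, core extraction targets, grand totals
PC_CORE_SUMMARY = _rows("PC", "core", "TOTAL", [
    ("NaCTeM", 54.14, 54.78, 54.46),
    ("TEES-2.1", 49.49, 57.02, 52.99),
])

# PC task, primary criteria, per event type: label -> (NaCTeM R,P,F, TEES R,P,F)
_PC_BY_TYPE = [
    ("Conversion", 34.33, 35.48, 34.90, 35.82, 42.86, 39.02),
    ("Phosphorylation", 62.46, 55.94, 59.02, 53.40, 66.00, 59.03),
    ("Dephosphorylation", 45.00, 56.25, 50.00, 35.00, 77.78, 48.28),
    ("Acetylation", 69.57, 72.73, 71.11, 82.61, 76.00, 79.17),
    ("Deacetylation", 33.33, 33.33, 33.33, 0.00, 0.00, 0.00),
    ("Methylation", 42.86, 60.00, 50.00, 57.14, 80.00, 66.67),
    ("Demethylation", 100.00, 100.00, 100.00, 100.00, 100.00, 100.00),
    ("Ubiquitination", 52.94, 64.29, 58.06, 58.82, 76.92, 66.67),
    ("Deubiquitination", 100.00, 100.00, 100.00, 100.00, 100.00, 100.00),
    ("Localization", 42.25, 61.22, 50.00, 43.66, 54.39, 48.44),
    ("Transport", 65.52, 61.29, 63.33, 56.55, 59.85, 58.16),
    ("Gene expression", 90.65, 83.15, 86.74, 84.55, 79.39, 81.89),
    ("Transcription", 71.15, 82.22, 76.29, 57.69, 73.17, 64.52),
    ("Translation", 0.00, 0.00, 0.00, 50.00, 100.00, 66.67),
    ("Simple total", 66.42, 64.80, 65.60, 60.40, 67.87, 63.92),
    ("Degradation", 78.57, 89.19, 83.54, 78.57, 78.57, 78.57),
    ("Activation", 78.54, 70.96, 74.56, 72.06, 72.06, 72.06),
    ("Inactivation", 44.62, 55.77, 49.57, 38.46, 45.45, 41.67),
    ("Binding", 64.96, 47.30, 54.74, 53.96, 53.96, 53.96),
    ("Dissociation", 38.46, 46.88, 42.25, 35.90, 45.16, 40.00),
    ("Pathway", 84.91, 75.50, 79.93, 70.94, 75.50, 73.15),
    ("General total", 69.07, 62.69, 65.72, 61.16, 65.74, 63.37),
    ("Regulation", 33.33, 33.97, 33.65, 29.73, 39.51, 33.93),
    ("Positive regulation", 35.49, 42.81, 38.81, 34.51, 45.45, 39.23),
    ("Negative regulation", 45.75, 50.64, 48.07, 41.02, 47.37, 43.97),
    ("Regulation total", 37.73, 42.79, 40.10, 35.17, 44.76, 39.39),
    ("Sub-total", 53.47, 53.96, 53.72, 48.23, 56.22, 51.92),
    ("Negation", 24.52, 35.87, 29.13, 25.16, 41.30, 31.27),
    ("Speculation", 15.79, 22.22, 18.46, 0.00, 0.00, 0.00),
    ("Modification total", 23.56, 34.65, 28.05, 22.41, 40.00, 28.73),
    ("TOTAL", 52.23, 53.48, 52.84, 47.15, 55.78, 51.10),
]

PC_PRIMARY_BY_TYPE = tuple(
    ReportedScore("PC", "primary", system, label, r, p, f)
    for label, nr, np_, nf, tr, tp, tf in _PC_BY_TYPE
    for system, r, p, f in (("NaCTeM", nr, np_, nf), ("TEES-2.1", tr, tp, tf))
)

ALL_REPORTED: tuple[ReportedScore, ...] = (
    CG_PRIMARY_SUMMARY + PC_PRIMARY_SUMMARY + PC_CORE_SUMMARY + PC_PRIMARY_BY_TYPE
)


def check_entry(entry: ReportedScore) -> tuple[float, float, bool]:
    """Recompute F from the entry's recall and precision.

    Returns (recomputed F rounded to 2 dp, |recomputed - printed|, whether
    the printed F is consistent with the printed recall/precision given
    their half-ulp rounding uncertainty).
    """
    f = round2(fscore(entry.recall, entry.precision))
    half = 0.005
    f_lo = fscore(max(entry.recall - half, 0.0), max(entry.precision - half, 0.0))
    f_hi = fscore(entry.recall + half, entry.precision + half)
    consistent = f_lo - 5e-3 <= entry.fscore <= f_hi + 5e-3
    return f, abs(f - entry.fscore), consistent
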