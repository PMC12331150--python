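"""Validation statistics for demultiplexed dual-column data.

Covers the three validation axes of the approach: empirical FDR via a
foreign-species entrapment proportion, column-assignment specificity on
single-column injections, and retention-time agreement between matched
single- and dual-column analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .demux import Assignment
from .synthdata import GroundTruth


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EntrapmentCounts:
    """Counts of entrapment (foreign-species) and target precursors in a
    filtered report.  Precursors matching both species count as targets."""

    n_entrapment: int
    n_target: int


@dataclass
class ConfusionResult:
    """Per-column assignment counts for a run, with the false positive
    rate (percent of confident assignments attributed to a column that
    carried no sample)."""

    n_col1: int
    n_col2: int
    loaded_columns: tuple[int, ...]
    fpr_percent: float | None


def entrapment_fdp(counts: EntrapmentCounts) -> float:
    """False discovery proportion in percent:
    FDP(%) = N_entrapment / (N_target + N_entrapment) * 100."""
    total = counts.n_entrapment + counts.n_target
    if counts.n_entrapment < 0 or counts.n_target < 0:
        raise EvaluationError("counts must be nonnegative")
    if total == 0:
        raise EvaluationError("FDP undefined for zero total precursors")
    return 100.0 * counts.n_entrapment / total


def entrapment_counts_from_assignments(assignments: list[Assignment]) -> EntrapmentCounts:
    n_e = sum(1 for a in assignments if a.species == "entrapment")
    return EntrapmentCounts(n_entrapment=n_e, n_target=len(assignments) - n_e)


def assignment_confusion(
    assignments: list[Assignment], ground_truth: GroundTruth
) -> ConfusionResult:
    """Column-assignment confusion for one run.

    For a single-column-loaded run the false positive rate is the
    percentage of confident assignments attributed to the unloaded
    column; for dual-loaded or blank runs no FPR is defined.
    """
    if not assignments:
        raise EvaluationError("no assignments to evaluate")
    n1 = sum(1 for a in assignments if a.column == 1)
    n2 = sum(1 for a in assignments if a.column == 2)
    loaded = tuple(c for c in (1, 2) if ground_truth.loads.get(c, 0) > 0)
    fpr = None
    if len(loaded) == 1:
        wrong = n2 if loaded[0] == 1 else n1
        fpr = 100.0 * wrong / (n1 + n2)
    return ConfusionResult(n_col1=n1, n_col2=n2, loaded_columns=loaded, fpr_percent=fpr)


def fpr_from_counts(n_loaded: int, n_unloaded: int) -> float:
    """False positive rate (%) from raw per-column assignment counts of a
    single-column injection."""
    if n_loaded + n_unloaded == 0:
        raise EvaluationError("no assignments")
    return 100.0 * n_unloaded / (n_loaded + n_unloaded)


def _rt_by_id(assignments: list[Assignment], column: int) -> dict[str, float]:
    return {a.precursor_id: a.observed_rt for a in assignments if a.column == column}


def rt_agreement(
    assignments_single: list[Assignment],
    assignments_dual: list[Assignment],
    column: int,
) -> tuple[float, float, float, int]:
    """OLS of dual-run observed RT on single-run observed RT over
    precursors confidently assigned to ``column`` in both runs.

    Returns (slope, intercept, r_squared, n_overlap).
    """
    single = _rt_by_id(assignments_single, column)
    dual = _rt_by_id(assignments_dual, column)
    shared = sorted(set(single) & set(dual))
    if len(shared) < 2:
        raise EvaluationError("need at least 2 overlapping precursors")
    x = np.array([single[p] for p in shared])
    y = np.array([dual[p] for p in shared])
    if np.allclose(x, x[0]):
        raise EvaluationError("degenerate regression: constant single-run RTs")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), len(shared)


def recovery_rate(
    assignments_single: list[Assignment],
    assignments_dual: list[Assignment],
    column: int,
) -> float:
    """Percentage of single-injection precursors (for a column) recovered
    in the dual-injection assignments."""
    single = {a.precursor_id for a in assignments_single if a.column == column}
    if not single:
        raise EvaluationError("single-run assignment set is empty")
    dual = {a.precursor_id for a in assignments_dual if a.column == column}
    return 100.0 * len(single & dual) / len(single)
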