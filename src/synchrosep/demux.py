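"""Column-resolved library search of dual-column chromatograms.

Every library precursor is searched under two hypotheses: the analyte
eluted from Column 1 (search window centered on its library RT) or from
Column 2 (window centered on the library RT shifted by the ΔRT model or
a scalar rt-shift).  Within a window of width ``rt_gap``, co-apexing
fragment peaks are grouped into candidates and scored by a transparent
composite: fragment coverage, spectral (cosine) agreement with the
library relative intensities, and retention-time proximity to the window
center.  Decoy library entries — fragment m/z shifted, retention time
randomized — are searched identically, and target-decoy q-values gate
the final report at q <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd

from .chromops import Trace, detect_peaks
from .drtmodel import DeltaRTModel, predict_offset
from .synthdata import LibraryEntry, MZ_RANGE


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchParams:
    """Demultiplexing search settings.

    ``rt_shift`` is either a scalar Column-2 offset in minutes or the
    string ``"model"`` to use a fitted ΔRT model.  ``rt_gap`` is the full
    window width in minutes, centered on the shifted library RT.
    """

    rt_shift: float | str = "model"
    rt_gap: float = 1.0
    min_fragments_matched: int = 3
    q_threshold: float = 0.01
    mz_tol: float = 0.01
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not self.rt_gap > 0:
            raise SearchError("rt_gap must be positive")
        if not 0 < self.q_threshold <= 1:
            raise SearchError("q_threshold must be in (0, 1]")


@dataclass
class Assignment:
    """One confident precursor match attributed to a column."""

    precursor_id: str
    protein_id: str
    column: int
    observed_rt: float
    score: float
    q_value: float
    area: float
    is_decoy: bool = False
    species: str = "target"
    run_id: str = "run"


@dataclass(frozen=True)
class Candidate:
    observed_rt: float
    score: float
    area: float
    n_matched: int
    fwhm: float


class PeakIndex:
    """All detected peaks of a run, indexed by trace m/z for fast
    fragment lookup."""

    def __init__(self, traces: list[Trace], min_snr: float = 3.0, min_points: int = 4):
        mzs, apexes, areas, fwhms = [], [], [], []
        for t in traces:
            for p in detect_peaks(t, min_snr=min_snr, min_points=min_points):
                mzs.append(p.trace_mz)
                apexes.append(p.apex_rt)
                areas.append(p.area)
                fwhms.append(p.fwhm)
        order = np.argsort(mzs) if mzs else np.array([], dtype=int)
        self.mz = np.asarray(mzs, dtype=float)[order]
        self.apex = np.asarray(apexes, dtype=float)[order]
        self.area = np.asarray(areas, dtype=float)[order]
        self.fwhm = np.asarray(fwhms, dtype=float)[order]

    def query(self, mz: float, tol: float) -> np.ndarray:
        lo = np.searchsorted(self.mz, mz - tol, side="left")
        hi = np.searchsorted(self.mz, mz + tol, side="right")
        return np.arange(lo, hi)


def shift_library(
    library: list[LibraryEntry],
    column: int,
    params: SearchParams,
    model: DeltaRTModel | None = None,
) -> np.ndarray:
    """Per-precursor search-window centers for a column hypothesis.

    Column 1 searches at the library RT; Column 2 at the library RT plus
    either the scalar rt-shift or the model-predicted offset.
    """
    refs = np.array([e.ref_rt for e in library])
    if column == 1:
        return refs
    if column != 2:
        raise SearchError("column must be 1 or 2")
    if params.rt_shift == "model":
        if model is None:
            raise SearchError("rt_shift='model' requires a fitted ΔRT model")
        return refs + predict_offset(model, refs)
    return refs + float(params.rt_shift)


def match_precursor(
    entry: LibraryEntry,
    peaks_by_mz: PeakIndex,
    center: float,
    rt_gap: float,
    min_fragments_matched: int = 3,
    mz_tol: float = 0.01,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> Candidate | None:
    """Best-scoring candidate for one precursor in one column's window,
    or None.

    Fragment peaks with apex inside [center - rt_gap/2, center + rt_gap/2]
    are clustered by apex proximity (spread <= one peak FWHM); a cluster
    needs >= ``min_fragments_matched`` distinct fragments.  Score =
    w1 * coverage + w2 * cosine(matched areas, library intensities) +
    w3 * (1 - |rt - center| / (rt_gap/2)).
    """
    if not rt_gap > 0:
        raise SearchError("rt_gap must be positive")
    half = rt_gap / 2.0
    hits_frag, hits_apex, hits_area, hits_fwhm = [], [], [], []
    for j, mz in enumerate(entry.fragment_mzs):
        for k in peaks_by_mz.query(float(mz), mz_tol):
            if abs(peaks_by_mz.apex[k] - center) <= half:
                hits_frag.append(j)
                hits_apex.append(peaks_by_mz.apex[k])
                hits_area.append(peaks_by_mz.area[k])
                hits_fwhm.append(peaks_by_mz.fwhm[k])
    if len(set(hits_frag)) < min_fragments_matched:
        return None
    order = np.argsort(hits_apex)
    frag = np.asarray(hits_frag)[order]
    apex = np.asarray(hits_apex)[order]
    area = np.asarray(hits_area)[order]
    fwhm = np.asarray(hits_fwhm)[order]
    co_tol = float(np.median(fwhm))

    w1, w2, w3 = weights
    rel = entry.fragment_rel_intensities
    best: Candidate | None = None
    start = 0
    for end in range(1, apex.size + 1):
        if end < apex.size and apex[end] - apex[start] <= co_tol:
            continue
        # cluster [start:end): keep the largest peak per fragment
        best_area: dict[int, tuple[float, float]] = {}
        for i in range(start, end):
            if frag[i] not in best_area or area[i] > best_area[frag[i]][0]:
                best_area[frag[i]] = (area[i], apex[i])
        if len(best_area) >= min_fragments_matched:
            fr = np.array(sorted(best_area))
            ar = np.array([best_area[j][0] for j in fr])
            ap = np.array([best_area[j][1] for j in fr])
            obs_rt = float(np.sum(ar * ap) / np.sum(ar))
            lib = rel[fr]
            cos = float(np.dot(ar, lib) / (np.linalg.norm(ar) * np.linalg.norm(lib)))
            coverage = len(fr) / rel.size
            rt_term = max(0.0, 1.0 - abs(obs_rt - center) / half)
            score = w1 * coverage + w2 * cos + w3 * rt_term
            cand = Candidate(
                observed_rt=obs_rt,
                score=score,
                area=float(ar.sum()),
                n_matched=len(fr),
                fwhm=co_tol,
            )
            if best is None or cand.score > best.score:
                best = cand
        start = end
    return best


def generate_decoys(
    library: list[LibraryEntry],
    seed: int = 0,
    mz_shift: float = 11.0,
) -> list[LibraryEntry]:
    """One decoy per target: fragment m/z shifted by ``mz_shift`` Th
    (wrapped into the acquisition range) and reference RT redrawn
    uniformly over the library's gradient window."""
    if not library:
        raise SearchError("library must be nonempty")
    rng = np.random.default_rng(seed)
    lo = min(e.ref_rt for e in library)
    hi = max(e.ref_rt for e in library)
    span = MZ_RANGE[1] - MZ_RANGE[0]
    decoys = []
    for e in library:
        shifted = MZ_RANGE[0] + (e.fragment_mzs - MZ_RANGE[0] + mz_shift) % span
        order = np.argsort(shifted)
        decoys.append(
            replace(
                e,
                precursor_id=f"DECOY_{e.precursor_id}",
                protein_id=f"DECOY_{e.protein_id}",
                fragment_mzs=shifted[order],
                fragment_rel_intensities=e.fragment_rel_intensities[order],
                ref_rt=float(rng.uniform(lo, hi)),
                decoy=True,
            )
        )
    return decoys


def compute_qvalues(records: list[Assignment]) -> list[Assignment]:
    """Target-decoy q-values in place.

    Sorted by descending score, q(s) = #decoys(score >= s) / max(1,
    #targets(score >= s)), made monotone nondecreasing down the list and
    capped at 1.
    """
    if not any(not r.is_decoy for r in records):
        raise SearchError("q-value estimation needs at least one target")
    order = sorted(range(len(records)), key=lambda i: -records[i].score)
    n_dec = 0
    n_tar = 0
    raw = [0.0] * len(order)
    pos = 0
    while pos < len(order):  # tie groups share one "score >= s" count
        end = pos
        s = records[order[pos]].score
        while end < len(order) and records[order[end]].score == s:
            if records[order[end]].is_decoy:
                n_dec += 1
            else:
                n_tar += 1
            end += 1
        q = min(1.0, n_dec / max(1, n_tar))
        for k in range(pos, end):
            raw[k] = q
        pos = end
    running = math.inf
    for pos in range(len(order) - 1, -1, -1):
        running = min(running, raw[pos])
        records[order[pos]].q_value = running
    return records


def assign_columns(
    run_traces: list[Trace],
    library: list[LibraryEntry],
    model: DeltaRTModel | None,
    params: SearchParams,
    decoy_seed: int = 0,
    run_id: str = "run",
    return_all: bool = False,
) -> list[Assignment]:
    """Demultiplex one run: search every target and decoy precursor under
    both column hypotheses, estimate q-values, and keep target
    assignments at q <= ``params.q_threshold``.

    A precursor genuinely loaded on both columns legitimately yields two
    assignments.  When the two column windows overlap and both
    hypotheses capture the same peak (observed RTs within one FWHM),
    only the higher-scoring hypothesis is kept, ties going to Column 1.
    """
    if not run_traces:
        return []
    index = PeakIndex(run_traces)
    decoys = generate_decoys(library, seed=decoy_seed)
    records: list[Assignment] = []
    for entries in (library, decoys):
        centers = {c: shift_library(entries, c, params, model) for c in (1, 2)}
        windows_overlap = bool(
            np.any(np.abs(centers[2] - centers[1]) < params.rt_gap)
        )
        for i, e in enumerate(entries):
            cands: dict[int, Candidate] = {}
            for col in (1, 2):
                cand = match_precursor(
                    e, index, float(centers[col][i]), params.rt_gap,
                    params.min_fragments_matched, params.mz_tol, params.weights,
                )
                if cand is not None:
                    cands[col] = cand
            if windows_overlap and len(cands) == 2:
                c1, c2 = cands[1], cands[2]
                if abs(c1.observed_rt - c2.observed_rt) <= max(c1.fwhm, c2.fwhm):
                    del cands[2 if c1.score >= c2.score else 1]
            for col, cand in cands.items():
                records.append(
                    Assignment(
                        precursor_id=e.precursor_id,
                        protein_id=e.protein_id,
                        column=col,
                        observed_rt=cand.observed_rt,
                        score=cand.score,
                        q_value=1.0,
                        area=cand.area,
                        is_decoy=e.decoy,
                        species=e.species,
                        run_id=run_id,
                    )
                )
    if not records or not any(not r.is_decoy for r in records):
        return []
    compute_qvalues(records)
    if return_all:
        return records
    return [
        r for r in records
        if not r.is_decoy and r.q_value <= params.q_threshold
    ]


def filter_report(assignments: list[Assignment], threshold: float = 0.01) -> list[Assignment]:
    """Keep assignments with q_value <= threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise SearchError("threshold must be in (0, 1]")
    return [a for a in assignments if a.q_value <= threshold]


# ---------------------------------------------------------------- I/O ----

REPORT_COLUMNS = [
    "run_id", "precursor_id", "protein_id", "column", "observed_rt_min",
    "score", "q_value", "area", "is_decoy", "species",
]


def to_report(assignments: list[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.run_id, a.precursor_id, a.protein_id, a.column, a.observed_rt,
             a.score, a.q_value, a.area, a.is_decoy, a.species)
            for a in assignments
        ],
        columns=REPORT_COLUMNS,
    )


def write_report(assignments: list[Assignment], path) -> None:
    to_report(assignments).to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def report_to_assignments(df: pd.DataFrame) -> list[Assignment]:
    return [
        Assignment(
            precursor_id=str(r.precursor_id),
            protein_id=str(r.protein_id),
            column=int(r.column),
            observed_rt=float(r.observed_rt_min),
            score=float(r.score),
            q_value=float(r.q_value),
            area=float(r.area),
            is_decoy=bool(r.is_decoy),
            species=str(getattr(r, "species", "target")),
            run_id=str(r.run_id),
        )
        for r in df.itertuples()
    ]
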