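"""Retention-time offset (ΔRT) modeling from duplicate identifications.

When two gradient separations share one MS inlet with a controlled delay,
every analyte present in both samples is identified twice, at retention
times separated by the delay.  Those duplicate PSMs are the raw material
for an empirical model of the offset as a function of Column 1 retention
time: filter PSMs to high confidence, pair precursors seen exactly twice
with a gap of more than 30 s, treat the earlier member as Column 1, and
smooth (rt2 - rt1) against rt1 with LOWESS.

The default fits a single LOWESS to the pairwise differences.  The
alternative (``method="difference"``) smooths each column's retention
times against Column 1 RT separately and differences the two curves on a
common grid; at the smoothing level the two are equivalent for paired
data, and both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


class ModelFitError(ValueError):
    """Raised when a ΔRT model cannot be fitted (e.g. too few pairs)."""


@dataclass(frozen=True)
class PSMRecord:
    """A peptide-spectrum match: precursor id, observed RT (min),
    expectation value (smaller is better) and quality rank."""

    precursor_id: str
    rt: float
    expect: float
    rank: int = 1


@dataclass(frozen=True)
class DuplicatePair:
    """One precursor identified on both columns; rt_col1 < rt_col2 by
    the earlier-is-Column-1 convention."""

    precursor_id: str
    rt_col1: float
    rt_col2: float


@dataclass
class DeltaRTModel:
    """Fitted RT-dependent offset between Column 1 and Column 2.

    ``support`` (strictly increasing Column-1 RTs, minutes) and
    ``offset`` (ΔRT at each support point) define the curve; prediction
    linearly interpolates inside ``valid_range`` and clamps to the
    boundary value outside it.
    """

    support: np.ndarray
    offset: np.ndarray
    lowess_frac: float
    valid_range: tuple[float, float]
    n_pairs: int = 0

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.support.size == 0:
            raise ModelFitError("empty model support")
        if not np.all(np.diff(self.support) > 0):
            raise ModelFitError("model support must be strictly increasing")
        if not np.all(np.isfinite(self.offset)) or np.any(self.offset <= 0):
            raise ModelFitError("model offsets must be finite and positive")

    def predict(self, rt_col1):
        return predict_offset(self, rt_col1)


def filter_psms(psms: list[PSMRecord], evalue_max: float = 1e-5) -> list[PSMRecord]:
    """Keep PSMs with expectation value strictly below ``evalue_max``."""
    if not evalue_max > 0:
        raise ValueError("evalue_max must be positive")
    return [p for p in psms if p.expect < evalue_max]


def pair_duplicates(
    psms: list[PSMRecord], min_gap_seconds: float = 30.0
) -> list[DuplicatePair]:
    """Pair precursors observed exactly twice with an RT gap strictly
    greater than ``min_gap_seconds``; the earlier RT becomes Column 1.

    Precursors seen once, or more than twice, are discarded outright:
    with more than two observations the pairing is ambiguous, and
    choosing among them risks mispairing.
    """
    if not min_gap_seconds > 0:
        raise ValueError("min_gap_seconds must be positive")
    min_gap_min = min_gap_seconds / 60.0
    by_id: dict[str, list[float]] = {}
    for p in psms:
        by_id.setdefault(p.precursor_id, []).append(p.rt)
    pairs = []
    for pid, rts in by_id.items():
        if len(rts) != 2:
            continue
        lo, hi = sorted(rts)
        if hi - lo > min_gap_min:
            pairs.append(DuplicatePair(pid, lo, hi))
    pairs.sort(key=lambda d: d.rt_col1)
    return pairs


def _dedupe_support(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # average y over tied x so the support is strictly increasing
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    return ux, uy


def fit_delta_rt(
    pairs: list[DuplicatePair],
    lowess_frac: float = 0.3,
    min_pairs: int = 20,
    method: str = "direct",
) -> DeltaRTModel:
    """Fit the LOWESS ΔRT model from duplicate pairs.

    ``method="direct"`` smooths (rt_col2 - rt_col1) against rt_col1;
    ``method="difference"`` smooths each column's RTs against rt_col1 and
    takes the difference of the two curves on the rt_col1 grid.
    """
    if not 0 < lowess_frac <= 1:
        raise ValueError("lowess_frac must be in (0, 1]")
    if len(pairs) < min_pairs:
        raise ModelFitError(
            f"need at least {min_pairs} duplicate pairs to fit; got {len(pairs)}"
        )
    x = np.array([p.rt_col1 for p in pairs], dtype=float)
    if method == "direct":
        y = np.array([p.rt_col2 - p.rt_col1 for p in pairs], dtype=float)
        sm = _sm_lowess(y, x, frac=lowess_frac, return_sorted=True)
        sx, sy = _dedupe_support(sm[:, 0], sm[:, 1])
    elif method == "difference":
        y2 = np.array([p.rt_col2 for p in pairs], dtype=float)
        y1 = np.array([p.rt_col1 for p in pairs], dtype=float)
        sm2 = _sm_lowess(y2, x, frac=lowess_frac, return_sorted=True)
        sm1 = _sm_lowess(y1, x, frac=lowess_frac, return_sorted=True)
        sx2, sy2 = _dedupe_support(sm2[:, 0], sm2[:, 1])
        sx1, sy1 = _dedupe_support(sm1[:, 0], sm1[:, 1])
        sx = np.unique(np.concatenate([sx1, sx2]))
        sy = np.interp(sx, sx2, sy2) - np.interp(sx, sx1, sy1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DeltaRTModel(
        support=sx,
        offset=sy,
        lowess_frac=lowess_frac,
        valid_range=(float(x.min()), float(x.max())),
        n_pairs=len(pairs),
    )


def predict_offset(model: DeltaRTModel, rt_col1):
    """ΔRT at the given Column 1 RT(s): linear interpolation over the
    support, clamped to the boundary value outside ``valid_range``."""
    if model is None or model.support.size == 0:
        raise ModelFitError("model is not fitted")
    out = np.interp(np.asarray(rt_col1, dtype=float), model.support, model.offset)
    return float(out) if np.ndim(rt_col1) == 0 else out


def evaluate_model(
    model: DeltaRTModel, standards: list[tuple[float, float]]
) -> tuple[np.ndarray, float]:
    """Signed model errors at standards given as (rt_col1, rt_col2).

    error_i = (rt_col2_i - rt_col1_i) - predict_offset(rt_col1_i).
    Returns (signed errors, max absolute error) in minutes.
    """
    if not standards:
        raise ValueError("standards must be nonempty")
    arr = np.asarray(standards, dtype=float)
    errors = (arr[:, 1] - arr[:, 0]) - predict_offset(model, arr[:, 0])
    return errors, float(np.max(np.abs(errors)))


# ---------------------------------------------------------------- I/O ----

PSM_COLUMNS = ["precursor_id", "rt_min", "expect", "rank"]


def read_psms(path) -> list[PSMRecord]:
    """Read the PSM TSV (precursor_id, rt_min, expect, rank); this table
    stands in for parsed search-engine PSM output."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PSMRecord(str(r.precursor_id), float(r.rt_min), float(r.expect), int(r.rank))
        for r in df.itertuples()
    ]


def write_psms(psms: list[PSMRecord], path) -> None:
    pd.DataFrame(
        [(p.precursor_id, p.rt, p.expect, p.rank) for p in psms],
        columns=PSM_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_model(model: DeltaRTModel, tsv_path, meta_path=None) -> None:
    """Write the model as a (support_rt_min, offset_min) TSV plus a JSON
    metadata block (frac, valid_range, n_pairs)."""
    pd.DataFrame(
        {"support_rt_min": model.support, "offset_min": model.offset}
    ).to_csv(tsv_path, sep="\t", index=False)
    if meta_path is None:
        meta_path = Path(tsv_path).with_suffix(".json")
    Path(meta_path).write_text(
        json.dumps(
            {
                "lowess_frac": model.lowess_frac,
                "valid_range": list(model.valid_range),
                "n_pairs": model.n_pairs,
            },
            indent=1,
        )
    )


def read_model(tsv_path, meta_path=None) -> DeltaRTModel:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    if meta_path is None:
        meta_path = Path(tsv_path).with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    return DeltaRTModel(
        support=df["support_rt_min"].to_numpy(),
        offset=df["offset_min"].to_numpy(),
        lowess_frac=float(meta["lowess_frac"]),
        valid_range=tuple(meta["valid_range"]),
        n_pairs=int(meta.get("n_pairs", 0)),
    )
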