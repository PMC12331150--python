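"""Quantitative matrices and performance metrics.

Builds precursor- or protein-level area matrices from filtered
demultiplexing reports (protein rollup = sum of precursor areas) and
computes the standard label-free figures of merit: replicate %RSD,
dilution-series linearity (per-row R^2 with an at-least-three-points
rule), cross-column log2 regression, cumulative identifications over
retention time, and retention-time-binned missingness between single-
and dual-column analyses.

Normalization is median-ratio scaling across runs and is off by default;
dilution series must be built with normalization off, since scaling to a
common median would erase the loading differences under study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .demux import Assignment


class QuantError(ValueError):
    pass


@dataclass
class QuantTable:
    """Area matrix: rows are precursor or protein ids, columns are
    (run_id, column) sample pairs; ``design`` maps each sample to its
    load in ng."""

    values: pd.DataFrame            # index: ids; columns: MultiIndex (run_id, column)
    design: pd.DataFrame            # index: MultiIndex (run_id, column); column: load_ng
    level: str = "precursor"

    def samples_for_column(self, column: int) -> pd.DataFrame:
        cols = [c for c in self.values.columns if c[1] == column]
        return self.values[cols]


def build_quant_table(
    reports: pd.DataFrame,
    level: str = "precursor",
    normalize: bool = False,
    design: dict[tuple[str, int], float] | None = None,
) -> QuantTable:
    """Pivot one or more run reports into a quantity matrix.

    ``reports`` is the concatenated report table (columns run_id,
    precursor_id, protein_id, column, area, ...), already filtered at
    q <= 0.01 and decoy-free.  Protein level sums precursor areas per
    sample.  ``normalize=True`` applies median-ratio scaling across
    samples; leave off for dilution series.
    """
    if level not in ("precursor", "protein"):
        raise QuantError(f"unknown level {level!r}")
    df = reports[~reports["is_decoy"].astype(bool)] if "is_decoy" in reports else reports
    if df.empty:
        raise QuantError("empty report")
    key = "precursor_id" if level == "precursor" else "protein_id"
    mat = df.pivot_table(
        index=key, columns=["run_id", "column"], values="area", aggfunc="sum"
    )
    if normalize:
        mat = _median_ratio_normalize(mat)
    if design is None:
        design_df = pd.DataFrame(
            {"load_ng": [np.nan] * len(mat.columns)}, index=mat.columns
        )
    else:
        design_df = pd.DataFrame(
            {"load_ng": [design.get(tuple(c), np.nan) for c in mat.columns]},
            index=mat.columns,
        )
    return QuantTable(values=mat, design=design_df, level=level)


def _median_ratio_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    complete = mat.dropna()
    if complete.empty:
        raise QuantError("normalization needs rows quantified in every sample")
    log_ref = np.log(complete).mean(axis=1)
    factors = {}
    for c in mat.columns:
        ratios = np.log(complete[c]) - log_ref
        factors[c] = np.exp(np.median(ratios))
    return mat / pd.Series(factors)


def percent_rsd(values) -> float:
    """100 * sample standard deviation / mean over replicate values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise QuantError("need at least 2 finite values")
    mean = v.mean()
    if mean == 0:
        raise QuantError("%RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def replicate_rsd_table(table: QuantTable, min_replicates: int = 2) -> pd.DataFrame:
    """Per-(row, column) %RSD across replicate runs at identical loads.

    Rows must be quantified in at least ``min_replicates`` replicates of
    a (column, load) group to contribute.
    """
    rows = []
    groups: dict[tuple[int, float], list] = {}
    for c in table.values.columns:
        load = float(table.design.loc[c, "load_ng"])
        groups.setdefault((c[1], load), []).append(c)
    for (column, load), cols in groups.items():
        if len(cols) < min_replicates:
            continue
        sub = table.values[cols]
        for rid, vals in sub.iterrows():
            v = vals.to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size >= min_replicates and v.mean() > 0:
                rows.append((rid, column, load, percent_rsd(v)))
    if not rows:
        raise QuantError("no rows with enough replicates")
    return pd.DataFrame(rows, columns=["id", "column", "load_ng", "rsd_percent"])


def dilution_r2(
    table: QuantTable,
    series_loads: list[float] | None = None,
    min_points: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Per-row dilution linearity for each LC column.

    For every row and column, replicate areas are averaged per
    concentration point (load), and mean area is regressed on load by
    OLS.  Rows detected at fewer than ``min_points`` concentration
    points on a column are excluded for that column.  Returns the
    per-(row, column) R^2 table and the median R^2.
    """
    loads = table.design["load_ng"]
    rows = []
    for column in sorted({c[1] for c in table.values.columns}):
        cols = [c for c in table.values.columns if c[1] == column]
        col_loads = loads[cols]
        use_loads = sorted(set(col_loads.dropna()))
        if series_loads is not None:
            use_loads = [l for l in use_loads if l in set(series_loads)]
        if len(use_loads) < min_points:
            continue
        means = {}
        for load in use_loads:
            rep_cols = [c for c in cols if col_loads[c] == load]
            means[load] = table.values[rep_cols].mean(axis=1)
        mean_mat = pd.DataFrame(means)
        for rid, vals in mean_mat.iterrows():
            mask = vals.notna()
            if mask.sum() < min_points:
                continue
            x = np.array([l for l in vals.index[mask]], dtype=float)
            y = vals[mask].to_numpy(dtype=float)
            fit = linregress(x, y)
            rows.append((rid, column, float(fit.rvalue**2)))
    if not rows:
        raise QuantError("no rows detected at enough concentration points")
    out = pd.DataFrame(rows, columns=["id", "column", "r_squared"])
    return out, float(out["r_squared"].median())


def cross_column_regression(
    table: QuantTable, log_base_2: bool = True
) -> tuple[float, float, float]:
    """OLS of Column 2 quantities on Column 1 quantities (log2 by
    default) over rows quantified on both columns; quantities are mean
    areas across that column's runs.  Returns (slope, intercept, r)."""
    q1 = table.samples_for_column(1).mean(axis=1)
    q2 = table.samples_for_column(2).mean(axis=1)
    both = q1.notna() & q2.notna() & (q1 > 0) & (q2 > 0)
    if both.sum() < 2:
        raise QuantError("need at least 2 rows quantified on both columns")
    x, y = q1[both].to_numpy(), q2[both].to_numpy()
    if log_base_2:
        x, y = np.log2(x), np.log2(y)
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def cumulative_ids(assignments: list[Assignment], rt_grid) -> np.ndarray:
    """Distinct (protein, column) identifications accumulated over RT.

    At each grid point: the number of distinct (protein_id, column)
    pairs whose earliest confident observation is at or before that RT.
    Identifications on different columns count separately.
    """
    grid = np.asarray(rt_grid, dtype=float)
    if grid.size and not np.all(np.diff(grid) > 0):
        raise QuantError("rt_grid must be increasing")
    first: dict[tuple[str, int], float] = {}
    for a in assignments:
        key = (a.protein_id, a.column)
        if key not in first or a.observed_rt < first[key]:
            first[key] = a.observed_rt
    firsts = np.sort(np.array(list(first.values()), dtype=float))
    return np.searchsorted(firsts, grid, side="right")


def missingness_by_rt(
    single_assignments: list[Assignment],
    dual_assignments: list[Assignment],
    bins: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-RT-bin fraction of single-injection precursors absent from
    the dual-injection assignments for the same column.

    Returns (bin_edges, fractions); empty bins yield NaN.
    """
    if np.ndim(bins) == 0 and int(bins) < 2:
        raise QuantError("need at least 2 bins")
    if not single_assignments:
        raise QuantError("single-run assignment set is empty")
    dual = {(a.precursor_id, a.column) for a in dual_assignments}
    rts = np.array([a.observed_rt for a in single_assignments])
    missing = np.array(
        [(a.precursor_id, a.column) not in dual for a in single_assignments],
        dtype=float,
    )
    edges = np.histogram_bin_edges(rts, bins=bins)
    which = np.clip(np.digitize(rts, edges) - 1, 0, len(edges) - 2)
    frac = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            frac[b] = missing[sel].mean()
    return edges, frac


# ---------------------------------------------------------------- I/O ----


def write_quant_table(table: QuantTable, tsv_path, design_path) -> None:
    flat = table.values.copy()
    flat.columns = [f"{r}|col{c}" for r, c in flat.columns]
    flat.to_csv(tsv_path, sep="\t")
    design = {
        f"{r}|col{c}": (None if not np.isfinite(l) else float(l))
        for (r, c), l in table.design["load_ng"].items()
    }
    import json
    from pathlib import Path

    Path(design_path).write_text(
        json.dumps({"level": table.level, "load_ng": design}, indent=1)
    )
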