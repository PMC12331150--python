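"""Synthetic dual-column LC-MS data with known ground truth.

Two gradient separations run into one MS inlet with a controlled delay,
so each analyte loaded on both columns elutes twice in the same extracted
ion chromatogram: once at its Column 1 retention time and once later by
ΔRT(t).  This module generates spectral libraries, fragment-level
chromatographic runs (Gaussian elution peaks sampled at the MS1 cycle
time), dilution series, and simulated PSM tables, together with sidecar
ground truth for every injected peak.

Model summary
-------------
* Library: precursors with 4-7 fragments, uniform reference RTs over the
  gradient window, m/z drawn in 380-980 Th, log-normal abundances
  (log10 sd 0.8) expressed as expected integrated area at the 200 ng
  reference load.  A configurable fraction is labeled as foreign-species
  ("entrapment") entries that exist only in the search space, never in
  the sample.
* Runs: per column, each target precursor is detected with logistic
  probability in log10 area (midpoint/scale configurable), its peak area
  scaled by load/200 and multiplied by log-normal measurement noise
  exp(N(0, noise_cv)).  Peaks are Gaussians with sigma = 4 s.  A peak
  whose apex falls where the other column's elution envelope is nonzero
  is attenuated by (1 - suppression): matrix suppression at the shared
  inlet, applied per peak so elution positions are never distorted.  At
  suppression 0 a dual run is exactly the sum of the two single runs.
* Seeds: detection and noise draws use numpy SeedSequence([seed, column])
  streams, so the Column 1 content of a single- and a dual-column run
  with the same seed is identical.  Dilution-series replicates derive
  per-run seeds from SeedSequence((master, point_index, replicate)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .chromops import Trace
from .drtmodel import PSMRecord

REFERENCE_LOAD_NG = 200.0
MZ_RANGE = (380.0, 980.0)
DEFAULT_PEAK_SIGMA_S = 4.0
DEFAULT_SAMPLE_STEP_S = 0.6
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ParameterError(ValueError):
    """Raised for non-finite or out-of-range simulation parameters."""


# ------------------------------------------------------------- types ----


@dataclass(frozen=True)
class OffsetProfile:
    """True ΔRT as a function of Column 1 retention time.

    kinds:
      * ``constant``: base_offset everywhere.
      * ``linear_drift``: base_offset + slope * (t - t_ref);
        drift_params = (slope_min_per_min, t_ref_min).
      * ``smooth_drift``: base_offset + amplitude * sin(2*pi*(t - phase)/period);
        drift_params = (amplitude_min, period_min, phase_min).
    """

    kind: str = "constant"
    base_offset: float = 4.0
    drift_params: tuple = ()

    def evaluate(self, rt):
        t = np.asarray(rt, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, self.base_offset)
        elif self.kind == "linear_drift":
            slope, t_ref = (self.drift_params + (0.0, 0.0))[:2]
            out = self.base_offset + slope * (t - t_ref)
        elif self.kind == "smooth_drift":
            amp, period, phase = (self.drift_params + (0.3, 30.0, 5.0))[:3]
            out = self.base_offset + amp * np.sin(2 * np.pi * (t - phase) / period)
        else:
            raise ParameterError(f"unknown offset profile kind {self.kind!r}")
        if np.any(out <= 0):
            raise ParameterError("offset profile must be positive (Column 2 later)")
        return float(out) if np.ndim(rt) == 0 else out


@dataclass(frozen=True)
class LibraryEntry:
    """One precursor: identity, fragment set, reference RT and labels.

    ``abundance`` is the expected integrated peak area (counts*min) at
    the reference 200 ng load; it is a property of the sample, so
    replicate injections share it.
    """

    precursor_id: str
    peptide: str
    charge: int
    precursor_mz: float
    fragment_mzs: np.ndarray
    fragment_rel_intensities: np.ndarray
    ref_rt: float
    protein_id: str
    species: str = "target"  # "target" | "entrapment"
    abundance: float = 1e5
    decoy: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_mzs", np.asarray(self.fragment_mzs, float))
        object.__setattr__(
            self, "fragment_rel_intensities",
            np.asarray(self.fragment_rel_intensities, float),
        )
        if self.charge < 1:
            raise ParameterError("charge must be >= 1")
        if len(self.fragment_mzs) < 3:
            raise ParameterError("need at least 3 fragments")
        if not np.all(np.diff(self.fragment_mzs) > 0):
            raise ParameterError("fragment_mzs must be strictly increasing")
        if abs(self.fragment_rel_intensities.sum() - 1.0) > 1e-9:
            raise ParameterError("fragment_rel_intensities must sum to 1")


@dataclass(frozen=True)
class RunDesign:
    """Configuration of one dual-column acquisition."""

    run_id: str
    load_col1: float
    load_col2: float
    delta_rt_profile: OffsetProfile = field(default_factory=OffsetProfile)
    suppression: float = 0.06
    noise_cv: float = 0.05
    detection_midpoint: float = 4.0  # log10 area at 50% detection
    detection_scale: float = 0.4
    seed: int = 0
    sample_step_s: float = DEFAULT_SAMPLE_STEP_S
    peak_sigma_s: float = DEFAULT_PEAK_SIGMA_S
    rt_pad_min: float = 1.0

    def __post_init__(self) -> None:
        for load in (self.load_col1, self.load_col2):
            if not np.isfinite(load) or load < 0:
                raise ParameterError("loads must be finite and >= 0")
        if not 0 <= self.suppression < 1:
            raise ParameterError("suppression must be in [0, 1)")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.sample_step_s <= 0 or self.peak_sigma_s <= 0:
            raise ParameterError("sampling step and peak sigma must be positive")


@dataclass
class GroundTruth:
    """Per-(precursor, column) truth sidecar for one simulated run.

    ``table`` columns: precursor_id, column, true_apex_rt_min, true_area,
    detected.  Every injected (target-species, loaded-column) peak is
    recorded, detected or not.
    """

    run_id: str
    loads: dict[int, float]
    table: pd.DataFrame

    def detected(self, column: int | None = None) -> pd.DataFrame:
        t = self.table[self.table["detected"]]
        if column is not None:
            t = t[t["column"] == column]
        return t

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# run_id: {self.run_id}\n")
            fh.write(f"# load_col1_ng: {self.loads[1]}\n")
            fh.write(f"# load_col2_ng: {self.loads[2]}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            run_id=meta.get("run_id", "run"),
            loads={1: float(meta.get("load_col1_ng", 0)),
                   2: float(meta.get("load_col2_ng", 0))},
            table=table,
        )


# ----------------------------------------------------------- library ----


def simulate_library(
    n_precursors: int,
    n_proteins: int,
    gradient_start_min: float = 5.0,
    gradient_end_min: float = 35.0,
    entrapment_fraction: float = 0.0,
    seed: int = 0,
    abundance_log10_mean: float = 5.5,
    abundance_log10_sd: float = 0.8,
) -> list[LibraryEntry]:
    """Generate a synthetic spectral library.

    Reference RTs are uniform over [gradient_start, gradient_end];
    floor(n_precursors * entrapment_fraction) entries are labeled as
    foreign-species entrapment entries mapping to their own proteins.
    Deterministic for a fixed seed.
    """
    vals = [n_precursors, n_proteins, gradient_start_min, gradient_end_min,
            entrapment_fraction]
    if not all(np.isfinite(v) for v in vals):
        raise ParameterError("library parameters must be finite")
    if n_precursors < 1 or n_proteins < 1:
        raise ParameterError("n_precursors and n_proteins must be >= 1")
    if not 0 <= entrapment_fraction < 1:
        raise ParameterError("entrapment_fraction must be in [0, 1)")
    if not gradient_end_min > gradient_start_min:
        raise ParameterError("gradient_end must exceed gradient_start")

    rng = np.random.default_rng(seed)
    n_entrap = int(np.floor(n_precursors * entrapment_fraction))
    n_target = n_precursors - n_entrap
    n_prot_entrap = min(n_entrap, max(1, round(n_proteins * entrapment_fraction))) if n_entrap else 0
    n_prot_target = max(1, n_proteins - n_prot_entrap)

    entries: list[LibraryEntry] = []
    for i in range(n_precursors):
        is_entrap = i >= n_target
        k = int(rng.integers(4, 8))
        mzs = np.sort(rng.uniform(*MZ_RANGE, size=k))
        while np.any(np.diff(mzs) <= 0):  # vanishing probability, but be safe
            mzs = np.sort(rng.uniform(*MZ_RANGE, size=k))
        rel = rng.gamma(1.5, size=k)
        rel = rel / rel.sum()
        length = int(rng.integers(8, 21))
        peptide = "".join(rng.choice(_AA, size=length))
        if is_entrap:
            j = i - n_target
            pid, prot, species = f"EP{j:06d}", f"ENTRAP{j % n_prot_entrap:05d}", "entrapment"
        else:
            pid, prot, species = f"P{i:06d}", f"PROT{i % n_prot_target:05d}", "target"
        entries.append(
            LibraryEntry(
                precursor_id=pid,
                peptide=peptide,
                charge=int(rng.integers(2, 4)),
                precursor_mz=float(rng.uniform(*MZ_RANGE)),
                fragment_mzs=mzs,
                fragment_rel_intensities=rel,
                ref_rt=float(rng.uniform(gradient_start_min, gradient_end_min)),
                protein_id=prot,
                species=species,
                abundance=float(10 ** rng.normal(abundance_log10_mean, abundance_log10_sd)),
            )
        )
    return entries


def write_library(entries: list[LibraryEntry], path) -> None:
    rows = [
        (
            e.precursor_id, e.peptide, e.charge, f"{e.precursor_mz:.4f}",
            ";".join(f"{m:.4f}" for m in e.fragment_mzs),
            ";".join(f"{r:.6f}" for r in e.fragment_rel_intensities),
            f"{e.ref_rt:.4f}", e.protein_id, e.species, f"{e.abundance:.4f}",
        )
        for e in entries
    ]
    pd.DataFrame(
        rows,
        columns=["precursor_id", "peptide", "charge", "precursor_mz",
                 "fragment_mzs", "fragment_rel_intensities", "ref_rt_min",
                 "protein_id", "species", "abundance"],
    ).to_csv(path, sep="\t", index=False)


def read_library(path) -> list[LibraryEntry]:
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for r in df.itertuples():
        rel = np.array([float(x) for x in str(r.fragment_rel_intensities).split(";")])
        rel = rel / rel.sum()  # absorb rounding from serialization
        entries.append(
            LibraryEntry(
                precursor_id=str(r.precursor_id),
                peptide=str(r.peptide),
                charge=int(r.charge),
                precursor_mz=float(r.precursor_mz),
                fragment_mzs=np.array([float(x) for x in str(r.fragment_mzs).split(";")]),
                fragment_rel_intensities=rel,
                ref_rt=float(r.ref_rt_min),
                protein_id=str(r.protein_id),
                species=str(r.species),
                abundance=float(getattr(r, "abundance", 1e5)),
            )
        )
    return entries


# --------------------------------------------------------------- runs ----


def _rt_grid(library, profile, step_s, pad) -> np.ndarray:
    refs = np.array([e.ref_rt for e in library])
    offs = profile.evaluate(refs)
    lo = float(refs.min()) - pad
    hi = float((refs + offs).max()) + pad
    step = step_s / 60.0
    n = int(np.ceil((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def simulate_run(
    library: list[LibraryEntry],
    design: RunDesign,
    render_traces: bool = True,
) -> tuple[list[Trace], GroundTruth]:
    """Simulate one dual-column acquisition.

    Returns the fragment XIC traces (only channels carrying signal; all
    share one rt grid object) and the ground-truth sidecar.  With
    ``render_traces=False`` the trace list is empty and only the ground
    truth is produced (cheap path for PSM-level studies).
    """
    if not library:
        raise ParameterError("library must be nonempty")
    profile = design.delta_rt_profile
    n = len(library)
    refs = np.array([e.ref_rt for e in library])
    abundance = np.array([e.abundance for e in library])
    target = np.array([e.species == "target" and not e.decoy for e in library])
    offsets = profile.evaluate(refs)
    apex = {1: refs, 2: refs + offsets}
    grid = _rt_grid(library, profile, design.sample_step_s, design.rt_pad_min)
    sigma = design.peak_sigma_s / 60.0
    loads = {1: design.load_col1, 2: design.load_col2}

    detected: dict[int, np.ndarray] = {}
    areas: dict[int, np.ndarray] = {}
    for col in (1, 2):
        rng = np.random.default_rng([design.seed, col])
        u = rng.random(n)
        z = rng.standard_normal(n)
        if loads[col] > 0:
            base = abundance * (loads[col] / REFERENCE_LOAD_NG)
            p = expit((np.log10(base) - design.detection_midpoint) / design.detection_scale)
            detected[col] = (u < p) & target
            areas[col] = base * np.exp(design.noise_cv * z)
        else:
            detected[col] = np.zeros(n, dtype=bool)
            areas[col] = np.zeros(n)

    # column elution envelopes -> co-elution suppression factor
    half_w = 5.0 * sigma
    envelope = {1: np.zeros(grid.size), 2: np.zeros(grid.size)}
    amp_norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for col in (1, 2):
        for i in np.flatnonzero(detected[col]):
            lo = np.searchsorted(grid, apex[col][i] - half_w)
            hi = np.searchsorted(grid, apex[col][i] + half_w)
            t = grid[lo:hi]
            envelope[col][lo:hi] += (
                areas[col][i] * amp_norm * np.exp(-0.5 * ((t - apex[col][i]) / sigma) ** 2)
            )
    # Per-peak suppression: a peak is attenuated by (1 - suppression)
    # when the other column's elution envelope is nonzero at its apex.
    # Constant per peak, so apex positions are never distorted.
    eps = 1e-9
    peak_factor: dict[int, np.ndarray] = {}
    for col in (1, 2):
        other = envelope[2 if col == 1 else 1]
        idx = np.clip(np.searchsorted(grid, apex[col]), 0, grid.size - 1)
        overlapped = other[idx] > eps
        peak_factor[col] = np.where(overlapped, 1.0 - design.suppression, 1.0)

    traces: list[Trace] = []
    if render_traces:
        present = np.flatnonzero(detected[1] | detected[2])
        frag_counts = [len(library[i].fragment_mzs) for i in present]
        inten = np.zeros((int(np.sum(frag_counts)), grid.size), dtype=np.float32)
        row_of: dict[int, int] = {}
        r = 0
        for i, c in zip(present, frag_counts):
            row_of[i] = r
            r += c
        for col in (1, 2):
            for i in np.flatnonzero(detected[col]):
                e = library[i]
                lo = np.searchsorted(grid, apex[col][i] - half_w)
                hi = np.searchsorted(grid, apex[col][i] + half_w)
                g = np.exp(-0.5 * ((grid[lo:hi] - apex[col][i]) / sigma) ** 2)
                base_row = row_of[i]
                scaled = areas[col][i] * peak_factor[col][i]
                for j, rel in enumerate(e.fragment_rel_intensities):
                    inten[base_row + j, lo:hi] += (
                        scaled * rel * amp_norm * g
                    ).astype(np.float32)
        for i in present:
            e = library[i]
            base_row = row_of[i]
            for j, mz in enumerate(e.fragment_mzs):
                traces.append(Trace(mz=float(mz), rt=grid, intensity=inten[base_row + j]))

    rows = []
    for col in (1, 2):
        if loads[col] <= 0:
            continue
        for i in range(n):
            if not target[i]:
                continue
            rows.append(
                (library[i].precursor_id, col, float(apex[col][i]),
                 float(areas[col][i] * peak_factor[col][i]),
                 bool(detected[col][i]))
            )
    gt = GroundTruth(
        run_id=design.run_id,
        loads={1: loads[1], 2: loads[2]},
        table=pd.DataFrame(
            rows, columns=["precursor_id", "column", "true_apex_rt_min",
                           "true_area", "detected"]
        ),
    )
    return traces, gt


# ----------------------------------------------------- dilution series ----

DILUTION_SCHEMES = {
    "direct": [(10.0, 10.0), (50.0, 50.0), (100.0, 100.0), (200.0, 200.0)],
    "inverted": [(200.0, 10.0), (100.0, 50.0), (50.0, 100.0), (10.0, 200.0)],
}


def derive_seed(master: int, *key: int) -> int:
    """Stable per-run seed (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence((int(master),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def dilution_designs(
    scheme: str, replicates: int, base_design: RunDesign
) -> list[RunDesign]:
    """RunDesigns for a dilution series: each load pair of the scheme,
    replicated with distinct derived seeds."""
    if scheme not in DILUTION_SCHEMES:
        raise ParameterError(f"unknown dilution scheme {scheme!r}")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    designs = []
    for p, (l1, l2) in enumerate(DILUTION_SCHEMES[scheme]):
        for rep in range(replicates):
            designs.append(
                replace(
                    base_design,
                    run_id=f"{scheme}_{int(l1)}x{int(l2)}_r{rep + 1}",
                    load_col1=l1,
                    load_col2=l2,
                    seed=derive_seed(base_design.seed, p, rep),
                )
            )
    return designs


def simulate_dilution_series(
    library: list[LibraryEntry],
    scheme: str,
    replicates: int,
    base_design: RunDesign,
    render_traces: bool = True,
) -> list[tuple[RunDesign, list[Trace], GroundTruth]]:
    """Simulate a full dilution series (materialized; for large libraries
    prefer iterating :func:`dilution_designs` and calling
    :func:`simulate_run` per run)."""
    out = []
    for d in dilution_designs(scheme, replicates, base_design):
        traces, gt = simulate_run(library, d, render_traces=render_traces)
        out.append((d, traces, gt))
    return out


# ----------------------------------------------------------- PSM table ----


def simulate_psm_table(
    traces: list[Trace],
    ground_truth: GroundTruth,
    library: list[LibraryEntry],
    evalue_model_params: dict | None = None,
    seed: int = 0,
) -> list[PSMRecord]:
    """Emit one PSM per detected ground-truth peak.

    The simulated expectation value is log-linear in log10 peak area with
    Gaussian scatter (higher-intensity peaks score better); observed RT
    is the true apex plus Gaussian jitter.  Precursors present on both
    columns appear twice at offset RTs — the duplicate-PSM phenomenon
    that drives ΔRT modeling.
    """
    params = {
        "log10_base": 2.0,     # -log10(e) at log10 area = 3
        "log10_slope": 2.2,    # per decade of area
        "log10_sd": 1.2,
        "rt_sd_min": 0.02,
    }
    if evalue_model_params:
        params.update(evalue_model_params)
    known = {e.precursor_id for e in library}
    rng = np.random.default_rng(seed)
    det = ground_truth.table[ground_truth.table["detected"]]
    records = []
    for r in det.sort_values(["column", "precursor_id"]).itertuples():
        if r.precursor_id not in known:
            raise ParameterError("ground truth references a precursor not in library")
        log10e = -(
            params["log10_base"]
            + params["log10_slope"] * (np.log10(max(r.true_area, 1.0)) - 3.0)
        ) + rng.normal(0.0, params["log10_sd"])
        records.append(
            PSMRecord(
                precursor_id=str(r.precursor_id),
                rt=float(r.true_apex_rt_min + rng.normal(0.0, params["rt_sd_min"])),
                expect=float(10.0 ** min(log10e, 2.0)),
                rank=1,
            )
        )
    return records


# ------------------------------------------------------------ trace I/O ----


def write_traces(traces: list[Trace], path, meta: dict | None = None) -> None:
    """Write run traces as JSON: a metadata block, the shared rt grid
    (start/step/n), and per-trace sparse intensity segments (leading and
    trailing zeros trimmed, values rounded to 4 decimals)."""
    if not traces:
        doc = {"meta": meta or {}, "rt_grid": None, "traces": []}
        Path(path).write_text(json.dumps(doc))
        return
    grid = traces[0].rt
    doc = {
        "meta": meta or {},
        "rt_grid": {"start_min": float(grid[0]),
                    "step_min": float(grid[1] - grid[0]),
                    "n": int(grid.size)},
        "traces": [],
    }
    for t in traces:
        nz = np.flatnonzero(t.intensity > 0)
        if nz.size == 0:
            doc["traces"].append({"mz": round(t.mz, 4), "offset": 0, "intensity": []})
            continue
        lo, hi = int(nz[0]), int(nz[-1]) + 1
        seg = [round(float(v), 4) for v in t.intensity[lo:hi]]
        doc["traces"].append({"mz": round(t.mz, 4), "offset": lo, "intensity": seg})
    Path(path).write_text(json.dumps(doc))


def read_traces(path) -> tuple[list[Trace], dict]:
    doc = json.loads(Path(path).read_text())
    if doc["rt_grid"] is None:
        return [], doc.get("meta", {})
    g = doc["rt_grid"]
    grid = g["start_min"] + g["step_min"] * np.arange(g["n"])
    traces = []
    for t in doc["traces"]:
        inten = np.zeros(g["n"], dtype=np.float32)
        seg = np.asarray(t["intensity"], dtype=np.float32)
        inten[t["offset"] : t["offset"] + seg.size] = seg
        traces.append(Trace(mz=float(t["mz"]), rt=grid, intensity=inten))
    return traces, doc.get("meta", {})
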