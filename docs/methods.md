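# Methods

## The measurement being emulated

Two capillary LC columns spray into one MS inlet. The second column's
sample injection is delayed so its gradient — and therefore the elution
of every analyte it carries — lags the first by a controlled offset
ΔRT ≈ 4 min over a ~30 min separation. The combined chromatogram is, to
good approximation, the superposition of the two individual ones, with a
small loss of total ion current where the columns co-elute (matrix
suppression at the shared emitter). Analytes present in both samples
appear as duplicate peaks separated by ΔRT(t), where the offset drifts
slowly over the gradient because no two columns or pumps are identical.

`synchrosep` contains the complete informatic chain for this experiment
plus a generative model of the data, so the chain can be validated with
known ground truth at desk scale.

## Simulator (`synthdata`)

**Library.** Precursors carry 4–7 fragments with strictly increasing
m/z drawn uniformly in 380–980 Th (the DIA acquisition range; no isotope
structure or mass-accuracy model), Dirichlet-like relative intensities
(gamma(1.5) normalized to sum 1), reference RTs uniform on the gradient
window (default 5–35 min), and charge 2–3. Abundance is log-normal with
log₁₀ sd 0.8 around a median integrated area of 10^5.5 counts·min at the
200 ng reference load. Abundance lives on the library entry, not the
run: it is a property of the sample, which is what makes replicate %RSD
a meaningful precision metric. A configurable fraction of entries is
labeled as foreign-species entrapment entries; these exist only in the
search space, never in the sample, mirroring how entrapment databases
estimate empirical FDR.

**Runs.** Per column, a precursor's expected area is abundance ×
load/200. Detection is Bernoulli with logistic probability in log₁₀
area (midpoint 4.0, scale 0.4), so lost identifications are
systematically low-intensity. Measurement noise is one multiplicative
log-normal factor exp(N(0, cv)) per peak per run (default cv 0.05).
Peaks are Gaussians with σ = 4 s (FWHM ≈ 9.4 s, typical for 75 µm i.d.
nano-LC on 30 min gradients), truncated at ±5σ, sampled on a shared
grid at the 0.6 s MS1 cycle time. Column 2 apexes sit at
ref_rt + ΔRT(ref_rt). Offset profiles: constant, linear drift, or
smooth drift (sinusoid, default amplitude 0.3 min, period 30 min); the
profile must stay positive (Column 2 always later).

**Suppression.** A peak whose apex falls where the other column's
elution envelope is nonzero is attenuated by a constant factor
(1 − suppression), default 0.06 — anchored to the observation that a
fully dual-loaded run carries ≈94% of the summed single-run ion
current. Applying the factor per peak rather than per time point keeps
apex positions exact (a step factor across a peak would shift its
sampled apex), at the cost of not modeling partial-overlap gradations
within a peak; the intensity- and RT-dependence of the loss is not
characterized experimentally, so a single scalar is exposed.

**Seeds.** Detection and noise streams are `SeedSequence([seed,
column])`, so a single- and dual-column run with the same seed share
identical Column 1 content — required for matched single-vs-dual
comparisons. Dilution replicates derive per-run seeds from
`SeedSequence((master, point, replicate))`; all derived seeds are
< 2³¹.

**Dilution schemes.** Direct: (10,10), (50,50), (100,100), (200,200) ng;
inverted: (200,10), (100,50), (50,100), (10,200) ng.

**PSM tables.** One record per detected ground-truth peak; −log₁₀
expectation value is linear in log₁₀ area (base 2.0 at area 10³, slope
2.2/decade) with Gaussian scatter (sd 1.2), and observed RT is the true
apex plus N(0, 0.02 min) jitter (0.05 min in the drift-model study).
This reproduces the two properties the downstream model depends on:
duplicate PSMs at offset RTs, and better scores for brighter peaks.

**What the simulator does not emulate.** Raw spectra, isolation
windows, interference/chimericity, peak tailing and shape variation,
correlated (batch) drift between replicates, RT-dependent suppression
structure, sequence-dependent fragmentation chemistry. Passing tests
demonstrate that the pipeline's logic is correct under the stated
generative model, not that real-data identification rates or score
distributions are reproduced.

## Peak processing (`chromops`)

Noise is estimated as 1.4826 × MAD of the trace; local maxima above
`min_snr` × noise with ≥ `min_points` samples above half height are
peaks. Boundaries walk from the apex to the nearest local minimum or
the 1%-of-apex crossing, whichever comes first; areas are trapezoidal;
FWHM is interpolated at half height. On noiseless traces MAD is zero
and the threshold degenerates gracefully to "any local maximum". No
deconvolution of partially co-eluting peaks is attempted beyond the
boundary rule.

## ΔRT model (`drtmodel`)

PSMs with expectation value strictly < 1e-5 are kept. Precursors seen
*exactly* twice whose RT gap is strictly > 30 s form pairs; the earlier
member is Column 1. Precursors seen more than twice are discarded
entirely — conservative, avoids mispairing. The default fit is one
LOWESS (statsmodels, frac 0.3, not reported experimentally) of
(rt₂ − rt₁) against rt₁; the alternative of smoothing each column's RTs
against rt₁ and differencing the curves on a grid is available as
`method="difference"` and agrees with the default at the smoothing
level. Prediction is linear interpolation over the LOWESS support with
clamping outside the fitted range — LOWESS has no principled
extrapolation, and clamping is stable. Fitting requires ≥ 20 pairs.

## Demultiplexing search (`demux`)

Column 1 hypotheses search a window of full width `rt_gap` (default
1.0 min) centered on the library RT; Column 2 windows are centered on
the library RT plus a scalar rt-shift or the model-predicted offset.
Fragment peaks inside the window are clustered by apex proximity
(spread ≤ the median peak FWHM); a candidate needs ≥ 3 distinct
fragments. Score = (coverage + cosine + RT-proximity)/3, an equally
weighted transparent composite (the reference search engine's scoring
is opaque). The observed RT is the area-weighted mean apex of matched
fragments. If both column windows overlap and capture the same peak for
one precursor, the higher-scoring hypothesis wins, ties to Column 1
(the earlier-elution convention).

Decoys are one-per-target with fragment m/z shifted +11 Th (wrapped
into 380–980 Th) and RT redrawn uniformly — RT randomization rather
than sequence reversal, because simulated entries have no meaningful
sequence chemistry. Decoy matches arise from the same mechanism as
target false matches (chance m/z coincidence with real co-apexing
peaks), which is what makes the estimate calibrated. q(s) =
#decoys(≥s) / max(1, #targets(≥s)), accumulated over tie groups, made
monotone by the step-up pass, capped at 1. Reports are filtered at
q ≤ 0.01 (inclusive). Protein-level confidence uses the best-peptide
rule implicitly through the protein rollup; peptidoform-level q-values
are out of scope.

## Evaluation and quantification (`evalkit`, `quantify`)

Entrapment FDP(%) = Nε/(Nτ + Nε) × 100; precursors mapping to both
species count as targets. Confusion on single-column runs: FPR(%) =
assignments to the unloaded column / total × 100. RT agreement and all
regressions use `scipy.stats.linregress`; the overlap key for RT
agreement is (precursor_id, column) at q ≤ 0.01 in both runs. Protein
quantities are plain sums of precursor areas per sample — interpretable
and sufficient for the metrics here; MaxLFQ-style quantification is out
of scope. Median-ratio normalization exists but defaults off and must
stay off for dilution series. Dilution R² regresses mean area per
concentration point on load (linear scale; log-log behind a flag is not
provided since linearity is the claim under test), excluding rows seen
at < 3 points. %RSD = 100 × sd(ddof=1)/mean. Missing values are never
imputed.

## Validation studies (`benchmarks`, `scripts/acceptance.py`)

Sizes chosen as the smallest that exercise each claim stably:

* **ΔRT accuracy** — 3500-precursor dual run → ~2600 duplicate pairs
  (smooth drift 4 ± 0.3 min, RT noise 0.05 min); max |error| at 15
  held-out standards from the true profile. Observed ≈ 0.02–0.03 min,
  dominated by the local-linear smoothing bias against the sinusoidal
  drift, well inside the ±0.4 min accuracy band.
* **Specificity** — 5000-precursor Column-1-only run, rt_gap 1.0,
  q ≤ 0.01; % assigned to Column 2. A false Column 2 call requires ≥3
  foreign fragment channels to co-apex inside a shifted window, so the
  observed rate is ~0%.
* **Linearity** — 300 proteins × 3 precursors, direct dilution series
  in triplicate, 5% CV noise, normalization off; median per-protein R²
  ≈ 0.999. The intercept term absorbs detection dropout at the 10 ng
  point.
* **Precision** — triplicate 200+200 ng dual runs, 2% CV noise; median
  protein %RSD ≈ 1.6% (per-peak noise partially averages out in the
  multi-precursor protein rollup).
* **RT agreement** — matched noiseless single/dual runs share detection
  draws by construction, so assigned RTs are grid-identical and the
  slope is 1.000.
* **FDR calibration** — 10 seeded 400-precursor dual runs; realized
  false-match proportion among q ≤ 0.01 assignments, pooled.

## Known limitations

* The composite score is not calibrated against real DIA score
  distributions; q-values are exact for the simulated null but only
  structurally analogous to a production search engine's.
* Fragment channels are precursor-private except for chance m/z
  coincidence; real DIA windows multiplex far more interference, so
  realized specificity here is an upper bound on what shared channels
  would allow.
* The simulator's suppression scalar, single-Gaussian peaks, and
  per-run-independent noise understate the structure of real
  chromatographic variation; quantitative metrics on simulation are
  best-case figures.
* `simulate_dilution_series` materializes all runs; for large libraries
  iterate `dilution_designs` + `simulate_run` instead (the benchmark
  studies do).
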