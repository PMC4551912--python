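# Methods

This note documents the models, estimators, numerical choices and known
limitations of biosensorkit. It states how quantities are computed; every
number quoted as a result is produced by the test suite or
`scripts/acceptance.py`, not asserted here.

## Data model and units

Time is minutes relative to inducer addition (pre-induction reads carry
negative times; no analysis currently requires them). Concentrations are
canonicalized on load: molar units (nM/µM/mM/M) to mol/L, volume-fraction
solvents kept as percent. Fluorescence is arbitrary units (AFU); expression
velocities are AFU·OD⁻¹·s⁻¹, so a constant velocity `v` acting for `t`
minutes accumulates `v·60·t` AFU/OD of growth-normalized signal. CSV I/O is
canonical (fixed column order, sorted rows, shortest-round-trip floats,
exact-round-trip parsing), so write → read → write is byte-identical — an
invariant the test suite enforces.

## Synthetic experiment generator

The generator emulates the characterization protocol the analysis assumes:
3 replicate wells per condition, 5 background-control wells (reporter-free
strain), readings every 10 min for 15 h.

**Growth.** Lagged logistic OD: flat at `initial_od` through `lag_min`, then
logistic with per-minute rate `rate` toward `carrying_capacity`. Defaults
(lag 20 min, rate 0.02 min⁻¹ ≈ 35-min doubling, capacity OD 1.0, inoculum
OD 0.05) are typical for *E. coli* in rich medium in a shaken microplate.
Stationary onset is defined crisply as OD ≥ 95% of capacity, which gives a
closed-form shutoff time. A lagged logistic was chosen over Gompertz because
it matches sigmoidal microplate OD traces while keeping the onset analytic.

**Expression.** Per-cell reporter density integrates
`dg/dt = [v_min + v_max·Iʰ/(Iʰ+K_Lʰ)] · phase(t)` with `phase = 1` from
induction until stationary onset when `stationary_shutoff` is set (the
behavior of most repressor-regulated constructs) and `phase = 1` throughout
for sensors flagged `post_stationary_accumulation` (the acrylate sensor keeps
accumulating reporter after growth arrest). Fluorophore maturation is treated
as instantaneous and degradation as absent — maturation is minutes against a
10-min sampling grid, and the reporter's half-life far exceeds the
experiment. Reported fluorescence is `(g + background)·OD`, with the
autofluorescence background defaulting to 500 AFU per OD.

**Noise.** Three terms:

* `well_cv` (default 0.05) — a lognormal factor on each well's realized
  expression velocity. This is the dominant term and represents
  replicate-to-replicate variation (inoculum, pipetting, plate position); it
  is what the 95% confidence bands over triplicate wells reflect.
* `fluor_cv` (default 0.0005) and `od_sd` (default 0.0005 OD) — small
  per-read multiplicative jitter on fluorescence and additive jitter on
  absorbance. Consecutive reads of one well on a plate reader track each
  other closely; these defaults reproduce the smooth kinetic traces and
  few-percent parameter standard errors that characterize such data. They
  must stay small for a second reason: the velocity estimator below takes a
  maximum of raw first differences, whose noise floor scales with the
  *accumulated* signal rather than the per-interval increment, so per-read
  jitter at the percent level would visibly inflate recovered maximal
  velocities. This coupling is a documented limitation of the raw-difference
  estimator, not of the generator.

Reproducibility: every well draws from an RNG substream keyed by
`(master seed, well index)`, with background controls in a reserved block, so
extending a configuration with more sensors never changes existing wells.

**Toxicity.** Dose scales the exponential growth rate (not the carrying
capacity) by `1 + (growth_benefit − max_inhibition)·cˢ/(cˢ + IC50ˢ)`;
metabolizable inducers (sugars) can thus show rate *increases*. Rates, not
capacities, are scaled because the toxicity readout of interest is the
exponential-phase growth-rate ratio.

**Cytometry.** Pre-gated events; each channel draws from an "on" or "off"
lognormal (median, geometric CV) according to whether its cognate inducer is
in the sample's induction state. Defaults put on/off medians two decades
apart (10⁴ vs 10² AFU, geometric CV 0.6), matching well-separated
induced/uninduced populations. A non-responder fraction (default 1%,
consistent with the observed sub-2% of dark cells under full induction)
samples "off" in every channel regardless of state.

**What the generator does not emulate.** Mechanistic
transcription–translation kinetics, mRNA dynamics, plasmid copy-number
fluctuation, inducer transport/depletion, spectral spillover between
channels, scatter-gating artifacts, and instrument saturation. Passing
recovery tests therefore demonstrate the correctness and calibration of the
estimators under the stated statistical model, not robustness to every
pathology of real instruments.

## Kinetics and velocity extraction

Growth-normalized fluorescence is `F(t)/OD(t)`; samples with OD ≤ 0.01 are
excluded (with a warning) to avoid division blow-ups at inoculation.
Background subtraction removes the mean control-well AFU/OD at matched
timepoints; controls must share the time grid (nearest sample within half an
interval), since the protocol reads all wells of one plate on one grid.

Promoter activity is the raw first difference of AFU/OD per interval divided
by the interval in seconds; the velocity used for fitting is the maximum over
post-induction intervals, taken per replicate well (each replicate
contributes its own point to the fit). No smoothing is applied by default —
an optional rolling median exists for pathological data but is off in every
shipped analysis. Velocities are reported per second to match the units in
which maximal/basal activities are conventionally quoted.

## Transfer function, fold induction, intervals

Endpoint responses use the sample nearest 900 min (no interpolation; the
grid is 10 min). Replicate means carry Student's-t 95% intervals; a
percentile bootstrap of the mean is provided as the non-parametric
alternative. Fold induction takes the induced group at the
maximum-mean-response concentration. All standard errors are SEMs. The
"within background" trigger for the lower-bound rule is
`Ū_B − 2·sqrt(σ_Ū² + σ_C̄²) ≤ 0`, the direct formalization of the uninduced
95% interval (doubled-SE approximation) touching zero.

## Hill fitting

Plain unbounded nonlinear least squares of
`v(I) = V_min + V_max·Iʰ/(Iʰ + K_Lʰ)`, evaluated through a logistic of
`h·log(I/K_L)` for numerical stability, with the Hill term exactly zero at
`I = 0`. Because the surface is multimodal in `(h, K_L)`, fitting multi-starts
from `V_max ← max v`, `V_min ← min v`, `h ∈ {0.7, 1, 2, 4}` and `K_L` at the
geometric mean of nonzero doses jittered ×/÷10; the lowest-RSS converged
start with positive `h, K_L` wins. Parameter standard errors are square roots
of the residual-variance-scaled covariance diagonal; negative basal-velocity
estimates are reported, not clipped. At least 4 distinct concentrations are
required. Dose exclusions (e.g. a top dose rejected for overt toxicity) are
explicit arguments and are recorded in the fit object and datasheet.

The default dose series for a preset sensor is 6 concentrations at the
sensor's published fold step (2-fold for acrylate and anhydrotetracycline,
3-fold otherwise), log-centered on `K_L` so the titration spans the full
transition; the published range endpoints are figure-level, so centering on
the half-maximal dose is the design choice that makes all four parameters
identifiable at every preset.

## Toxicity estimation

The exponential window is the maximal-slope contiguous run of ≥ 4 samples
whose ln(OD)–time regression reaches R² ≥ 0.99 with positive slope, widest
among near-ties. Slope-primacy matters: the widest qualifying window on a
logistic trace drags in lag and saturation curvature and underestimates the
rate, while the steepest qualifying window sits in the genuinely linear
region. The R²/window thresholds are this module's own choices. Wells with
no qualifying window in profile mode are reported as zero growth (fully
arrested cultures have no measurable exponential phase); `growth_rate`
itself raises for them. Both normalizations of the protocol are implemented
— exponential-rate ratio (default) and 15-h endpoint-OD ratio — selected by
flag, since the source describes both and attributes neither exclusively.

## Cross-reactivity and orthogonality

A cell of the matrix is the mean endpoint AFU/OD of a sensor × chemical
exposure minus the sensor's uninduced mean; its activation flag fires when
the value exceeds `k`× the combined SE (default `k = 3`). The rule is this
package's formalization of a visual "no cross-reactivity" call; with n = 3
replicates the SE is t-distributed with few degrees of freedom, so the flag
is anti-conservative at `k = 3` (a few percent false-positive rate per
cell) — `k` is configurable where a stricter panel call is needed. Solvents
(DMSO, ethanol) are ordinary panel chemicals. A sensor passes orthogonality
when no non-cognate chemical in its row is flagged.

## Cytometry classification

Events are transformed by `asinh(x/150)` (cofactor configurable; the value
sets where the scale transitions from linear to logarithmic). Per-channel
gates are midpoints of transformed calibration medians — deterministic and
adequate for well-separated populations; mixture modeling is deliberately out
of scope. A sample's state is its modal code over `levelsⁿ` possibilities;
purity is the modal fraction; the non-responder estimate is the all-dark
fraction of induced samples (undefined for the all-off state, where
non-responders are invisible). The bimodality score is the best two-cluster
split of the transformed values (between-means over pooled within-spread,
each cluster ≥ 5% of events); the flag threshold of 4 sits above the scores
any unimodal shape can reach (≈2.7 Gaussian, ≈3.5 uniform) and far below
well-separated mixtures.

## Variant screening

Variants are ranked by replicate-mean fluorescence, ties broken by id;
concordance with measured titers uses Spearman's rank correlation because the
sensor transfer function is monotone but saturating — rank agreement, not
linearity, is what a screen needs. Dynamic range is max/min of replicate
means and is reported absent when the minimum is non-positive.

## Problem sizes in the shipped analyses

The recovery studies used by the acceptance script and tests run 20 seeds ×
(3 replicates × 6 + 1 concentrations + 5 controls) wells × 91 timepoints per
sensor, and Monte-Carlo oracles use 10⁶ draws; these sizes give stable
medians and sub-percent Monte-Carlo error for every quantity checked.

## Known limitations

* The max-of-raw-differences velocity statistic is upward-biased in the
  presence of per-read noise (bias grows with accumulated signal over
  interval increment); it is faithful to the source protocol, and the bias
  is multiplicative and common across doses, leaving `h` and `K_L`
  essentially unaffected — but absolute `V_max` from noisy data should be
  read with that caveat.
* Replicate SEs from n = 3 are themselves noisy; the `3·SE` activation rule
  and the t-intervals inherit heavy tails.
* The lumped `K_L` cannot be decomposed from dose–response data;
  `LumpedDecomposition` is documentation-grade bookkeeping with a consistency
  check, not an estimator.
* Percent-unit (solvent) and molar doses live on different scales; they are
  never mixed within one fit.
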