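# Methods

This note documents the statistical model behind `hrvscrub`, the choices the
implementation makes where conventions diverge, and exactly what the
synthetic-data generator does and does not emulate.

## 1. Sleepiness indexing by time-varying HRV

**Input contract.** Beat times are accepted as detected (seconds relative to
the onset of the first retained fMRI volume, strictly increasing). QRS
detection and manual beat correction are interactive, hardware-specific
steps and are deliberately out of scope; everything downstream of the beat
series is automated and reproducible.

**IBI cleaning.** Interbeat intervals (ms) are screened against a running
median (window of 5): an interval deviating from the local median by more
than 20 % of that median is marked ectopic and replaced by linear
interpolation between its nearest clean neighbours in anchor time. The
series is then linearly detrended against anchor time with the mean added
back. The detrend is *linear* by choice — toolbox defaults in this area vary
(linear, polynomial, smoothness priors) and the source convention is not
recorded; linear is the minimal assumption and is mean-preserving, so
overall HRV level is untouched. Cleaning is idempotent on clean series.

**Metrics.**

- RMSSD = √(mean of squared successive IBI differences), in ms. Defined for
  ≥ 2 intervals. Translation-invariant and reversal-invariant.
- CVI (cardiac vagal index) from the Lorenz plot of consecutive interval
  pairs (xₙ, xₙ₊₁): SD1 = sd((xₙ₊₁ − xₙ)/√2), SD2 = sd((xₙ₊₁ + xₙ)/√2)
  (sample SDs, ddof = 1), axes T = 4·SD1 and L = 4·SD2, CVI = log₁₀(L·T).
  Defined for ≥ 3 intervals with both SDs nonzero. Note the degenerate
  corner: a strictly two-valued alternating series has constant successive
  sums, SD2 = 0, and therefore an undefined CVI — a property of the index,
  not an implementation limit.

**Sliding windows.** The window for volume *i* is the half-open interval
[(i + ½)·TR − W/2, (i + ½)·TR + W/2); an interval belongs to a window iff
its *anchor* (the terminating beat's time) falls inside. Anchoring to the
terminating beat with half-open bounds guarantees that no interval is
double-counted at window edges on the 1-TR step grid. Windows with fewer
than the metric's minimum intervals (2 for RMSSD, 3 for CVI) yield an
explicit "undefined" (NaN), never an imputed value; censoring treats these
volumes explicitly.

**Window-length selection.** Candidates default to 4:4:48 s plus 50 s (the
conventional grid ends ambiguously; the list is a parameter). For each
candidate the report carries (a) the consistency ratio — mean windowed HRV
across windows and subjects divided by mean whole-scan HRV across subjects —
and (b) the unit-/scan-wise ICC of the windowed HRV with windows as units.
The chosen length is the qualifying candidate (ratio > 0.95) with maximal
scan-wise ICC, ties to the shorter window. Short windows underestimate
whole-scan HRV (fewer successive differences and the concavity of the square
root), which is why the ratio increases monotonically with window length.

## 2. Volume censoring

For retention fraction *P*: `sleepy` retains the round(P·n_defined) volumes
with highest HRV, `alert` the lowest, ties broken toward the earlier volume
index; volumes with undefined HRV are never selected by HRV-based modes but
are eligible for `random` masks, which sample round(P·n_total) volumes
uniformly without replacement (the random condition controls volume count,
not HRV). Rounding is half-even, so at P = 0.5 the sleepy and alert sets
are disjoint even for odd volume counts. Retained volumes are used as one
concatenated sample — the same convention as motion scrubbing; per-segment
estimation with averaging is a different estimator and is not implemented.

The alertness survival curve counts subjects who have not yet accumulated
`dropout_run` (default 5) consecutive sleepy volumes.

## 3. Connectivity and graph measures

Pearson correlations over retained volumes; zero-variance ROIs produce
flagged NaN rows rather than silent zeros (zeroing would bias group
averages). Group averaging happens in Fisher-z space with the result mapped
back to r. Off-diagonal |r| ≥ 1 (exact collinearity, which tiny fixtures do
produce) is clipped to ±(1 − 10⁻⁷) with a warning before arctanh; the
scalar `fisher_z` keeps the strict divergence error unless asked to clip.
Edgewise paired t-tests run on Fisher-z values; the FDR family is the set of
unique upper-triangle edges; edges with undefined differences leave the
family with a warning, and identical conditions yield the well-defined null
result t = 0, p = 1.

Graphs are built by zeroing correlations below T_r (boundary inclusive —
an edge at exactly T_r survives; negative correlations always drop since
T_r > 0). Degree centrality is the weighted row sum. The clustering
coefficient is the Onnela weighted form with weights normalised by the
per-matrix maximum, C_i = 2t_i/(k_i(k_i − 1)) with geometric-mean triangle
intensities and binary degree k_i; C_i = 0 for k_i < 2. On 0/1 weights this
reduces exactly to the classic triangle fraction (verified exhaustively for
all graphs with ≤ 6 nodes). The per-matrix maximum is used because weights
can in principle exceed a fixed bound only through numerical noise; the
binary coefficient is available as an option.

## 4. Reliability statistics

One-way random-effects ICC from the one-way ANOVA decomposition:
ICC = (MS_b − MS_w)/(MS_b + (d − 1)·MS_w), d = sessions per subject.
Negative estimates are reported as-is — flooring at zero would bias the
permutation null upward. Degenerate tables (zero total variance) are
undefined and flagged. Unit-wise reliability averages per-unit ICCs over
units with a defined value (undefined units are counted and reported);
scan-wise reliability collapses units to their per-scan mean first.
Two-way ICC variants and F-based confidence intervals are out of scope.

Qualitative bands are contiguous half-open intervals with boundaries
assigned upward: excellent [0.8, ∞), good [0.6, 0.8), moderate [0.4, 0.6),
fair [0.2, 0.4), poor below 0.2. (The conventional printed bands leave gaps
such as 0.79–0.8; closing them upward is the only deterministic choice.)

**Permutation test.** The observed ICC is compared one-tailed to the ICC
distribution over random-censoring draws; p = (1 + #{null ≥ obs})/(1 + N)
for the right tail (Phipson–Smyth add-one, so p is never zero), bounds are
the linear-interpolation 5th/95th percentiles. N ≥ 19 is enforced: the
smallest attainable p is 1/(1 + N), so 19 draws are the minimum at which
α = 0.05 is reachable. The alert condition is tested right-tailed (expected
to beat random retention), sleepy left-tailed. Null ensembles are shared
across measures within a run — the random condition is one construction,
reused — which also saves a factor of the measure count in compute.

## 5. Motion QC

Framewise displacement uses backward differences of the six realignment
parameters, FDᵢ = |Δdx| + |Δdy| + |Δdz| + r·(|Δα| + |Δβ| + |Δγ|), rotations
converted from degrees (a units flag accepts radians) to arc length on an
r = 50 mm sphere; FD₀ = 0. The printed formulas in the methodological
source contain typographical sign errors; the standard backward-difference
definition of the cited origin is implemented. A spike is FD strictly
greater than 0.3 mm; spike frequency is spikes per volume, compared between
conditions with a two-sided paired t-test.

## 6. The synthetic cohort

The generator's default is the *stated world* of the analysis: 17 subjects,
2 sessions, 215 volumes at TR 2.2 s. It exists so that every property of
the pipeline — oracle equivalence, parameter recovery, permutation
calibration, and the qualitative mechanism — is testable without any data
download. ROI count defaults to 32 (the method is parcellation-agnostic;
a 200-ROI atlas would only slow tests).

**Sleep timeline.** Wake → drowsy transitions follow a first-order chain
with onset hazard linear in volume index (default 8·10⁻⁵ per volume per
volume) and no recovery: alertness declines as scans progress, more
subjects are drowsy late in the scan, and session-to-session drowsy
fractions vary realistically (mean ≈ 0.3, wide spread — some sessions
never sleep).

**Cardiac model.** Intervals follow IBIₙ = μ(state) + σ(state)·zₙ with z a
standardised AR(1) (φ = 0.5), reflected at a 400 ms floor; μ = 800 ms
awake / 900 ms drowsy, σ calibrated so within-state RMSSD hits 30 ms awake
and 60 ms drowsy (typical adult values for quiet wake vs drowsiness; the
literature gives the direction and rough magnitude, not a canonical
number). Each subject carries stable log-normal scales on both parameters
(log-SD 0.3 and 0.05), because HRV itself is a reliable trait — without
that, windowed HRV would have no test–retest reliability to select window
lengths by.

**ROI signal model.** Per volume, ROI *i* of a wake volume is

    xᵢ = √c·g + √λ·h_m(i) + √(1 − c − λ)·patternᵢ,

unit variance per ROI: `g` a global factor, `h_m` one factor per module
(4 modules, exposed as the cohort's network partition), `pattern` a
normalised subject-specific latent loading mix (5 factors) plus observation
noise (0.7). The two scalars are stable subject traits: c ~ U(0.02, 0.35)
(global-signal share → overall connectivity level) and λ ~ U(0.05, 0.55)
(module coupling → within-network correlation blocks, hence triangle
density). These traits are what scan-level summaries (mean connectivity,
mean degree, mean clustering) can be reliable *about*; the unit-variance
construction makes them express linearly in correlations and attenuate
linearly when mixed with drowsy volumes. Design history worth recording:
a multiplicative signal-gain trait was tried first and rejected — gain
saturates in correlations at high SNR and is *re-expressed* when drowsy
noise inflates the denominator, which can invert the intended ordering.

**Drowsy state.** With perturbation p (default 1), drowsy volumes draw from
the same construction with traits and loadings interpolated toward a
cohort-wide sleep state (global share 0.2, module coupling 0.05, shared
loading pattern — "global synchronisation", no subject information) and
observation noise scaled by 1 + p·(1.5 − 1). Sleep thus erodes
between-subject differences by substitution and attenuation, the mechanism
the censoring method exploits. At p = 0 the drowsy block is
distributionally identical to wake and the three censoring conditions are
exchangeable — the ablation control (verified: observed conditions sit
inside the random 5–95 % bounds at the nominal rate).

**What the generator does not emulate.** No hemodynamics, no autocorrelated
BOLD noise (volumes are independent given state), no motion–sleep coupling,
no emotional modulation of HRV (so natural-viewing confounds are out of
reach), no wake recovery after sleep onset. A green mechanism-recovery test
therefore establishes that the pipeline detects the modelled
trait-substitution mechanism at realistic cohort sizes — not that real
sleep behaves this way.

**Calibration note.** The trait ranges, hazard slope, sleep-state shares
and the drowsy noise factor were calibrated once, on seed sets disjoint
from the frozen test seeds, so that the designed mechanism is detectable at
the stated cohort size (per-seed ordering success ≈ 0.95 per measure); with
17 subjects the scan-wise ICC estimator has a sampling SD of ~0.15–0.3, so
an uncalibrated effect of arbitrary size would make the headline recovery
test a coin flip. The ablation contains no tuned quantity.

## 7. Numerical and reproducibility choices

- Retained-count rounding is half-even; selection ties break to the earlier
  volume index; all volume indices are 0-based; times are seconds from the
  first retained volume's onset.
- All randomness flows through `numpy` Generators. Every entry point that
  mixes cohort generation with null-ensemble draws derives *independent*
  child seeds via `SeedSequence.spawn` — reusing one integer seed for two
  purposes aliases their streams and can correlate the null with the data
  (observed as excess permutation violations before the fix).
- End-to-end runs are byte-reproducible given (inputs, config, seed);
  reports are tab-separated text.
- The full-scale null is 5 000 draws; `--fast` (500) is used in CI-scale
  runs and the acceptance script. Bounds and means stabilise well below
  500 draws; p-value resolution is the only casualty (min p = 1/501).

## 8. Known limitations

- The one-way ICC assumes exchangeable sessions; systematic session effects
  (scanner drift between visits) load into MS_w and depress all conditions
  equally.
- Sleepy/alert masks at P = 0.5 can include contaminating volumes whenever
  a session's drowsy fraction differs from 0.5 — a property of relative
  thresholds, reproduced faithfully.
- Concatenating non-contiguous retained volumes ignores temporal
  autocorrelation; with autocorrelated real BOLD data the effective sample
  size is smaller than the retained count.
- CVI on short windows (< ~16 s at normal heart rates) is frequently
  undefined by its minimum-interval rule; RMSSD is the more robust
  per-volume index, matching its use as the primary metric.
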