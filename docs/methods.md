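# Methods

This note documents the statistical models implemented in
`dielrhythms`, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
decisions a user auditing results should know about.

## 1. Data model

Biology: visual counts from back-and-forth transect pairs, pooled per
pair and normalized to **individuals per 10 min of usable footage**,
on a regular 4-h grid (6 slots/day; timestamps label slot starts;
local time throughout, PST-like naive timestamps). Environment: one
variable per series on a 1-h (raw analysis) or 4-h (coupling analysis)
grid. Gaps are kept as missing values on the grid; no stage imputes —
the sinusoid fit drops missing slots while `t` keeps calendar spacing,
the CCF drops pairs, the periodogram by construction tolerates uneven
sampling.

Preprocessing conventions that the field protocol leaves open, fixed
here:

* **Slot anchoring.** 4-h slots anchor at local midnight; a record
  belongs to the slot containing its timestamp. Midnight anchoring is
  what produces clean 6-bin time-of-day waveforms.
* **Zero-inflation filter.** A taxon is discarded iff zero counts
  occupy *strictly more* than 1/3 of its observations (exactly 1/3 is
  kept). Short zero-inflated count series cannot support a credible
  periodicity claim.
* **Flow direction.** Components (N-S, E-W, m/s) are converted to
  magnitude `√(ns²+ew²)` and direction `atan2(ew, ns)` in degrees
  clockwise from North, the bearing the flow moves **toward** (ADCP
  convention). Directions are circular: hourly/4-h averages use the
  unit-vector mean, and an antipodal (zero-resultant) bin is flagged
  undefined rather than silently averaged. Direction never enters the
  CCF or RDA (it would need circular-linear statistics, out of scope).
* **Standardization.** z-scores use the sample (n−1) standard
  deviation; sample sd is used everywhere an sd is needed.

## 2. Sinusoidal period model

For counts `y_t`, `t = 1..n` in 4-h steps:

    y_t = a1·cos(2πt/a4) + a2·sin(2πt/a4) + a3 [+ a5·t] + ε_t

`a4` is the free period in steps (reported ×4 in hours), `a3` the
midline, `a5` an optional linear trend used for taxa whose counts ride
a signal slower than the record (e.g. the spring-tide build-up across
a 5-day window). The cos/sin parameterization keeps the problem linear
in all but `a4`: amplitude `A = √(a1²+a2²)` and the acrophase follow
from `atan2(a2, a1)`.

Numerics:

* **Initialization.** `a4` starts at 24 h (the diel hypothesis);
  `a1, a2, a3[, a5]` start at their closed-form harmonic-regression
  values for that period. Trust-region least squares
  (`scipy.optimize.least_squares`, tolerances 1e-12) then moves only
  meaningfully along the period axis.
* **Period search band** [16, 32] h by default — wide enough for any
  credible diel estimate, narrow enough to keep the optimizer off the
  semidiurnal branch. A solution at a band edge is flagged `pinned`
  with a warning; because the optimizer starts from the fixed-24-h
  solution, the free-period SSE never exceeds the fixed-24-h SSE.
* **Uncertainty.** Covariance = s²(JᵀJ)⁻¹ at the optimum
  (s² = SSE/(n−k), k = 4 or 5); two-sided t tests on n−k df.
  Non-convergence and singular covariance produce a flagged result
  (`converged=False`, NaN se/p), never an exception. A constant series
  is the canonical degenerate input: amplitude ≈ 0, period
  unidentifiable, p undefined.
* **Fixed-period mode** (`fix_period_h`) reduces to exact harmonic
  regression and is the oracle-comparison path in the tests.

**Caveat on the period p-value.** The reported p tests `a4 = 0` by a
Wald t, mirroring how an NLS coefficient table reports period
significance. It is *not* a calibrated rhythm-detection test: under
pure noise the locally fitted period is still a well-defined number
with a finite standard error, so this p is small even when no rhythm
exists (simulation: median null p ≈ 1e-14). Detection questions should
go to the periodogram (whose null is calibrated; see §3) or to the
amplitude, not to this p. Residual autocorrelation is also not
corrected for; with n ≈ 30 robust variants are less stable than the
plain fit.

## 3. Lomb-Scargle periodogram

Classic variance-normalized Lomb-Scargle (mean subtracted, power =
half the SSE reduction of a per-frequency phased-cosine fit divided by
the sample variance; `scipy.signal.lombscargle` supplies the
numerator). Defaults: period band 2–48 h, oversampling `ofac = 8` —
about 0.2–0.6 h resolution near 24 h on a 5-day hourly record, enough
to separate nearby diel peaks; both are configurable.

Significance: each normalized power is Exp(1) under Gaussian white
noise; the peak over `M` independent frequencies has false-alarm
probability `1 − (1 − e^{−z})^M`. `M` uses the Horne–Baliunas
approximation (≈ `−6.4 + 1.19n + 0.00098n²`), the convention behind
the usual R significance line. It is documented as approximate — for
a restricted band it overcounts independent frequencies, making the
line slightly conservative; the measured null false-alarm rate at
α = 0.05 on 5-day hourly white noise is ≈ 0.04. Exact ties in peak
power break toward the longer period, with a warning.

## 4. Cross-correlation and RDA

**CCF.** `ccf(k) = Σ(x_t − x̄)(y_{t+k} − ȳ)/(n·s_x·s_y)` with overall
means and divisor-n sds held fixed across lags — the convention whose
lag-0 value is exactly Pearson's r and whose white-noise band is
±z_{1−α/2}/√n. Only non-negative lags (environment leading) are
computed: abundance cannot drive the oceanography. Both α = 0.05 and
α = 0.10 bands are reported; weak couplings may clear only the laxer
one. Only variables with a significant periodogram peak are tested
(an aperiodic driver cannot explain a periodic count series).

**RDA.** Response = centered taxa matrix (common abundance units, so
not scaled), predictors = z-scored 4-h environmental series, biology
lagged 12 h by default so the ordination reads "environment at t vs
biology at t+12 h". Fit `Ŷ = X(XᵀX)⁻¹XᵀY`, SVD of `Ŷ`; eigenvalues
are fitted-value variances (n−1), proportions divide by total response
variance. Scores follow the correlation-biplot (scaling-2)
convention: site scores unit-variance, species scores = response
loadings weighted by the axis singular value, environmental biplot
scores = predictor-axis Pearson correlations (hence in [−1, 1]).
Eigenvector signs are arbitrary, so each axis is canonicalized by
making the predictor with the largest |biplot score| positive.
Collinear predictors are greedily dropped (SVD null-vector heuristic)
with a warning; complete cases only.

## 5. Waveforms, MESOR, phase

Fold each series onto the clock (bin width = sampling interval: 6 bins
for biology, 24 for environment); per bin, mean ± sample sd across
days, missing slots excluded, empty bins excluded from the MESOR with
a warning. **MESOR** = unweighted mean of the bin means (an exact
identity, asserted to 1e-12). The **peak** is the set of bins strictly
above the MESOR.

Phase classification against a night window `[night_start, night_end)`
(may wrap midnight): any peak bin with a sunrise/sunset strictly
inside it → crepuscular (C); otherwise all peak bins in daylight → D,
all in night → N, else mixed. Default windows approximate a
mid-latitude NE-Pacific photoperiod — summer 21:30–05:30, winter
16:45–08:00 — and are fully configurable, since real campaigns should
supply their site's almanac values. A robustness variant removes each
bin's single maximum observation and recomputes; a peak that survives
is not an artifact of one lucky transect.

## 6. Synthetic-study generator

The generator produces exactly the world the analysis assumes:

* monthly 5-day campaigns; biology every 4 h as two transect legs of
  10 usable minutes each; hourly environment;
* environmental variables = baseline + sinusoids (diel 24 h and/or
  tidal 12.42 h M2) + Gaussian sensor noise; flow synthesized as a
  magnitude model projected onto a fixed bearing, so
  components → polar round-trips exactly;
* count rate λ(t) = max(0, mesor + A·cos(2π(t − acrophase)/period)
  + trend·step + gain·⟨driver over [t−lag, t−lag+4 h)⟩), acrophase in
  clock hours; default lag 12 h. The lagged driver term is the mean
  over the lagged *sampling window*, not an instant: counts accrue
  across the whole slot, and window averaging is what makes the
  generator's true CCF peak sit exactly on the nominal lag;
* per leg, counts ~ Poisson(λ·minutes/10), independently per leg, so
  the pooled pair count is Poisson(λ·pair-minutes/10) and the
  normalized slot value is an unbiased estimate of λ. Poisson noise
  and the even leg split are generator choices (field protocols report
  only the pooled pair) and are recorded in the study manifest;
* one seed per study; per-month/per-taxon/per-variable substreams are
  derived deterministically (CRC of the label), so adding a taxon
  never changes another taxon's draws, and written bundles are
  byte-identical under a fixed seed.

Default magnitudes picture a deep (~900 m) NE-Pacific canyon station:
weak near-bottom flow (0.10 ± 0.05 m/s diel + 0.02 m/s tidal), ~3.5 °C
with small diel/tidal excursions, hypoxic oxygen (0.40 ± 0.06 ml/l),
low chlorophyll (0.25 ± 0.08 µg/l), sigma-density ≈ 27.6 kg/m³; taxa
at mesor 2–6 ind/10 min with amplitude/mesor ≈ 0.7 and 12-h-lagged
couplings. These are plausibility anchors, not fits to any dataset.

What the generator does **not** emulate: animal movement or spatial
structure (counts are exchangeable Poisson draws), observation-level
overdispersion beyond Poisson, irregular/missed transects (available
only via explicit masking), autocorrelated sensor noise, reverse-flow
events, or tidal harmonic families beyond user-specified sinusoids.
A green test therefore certifies the *statistical machinery* —
estimator correctness, calibration of significance bands, recovery of
generating parameters under Poisson noise — not robustness to every
field pathology.

## 7. Known limitations

* The period p-value calibration caveat of §2 is the main statistical
  sharp edge.
* Horne–Baliunas `M` is an approximation tuned to full-Nyquist scans;
  restricted bands make the significance line conservative.
* RDA significance is not tested (no permutation test), matching the
  descriptive use of ordination here.
* The species-score weighting is one member of the scaling-2 family;
  cross-package comparisons should compare scores up to axis sign and
  an overall per-axis constant.
* Night windows are user inputs; the phase classes are only as good
  as the photoperiod supplied.
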