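# Methods

This note documents the models, defaults and numerical choices behind
the pipeline, what the synthetic soundscape generator does and does not
emulate, and the reduced problem sizes used by the test suite and the
acceptance script.

## Audio and spectral conventions

Recordings are mono PCM 16-bit WAV, nominally 44.1 kHz; samples are
normalized to [−1, 1] on read (dividing by 32768). Spectrograms are
magnitude STFTs with a periodic Hann window, default length 512 samples
and no overlap (frequency resolution `sample_rate / 512`, rows =
`512 // 2 + 1` rfft bins including Nyquist). Band-pass filtering is
FFT-domain masking — brick-wall, zero-phase — matching the dialect of
the frequency-filter routines common in ecoacoustics toolchains. The
amplitude envelope is the Hilbert analytic-signal magnitude. Mean
spectra carry the Hann amplitude correction `2 / sum(window)` and are
normalized to a maximum of 1; a silent clip returns a zero vector with a
flag rather than dividing by zero.

## Acoustic indices (3–10 kHz)

All five indices target the insect band. Defaults follow the classical
implementations where those fix a value; everything is configurable.

* **ACI** — per frequency bin and temporal chunk (default 5 s):
  `d = Σ|I_k − I_{k+1}| / ΣI_k`, summed over bins and chunks; zero-sum
  chunks contribute 0. Invariant under uniform gain.
* **ADI** — computed on the clip *after* band-pass filtering (the
  recipe order): per-1-kHz-band occupancy = fraction of spectrogram
  cells above −50 dB relative to the spectrogram maximum; occupancies
  normalized to proportions; ADI = Shannon entropy in nats. With the
  3–10 kHz pre-filter the 0–3 kHz bands have zero occupancy, which
  deflates ADI relative to an unfiltered computation; this is
  replicated deliberately. The threshold is relative to the clip
  maximum, so ADI is also gain-invariant here.
* **BI** — mean band spectrum in dB minus its quietest bin, summed ×
  bin width in kHz (a dB·kHz area). Invariant under dB translation.
* **H** — product of normalized spectral entropy (mean spectrum as a
  PMF, divided by log bin count) and normalized temporal entropy
  (envelope PMF); in [0, 1]; computed on the filtered clip.
* **NP** — count of local maxima of the mean spectrum above 300 Hz with
  amplitude prominence ≥ 1% of the spectrum maximum, counted strictly
  inside (3000, 10000) Hz. The low-cut is interpreted in Hz; both the
  cut and the prominence threshold are exposed because classical
  descriptions leave them loose.

Clips with RMS below 10⁻⁴ (well under any recordable ambient level, but
above numerical noise) are flagged silent, excluded from scaling and
auto-removed at QC. Index scaling is the affine map onto
[0.0001, 0.9999] fitted per column *after* QC (post-cleaning), with the
(min, max) persisted to JSON so the identical map can be applied to new
data.

## Quality control

Rain screening uses two diagnostic bands, 0.6–1.2 kHz and 4.4–5.6 kHz:
mean band power (PSD) and the temporal mean/SD ratio of band amplitude
(SNR — steady rain is high, impulsive biophony low). Thresholds are the
per-metric minima over known rain clips shrunk by a safety factor
(0.95); a clip is flagged when all four metrics meet their thresholds.
This is a deliberately simple stand-in for threshold-based hard-rain
detectors; it is calibrated per deployment, not universal.

Mahalanobis screening then removes multivariate outliers of the raw
five-index vectors: squared distance from the corpus mean under the
non-robust sample covariance (estimated on *all* clips, outliers
included), threshold 12 interpreted as **squared** distance — the
convention of the standard statistical routine. Distances are computed
on the correlation scale internally, which is numerically stable and
makes the affine invariance explicit: distances are identical on raw and
min–max-scaled indices. Screening order is rain first, then
Mahalanobis; re-screening the retained set with the fitted mean and
covariance flags nothing new.

## Calibration regressions

Coverage (a proportion) is modelled by beta regression with a logit
mean link and constant precision φ; per-observation log-likelihood
`lnΓ(φ) − lnΓ(μφ) − lnΓ((1−μ)φ) + (μφ−1)ln y + ((1−μ)φ−1)ln(1−y)`.
Sonotype counts use a Poisson GLM with log link. Manual coverage
quantized to 5% can be exactly 0 or 1, outside the beta support, so the
standard squeeze `y' = (y(n−1) + 0.5)/n` is applied before fitting.

Both families are fitted in-package — Newton scoring for Poisson,
L-BFGS with the analytic score (and log φ bounded above, since
zero-noise responses push φ → ∞) for beta — because all-subsets
enumeration and repeated cross-validation require thousands of fits per
dataset; coefficient covariances are inverse observed information
(finite differences of the analytic score at the optimum for beta).
The fitted coefficients, standard errors and log-likelihoods are
verified against independent reference implementations in the test
suite.

The candidate set holds 12 terms: the five scaled indices as linear and
quadratic terms (quadratics may enter without their linear counterpart
— inclusion is counted per term), plus site and year as factors
(treatment coding; year as a 2-level factor). All 4096 subsets are
fitted (intercept always present), ranked by AICc with deterministic
tie-breaking (fewer terms, then lexicographic). Models with ΔAICc < 2
of the best are averaged with Akaike weights and zero substitution for
absent terms ("full" averaging); averaged predictions use the weight
mixture, with variance `Σ wᵢ (seᵢ² + (μᵢ − μ̄)²)` so between-model
spread is not discarded. Cross-validation (5 folds × 100 repeats,
unstratified random folds) evaluates the single best model on the
response scale; test observations with a factor level unseen in the
training fold are skipped with a warning.

The calibration models are fixed-effects GLMs: the design contains only
fixed terms (indices, site, year), and no random-effects structure is
imposed.

## Cyclic GAMs

Each scaled index is smoothed by a Gaussian additive model: intercept,
site × year interaction (sum-to-zero contrasts over the observed
cells), and two cyclic cubic regression splines — hour with period 24,
day of year with period 365 (non-leap study calendar, hour mapped to
1…24). Basis dimension is k = 4 *before* the identifiability
(centering) constraint — low on purpose so the smooths track broad
phenological trends rather than short-term variation; a `k` knob allows
more flexibility.

The basis is the classical cyclic natural-spline parameterization:
function values at k evenly spaced knots, with second derivatives
implied by periodic continuity (value, first and second derivative
match across the wrap); the penalty is the integrated squared second
derivative expressed in that basis, so constants are unpenalized.
Penalties are normalized to unit spectral norm so one λ grid serves
both cycle lengths. Fitting is penalized least squares; λ_hour and
λ_doy are chosen by GCV over a 41-point log grid per smooth
(10⁻⁴…10⁶), taking the smallest λ on a flat plateau; a tiny ridge
(10⁻¹⁰ · tr(XᵀX)/p) guards exact collinearity at λ ≈ 0. The Bayesian
coefficient covariance `(XᵀX + Σλᵢ Sᵢ)⁻¹ σ̂²` supplies prediction
standard errors; predictions are exactly periodic because evaluation
reduces the covariate modulo the period.

## Uncertainty propagation

For each grid point and each of 1000 iterations: (i) each index is
drawn independently from Normal(GAM mean, GAM se) and clamped to the
scaled support [0.0001, 0.9999]; (ii) the drawn values feed the
calibration model (quadratics are squared *after* drawing — they are
deterministic transforms of the index, not independent draws); (iii)
activity is drawn from Normal(calibration mean, calibration se) on the
response scale and clamped to the response support ([0, 1] for
coverage, ≥ 0 for counts). Clamp counts are recorded in the output, so
truncation is never silent. Draws are vectorized over blocks of
iterations; a fixed seed yields bit-identical draw tables.

Two documented simplifications: the five index draws are independent
(no joint covariance across indices is estimated), and step (iii) draws
on the response scale rather than the link scale. Both follow the
stated procedure exactly; an `index_se_scale` knob supports the
widening diagnostic (propagated intervals are never narrower than the
plug-in-index intervals).

## The synthetic soundscape generator

The generator is first-class, tested code — it defines the study
conditions under which the pipeline is verified.

* **Sonotypes**: 20 templates spanning 3.4–9.6 kHz; ~50% narrowband
  trills (150–500 Hz bandwidth, band-limited noise carriers), 30%
  broadband bursts (0.8–2 kHz), 20% tonal whines (slow FM sinusoids);
  60% pulsed at 2–12 Hz with duty cycles 0.3–0.8; peak levels −34 to
  −14 dBFS. All template bands lie inside 3–10 kHz.
* **Activity**: per-sonotype logit-cosine model
  `p(h, d) = invlogit(b + a_h cos(2π(h−h₀)/24) + a_d cos(2π(d−d₀)/365))`
  with baselines −1.6…−0.2, diel peaks 21:00–01:00 (amplitude 0.8–1.8)
  and seasonal peaks at day-of-year 220–280 (amplitude 0.5–1.2) — a
  nocturnal, dry-season-peaking community.
* **Clips**: active calls summed over Gaussian background noise at
  −45 dBFS RMS; if the mixture clips it is rescaled to −1 dBFS with a
  warning (an error mode is available). Per-clip and per-template
  sub-seeds make corpora bit-reproducible and make each template's
  waveform independent of which other templates are active (so truth
  labels are monotone in the activated set).
* **Ground truth** over the first 15 s: a sonotype counts as audible
  when its pulse envelope keeps it ≥ 6 dB above the noise floor for at
  least 1 s (proxying an annotator noticing it); coverage is the
  fraction of 3–10 kHz spectrogram cells where the mixture exceeds the
  known noise component's own cell amplitude by 6 dB, rounded to the
  nearest 0.05 (so a pure-noise clip scores exactly 0, mirroring a
  "nearest 5%" manual protocol).
* **Contamination**: rain clips add broadband noise shaped
  `1/sqrt(1 + (f/1200 Hz)²)` at −18 dBFS; fault clips are near-silent
  (dead microphone) or a constant mid-frequency tone; missing files are
  dropped per clip at the configured rate. Schedule default: 1 min
  every 10 min, 3 sites, 2018–2019 (non-leap calendar, day-of-year
  1–365).

What it does **not** emulate: perceptually realistic calls or
species-level mimicry, bird/anuran biophony, wind and other geophony
beyond rain, annotator confusion between overlapping sonotypes (template
identity is treated as truth), lunar effects, and diel changes in
background noise. Passing tests therefore show the *statistical
machinery* is correct under the assumed structure, not that acoustic
indices track real insect communities in any particular forest.

## Problem sizes in tests and the acceptance script

The full study scale (3 sites × 730 days × 144 one-minute clips/day =
315,360 clips at 44.1 kHz) is kept for schedule arithmetic only. The
executed synthetic studies are scaled down as a package choice: 15-s
clips at 22.05 kHz, 2 sites, every 15th day of 2018–2019, one clip per
3 h (≈ 780 planned clips), with the generator's statistical conditions
(activity model, contamination rates, band limits, quantization)
unchanged. Simulation-based checks use n = 800–2000 observations and
100–200 replicates; the Monte Carlo chain always runs its full 1000
iterations.

## Known limitations

* The rain classifier is a calibrated two-band heuristic; it will not
  transfer across recorder hardware without re-calibration.
* Beta-regression covariances assume the observed-information
  approximation is adequate; heavily quantized responses (5% steps)
  are treated as continuous after the boundary squeeze.
* GCV can undersmooth on small n; the λ plateau rule and the low k = 4
  basis bound the damage.
* Model-averaged standard errors use the standard mixture formula;
  they do not account for selection uncertainty beyond the ΔAICc < 2
  set.
* The propagation chain double-counts neither residual noise nor
  index-GAM correlation structure — indices are drawn independently,
  which is conservative for sums and anti-conservative for
  differences.
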