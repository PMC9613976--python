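# Methods

This document describes the algorithms and modelling choices implemented in
`speechdx`. All symbols refer to code in `src/speechdx/`.

## 1. Feature registry

Twenty-six acoustic features are keyed `<base>_<task>`, where the task is
`a` (sustained vowel), `s` (syllable repetition / diadochokinesis), `m`
(monologue) or `t` (reading text). Each feature carries an *impairment
direction*: `+1` when larger raw values indicate worse speech (e.g. jitter,
DUS, RFA, stdF0_a, stdPSD, VD, DDKI, PSI, RSR) and `−1` when smaller raw
values do (e.g. RLR, PIR, GVI, EST, RST, AST, stdF0_m/t, DDKR, NSR). The
registry (`registry.py`) also defines the subsystem membership used by the
combination search and the canonical column orders.

## 2. Synthetic cohort generator

`synthesis.simulate_feature_cohort` draws a cohort from per-group, per-feature
calibration statistics (mean, SD, observed lo/hi range) stored in
`data/group_stats.json`.

For subject *i* in group *g*, feature *f*:

```
x_if = μ_HC,f + (1 + λ·s_i) · k · (μ_g,f − μ_HC,f) + ε_if
```

- `s_i ~ N(0, 1)` is a latent per-subject severity shared by all features,
  so more severe subjects deviate further from HC on every feature at once.
- `k` (`effect_scale`) scales the group mean shift; `k = 0` is an exact null
  (no group signal at all), `k = 1` reproduces the calibration group means.
- `λ` (`severity_coupling`) controls how strongly severity modulates the
  shift. `λ = None` solves `λ` by Brent's method so that the *implied*
  Pearson correlation between the DTI2 index and the synthetic clinical
  total equals a target (default 0.5); the implied correlation is computed
  in closed form from the linear mixture model, no simulation involved.
- `ε_if ~ N(0, σ)` with rejection resampling (1000 attempts, then clipping)
  into the truncation range, so every simulated value respects the observed
  feature range.
- Optional equicorrelation `ρ` (`correlation_rho`) across a subject's noise
  vector.

**Null-exactness interpolation.** The noise SD and the truncation range
interpolate linearly from the HC marginal at `k = 0` to the group marginal
at `k ≥ 1` with weight `t = min(k, 1)`, using the form
`(1−t)·a + t·b` so the endpoints are exact in floating point. Without this,
group-specific variances and ranges would leak group identity even at
`k = 0` (several group ranges exclude the HC mean region entirely),
contradicting the contract that `k = 0` carries no signal. At the default
`k = 1`, the marginals are exactly the calibration group marginals.

**Truncation bias.** Because the observed ranges are tight relative to a
normal marginal, rejection sampling shifts some realised means away from the
calibration means (worst case ≈ 0.5 SD for zero-floored features such as
PSI_a; typically 0.05–0.3 SD). The generator matches the hard ranges exactly
and accepts this bias.

A linear clinical model (`NNIPPSModel`) maps the same latent severity to a
clinical total per patient group (patients only), with additive Gaussian
noise, so index–clinical correlations are meaningful.

`audio.py` synthesises mono WAV fixtures (pulse-train vowels with
controllable drift, jitter and sub-harmonic depth; syllable trains with
controllable rate and irregularity) for exercising the front-end without any
recorded speech.

## 3. Acoustic front-end

All analysis operates on mono WAV files read via `scipy.io.wavfile` and
normalised to float. Framing: 40 ms windows, 10 ms hop.

- **Pitch** (`track_pitch`): autocorrelation per frame, searched over
  60–400 Hz, with parabolic peak interpolation; frames failing energy or
  periodicity thresholds are unvoiced.
- **Segmentation** (`segment_speech`): energy-based voiced/unvoiced/pause labelling
  with minimum durations (60 ms pause, 30 ms voiced) to suppress spurious
  segments. Segments exactly partition the recording.
- **Vowel task** (`a`): `stdF0_a` is the pitch SD in semitones; `jitter` the
  mean absolute cycle-to-cycle period perturbation (%); `stdPSD` the SD of
  the long-term average log-spectrum; `PSI` the percentage of voiced frames
  exhibiting sub-harmonic structure. The sub-harmonic detector compares the
  bias-corrected ACF peak at twice the dominant period against the dominant
  peak and flags ratios in [0.10, 0.55] — the band an alternating-amplitude
  (period-doubled) source produces and a clean source does not.
- **Syllable task** (`s`): onsets from the voiced segments give `DDKR`
  (rate, syllables/s), `DDKI` (SD of inter-onset intervals, ms) and `VD`
  (mean voiced-segment duration, ms). At least 3 onsets are required.
- **Timing features** (connected speech): `EST` is the base-2 entropy of the
  voiced/unvoiced/pause interval-type distribution (bounded by
  log₂ 3 ≈ 1.585); `RST` the speech-interval rate per minute; `AST` the
  late-minus-early half difference of RST divided by total duration in
  minutes (a deceleration/acceleration slope); `GVI` the rate of voiced
  intrusions inside pauses. At least 10 intervals and 2 s (timing) / 5 s
  (prosody) of signal are required.
- **Prosody** (`stdF0_m/t`): robust pitch-variability estimator
  1.4826 × MAD of the semitone pitch track around its modal value, which
  ignores octave jumps and isolated tracking errors.

Inputs that are too short, silent or degenerate raise typed exceptions
(`ValidationError`, `InsufficientDataError`) rather than returning NaNs.

## 4. Normalization and indices

`fit_normalizer` estimates per-feature HC mean and SD (ddof = 1) and stores
the direction conventions; `apply_normalizer` produces impairment-oriented
z-scores

```
z = direction × (x − mean_HC) / sd_HC
```

so higher always means more impaired and the HC group has exactly zero mean
and unit SD per feature. Constant HC features raise
`DegenerateFeatureError`; directions are overridable per feature. The fitted
normalizer serialises to JSON for exact reuse.

`compute_indices` evaluates the subsystem scores and composites as fixed
linear forms of the z-columns:

```
F_resp = ½[(RLR_m + RLR_t + PIR_m + PIR_t)/4 + RSR_m + RSR_t]
F_phon = ½[(jitter_a + GVI_m + GVI_t)/3 + 2·stdF0_a]
F_art  = (RFA_m + RFA_t + stdPSD_a)/3
F_pros = (stdF0_m + stdF0_t)/2
F_time = (EST_m + RST_m + AST_t)/3

SSI1 = F_resp + DUS_m/2 + F_pros/2
SSI2 = F_art + F_phon/2 + F_time/2

H1 = SSI1                         (hypokinetic component 1)
H_art  = (RFA_m + RFA_t)/2
H_phon = (jitter_a + GVI_m + GVI_t)/3
H_time = (EST_m + RST_m + AST_t)/3
H2 = H_art + H_phon/2 + H_time/2
A1 = (VD_s + DDKI_s)/2            A2 = (stdF0_a + stdPSD_a)/2
S1 = ½[(NSR_t + DDKR_s)/2 + PSI_a]

DTI1 = H1 + (A1 + S1)/2           DTI2 = H2 + A2
```

Linearity makes the indices exactly verifiable against hand-computed cases
(e.g. all z = 1 gives SSI1 = 2.5, SSI2 = 2.25, DTI1 = 3.5, DTI2 = 3.0).

## 5. Combination search

For each subsystem, `search.best_combination` enumerates all non-empty
subsets of the subsystem's features (capped at 12 features), averages the
z-scores within a subset per subject, and tests the two contrast groups
(Welch's t by default; Mann–Whitney optionally). The decision rule has three
deterministic stages:

1. **single-significant** — the lowest-p subset if it is significant at α;
2. **weighted-pair** — if a disjoint second subset is also significant, the
   weighted combination (2·best + second)/2 is reported alongside;
3. **best-nonsignificant** — otherwise the lowest-p subset is reported as
   non-significant.

Ties break by (p-value, subset size, lexicographic feature ids), making the
result invariant to input column order. Undefined p-values (e.g. constant
samples) are treated as 1.0. The implementation is tested for exact equality
against an independently written brute-force oracle.

## 6. Statistics

Every variable is routed through a normality screen: a Lilliefors-corrected
one-sample KS test (the mean/SD are estimated from the sample), with the
Dallal–Wilkinson p-value approximation, which is accurate near the α = 0.05
routing boundary where the interpolation table is conservative at large n.

- All four groups normal → one-way **ANOVA** with **Tukey HSD** post hoc on
  raw values.
- Otherwise → **Kruskal–Wallis** with Tukey HSD on pooled ranks.

Only the four clinically relevant contrasts are reported: HC–PD, HC–PSP,
HC–MSA, PSP–MSA. Correlations use Pearson when both margins pass the screen
and Spearman otherwise. Raw p-values are reported without multiple-testing
correction.

## 7. Classification

`classify.loso_logistic` runs leave-one-subject-out logistic regression:
each fold fits unpenalised maximum likelihood (lbfgs); a perfectly separated
training fold (no ML optimum) falls back to a tiny ridge (λ = 1e-4) and the
event count is reported. Held-out probabilities pool into accuracy,
sensitivity and specificity at threshold 0.5, the ROC AUC, and the
Youden-optimal operating point. Positive labels per contrast: PSP vs MSA →
PSP, PD vs MSA → MSA, PD vs PSP → PSP. The full-fit decision boundary is
exported as coefficients and, for 2-D predictor sets, a matplotlib plot.

## 8. Pipeline, CLI and reproducibility

`pipeline.run_pipeline` chains config → simulate → ingest → normalize →
indices → search → stats → classify → report, each stage mapped to a
distinct process exit code (9–17) so a failing run identifies its stage.
The report bundle contains every intermediate table, a Markdown report, and
a `MANIFEST` listing completeness plus SHA-256 checksums of all files.

Determinism guarantees:

- all randomness flows through `numpy.random.default_rng(seed)` seeded from
  the config;
- no timestamps or environment-dependent content appear in any output file;
- rerunning the same config produces byte-identical bundles (asserted by
  test).

## 9. Limitations

- The cohort generator matches first/second moments and hard ranges of the
  calibration statistics per feature, with a single shared severity factor;
  it does not model realistic cross-feature covariance structure beyond the
  severity factor and optional equicorrelation.
- The front-end extracts vowel-, syllable- and timing-based features from
  audio; consonant- and respiration-specific features (DUS, RFA, RLR, RSR,
  PIR, NSR, VOT) require task-specific modelling and enter only through
  feature tables.
- Synthetic classification results characterise the pipeline, not clinical
  performance; no real recordings are included.
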