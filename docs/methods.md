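# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data generator does and does not
emulate.

## Photometry preprocessing

The chain is detrend → ΔF/F → z-score, applied independently to each
LED-ON block (the acquisition duty cycle of 90 min ON / 30 min OFF makes
each block its own photobleaching epoch).

**Offset-preserving detrend.** A 5th-order polynomial is fit to the raw
trace by least squares and subtracted, *with the fit's mean added back*.
Subtracting the full fit yields a zero-mean residual on which a
1st-percentile F0 is nonpositive and ΔF/F is ill-posed; re-centering keeps
the raw amplitude scale so the percentile baseline stays positive for any
realistic fluorescence trace. The residual remains orthogonal to the
centered polynomial basis. The fit uses an abscissa rescaled to [−1, 1]
for conditioning.

**ΔF/F and z-units.** F0 is the 1st percentile computed with linear
interpolation between order statistics (numpy's default convention; the
test suite pins it against a sort-based oracle). Z-scoring uses the mean
and s.d. of the whole block, making the chain idempotent: re-running the
z-score changes nothing.

**Isosbestic correction.** In z-units, using the control channel as a
sample-wise F0 reduces to subtraction. Plain subtraction
(`scale="unit"`) assumes the shared artifact has the same z-magnitude in
both channels; when the calcium channel carries substantial
kernel-driven variance this assumption fails, so `preprocess_session`
defaults to `scale="fit"`, which rescales the control by its least-squares
projection onto the signal before subtracting. Whether correction happens
before or after the final z-score is configurable
(`correct_before_zscore`); the default corrects after, and the order only
matters when artifact scales differ strongly between channels.

**Alignment.** Windows are half-open [−5, 15) s with the event sample at
t = 0 and 0-based sample indexing; a 100-Hz trace yields 2000 samples per
trial. Trials are excluded (with reason codes, never dropped) when the
window leaves the recording (`edge`), crosses an LED-OFF gap (`led_off`),
or — for sensory-response analyses — when an impulsive lick occurred
within 1 s of the event (`early_lick`).

**Session-baseline correction** fits `baseline ~ outcome + session` by
OLS with *hit* as the reference outcome level and subtracts only the
intercept and session effects. Reference coding (not sum-to-zero) is
deliberate: it pins the mean baseline of hit trials in each session at
zero while leaving outcome contrasts untouched. A session without hit
trials still receives its pooled-model session estimate, with a warning.

## Sleep staging

The stager codifies the standard manual criteria as a threshold cascade
on 4-s epoch features: EMG RMS above threshold → wake; otherwise frontal
power ratio (power > 25 Hz ÷ power < 5 Hz, per-epoch periodogram) below
threshold → NREM; otherwise parietal θ/δ above threshold → REM, else
wake. Thresholds are fitted per recording by a one-dimensional
two-means split of each feature in log10 space — EMG and the power ratio
over all epochs, θ/δ over low-EMG (sleep) epochs only, where the NREM/REM
contrast is not diluted by wake. Per-recording fitting makes staging
invariant to affine rescaling of the raw channels. A split whose centers
are closer than 0.3 log10 units is treated as unimodal and falls back to
fixed thresholds with a warning. A 3-epoch minimum-duration rule merges
short runs into the preceding state.

## Tone-evoked arousal

A tone is scorable only if the last complete epoch before onset is staged
NREM (the scorer's "ongoing sleep" judgment). Awakening requires a
desynchronized run — sliding 1-s power-ratio windows (0.25-s step) above
the recording's wake-side threshold — starting within 3 s of onset,
persisting ≥ 2 s, without dominant parietal theta (run-median θ/δ below
the REM threshold), and with EMG RMS during the run above 2× the 4-s
pre-onset level. The 2× activation factor and both spectral thresholds
are configurable; they operationalize criteria that were applied by eye
in manual scoring, so their exact values are a design choice validated by
generator recovery. Trials already desynchronized immediately before
onset return `pre_desync` (not scorable); without this guard, tones
landing just after a natural NREM→wake transition masquerade as
awakenings and inflate the recovered awakening fraction by about one
percentage point.

Maintained trials are then screened by the slow-wave-activity filter:
SWA is power < 10 Hz in 5-s windows, and a pre/post ratio above 1.5
excludes the trial (sleep was not purely maintained). Group-level
baselines combine per-mouse means with weights n_i / mean(n), i.e. a
trial-count-weighted mean. A 2-h window selector supports
post-injection analyses.

## Encoding model

Event trains are expanded into lagged indicator columns over per-variable
kernel windows (defaults: trial onset (0, 2) s, cue (0, 2) s, lick
(−0.5, 2) s, run onset (−1, 3) s — configurable placeholders, since the
windows are protocol choices). Ridge coefficients solve
(XᵀX + λI)β = Xᵀy without an intercept. Explained variance is a pooled
10-fold cross-validated R² with *contiguous* time blocks as folds: random
folds let slow drift leak between train and test and inflate R², which
the test suite demonstrates directly. λ is chosen once on a log grid
(10⁻²…10⁴) by the same contiguous CV and shared across the full,
single-variable and omission models — the selection is therefore mildly
optimistic for the full model's CVR², but identical folds and a shared λ
keep ΔR² comparisons across variables unbiased. Held-out R² may be
negative and is reported unclipped; it is clipped only as the
normalization denominator. Unique contributions divide by the variable's
window size in samples and by the full-model CVR².

## Behavior

Outcomes are exhaustive and mutually exclusive: a first lick strictly
inside the delay is an impulsive error (RT from trial onset), a lick in
the 1.5-s window from the Go cue is a hit (RT from the cue), anything
else a miss. A lick exactly at cue onset counts as post-cue (closed-left
convention). Hit-rate denominators exclude impulsive-terminated trials —
the Go cue was never delivered there. The quantile coupling curve bins
each mouse's pre-trial activity into deciles (count configurable),
normalizes the per-bin error rate by that mouse's overall rate, and pools
bins across mice into a simple linear regression on bin index (per-mouse
averaging and regression on bin-mean activity are alternatives exposed in
the API). The strategy split is 2-means with 100 restarts on
standardized (impulsive rate, cloud modulation index); the
higher-impulsivity cluster is labeled explorer. Streaks are run-length
encodings of consecutive misses.

## Statistics

Bootstrap CIs are bias-corrected-and-accelerated (the estimation-stats
convention); a constant sample short-circuits to a zero-width interval.
Permutation p-values use the add-one convention
p = (1 + #{|Δperm| ≥ |Δobs|}) / (1 + n_perm), so the smallest attainable
p is 1/(n_perm + 1). The paired t and simple regression are classical;
the regression carries a 95% confidence band for the mean response.

## The synthetic-data generator

The generator's defaults are the study conditions; they are not tuned per
analysis.

**Task.** 360 trials initiated every 20 s (a 2-h session), four equally
probable cue intensities, tone cloud on 50% and visual aid on 25% of
trials, delay uniform on [0.5, 3.0] s. Flags are assigned by stratified
shuffling so session marginals are exact (i.i.d. assignment is available);
the original block composition ("15 occurrences of each combination") is
arithmetically inconsistent with a 25% aid marginal under full crossing,
and the marginals are what every analysis consumes.

**Agent.** Engagement follows a unit-variance AR(1) across trials
(ρ = 0.9); the latent ACCp proxy is a negative affine transform of
engagement plus noise, with coupling = |corr|. P(impulsive) decreases and
P(miss) increases linearly in the proxy, clipped to [0, 1]; detection
adds per-intensity psychometric bases, an aid boost and cloud penalties.
Explorer and exploiter presets differ in baseline impulsivity (0.20 vs
0.05), cloud sensitivity, aid reliance, psychometric floor and coupling
(0.8 vs 0.25) — chosen to reproduce the qualitative phenotype contrast
(overall outcome rates near 26/45/29% impulsive/hit/miss for explorers)
rather than any specific mouse.

**Photometry.** Calcium = exponential bleaching drift × (1 + Σ kernels ⊛
event trains) + noise + shared artifacts; the isosbestic channel carries
drift, artifacts and independent noise but no kernels. Synthesis runs at
100 Hz by default — the signal band is < 4 Hz, so this stands in for the
1017.25-Hz acquisition at desk scale (the rate is configurable).

**Sleep.** Vigilance states follow a 3-state Markov chain on 4-s epochs
with the physiological topology wake→NREM, NREM→{wake, REM}, REM→wake.
Given target stationary occupancies and mean NREM/REM bout lengths (45
and 20 epochs), the remaining rates follow from the balance equations, so
the chain's stationary distribution equals the target *exactly*. Default
occupancies are 55.96% NREM / 35.65% wake / 8.39% REM — the reported
undisturbed-sleep percentages renormalized to sum to one (as printed they
sum to 96.5%, the remainder being unscored time). EEG is band-limited
Gaussian noise (δ 0.5–5, θ 5–10, high 25–49 Hz) mixed with per-state
amplitudes; EMG is 10–49 Hz noise scaled per state. No spindles,
K-complexes or oscillatory phase structure are synthesized — staging
features depend only on band powers, so passing recovery tests shows the
cascade logic is correct, not that it would survive real EEG
microstructure, scorer disagreement or electrode artifacts.

**Arousals.** Tones (65/80 dB, randomized) arrive every 60 ± 0.5 s.
For a tone in NREM, awakening probability is a logistic in the latent
ACCp baseline with a per-dB intercept calibrated by Gauss–Hermite
quadrature so the *marginal* probability over NREM trials equals the
configured per-dB value (defaults 19.8% at 80 dB, 8.1% at 65 dB). An
awakening inserts wake-like EEG and an EMG burst starting 0.5–2 s after
onset and forces a wake bout (geometric, mean 5 epochs); a maintained
trial holds NREM through the 3-s scoring window so ground-truth labels
match the realized signal. Awakening latencies beyond the 3-s onset rule
are not modeled.

## Problem sizes and determinism

All generators are deterministic given their seed. The acceptance script
uses 6 × 12-h sessions for staging recovery and 12 × ~10-h sessions
(matching the reported cohort of 12 mice) for arousal recovery, at 100-Hz
synthesis; the full run takes about a minute on one CPU. Child seeds are
drawn from `numpy.random.SeedSequence(seed)`.

## Known limitations

- The staging thresholds assume bimodal feature distributions; recordings
  dominated by a single state fall back to fixed thresholds.
- The arousal classifier's constants (2× EMG activation, wake-side
  desynchronization threshold) are calibrated implicitly by the
  generator's contrast between states; real recordings may need the
  configurable variants.
- The encoding model assumes linear, time-invariant event kernels and
  penalizes all columns equally; analog regressors are not standardized
  internally.
- Explorer/exploiter classification is a 2-means heuristic on two
  features; it reproduces a clearly separated cohort but is not a model
  of strategy.
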