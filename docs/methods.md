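# Methods

## Scope and model

`amdyn` implements a feature framework for active brain–computer
interfaces built on the *amplitude-modulation dynamics* of EEG
sub-bands. The core object is the two-stage filter-bank decomposition:
a channel is split into the five classical bands (delta 1–4, theta 4–8,
alpha 8–12, beta 12–30, gamma 30–50 Hz), the Hilbert envelope of each
band signal is taken, and each envelope is re-filtered through the same
bank. The resulting carrier × modulant time series (written
`beta_mtheta` for the theta-range dynamics of the beta envelope)
quantify amplitude–amplitude cross-frequency coupling.

A narrowband carrier of bandwidth *B* cannot express envelope
fluctuations faster than *B* (the Hilbert product condition for
separating a slow envelope from a fast carrier), so pairs whose
modulant band starts above the carrier bandwidth are physically
meaningless. The mask is `modulant.f_lo <= carrier bandwidth`, which
invalidates 11 of the 25 canonical pairs; the within-gamma pair
(30–50 Hz modulation of a 20 Hz-wide carrier) fails the rule but is
conventionally analysed and is admitted through an explicit,
configurable override, giving the standard 14-pair set. Invalid pairs
are computed implicitly but never stored.

Three feature families are extracted per trial:

- **AMP** — per 4 s analysis frame (hop 1 s, 11 frames on the 16 s
  epoch running from −1 s to +15 s around task onset), the mean-square
  power of each valid AM series, normalized so the 14 powers of one
  channel/frame sum to 1.
- **CCORAM** — per frame and unordered electrode pair (default
  ten-electrode spatial-span subset: F7, F8, T7, T8, C3, C4, P7, P8,
  O1, O2), the Jammalamadaka–SenGupta circular correlation of the two
  channels' AM-series instantaneous phases:
  ρ = Σ sin(φ₁−μ₁)sin(φ₂−μ₂) / √(Σ sin²(φ₁−μ₁)·Σ sin²(φ₂−μ₂)),
  with μ the circular means. 45 pairs × 14 bands = 630 values per
  frame.
- **PSD** — baseline features: non-overlapping 1 s windows, Welch
  spectrum normalized to relative power, band sums over theta, alpha1
  (8–10), alpha2 (10–12), beta1 (12–21), beta2 (21–30), 8–30 and
  0–50 Hz, plus alpha/beta and theta/beta ratios, all log-scaled with a
  1e−10 floor. Band edges are half-open `[f_lo, f_hi)`, so a 10 Hz bin
  belongs to alpha2.

Evaluation ranks features per task pair with the two-class Fisher
criterion J = (μ₁−μ₂)²/(σ₁²+σ₂²) (unbiased variances), selects the
top-k on the *training* portion of each stratified 90/10 shuffle split,
tunes an RBF-SVM (grid over C and gamma, 3-fold inner CV), and scores
held-out predictions with Cohen's kappa. Feature-set comparisons use a
two-sided Wilcoxon rank-sum over the per-split kappas at α = 0.05,
without multiplicity correction.

The 21 pairwise metrics of the seven-task protocol (mental rotation,
word generation, subtraction, singing, navigation, motor imagery, face
imagery) fill a symmetric 7×7 interaction matrix with zero diagonal
(a task has no self-discrimination value; negative kappas are clipped
to 0 with a logged count so the matrix stays nonnegative). The
*prestige score* is the eigenvector of its algebraically largest
eigenvalue — elementwise nonnegative for irreducible nonnegative
matrices by Perron–Frobenius — normalized to unit Euclidean norm
(an L1 option exists) and scaled by the eigenvalue so that fold-wise
averaging preserves relative interaction magnitudes. Averages across
folds are reported without re-normalization. The same machinery applied
to per-feature Fisher matrices yields per-feature prestige vectors,
aggregated by feature type, channel, or band with both mean and sum
("cumulative score") statistics.

## Numerical choices

- **Filters.** Every filter is a Hamming-window linear-phase FIR
  applied forward and backward on an even-mirror-padded signal (exactly
  `scipy.signal.filtfilt(taps, 1, x, padtype="even")`, verified to
  machine precision), giving zero group delay and squared single-pass
  magnitude. Band filters place their −6 dB cutoffs half a transition
  width outside the band; the transition width is `clip(f_lo/2, 1, 2)`
  Hz. The classical bands are contiguous, so transitions wider than
  2 Hz would leak a neighbouring band's centre frequency into the
  envelope stage; the 2 Hz cap keeps a mid-band tone's envelope ≥ 10×
  stronger in its own band than in any other. Filtering requires
  `len(x) > 3 × len(taps)`; at the 256 Hz working rate the longest bank
  filter (delta, 845 taps) fits a 16 s epoch with margin.
- **Broadband 0.1–50 Hz pre-filter.** At practical lengths the 0.1 Hz
  cutoff transition straddles DC, so the designed taps are shifted by
  their mean to an exact zero DC gain; the perturbation elsewhere is
  < 0.5 % while offsets and drift vanish completely.
- **Working rate.** Recordings are resampled to 256 Hz by default —
  comfortably above twice the 50 Hz analysis ceiling while bounding
  filter lengths; configurable.
- **Welch resolution.** Within a 1 s window, segments of at most 1 s
  are used (a single Hamming-tapered segment by default). Sub-second
  segments would give ≥ 2 Hz bins, which cannot separate the 2 Hz-wide
  alpha sub-bands and push a 6 Hz tone's leakage into the excluded
  8 Hz bin.
- **Frame placement.** A 1 s hop admits 13 windows on a 16 s epoch; the
  first 11 from epoch start (starts −1 … +9 s) are retained, matching
  one decision frame per second after the initial 4 s buffer. Placement
  and count are configurable.
- **PSD–AMP sample alignment.** A classification sample is one AMP
  frame; its PSD features are those of the 1 s window ending at the
  frame's end — the freshest spectrum available when that frame's
  decision would be made.
- **Degenerate cases.** All-zero AMP frames emit zeros with a warning
  (no division); constant AM windows have no phase and CCORAM emits
  NaN, imputed with training-set medians at the classification stage;
  an all-zero interaction matrix yields a zero prestige vector; exact
  Fisher ties break lexicographically by feature name so selection is
  deterministic.
- **Determinism.** The harness derives per-split seeds from one
  configuration seed; the generator is a pure function of
  (task specs, seed).

## What the synthetic generator emulates

Each task is 1/f^β background noise (β = 1 default) plus
amplitude-modulated oscillatory components
x(t) = A·(1 + d·sin φ_m(t))·c(t) injected during 15 s task segments,
with the session protocol (30 s leading baseline, randomized task
order, uniform 10–15 s rest gaps) of a typical multi-task recording.
The carrier c(t) is unit-RMS narrowband-filtered Gaussian noise (a
deterministic-tone mode exists for closed-form tests), and the
modulator phase φ_m advances at the modulant frequency plus a Wiener
diffusion term (default 0.5 rad²/s).

The diffusion is structural, not cosmetic: a strictly periodic
modulator has a uniform phase marginal, whose circular mean — the
anchor of the circular correlation — is undefined in the limit, so ρ
between two *independent* same-frequency modulators would be an
arbitrary cos(offset) rather than near zero. Aperiodic modulators are
also the realistic case: cortical envelope dynamics do not phase-lock
across 15 s. The coupling scenario raises the diffusion to 5 rad²/s so
independent channels wander apart by several radians within one 4 s
frame, while channels in a coupling group share the whole AM source
(modulator phase and carrier realization) — one cortical source seen
at several electrodes.

Three canonical scenarios drive the acceptance experiments:

1. **AM-only contrast** — two tasks whose only difference is the
   modulant frequency (2 vs 6 Hz) of a gamma carrier at 39–41 Hz,
   depth 0.7, over unit-level 1/f background on six channels,
   18 trials/task (198 frame-samples per class). The narrow 2 Hz
   carrier keeps all half-power content — carrier, filter skirts, and
   sidebands — inside 30–50 Hz, where the baseline PSD band set has no
   sub-band resolution, so every PSD feature is distributionally
   identical across tasks by construction; only gamma_mdelta vs
   gamma_mtheta AMP features separate them. Evaluated with 20 splits.
2. **Planted coupling** — one task, an alpha-band component
   (10 Hz carrier, 2 Hz modulant, depth 0.8) on all ten electrodes with
   only {C3, C4} sharing the source; recovery is the coupled pair's
   mean CCORAM over the non-coupled pairs' mean |ρ| in the planted
   band.
3. **Depth response** — the normalized alpha_mdelta AMP feature across
   planted depths {0, 0.25, 0.5, 0.75}, averaged over 10 background
   seeds. This experiment uses the deterministic-carrier mode: a
   stochastic carrier's own 0–2 Hz envelope fluctuations sit in the
   delta modulant band and would mask the d²/2 increment of the
   smallest depth step, and the experiment's object is the planted
   modulator, not carrier self-modulation.

What passing these does **not** show about real EEG: the generator has
no artifacts (ocular, muscle, line), no volume conduction or realistic
head geometry, no inter-subject or inter-session variability, one
simulated participant, and stationary task signatures. Classification
numbers on it are ground-truth-recovery checks of the pipeline, not
performance forecasts for recorded data. Samples from the same trial
are correlated; the default split ignores this (a trial-grouped split
option exists), which inflates absolute kappas slightly — visible as
PSD-only kappas of ~0.0–0.15 where chance is 0.

## Problem sizes

Default experiment sizes are chosen for interactive desk-scale runs:
the contrast scenario uses 18 trials/task on 6 channels with 20
evaluation splits; coupling uses 6 trials on 10 channels; the eigen
oracle uses 1000 random 7×7 matrices against 500-step power iteration.
The evaluation harness defaults (100 splits, top-2000 features) match
full-study settings and are what `EvalConfig` ships with; the
scenarios pass smaller values explicitly.

## Known limitations

- EDF/BDF reading is delegated to MNE and covered only by error-path
  tests (no EDF/BDF writer is available to build fixtures); the
  internal `.npz` container is the tested round-trip path.
- Artifact removal is a hook (`artifact_hook`) for external cleaners;
  the package performs none itself.
- The 8–30 Hz broad band keeps the source label "theta to beta" only in
  documentation; it is implemented literally by its printed edges, as
  is the 0–50 Hz band.
- Per-frame CCORAM (rather than whole-trial) was chosen so AMP and
  CCORAM samples align exactly; whole-trial phases would be better
  conditioned but break the frame-synchronous decision model.
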