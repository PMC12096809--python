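# Methods

This note documents the models, estimators and numerical choices behind
`batvoc`, and what the synthetic data can and cannot establish.

## Stimulus synthesis

The library holds 15 calls, five variants in each of three categories,
peak-normalized at 192 kHz:

| category | duration | spectrum | temporal structure |
|---|---|---|---|
| echolocation | < 3 ms | multiharmonic downward FM, fundamental ≈ 90→40 kHz | single sweep |
| appeasement | 25–46 ms | harmonic stack, F0 ≈ 17 kHz ± ~6 % | shallow slow FM, arched envelope |
| aggression | 134–271 ms | broadband elements, F0 7.5–13 kHz + dense harmonics + noise | pulse train, ~8 ms inter-element interval |

Variants differ deterministically in duration, F0 and modulation depth
(pure functions of `(seed, variant)`), giving within-category
variability.  Harmonics are amplitude-gated wherever `h·f0(t)` exceeds
95 % of Nyquist so the fast high sweeps never alias; for the
echolocation calls this means the second harmonic is present only over
the lower part of the sweep.  Absolute level is deliberately not a
stimulus property: calls are peak-normalized and level enters only
through each simulated unit's driven gain, mirroring presentation at a
fixed sensation level per unit.

Acoustic features: spectral centroid (power-weighted mean of the
magnitude spectrum), temporal centroid (energy-weighted mean time of the
Hilbert envelope), duration, and harmonic ratio — the fraction of
spectral energy within ±3 % bands around the autocorrelation-estimated
F0 and its first 10 multiples.  Duration alone separates all three
categories; harmonic ratio separates the noisy sweeps from the strongly
harmonic aggression elements.

## Unit simulation

Spike trains are inhomogeneous-Poisson draws by thinning (exact for any
bounded rate).  The trial rate is

    rate(t) = baseline + gain · w_category · kernel(t − onset − latency)

with per-trial latency jitter drawn from a zero-truncated Gaussian
(SD `jitter_ms`; truncation prevents acausal responses).

* **Phasic kernel** (dAC-like): the call's amplitude envelope, peak 1,
  raised to `phasic_sharpness`.  The exponent concentrates firing at
  envelope peaks and is how sub-millisecond envelope locking is
  expressed within a Poisson framework; sharpness 1 reproduces plain
  envelope-following, sharpness ≈ 3 the default dAC phenotype, and the
  idealized demonstration unit uses 10.
* **Tonic kernel** (FAF-like): a plateau of `response_duration_ms`
  starting at the (jittered) latency, ignoring envelope detail.  The
  same plateau shape is used for 20-ms tones, so the programmed response
  duration is recoverable from tone PSTHs.

Default phenotypes anchor to the population medians of the two regions:
FAF-like — latency 35 ms, tonic 95 ms, jitter 8 ms, CF 56 kHz, Q10 4.4;
dAC-like — latency 6 ms, phasic, 48 ms, jitter 1 ms, CF 36 kHz, Q10 3.8.
Baseline rates (8 and 5 Hz) and driven gains (80 and 400 Hz) are not
constrained by any published per-unit statistic; they are package
defaults chosen to give realistic spike counts (tens of driven spikes
per trial) and are stated in the templates, not inferred from data.

The tone-grid generator uses a V-shaped excitatory area, symmetric in
log frequency, whose slope is set so that the bandwidth 10 dB above the
tip equals CF/Q10 — the minimal generator from which BF, CF and Q10dB
are all recoverable.  Above threshold the driven rate grows with the
suprathreshold margin (saturating over 40 dB), which puts the strongest
response at CF at the highest level.

Populations are built by multiplicative lognormal jitter (relative SD
0.1) on all continuous parameters including the per-category weights;
category-weight spread is what gives individual units a preferred
category.

## Tuning metrics

The FRA is the median (over 10 repetitions) spontaneous-subtracted spike
count per (frequency, level) cell, counted from tone onset over a 100-ms
window (configurable; long enough for tonic responses).  The
responsiveness criterion everywhere is pre-stimulus mean + 2·SD, with
Poisson-consistent scaling of the 50-ms pre-window statistics to the
counting window (mean linearly, SD by square root).

* **BF**: argmax cell; ties toward the lowest frequency, then the
  highest level.
* **CF**: lowest-level responsive cell, restricted to the 4-connected
  responsive component containing BF.  The restriction matters: with 462
  cells screened at 2 SD, isolated false-positive cells at low levels
  otherwise capture the CF.  Level ties break toward the frequency
  nearest BF.
* **Q10dB**: CF divided by the bandwidth of the responsive run at the
  grid level nearest CF-threshold + 10 dB; band edges are interpolated
  in log2 frequency between the outermost responsive cells and their
  non-responsive neighbours, against the criterion.  Runs touching the
  grid edge are flagged censored.  Note a quantization property of the
  method itself: when the true CF falls between grid frequencies, the
  measured CF threshold lands one 5-dB step above the tip and the
  bandwidth is effectively read ~3 dB too high, biasing Q10 low by
  roughly 25 % — visible in recovery experiments and inherent to any
  implementation of this estimator on a 1/8-octave × 5-dB grid.
* **Latency / duration**: from a 1-ms PSTH pooling the trials of all
  cells in the responsive component.  Latency is the first run of ≥ 3
  consecutive suprathreshold bins after onset; the evoked epoch extends
  over later runs separated by ≤ 15 ms; duration is onset-to-offset of
  that epoch.  Three consecutive bins (not two) are required at 1-ms
  resolution: pooled PSTHs span hundreds of trials, and at a 2-SD
  criterion two adjacent suprathreshold baseline bins occur in a few
  percent of units, producing spurious 15–25 ms early onsets.  The
  2-bin rule is retained for the 2-ms-binned shared-window detection,
  where counts per bin are higher and the false-positive rate is
  negligible.

The SPL step of the tone grid defaults to 5 dB (80→15 dB, 14 levels);
the frequency grid is 5–80 kHz in 1/8-octave steps (33 frequencies).

## Response-strength selectivity

All 15 calls share one response window: per call, the evoked epoch of
the 2-ms trial-summed PSTH is detected with the mean + 2·SD criterion;
the shared window starts at the earliest onset across calls and its
length is the longest per-call evoked duration.  A call's response
strength is the maximum bin count (spikes per 2-ms bin, summed over the
20 presentations) inside the window.  The category response is the sum
of its five per-call strengths — the sum-of-max reading, which keeps
PIcat and PIcall on the same per-call statistic (the alternative
max-of-summed-PSTH reading is not exposed).  PIcat counts categories at
≥ 50 % of the best category (inclusive); PIcall does the same within a
category.  Both are invariant under uniform positive scaling of the
responses.

## Pattern classification

Single-trial PSTHs use 1-ms bins over the whole trial, convolved
('same' length) with a unit-area Gaussian kernel and then restricted to
the shared window; trials shorter than the window are zero-padded.  The
kernel's *integration window* parameter is its total support, with
σ = support/6 and truncation at ±3σ — so the 2-ms window has σ = 1/3 ms
(nearly a delta on the 1-ms grid) and the 200-ms window σ = 33 ms.  A
consequence worth knowing: two equal Gaussian bumps merge into a single
maximum only when closer than 2σ, i.e. 67 ms for the 200-ms window.

Each of the 10,000 resamples draws a stratified test trial (calls take
turns as test call, the trial is uniform) and one uniform template trial
per candidate call, excluding the test trial for the test call itself.
The test pattern is assigned to the class of the minimal Euclidean
distance template; exact distance ties are resolved uniformly among the
tied *classes* (forced choice).  At category level the candidates are
all 15 calls and the winning call's category is assigned; within a
category only its five calls compete.  Assignment counts divided by row
totals give the row-stochastic confusion matrix; everything is
deterministic given the seed.

Two structural properties of this estimator, established during
validation and worth knowing when reading confusion matrices from few
trials:

1. **Sparse-pattern attraction.**  With σ = 1/3 ms the Euclidean
   distance between two spike patterns is ≈ √(N₁ + N₂ − 2·overlap)
   in kernel-norm units.  When within-class overlap is low, the
   smallest-norm class (fewest spikes — here the short echolocation
   responses) attracts assignments from all rows.  High diagonal
   probabilities for all classes therefore require genuinely
   reproducible timing with more than one spike per envelope peak;
   rate-coded (tonic) units collapse toward the sparsest class at fine
   integration windows.  This asymmetry, not fine-pattern decoding, is
   why even temporally imprecise cohorts score above chance at 2 ms.
2. **Finite-template-pool structure.**  For a unit with no signal, a
   single 20-trial dataset does not produce an exactly uniform matrix:
   calls that happen to have more non-empty trials are systematically
   under-assigned on forced-choice ties, with deviations of a few
   percentage points.  The effect is zero-mean across dataset
   realizations (verified by averaging 40 independent baseline units),
   so chance-level validation averages matrices over units.

The selectivity index of a probability row is
`SI = max − (mean + SD of remaining entries)`, SD with the sample (n−1)
convention; with a single remaining entry the SD term is 0.  A unit's
SI is computed on the row with the largest diagonal entry (its best
category).  SI ≤ 1 always; a uniform row gives 0.

## Pipeline and statistics

`run_pipeline` is a pure function of `RunConfig` (seed, cohort sizes,
trial counts, integration windows, resample count): stimulus synthesis →
population construction → per-unit preference indices and confusion
matrices → group statistics, with per-unit failures (non-responsive
units) logged and flagged rather than aborting the run.  Group
comparisons delegate to `scipy.stats.ttest_ind`, `scipy.stats.ranksums`,
`scipy.stats.f_oneway` and statsmodels' Tukey HSD; α = 0.05.  Run-level
seeds fan out to per-unit/per-stimulus RNG streams by CRC32 hashing of
the identifiers, so adding a unit never perturbs another unit's data.

## Problem sizes and limitations

Validation and demonstration runs use desk-scale sizes chosen to keep
estimator noise well below the assertion margins: cohorts of 20 + 20
units at 2,000 resamples for directional population contrasts, 40 units
for tuning-parameter recovery, 20 averaged baseline units at 10,000
resamples for the chance oracle, and 10,000 resamples wherever a single
confusion matrix is reported.

The synthetic generators emulate the stimulus parameters and the two
response phenotypes, not recorded biology: no adaptation across the
presentation sequence, no patchy FRAs as a distinct mechanism (weakly
responsive units are represented by low gain and high jitter), no
inhibitory sidebands, no LFPs, and Poisson variability throughout
(real dAC units are likely sub-Poisson at envelope peaks).  Passing
tests therefore establish that the estimators recover what the
generative model programs and that the population contrasts follow from
the phenotype definitions — not that recorded FAF/dAC data would
reproduce any particular number.
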