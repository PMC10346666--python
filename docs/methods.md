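# Methods

This note documents the models, algorithms, parameters and design choices
behind `mibci`, and what its synthetic benchmarks do and do not show.

## Synthetic EEG sessions (`mibci.synthdata`)

Each run is a continuous multichannel record built additively per channel:

* **Background**: 1/f noise, synthesized by spectrally shaping white
  Gaussian noise (`PSD ∝ f^{-α}`), default exponent α = 1.0 and RMS 8 µV —
  a typical broadband level for dry-electrode scalp EEG.
* **Rhythms**: mu (8–12 Hz) and beta (16–26 Hz) carriers generated as
  bandpass-filtered noise, not sinusoids, so that their trial-to-trial
  variance structure resembles real sensorimotor rhythms and CSP has
  something realistic to work with (ERD is a power phenomenon, not a phase
  phenomenon). Per-channel RMS amplitudes peak at C3/C4 (5 µV mu, 2.5 µV
  beta) and taper frontally/occipitally.
* **ERD**: during the imagery interval (default 2.5–6.0 s of the 7 s
  trial) the rhythm amplitude on the central channel contralateral to the
  cued hand is multiplied by `1 − erd_depth`, with 0.25 s raised-cosine
  ramps at the interval edges to avoid spectral splatter. A `laterality`
  parameter in [0, 1] applies the same fraction of suppression
  ipsilaterally, because real subjects range from strictly contralateral
  to bilateral ERD; the default is purely contralateral.
* **Artifacts**: blinks (350 ms bumps, 120 µV, frontal weighting, Poisson
  10/min), cardiac pulse artifacts (80 ms biphasic spikes, 25 µV, occipital
  weighting, periodic at 72 bpm), and broadband vibration bursts (300 ms,
  Poisson 2/min, all channels). The first 6 s of each run are kept
  artifact-free so an ASR baseline always exists. All events are logged as
  ground truth.

Trials are concatenated with uniformly random 1.00–2.00 s rest gaps.
Classes are balanced and shuffled per run. Each run draws from an
independent RNG stream seeded by `(session seed, run index)`, so sessions
are bitwise reproducible and runs are independently regenerable.

**What this generator does not model**: volume conduction (channels are
spatially correlated only through the artifact-weight vectors, not a head
model), non-stationary vigilance drifts, electrode impedance changes, line
noise, or the physics of the haptic vest. Passing tests on this data shows
the pipeline recovers the class- and time-structure it is supposed to
recover at realistic SNR; it does not certify performance on recorded EEG,
where subject-specific SNR is typically far lower (chance-level subjects
are common in the modelled protocol).

## I/O and epoching (`mibci.io_epochs`)

EDF files are 16-bit with a ±3200 µV physical range (quantization step
≈ 0.098 µV); reading goes through `mne.io.read_raw_edf`, writing through a
minimal EDF encoder with 1 s data records, zero-padding the final partial
record (markers always point inside real data, so epoching is unaffected).
A plain CSV dialect (`# key=value` header lines + one column per channel)
is provided for interchange. Markers are TSV rows `(sample, class, run,
phase)` where `sample` is the 0-based cue-onset index.

Trial time 0 is the **fixation onset**; the cue sits at 2.00 s. Epochs are
half-open sample windows `[start, end)`, 0.00–7.00 s by default, i.e.
`round(7.0 × fs)` = 3584 samples at 512 Sa/s. Truncated trials raise an
error naming the offending trials rather than being silently dropped.

## Artifact subspace reconstruction (`mibci.asr`)

Calibration eigendecomposes the covariance of an artifact-free baseline
(designated segment, or the lowest-RMS-quantile windows when none is
designated) into a fixed component basis, and records per-component
thresholds `mean + cutoff × std` of the windowed component RMS. Cleaning
slides 0.5 s windows at 50% overlap, projects onto the basis, zeroes
components whose RMS exceeds their threshold, rebuilds the window from the
retained components, and blends windows with a raised-cosine (Hann) taper
normalized by the accumulated taper weight.

Zeroing is the correct reconstruction under this model: the basis
diagonalizes the baseline covariance, so components are uncorrelated under
the baseline distribution and the conditional expectation of a flagged
component given the retained ones is zero. If every component is flagged
the window reconstructs to the baseline mean (zero) and stays finite.

Defaults: cutoff 20, window 0.5 s, 50% overlap — conventional settings for
this family of cleaners, exposed in the config because the modelled study
does not report its values. ASR is offline-only; the online loop never
sees it. Measured properties (enforced by tests): <5% RMS distortion of
clean data, ≥50% RMS attenuation inside 10× bursts, <1% RMS change on a
second pass.

## FBCSP + NBPW (`mibci.fbcsp`)

* **Filter bank**: 17 bands of 4 Hz width stepped by 2 Hz, (4,8) … (36,40)
  — the unique uniform overlapped grid with 17 bands spanning 4–40 Hz.
  Chebyshev type II, overall bandpass order 10, designed as second-order
  sections with stopband edges 2 Hz outside each band and 40 dB
  attenuation; verified stable at 512 Sa/s. Offline filtering is
  zero-phase (forward–backward); the online path applies the same
  sections causally, as a real-time system must.
* **CSP**: per-trial covariances are trace-normalized, averaged per class,
  and shrunk toward scaled identity with weight 1e-3 (guarantees positive
  definiteness at 90-trial estimates). The generalized eigenproblem is
  solved by whitening the composite covariance and eigendecomposing the
  whitened class covariance, batched over bands; tests verify equivalence
  with a direct generalized eigensolver to 1e-8. `m = 2` pairs per band
  are retained (filter j pairs with 2m−1−j).
* **Features**: band-major `log(var_i / Σ_i var_i)` over the 2m retained
  projections, 68 dimensions total. Because `var(wX) = w C wᵀ`, features
  are computed from cached per-trial covariances during cross-validation —
  algebraically identical to refiltering each window, and the reason the
  21-window × 25-fold search runs in seconds.
* **MI / MIBIF**: `I(f; y) = H(y) − H(y|f)` with class-conditional Parzen
  densities (Gaussian kernel, Silverman bandwidth per class), `H(y|f)`
  averaged over training samples, estimates clipped at 0. Ranking uses the
  stable key (−MI, feature index); the top `k = 4` features are closed
  under CSP pairing, giving 4–8 selected features. The estimator is exactly
  affine-equivariant and stable under mild monotone warping (< 0.05 bits at
  n = 200 for cube-root or arctan), but strong tail-stretching transforms
  (e.g. cubing) degrade it by oversmoothing — a known property of fixed
  Silverman bandwidths.
* **NBPW**: class priors from training counts; per-feature pooled Silverman
  bandwidths (with a small-scale fallback for near-constant features);
  naive product of per-feature kernel densities evaluated in the log domain
  with a stable log-sum-exp. Posteriors sum to 1 to 1e-12; with balanced
  priors the reported winning-class posterior lies in [0.5, 1].

`m`, `k`, kernel and attenuation follow the standard FBCSP reference
configuration and are config-exposed, since the modelled study does not
print them.

## Window selection (`mibci.windows`)

Candidates: 2.00 s windows from 0.00 to 5.00 s start in 0.25 s steps (21).
Each is scored by stratified 5-fold CV with 5 repetitions (repetition r
re-randomizes folds with seed + r); CSP, MI ranking, feature selection and
NBPW are refit inside every training fold, so test trials never influence
any fitted component. The published dual criterion ("highest mean accuracy
and lowest per-class accuracy difference") cannot generally be optimized
jointly, so it is operationalized **lexicographically**: mean accuracy at
1-percentage-point resolution first, then the smaller per-class gap, then
the earlier start. This interpretation is deliberate and is the main open
design decision of the module.

A selection effect worth knowing: under the null (no ERD), the *maximum*
CV accuracy over the 21 correlated candidates is upward-biased relative to
any single window — occasionally exceeding the single-window chance band.
Chance-compatibility of a null pipeline is therefore judged per window
(the tests use the online processing window, 2.5–4.5 s), not on the
post-selection maximum.

## Online loop (`mibci.online`)

Acquisition starts at trial time 2.50 s with a 2.00 s causal buffer, so the
first decision lands at 4.50 s; decisions repeat every 0.25 s until 6.00 s
(7 per trial). A decision at time t uses only samples strictly before t.
Positive bias: if the decoded label matches the cue, the feedback command
carries the cue direction with magnitude `clip((p − 0.5)/0.5, 0, 1)` — the
simplest monotone map from the informative posterior range, config-exposed;
otherwise direction `none` with magnitude 0. Consequently an emitted
direction can never contradict the cue, which the tests check on every
simulated trial.

`simulate_nf_session` reproduces one subject-session: phase-1 runs are
generated, a fresh pipeline is trained from scratch on them (best-window
selection included — no state crosses sessions), and phase-2 trials are
streamed through the decoder. Per-trial online accuracy is the majority
vote of the 7 decisions (odd count; the degenerate even-count tie falls
back to summed posteriors); phase 2 is also re-scored offline with the
best-window CV procedure, since both readouts are plausible and the
modelled protocol does not say which was reported.

## Evaluation (`mibci.evaluation`)

* **Chance model**: accuracy of a random classifier ~ Binomial(n, 0.5)/n.
  Lower bound: smallest k with CDF ≥ α/2. Non-randomness threshold:
  largest k with P(X ≥ k) ≥ α — accuracies strictly above it are
  non-random at one-sided α. Both conventions are carried in the output;
  at n = 90 they give 40% and 59% (a central quantile convention would put
  the upper end at 60%, which is why the threshold convention is stated
  explicitly). Rounding is to the nearest percent. For n = 1 the interval
  degenerates to {0%, 100%} and the threshold is 100%: one correct trial
  is never significant.
* **Type-A uncertainty**: standard error of the mean across subjects,
  `sd/√n` — the metrological reading of "type A" for repeated
  observations.
* **ERSP**: per-trial short-time Fourier spectrograms (0.5 s Hann, 90%
  overlap), averaged over trials, expressed per frequency in dB against the
  **geometric** mean baseline power over the pre-cue interval (0–2 s), so
  the baseline-interval mean is exactly 0 dB. Negative values mark
  desynchronization. The time–frequency method is a package choice; the
  modelled study does not state its own.
* **Statistics battery**: Jarque–Bera normality per group → if rejected,
  Kruskal–Wallis (unpaired) or Wilcoxon signed-rank (paired); otherwise
  Bartlett homoscedasticity → one-way / repeated-measures ANOVA, or a
  Welch-corrected test on violation (Welch t for two groups, Welch ANOVA
  beyond). Mann–Whitney U serves unpaired scale comparisons. α = 0.05.
  Repeated-measures structure is handled as one-way within-subject ANOVA
  (via `pingouin`), the simplest model consistent with the described
  design. Degenerate zero-variance inputs short-circuit to a documented
  report instead of crashing. Under the null (identical chance-level
  groups) the battery triggers at ≈5% of 200 seeded runs, which the tests
  enforce within exact binomial tolerance.

## Problem sizes and numerical tolerances

Tests and the acceptance script use the protocol's native sizes: 90-trial
training pools (3 runs × 30 trials), the full 21-window × 5×5-fold search,
20 seeded replicates for the stochastic recovery checks, and 200 seeded
runs for statistical calibration. Core numeric tolerances: CSP vs oracle
1e-8; NBPW normalization 1e-12; covariance shrinkage 1e-3; ASR
idempotence 1%; MI estimator tolerance 0.05 bits at n = 200.

## Known limitations

* The component basis of ASR is fixed at calibration; per-window adaptive
  bases (as in some production cleaners) are out of scope, as are
  Riemannian variants and bad-channel interpolation.
* The MI estimator's monotone-invariance holds only for mild warpings (see
  above).
* No multiclass extension, no adaptive retraining within a session, and no
  modelling of rendering/haptic latency in the online loop.
* Synthetic benchmarks bound what can be claimed: they validate the
  machinery, not recorded-EEG performance.
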