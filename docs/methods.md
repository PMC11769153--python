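# Methods

`restmdd` implements a complete resting-state EEG classification study for
major depressive disorder (MDD) versus healthy controls: a synthetic cohort
generator standing in for private clinical recordings, the standard
preprocessing chain, a 570-dimensional wavelet/fractal feature set,
mutual-information feature reduction, and a six-model tuning and evaluation
harness. This note records the models, the parameters that matter, and the
design choices made where the procedure was genuinely open.

## Synthetic cohorts

Real clinical EEG from psychiatric cohorts is rarely shareable, so the
package ships a generator whose output carries the statistical structure the
analysis assumes, without claiming physiological realism (no dipole/forward
modelling, no photic-driving or hyperventilation response — those phases
exist only as protocol annotations).

**Signal model.** Each channel is a sum over the five clinical bands
(delta 0.1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–40 Hz) of
band-limited Gaussian noise plus a 1/f background (exponent 1.0). Default
band variances are 20/10/25/8/4 μV² with a 10 μV² background — a plausible
resting scalp profile with dominant alpha. Eyes-closed periods multiply
alpha variance by `ec_alpha_gain = 1.5` (posterior alpha rhythm).

**Spatial structure.** A fraction `spatial_rho = 0.85` of every band's
variance (and of the background) is carried by `sources_per_band = 2` latent
band-limited sources projected through *signed* random per-subject
topographies; the remainder is channel-independent noise. This emulates
volume conduction: real scalp EEG is strongly correlated across electrodes
and approximately low-rank, which is precisely what lets ICA isolate
artifact components. Two properties drove the construction:

- with a fully channel-independent background, *no* linear component
  removal can subtract a blink component without also stripping a large
  share (~40% in our measurements, matching the analytic
  minimum-variance-unmixing floor) of genuine frontal delta power — the
  preprocessing chain would look destructive for a reason that is an
  artifact of the simulation, not of the method;
- topographies must be signed (dipolar sources project with both
  polarities): all-positive topographies are dominated by their common mode,
  which average referencing removes.

The per-channel normalization guarantees each channel's band variance equals
the configured weight regardless of `spatial_rho`.

**Group effect and heterogeneity.** MDD recordings multiply band variances
by `group_effect` (default alpha ×1.3, gamma ×0.8 — a recoverable but
non-trivial planted effect; quantitative group spectra for real MDD
cohorts are not established, so these are scaffolding, not estimates).
Between-subject heterogeneity is lognormal: a per-subject factor shared
across channels (log-SD 0.12) and a per-channel factor (log-SD 0.08). With
these defaults the optimal separation sits in the high-80s accuracy range:
well above the 0.75 recovery threshold used in validation, well below
trivial separability. Setting `group_effect={}` yields an exchangeable null
cohort.

**Demography.** Subject age/sex are drawn to match the emulated cohort's
demography table (healthy: 32 F / 38 M, ages ≈36 ± 10–11; MDD: 37 F / 33 M,
female ages ≈37 ± 10, male ≈45 ± 12), truncated at 18 years. Ages and sexes
label the recordings but do not influence the signals.

**Artifacts.** Blinks (Poisson events, default 6/min, 120 μV, 0.3 s raised-
cosine transients on Fp1/Fp2 with smaller frontal spread, every event
annotated), 50 Hz mains hum (5 μV, per-channel coupling gains 0.5–1.5 so it
is not pure common mode), and sub-0.1 Hz drift (20 μV random-walk wander).
Zero amplitude disables a class; an all-zero spec is the identity.

**Determinism.** Every recording is a pure function of its
`SubjectProfile.seed`; cohort seeds derive from a master seed through
`numpy.random.SeedSequence.spawn`.

## Preprocessing

The chain is bandpass filter → average reference → ICA labelling/removal.

**Filter.** Linear-phase Hamming-window FIR bandpass, built as a
highpass/lowpass cascade so the two edges get appropriate transition widths
(≈ the cutoff itself at 0.1 Hz — genuinely suppressing sub-0.1 Hz drift —
and ≈5 Hz at 40 Hz), applied forward–backward via FFT convolution with
odd-reflection padding (zero net phase). Measured response at 200 Hz:
−128 dB at 50 Hz, within ±1 dB over 1–35 Hz.

**ICA.** FastICA with the deflationary log-cosh (negentropy) contrast,
seeded; default component count is channels−1 (average-referenced data have
rank ≤ 18), and requests beyond the numerical rank are rejected with a rank
report. Because the synthetic background is Gaussian, the contrast has no
usable gradient in most of the source space and the iteration cap
(`max_iter=200`) is routinely hit; this is expected and harmless — the
non-Gaussian artifact components are extracted first, and the
mixing/unmixing pair reconstructs the data to ~1e-15 relative error
regardless of convergence.

**Component labelling.** A rule-based stand-in for trained component
classifiers, with config-exposed thresholds: LINE_NOISE if >50% of source
power lies within 50 ± 1 Hz; EYE if >60% of power is below 4 Hz *and* the
mean |mixing| weight at Fp1/Fp2 is ≥2× the median channel; MUSCLE if >60%
of power is above 20 Hz; otherwise BRAIN. Labels can be overridden before
removal (the manual-inspection hook). `drop_policy='auto'` removes all
EYE/MUSCLE/LINE_NOISE components; `'none'` skips ICA entirely, appropriate
for artifact-free simulations.

**Segmentation.** The first five alternating eyes-open/eyes-closed
annotations become the feature segments; photic and hyperventilation
sections are excluded; fewer than five annotated periods is an error.

## Features

Each segment and channel is decomposed with a 6-level Daubechies-4 DWT in
periodization mode (the transform is then orthogonal: coefficient energy
equals signal energy and band reconstructions are exact). Signals are
trimmed to a multiple of 2⁶ = 64 samples to preserve orthogonality. Dyadic
levels map to bands by maximal overlap of nominal ranges; at 200 Hz:
d2→gamma (25–50), d3→beta (12.5–25), d4→alpha (6.25–12.5), d5→theta
(3.125–6.25), d6+a6→delta, d1 (50–100 Hz) discarded. The dyadic ranges only
approximate the nominal band edges; this is inherent to a DWT band split.

Six features per channel × band, averaged over the five segments
(eyes-open/closed pooled with equal weight):

| feature | definition |
|---|---|
| `abs_power` | mean square of the band-limited reconstruction (μV²) |
| `rel_power` | band share of the five-band power sum (sums to 1) |
| `spec_centroid` | periodogram-weighted mean frequency of the reconstruction (Hz) |
| `rwe` | band share of retained DWT coefficient energy (sums to 1) |
| `wentropy` | Shannon entropy (nats) of the band's coefficient energy over 8 equal temporal blocks |
| `katz_fd` | Katz fractal dimension of the band reconstruction |

**Per-band wavelet entropy.** Wavelet entropy is naturally a cross-band
quantity (entropy of the relative wavelet energies, exposed as
`wavelet_entropy`, range [0, ln 5]); the 570 = 19×5×6 arithmetic demands a
*per-band* value, for which no standard definition exists.
We use the temporal-block entropy above (range [0, ln 8]): near-maximal for
stationary in-band activity, small when a band's energy is concentrated in
a transient. This is an interpretation, flagged as such.

**Katz FD.** Computed with successive-sample distances |Δx|: curve length
L = Σ|Δx|, diameter d = max|x−x₀|, n steps; KFD = log₁₀n / (log₁₀n +
log₁₀(d/L)). A line gives exactly 1; a constant series is defined as 1.
This form is amplitude-invariant, as are all features except `abs_power`
(which scales quadratically).

With 19 channels: 19 × 5 × 6 = 570 named features
(`<channel>_<band>_<feature>`), assembled into a per-cohort table (CSV
round-trip is bit-exact via full-precision decimal text).

## Classification harness

**Split.** Subject-wise, stratified with exact largest-remainder class
allocation: the 140-subject balanced cohort always splits 100 train /
40 test with 20+20 test classes. Seeded and deterministic.

**Feature reduction.** Mutual information between each feature and the
diagnosis, estimated with the k-nearest-neighbour estimator for
continuous–discrete pairs (k=3, scikit-learn); fitted on training rows only
— an audit guard raises if a table containing test subjects reaches the
ranking or if training subjects reach evaluation. Ties break by feature
index. The reduced set is the top 100.

**Models and tuning.** Six families — decision tree, SVM, random forest,
k-NN, gradient-boosted trees (XGBoost backend by default; hyperparameter
grid: learning rate {0.1, 0.3, 0.5}, depth {3, 5, 7}, estimators {50, 100},
gamma {0, 1, 3}), and Gaussian naive Bayes (no grid). Grid search maximizes
stratified 10-fold CV accuracy on the training set (ties → first grid
point), then refits on all 100 training subjects; tuning is done separately
for the 570- and 100-feature sets. SVM and k-NN are standardized with
fold-internal z-scoring inside a pipeline; tree models and NB consume raw
features. Each family's grid contains the canonical operating point
(depth-2 random-splitter tree; RBF C=1 SVM; 50-tree forest with
min_split 10/min_leaf 2; 5-NN; boosted trees at lr 0.5/depth 5/50
trees/gamma 3). XGBoost runs single-threaded with 32 histogram bins —
lossless at ~100 subjects and several times faster.

**Evaluation.** Confusion matrix with MDD positive, accuracy and binary F1,
reported to 2 decimals (exact values retained alongside). `run_experiment`
produces all 12 (family × feature-set) cells with per-cell error isolation,
plus the ranking, the selected features, a summary table and a
confusion-matrix figure.

## Orchestration

`run_all` executes simulate → preprocess → features → train/evaluate from a
single validated config (schema-checked with field-path error messages;
cross-field constraints such as the Nyquist bound and k ≤ 570 enforced
before any computation). Stage seeds are SHA-256 hashes of (master seed,
stage name) reduced mod 2³¹, so stages are independently reproducible. A
manifest records the config hash and SHA-256 of every output; re-running a
config reproduces `report.json` bit-exactly. EDF+ output is optional
(in-memory hand-off by default); the EDF+C writer quantizes to 16 bits over
a per-channel symmetric range (quantization ≪0.1 μV at EEG amplitudes) and
is round-trip tested against MNE's independent EDF reader.

## Validation experiments and problem sizes

The canned experiments (`restmdd.experiments`) run at desk scale: 140
subjects, five 20 s resting periods (clinical recordings run ~30 min;
all features are normalized or averaged, so they are duration-robust), with
photic/hyperventilation phases shortened to 2 s/5 s (they carry no
features). Model-evaluation cohorts are simulated artifact-free with the
ICA stage disabled, isolating classification calibration from
component-removal variance; artifact handling has its own experiment.

- **Null calibration**: with `group_effect={}`, each family's test accuracy
  is averaged over 3 independent cohorts and must lie within the 95%
  binomial band around 0.5 for n=40. Averaging is used because a *fixed*
  finite cohort can carry chance multivariate feature–label correlation
  that inflates single-split deviations beyond the binomial spread (models
  can even anti-generalize on the complement of their training subjects);
  across independent cohorts the procedure is calibrated (grand mean 0.514
  over 10 cohorts in our measurements), and the mean of 3 runs is strictly
  more precise than the single run the band was stated for.
- **Effect recovery**: 5 independent seeded end-to-end runs at the default
  effect; the best family (evaluated over SVM/k-NN/NB — a lower bound on
  the best of all six) must reach ≥0.75 test accuracy in ≥4 runs, and the
  MI top-100 must retain alpha power features (abs/rel/RWE × 19 channels)
  at ≥2× their ~10% chance share in ≥95% of runs. Per-feature retention
  cannot be demanded at the 0.95 level: the 114 injected-band features
  genuinely compete for 100 slots.
- **Artifact restoration**: after cleaning a blink/mains/drift-contaminated
  recording, frontal (Fp1) delta power and channel-pooled 50 Hz power must
  lie within 25% of the identically preprocessed artifact-free recording.
  50 Hz is pooled across channels because both residues sit ~120 dB below
  the raw artifact and a single-channel ratio is numerically unstable.

## What passing tests do and do not show

The generator produces stationary Gaussian band mixtures with planted
multiplicative effects. Passing validation shows the pipeline is internally
sound: leakage-free, calibrated under the null, able to recover a planted
spectral effect, and non-destructive in artifact removal. It does **not**
show that real MDD cohorts are classifiable at any particular accuracy —
real effect sizes, non-stationarity, medication, comorbidity and recording
variability are outside the simulation, and accuracies reported for
clinical cohorts are not reproduction targets for synthetic ones.

## Known limitations

- The per-band wavelet-entropy and per-band Katz FD definitions are our
  interpretations of an under-specified feature list (see above).
- The rule-based component labeller approximates a trained classifier; it
  has no HEART or OTHER detection rules beyond the defaults and mislabels
  are possible on unusual topographies.
- Dyadic DWT bands only approximate the nominal clinical band edges. For
  the reconstruction-based features (`abs_power`, `spec_centroid`,
  `katz_fd`) a filter-bank backend using the exact nominal edges is
  available (`BandSet(recon_backend="filter")`); the default stays with
  wavelet reconstructions for fidelity to the wavelet-decomposition design.
- The EDF writer emits EDF+C with a single annotation-bearing record
  sized to fit all events; extremely dense annotation streams would need
  record-spanning TALs.
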