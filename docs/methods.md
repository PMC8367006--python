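# Methods

`emgweight` decodes the weight of a lifted object (165 / 330 / 660 g) from
multi-channel surface EMG of a reach-grasp-lift task. The pipeline is:
preprocessing → fixed-length feature assembly → spectral dimensionality
reduction (Laplacian Eigenmaps with a Nyström out-of-sample extension) →
classification → per-subject macro-F1 evaluation, plus an event-aligned
sliding-window analysis of how decodability evolves around object contact.
A synthetic cohort generator reproduces the statistical structure of the
target 12-subject dataset so that every stage is testable offline.

## Preprocessing and feature assembly

Each trial is a 5-channel recording at 4 kHz. The chain is:

1. **Full-wave rectification** — elementwise absolute value.
2. **Peak normalization** — each channel divided by its own per-trial
   maximum absolute value, so every channel spans [0, 1]. Normalization is
   per trial and per channel; per-subject (MVC-style) normalization is a
   possible alternative but is not the default.
3. **Band-pass filtering** — zero-phase (forward–backward) 4th-order
   Butterworth, 5–450 Hz at 4 kHz. Zero-phase filtering is used so that
   event-aligned windows stay aligned with the underlying bursts; the cost
   is an acausal smear of sharp onsets of roughly the filter's impulse
   response width (relevant below).

Trials are truncated to their first 8 s (shorter trials are rejected, never
padded) and subsampled by taking every 5th sample starting at index 0 in
each channel. Channels are concatenated in channel order, giving
l = C · T · (R / step) features per trial — 5 × 8 × 800 = 32,000 at study
scale. Rows of the resulting feature matrix follow trial order, and labels
are carried alongside.

## Laplacian Eigenmaps

Given trials x_1 … x_N, an edge joins i and j when either is among the
other's n nearest neighbors in Euclidean distance (union rule; ties broken
toward the lower index). Edge weights are either *simple-minded* (W_ij = 1)
or the *heat kernel* W_ij = exp(−‖x_i − x_j‖² / (2σ²)) — equivalently an
RBF kernel with γ = 1/(2σ²). With D the diagonal degree matrix
(D_ii = Σ_j W_ji) and L = D − W, the embedding solves the generalized
eigenproblem L f = λ D f, discards the zero eigenvalue's constant
eigenvector, and uses the next m eigenvectors as coordinates
y_i = (f_1(i), …, f_m(i)).

Numerically the problem is reduced to the symmetric normalized form
S = D^(−1/2) L D^(−1/2), whose spectrum lies in [0, 2]; eigenvectors map
back as f = D^(−1/2) u, making the normalization f^T D f = 1 automatic.
Signs are fixed deterministically (largest-magnitude entry positive). A
dense symmetric solver is used: training sets here never exceed a few
thousand points, where LAPACK is faster and more accurate near the zero
eigenvalue than iterative sparse solvers. Tests verify the implementation
against a direct generalized eigensolve of (L, D) and against closed forms
for the 2-node and 3-node-path graphs.

**Disconnected graphs are a hard error.** On a disconnected graph the zero
eigenvalue is degenerate and the embedding undefined; the error message
suggests a larger neighborhood or a longer window. No silent
largest-component fallback is applied by default.

## Nyström out-of-sample extension

The eigenproblem implies the row identity W f = (1 − λ) D f. A new point x
is therefore assigned weights w_i to its n nearest training points (under
the fitted scheme) and mapped to

    y_j(x) = Σ_i w_i f_j(i) / ( d(x) · (1 − λ_j) ),   d(x) = Σ_i w_i.

This form makes re-embedding of a training point from its stored weight row
*exact* — the package's primary correctness anchor for the extension (tested
to 1e-8 relative error; in practice ~1e-15). A retained eigenvalue equal to
1 makes the denominator vanish; this raises a dedicated error
(`SingularExtensionError`). λ = 1 arises in practice for structurally
degenerate graphs (stars, twin nodes), which occur in small or
near-duplicate window data; window-level analyses record such windows as
failed rather than aborting.

**Geometry of the extension.** The sum Σ w_i f_j(i)/d(x) is a convex
combination of the neighbors' coordinates, so before the 1/(1 − λ_j) factor
the extended point lies exactly in the convex hull of its neighbors'
embeddings. The factor then inflates the point radially by λ_j/(1 − λ_j)
per coordinate. With simple-minded weights on a ~1800-point Swiss-roll
graph λ_1 ≈ 4e-4, and this inflation — though only ~0.04 % of the global
coordinate scale — exceeds the thickness of the flattest local hulls, so
roughly a fifth of the extensions fall marginally outside their local hull.
The hull-membership diagnostic is therefore run with a heat kernel at a
small bandwidth (σ = 0.15 on the unit-scale Swiss roll), where the retained
eigenvalues are at numerical zero and the extension is an exact convex
combination; membership is decided by a linear program on centered and
rescaled hull coordinates, because simplex-based point location returns
false negatives on thin, nearly collinear local hulls.

## Baseline embeddings and intrinsic dimension

PCA, LDA, LLE and ISOMAP are scikit-learn-backed behind a uniform
fit/transform facade (PCA/LDA extend new points by projection, LLE/ISOMAP
by their built-in out-of-sample machinery); LDA is capped at
n_classes − 1 = 2 components. Only Laplacian Eigenmaps and the k-NN
classifier are bespoke.

Intrinsic dimension uses the Levina–Bickel maximum-likelihood estimator:
per point, m̂_k(x) = [(1/(k−1)) Σ_{j<k} log(T_k/T_j)]^(−1) with T_j the
distance to the j-th neighbor; per-point inverses are averaged before
inverting (the standard stabilization), and the result is averaged over
k ∈ [n_neighbors − 2, n_neighbors]. Duplicate-point zero distances are
floored at 1e-12. On 2000-point Swiss-roll and sphere fixtures the
estimates fall in [1.7, 2.3].

## Classification and evaluation protocol

k-NN is implemented directly: Euclidean majority vote over k = 8 neighbors,
vote ties broken by the smaller summed distance to the tied label's
neighbors, then the lower label. SVMs (linear, and RBF with C = 32,
γ = 0.01) and Random Forest (100 trees, seed-controlled) are
scikit-learn-backed.

Per subject: a stratified 90/10 train/test split; hyperparameters (graph
neighbors, σ, embedding dimension m) selected by stratified 10-fold CV *on
the training set only*; the embedding re-fit on the full training set; test
trials mapped by the method's out-of-sample transform; one-vs-rest
precision/recall/F1 per class and the unweighted (macro) mean. Macro
averaging is the standard choice for this imbalance (worst per-subject
ratio 0.61); a class absent from both truth and predictions is excluded
from the macro mean with a log note. Stratification is used because plain
folds can lose the smallest class (56–57 trials) entirely. An audit log
records which row indices each stage read; tests assert that held-out rows
appear only in the final scoring call.

Grid search is exhaustive over the axes n_neighbors ∈ {4…20},
σ ∈ {0.1, 1, 10, 100, 1000}, m ∈ {1, 5, 10, …}; ties prefer smaller m, then
fewer neighbors, then smaller σ (smaller models win ties). Cells whose
graph disconnects — or whose extension is singular — are recorded as failed
and excluded from the argmax.

Cross-method comparison: one-way repeated-measures ANOVA with subjects as
blocks, computed from the two-way sums-of-squares decomposition
(F = MS_method/MS_error with df = (m−1, (m−1)(s−1))), pairwise paired
t-tests, and Shapiro–Wilk normality checks on pairwise differences. The
ANOVA is cross-checked in tests against `pingouin.rm_anova`.

## Sliding-window analysis

Windows of 100 ms, stepped by 40 ms, tile the 0.74 s before and 1.82 s
after touch onset (left-aligned; trailing partial windows dropped):
17 pre-touch and 44 post-touch offsets by default. 100 ms is a hard floor —
narrower windows are rejected up front, since their neighbor graphs
disconnect. Each window is subsampled and concatenated exactly like the
full pipeline (5 ch × 100 ms × 800 Hz = 400 features at study scale). Per
offset, the pipeline is re-fit independently; a single stratified 90/10
split per subject is reused across offsets so the time course is measured
on a fixed test set. The embedding dimension (study default 120) is clamped
to N_train − 2 for small windows. Per-window macro F1 is aggregated as
mean ± SE across subjects; failed windows (disconnected or singular) are
marked, never silently skipped.

## Synthetic cohort generator

The generator emulates the cohort the analysis assumes: 12 subjects with
the published per-subject class counts (220–221 trials each; 2645 total;
worst imbalance 0.61), 5 muscles, 4 kHz, 10 s trials, a blocked trial
sequence (next trial repeats the previous weight with probability
`p_repeat`, default 0.5), and ordered jittered events (LED on ≈ 0.3–0.7 s,
touch ≈ 2.0 s, LED off 3.5–4.5 s after touch).

Per trial and muscle the signal is

    x(t) = b_m · s_m · c(t) · env(t) + noise_sd · ε(t)

with c(t) a band-limited (20–450 Hz at 4 kHz) unit-variance Gaussian
carrier, independent across trials; b_m a per-muscle base gain; s_m a
log-normal per-subject gain (sd 0.3); ε white noise (default sd 0.1). The
envelope env(t) is exactly zero before touch and is built from Hann bumps:

- a **contact burst** (50–450 ms after touch) of weight-independent
  amplitude;
- a **lift/hold bump** (200 ms after touch until LED off) scaled by the
  weight- and muscle-specific gain g_m(w) = 3 · (w/330)^p_m with exponents
  p_m = 0.5…1.3 across muscles — strictly increasing in weight for every
  muscle, so raw post-touch amplitude is ordered 165 < 330 < 660 in every
  trial;
- an optional **anticipation bump** (650–50 ms before touch) scaled by the
  *previous* trial's weight, so pre-touch decodability can arise only
  through blocked repetition.

Both post-touch bumps are amplitude-modulated by a contact-locked grip
tremor at a weight-specific frequency (10 / 8 / 6 Hz for 165 / 330 / 660 g;
inertial loading lowers tremor frequency). This modulation is the
generator's reproducible, load-dependent component and the reason the
pipeline can decode at all: full-wave rectification passes an amplitude
modulation linearly (E|x| = E|c| · env), it survives the 5 Hz high-pass,
and — because it changes the waveform's direction in feature space, not
just its scale — it survives per-channel peak normalization, which cancels
any per-channel gain. A variance-only (amplitude-only) code would be
invisible to Euclidean neighborhoods: with independent carriers, every
trial's nearest neighbors would be the lowest-energy trials regardless of
class. The modulation depth on the hold bump varies per trial
(uniform 0.2–0.7, grip steadiness fluctuating); the weakly modulated tail
makes trials of different weights resemble one another, which keeps the
k = 8 trial graph connected across classes — the synthetic counterpart of
the genuine class overlap in real recordings. The contact burst carries a
deeper fixed modulation (0.9) so the label is present from the first
post-touch window.

Deliberate simplifications, and what they mean for the tests:

- **Touch-time jitter is ±15 ms** (a tightly cue-locked paradigm). Real
  reaction times vary by 100 ms or more; the tight jitter keeps
  trial-start-aligned features phase-coherent within a class. Passing tests
  therefore demonstrate the pipeline's mechanics, not robustness to
  realistic temporal variability.
- **Pre-touch silence is exact at noise_sd = 0.** With noise on, per-trial
  peak normalization rescales the pre-touch noise floor by the inverse of
  the (weight-dependent) post-touch peak, so even pure noise before touch
  carries a trace of the label through its scale; this scale code is
  largely invisible to the k-NN pipeline, and measured pre-touch window
  scores stay inside the permutation chance band, but "no pre-touch label
  information" is strictly true only at zero noise.
- **Zero-phase filter smear**: at zero noise, the acausal tail of the 5 Hz
  high-pass back-propagates a small deterministic trace of the contact
  burst into the last pre-touch windows; the envelope's 50 ms
  electromechanical-delay guard reduces but does not remove it, and any
  realistic noise floor masks it. Pre-touch chance-level checks therefore
  run at the default noise, and the zero-noise setting is used only for the
  post-touch checks the smear cannot affect.
- No motor-unit physiology, fatigue drift, or surface-material effects.

Determinism: a `SimConfig` (including its seed) fully determines the cohort
bit-for-bit; subjects use independent child seeds.

## Problem sizes used in tests and the acceptance script

Full-rate 12-subject generation (2645 trials × 5 ch × 40,000 samples)
needs ≈ 4 GB for the raw signals alone; the package's own test and
reporting runs therefore keep the full cohort structure but reduce the
sampling rate — 250 Hz for full-trial decoding (feature length
5 × 8 × 50 = 2000, band-pass 5–100 Hz) and 1 kHz with 4 s trials for the
window analysis (window feature length 100, band-pass 5–400 Hz) — and use
m = 10 embedding dimensions, appropriate to the reduced feature count (at
desk scale, m = 120 of ~198 training points reaches into the part of the
normalized spectrum near λ = 1 where the extension is ill-conditioned).
The 4 kHz worked example (32,000 features) is retained as a single-trial
computation. The window chance band is computed by permutation (per-subject
label permutations plus the constant-predictor scores, 2.5–97.5
percentiles).

## Interchange formats

Cohorts are stored in HDF5 (`/subjects/<id>/trials/<idx>` datasets of shape
[n_channels, n_samples] with rate/label/event attributes; root attributes
carry the format version, channel names and subject order), with a
CSV-directory fallback (one file per trial, one column per channel, one
`metadata.json` sidecar) for tiny fixtures. Signals are 64-bit floats and
round-trip bit-exactly. Event times are stored in seconds; sample indices
are derived by half-up rounding at the stated rate. Parsing the source
dataset's original MATLAB files is out of scope.
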