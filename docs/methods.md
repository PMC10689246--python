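# Methods

This note documents the models the package implements, the defaults and
tunable parameters, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the procedure
was genuinely open.

## Encoding models

The temporal receptive field (TRF) is the lagged linear model
y(t) = Σ_f Σ_τ β_f(τ) x_f(t−τ) + ε, fit by ridge regression. Lags sit on
a 10-ms grid, so a window of T ms contributes T/10 + 1 lags per feature
at the 100-Hz frame rate; the design matrix is feature-major, lag-minor,
with out-of-range lags zero-padded.

Cross-validation follows an 80/10/10 scheme with five rotations: frames
(or whole sentences, when sentence ids are supplied — the default in the
pipeline, which prevents temporal leakage across partitions) are split
into ten contiguous chunks; rotation r tests on chunk 2r, validates on
chunk 2r+1 and trains on the rest, so the five test sets are mutually
exclusive. The ridge penalty is chosen per target on the validation set
from a 10-point grid log-spaced 10⁻²…10⁵ applied to column-standardized
predictors. Reported performance is the mean across the five test sets.

*R² convention.* Held-out R² is the square of the Pearson correlation
between predicted and actual activity; the signed correlations are kept
alongside (`cv_r`) so masking or sign-sensitive analyses can use them,
and `r_squared(..., kind="sse")` provides the 1 − SSE/SST variant (used,
e.g., for the training-error monotonicity property, which holds exactly
for that definition). Squared correlation is the primary definition
because it is what a correlation-evaluated, figure-reported R² pipeline
computes; the two agree for a well-calibrated linear predictor. A known
side effect is a small positive bias on null data (spurious held-out
correlations square to positive numbers), visible in the unique-variance
benchmarks at short fold lengths.

Final reported weights are refit on all frames at the modal
cross-validated penalty (ties toward the smaller penalty) and mapped back
to the original predictor scale.

The solver eigendecomposes the Gram matrix once per training set and
reuses the factorization across the whole penalty grid; for wide designs
(more columns than frames) it switches to the dual (kernel) form. A
rank-deficient design combined with λ = 0 is rejected rather than
silently pseudo-inverted.

*Delay-window search.* Candidate representations may search window
lengths over {0, 50, …, 400} ms; the window maximizing mean validation
correlation wins, with ties broken toward the shorter window
(parsimony). The baseline and spectrogram-only models use a fixed 400-ms
window. The 400-ms cap is enforced.

*Brain-prediction score.* BPS = R²_model / R²_baseline per site.
Sites whose baseline R² is ≤ 0.05 are masked (NaN) everywhere: the ratio
is numerically unstable near a zero denominator and such sites are not
speech-responsive.

*Noise ceiling.* For each sentence and repeat, the left-out repeat is
correlated with the mean of the remaining repeats; correlations average
over repeats, then sentences. With two repeats this reduces exactly to
the pairwise correlation. Constant-in-time trials have undefined
correlations and are excluded with a warning.

*Unique variance.* ΔR²(set) = mean CV R²(full) − mean CV R²(without the
set), using the identical partition and penalty-grid machinery for both
fits. ΔR² of a duplicated set is ~0 by construction (redundancy), and
small negative values at sampling noise scale are expected.

## The 208-feature baseline

- **Spectrogram (161):** magnitude STFT with a 20-ms Hann window and
  10-ms hop (100-Hz frames), interpolated onto 161 log-spaced center
  frequencies from 50 Hz to 8 kHz. The 50-Hz floor replaces the nominal
  0-Hz endpoint, which has no logarithmic representation. Magnitudes are
  linear (no compression) — an explicit choice where either convention
  was defensible; linearity keeps the amplitude-scaling contract exact.
- **Phonetic (13):** binary articulatory features per frame (3 places ×
  3 manners × voicing for consonants; 5 vowel-place features; a single
  consonant/vowel indicator bit), looked up from a packaged 39-phoneme +
  silence table. Silence frames are all-zero.
- **Pitch (31):** absolute pitch ln F₀, relative pitch (within-sentence
  z-score of ln F₀) and pitch change (first difference of ln F₀), each
  one-hot discretized into 10 bins spanning the 2.5th–97.5th percentile
  of the corpus's voiced frames with tails clipped into the end bins,
  plus one voicing bit. Unvoiced frames are all-zero. Percentiles are
  computed over the whole supplied track (corpus scope). Zero-variance
  cases (constant F₀) place all mass in the middle bin, consistent with
  a z-score of 0 sitting at the distribution center. Pitch change at the
  first frame of a voiced run is defined as 0.
- **Envelope (3):** RMS intensity in the same 20-ms windows; a sparse
  sentence-onset indicator; and peak rate — the envelope-derivative
  value at local maxima of the positive first difference, zero
  elsewhere.

## High-gamma preprocessing

Eight Gaussian band filters with center frequencies log-spaced 70–150 Hz
(log spacing is an assumption; linear would be defensible), constant-Q
with fractional bandwidth 0.1. Each band's analytic amplitude comes from
the frequency-domain analytic signal (negative frequencies zeroed,
Gaussian weighting applied); the high-gamma trace is the mean across
bands, polyphase-resampled to 100 Hz and z-scored per recording block.
The first and last 200 ms of each block are excluded from the z-score
statistics (filter warm-up) but still transformed. Constant channels
z-score to zero with a warning. Stream alignment to the neural rate uses
frame repetition for integer upsampling (the default 50→100 Hz path for
transformer embeddings), block averaging for integer downsampling, or
linear interpolation.

## Attention templates and scores

Templates are T×T binary indicators over (query frame i, key frame j):
phoneme(d) is 1 when i lies in phoneme k and j in phoneme k+d for
d ∈ {0, −1, −2}; likewise for syllables; the current-syllable template
is used in phoneme-excluded form A′_sy(0) = A_sy(0) − A_ph(0). Frames
whose context does not exist (sentence-initial segments) yield all-zero
rows rather than being dropped. Correlations are computed over all T²
entries, diagonal included; the averaging order is heads first, then
sentences. All-zero templates for a sentence (e.g., phoneme(−1) in a
one-phoneme utterance) are skipped with a logged count.

The AS–BPS permutation test shuffles whole sentences of the response,
breaking the speech–neural pairing while keeping features fixed, refits
the per-layer and baseline models, and recomputes the cross-layer
correlation; the one-sided p is (1 + #{r_perm ≥ r_obs})/(1 + n_perm).
For speed the null uses a reduced, fixed-penalty evaluator whose
per-fold solves are vectorized over all shuffles in single BLAS calls;
the observed statistic is computed by the identical reduced procedure,
so the null remains exchangeable and the test exactly calibrated (the
type-I benchmark confirms ~5% rejection at α = 0.05). The test requires
equal-length sentence blocks; the pipeline truncates sentences to the
common minimum length for this stage only. n_perm defaults to 200 in
tests and is configurable (800 is a typical production setting).

For profile-level correlations (unique-variance profile vs per-layer
BPS) no raw responses are available to shuffle, so the p-value comes
from uniform permutations of the layer pairing instead.

## Convex NMF clustering

The ERP matrix X (time × electrode) is the onset-aligned average over
sentences, baseline-corrected by the mean of the pre-onset 200 ms;
default window −200…+1000 ms around sentence onset (the pipeline demo
uses a shorter +600-ms window to fit its short synthetic sentences).
Factorization follows the convex-NMF formulation in which X may be
mixed-sign and only W and G are nonnegative; multiplicative updates run
from a k-means-based initialization (indicator matrix + 0.2 smoothing),
with 20 random restarts by default keeping the best objective, stopping
when the relative objective change falls below 10⁻⁷ or at 1000
iterations (a warning flags non-convergence). Variance explained is
1 − ‖X − FGᵀ‖²_F / ‖X‖²_F.

For k selection, each k additionally warm-starts from the best (k−1)
solution augmented by a near-zero column, which makes the variance curve
non-decreasing in k by construction. The elbow is formalized as the k
maximizing the discrete curvature of the variance curve (a
visual-inspection rule made reproducible); a maximum curvature below
0.02 triggers a "no pronounced elbow" warning, as does a k-range too
short to evaluate curvature (fallback: max-variance k). Cluster labels
are the per-electrode argmax of G, ties toward the lower index (tie
fraction logged), all-zero rows flagged as unassigned.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure each stage assumes:

- **Segmentations:** phoneme durations log-normal with 80-ms median and
  log-SD 0.4 (conversational-speech-like; duration statistics are a
  conventional choice, not corpus-derived), rounded to whole frames;
  labels uniform over the 39-phoneme inventory; syllables group 1–3
  consecutive phonemes.
- **Responses:** exactly the TRF generative model — lagged convolution
  of features with smooth random kernels plus Gaussian noise (optionally
  AR(1) to mimic high-gamma autocorrelation), z-scored per repeat block.
  Repeated-trial blocks (default 10 sentences × 10 repeats) share the
  clean response and differ only in noise.
- **Attention:** nonnegative mixtures of the six templates plus
  half-normal noise. Row renormalization (rows summing to 1, as in
  transformer attention) is available but off by default: it rescales
  rows by segment length and would break the exact-template contract
  (AS = 1 for a pure mixture) that anchors the score's calibration
  tests.
- **Layer activations:** random projections of named feature sets,
  variance-weighted by a planted mixing recipe and passed through an
  optional nonlinearity, giving layers a controllable
  spectrogram→phonetic gradient for recovery tests.

It does **not** emulate acoustic realism of audio, biophysical auditory
periphery responses, cortical nonlinearities beyond the planted mixing,
non-stationary noise, or artifacts. Passing tests therefore show that
the analysis recovers what it assumes when the assumptions hold — a
correctness statement about the machinery, not evidence about real
cortex.

## Benchmark problem sizes

The self-validation studies (`speechenc.validation`, run by
`scripts/acceptance.py` and the acceptance tests) use: TRF recovery with
208 features × 6 lags at 50,000 frames and SNR 1 (analytic R² ceiling
0.5); 50 random systems for closed-form equivalence; 200 simulated
electrodes at 500 frames for the null noise ceiling; 100 random
segmentations against brute-force template enumeration; 200 replicates ×
200 shuffles for permutation calibration; 20 seeds of planted
two-cluster ERPs at SNR 2; and 4-layer planted gradients for
unique-variance profiles. These sizes keep the full run at about a
minute on one CPU while leaving the stated tolerances comfortably
testable.

## Known limitations

- Squared-correlation R² is biased upward on null data at short fold
  lengths; SSE-based R² is available where unbiasedness matters.
- The elbow rule and its 0.02 curvature threshold formalize a visual
  judgement; heavily smeared cluster structure can still yield a
  warning rather than a decision.
- The permutation machinery requires equal-length sentence blocks; real
  corpora need truncation or padding for that stage.
- Convex-NMF multiplicative updates converge to local optima; restarts
  mitigate but do not guarantee the global solution.
- The TextGrid reader handles long-format interval tiers only.
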