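"""Synthetic study data with the statistical structure the analysis assumes.

Real inputs to the pipeline — patient high-gamma recordings, speech
alignments, network embeddings and attention tensors — are not
distributable, so this module generates surrogates whose generative
structure matches what each analysis stage assumes: responses are noisy
lagged-linear functions of feature streams (the TRF's own generative
model), attention matrices are controlled nonnegative mixtures of the six
context templates plus noise, and layer activations are (optionally
nonlinear) mixtures of named feature sets with a planted depth gradient.
Ground truth is returned alongside, enabling parameter-recovery tests.

Everything is driven by ``numpy.random.default_rng`` seeds and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datatypes import FeatureStream, GroundTruth, NeuralResponse, Segmentation
from . import attention as _attention
from . import encoding as _encoding
from .features import load_phoneme_table

DEFAULT_FRAME_RATE = 100.0


@dataclass
class DurationSpec:
    """Phoneme-duration distribution for the segmentation generator.

    ``lognormal`` draws durations with the given median (ms) and log-SD
    sigma; ``fixed`` makes every phoneme exactly ``median_ms`` long.
    The 80-ms default median and sigma 0.4 give conversational-speech-like
    durations (roughly 40-160 ms central range).
    """

    dist: str = "lognormal"
    median_ms: float = 80.0
    sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "fixed"):
            raise ValueError(f"unknown duration distribution {self.dist!r}")
        if self.median_ms <= 0:
            raise ValueError("median_ms must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def draw_ms(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "fixed":
            return np.full(n, self.median_ms)
        return self.median_ms * np.exp(self.sigma * rng.standard_normal(n))


def gen_segmentation(
    n_sentences: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
    duration_params: DurationSpec | None = None,
    seed: int = 0,
    phonemes_per_sentence: tuple[int, int] = (25, 45),
    inventory: list[str] | None = None,
) -> list[Segmentation]:
    """TIMIT-style phoneme/syllable segmentations.

    Phoneme durations are drawn from ``duration_params`` (default
    log-normal, median 80 ms) and rounded to whole frames (min 1); labels
    are drawn uniformly from the 39 speech phonemes of the packaged
    inventory; syllables group 1-3 consecutive phonemes.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    duration_params = duration_params or DurationSpec()
    if inventory is None:
        inventory = [p for p in load_phoneme_table() if p != "sil"]
    rng = np.random.default_rng(seed)
    segs = []
    for _ in range(n_sentences):
        m = int(rng.integers(phonemes_per_sentence[0], phonemes_per_sentence[1] + 1))
        dur_frames = np.maximum(
            1, np.round(duration_params.draw_ms(m, rng) * frame_rate / 1000.0).astype(int))
        ph_bounds = np.concatenate([[0], np.cumsum(dur_frames)[:-1]])
        n_frames = int(np.sum(dur_frames))
        labels = rng.choice(inventory, size=m)
        # syllables: consume 1-3 phonemes at a time
        sy_starts = []
        i = 0
        while i < m:
            sy_starts.append(ph_bounds[i])
            i += int(rng.integers(1, 4))
        segs.append(Segmentation(ph_bounds, np.array(sy_starts), labels, n_frames))
    return segs


def gen_feature_stream(
    n_frames: int,
    sets: dict[str, int] | None = None,
    seed: int = 0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    smooth_frames: float = 3.0,
) -> FeatureStream:
    """Smoothed Gaussian feature streams with named sets (unit variance).

    A generic stimulus surrogate for encoding-model simulations: each row
    is low-pass Gaussian noise (temporal smoothing mimics the ~30-ms
    autocorrelation of speech features), standardized per row. Sets are
    generated independently, so distinct sets are orthogonal in
    expectation.
    """
    sets = sets or {"spectrogram": 20, "phonetic": 13}
    rng = np.random.default_rng(seed)
    blocks, labels, names = [], [], []
    for set_name, n in sets.items():
        x = rng.standard_normal((n, n_frames))
        if smooth_frames > 0:
            x = ndimage.gaussian_filter1d(x, smooth_frames, axis=1)
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        blocks.append(x)
        labels.extend([set_name] * n)
        names.extend([f"{set_name}_{i}" for i in range(n)])
    return FeatureStream(np.vstack(blocks), frame_rate,
                         np.array(labels, dtype=object), np.array(names, dtype=object))


def gen_ground_truth(
    n_electrodes: int,
    n_features: int,
    n_lags: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    kernel_smoothness: float = 1.5,
) -> GroundTruth:
    """Random smooth TRF weights for simulated electrodes."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_electrodes, n_features, n_lags))
    if kernel_smoothness > 0 and n_lags > 1:
        w = ndimage.gaussian_filter1d(w, kernel_smoothness, axis=2)
    return GroundTruth(trf_weights=w, noise_sd=noise_sd, seed=seed)


def gen_neural_responses(
    features: FeatureStream,
    truth: GroundTruth,
    n_repeats: int = 1,
    seed: int | None = None,
    zscore: bool = True,
    ar1: float = 0.0,
) -> NeuralResponse:
    """Responses following the TRF generative model.

    Each repeat is the lagged convolution of the features with the
    ground-truth weights plus independent Gaussian noise of SD
    ``truth.noise_sd`` (optionally AR(1)-correlated with coefficient
    ``ar1``, since real high-gamma noise is autocorrelated), z-scored per
    repeat block. Repeats are concatenated along frames with block and
    repeat index vectors.
    """
    n_el, n_feat, n_lags = truth.trf_weights.shape
    if n_feat != features.n_features:
        raise ValueError(
            f"feature dimensionality mismatch: truth has {n_feat}, stream has {features.n_features}")
    window_ms = (n_lags - 1) * 1000.0 / features.frame_rate
    if window_ms > _encoding.MAX_WINDOW_MS:
        raise ValueError("ground-truth lag axis exceeds the supported 400-ms window")
    X = _encoding.build_design_matrix(features, window_ms)  # (T, F*L)
    clean = X @ truth.trf_weights.reshape(n_el, -1).T  # (T, n_el)
    T = features.n_frames
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    reps = []
    for _ in range(n_repeats):
        noise = rng.standard_normal((T, n_el)) * truth.noise_sd
        if ar1 > 0:
            for t in range(1, T):
                noise[t] += ar1 * noise[t - 1]
            noise *= np.sqrt(1 - ar1**2)
        reps.append(clean + noise)
    act = np.hstack([r.T for r in reps])  # (n_el, n_repeats*T)
    block = np.repeat(np.arange(n_repeats), T)
    if zscore:
        for b in range(n_repeats):
            m = block == b
            mu = act[:, m].mean(axis=1, keepdims=True)
            sd = act[:, m].std(axis=1, keepdims=True)
            sd = np.where(sd == 0, 1.0, sd)
            act[:, m] = (act[:, m] - mu) / sd
    return NeuralResponse(
        activity=act,
        frame_rate=features.frame_rate,
        block_ids=block,
        repeat_index=block.copy(),
        sentence_index=np.zeros(n_repeats * T, dtype=int),
    )


def gen_attention_matrices(
    seg: Segmentation,
    mixture: np.ndarray,
    noise_sd: float = 0.0,
    n_heads: int = 4,
    seed: int = 0,
    normalize_rows: bool = False,
) -> np.ndarray:
    """Per-layer, per-head attention matrices as template mixtures.

    W = sum_q mixture[layer, q] * A_q + noise, with nonnegative half-normal
    noise of scale ``noise_sd`` added independently per head. ``mixture``
    is (n_layers, 6) over the contexts in ``TEMPLATE_CONTEXTS`` order.
    With ``normalize_rows=True`` each row is renormalized to sum to 1,
    mimicking transformer attention rows being distributions (this scales
    rows unequally, so template correlations are then no longer exactly 1
    for pure mixtures). Returns (n_layers, n_heads, T, T).
    """
    mixture = np.atleast_2d(np.asarray(mixture, float))
    if np.any(mixture < 0):
        raise ValueError("mixture weights must be nonnegative")
    if mixture.shape[1] != 6:
        raise ValueError("mixture must have one weight per template (6)")
    templates = _attention.build_templates(seg)
    stack = np.stack([templates[c].matrix.astype(float)
                      for c in _attention.TEMPLATE_CONTEXTS])  # (6, T, T)
    rng = np.random.default_rng(seed)
    n_layers = mixture.shape[0]
    T = seg.n_frames
    out = np.empty((n_layers, n_heads, T, T))
    for x in range(n_layers):
        base = np.tensordot(mixture[x], stack, axes=1)
        for h in range(n_heads):
            W = base + noise_sd * np.abs(rng.standard_normal((T, T)))
            if normalize_rows:
                row_sums = W.sum(axis=1, keepdims=True)
                W = np.divide(W, row_sums, out=np.zeros_like(W), where=row_sums > 0)
            out[x, h] = W
    return out


@dataclass
class LayerSpec:
    """Recipe for one synthetic network layer.

    ``mixing`` gives nonnegative variance weights over feature-set names;
    units project each set through random unit vectors, combine them with
    these weights, and pass through ``nonlinearity``
    (identity/relu/tanh).
    """

    mixing: dict[str, float]
    n_units: int = 32
    nonlinearity: str = "identity"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.nonlinearity not in ("identity", "relu", "tanh"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if any(v < 0 for v in self.mixing.values()):
            raise ValueError("mixing weights must be nonnegative")


_NONLIN = {"identity": lambda z: z, "relu": lambda z: np.maximum(z, 0), "tanh": np.tanh}


def gen_layer_activations(
    features: FeatureStream,
    layer_spec: list[LayerSpec],
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Unit x time activations for each synthetic layer.

    Each unit u of a layer computes g(sum_set w_set * v_u,set . x_set(t))
    where v_u,set is a random projection normalized so each set contributes
    unit variance before weighting; the planted mixing weights therefore
    control the variance share (and hence the unique variance) of each
    feature set, which downstream recovery tests exploit.
    """
    rng = np.random.default_rng(seed)
    available = set(features.sets)
    out: dict[str, np.ndarray] = {}
    for li, spec in enumerate(layer_spec):
        unknown = set(spec.mixing) - available
        if unknown:
            raise KeyError(f"unknown feature set(s) in layer {li}: {sorted(unknown)}")
        acts = np.zeros((spec.n_units, features.n_frames))
        for set_name, w in spec.mixing.items():
            if w == 0:
                continue
            block = features.subset([set_name]).values
            V = rng.standard_normal((spec.n_units, block.shape[0]))
            proj = V @ block
            sd = proj.std(axis=1, keepdims=True)
            proj = proj / np.where(sd == 0, 1.0, sd)
            acts += np.sqrt(w) * proj
        acts = _NONLIN[spec.nonlinearity](acts)
        if spec.noise_sd > 0:
            acts = acts + spec.noise_sd * rng.standard_normal(acts.shape)
        out[f"layer{li}"] = acts
    return out


def gen_repeated_trial_block(
    n_sentences: int = 10,
    n_repeats: int = 10,
    n_electrodes: int = 4,
    T: int = 300,
    noise_sd: float = 1.0,
    n_features: int = 12,
    n_lags: int = 11,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Repeated-presentation block for noise-ceiling analysis.

    Emulates the repeat task (10 sentences x 10 repeats by default): each
    sentence has a fixed clean response drawn from the TRF generative
    model, and each repeat adds fresh Gaussian noise. Returns an array of
    shape (n_electrodes, n_sentences, n_repeats, T) plus the ground truth.
    """
    rng = np.random.default_rng(seed)
    truth = gen_ground_truth(n_electrodes, n_features, n_lags,
                             noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1)))
    out = np.empty((n_electrodes, n_sentences, n_repeats, T))
    for i in range(n_sentences):
        feats = gen_feature_stream(T, {"spectrogram": n_features},
                                   seed=int(rng.integers(2**31 - 1)))
        X = _encoding.build_design_matrix(feats, (n_lags - 1) * 1000.0 / feats.frame_rate)
        clean = (X @ truth.trf_weights.reshape(n_electrodes, -1).T).T  # (E, T)
        for j in range(n_repeats):
            out[:, i, j, :] = clean + noise_sd * rng.standard_normal((n_electrodes, T))
    return out, truth
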