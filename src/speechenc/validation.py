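"""Self-validation benchmarks: simulation studies with known ground truth.

Each function generates data from the synthetic module under stated study
conditions, runs the corresponding analysis stage, and returns the
recovery/calibration metrics. They are used by the acceptance test suite
and by ``scripts/acceptance.py``; problem sizes are chosen so the full set
runs on one desktop CPU in a few minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import attention, clustering, encoding, features, synthetic
from .datatypes import FeatureStream, Segmentation, TEMPLATE_CONTEXTS


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# TRF recovery

def trf_recovery(seed: int = 0, n_frames: int = 50_000, n_features: int = 208,
                 window_ms: float = 50.0) -> dict:
    """Fit a TRF to synthetic responses at SNR 1 with known weights.

    Returns the correlation between recovered and true weights, the mean
    held-out R^2, and the analytic ceiling SNR^2/(1+SNR^2) = 0.5 implied by
    equal signal and noise variance.
    """
    s1, s2, s3 = _child_seeds(seed, 3)
    sizes = {"spectrogram": 161, "phonetic": 13, "pitch": 31, "envelope": 3}
    if n_features != 208:
        sizes = {"spectrogram": n_features}
    feats = synthetic.gen_feature_stream(n_frames, sizes, seed=s1)
    n_lags = encoding.n_lags_for_window(window_ms)
    truth = synthetic.gen_ground_truth(1, n_features, n_lags, noise_sd=0.0, seed=s2)
    X = encoding.build_design_matrix(feats, window_ms)
    clean = X @ truth.trf_weights.reshape(1, -1).T
    truth.noise_sd = float(clean.std())  # SNR 1
    resp = synthetic.gen_neural_responses(feats, truth, seed=s3)
    model = encoding.fit_trf(X, resp.activity[0], encoding.cv_partitions(n_frames),
                             n_features=n_features, window_ms=window_ms)
    weight_corr = float(np.corrcoef(model.weights.ravel(),
                                    truth.trf_weights.ravel())[0, 1])
    return {"weight_corr": weight_corr, "mean_r2": model.mean_r2,
            "analytic_ceiling_r2": 0.5, "n_frames": n_frames}


def ridge_oracle(seed: int = 0, n_systems: int = 50) -> dict:
    """Closed-form equivalence of the CV fitter at a fixed penalty."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_systems):
        n, p = int(rng.integers(20, 80)), int(rng.integers(3, 12))
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        lam = 10 ** rng.uniform(-2, 2)
        all_true = np.ones(n, dtype=bool)
        none = np.zeros(n, dtype=bool)
        m = encoding.fit_trf(X, y, [(all_true, none, none)], [lam],
                             standardize=False, fit_intercept=False)
        oracle = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
        worst = max(worst, float(np.max(np.abs(m.weights.ravel() - oracle))))
    return {"max_abs_diff": worst, "n_systems": n_systems}


# ---------------------------------------------------------------------------
# BPS

def bps_contract(seed: int = 0) -> dict:
    """Baseline-vs-itself identity and responsiveness masking, from a real fit."""
    feats = synthetic.gen_feature_stream(2000, {"spectrogram": 6}, seed=seed)
    truth = synthetic.gen_ground_truth(1, 6, 6, noise_sd=1.0, seed=seed + 1)
    resp = synthetic.gen_neural_responses(feats, truth, seed=seed + 2)
    m = encoding.fit_encoding(feats, resp.activity[0], 50.0)
    self_bps = encoding.brain_prediction_score(m.mean_r2, m.mean_r2)
    r2b = np.array([0.2, 0.05, 0.01, m.mean_r2])
    bps = encoding.brain_prediction_score(np.full(4, 0.1), r2b)
    return {"self_bps": float(self_bps),
            "n_masked": int(np.sum(np.isnan(bps))),
            "n_below_threshold": int(np.sum(r2b <= encoding.RESPONSIVE_THRESHOLD))}


# ---------------------------------------------------------------------------
# noise ceiling

def noise_ceiling_behavior(seed: int = 0, n_electrodes: int = 200, T: int = 500) -> dict:
    """Reliability under perfect, null and two-repeat conditions."""
    rng = np.random.default_rng(seed)
    trial = rng.standard_normal(T)
    # identical repeats across 2 sentences x 5 repeats
    identical = encoding.noise_ceiling(np.broadcast_to(trial, (2, 5, T)).copy())
    null_rs = []
    for _ in range(n_electrodes):
        reps = rng.standard_normal((2, 5, T))
        null_rs.append(encoding.noise_ceiling(reps).r[0])
    s1, s2 = rng.standard_normal((2, T))
    two = encoding.noise_ceiling(np.stack([s1, s2])[None])
    exact = np.corrcoef(s1, s2)[0, 1]
    return {"identical_r": float(identical.r[0]),
            "null_mean_abs_r": float(abs(np.mean(null_rs))),
            "two_repeat_diff": float(abs(two.r[0] - exact)),
            "n_electrodes": n_electrodes}


# ---------------------------------------------------------------------------
# templates

def _brute_force_templates(seg: Segmentation) -> dict[str, np.ndarray]:
    """Literal per-entry evaluation of the six indicator definitions."""
    T = seg.n_frames

    def seg_of(bounds, i):
        k = None
        for idx, b in enumerate(bounds):
            if b <= i:
                k = idx
        return k

    def build(bounds, offset):
        A = np.zeros((T, T), dtype=int)
        for i in range(T):
            for j in range(T):
                ki, kj = seg_of(bounds, i), seg_of(bounds, j)
                if ki is not None and kj is not None and kj == ki + offset:
                    A[i, j] = 1
        return A

    ph0 = build(seg.phoneme_bounds, 0)
    sy0 = build(seg.syllable_bounds, 0)
    return {
        "phoneme(0)": ph0,
        "phoneme(-1)": build(seg.phoneme_bounds, -1),
        "phoneme(-2)": build(seg.phoneme_bounds, -2),
        "syllable(0)'": sy0 - ph0,
        "syllable(-1)": build(seg.syllable_bounds, -1),
        "syllable(-2)": build(seg.syllable_bounds, -2),
    }


def template_oracle(seed: int = 0, n_segmentations: int = 100) -> dict:
    """Exact agreement with brute-force template enumeration + disjointness."""
    segs = synthetic.gen_segmentation(
        n_segmentations, seed=seed, phonemes_per_sentence=(3, 8),
        duration_params=synthetic.DurationSpec(median_ms=40, sigma=0.3))
    mismatches = 0
    disjoint_violations = 0
    for seg in segs:
        fast = attention.build_templates(seg)
        slow = _brute_force_templates(seg)
        for c in TEMPLATE_CONTEXTS:
            if not np.array_equal(fast[c].matrix, slow[c]):
                mismatches += 1
        p0, p1, p2 = (fast[c].matrix for c in
                      ("phoneme(0)", "phoneme(-1)", "phoneme(-2)"))
        if np.any(p0 & p1) or np.any(p0 & p2) or np.any(p1 & p2):
            disjoint_violations += 1
    return {"mismatches": mismatches, "disjoint_violations": disjoint_violations,
            "n_segmentations": n_segmentations}


# ---------------------------------------------------------------------------
# attention score contract

def as_contract(seed: int = 0) -> dict:
    """AS on exact templates, row-normalized noise, and a mixture sweep."""
    seeds = _child_seeds(seed, 4)
    seg = synthetic.gen_segmentation(1, seed=seeds[0],
                                     phonemes_per_sentence=(8, 12))[0]
    tmpl = attention.build_templates(seg)
    A = tmpl["phoneme(0)"].matrix.astype(float)
    exact = attention.attention_score([A[None, None]], [tmpl], "phoneme(0)")[0].as_value

    rng = np.random.default_rng(seeds[1])
    noise_scores = []
    for _ in range(40):
        W = rng.random((1, 1, seg.n_frames, seg.n_frames))
        W /= W.sum(axis=-1, keepdims=True)
        noise_scores.append(
            attention.attention_score([W], [tmpl], "phoneme(0)")[0].as_value)
    noise_abs = float(abs(np.mean(noise_scores)))

    sweep = []
    for w in (0.0, 0.25, 0.5, 0.75, 1.0):
        mix = np.zeros((1, 6))
        mix[0, 0] = w
        vals = [attention.attention_score(
                    [synthetic.gen_attention_matrices(seg, mix, noise_sd=0.5,
                                                      n_heads=2, seed=s)],
                    [tmpl], "phoneme(0)")[0].as_value
                for s in _child_seeds(seeds[2], 10)]
        sweep.append(float(np.mean(vals)))
    return {"exact_as": float(exact), "noise_abs_as": noise_abs,
            "sweep": sweep, "monotone": bool(np.all(np.diff(sweep) > 0))}


# ---------------------------------------------------------------------------
# permutation calibration

def permutation_calibration(seed: int = 0, n_replicates: int = 200,
                            n_perm: int = 200, alpha: float = 0.05) -> dict:
    """Type-I error of the AS-BPS permutation test under a null simulation.

    Responses are white noise independent of every feature stream, so any
    AS-BPS correlation is spurious; the rejection rate at ``alpha`` should
    match ``alpha``.
    """
    n_sent, T, n_layers = 6, 60, 5
    ps = []
    for rep_seed in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        base = [synthetic.gen_feature_stream(
                    T, {"spectrogram": 6}, seed=int(rng.integers(2**31 - 1)))
                for _ in range(n_sent)]
        layers = {
            f"l{l}": [synthetic.gen_feature_stream(
                          T, {"embedding": 4}, seed=int(rng.integers(2**31 - 1)))
                      for _ in range(n_sent)]
            for l in range(n_layers)
        }
        y = rng.standard_normal(n_sent * T)
        sid = np.repeat(np.arange(n_sent), T)
        as_vec = rng.random(n_layers)
        _, p, _ = attention.permutation_null(layers, base, y, sid, as_vec,
                                             n_perm=n_perm,
                                             seed=int(rng.integers(2**31 - 1)))
        ps.append(p)
    ps = np.array(ps)
    return {"type1_error": float(np.mean(ps <= alpha)),
            "n_replicates": n_replicates, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# convex NMF

def cnmf_recovery(seed: int = 0, n_seeds: int = 20, snr: float = 2.0) -> dict:
    """Planted two-cluster ERP recovery and variance-curve monotonicity."""
    t = np.arange(100)
    transient = np.exp(-0.5 * ((t - 25) / 5.0) ** 2)
    sustained = 1.0 / (1 + np.exp(-(t - 30) / 5.0))
    labels = np.array([0] * 12 + [1] * 12)
    k_correct = 0
    accs = []
    monotone_ok = 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        X = np.empty((100, 24))
        for i, l in enumerate(labels):
            proto = transient if l == 0 else sustained
            X[:, i] = snr * proto + rng.standard_normal(100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k, curve, fits = clustering.choose_k(X, range(1, 7), seed=s, n_restarts=4)
        if k == 2:
            k_correct += 1
        got = fits[2].labels
        accs.append(max(np.mean(got == labels), np.mean(got == 1 - labels)))
        if np.all(np.diff(curve) >= -1e-9):
            monotone_ok += 1
    return {"k2_fraction": k_correct / n_seeds,
            "mean_accuracy": float(np.mean(accs)),
            "min_accuracy": float(np.min(accs)),
            "variance_monotone_fraction": monotone_ok / n_seeds,
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# unique variance

def unique_variance_partition(seed: int = 0) -> dict:
    """Planted single-set dependence, duplicated sets, and a depth gradient."""
    s1, s2, s3, s4 = _child_seeds(seed, 4)
    # single-set dependence: the unused set must have ~zero unique variance
    feats = synthetic.gen_feature_stream(4000, {"a": 5, "b": 5}, seed=s1)
    rng = np.random.default_rng(s2)
    y = feats.subset(["a"]).values.T @ rng.standard_normal(5) \
        + 0.5 * rng.standard_normal(4000)
    _, d = encoding.unique_variance(y, feats, window_ms=0.0)
    offset_delta = abs(d["b"])

    base = synthetic.gen_feature_stream(3000, {"a": 4}, seed=s3)
    dup = FeatureStream(np.vstack([base.values, base.values]), 100.0,
                        ["a"] * 4 + ["a_copy"] * 4,
                        [f"x{i}" for i in range(8)])
    y2 = base.values.T @ rng.standard_normal(4) + 0.3 * rng.standard_normal(3000)
    _, d2 = encoding.unique_variance(y2, dup, window_ms=0.0)
    dup_delta = max(abs(d2["a"]), abs(d2["a_copy"]))

    feats_g = synthetic.gen_feature_stream(2500, {"spectrogram": 6, "phonetic": 6},
                                           seed=s4)
    grads = np.linspace(0.1, 0.9, 4)
    specs = [synthetic.LayerSpec(
                 mixing={"spectrogram": float(1 - g), "phonetic": float(g)},
                 n_units=4, noise_sd=0.3) for g in grads]
    acts = synthetic.gen_layer_activations(feats_g, specs, seed=s4 // 2 + 1)
    from .variance import profile_layers
    profiles = profile_layers(acts, feats_g, window_ms=0.0, seed=0)
    ph = [p.delta_r2["phonetic"] for p in profiles]
    sp = [p.delta_r2["spectrogram"] for p in profiles]
    return {"offset_delta_abs": float(offset_delta),
            "dup_delta_abs": float(dup_delta),
            "phonetic_gradient_spearman": float(stats.spearmanr(grads, ph).statistic),
            "spectrogram_gradient_spearman": float(stats.spearmanr(grads, sp).statistic)}


# ---------------------------------------------------------------------------
# feature contracts

def feature_contracts(seed: int = 0) -> dict:
    """Baseline assembly shape, pitch one-hot contract, spectrogram peak."""
    rng = np.random.default_rng(seed)
    seg = synthetic.gen_segmentation(1, seed=seed, phonemes_per_sentence=(20, 25))[0]
    fs = 16000.0
    wave = rng.standard_normal(int(seg.n_frames / 100.0 * fs))
    spec = features.compute_spectrogram(wave, fs, n_frames=seg.n_frames)
    phon = features.phonetic_features(seg)
    f0 = np.where(rng.random(seg.n_frames) < 0.6,
                  rng.uniform(80, 250, seg.n_frames), 0.0)
    pitch = features.pitch_features(f0)
    env = features.envelope_features(wave, fs, [0], n_frames=seg.n_frames)
    base = features.assemble_baseline(spec, phon, pitch, env)
    voiced = f0 > 0
    col_sums = pitch.values.sum(axis=0)
    onehot_ok = bool(np.all(col_sums[voiced] == 4.0)
                     and np.all(col_sums[~voiced] == 0.0))

    t = np.arange(int(fs)) / fs
    tone = np.sin(2 * np.pi * 1000.0 * t)
    sp = features.compute_spectrogram(tone, fs)
    centers = features.spectrogram_center_frequencies()
    peak = int(np.argmax(sp.values[:, 10:-10].mean(axis=1)))
    target = int(np.argmin(np.abs(centers - 1000.0)))
    return {"n_rows": base.n_features,
            "partition": {s: int(np.sum(base.set_labels == s)) for s in base.sets},
            "pitch_onehot_ok": onehot_ok,
            "tone_peak_bin_offset": abs(peak - target)}
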