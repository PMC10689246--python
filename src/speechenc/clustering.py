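"""Functional clustering of speech-responsive electrodes via convex NMF.

Trial-averaged, onset-aligned ERPs form a time x electrode matrix X that is
factorized as X ~ F G^T with F = X W, where W and G are nonnegative but X
may be mixed-sign (z-scored high-gamma is). Each basis time course in F is
thus a nonnegative combination of observed electrode ERPs, which keeps the
factors interpretable as response prototypes (e.g. onset-transient versus
sustained). Electrodes are assigned to the cluster with the largest G
weight, and the cluster count k is chosen at the elbow of the
variance-explained curve.

The multiplicative-update algorithm follows the convex-NMF formulation of
Ding, Li & Jordan (2010), initialized from a k-means partition of the
electrode ERPs.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import KMeans

from .datatypes import ERPDecomposition, NeuralResponse

_EPS = 1e-12
ELBOW_MIN_DROP = 0.02  # minimum curvature for a pronounced elbow


def average_erp(
    resp: NeuralResponse,
    onsets: np.ndarray,
    window: tuple[float, float] = (-200.0, 1000.0),
    baseline_ms: float = 200.0,
) -> np.ndarray:
    """Onset-aligned, baseline-corrected average ERP matrix (time x electrode).

    Segments of ``window`` (ms, relative to each sentence onset) are
    averaged across sentences per electrode, then the mean over the
    pre-onset ``baseline_ms`` is subtracted so the resting-state baseline
    sits at zero.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < 2:
        raise ValueError("need at least 2 sentences to average")
    fr = resp.frame_rate
    lo = int(round(window[0] * fr / 1000.0))
    hi = int(round(window[1] * fr / 1000.0))
    if np.any(onsets + lo < 0) or np.any(onsets + hi > resp.n_frames):
        raise ValueError("ERP window extends beyond recording bounds")
    segs = np.stack([resp.activity[:, o + lo: o + hi] for o in onsets])  # (S, E, T)
    erp = segs.mean(axis=0).T  # (T, E)
    n_base = int(round(baseline_ms * fr / 1000.0))
    erp -= erp[:n_base].mean(axis=0, keepdims=True)
    return erp


def _cnmf_updates(X: np.ndarray, W: np.ndarray, G: np.ndarray, max_iter: int, tol: float):
    """Multiplicative updates for min ||X - X W G^T||_F^2 with W, G >= 0."""
    A = X.T @ X
    Ap = np.clip(A, 0, None)
    An = np.clip(-A, 0, None)
    normX2 = np.sum(X**2)
    obj_path = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        GtG = None
        # G update
        AW_p, AW_n = Ap @ W, An @ W
        WtAW_p, WtAW_n = W.T @ AW_p, W.T @ AW_n
        G = G * np.sqrt((AW_p + G @ WtAW_n + _EPS) / (AW_n + G @ WtAW_p + _EPS))
        # W update
        AG_p, AG_n = Ap @ G, An @ G
        GtG = G.T @ G
        W = W * np.sqrt((AG_p + An @ (W @ GtG) + _EPS) / (AG_n + Ap @ (W @ GtG) + _EPS))
        obj = normX2 - 2 * np.trace((W.T @ A) @ G) + np.trace(GtG @ (W.T @ A @ W))
        obj_path.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = obj
    return W, G, np.array(obj_path), converged


def convex_nmf(
    X: np.ndarray,
    k: int,
    max_iter: int = 1000,
    tol: float = 1e-7,
    seed: int = 0,
    n_restarts: int = 20,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> ERPDecomposition:
    """Convex NMF of a time x electrode ERP matrix.

    Runs ``n_restarts`` k-means-seeded multiplicative-update optimizations
    (plus an optional externally supplied (W, G) warm start) and keeps the
    best objective. Reports variance_explained = 1 - ||X - FG^T||_F^2 /
    ||X||_F^2 and max-G cluster labels.
    """
    X = np.asarray(X, float)
    p = X.shape[1]
    if not (1 <= k <= p):
        raise ValueError("k must lie in [1, n_electrodes]")
    rng = np.random.default_rng(seed)
    normX2 = np.sum(X**2)

    best = None
    inits = []
    for r in range(n_restarts):
        km = KMeans(n_clusters=k, n_init=2, random_state=int(rng.integers(2**31 - 1)))
        labels0 = km.fit_predict(X.T)
        H = np.zeros((p, k))
        H[np.arange(p), labels0] = 1.0
        counts = H.sum(axis=0)
        G0 = H + 0.2
        W0 = (H / np.maximum(counts, 1)) + 0.2 / p
        inits.append((W0, G0))
    if init is not None:
        inits.append((np.maximum(init[0], _EPS), np.maximum(init[1], _EPS)))

    for W0, G0 in inits:
        W, G, path, conv = _cnmf_updates(X, W0.copy(), G0.copy(), max_iter, tol)
        obj = path[-1] if len(path) else np.inf
        if best is None or obj < best[0]:
            best = (obj, W, G, path, conv)

    obj, W, G, path, conv = best
    if not conv:
        warnings.warn(f"convex NMF did not converge within {max_iter} iterations")
    F = X @ W
    resid = X - F @ G.T
    ve = 1.0 - np.sum(resid**2) / normX2
    labels, tie_frac = assign_clusters(G, return_tie_fraction=True)
    return ERPDecomposition(
        X=X, F=F, G=G, W=W, k=k,
        variance_explained=float(ve),
        labels=labels,
        objective_path=path,
        converged=conv,
        tie_fraction=tie_frac,
    )


def choose_k(
    X: np.ndarray,
    k_range=range(1, 11),
    seed: int = 0,
    n_restarts: int = 10,
    **nmf_kwargs,
) -> tuple[int, np.ndarray, dict[int, ERPDecomposition]]:
    """Elbow-based selection of the cluster count.

    Fits convex NMF for each k (warm-starting each k from the previous
    solution augmented with a fresh column, which makes the variance curve
    non-decreasing) and returns the k maximizing the discrete curvature
    (second difference) of the variance-explained curve. With fewer than 3
    candidate k values the max-variance k is returned with a warning, and
    an elbow shallower than ELBOW_MIN_DROP triggers a no-pronounced-elbow
    warning.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    fits: dict[int, ERPDecomposition] = {}
    prev = None
    for k in ks:
        init = None
        if prev is not None and prev.W.shape[1] == k - 1:
            W_aug = np.hstack([prev.W, np.full((prev.W.shape[0], 1), _EPS)])
            G_aug = np.hstack([prev.G, np.full((prev.G.shape[0], 1), _EPS)])
            init = (W_aug, G_aug)
        fits[k] = convex_nmf(X, k, seed=seed, n_restarts=n_restarts, init=init, **nmf_kwargs)
        prev = fits[k]
    curve = np.array([fits[k].variance_explained for k in ks])

    if len(ks) < 3:
        warnings.warn("fewer than 3 k values: falling back to max-variance k")
        return ks[int(np.argmax(curve))], curve, fits
    # curvature: gain up to k minus gain after k; the elbow bends hardest
    # where the curve stops rising
    curvature = curve[1:-1] - (curve[:-2] + curve[2:]) / 2.0
    best_i = int(np.argmax(curvature))
    if curvature[best_i] < ELBOW_MIN_DROP:
        warnings.warn("no pronounced elbow in the variance curve")
    return ks[best_i + 1], curve, fits


def assign_clusters(G: np.ndarray, return_tie_fraction: bool = False):
    """Max-weight cluster assignment from the G matrix.

    Ties break toward the lower cluster index; all-zero rows get label -1
    and are flagged. Returns labels (and the tie fraction when requested).
    """
    G = np.asarray(G, float)
    if np.any(G < -_EPS):
        raise ValueError("G must be nonnegative")
    labels = np.argmax(G, axis=1)
    zero_rows = ~G.any(axis=1)
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} electrode(s) with all-zero weights left unassigned")
        labels = labels.copy()
        labels[zero_rows] = -1
    n_max = (G == G.max(axis=1, keepdims=True)).sum(axis=1)
    tie_frac = float(np.mean((n_max > 1) & ~zero_rows))
    if return_tie_fraction:
        return labels, tie_frac
    return labels
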