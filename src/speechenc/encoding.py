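"""Time-delayed ridge encoding models (TRFs) and their evaluation.

The linear model is y(t) = sum_f sum_tau beta_f(tau) x_f(t - tau) + eps,
fit per electrode/unit with L2 regularization and a 5-rotation 80/10/10
cross-validation: each rotation trains on 80% of frames, picks the ridge
penalty on a 10% validation set and reports performance on a held-out 10%
test set; the model score is the mean across the five test sets. Held-out
R^2 is the square of the Pearson correlation between predicted and actual
activity (the signed correlations are retained alongside).

Also provides the normalized brain-prediction score (BPS = R^2_model /
R^2_baseline on speech-responsive electrodes), the delay-window search, the
leave-one-repeat-out noise ceiling, and unique-variance partitioning over
named feature sets.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter

import numpy as np

from .datatypes import EncodingResult, FeatureStream, NoiseCeiling, TRFModel

logger = logging.getLogger(__name__)

MAX_WINDOW_MS = 400.0
RESPONSIVE_THRESHOLD = 0.05
DEFAULT_LAMBDA_GRID = np.geomspace(1e-2, 1e5, 10)
DEFAULT_WINDOW_GRID = tuple(range(0, 401, 50))


# ---------------------------------------------------------------------------
# design matrix

def n_lags_for_window(window_ms: float, frame_rate: float = 100.0) -> int:
    """Number of 10-ms-grid lags tau = 0, 10, ..., window_ms."""
    return int(round(window_ms * frame_rate / 1000.0)) + 1


def build_design_matrix(features: FeatureStream, window_ms: float) -> np.ndarray:
    """Lagged predictor matrix with columns x_f(t - tau).

    Column order is feature-major, lag-minor: column f * L + l holds feature
    f delayed by l frames (tau = 10*l ms at 100 Hz). Out-of-range lags are
    zero-padded. Shape (n_frames, n_features * L).
    """
    if not (0 <= window_ms <= MAX_WINDOW_MS):
        raise ValueError(f"window_ms must lie in [0, {MAX_WINDOW_MS:.0f}]")
    X = features.values  # (F, T)
    F, T = X.shape
    L = n_lags_for_window(window_ms, features.frame_rate)
    out = np.zeros((T, F * L))
    for l in range(L):
        if l == 0:
            out[:, 0::L] = X.T
        else:
            out[l:, l::L] = X[:, :-l].T
    return out


# ---------------------------------------------------------------------------
# CV partitions

def cv_partitions(
    n_frames: int,
    n_rotations: int = 5,
    group_ids: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Five 80/10/10 train/validation/test rotations over contiguous blocks.

    Frames (or whole groups, e.g. sentences, when ``group_ids`` is given)
    are split into 10 contiguous chunks; rotation r tests on chunk 2r,
    validates on chunk 2r+1 and trains on the rest, so test sets are
    mutually exclusive across rotations. Returns boolean masks.
    """
    if group_ids is not None:
        group_ids = np.asarray(group_ids)
        uniq = list(dict.fromkeys(group_ids.tolist()))
        chunk_of_group = {g: (10 * i) // len(uniq) for i, g in enumerate(uniq)}
        chunk = np.array([chunk_of_group[g] for g in group_ids])
    else:
        chunk = (10 * np.arange(n_frames)) // n_frames
    parts = []
    for r in range(n_rotations):
        test = chunk == 2 * r
        val = chunk == 2 * r + 1
        train = ~(test | val)
        parts.append((train, val, test))
    return parts


# ---------------------------------------------------------------------------
# ridge core

def _ridge_factor(Xc: np.ndarray):
    """Eigendecomposition reused across the lambda grid.

    Works in the smaller of predictor/sample space so wide designs stay
    tractable.
    """
    n, p = Xc.shape
    if p <= n:
        s, V = np.linalg.eigh(Xc.T @ Xc)
        return ("primal", s, V)
    s, U = np.linalg.eigh(Xc @ Xc.T)
    return ("dual", s, U)


def _ridge_solve(factor, Xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    mode, s, Q = factor
    if mode == "primal":
        z = Q.T @ (Xc.T @ yc)
        return Q @ (z / (s + lam))
    z = Q.T @ yc
    alpha = Q @ (z / (s + lam))
    return Xc.T @ alpha


def r_squared(y: np.ndarray, yhat: np.ndarray, kind: str = "corr") -> float:
    """Model fit: squared Pearson correlation (default) or 1 - SSE/SST."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if kind == "sse":
        sst = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum((y - yhat) ** 2) / sst
    sy, syh = np.std(y), np.std(yhat)
    if sy == 0 or syh == 0:
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r**2)


def _pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(yhat) == 0:
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1])


def fit_trf(
    X: np.ndarray,
    y: np.ndarray,
    partitions: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    lambda_grid: np.ndarray | None = None,
    *,
    n_features: int | None = None,
    window_ms: float = MAX_WINDOW_MS,
    frame_rate: float = 100.0,
    standardize: bool = True,
    fit_intercept: bool = True,
) -> TRFModel:
    """Fit a time-delayed ridge model with 80/10/10 cross-validation.

    For each rotation the ridge solution is computed on the training frames
    for every penalty in ``lambda_grid``; the penalty maximizing validation
    correlation is kept and held-out R^2 is reported on the test frames.
    The returned weights are refit on all frames at the modally chosen
    penalty, mapped back to the original predictor scale.

    With ``standardize=False`` and ``fit_intercept=False`` and a single
    trivial partition, the solution equals the closed-form normal-equations
    estimator (X'X + lam I)^-1 X'y.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y have different numbers of frames")
    lambda_grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.atleast_1d(lambda_grid)
    if np.any(lambda_grid < 0):
        raise ValueError("ridge penalties must be nonnegative")

    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("excluding %d non-finite frames from TRF fit", n_bad)
        X, y = X[ok], y[ok]

    if partitions is None:
        partitions = cv_partitions(X.shape[0])
    else:
        partitions = [(tr[ok], va[ok], te[ok]) if n_bad else (tr, va, te)
                      for tr, va, te in partitions]

    def _prep(Xtr, ytr):
        if fit_intercept:
            mu, ym = Xtr.mean(axis=0), ytr.mean()
        else:
            mu, ym = np.zeros(Xtr.shape[1]), 0.0
        sd = Xtr.std(axis=0) if standardize else np.ones(Xtr.shape[1])
        sd = np.where(sd == 0, 1.0, sd)
        return mu, sd, ym

    cv_r, cv_r2, chosen, val_r = [], [], [], []
    for train, val, test in partitions:
        Xtr, ytr = X[train], y[train]
        if Xtr.shape[0] == 0:
            raise ValueError("empty training set in partition")
        mu, sd, ym = _prep(Xtr, ytr)
        Xc = (Xtr - mu) / sd
        factor = _ridge_factor(Xc)
        if np.any(lambda_grid == 0):
            mode, s, _ = factor
            if s.min() < 1e-10 * max(s.max(), 1.0):
                raise np.linalg.LinAlgError(
                    "rank-deficient design with lambda=0; use a positive penalty")
        best_lam, best_val = None, -np.inf
        betas = {}
        for lam in lambda_grid:
            beta = _ridge_solve(factor, Xc, ytr - ym, lam)
            betas[lam] = beta
            if val.sum() == 0:
                score = np.inf  # trivial partition: no model selection
            else:
                pred_val = ((X[val] - mu) / sd) @ beta + ym
                score = _pearson(y[val], pred_val)
            if score > best_val:
                best_val, best_lam = score, lam
        pred_test = ((X[test] - mu) / sd) @ betas[best_lam] + ym if test.sum() else np.array([])
        r = _pearson(y[test], pred_test) if test.sum() else np.nan
        cv_r.append(r)
        cv_r2.append(r**2 if np.isfinite(r) else np.nan)
        chosen.append(best_lam)
        val_r.append(best_val if np.isfinite(best_val) else np.nan)

    # final weights: refit on all frames at the modal penalty (ties -> smaller)
    counts = Counter(chosen)
    top = max(counts.values())
    final_lam = min(l for l, c in counts.items() if c == top)
    mu, sd, ym = _prep(X, y)
    Xc = (X - mu) / sd
    beta_std = _ridge_solve(_ridge_factor(Xc), Xc, y - ym, final_lam)
    beta = beta_std / sd
    intercept = ym - beta @ mu

    if n_features is None:
        weights = beta[None, :]
    else:
        weights = beta.reshape(n_features, -1)
    cv_r2 = np.array(cv_r2, float)
    mean_r2 = float(np.nanmean(cv_r2)) if np.any(np.isfinite(cv_r2)) else float("nan")
    return TRFModel(
        weights=weights,
        lam=float(final_lam),
        window_ms=window_ms,
        frame_rate=frame_rate,
        cv_r2=cv_r2,
        mean_r2=mean_r2,
        cv_r=np.array(cv_r, float),
        intercept=float(intercept),
        lam_per_fold=np.array(chosen, float),
        cv_val_r=np.array(val_r, float),
    )


def fit_encoding(
    features: FeatureStream,
    y: np.ndarray,
    window_ms: float = MAX_WINDOW_MS,
    lambda_grid: np.ndarray | None = None,
    group_ids: np.ndarray | None = None,
    **kwargs,
) -> TRFModel:
    """Convenience wrapper: lag the features, partition, and fit."""
    X = build_design_matrix(features, window_ms)
    parts = cv_partitions(X.shape[0], group_ids=group_ids)
    return fit_trf(
        X, y, parts, lambda_grid,
        n_features=features.n_features,
        window_ms=window_ms,
        frame_rate=features.frame_rate,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# scores

def brain_prediction_score(
    r2_model: np.ndarray | float,
    r2_baseline: np.ndarray | float,
    threshold: float = RESPONSIVE_THRESHOLD,
) -> np.ndarray | float:
    """Normalized brain-prediction score R^2_model / R^2_baseline.

    Electrodes whose baseline R^2 does not exceed the speech-responsiveness
    threshold (0.05) are masked (NaN): dividing by a near-zero baseline R^2
    is numerically unstable and such sites are excluded from analysis.
    """
    r2_model = np.asarray(r2_model, float)
    r2_baseline = np.asarray(r2_baseline, float)
    responsive = r2_baseline > threshold
    bps = np.where(responsive, r2_model / np.where(responsive, r2_baseline, 1.0), np.nan)
    if bps.ndim == 0:
        return float(bps)
    return bps


def select_window(
    features: FeatureStream,
    y: np.ndarray,
    window_grid: tuple[float, ...] = DEFAULT_WINDOW_GRID,
    lambda_grid: np.ndarray | None = None,
    group_ids: np.ndarray | None = None,
) -> tuple[float, TRFModel, dict[float, float]]:
    """Delay-window search: pick the window maximizing validation score.

    Windows are compared by their mean validation correlation across CV
    rotations; ties break toward the shorter window (parsimony). Returns
    (best window, fitted model at that window, per-window validation score).
    """
    grid = sorted(set(window_grid))
    if not grid:
        raise ValueError("empty window grid")
    if any(w < 0 or w > MAX_WINDOW_MS for w in grid):
        raise ValueError(f"window grid must lie within [0, {MAX_WINDOW_MS:.0f}] ms")

    scores: dict[float, float] = {}
    models: dict[float, TRFModel] = {}
    for w in grid:
        X = build_design_matrix(features, w)
        parts = cv_partitions(X.shape[0], group_ids=group_ids)
        model = fit_trf(X, y, parts, lambda_grid, n_features=features.n_features,
                        window_ms=w, frame_rate=features.frame_rate)
        scores[w] = float(np.nanmean(model.cv_val_r))
        models[w] = model
    best = max(grid, key=lambda w: (scores[w], -w))
    return float(best), models[best], scores


def noise_ceiling(repeats) -> NoiseCeiling:
    """Leave-one-repeat-out reliability.

    For each sentence and each repeat, the left-out repeat is correlated
    with the mean of the remaining repeats; correlations are averaged over
    repeats, then sentences, and the square of the mean correlation bounds
    the predictable variance. Accepts, per electrode, an (n_sentences,
    n_repeats, T) array or a list of (n_repeats, T_i) arrays; a leading
    electrode axis is allowed.
    """
    if isinstance(repeats, np.ndarray) and repeats.ndim == 4:
        ncs = [noise_ceiling(repeats[e]) for e in range(repeats.shape[0])]
        return NoiseCeiling(
            np.array([nc.r[0] for nc in ncs]),
            ncs[0].n_sentences, ncs[0].n_repeats,
        )
    if isinstance(repeats, np.ndarray):
        sentences = list(repeats)
    else:
        sentences = [np.asarray(s, float) for s in repeats]
    n_rep = sentences[0].shape[0]
    if any(s.shape[0] != n_rep for s in sentences):
        raise ValueError("all sentences must have the same number of repeats")
    if n_rep < 2:
        raise ValueError("need at least 2 repeats per sentence")

    sent_means = []
    for i, s in enumerate(sentences):
        rs = []
        for j in range(n_rep):
            left_out = s[j]
            others = np.delete(s, j, axis=0).mean(axis=0)
            if np.std(left_out) == 0 or np.std(others) == 0:
                warnings.warn(
                    f"constant trial in sentence {i}: correlation undefined, excluded")
                continue
            rs.append(np.corrcoef(others, left_out)[0, 1])
        if rs:
            sent_means.append(np.mean(rs))
    r = float(np.mean(sent_means)) if sent_means else np.nan
    return NoiseCeiling(np.array([r]), len(sentences), n_rep)


def unique_variance(
    target: np.ndarray,
    features: FeatureStream,
    window_ms: float = MAX_WINDOW_MS,
    lambda_grid: np.ndarray | None = None,
    group_ids: np.ndarray | None = None,
) -> tuple[float, dict[str, float]]:
    """Unique variance of each feature set for one target signal.

    DeltaR^2(set) = mean CV R^2 of the full model minus the mean CV R^2 of
    the model with that set omitted. Returns (full-model R^2, per-set
    DeltaR^2).
    """
    sets = features.sets
    if len(sets) < 2:
        raise ValueError("unique variance needs at least 2 named feature sets")
    full = fit_encoding(features, target, window_ms, lambda_grid, group_ids)
    deltas: dict[str, float] = {}
    for s in sets:
        reduced = fit_encoding(features.drop([s]), target, window_ms, lambda_grid, group_ids)
        deltas[s] = full.mean_r2 - reduced.mean_r2
    return full.mean_r2, deltas


def responsive_mask(r2_baseline: np.ndarray, threshold: float = RESPONSIVE_THRESHOLD) -> np.ndarray:
    """Speech-responsive electrode mask: baseline R^2 above threshold."""
    return np.asarray(r2_baseline, float) > threshold


def encoding_result(
    r2_model: np.ndarray,
    r2_baseline: np.ndarray,
    best_window_ms=None,
    best_layer=None,
    threshold: float = RESPONSIVE_THRESHOLD,
) -> EncodingResult:
    bps = brain_prediction_score(r2_model, r2_baseline, threshold)
    return EncodingResult(
        r2_model=np.asarray(r2_model, float),
        r2_baseline=np.asarray(r2_baseline, float),
        bps=np.atleast_1d(bps),
        best_window_ms=best_window_ms,
        best_layer=best_layer,
    )
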