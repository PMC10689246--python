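"""Phonemic/syllabic context templates and attention-score analysis.

Transformer self-attention over a sentence of T frames is a T x T weight
matrix per layer and head. To ask whether a layer attends within the
current phoneme, the previous phoneme, the current syllable minus its
current phoneme, and so on, six binary indicator templates are built from
the sentence's segmentation. The attention score (AS) of a layer for a
template is the Pearson correlation between the observed weights and the
template over all T^2 entries, averaged over heads and then over
sentences.

The AS-BPS analysis correlates, across layers, the AS profile with the
brain-prediction-score profile of an electrode group, and assesses it with
a permutation null that shuffles the sentence-to-response pairing and
refits the encoding models.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .datatypes import (
    AttentionScore,
    AttentionTemplate,
    FeatureStream,
    Segmentation,
    TEMPLATE_CONTEXTS,
)
from . import encoding

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# templates

def build_templates(seg: Segmentation) -> dict[str, AttentionTemplate]:
    """The six context-indicator templates for one segmentation.

    phoneme(d): entry (i, j) is 1 when frame i lies in phoneme k and frame
    j lies in phoneme k+d (d = 0, -1, -2); likewise for syllables. The
    current-syllable template is returned with the current phoneme removed,
    A'_sy(0) = A_sy(0) - A_ph(0), so it captures within-syllable but
    cross-phoneme attention. Frames whose context does not exist (e.g. the
    first phoneme for phoneme(-1)) give all-zero rows.
    """
    ph = seg.phoneme_index  # per-frame phoneme segment index
    sy = seg.syllable_index

    def indicator(idx: np.ndarray, offset: int) -> np.ndarray:
        valid_i = idx >= 0
        valid_j = idx >= 0
        A = (idx[:, None] + offset == idx[None, :]) & valid_i[:, None] & valid_j[None, :]
        if offset:
            A &= (idx[:, None] + offset) >= 0
        return A.astype(np.uint8)

    a_ph0 = indicator(ph, 0)
    a_sy0 = indicator(sy, 0)
    mats = {
        "phoneme(0)": a_ph0,
        "phoneme(-1)": indicator(ph, -1),
        "phoneme(-2)": indicator(ph, -2),
        "syllable(0)'": (a_sy0.astype(int) - a_ph0.astype(int)).clip(min=0).astype(np.uint8),
        "syllable(-1)": indicator(sy, -1),
        "syllable(-2)": indicator(sy, -2),
    }
    # a phoneme never spans syllables, so A_ph(0) <= A_sy(0) entrywise and
    # the clip above changes nothing; it guards degenerate segmentations
    return {c: AttentionTemplate(m, c) for c, m in mats.items()}


# ---------------------------------------------------------------------------
# attention scores

def template_correlation(W: np.ndarray, A: np.ndarray) -> float:
    """Pearson correlation between observed weights and a template over all
    T^2 flattened entries (diagonal included)."""
    w = np.asarray(W, float).ravel()
    a = np.asarray(A, float).ravel()
    if w.shape != a.shape:
        raise ValueError("attention matrix and template shapes differ")
    if np.std(a) == 0 or np.std(w) == 0:
        return np.nan
    return float(np.corrcoef(w, a)[0, 1])


def attention_score(
    mats: list[np.ndarray],
    templates: list[dict[str, AttentionTemplate]],
    context: str,
) -> list[AttentionScore]:
    """AS per layer for one context.

    ``mats`` holds one (n_layers, n_heads, T, T) array per sentence and
    ``templates`` the matching per-sentence template dict. Per (sentence,
    layer, head) the template correlation is computed, averaged over heads
    and then over sentences. Sentences whose template is all-zero for this
    context are skipped (count logged).
    """
    if context not in TEMPLATE_CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    n_layers = np.asarray(mats[0]).shape[0]
    per_sentence = np.full((n_layers, len(mats)), np.nan)
    n_skipped = 0
    for s, (W_s, tmpl_s) in enumerate(zip(mats, templates)):
        A = tmpl_s[context].matrix
        if not A.any():
            n_skipped += 1
            logger.info("sentence %d: all-zero %s template skipped", s, context)
            continue
        W_s = np.asarray(W_s, float)
        for x in range(n_layers):
            head_rs = [template_correlation(W_s[x, h], A) for h in range(W_s.shape[1])]
            per_sentence[x, s] = np.nanmean(head_rs)
    out = []
    for x in range(n_layers):
        vals = per_sentence[x]
        mean_val = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
        out.append(AttentionScore(
            as_value=mean_val,
            context=context,
            layer=x,
            per_sentence=vals,
            n_skipped=n_skipped,
        ))
    return out


def attention_scores_by_layer(
    mats: list[np.ndarray],
    templates: list[dict[str, AttentionTemplate]],
    contexts=TEMPLATE_CONTEXTS,
) -> dict[str, np.ndarray]:
    """AS per (context, layer) as {context: (n_layers,) array}."""
    return {
        c: np.array([s.as_value for s in attention_score(mats, templates, c)])
        for c in contexts
    }


def as_bps_correlation(as_per_layer: np.ndarray, bps_per_layer: np.ndarray) -> float:
    """Pearson correlation of AS and BPS profiles across layers."""
    a = np.asarray(as_per_layer, float)
    b = np.asarray(bps_per_layer, float)
    if len(a) != len(b):
        raise ValueError("profiles have different numbers of layers")
    if len(a) < 3:
        raise ValueError("need at least 3 layers to correlate")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant profile: AS-BPS correlation undefined")
        return np.nan
    return float(stats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# permutation inference

def _cv_r2_many(
    X: np.ndarray,
    Y: np.ndarray,
    partitions,
    lam: float,
) -> np.ndarray:
    """Mean CV R^2 (squared held-out correlation) for many targets at once.

    Vectorizes the per-rotation ridge solve over the columns of ``Y`` so a
    full permutation batch is a handful of BLAS calls.
    """
    n, _ = X.shape
    folds = [p for p in partitions if p[2].sum() > 1]
    r2 = np.zeros((Y.shape[1], len(folds)))
    for f, (train, val, test) in enumerate(folds):
        Xtr = X[train]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xc = (Xtr - mu) / sd
        G = Xc.T @ Xc + lam * np.eye(X.shape[1])
        Ytr = Y[train]
        B = np.linalg.solve(G, Xc.T @ (Ytr - Ytr.mean(axis=0)))
        Xte = (X[test] - mu) / sd
        P = Xte @ B
        Yte = Y[test] - Y[test].mean(axis=0)
        Pc = P - P.mean(axis=0)
        num = np.einsum("ij,ij->j", Pc, Yte)
        den = np.sqrt(np.einsum("ij,ij->j", Pc, Pc) * np.einsum("ij,ij->j", Yte, Yte))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        r2[:, f] = r**2
    return r2.mean(axis=1)


def permutation_null(
    layer_features: dict[str, FeatureStream] | dict[str, list[FeatureStream]],
    baseline_features: FeatureStream | list[FeatureStream],
    response: np.ndarray,
    sentence_ids: np.ndarray,
    as_per_layer: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    lam: float = 10.0,
    n_rotations: int = 5,
) -> tuple[float, float, np.ndarray]:
    """Sentence-shuffling permutation test for the AS-BPS correlation.

    Each permutation shuffles whole sentences of the response (breaking the
    speech-neural correspondence while keeping the features fixed), refits
    the per-layer and baseline encoding models at a fixed ridge penalty,
    recomputes BPS per layer and the AS-BPS correlation. The one-sided p
    is (1 + #{r_perm >= r_obs}) / (1 + n_perm); the observed statistic is
    computed by the identical reduced procedure so the null is exchangeable.

    Sentences must all have the same frame count (shuffling then preserves
    alignment structure exactly). Returns (r_obs, p, null distribution).
    """
    if isinstance(baseline_features, list):
        baseline_features = FeatureStream.concat(baseline_features, axis="frames")
        layer_features = {k: FeatureStream.concat(v, axis="frames")
                          for k, v in layer_features.items()}
    sentence_ids = np.asarray(sentence_ids)
    uniq, counts = np.unique(sentence_ids, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 sentences to permute")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(set(counts)) != 1:
        raise ValueError("permutation null requires equal-length sentences")
    n_sent = len(uniq)
    import math
    if n_perm > math.factorial(n_sent):
        warnings.warn("n_perm exceeds distinct permutations; sampling with replacement")

    y = np.asarray(response, float).ravel()
    T = counts[0]
    blocks = np.stack([y[sentence_ids == u] for u in uniq])  # (n_sent, T)

    rng = np.random.default_rng(seed)
    perms = np.stack([np.arange(n_sent)] + [rng.permutation(n_sent) for _ in range(n_perm)])
    Y = blocks[perms].reshape(n_perm + 1, n_sent * T).T  # column 0 = observed

    parts = encoding.cv_partitions(len(y), n_rotations=n_rotations, group_ids=sentence_ids)

    layers = list(layer_features)
    window_ms = 0.0  # current-frame models keep the null cheap and exchangeable
    Xb = encoding.build_design_matrix(baseline_features, window_ms)
    r2_base = _cv_r2_many(Xb, Y, parts, lam)
    r_all = np.zeros(n_perm + 1)
    bps = np.zeros((len(layers), n_perm + 1))
    for i, name in enumerate(layers):
        Xl = encoding.build_design_matrix(layer_features[name], window_ms)
        r2_l = _cv_r2_many(Xl, Y, parts, lam)
        with np.errstate(invalid="ignore", divide="ignore"):
            bps[i] = np.where(r2_base > 0, r2_l / r2_base, np.nan)
    as_vec = np.asarray(as_per_layer, float)
    for p_i in range(n_perm + 1):
        col = bps[:, p_i]
        if np.std(col) == 0 or not np.all(np.isfinite(col)):
            r_all[p_i] = 0.0
        else:
            r_all[p_i] = np.corrcoef(as_vec, col)[0, 1]
    r_obs, null = r_all[0], r_all[1:]
    p = (1 + np.sum(null >= r_obs)) / (1 + n_perm)
    return float(r_obs), float(p), null


def pearson_permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation p for a Pearson correlation by shuffling the
    pairing of one vector (used where a sentence-shuffling null is not
    available)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    null = np.array([stats.pearsonr(x, rng.permutation(y))[0] for _ in range(n_perm)])
    p = (1 + np.sum(null >= r_obs)) / (1 + n_perm)
    return r_obs, float(p)
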