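"""Core containers shared across the pipeline.

The analysis operates on a small set of array-backed objects: feature
streams at a fixed frame rate, z-scored high-gamma responses with
block/sentence/repeat structure, phoneme/syllable segmentations, fitted
temporal-receptive-field (TRF) models, and attention templates/matrices.
All containers are plain dataclasses around numpy arrays; validation
happens at construction time so downstream code can assume invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FEATURE_SETS = ("spectrogram", "phonetic", "pitch", "envelope", "embedding")

#: rows per set in the heuristic baseline model
BASELINE_SET_SIZES = {"spectrogram": 161, "phonetic": 13, "pitch": 31, "envelope": 3}
BASELINE_N_FEATURES = 208


@dataclass
class FeatureStream:
    """A named feature-set x time matrix at a fixed frame rate.

    ``values`` has shape (n_features, n_frames). ``set_labels`` assigns each
    row to a feature set (spectrogram/phonetic/pitch/envelope/embedding) so
    models can be fit on subsets and unique-variance partitions can omit one
    set at a time.
    """

    values: np.ndarray
    frame_rate: float
    set_labels: np.ndarray
    feature_names: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x frames)")
        self.set_labels = np.asarray(self.set_labels, dtype=object)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        if len(self.set_labels) != self.values.shape[0]:
            raise ValueError("set_labels length must equal number of feature rows")
        if len(self.feature_names) != self.values.shape[0]:
            raise ValueError("feature_names length must equal number of feature rows")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def sets(self) -> list[str]:
        seen: list[str] = []
        for s in self.set_labels:
            if s not in seen:
                seen.append(s)
        return seen

    def subset(self, sets: Sequence[str]) -> "FeatureStream":
        """Rows belonging to the given feature sets, order preserved."""
        wanted = set(sets)
        unknown = wanted - set(self.set_labels)
        if unknown:
            raise KeyError(f"unknown feature set(s): {sorted(unknown)}")
        mask = np.array([s in wanted for s in self.set_labels])
        return FeatureStream(
            self.values[mask],
            self.frame_rate,
            self.set_labels[mask],
            self.feature_names[mask],
        )

    def drop(self, sets: Sequence[str]) -> "FeatureStream":
        """All rows except those in the given feature sets."""
        keep = [s for s in self.sets if s not in set(sets)]
        if not keep:
            raise ValueError("dropping these sets would leave an empty stream")
        return self.subset(keep)

    @staticmethod
    def concat(streams: Sequence["FeatureStream"], axis: str = "features") -> "FeatureStream":
        """Stack streams along features (same frames) or frames (same rows)."""
        rates = {s.frame_rate for s in streams}
        if len(rates) != 1:
            raise ValueError("frame rates differ")
        if axis == "features":
            return FeatureStream(
                np.vstack([s.values for s in streams]),
                streams[0].frame_rate,
                np.concatenate([s.set_labels for s in streams]),
                np.concatenate([s.feature_names for s in streams]),
            )
        if axis == "frames":
            first = streams[0]
            for s in streams[1:]:
                if list(s.set_labels) != list(first.set_labels):
                    raise ValueError("set labels differ across streams")
            return FeatureStream(
                np.hstack([s.values for s in streams]),
                first.frame_rate,
                first.set_labels,
                first.feature_names,
            )
        raise ValueError("axis must be 'features' or 'frames'")


@dataclass
class Segmentation:
    """Frame-indexed phoneme and syllable boundaries for one utterance.

    ``phoneme_bounds[k]`` is the first frame of phoneme ``k``; the segment
    extends to ``phoneme_bounds[k+1]`` (or ``n_frames`` for the last one).
    Every syllable boundary coincides with a phoneme boundary, since
    syllables are groups of whole phonemes.
    """

    phoneme_bounds: np.ndarray
    syllable_bounds: np.ndarray
    labels: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.phoneme_bounds = np.asarray(self.phoneme_bounds, dtype=int)
        self.syllable_bounds = np.asarray(self.syllable_bounds, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        for name, b in (("phoneme", self.phoneme_bounds), ("syllable", self.syllable_bounds)):
            if len(b) and (np.any(np.diff(b) <= 0)):
                raise ValueError(f"{name} bounds must be strictly increasing")
            if len(b) and (b[0] < 0 or b[-1] >= self.n_frames):
                raise ValueError(f"{name} bounds must lie in [0, n_frames)")
        if not set(self.syllable_bounds).issubset(set(self.phoneme_bounds)):
            raise ValueError("every syllable boundary must coincide with a phoneme boundary")
        if len(self.labels) != len(self.phoneme_bounds):
            raise ValueError("one label per phoneme segment required")

    @property
    def n_phonemes(self) -> int:
        return len(self.phoneme_bounds)

    def segment_index(self, bounds: np.ndarray) -> np.ndarray:
        """Per-frame index of the segment each frame falls in (-1 before the
        first boundary)."""
        return np.searchsorted(bounds, np.arange(self.n_frames), side="right") - 1

    @property
    def phoneme_index(self) -> np.ndarray:
        return self.segment_index(self.phoneme_bounds)

    @property
    def syllable_index(self) -> np.ndarray:
        return self.segment_index(self.syllable_bounds)


@dataclass
class NeuralResponse:
    """Electrode x frame z-scored high-gamma activity at 100 Hz.

    Per-frame index vectors carry the recording-block, sentence and repeat
    structure needed for z-scoring, CV partitioning and noise ceilings.
    """

    activity: np.ndarray
    frame_rate: float = 100.0
    block_ids: np.ndarray | None = None
    sentence_index: np.ndarray | None = None
    repeat_index: np.ndarray | None = None
    electrode_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activity = np.atleast_2d(np.asarray(self.activity, dtype=float))
        n = self.activity.shape[1]
        if self.block_ids is None:
            self.block_ids = np.zeros(n, dtype=int)
        if self.sentence_index is None:
            self.sentence_index = np.zeros(n, dtype=int)
        if self.repeat_index is None:
            self.repeat_index = np.zeros(n, dtype=int)
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(self.activity.shape[0])
        for name in ("block_ids", "sentence_index", "repeat_index"):
            v = np.asarray(getattr(self, name))
            if len(v) != n:
                raise ValueError(f"{name} must have one entry per frame")
            setattr(self, name, v)

    @property
    def n_electrodes(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]


@dataclass
class GroundTruth:
    """Simulation ground truth for parameter-recovery tests."""

    trf_weights: np.ndarray  # (n_electrodes, n_features, n_lags)
    noise_sd: float
    template_mixture: np.ndarray | None = None  # (n_layers, 6), nonnegative
    seed: int = 0

    def __post_init__(self) -> None:
        self.trf_weights = np.asarray(self.trf_weights, dtype=float)
        if self.trf_weights.ndim == 2:
            self.trf_weights = self.trf_weights[None]
        if not np.all(np.isfinite(self.trf_weights)):
            raise ValueError("trf_weights must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.template_mixture is not None:
            self.template_mixture = np.atleast_2d(np.asarray(self.template_mixture, dtype=float))
            if np.any(self.template_mixture < 0):
                raise ValueError("template mixture weights must be nonnegative")


@dataclass
class TRFModel:
    """A fitted time-delayed ridge model for one electrode/unit.

    ``weights`` is the feature x lag coefficient matrix beta_f(tau) on the
    original (unstandardized) predictor scale; ``cv_r2`` holds the held-out
    R^2 of each CV rotation and ``cv_r`` the signed held-out correlations.
    """

    weights: np.ndarray
    lam: float
    window_ms: float
    frame_rate: float
    cv_r2: np.ndarray
    mean_r2: float
    cv_r: np.ndarray = field(default=None)  # type: ignore[assignment]
    intercept: float = 0.0
    lam_per_fold: np.ndarray | None = None
    cv_val_r: np.ndarray | None = None

    @property
    def n_lags(self) -> int:
        return self.weights.shape[1]


@dataclass
class EncodingResult:
    """Per-electrode encoding performance and normalized scores."""

    r2_model: np.ndarray
    r2_baseline: np.ndarray
    bps: np.ndarray  # NaN where baseline R^2 <= threshold
    best_window_ms: float | np.ndarray | None = None
    best_layer: str | np.ndarray | None = None


@dataclass
class NoiseCeiling:
    """Leave-one-repeat-out reliability per electrode."""

    r: np.ndarray
    n_sentences: int
    n_repeats: int

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        ok = self.r[np.isfinite(self.r)]
        if np.any(ok < -1 - 1e-12) or np.any(ok > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2


TEMPLATE_CONTEXTS = (
    "phoneme(0)",
    "phoneme(-1)",
    "phoneme(-2)",
    "syllable(0)'",
    "syllable(-1)",
    "syllable(-2)",
)


@dataclass
class AttentionTemplate:
    """T x T binary context-indicator matrix for one sentence."""

    matrix: np.ndarray
    context: str
    T: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("template must be square")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("template entries must be binary")
        if self.context not in TEMPLATE_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        self.T = self.matrix.shape[0]


@dataclass
class AttentionMatrix:
    """Observed T x T attention weights at one layer/head for one sentence."""

    weights: np.ndarray
    layer: int
    head: int
    sentence_id: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("attention weights must be finite")
        if np.any(self.weights < -1e-12):
            raise ValueError("attention weights must be nonnegative")


@dataclass
class AttentionScore:
    """Template-correlation attention score for one layer and context."""

    as_value: float
    context: str
    layer: int
    per_head: np.ndarray | None = None       # (n_heads,) head means
    per_sentence: np.ndarray | None = None   # (n_sentences,) sentence means
    n_skipped: int = 0


@dataclass
class ERPDecomposition:
    """Convex-NMF factorization of a time x electrode averaged-ERP matrix.

    X ~ F G^T with F = X W; W and G are nonnegative while X may be
    mixed-sign. ``labels`` assigns each electrode to its max-weight cluster.
    """

    X: np.ndarray
    F: np.ndarray
    G: np.ndarray
    W: np.ndarray
    k: int
    variance_explained: float
    labels: np.ndarray
    objective_path: np.ndarray | None = None
    converged: bool = True
    tie_fraction: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.G < -1e-12) or np.any(self.W < -1e-12):
            raise ValueError("G and W must be nonnegative")
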