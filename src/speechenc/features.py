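"""Heuristic acoustic/phonetic/prosodic feature extraction.

Builds the 208-dimensional baseline feature model used to benchmark every
other representation: 161 log-spaced spectrogram channels, 13 binary
phonetic (articulatory) features, 31 pitch features (3 x 10 one-hot binned
pitch variables + 1 voicing indicator) and 3 envelope features (intensity,
sentence onset, peak rate), all at the neural frame rate of 100 Hz.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import BASELINE_SET_SIZES, FeatureStream, Segmentation

FRAME_RATE = 100.0
N_SPECTROGRAM = 161
N_PHONETIC = 13
N_PITCH = 31
N_ENVELOPE = 3
F_MAX = 8000.0
F_MIN = 50.0  # lowest log-spaced spectrogram center frequency
PITCH_BINS = 10
PHONETIC_FEATURE_NAMES = (
    "dorsal", "coronal", "labial",
    "plosive", "fricative", "nasal",
    "voiced",
    "high", "mid", "low", "front", "back",
    "vowel",
)


def load_phoneme_table() -> dict[str, np.ndarray]:
    """Packaged phoneme -> 13-bit articulatory-feature lookup (40 symbols)."""
    ref = importlib.resources.files("speechenc").joinpath("data/phoneme_features.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="phoneme")
    df = df[list(PHONETIC_FEATURE_NAMES)]
    return {ph: row.to_numpy(dtype=float) for ph, row in df.iterrows()}


def spectrogram_center_frequencies(n_bins: int = N_SPECTROGRAM) -> np.ndarray:
    """Log-spaced center frequencies up to 8 kHz."""
    return np.geomspace(F_MIN, F_MAX, n_bins)


def _stft_magnitude(wave: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude STFT with a 20-ms Hann window and 10-ms hop (100-Hz frames)."""
    nperseg = int(round(0.02 * fs))
    hop = int(round(0.01 * fs))
    f, _, Z = signal.stft(
        wave, fs=fs, nperseg=nperseg, noverlap=nperseg - hop,
        boundary="zeros", padded=True,
    )
    return f, np.abs(Z)


def compute_spectrogram(wave: np.ndarray, fs: float, n_frames: int | None = None) -> FeatureStream:
    """161-channel log-frequency magnitude spectrogram at 100 Hz.

    Linear-frequency STFT magnitudes are interpolated onto 161 log-spaced
    center frequencies from 50 Hz to 8 kHz. Magnitudes are linear (no
    compression), so doubling the waveform amplitude doubles every channel.
    """
    wave = np.asarray(wave, dtype=float)
    if fs < 16000:
        raise ValueError(f"sampling rate {fs} Hz too low: 8-kHz band unrepresentable")
    freqs, mag = _stft_magnitude(wave, fs)
    centers = spectrogram_center_frequencies()
    # interpolate each frame's magnitude onto the log-spaced grid
    out = np.empty((len(centers), mag.shape[1]))
    for t in range(mag.shape[1]):
        out[:, t] = np.interp(centers, freqs, mag[:, t])
    out = _fit_length(out, n_frames)
    names = np.array([f"spec_{c:.0f}Hz" for c in centers], dtype=object)
    return FeatureStream(out, FRAME_RATE, np.repeat("spectrogram", len(centers)), names)


def _fit_length(values: np.ndarray, n_frames: int | None) -> np.ndarray:
    if n_frames is None:
        return values
    T = values.shape[1]
    if T >= n_frames:
        return values[:, :n_frames]
    pad = np.zeros((values.shape[0], n_frames - T))
    return np.hstack([values, pad])


def phonetic_features(seg: Segmentation, lookup: dict[str, np.ndarray] | None = None) -> FeatureStream:
    """Per-frame 13-bit binary articulatory features from an alignment.

    Each frame carries the feature vector of the phoneme it falls in;
    silence frames (label 'sil' or frames before the first boundary) are
    all-zero.
    """
    if lookup is None:
        lookup = load_phoneme_table()
    unknown = [str(l) for l in seg.labels if l not in lookup]
    if unknown:
        raise KeyError(f"unknown phoneme label(s): {sorted(set(unknown))}")
    out = np.zeros((N_PHONETIC, seg.n_frames))
    idx = seg.phoneme_index
    for k, label in enumerate(seg.labels):
        out[:, idx == k] = lookup[label][:, None]
    names = np.array(PHONETIC_FEATURE_NAMES, dtype=object)
    return FeatureStream(out, FRAME_RATE, np.repeat("phonetic", N_PHONETIC), names)


def _bin_onehot(values: np.ndarray, voiced: np.ndarray, n_bins: int = PITCH_BINS) -> np.ndarray:
    """One-hot bin voiced-frame values into ``n_bins`` bins spanning the
    2.5th..97.5th percentile; tail values are clipped into the end bins."""
    out = np.zeros((n_bins, len(values)))
    v = values[voiced]
    if v.size == 0:
        return out
    lo, hi = np.percentile(v, [2.5, 97.5])
    if hi <= lo:
        # zero-variance input: place all mass in the middle bin
        out[n_bins // 2 - 1, voiced] = 1.0
        return out
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(values, edges) - 1, 0, n_bins - 1)
    out[idx[voiced], np.nonzero(voiced)[0]] = 1.0
    return out


def pitch_features(
    f0: np.ndarray,
    sentence_bounds: list[tuple[int, int]] | None = None,
) -> FeatureStream:
    """31 binary pitch features from a fundamental-frequency track.

    Absolute pitch is ln(F0); relative pitch is the within-sentence z-score
    of ln(F0); pitch change is the first difference of ln(F0). Each is
    discretized into 10 one-hot bins spanning the 2.5th-97.5th percentile of
    the corpus's voiced frames, with the tails clipped into the end bins,
    plus one voicing indicator. Unvoiced frames are all-zero.

    ``f0`` uses 0 (or NaN) to mark unvoiced frames; ``sentence_bounds`` are
    half-open (start, stop) frame ranges, defaulting to the whole track.
    """
    f0 = np.asarray(f0, dtype=float)
    f0 = np.where(np.isnan(f0), 0.0, f0)
    voiced = f0 > 0
    if np.any(f0 < 0):
        raise ValueError("negative F0 on a voiced frame")
    T = len(f0)
    if sentence_bounds is None:
        sentence_bounds = [(0, T)]

    logf0 = np.zeros(T)
    logf0[voiced] = np.log(f0[voiced])

    rel = np.zeros(T)
    for start, stop in sentence_bounds:
        m = np.zeros(T, dtype=bool)
        m[start:stop] = True
        m &= voiced
        if m.sum() >= 2 and np.std(logf0[m]) > 0:
            rel[m] = (logf0[m] - np.mean(logf0[m])) / np.std(logf0[m])
        # constant or single-frame sentence: z-score 0 by convention

    change = np.zeros(T)
    prev_voiced = np.zeros(T, dtype=bool)
    prev_voiced[1:] = voiced[:-1]
    both = voiced & prev_voiced
    change[both] = logf0[both] - np.roll(logf0, 1)[both]

    rows = [
        _bin_onehot(logf0, voiced),
        _bin_onehot(rel, voiced),
        _bin_onehot(change, voiced),
        voiced.astype(float)[None, :],
    ]
    out = np.vstack(rows)
    names = (
        [f"abs_pitch_bin{i}" for i in range(PITCH_BINS)]
        + [f"rel_pitch_bin{i}" for i in range(PITCH_BINS)]
        + [f"pitch_change_bin{i}" for i in range(PITCH_BINS)]
        + ["voicing"]
    )
    return FeatureStream(out, FRAME_RATE, np.repeat("pitch", N_PITCH), np.array(names, dtype=object))


def amplitude_envelope(wave: np.ndarray, fs: float, n_frames: int | None = None) -> np.ndarray:
    """RMS amplitude in 20-ms windows hopped every 10 ms (100-Hz frames)."""
    wave = np.asarray(wave, dtype=float)
    win = int(round(0.02 * fs))
    hop = int(round(0.01 * fs))
    n_out = 1 + len(wave) // hop if n_frames is None else n_frames
    env = np.zeros(n_out)
    for t in range(n_out):
        center = t * hop
        seg = wave[max(0, center - win // 2): center + win // 2]
        if seg.size:
            env[t] = np.sqrt(np.mean(seg**2))
    return env


def envelope_features(
    wave: np.ndarray,
    fs: float,
    sentence_onsets: np.ndarray,
    n_frames: int | None = None,
) -> FeatureStream:
    """Intensity, sentence-onset and peak-rate rows at 100 Hz.

    Peak rate is a sparse series holding the envelope-derivative value at
    local maxima of the (positive) first difference of the amplitude
    envelope, and zero elsewhere.
    """
    env = amplitude_envelope(wave, fs, n_frames)
    T = len(env)
    onsets = np.asarray(sentence_onsets, dtype=int)
    if len(onsets) and (onsets.min() < 0 or onsets.max() >= T):
        raise ValueError("sentence onset outside frame range")

    onset_row = np.zeros(T)
    onset_row[onsets] = 1.0

    deriv = np.zeros(T)
    deriv[1:] = np.diff(env)
    peak_row = np.zeros(T)
    peaks, _ = signal.find_peaks(deriv)
    peaks = peaks[deriv[peaks] > 0]
    peak_row[peaks] = deriv[peaks]

    out = np.vstack([env, onset_row, peak_row])
    names = np.array(["intensity", "sentence_onset", "peak_rate"], dtype=object)
    return FeatureStream(out, FRAME_RATE, np.repeat("envelope", N_ENVELOPE), names)


def assemble_baseline(
    spectrogram: FeatureStream,
    phonetic: FeatureStream,
    pitch: FeatureStream,
    envelope: FeatureStream,
) -> FeatureStream:
    """Stack the four feature sets into the 208-row baseline stream."""
    stream = FeatureStream.concat([spectrogram, phonetic, pitch, envelope])
    for set_name, n in BASELINE_SET_SIZES.items():
        got = int(np.sum(stream.set_labels == set_name))
        if got != n:
            raise ValueError(f"{set_name} set has {got} rows, expected {n}")
    return stream
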