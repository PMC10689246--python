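"""Raw voltage to 100-Hz z-scored high-gamma, and frame-rate alignment.

High-gamma extraction follows the standard analytic-amplitude recipe:
eight Gaussian band filters with center frequencies log-spaced between 70
and 150 Hz, per-band analytic amplitude via the analytic-signal (Hilbert)
transform, averaged across bands, downsampled to 100 Hz and z-scored per
recording block. Notch filtering and common-average rereferencing are
assumed done upstream.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .datatypes import FeatureStream, NeuralResponse

logger = logging.getLogger(__name__)

TARGET_RATE = 100.0
N_BANDS = 8
BAND_LO, BAND_HI = 70.0, 150.0
FRACTIONAL_BANDWIDTH = 0.1  # constant-Q Gaussian filters
EDGE_MS = 200.0  # filter warm-up excluded from z-score statistics


def highgamma_center_frequencies(n_bands: int = N_BANDS) -> np.ndarray:
    """Log-spaced center frequencies spanning 70-150 Hz."""
    return np.geomspace(BAND_LO, BAND_HI, n_bands)


def _analytic_band_amplitude(raw: np.ndarray, fs: float, cf: float) -> np.ndarray:
    """Analytic amplitude of one Gaussian frequency band.

    The analytic signal is built in the frequency domain (negative
    frequencies zeroed, positive doubled) with a Gaussian weighting of
    width ``FRACTIONAL_BANDWIDTH * cf`` around the center frequency.
    """
    n = raw.shape[-1]
    spec = np.fft.fft(raw, axis=-1)
    f = np.fft.fftfreq(n, d=1.0 / fs)
    h = np.zeros(n)
    h[f > 0] = 2.0
    h[f == 0] = 1.0
    sigma = FRACTIONAL_BANDWIDTH * cf
    g = np.exp(-0.5 * ((np.abs(f) - cf) / sigma) ** 2)
    analytic = np.fft.ifft(spec * (h * g), axis=-1)
    return np.abs(analytic)


def zscore_blocks(
    activity: np.ndarray,
    block_ids: np.ndarray | None = None,
    edge_frames: int = 0,
) -> np.ndarray:
    """Z-score each electrode within each recording block.

    ``edge_frames`` frames at both block edges are excluded from the
    mean/SD estimates (filter warm-up) but still transformed. Constant
    channels map to zeros (flagged).
    """
    activity = np.atleast_2d(np.asarray(activity, float))
    n = activity.shape[1]
    block_ids = np.zeros(n, dtype=int) if block_ids is None else np.asarray(block_ids)
    out = np.empty_like(activity)
    for b in np.unique(block_ids):
        m = block_ids == b
        idx = np.nonzero(m)[0]
        core = idx[edge_frames: len(idx) - edge_frames] if len(idx) > 2 * edge_frames else idx
        mu = activity[:, core].mean(axis=1, keepdims=True)
        sd = activity[:, core].std(axis=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            warnings.warn(f"{int(flat.sum())} constant channel(s) in block {b}: z-score set to 0")
        sd = np.where(sd == 0, 1.0, sd)
        out[:, m] = (activity[:, m] - mu) / sd
        if flat.any():
            out[np.ix_(flat, m)] = 0.0
    return out


def extract_high_gamma(
    raw: np.ndarray,
    fs: float,
    block_ids: np.ndarray | None = None,
    zscore: bool = True,
) -> NeuralResponse:
    """High-gamma analytic amplitude at 100 Hz, z-scored per block.

    ``raw`` is electrode x sample voltage; ``block_ids`` (per output
    frame, optional) delimit recording blocks for z-scoring.
    """
    raw = np.atleast_2d(np.asarray(raw, float))
    if fs < 400:
        raise ValueError(f"sampling rate {fs} Hz too low for the 70-150 Hz band")
    amps = np.zeros_like(raw)
    for cf in highgamma_center_frequencies():
        amps += _analytic_band_amplitude(raw, fs, cf)
    hg = amps / N_BANDS

    frac = Fraction(TARGET_RATE / fs).limit_denominator(10000)
    hg_ds = sps.resample_poly(hg, frac.numerator, frac.denominator, axis=-1)
    edge = int(round(EDGE_MS * TARGET_RATE / 1000.0))
    if zscore:
        act = zscore_blocks(hg_ds, block_ids, edge_frames=edge)
    else:
        act = hg_ds
    return NeuralResponse(activity=act, frame_rate=TARGET_RATE, block_ids=block_ids)


def align_streams(
    stream: FeatureStream,
    target_rate: float,
    mode: str = "repeat",
    n_frames: int | None = None,
) -> FeatureStream:
    """Resample a feature stream to the neural frame rate.

    ``repeat`` duplicates frames for integer upsampling (the default
    50->100 Hz path) and averages consecutive frames for integer
    downsampling; ``interp`` linearly interpolates at the target frame
    times. ``n_frames`` optionally pins the output length (tolerance one
    frame, otherwise rejected).
    """
    src, tgt = stream.frame_rate, float(target_rate)
    V = stream.values
    if tgt == src:
        out = V.copy()
    elif mode == "repeat":
        if tgt > src and (tgt / src) == int(tgt / src):
            out = np.repeat(V, int(tgt / src), axis=1)
        elif src > tgt and (src / tgt) == int(src / tgt):
            f = int(src / tgt)
            T = (V.shape[1] // f) * f
            out = V[:, :T].reshape(V.shape[0], -1, f).mean(axis=2)
        else:
            raise ValueError(
                "repeat mode needs an integer rate ratio; use mode='interp'")
    elif mode == "interp":
        t_src = np.arange(V.shape[1]) / src
        T_out = int(round(V.shape[1] * tgt / src))
        t_tgt = np.arange(T_out) / tgt
        out = np.vstack([np.interp(t_tgt, t_src, row) for row in V])
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    if n_frames is not None:
        if abs(out.shape[1] - n_frames) > 1:
            raise ValueError(
                f"aligned length {out.shape[1]} differs from target {n_frames} by > 1 frame")
        out = out[:, :n_frames]
        if out.shape[1] < n_frames:
            out = np.hstack([out, out[:, -1:]])
    return FeatureStream(out, tgt, stream.set_labels.copy(), stream.feature_names.copy())
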