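"""File formats: WAV, TextGrid/TSV alignments, F0 tracks, HDF5 containers.

HDF5 layouts
------------
feature stream : datasets ``values`` (features x frames), ``set_labels``,
                 ``feature_names``; attr ``frame_rate``.
neural response: dataset ``activity`` (electrodes x frames) plus index
                 datasets ``block_ids``/``sentence_index``/``repeat_index``/
                 ``electrode_ids``; attr ``frame_rate``.
raw voltage    : dataset ``voltage`` (electrodes x samples); attr ``fs``.
attention      : one dataset per sentence, ``sentence<NNN>`` of shape
                 (layers, heads, T, T).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .datatypes import FeatureStream, NeuralResponse, Segmentation


# ---------------------------------------------------------------------------
# audio

def read_wav(path) -> tuple[np.ndarray, float]:
    """Mono float waveform in [-1, 1] and its sampling rate."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(fs)


def write_wav(path, wave: np.ndarray, fs: float) -> None:
    w = np.clip(np.asarray(wave, float), -1, 1)
    wavfile.write(path, int(fs), (w * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# alignments

def read_alignment_tsv(path, frame_rate: float = 100.0) -> Segmentation:
    """4-column alignment TSV (onset_s, offset_s, label, tier) -> Segmentation.

    Tiers named ``phone``/``phoneme`` and ``syllable`` are used; intervals
    must be contiguous within a tier.
    """
    df = pd.read_csv(path, sep="\t", names=["onset_s", "offset_s", "label", "tier"],
                     header=0 if _has_header(path) else None)
    return _segmentation_from_intervals(df, frame_rate)


def _has_header(path) -> bool:
    with open(path) as fh:
        first = fh.readline().split("\t")
    try:
        float(first[0])
        return False
    except ValueError:
        return True


def _segmentation_from_intervals(df: pd.DataFrame, frame_rate: float) -> Segmentation:
    ph = df[df["tier"].str.lower().isin(["phone", "phones", "phoneme", "phonemes"])]
    sy = df[df["tier"].str.lower().isin(["syllable", "syllables"])]
    if ph.empty:
        raise ValueError("no phoneme tier found")
    ph = ph.sort_values("onset_s")
    n_frames = int(round(ph["offset_s"].max() * frame_rate))
    ph_bounds = np.round(ph["onset_s"].to_numpy() * frame_rate).astype(int)
    labels = ph["label"].to_numpy(dtype=object)
    if sy.empty:
        sy_bounds = ph_bounds.copy()
    else:
        sy_bounds = np.round(np.sort(sy["onset_s"].to_numpy()) * frame_rate).astype(int)
        # snap syllable bounds onto the nearest phoneme bound
        sy_bounds = np.array([ph_bounds[np.argmin(np.abs(ph_bounds - b))] for b in sy_bounds])
        sy_bounds = np.unique(sy_bounds)
    return Segmentation(ph_bounds, sy_bounds, labels, n_frames)


def read_textgrid(path, frame_rate: float = 100.0) -> Segmentation:
    """Minimal Praat TextGrid (long format) interval-tier reader."""
    rows = []
    tier = None
    xmin = xmax = None
    with open(path, encoding="utf-8", errors="replace") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("name ="):
                tier = line.split("=", 1)[1].strip().strip('"')
            elif line.startswith("xmin ="):
                xmin = float(line.split("=", 1)[1])
            elif line.startswith("xmax ="):
                xmax = float(line.split("=", 1)[1])
            elif line.startswith("text =") and tier is not None:
                label = line.split("=", 1)[1].strip().strip('"')
                if label:
                    rows.append({"onset_s": xmin, "offset_s": xmax,
                                 "label": label, "tier": tier})
    if not rows:
        raise ValueError(f"no labeled intervals found in {path}")
    return _segmentation_from_intervals(pd.DataFrame(rows), frame_rate)


def write_alignment_tsv(path, seg: Segmentation, frame_rate: float = 100.0) -> None:
    rows = []
    bounds = list(seg.phoneme_bounds) + [seg.n_frames]
    for k, label in enumerate(seg.labels):
        rows.append((bounds[k] / frame_rate, bounds[k + 1] / frame_rate, label, "phoneme"))
    sy = list(seg.syllable_bounds) + [seg.n_frames]
    for k in range(len(seg.syllable_bounds)):
        rows.append((sy[k] / frame_rate, sy[k + 1] / frame_rate, f"syl{k}", "syllable"))
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "label", "tier"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# F0 tracks

def read_f0_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """2-column (time_s, f0_hz) track; 0 marks unvoiced frames."""
    df = pd.read_csv(path, sep="\t", names=["time_s", "f0_hz"],
                     header=0 if _has_header(path) else None)
    return df["time_s"].to_numpy(float), df["f0_hz"].to_numpy(float)


def write_f0_tsv(path, times: np.ndarray, f0: np.ndarray) -> None:
    pd.DataFrame({"time_s": times, "f0_hz": f0}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HDF5 containers

def _write_str_ds(g, name, values) -> None:
    g.create_dataset(name, data=np.asarray([str(v) for v in values], dtype=object),
                     dtype=h5py.string_dtype())


def write_features_h5(path, stream: FeatureStream) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=stream.values)
        _write_str_ds(f, "set_labels", stream.set_labels)
        _write_str_ds(f, "feature_names", stream.feature_names)
        f.attrs["frame_rate"] = stream.frame_rate


def read_features_h5(path) -> FeatureStream:
    with h5py.File(path, "r") as f:
        return FeatureStream(
            f["values"][()],
            float(f.attrs["frame_rate"]),
            np.array([s.decode() if isinstance(s, bytes) else s for s in f["set_labels"][()]],
                     dtype=object),
            np.array([s.decode() if isinstance(s, bytes) else s for s in f["feature_names"][()]],
                     dtype=object),
        )


def write_response_h5(path, resp: NeuralResponse) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=resp.activity)
        for name in ("block_ids", "sentence_index", "repeat_index", "electrode_ids"):
            f.create_dataset(name, data=np.asarray(getattr(resp, name)))
        f.attrs["frame_rate"] = resp.frame_rate


def read_response_h5(path) -> NeuralResponse:
    with h5py.File(path, "r") as f:
        return NeuralResponse(
            activity=f["activity"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            block_ids=f["block_ids"][()],
            sentence_index=f["sentence_index"][()],
            repeat_index=f["repeat_index"][()],
            electrode_ids=f["electrode_ids"][()],
        )


def write_raw_voltage_h5(path, voltage: np.ndarray, fs: float) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=np.atleast_2d(voltage))
        f.attrs["fs"] = fs


def read_raw_voltage_h5(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        return f["voltage"][()], float(f.attrs["fs"])


def write_attention_h5(path, mats: list[np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        for s, m in enumerate(mats):
            f.create_dataset(f"sentence{s:03d}", data=np.asarray(m))


def read_attention_h5(path) -> list[np.ndarray]:
    with h5py.File(path, "r") as f:
        return [f[k][()] for k in sorted(f.keys())]
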