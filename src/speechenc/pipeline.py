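"""End-to-end orchestration of the synthetic-study pipeline.

A single seeded configuration drives: segmentation and stimulus-feature
generation, simulated neural responses, baseline TRF fits, per-layer
encoding models and brain-prediction scores, convex-NMF ERP clustering,
attention-template scoring with the AS-BPS permutation test, and
layer-wise unique-variance profiles. Every output CSV records the config
hash and seed; a manifest lists each artifact with its content hash so
runs are auditable and resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attention, clustering, encoding, synthetic, variance
from .datatypes import FeatureStream

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full synthetic run."""

    out_dir: str = "pwe_run"
    seed: int = 0
    n_sentences: int = 8
    phonemes_per_sentence: tuple[int, int] = (20, 30)
    n_electrodes: int = 8
    noise_sd: float = 1.0
    n_layers: int = 4
    n_heads: int = 2
    units_per_layer: int = 8
    frame_rate: float = 100.0
    window_ms: float = 100.0
    window_grid: tuple[float, ...] = (0.0, 50.0, 100.0)
    lambda_grid: tuple[float, ...] = tuple(np.geomspace(1e-2, 1e5, 10))
    n_perm: int = 100
    k_range: tuple[int, ...] = tuple(range(1, 7))
    erp_window: tuple[float, float] = (-200.0, 600.0)
    feature_set_sizes: dict = field(default_factory=lambda: {
        "spectrogram": 16, "phonetic": 8, "pitch": 6, "envelope": 3})
    stages: tuple[str, ...] = (
        "synth", "baseline", "encoding", "clustering", "attention", "variance")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = RunConfig(**raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    df = df.copy()
    df["config_hash"] = cfg.config_hash()
    df["seed"] = cfg.seed
    df.to_csv(path, index=False)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the result bundle.

    Any stage failure raises with the stage name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    bundle: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    timings: dict[str, float] = {}

    stage = "synth"
    try:
        t0 = time.time()
        segs = synthetic.gen_segmentation(
            cfg.n_sentences, cfg.frame_rate,
            phonemes_per_sentence=cfg.phonemes_per_sentence,
            seed=int(rng.integers(2**31 - 1)))
        feats_by_sentence = [
            synthetic.gen_feature_stream(s.n_frames, cfg.feature_set_sizes,
                                         seed=int(rng.integers(2**31 - 1)))
            for s in segs
        ]
        feats = FeatureStream.concat(feats_by_sentence, axis="frames")
        sentence_ids = np.concatenate(
            [np.full(s.n_frames, i) for i, s in enumerate(segs)])
        n_lags = encoding.n_lags_for_window(cfg.window_ms, cfg.frame_rate)
        truth = synthetic.gen_ground_truth(
            cfg.n_electrodes, feats.n_features, n_lags,
            noise_sd=cfg.noise_sd, seed=int(rng.integers(2**31 - 1)))
        resp = synthetic.gen_neural_responses(feats, truth)
        # planted depth gradient: early layers acoustic, late layers phonetic
        mix_grad = np.linspace(0, 1, cfg.n_layers)
        layer_specs = [
            synthetic.LayerSpec(
                mixing={"spectrogram": float(1 - g), "phonetic": float(g)},
                n_units=cfg.units_per_layer, noise_sd=0.5)
            for g in mix_grad
        ]
        acts = synthetic.gen_layer_activations(feats, layer_specs,
                                               seed=int(rng.integers(2**31 - 1)))
        # attention mixtures: weight on the current-phoneme template rises
        # with depth
        mixture = np.zeros((cfg.n_layers, 6))
        mixture[:, 0] = mix_grad
        att = [synthetic.gen_attention_matrices(
                   s, mixture, noise_sd=0.3, n_heads=cfg.n_heads,
                   seed=int(rng.integers(2**31 - 1)))
               for s in segs]
        bundle.update(segs=segs, features=feats, response=resp, truth=truth,
                      activations=acts, attention=att, sentence_ids=sentence_ids)
        timings[stage] = time.time() - t0

        if "baseline" in cfg.stages:
            stage = "baseline"
            t0 = time.time()
            lam = np.asarray(cfg.lambda_grid)
            r2_base = np.array([
                encoding.fit_encoding(feats, resp.activity[e], cfg.window_ms,
                                      lam, group_ids=sentence_ids).mean_r2
                for e in range(cfg.n_electrodes)
            ])
            bundle["r2_baseline"] = r2_base
            _write_csv(pd.DataFrame({
                "electrode": np.arange(cfg.n_electrodes),
                "r2_baseline": r2_base,
                "responsive": encoding.responsive_mask(r2_base),
            }), out / "baseline.csv", cfg)
            timings[stage] = time.time() - t0

        if "encoding" in cfg.stages:
            stage = "encoding"
            t0 = time.time()
            rows = []
            bps_per_layer = {}
            for layer, A in acts.items():
                layer_stream = FeatureStream(
                    A, cfg.frame_rate,
                    np.repeat("embedding", A.shape[0]),
                    np.array([f"{layer}_u{i}" for i in range(A.shape[0])], dtype=object))
                r2_model = np.array([
                    encoding.fit_encoding(layer_stream, resp.activity[e], cfg.window_ms,
                                          np.asarray(cfg.lambda_grid),
                                          group_ids=sentence_ids).mean_r2
                    for e in range(cfg.n_electrodes)
                ])
                bps = encoding.brain_prediction_score(r2_model, bundle["r2_baseline"])
                bps_per_layer[layer] = float(np.nanmean(bps))
                for e in range(cfg.n_electrodes):
                    rows.append({"electrode": e, "layer": layer,
                                 "window_ms": cfg.window_ms,
                                 "r2_model": r2_model[e],
                                 "r2_baseline": bundle["r2_baseline"][e],
                                 "bps": np.atleast_1d(bps)[e]})
            bundle["bps_per_layer"] = bps_per_layer
            _write_csv(pd.DataFrame(rows), out / "encoding.csv", cfg)
            timings[stage] = time.time() - t0

        if "clustering" in cfg.stages:
            stage = "clustering"
            t0 = time.time()
            onsets = np.array([np.nonzero(sentence_ids == i)[0][0]
                               for i in range(cfg.n_sentences)])
            fr = cfg.frame_rate
            lo = int(round(cfg.erp_window[0] * fr / 1000.0))
            hi = int(round(cfg.erp_window[1] * fr / 1000.0))
            ok = (onsets + lo >= 0) & (onsets + hi <= resp.n_frames)
            X = clustering.average_erp(resp, onsets[ok], cfg.erp_window)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                k, curve, fits = clustering.choose_k(X, cfg.k_range,
                                                     seed=int(rng.integers(2**31 - 1)))
            bundle["clusters"] = fits[k]
            _write_csv(pd.DataFrame({
                "electrode": np.arange(X.shape[1]),
                "cluster": fits[k].labels,
            }), out / "clusters.csv", cfg)
            _write_csv(pd.DataFrame({"k": list(cfg.k_range),
                                     "variance_explained": curve}),
                       out / "variance_curve.csv", cfg)
            timings[stage] = time.time() - t0

        if "attention" in cfg.stages:
            stage = "attention"
            t0 = time.time()
            templates = [attention.build_templates(s) for s in segs]
            as_by_context = attention.attention_scores_by_layer(att, templates)
            rows = [{"layer": x, "context": c, "as": v}
                    for c, vec in as_by_context.items() for x, v in enumerate(vec)]
            _write_csv(pd.DataFrame(rows), out / "attention_scores.csv", cfg)
            as_vec = as_by_context["phoneme(0)"]
            bps_vec = np.array(list(bundle["bps_per_layer"].values()))
            r_obs = attention.as_bps_correlation(as_vec, bps_vec)
            # the shuffling null needs equal-length sentence blocks: truncate
            # every sentence to the shortest one for the test only
            L_min = min(s.n_frames for s in segs)
            keep = np.concatenate([
                np.nonzero(sentence_ids == i)[0][:L_min]
                for i in range(cfg.n_sentences)])
            sid_t = sentence_ids[keep]

            def _trunc(values):
                return values[:, keep]

            layer_streams = {
                layer: FeatureStream(
                    _trunc(A), cfg.frame_rate, np.repeat("embedding", A.shape[0]),
                    np.array([f"u{i}" for i in range(A.shape[0])], dtype=object))
                for layer, A in acts.items()
            }
            feats_t = FeatureStream(_trunc(feats.values), cfg.frame_rate,
                                    feats.set_labels, feats.feature_names)
            _, p, _ = attention.permutation_null(
                layer_streams, feats_t, resp.activity[0][keep], sid_t, as_vec,
                n_perm=cfg.n_perm, seed=int(rng.integers(2**31 - 1)))
            bundle["as_bps"] = {"r": r_obs, "p": p}
            _write_csv(pd.DataFrame([{"context": "phoneme(0)", "r": r_obs, "p": p,
                                      "n_perm": cfg.n_perm}]),
                       out / "as_bps.csv", cfg)
            timings[stage] = time.time() - t0

        if "variance" in cfg.stages:
            stage = "variance"
            t0 = time.time()
            profiles = variance.profile_layers(
                acts, feats.subset(["spectrogram", "phonetic"]),
                window_ms=0.0, unit_cap=4,
                seed=int(rng.integers(2**31 - 1)),
                bps_per_layer=bundle.get("bps_per_layer"))
            bundle["profiles"] = profiles
            _write_csv(variance.profiles_to_frame(profiles),
                       out / "variance_profile.csv", cfg)
            timings[stage] = time.time() - t0
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {p.name: _file_hash(p)
                      for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle
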