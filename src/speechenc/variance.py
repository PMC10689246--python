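"""Layer-wise unique-variance profiles over named feature sets.

For each representation layer, every unit's activation time course is
modeled by the full multi-set encoding model and by reduced models that
each omit one feature set; the per-set drop in cross-validated R^2
(DeltaR^2) is averaged over units. Profiles across layers expose the
spectrogram-to-phonetic transformation a hierarchy performs, and can be
correlated with per-layer brain-prediction scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureStream
from .encoding import unique_variance
from .attention import pearson_permutation_p

DEFAULT_UNIT_CAP = 256


@dataclass
class LayerProfile:
    """Mean unique variance per feature set for one layer."""

    layer: str
    delta_r2: dict[str, float]
    full_r2: float
    n_units: int
    bps: float | None = None

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("unit count must be positive")


def profile_layers(
    activations: dict[str, np.ndarray],
    features: FeatureStream,
    window_ms: float = 400.0,
    unit_cap: int = DEFAULT_UNIT_CAP,
    seed: int = 0,
    bps_per_layer: dict[str, float] | None = None,
    **fit_kwargs,
) -> list[LayerProfile]:
    """Per-layer unique-variance profiles.

    ``activations`` maps layer label -> (n_units, n_frames) array aligned
    to the feature frame rate. Units beyond ``unit_cap`` are subsampled
    (seeded) to keep runtime desk-scale.
    """
    if not activations:
        raise ValueError("empty activation set")
    rng = np.random.default_rng(seed)
    profiles = []
    for layer, acts in activations.items():
        acts = np.atleast_2d(np.asarray(acts, float))
        if acts.shape[1] != features.n_frames:
            raise ValueError(
                f"layer {layer}: {acts.shape[1]} frames vs {features.n_frames} feature frames")
        idx = np.arange(acts.shape[0])
        if len(idx) > unit_cap:
            idx = np.sort(rng.choice(idx, unit_cap, replace=False))
        deltas: dict[str, list[float]] = {s: [] for s in features.sets}
        fulls = []
        for u in idx:
            full_r2, d = unique_variance(acts[u], features, window_ms, **fit_kwargs)
            fulls.append(full_r2)
            for s, v in d.items():
                deltas[s].append(v)
        profiles.append(LayerProfile(
            layer=layer,
            delta_r2={s: float(np.mean(v)) for s, v in deltas.items()},
            full_r2=float(np.mean(fulls)),
            n_units=len(idx),
            bps=None if bps_per_layer is None else bps_per_layer.get(layer),
        ))
    return profiles


def profiles_to_frame(profiles: list[LayerProfile]) -> pd.DataFrame:
    """Tidy (layer, set, mean DeltaR^2, n_units) table."""
    rows = []
    for p in profiles:
        for s, v in p.delta_r2.items():
            rows.append({"layer": p.layer, "set": s, "mean_delta_r2": v,
                         "full_r2": p.full_r2, "n_units": p.n_units, "bps": p.bps})
    return pd.DataFrame(rows)


def profile_bps_correlation(
    profiles: list[LayerProfile],
    set_name: str,
    area_bps: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation across layers between a set's DeltaR^2 profile and BPS.

    Returns (Pearson r, one-sided permutation p) where the null shuffles
    the layer pairing of the BPS vector.
    """
    prof = np.array([p.delta_r2[set_name] for p in profiles], float)
    bps = np.asarray(area_bps, float)
    if len(prof) != len(bps):
        raise ValueError("profile and BPS vectors have different layer counts")
    if len(prof) < 3:
        raise ValueError("need at least 3 layers")
    if np.std(prof) == 0 or np.std(bps) == 0:
        raise ValueError("constant profile: correlation undefined")
    return pearson_permutation_p(bps, prof, n_perm=n_perm, seed=seed)
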