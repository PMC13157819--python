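"""Autoregressive coarse-grained MD with a trained forecaster.

Replicas start from randomly selected held-out (test-split) history windows
and are rolled forward in a single batched forward pass per step: sample
R_{t+1} from the forecast distribution, append it to the history, drop the
oldest frame, repeat. The training-time input-noise layer is off, the six
pinned features stay exactly zero, and the tanh output bound keeps every
generated feature inside (-0.75, 0.75).

Each replica draws its Gaussian innovations from its own counter-style
substream (seed spawned per replica index), so a replica's trajectory is
independent of how many other replicas run beside it — batching is purely a
performance detail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .featurize import FeatureSeries, invert_scaler
from .model import PFCGModel, ForecastDistribution, sample_next
from .train import WindowDataset

__all__ = [
    "SimulationConfig",
    "initialize_histories",
    "run_autoregressive",
    "unscale_rollout",
    "displacement_variance",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_replicas: int = 8
    n_steps: int = 20_000
    save_stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_replicas < 1 or self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("replicas, steps and save_stride must be >= 1")


def initialize_histories(dataset: WindowDataset, n_replicas: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Pick n_replicas contiguous test-split windows as initial histories.

    Sampling is without replacement; if the test split holds fewer windows
    than replicas, sampling falls back to with-replacement (logged).
    """
    idx = dataset.split["test"]
    if idx.size == 0:
        raise ValueError("empty test split")
    if idx.size >= n_replicas:
        chosen = rng.choice(idx, size=n_replicas, replace=False)
    else:
        logger.warning(
            "test split has %d windows < %d replicas; sampling with "
            "replacement", idx.size, n_replicas,
        )
        chosen = rng.choice(idx, size=n_replicas, replace=True)
    return dataset.inputs[chosen].copy()


def run_autoregressive(model: PFCGModel, histories: np.ndarray,
                       config: SimulationConfig,
                       sigma_override: float | None = None) -> FeatureSeries:
    """Roll the forecaster forward; returns scaled features per replica.

    Output values have shape (n_replicas, n_saved + 1, 3N) — the last input
    frame is saved as frame 0. ``sigma_override = 0`` forces a deterministic
    rollout (mu only). Aborts with the step index on any non-finite sample.
    """
    h = np.array(histories, dtype=float)
    if h.ndim != 3 or h.shape[0] != config.n_replicas:
        raise ValueError("histories must be (n_replicas, l, 3N)")
    if h.shape[1] != model.config.history_len:
        raise ValueError(
            f"history length {h.shape[1]} != model history_len "
            f"{model.config.history_len}"
        )
    n_rep = config.n_replicas
    n_feat = model.config.n_features
    streams = [
        np.random.default_rng(np.random.SeedSequence(config.seed).spawn(n_rep)[r])
        for r in range(n_rep)
    ]
    n_saved = config.n_steps // config.save_stride
    out = np.empty((n_rep, n_saved + 1, n_feat))
    out[:, 0] = h[:, -1]
    for step in range(1, config.n_steps + 1):
        dist = model.predict(h)
        if sigma_override is not None and dist.sigma is not None:
            dist = ForecastDistribution(
                dist.mu, np.full_like(dist.sigma, sigma_override), dist.mask
            )
        if dist.sigma is None:
            z = None
        else:
            z = np.stack([s.standard_normal(n_feat) for s in streams])
        nxt = sample_next(dist, None, z=z)
        # keep generated features strictly inside the trained feature range;
        # the Gaussian tail beyond the tanh bound would otherwise push the
        # rollout into states the model never saw
        bound = model.config.mu_bound - 1e-9
        np.clip(nxt, -bound, bound, out=nxt)
        nxt[..., model.zero_mask] = 0.0
        if not np.all(np.isfinite(nxt)):
            bad = np.where(~np.isfinite(nxt).all(axis=1))[0]
            raise FloatingPointError(
                f"non-finite sample at step {step} (replicas {bad.tolist()})"
            )
        h = np.concatenate([h[:, 1:], nxt[:, None]], axis=1)
        if step % config.save_stride == 0:
            out[:, step // config.save_stride] = nxt
    return FeatureSeries(
        values=out,
        zero_mask=model.zero_mask,
        dt_save=1.0,
        scaler=model.scaler,
        scaled=True,
        metadata={"n_replicas": n_rep, "n_steps": config.n_steps,
                  "save_stride": config.save_stride, "seed": config.seed},
    )


def unscale_rollout(series: FeatureSeries) -> np.ndarray:
    """Map generated scaled features back to unscaled F-hat for analysis."""
    if series.scaler is None:
        raise ValueError("rollout carries no scaler")
    vals = invert_scaler(series.values, series.scaler)
    vals[..., series.zero_mask] = 0.0
    return vals


def displacement_variance(values: np.ndarray, burn_in: int = 100) -> float:
    """Mean per-step displacement variance after a burn-in.

    Near zero for a 'pinned' rollout (deterministic models collapsing to a
    fixed point); of order sigma^2 for a healthy probabilistic rollout.
    """
    x = values[:, burn_in:] if values.ndim == 3 else values[None, burn_in:]
    d = np.diff(x, axis=1)
    return float(np.mean(d**2))
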