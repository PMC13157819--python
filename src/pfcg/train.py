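"""Windowing, noise regularization, NLL loss, and two-stage training.

Training minimizes the Gaussian negative log likelihood of the one-step
transition, averaged over the batch and the unmasked features; by the usual
cross-entropy decomposition this drives the learned conditional toward the
data-generating conditional, with the path entropy as the unreachable floor
(the KL term is non-negative).

Stage 1 fits the Markovian block on single-step windows. Stage 2 freezes
theta_m and fits the non-Markovian block on windows carrying five future
frames, scored as five parallel teacher-forced one-step predictions (the
history for offset s is the true window ending at t+s-1; no rollout during
training). Inputs are corrupted with zero-mean Gaussian noise of width
sigma_g in scaled-feature space (resampled every batch draw, masked features
left at zero); noise is disabled at inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .featurize import FeatureSeries
from .model import PFCGModel

__all__ = [
    "WindowDataset",
    "TrainConfig",
    "make_windows",
    "corrupt_with_noise",
    "nll_loss",
    "mse_loss",
    "train_markovian_stage",
    "train_nonmarkovian_stage",
    "gaussian_entropy",
    "transfer_markovian_weights",
]


@dataclass
class WindowDataset:
    """(history, future) sample windows at spacing dt_steps * dt_save."""

    inputs: np.ndarray   # (samples, l, 3N)
    targets: np.ndarray  # (samples, n_future, 3N)
    zero_mask: np.ndarray
    dt_steps: int
    dt_save: float
    split: dict = field(default_factory=dict)  # name -> index array

    @property
    def n_samples(self):
        return self.inputs.shape[0]

    def subset(self, name: str):
        idx = self.split[name]
        return self.inputs[idx], self.targets[idx]


@dataclass
class TrainConfig:
    batch_size: int = 256
    sigma_g: float = 0.01
    learning_rate: float = 5e-5
    weight_decay: float = 0.1
    patience: int = 7
    max_epochs: int = 200
    optimizer: str = "lion"  # or "adamw"
    seed: int = 0

    def __post_init__(self):
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer not in ("lion", "adamw"):
            raise ValueError("optimizer must be 'lion' or 'adamw'")


def make_windows(
    features,
    l: int,
    dt_steps: int = 1,
    n_future: int = 1,
    max_samples: int | None = 50_000,
    split_seed: int = 0,
    split_fractions=(0.70, 0.15, 0.15),
) -> WindowDataset:
    """Slice feature series into contiguous windows at spacing dt_steps.

    ``features`` is one :class:`FeatureSeries` or a list of them (multiple
    trajectories; no window crosses a trajectory boundary). Each trajectory
    is first subsampled to every ``dt_steps``-th frame, then yields
    ``max(0, frames - l - n_future + 1)`` windows whose first ``l`` frames
    are the input and following ``n_future`` frames the targets. If
    ``max_samples`` caps the total, windows are kept at uniform stride.
    The sample index is shuffled and split 70/15/15 by default.
    """
    if isinstance(features, FeatureSeries):
        features = [features]
    if l < 1 or n_future < 1 or dt_steps < 1:
        raise ValueError("l, n_future and dt_steps must be >= 1")
    ins, outs = [], []
    for fs in features:
        frames = fs.values[::dt_steps]
        n_win = frames.shape[0] - l - n_future + 1
        if n_win <= 0:
            raise ValueError(
                f"trajectory too short: {fs.n_frames} frames gives no "
                f"window of length {l}+{n_future} at stride {dt_steps}"
            )
        sliding = np.lib.stride_tricks.sliding_window_view(
            frames, (l + n_future, frames.shape[1])
        )[:, 0]  # (n_win, l+n_future, 3N)
        ins.append(sliding[:, :l])
        outs.append(sliding[:, l:])
    inputs = np.concatenate(ins, axis=0)
    targets = np.concatenate(outs, axis=0)
    if max_samples is not None and inputs.shape[0] > max_samples:
        keep = np.linspace(0, inputs.shape[0] - 1, max_samples).astype(int)
        inputs, targets = inputs[keep], targets[keep]
    inputs = np.ascontiguousarray(inputs)
    targets = np.ascontiguousarray(targets)
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(inputs.shape[0])
    n = inputs.shape[0]
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    split = {
        "train": order[:n_train],
        "val": order[n_train:n_train + n_val],
        "test": order[n_train + n_val:],
    }
    fs0 = features[0]
    return WindowDataset(inputs, targets, fs0.zero_mask, dt_steps,
                         fs0.dt_save, split)


def corrupt_with_noise(inputs: np.ndarray, sigma_g: float,
                       rng: np.random.Generator,
                       zero_mask: np.ndarray | None = None) -> np.ndarray:
    """Add N(0, sigma_g^2) to every unmasked entry (training-time only)."""
    if sigma_g == 0.0:
        return inputs
    noisy = inputs + sigma_g * rng.standard_normal(inputs.shape)
    if zero_mask is not None:
        noisy[..., zero_mask] = inputs[..., zero_mask]
    return noisy


def nll_loss(mu, sigma, target, zero_mask):
    """Mean Gaussian negative log density over batch and unmasked features."""
    keep = ~np.asarray(zero_mask, dtype=bool)
    target = target if isinstance(target, nn.Tensor) else nn.Tensor(target)
    d = (target - mu)[:, keep]
    s = sigma[:, keep]
    return (0.5 * math.log(2.0 * math.pi) + s.log()
            + d * d / (2.0 * s * s)).mean()


def mse_loss(mu, target, zero_mask):
    keep = ~np.asarray(zero_mask, dtype=bool)
    target = target if isinstance(target, nn.Tensor) else nn.Tensor(target)
    d = (target - mu)[:, keep]
    return (d * d).mean()


def gaussian_entropy(sigma: float) -> float:
    """Differential entropy (nats) per dimension of N(mu, sigma^2)."""
    return 0.5 * math.log(2.0 * math.pi * math.e * sigma**2)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------


def _batch_loss(model: PFCGModel, xb, yb, freeze_markovian, training,
                noise_rng, dropout_rng, sigma_g):
    """Average teacher-forced one-step loss over all future offsets."""
    n_future = yb.shape[1]
    total = None
    for s in range(n_future):
        if s == 0:
            hist = xb
        else:
            hist = np.concatenate([xb[:, s:], yb[:, :s]], axis=1)
        if training and sigma_g > 0:
            hist = corrupt_with_noise(hist, sigma_g, noise_rng,
                                      model.zero_mask)
        mu, sigma = model.forward(hist, training=training, rng=dropout_rng,
                                  freeze_markovian=freeze_markovian)
        if model.config.probabilistic:
            loss = nll_loss(mu, sigma, yb[:, s], model.zero_mask)
        else:
            loss = mse_loss(mu, yb[:, s], model.zero_mask)
        total = loss if total is None else total + loss
    return total * (1.0 / n_future)


def _eval_loss(model, inputs, targets, freeze_markovian, batch_size=1024):
    losses, weights = [], []
    with nn.no_grad():
        for a in range(0, inputs.shape[0], batch_size):
            xb = inputs[a:a + batch_size]
            yb = targets[a:a + batch_size]
            loss = _batch_loss(model, xb, yb, freeze_markovian,
                               training=False, noise_rng=None,
                               dropout_rng=None, sigma_g=0.0)
            losses.append(float(loss.data))
            weights.append(xb.shape[0])
    return float(np.average(losses, weights=weights))


def _train_loop(model: PFCGModel, dataset: WindowDataset, config: TrainConfig,
                stage: str):
    freeze = stage == "nonmarkovian"
    params = model.theta_nm() if freeze else model.theta_m()
    if not params:
        raise ValueError(f"no trainable parameters for stage '{stage}'")
    if config.optimizer == "lion":
        opt = nn.Lion(params, lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    else:
        opt = nn.AdamW(params, lr=config.learning_rate,
                       weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(rng.integers(2**31))
    dropout_rng = np.random.default_rng(rng.integers(2**31))
    x_train, y_train = dataset.subset("train")
    x_val, y_val = dataset.subset("val")
    best_val = math.inf
    best_weights = None
    bad_epochs = 0
    log = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(x_train.shape[0])
        epoch_losses = []
        for a in range(0, order.size, config.batch_size):
            idx = order[a:a + config.batch_size]
            loss = _batch_loss(model, x_train[idx], y_train[idx], freeze,
                               training=True, noise_rng=noise_rng,
                               dropout_rng=dropout_rng,
                               sigma_g=config.sigma_g)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val = _eval_loss(model, x_val, y_val, freeze)
        log.append({"epoch": epoch, "train_nll": float(np.mean(epoch_losses)),
                    "val_nll": val})
        if val < best_val:
            best_val = val
            best_weights = [w.copy() for w in
                            (p.data for p in params)]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p.data = w
    x_test, y_test = dataset.subset("test")
    history = pd.DataFrame(log)
    history.attrs["test_nll"] = _eval_loss(model, x_test, y_test, freeze)
    history.attrs["best_val_nll"] = best_val
    history.attrs["stage"] = stage
    return history


def train_markovian_stage(dataset: WindowDataset, model: PFCGModel,
                          config: TrainConfig) -> pd.DataFrame:
    """Stage 1: fit theta_m on one-step windows; returns the loss log.

    The lowest-validation-loss weights are restored at the end; training
    stops once validation loss fails to improve for ``config.patience``
    consecutive epochs. Test NLL is stored in ``history.attrs``.
    """
    if model.config._uses_nm:
        raise ValueError("stage-1 model must be markovian/nonprobabilistic")
    return _train_loop(model, dataset, config, stage="markovian")


def train_nonmarkovian_stage(dataset: WindowDataset, model: PFCGModel,
                             config: TrainConfig) -> pd.DataFrame:
    """Stage 2: fit theta_nm with theta_m frozen (bit-identical afterwards).

    Expects windows with several (typically five) future frames; the loss is
    the mean of the teacher-forced one-step NLLs at each offset.
    """
    if not model.config._uses_nm:
        raise ValueError("stage-2 model must be non-Markovian")
    if model.markovian is None and model.config.mode == "nonmarkovian":
        raise ValueError("missing pretrained Markovian block")
    return _train_loop(model, dataset, config, stage="nonmarkovian")


def transfer_markovian_weights(src: PFCGModel, dst: PFCGModel):
    """Copy trained theta_m from a stage-1 model into a stage-2 model."""
    src_p, dst_p = src.theta_m(), dst.theta_m()
    if len(src_p) != len(dst_p):
        raise ValueError("Markovian architectures differ")
    for a, b in zip(src_p, dst_p):
        if a.data.shape != b.data.shape:
            raise ValueError("Markovian architectures differ")
        b.data = a.data.copy()
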