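"""The PFCG forecaster: a diagonal-Gaussian one-step transition model.

The model approximates the conditional density of the next coarse-grained
configuration given a history of scaled local-frame features,

    R_{t+1} ~ N(mu_{t+1}, diag(sigma_{t+1}^2)),

and splits its parameters into a Markovian part (effective force, a function
of R_t alone) and a non-Markovian part (effective memory, a function of the
trailing history of length l):

    mu_{t+1}    = R_t + mu_m (+ mu_nm),   then bounded by 0.75 tanh(. / 0.75)
    sigma_{t+1} = sigma_m (+ sigma_nm),   each block's sigma from a softplus

Both blocks share a transformer-style trunk: each scalar feature is embedded
as a token, multi-head self-attention mixes tokens, and a residual MLP stack
follows; the non-Markovian block first time-differences the history (a proxy
for velocities) and integrates it with a stacked GRU whose final hidden state
feeds the same trunk. The six features that the local frame transformation
pins to zero are overwritten to exactly zero at the output.

Ablation modes: ``nonprobabilistic`` (mu-only output, trained with MSE, so
inference is deterministic), ``nm_only`` (no Markovian block), and the
standard ``markovian`` / ``nonmarkovian`` pair.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .featurize import FeatureScaler

__all__ = [
    "ArchitectureConfig",
    "ForecastDistribution",
    "PFCGModel",
    "sample_next",
    "save_checkpoint",
    "load_checkpoint",
]

MODES = ("markovian", "nonmarkovian", "nonprobabilistic", "nm_only")
MASKED_SIGMA = 1e-12


@dataclass
class ArchitectureConfig:
    n_features: int
    history_len: int = 1
    h_dim: int = 24
    n_mha_mlp: int = 1
    n_heads: int = 4
    embed_dim: int = 8
    n_gru: int = 2
    mlp_hidden: int = 64
    dropout: float = 0.1
    mu_bound: float = 0.75
    tanh_inner_scale: bool = True
    mode: str = "markovian"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.history_len < 1:
            raise ValueError("history_len must be >= 1")
        if self._uses_nm and self.history_len < 2:
            raise ValueError("non-Markovian modes need history_len >= 2")
        if self._uses_nm and self.h_dim < self.n_features:
            raise ValueError("h_dim should be >= the feature count")

    @property
    def _uses_nm(self):
        return self.mode in ("nonmarkovian", "nm_only")

    @property
    def probabilistic(self):
        return self.mode != "nonprobabilistic"


@dataclass
class ForecastDistribution:
    """Diagonal Gaussian over the next scaled feature vector.

    ``sigma`` is None for the nonprobabilistic ablation. Numpy arrays at
    inference; the training path keeps autodiff tensors internally.
    """

    mu: np.ndarray
    sigma: np.ndarray | None
    mask: np.ndarray


class _AttentionTrunk(nn.Module):
    """Fig-style trunk: token embedding, repeated (MHA + MLP) cycles with
    residuals and layer norm, then a dropout MLP and a linear head."""

    def __init__(self, n_tokens, out_dim, cfg: ArchitectureConfig, rng,
                 zero_init_head=False):
        e = cfg.embed_dim
        self.n_tokens = n_tokens
        self.embed = nn.Linear(1, e, rng)
        self.mha = [nn.MultiheadAttention(e, cfg.n_heads, rng)
                    for _ in range(cfg.n_mha_mlp)]
        self.ln_att = [nn.LayerNorm(e) for _ in range(cfg.n_mha_mlp)]
        flat = n_tokens * e
        self.mlp = [nn.MLP([flat, cfg.mlp_hidden, cfg.mlp_hidden, flat], rng)
                    for _ in range(cfg.n_mha_mlp)]
        self.ln_mlp = [nn.LayerNorm(flat) for _ in range(cfg.n_mha_mlp)]
        self.final_mlp = nn.MLP([flat, cfg.mlp_hidden, cfg.mlp_hidden], rng)
        self.head = nn.Linear(cfg.mlp_hidden, out_dim, rng,
                              zero_init=zero_init_head)
        self.dropout = cfg.dropout

    def __call__(self, x, training=False, rng=None):
        # x: (batch, n_tokens)
        b = x.shape[0]
        h = self.embed(x.reshape(b, self.n_tokens, 1))
        for mha, ln_a, mlp, ln_m in zip(self.mha, self.ln_att,
                                        self.mlp, self.ln_mlp):
            h = ln_a(h + mha(h))
            flat = h.reshape(b, -1)
            flat = ln_m(flat + mlp(flat))
            h = flat.reshape(h.shape)
        out = self.final_mlp(h.reshape(b, -1)).silu()
        out = nn.apply_dropout(out, self.dropout, rng, training)
        return self.head(out)


class PFCGModel(nn.Module):
    """Markovian + non-Markovian probabilistic forecaster.

    Parameters are partitioned into ``theta_m`` (Markovian block) and
    ``theta_nm`` (non-Markovian block) so the second training stage can
    freeze the first.
    """

    def __init__(self, config: ArchitectureConfig, zero_mask: np.ndarray,
                 scaler: FeatureScaler | None = None, seed: int = 0):
        self.config = config
        self.zero_mask = np.asarray(zero_mask, dtype=bool)
        if self.zero_mask.shape != (config.n_features,):
            raise ValueError("zero_mask length must equal n_features")
        self.scaler = scaler
        rng = np.random.default_rng(seed)
        f = config.n_features
        out_dim = 2 * f if config.probabilistic else f
        self.markovian = None
        self.nonmarkovian = None
        self.gru = None
        if config.mode != "nm_only":
            self.markovian = _AttentionTrunk(f, out_dim, config, rng)
        if config._uses_nm:
            self.gru = nn.GRU(f, config.h_dim, config.n_gru, rng)
            # zero-initialized head: the non-Markovian block starts as an
            # exact no-op on top of the trained Markovian block
            self.nonmarkovian = _AttentionTrunk(config.h_dim, out_dim,
                                                config, rng,
                                                zero_init_head=True)

    # -- parameter groups -------------------------------------------------

    def theta_m(self):
        return self.markovian.parameters() if self.markovian else []

    def theta_nm(self):
        params = []
        if self.gru is not None:
            params += self.gru.parameters()
        if self.nonmarkovian is not None:
            params += self.nonmarkovian.parameters()
        return params

    def parameters(self):
        return self.theta_m() + self.theta_nm()

    # -- forward passes ----------------------------------------------------

    def _split_head_raw(self, raw):
        f = self.config.n_features
        if not self.config.probabilistic:
            return raw, None
        return raw[:, :f], raw[:, f:]

    def markovian_forward(self, r_t, training=False, rng=None):
        """(mu_m, sigma_m) from the current configuration (batch, 3N)."""
        mu, raw_sigma = self._markovian_raw(r_t, training, rng)
        return mu, None if raw_sigma is None else raw_sigma.softplus()

    def _markovian_raw(self, r_t, training=False, rng=None):
        r_t = r_t if isinstance(r_t, nn.Tensor) else nn.Tensor(r_t)
        raw = self.markovian(r_t, training=training, rng=rng)
        return self._split_head_raw(raw)

    def nonmarkovian_forward(self, history, training=False, rng=None):
        """(mu_nm, sigma_nm) from the history (batch, l, 3N).

        The history is time-differenced (R_j - R_{j-1}) before the GRU, so
        any constant offset of the whole history leaves the output unchanged.
        """
        mu, raw_sigma = self._nonmarkovian_raw(history, training, rng)
        return mu, None if raw_sigma is None else raw_sigma.softplus()

    def _nonmarkovian_raw(self, history, training=False, rng=None):
        h = history if isinstance(history, nn.Tensor) else nn.Tensor(history)
        if h.shape[1] < 2:
            raise ValueError("non-Markovian forward needs history length >= 2")
        diff = h[:, 1:, :] - h[:, :-1, :]
        hidden = self.gru(diff)
        raw = self.nonmarkovian(hidden, training=training, rng=rng)
        return self._split_head_raw(raw)

    def forward(self, history, training=False, rng=None,
                freeze_markovian=False):
        """Full forecast from a history batch (batch, l, 3N).

        Returns autodiff tensors ``(mu, sigma)``; use :meth:`predict` for a
        numpy :class:`ForecastDistribution`. ``freeze_markovian`` detaches
        the Markovian block so no gradient reaches theta_m.
        """
        h = history if isinstance(history, nn.Tensor) else nn.Tensor(history)
        r_t = h[:, -1, :]
        cfg = self.config
        mu_parts, raw_sigma_parts = [], []
        if self.markovian is not None:
            if freeze_markovian:
                with nn.no_grad():
                    mu_m, raw_m = self._markovian_raw(
                        nn.Tensor(r_t.data), training=training, rng=rng)
                mu_m = nn.Tensor(mu_m.data)
                raw_m = None if raw_m is None else nn.Tensor(raw_m.data)
            else:
                mu_m, raw_m = self._markovian_raw(r_t, training=training,
                                                  rng=rng)
            mu_parts.append(mu_m)
            raw_sigma_parts.append(raw_m)
        if cfg._uses_nm:
            mu_nm, raw_nm = self._nonmarkovian_raw(h, training=training,
                                                   rng=rng)
            mu_parts.append(mu_nm)
            raw_sigma_parts.append(raw_nm)
        mu_raw = r_t
        for part in mu_parts:
            mu_raw = mu_raw + part
        b = cfg.mu_bound
        mu = (mu_raw * (1.0 / b)).tanh() * b if cfg.tanh_inner_scale \
            else mu_raw.tanh() * b
        keep = nn.Tensor((~self.zero_mask).astype(float))
        mu = mu * keep
        if not cfg.probabilistic:
            return mu, None
        # additive raw contributions, single softplus: a zero-initialized
        # non-Markovian head is an exact no-op on top of the Markovian block
        raw = raw_sigma_parts[0]
        for part in raw_sigma_parts[1:]:
            raw = raw + part
        sigma = raw.softplus()
        sigma = sigma * keep + nn.Tensor(self.zero_mask * MASKED_SIGMA)
        return mu, sigma

    def predict(self, history, freeze_markovian=False) -> ForecastDistribution:
        """Inference forecast: numpy in, numpy out, no graph, no dropout."""
        with nn.no_grad():
            mu, sigma = self.forward(np.asarray(history, dtype=float))
        return ForecastDistribution(
            mu=mu.data, sigma=None if sigma is None else sigma.data,
            mask=self.zero_mask,
        )


def sample_next(dist: ForecastDistribution, rng: np.random.Generator,
                z: np.ndarray | None = None) -> np.ndarray:
    """Draw R_{t+1} = mu + sigma * z with masked entries exactly zero.

    ``z`` may be supplied (per-replica substreams); otherwise drawn from
    ``rng``. The nonprobabilistic ablation returns mu deterministically.
    """
    mu = dist.mu
    if dist.sigma is None:
        out = mu.copy()
    else:
        if z is None:
            z = rng.standard_normal(mu.shape)
        out = mu + dist.sigma * z
    out[..., dist.mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: PFCGModel, extra: dict | None = None):
    """Single-file checkpoint: weight arrays + JSON metadata."""
    meta = {
        "config": asdict(model.config),
        "zero_mask": model.zero_mask.tolist(),
        "scaler": model.scaler.to_dict() if model.scaler else None,
        "extra": extra or {},
        "format_version": 1,
    }
    arrays = {f"w{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> PFCGModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    cfg = ArchitectureConfig(**meta["config"])
    scaler = (FeatureScaler.from_dict(meta["scaler"])
              if meta["scaler"] else None)
    model = PFCGModel(cfg, np.asarray(meta["zero_mask"], dtype=bool), scaler)
    model.load_arrays(arrays)
    return model
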