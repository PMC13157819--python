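"""Windowing, loss oracles, noise regularization, and the two-stage loop."""

import hashlib
import math

import numpy as np
import pytest

from pfcg import (
    ArchitectureConfig,
    FeatureSeries,
    PFCGModel,
    TrainConfig,
    corrupt_with_noise,
    gaussian_entropy,
    make_windows,
    nll_loss,
    train_markovian_stage,
    train_nonmarkovian_stage,
    transfer_markovian_weights,
)
from pfcg import nn

NFEAT = 12
MASK = np.zeros(NFEAT, dtype=bool)
MASK[[3, 4, 5, 7, 8, 11]] = True


def series_of(values, dt_save=1.0):
    values = np.asarray(values, dtype=float)
    values[..., MASK] = 0.0
    return FeatureSeries(values, MASK, dt_save, scaled=True)


def ar1_series(n, a=0.9, sigma=0.05, seed=0):
    rng = np.random.default_rng(seed)
    x = np.zeros((n, NFEAT))
    for t in range(1, n):
        x[t] = a * x[t - 1] + sigma * rng.standard_normal(NFEAT)
    return series_of(x)


# -- windowing ---------------------------------------------------------------


def test_window_counts():
    assert make_windows(series_of(np.zeros((101, NFEAT))), l=1,
                        n_future=1, max_samples=None).n_samples == 100
    ds = make_windows(series_of(np.zeros((100, NFEAT))), l=75, n_future=5,
                      max_samples=None)
    assert ds.n_samples == 100 - 75 - 5 + 1 == 21
    assert ds.inputs.shape == (21, 75, NFEAT)
    assert ds.targets.shape == (21, 5, NFEAT)


def test_windows_never_cross_trajectory_boundaries():
    a = series_of(np.full((30, NFEAT), 1.0))
    b = series_of(np.full((40, NFEAT), 2.0))
    ds = make_windows([a, b], l=3, n_future=2, max_samples=None)
    assert ds.n_samples == (30 - 4) + (40 - 4)
    # every window is constant: it came from exactly one trajectory
    whole = np.concatenate([ds.inputs, ds.targets], axis=1)[..., ~MASK]
    assert np.all(whole.min(axis=(1, 2)) == whole.max(axis=(1, 2)))


def test_window_stride_and_too_short_errors():
    ds = make_windows(series_of(np.arange(100)[:, None]
                                * np.ones((1, NFEAT))),
                      l=2, dt_steps=10, n_future=1, max_samples=None)
    assert ds.n_samples == 10 - 2 - 1 + 1
    step = ds.inputs[0, 1, 0] - ds.inputs[0, 0, 0]
    assert step == 10  # Delta t spacing in saved frames
    with pytest.raises(ValueError):
        make_windows(series_of(np.zeros((5, NFEAT))), l=10, n_future=1)


def test_split_is_disjoint_and_seed_deterministic():
    s = series_of(np.random.default_rng(0).standard_normal((500, NFEAT)))
    d1 = make_windows(s, l=1, n_future=1, split_seed=5, max_samples=None)
    d2 = make_windows(s, l=1, n_future=1, split_seed=5, max_samples=None)
    all_idx = np.concatenate([d1.split[k] for k in ("train", "val", "test")])
    assert np.array_equal(np.sort(all_idx), np.arange(d1.n_samples))
    assert len(d1.split["train"]) == round(0.7 * d1.n_samples)
    for k in d1.split:
        assert np.array_equal(d1.split[k], d2.split[k])


def test_sample_cap_uses_uniform_stride():
    s = series_of(np.arange(1001)[:, None] * np.ones((1, NFEAT)))
    ds = make_windows(s, l=1, n_future=1, max_samples=100)
    assert ds.n_samples == 100
    starts = ds.inputs[:, 0, 0]
    gaps = np.diff(np.sort(starts))
    assert gaps.max() - gaps.min() <= 1  # near-uniform coverage


# -- noise -------------------------------------------------------------------


def test_corrupt_with_noise_contract():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2000, 5, NFEAT))
    x[..., MASK] = 0.0
    assert corrupt_with_noise(x, 0.0, rng, MASK) is x
    noisy = corrupt_with_noise(x, 0.01, np.random.default_rng(1), MASK)
    delta = (noisy - x)[..., ~MASK].ravel()
    assert delta.std() == pytest.approx(0.01, rel=0.02)
    assert abs(delta.mean()) < 4 * 0.01 / math.sqrt(delta.size)
    assert np.array_equal(noisy[..., MASK], x[..., MASK])


# -- loss oracles ------------------------------------------------------------


def test_nll_closed_form_values():
    mu = nn.Tensor(np.zeros((4, NFEAT)))
    target = np.zeros((4, NFEAT))
    # sigma = (2 pi)^(-1/2): unit density, loss exactly 0
    s0 = nn.Tensor(np.full((4, NFEAT), (2 * math.pi) ** -0.5))
    assert float(nll_loss(mu, s0, target, MASK).data) == pytest.approx(
        0.0, abs=1e-12)
    # sigma = 1 at the mean: loss = ln(2 pi) / 2
    s1 = nn.Tensor(np.ones((4, NFEAT)))
    assert float(nll_loss(mu, s1, target, MASK).data) == pytest.approx(
        0.5 * math.log(2 * math.pi), abs=1e-12)


def test_nll_minimized_at_sample_mean_and_biased_std():
    rng = np.random.default_rng(2)
    target = rng.normal(0.3, 0.7, size=(500, NFEAT))
    target[:, MASK] = 0.0
    m_hat = target[:, ~MASK].mean()
    s_hat = target[:, ~MASK].std()  # biased ML estimate

    def loss_at(m, s):
        mu = nn.Tensor(np.full((500, NFEAT), m))
        sg = nn.Tensor(np.full((500, NFEAT), s))
        return float(nll_loss(mu, sg, target, MASK).data)

    best = loss_at(m_hat, s_hat)
    for dm, ds in [(0.05, 0), (-0.05, 0), (0, 0.05), (0, -0.05),
                   (0.02, 0.02)]:
        assert loss_at(m_hat + dm, s_hat + ds) > best


def test_gaussian_entropy_value():
    assert gaussian_entropy(1.0) == pytest.approx(
        0.5 * math.log(2 * math.pi * math.e))


# -- training loops ----------------------------------------------------------


def tiny_dataset(n=600, l=1, n_future=1, seed=0):
    return make_windows(ar1_series(n + 50, seed=seed), l=l,
                        n_future=n_future, max_samples=None)


def test_training_reaches_conditional_gaussian_entropy(ar1_trained):
    """Validation NLL approaches the generator's per-dimension path entropy
    (the KL gap shrinks toward the entropy floor)."""
    floor = ar1_trained["entropy_floor"]
    best = ar1_trained["best_val_nll"]
    assert best >= floor - 0.02  # KL non-negativity up to estimation noise
    assert abs(best - floor) <= 0.05 * abs(floor)


def test_training_is_seed_reproducible():
    kw = dict(optimizer="adamw", learning_rate=1e-3, max_epochs=3, seed=9)
    logs = []
    for _ in range(2):
        model = PFCGModel(ArchitectureConfig(NFEAT, 1, mode="markovian"),
                          MASK, seed=1)
        logs.append(train_markovian_stage(tiny_dataset(), model,
                                          TrainConfig(**kw)))
    assert np.array_equal(logs[0]["train_nll"].values,
                          logs[1]["train_nll"].values)
    assert np.array_equal(logs[0]["val_nll"].values, logs[1]["val_nll"].values)


def test_early_stopping_after_patience_epochs():
    """With a zero learning rate the validation loss never improves, so
    training halts after exactly 1 + patience epochs (default patience 7)."""
    model = PFCGModel(ArchitectureConfig(NFEAT, 1, mode="markovian"),
                      MASK, seed=0)
    cfg = TrainConfig(optimizer="adamw", learning_rate=0.0, max_epochs=50,
                      seed=0)
    history = train_markovian_stage(tiny_dataset(), model, cfg)
    assert len(history) == 1 + cfg.patience == 8


def _theta_digest(params):
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def test_nonmarkovian_stage_freezes_markovian_weights():
    ds1 = tiny_dataset(l=1)
    m1 = PFCGModel(ArchitectureConfig(NFEAT, 1, mode="markovian"), MASK,
                   seed=0)
    train_markovian_stage(ds1, m1, TrainConfig(optimizer="adamw",
                                               learning_rate=1e-3,
                                               max_epochs=2, seed=0))
    ds5 = tiny_dataset(l=4, n_future=5)
    m2 = PFCGModel(ArchitectureConfig(NFEAT, 4, mode="nonmarkovian"),
                   MASK, seed=0)
    transfer_markovian_weights(m1, m2)
    digest_before = _theta_digest(m2.theta_m())
    history = train_nonmarkovian_stage(
        ds5, m2, TrainConfig(optimizer="adamw", learning_rate=1e-3,
                             max_epochs=2, seed=0))
    assert _theta_digest(m2.theta_m()) == digest_before
    assert len(history) >= 1


def test_stage_mode_validation():
    ds = tiny_dataset()
    nm = PFCGModel(ArchitectureConfig(NFEAT, 4, mode="nonmarkovian"),
                   MASK, seed=0)
    with pytest.raises(ValueError):
        train_markovian_stage(ds, nm, TrainConfig())
    m = PFCGModel(ArchitectureConfig(NFEAT, 1, mode="markovian"), MASK,
                  seed=0)
    with pytest.raises(ValueError):
        train_nonmarkovian_stage(ds, m, TrainConfig())
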