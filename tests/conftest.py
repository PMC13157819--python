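"""Shared fixtures: reference simulations and trained desk-scale models.

The heavy session-scoped fixtures are shared between the end-to-end
acceptance checks so each reference trajectory is simulated once and each
model is trained once per session.
"""

import numpy as np
import pytest

from pfcg import (
    ArchitectureConfig,
    ChainPotential,
    GLEParams,
    LangevinParams,
    PFCGModel,
    TrainConfig,
    featurize_trajectory,
    invert_scaler,
    make_windows,
    simulate_gle_chain,
    simulate_langevin_chain,
    train_markovian_stage,
    train_nonmarkovian_stage,
    transfer_markovian_weights,
)


def unscaled_reference(series):
    ref = invert_scaler(series.values, series.scaler)
    ref[:, series.zero_mask] = 0.0
    return ref


@pytest.fixture(scope="session")
def chain_potential():
    return ChainPotential()


@pytest.fixture(scope="session")
def langevin_reference(chain_potential):
    """Markovian double-well chain: 4e6 steps saved every 40 (1e5 frames)."""
    traj = simulate_langevin_chain(
        chain_potential,
        LangevinParams(gamma=1.0, n_steps=4_000_000, seed=11),
        save_stride=40,
    )
    series = featurize_trajectory(traj, fit=True)
    return {"traj": traj, "series": series, "ref": unscaled_reference(series)}


@pytest.fixture(scope="session")
def gle_reference(chain_potential):
    """Strong-memory GLE chain: kernel friction 8, memory time 2.0."""
    traj = simulate_gle_chain(
        chain_potential,
        GLEParams(gamma=0.1, c2=8.0, tau_m=2.0, n_steps=2_000_000, seed=21),
        save_stride=20,
    )
    series = featurize_trajectory(traj, fit=True)
    return {"traj": traj, "series": series, "ref": unscaled_reference(series)}


@pytest.fixture(scope="session")
def gle_fine_reference(chain_potential):
    """Same GLE chain saved every 5 steps (near-deterministic transitions)."""
    traj = simulate_gle_chain(
        chain_potential,
        GLEParams(gamma=0.1, c2=8.0, tau_m=2.0, n_steps=2_000_000, seed=21),
        save_stride=5,
    )
    series = featurize_trajectory(traj, fit=True)
    return {"series": series, "ref": unscaled_reference(series)}


def train_markovian(series, *, dt_steps=1, sigma_g=0.01, max_epochs=15,
                    mode="markovian", max_samples=20_000, seed=0):
    ds = make_windows(series, l=1, dt_steps=dt_steps, n_future=1,
                      max_samples=max_samples)
    net = PFCGModel(
        ArchitectureConfig(series.n_features, history_len=1, mode=mode),
        series.zero_mask, scaler=series.scaler, seed=seed,
    )
    cfg = TrainConfig(optimizer="adamw", learning_rate=1e-3,
                      max_epochs=max_epochs, sigma_g=sigma_g, seed=seed)
    history = train_markovian_stage(ds, net, cfg)
    return net, ds, history


@pytest.fixture(scope="session")
def ar1_trained():
    """Markovian model trained on a known conditional-Gaussian process.

    Each unmasked feature follows x_{t+1} = 0.9 x_t + 0.05 z, whose
    conditional (path) entropy per dimension is known in closed form; the
    fixture returns the best validation NLL and that analytic floor.
    """
    from pfcg import FeatureSeries, gaussian_entropy

    a_true, sigma_true, n_feat, n_frames = 0.9, 0.05, 12, 30_000
    mask = np.zeros(n_feat, dtype=bool)
    mask[[3, 4, 5, 7, 8, 11]] = True
    rng = np.random.default_rng(0)
    x = np.zeros((n_frames, n_feat))
    for t in range(1, n_frames):
        x[t] = a_true * x[t - 1] + sigma_true * rng.standard_normal(n_feat)
    x[:, mask] = 0.0
    series = FeatureSeries(x, mask, 1.0, scaled=True)
    ds = make_windows(series, l=1, n_future=1, max_samples=None)
    model = PFCGModel(
        ArchitectureConfig(n_feat, 1, mode="markovian", dropout=0.0),
        mask, seed=0,
    )
    history = train_markovian_stage(
        ds, model,
        TrainConfig(optimizer="adamw", learning_rate=1e-3, max_epochs=40,
                    sigma_g=0.0, seed=0),
    )
    return {"best_val_nll": history.attrs["best_val_nll"],
            "entropy_floor": gaussian_entropy(sigma_true)}


@pytest.fixture(scope="session")
def gle_markovian(gle_reference):
    net, ds, history = train_markovian(gle_reference["series"])
    return {"model": net, "dataset": ds, "history": history}


@pytest.fixture(scope="session")
def gle_nonmarkovian(gle_reference, gle_markovian):
    series = gle_reference["series"]
    ds = make_windows(series, l=10, dt_steps=1, n_future=5,
                      max_samples=15_000)
    net = PFCGModel(
        ArchitectureConfig(series.n_features, history_len=10,
                           mode="nonmarkovian"),
        series.zero_mask, scaler=series.scaler, seed=0,
    )
    transfer_markovian_weights(gle_markovian["model"], net)
    history = train_nonmarkovian_stage(
        ds, net,
        TrainConfig(optimizer="adamw", learning_rate=1e-3, max_epochs=20,
                    seed=0),
    )
    return {"model": net, "dataset": ds, "history": history}
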