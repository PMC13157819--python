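"""Fidelity metrics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from pfcg import (
    acf,
    analytic_ou_acf,
    build_msm,
    epsilon_acf,
    fit_tica,
    hist2d,
    jsd_2d,
    mare_mfpt,
    mfpt,
    pmf_2d,
    project_tica,
)
from pfcg.analyze import MSMResult, shared_range


def ou_series(n, rho, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = 0.0
    noise = math.sqrt(1 - rho**2) * rng.standard_normal(n)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + noise[t]
    return scale * x


# -- TICA --------------------------------------------------------------------


def test_tica_recovers_slow_process_from_linear_mixture():
    n = 100_000
    slow = ou_series(n, math.exp(-1 / 10), seed=0)   # relaxation 10 frames
    fast = ou_series(n, math.exp(-1 / 1), seed=1)    # relaxation 1 frame
    mix = np.stack([0.7 * slow + 0.3 * fast,
                    -0.4 * slow + 0.9 * fast,
                    0.2 * slow - 0.5 * fast], axis=1)
    model = fit_tica(mix, lag=5, n_components=2)
    tic1 = project_tica(mix, model)[:, 0]
    corr = np.corrcoef(tic1, slow)[0, 1]
    assert abs(corr) > 0.99
    assert np.all(np.diff(model.eigenvalues) <= 1e-12)  # sorted descending
    assert model.eigenvalues.max() <= 1.0 + 1e-8


def test_tica_eigenvalue_identity_on_fitting_data():
    """lag-tau autocovariance of TIC_i equals lambda_i * var(TIC_i)."""
    n = 50_000
    data = np.stack([ou_series(n, 0.9, s) for s in range(3)], axis=1)
    lag = 3
    model = fit_tica(data, lag=lag, n_components=3)
    tics = project_tica(data, model)
    for i in range(3):
        x = tics[:, i] - tics[:, i].mean()
        autocov = np.mean(x[:-lag] * x[lag:])
        var = np.mean(x * x)
        assert autocov == pytest.approx(model.eigenvalues[i] * var,
                                        rel=0.05, abs=1e-4)


def test_tica_tolerates_constant_columns():
    n = 20_000
    data = np.stack([ou_series(n, 0.9, 0), np.zeros(n), np.zeros(n)], axis=1)
    model = fit_tica(data, lag=5, n_components=2)
    # constant (masked) features get ~zero loading on the leading component
    lead = model.projection[:, 0]
    assert abs(lead[1]) < 1e-6 * abs(lead[0])
    assert abs(lead[2]) < 1e-6 * abs(lead[0])


# -- PMF and JSD -------------------------------------------------------------


def test_pmf_uniform_occupancy_is_flat_zero():
    edges = np.linspace(0, 1, 4)
    centers = 0.5 * (edges[:-1] + edges[1:])
    grid = np.array([(x, y) for x in centers for y in centers])
    pmf, _ = pmf_2d(grid, bins=3, ranges=[(0, 1), (0, 1)])
    assert np.abs(pmf).max() < 1e-12


def test_pmf_two_state_free_energy_difference():
    # occupancy 0.8 / 0.2 -> Delta F = kT ln 4
    samples = np.array([[0.25, 0.5]] * 8 + [[0.75, 0.5]] * 2)
    pmf, _ = pmf_2d(samples, bins=2, kT=1.0, ranges=[(0, 1), (0, 1)])
    finite = pmf[np.isfinite(pmf)]
    assert finite.min() == 0.0
    assert finite.max() == pytest.approx(math.log(4.0), abs=1e-12)


def test_jsd_identity_symmetry_and_bounds():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((5000, 2))
    b = rng.standard_normal((5000, 2)) + 0.5
    ranges = shared_range(a, b)
    ha, hb = hist2d(a, 24, ranges), hist2d(b, 24, ranges)
    assert jsd_2d(ha, ha) == 0.0
    assert jsd_2d(ha, hb) == pytest.approx(jsd_2d(hb, ha))
    assert 0.0 < jsd_2d(ha, hb) < math.log(2.0)


def test_jsd_disjoint_supports_reach_ln2():
    left = np.full((100, 2), 0.2)
    right = np.full((100, 2), 0.8)
    ranges = [(0, 1), (0, 1)]
    assert jsd_2d(hist2d(left, 4, ranges),
                  hist2d(right, 4, ranges)) == pytest.approx(math.log(2.0),
                                                             abs=1e-15)


def test_jsd_two_bin_brute_force_value():
    """P=(1,0), Q=(0.5,0.5): direct summation gives 0.21576."""
    p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])
    m = 0.5 * (p + q)
    expected = 0.5 * sum(pi * math.log(pi / mi) for pi, mi in zip(p, m)
                         if pi > 0) \
        + 0.5 * sum(qi * math.log(qi / mi) for qi, mi in zip(q, m) if qi > 0)
    assert expected == pytest.approx(0.21576, abs=5e-6)
    grid_p = hist2d(np.array([[0.25, 0.5]] * 10), 2, [(0, 1), (0, 1)])
    grid_q = hist2d(np.array([[0.25, 0.5]] * 5 + [[0.75, 0.5]] * 5), 2,
                    [(0, 1), (0, 1)])
    assert jsd_2d(grid_p, grid_q) == pytest.approx(expected, abs=1e-12)


def test_jsd_binning_mismatch_raises():
    a = hist2d(np.random.default_rng(0).random((100, 2)), 8, [(0, 1), (0, 1)])
    b = hist2d(np.random.default_rng(1).random((100, 2)), 9, [(0, 1), (0, 1)])
    with pytest.raises(ValueError):
        jsd_2d(a, b)


# -- ACF ---------------------------------------------------------------------


def test_acf_lag_zero_and_white_noise_bound():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(40_000)
    curve = acf(x, 20)
    assert curve[0] == 1.0
    assert np.abs(curve[1:]).max() < 4 / math.sqrt(x.size)


def test_acf_of_ou_matches_analytic_curve():
    gamma = 0.1  # per frame
    x = ou_series(300_000, math.exp(-gamma), seed=2)
    est = acf(x, 30)
    ref = analytic_ou_acf(gamma, np.arange(31).astype(float))
    assert est[10] == pytest.approx(math.exp(-1.0), abs=0.03)
    assert np.abs(est - ref).max() < 0.05


def test_acf_replica_averaging_and_errors():
    reps = [ou_series(5000, 0.9, s) for s in range(4)]
    curve = acf(reps, 10)
    assert curve[0] == 1.0
    with pytest.raises(ValueError):
        acf(np.zeros(100), 10)  # zero variance
    with pytest.raises(ValueError):
        acf(np.ones(5) + np.arange(5), 10)  # lag too long


def test_epsilon_acf_definition():
    a = np.array([1.0, 0.5, 0.2])
    b = np.array([1.0, 0.3, 0.0])
    assert epsilon_acf(a, a) == 0.0
    assert epsilon_acf(a, b) == pytest.approx((0.04 + 0.04) / 3)
    assert epsilon_acf([a, a], [b, a]) == pytest.approx(epsilon_acf(a, b))


# -- MSM / MFPT --------------------------------------------------------------


def simulate_dtraj(t_mat, n_steps, seed, start=0):
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps, dtype=int)
    states[0] = start
    cum = np.cumsum(t_mat, axis=1)
    draws = rng.random(n_steps)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum[states[t - 1]], draws[t])
    return states


def test_two_state_msm_closed_form():
    t_true = np.array([[0.9, 0.1], [0.2, 0.8]])
    dtraj = simulate_dtraj(t_true, 400_000, seed=3)
    tics = dtraj[:, None].astype(float)
    msm = build_msm(tics, lag=1, n_micro=2, seed=0)
    # macrostates coincide with microstates
    assert set(msm.macro_of_micro.tolist()) == {0, 1}
    perm = msm.clustering.predict(np.array([[0.0], [1.0]]))
    t_est = msm.transition_matrix[np.ix_(perm, perm)]
    assert np.abs(t_est - t_true).max() < 0.01
    assert np.allclose(msm.transition_matrix.sum(axis=1), 1.0, atol=1e-12)
    # implied timescale of the exact chain: -lag / ln(0.7)
    its_true = -1 / math.log(0.7)
    assert msm.implied_timescales[0] == pytest.approx(its_true, rel=0.05)


def test_block_structured_chain_recovers_macrostates():
    eps = 0.02
    t_true = np.array([
        [0.70 - eps / 2, 0.30, eps / 2, 0.0],
        [0.30, 0.70 - eps / 2, 0.0, eps / 2],
        [eps / 2, 0.0, 0.70 - eps / 2, 0.30],
        [0.0, eps / 2, 0.30, 0.70 - eps / 2],
    ])
    dtraj = simulate_dtraj(t_true, 200_000, seed=4)
    # embed microstates at separated 2D points so k-means finds them
    coords = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 1.0], [1.1, 1.0]])
    msm = build_msm(coords[dtraj], lag=1, n_micro=4, seed=1)
    centers = msm.clustering.cluster_centers_[msm.active_set]
    blocks = (centers[:, 0] > 0.5).astype(int)
    macro = msm.macro_of_micro
    same = (macro == blocks).all() or (macro == 1 - blocks).all()
    assert same


def analytic_two_state_msm(p01, p10, lag=1):
    t_mat = np.array([[1 - p01, p01], [p10, 1 - p10]])
    pi = np.array([p10, p01]) / (p01 + p10)
    return MSMResult(
        lag=lag, transition_matrix=t_mat, stationary=pi,
        micro_labels=[], macro_of_micro=np.array([0, 1]),
        macro_assignment=np.array([0, 1]), active_set=np.arange(2),
        clustering=None, implied_timescales=np.array([]),
    )


def test_mfpt_geometric_waiting_times():
    msm = analytic_two_state_msm(0.1, 0.2)
    f01, f10 = mfpt(msm)
    assert f01 == pytest.approx(10.0, abs=1e-12)
    assert f10 == pytest.approx(5.0, abs=1e-12)


def test_mfpt_matches_monte_carlo_first_passage():
    """Linear-system MFPT agrees with 1e5 simulated first-passage events."""
    rng = np.random.default_rng(5)
    t_mat = rng.random((4, 4)) + 0.1
    t_mat /= t_mat.sum(axis=1, keepdims=True)
    w, v = np.linalg.eig(t_mat.T)
    pi = np.abs(v[:, np.argmax(w.real)].real)
    pi /= pi.sum()
    macro = np.array([0, 0, 1, 1])
    msm = MSMResult(lag=1, transition_matrix=t_mat, stationary=pi,
                    micro_labels=[], macro_of_micro=macro,
                    macro_assignment=macro, active_set=np.arange(4),
                    clustering=None, implied_timescales=np.array([]))
    f01, _ = mfpt(msm)
    # brute force: draw starts from pi restricted to macro 0, walk to macro 1
    n_real = 100_000
    cum = np.cumsum(t_mat, axis=1)
    p_src = pi[:2] / pi[:2].sum()
    starts = rng.choice(2, size=n_real, p=p_src)
    total = 0
    for s in starts:
        state, steps = s, 0
        while macro[state] == 0:
            state = int(np.searchsorted(cum[state], rng.random()))
            steps += 1
        total += steps
    assert f01 == pytest.approx(total / n_real, rel=0.02)


def test_mare_mfpt_definition():
    assert mare_mfpt((10.0, 5.0), (10.0, 5.0)) == 0.0
    assert mare_mfpt((10.0, 4.0), (5.0, 2.0)) == pytest.approx(0.5)
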