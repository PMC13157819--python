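"""Stationary and dynamical fidelity metrics for generated CG trajectories.

Configurational fidelity: reference (fine-grained, mapped) and generated
features are projected onto the leading time-lagged independent components
(TICA, fitted on the reference only), histogrammed on a shared 2D grid, and
compared with the Jensen-Shannon divergence (natural log, bounded by ln 2).
The 2D potential of mean force is -kT ln P, minimum shifted to zero.

Dynamical fidelity: normalized autocorrelation functions of each TIC,
averaged over time origins and replicas; epsilon_ACF is the mean squared
difference between reference and generated ACF curves over the lag grid
(summed over the configured components). For multi-state systems a Markov
state model is estimated at a lag time: k-means microstates (fitted on the
reference, applied unchanged to the generated data), a row-stochastic
transition matrix on the largest connected set, two macrostates from the
sign structure of the second right eigenvector (PCCA-style lumping hardened
at 2 states), mean first passage times from the microstate linear system,
and the mean absolute relative error between reference and generated MFPTs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.cluster import KMeans

__all__ = [
    "TICAModel",
    "Histogram2D",
    "MSMResult",
    "FidelityReport",
    "fit_tica",
    "project_tica",
    "pmf_2d",
    "hist2d",
    "jsd_2d",
    "acf",
    "epsilon_acf",
    "build_msm",
    "mfpt",
    "mare_mfpt",
    "evaluate_fidelity",
]

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def _as_traj_list(x):
    """Accept (frames, d), (replicas, frames, d), or a list of (frames, d)."""
    if isinstance(x, (list, tuple)):
        return [np.asarray(t, dtype=float) for t in x]
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return [x]
    if x.ndim == 3:
        return [x[i] for i in range(x.shape[0])]
    raise ValueError("expected 2D or 3D array of feature frames")


# ---------------------------------------------------------------------------
# TICA
# ---------------------------------------------------------------------------


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    eigenvalues: np.ndarray    # descending
    projection: np.ndarray     # (d, n_components) column eigenvectors

    @property
    def timescales(self):
        lam = np.clip(self.eigenvalues, 1e-12, 1 - 1e-12)
        return -self.lag / np.log(lam)


def fit_tica(features, lag: int, n_components: int = 2,
             ridge: float = 1e-6) -> TICAModel:
    """Symmetrized time-lagged generalized eigenproblem on mean-free data.

    Solves C_tau v = lambda C_0 v with C_tau <- (C_tau + C_tau^T)/2 and a
    ridge shrinkage on C_0 (regularizes constant/masked columns to zero
    loading). Components are ordered by decreasing eigenvalue.
    """
    trajs = _as_traj_list(features)
    if any(t.shape[0] <= lag for t in trajs):
        raise ValueError("lag must be smaller than every trajectory length")
    d = trajs[0].shape[1]
    n_pairs = sum(t.shape[0] - lag for t in trajs)
    mean = sum(t[:].sum(axis=0) for t in trajs) / sum(t.shape[0] for t in trajs)
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    for t in trajs:
        x0 = t[:-lag] - mean
        xt = t[lag:] - mean
        c0 += x0.T @ x0 + xt.T @ xt
        ct += x0.T @ xt
    c0 /= 2.0 * n_pairs
    ct /= n_pairs
    ct = 0.5 * (ct + ct.T)
    c0reg = c0 + ridge * np.eye(d)
    w, v = scipy.linalg.eigh(ct, c0reg)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(n_components, d)
    return TICAModel(lag=lag, mean=mean, eigenvalues=w[:k],
                     projection=v[:, :k])


def project_tica(features, model: TICAModel):
    """Project onto the fitted components (mean subtracted).

    Returns the same nesting as the input: a single (frames, k) array for 2D
    input, a list for list/3D input.
    """
    trajs = _as_traj_list(features)
    out = [(t - model.mean) @ model.projection for t in trajs]
    if isinstance(features, np.ndarray) and features.ndim == 2:
        return out[0]
    return out


# ---------------------------------------------------------------------------
# Histograms, PMF, Jensen-Shannon divergence
# ---------------------------------------------------------------------------


@dataclass
class Histogram2D:
    edges_x: np.ndarray
    edges_y: np.ndarray
    p: np.ndarray        # probability mass, sums to 1
    counts: np.ndarray


def hist2d(samples: np.ndarray, bins: int = 72,
           ranges=None) -> Histogram2D:
    """2D probability mass function of (n, 2) samples."""
    s = np.asarray(samples, dtype=float).reshape(-1, 2)
    if s.shape[0] < 1:
        raise ValueError("need at least one sample")
    counts, ex, ey = np.histogram2d(s[:, 0], s[:, 1], bins=bins, range=ranges)
    return Histogram2D(ex, ey, counts / counts.sum(), counts)


def shared_range(*sample_sets, pad: float = 1e-9):
    """Axis ranges spanning the union of all sample sets."""
    stacked = np.vstack([np.asarray(s, dtype=float).reshape(-1, 2)
                         for s in sample_sets])
    lo, hi = stacked.min(axis=0), stacked.max(axis=0)
    return [(lo[0] - pad, hi[0] + pad), (lo[1] - pad, hi[1] + pad)]


def pmf_2d(samples: np.ndarray, bins: int = 72, kT: float = 1.0,
           ranges=None):
    """Potential of mean force -kT ln P, minimum shifted to zero.

    Empty bins are infinite. Returns ``(pmf, Histogram2D)``.
    """
    h = hist2d(samples, bins=bins, ranges=ranges)
    with np.errstate(divide="ignore"):
        pmf = -kT * np.log(h.p)
    pmf -= pmf[np.isfinite(pmf)].min()
    return pmf, h


def jsd_2d(p_hist: Histogram2D, q_hist: Histogram2D) -> float:
    """Jensen-Shannon divergence (natural log) of two aligned histograms."""
    if (p_hist.p.shape != q_hist.p.shape
            or not np.allclose(p_hist.edges_x, q_hist.edges_x)
            or not np.allclose(p_hist.edges_y, q_hist.edges_y)):
        raise ValueError("histograms must share identical binning")
    p, q = p_hist.p.ravel(), q_hist.p.ravel()
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(p > 0, p * np.log(p / m), 0.0)
        term_q = np.where(q > 0, q * np.log(q / m), 0.0)
    return float(0.5 * term_p.sum() + 0.5 * term_q.sum())


# ---------------------------------------------------------------------------
# Autocorrelation
# ---------------------------------------------------------------------------


def acf(series, max_lag: int, mean_subtract: bool = True) -> np.ndarray:
    """Normalized autocorrelation over lags 0..max_lag.

    ``series`` is one 1D array or a list/2D stack of replicas; averages run
    over time origins and replicas, normalized by the lag-0 value so
    ACF(0) = 1. TICs are near mean-free by construction; subtracting the
    pooled mean is the default and is logged when disabled.
    """
    if isinstance(series, np.ndarray) and series.ndim == 1:
        reps = [series.astype(float)]
    else:
        reps = [np.asarray(r, dtype=float) for r in series]
    if any(r.shape[0] <= max_lag for r in reps):
        raise ValueError("max_lag must be smaller than the series length")
    if mean_subtract:
        mu = np.mean(np.concatenate(reps))
        reps = [r - mu for r in reps]
    else:
        logger.info("acf computed without mean subtraction")
    c0 = np.mean(np.concatenate([r * r for r in reps]))
    if c0 == 0:
        raise ValueError("zero-variance series")
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        num = np.concatenate([r[: r.shape[0] - lag] * r[lag:] for r in reps])
        out[lag] = np.mean(num) / c0
    return out


def epsilon_acf(acf_ref, acf_cg) -> float:
    """Mean squared difference between two curves on a common lag grid.

    Pass per-component curves and sum the results for a multi-component
    score; or pass lists of curves to get the summed score directly.
    """
    if isinstance(acf_ref, (list, tuple)):
        return float(sum(epsilon_acf(a, b) for a, b in zip(acf_ref, acf_cg)))
    a, b = np.asarray(acf_ref), np.asarray(acf_cg)
    if a.shape != b.shape:
        raise ValueError("ACF curves must share the lag grid")
    return float(np.mean((a - b) ** 2))


# ---------------------------------------------------------------------------
# Markov state models
# ---------------------------------------------------------------------------


@dataclass
class MSMResult:
    lag: int
    transition_matrix: np.ndarray
    stationary: np.ndarray
    micro_labels: list              # per-trajectory label arrays
    macro_of_micro: np.ndarray      # macrostate id per active microstate
    macro_assignment: np.ndarray    # macrostate id per microstate (-1 unused)
    active_set: np.ndarray          # microstate ids kept (largest connected)
    clustering: KMeans
    implied_timescales: np.ndarray

    @property
    def n_macrostates(self):
        return int(self.macro_of_micro.max()) + 1


def _count_matrix(dtrajs, n_states, lag):
    c = np.zeros((n_states, n_states))
    for d in dtrajs:
        np.add.at(c, (d[:-lag], d[lag:]), 1.0)
    return c


def build_msm(tics, lag: int, n_micro: int = 250, n_macro: int = 2,
              clustering: KMeans | None = None, seed: int = 0,
              dtrajs=None, macro_assignment: np.ndarray | None = None
              ) -> MSMResult:
    """Estimate a two-level Markov state model from TIC series.

    K-means microstates (k-means++ init) are fitted here unless a fitted
    ``clustering`` is supplied (fit on reference data, apply to generated
    data). Counts use the sliding window at ``lag``; if the chain is
    disconnected the largest strongly connected set is kept with a warning.
    Macrostates come from the sign split of the second right eigenvector;
    implied timescales are -lag / ln lambda_i.
    """
    trajs = _as_traj_list(tics)
    if dtrajs is None:
        if clustering is None:
            data = np.vstack(trajs)
            n_micro = min(n_micro, data.shape[0])
            clustering = KMeans(n_clusters=n_micro, init="k-means++",
                                n_init=5, random_state=seed).fit(data)
        dtrajs = [clustering.predict(t) for t in trajs]
    n_states = clustering.n_clusters if clustering is not None else (
        max(int(d.max()) for d in dtrajs) + 1)
    counts = _count_matrix(dtrajs, n_states, lag)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        counts > 0, directed=True, connection="strong")
    if n_comp > 1:
        # keep the component with the most counts
        weights = np.array([counts[labels == i][:, labels == i].sum()
                            for i in range(n_comp)])
        keep_label = int(np.argmax(weights))
        warnings.warn(
            f"transition graph disconnected ({n_comp} components); using "
            "largest connected set", RuntimeWarning, stacklevel=2,
        )
    else:
        keep_label = 0
    active = np.where(labels == keep_label)[0]
    sub = counts[np.ix_(active, active)]
    t_mat = sub / sub.sum(axis=1, keepdims=True)
    evals, evecs = scipy.linalg.eig(t_mat)
    order = np.argsort(-evals.real)
    evals = evals[order].real
    evecs = evecs[:, order].real
    # stationary distribution: left eigenvector at lambda = 1
    wl, vl = scipy.linalg.eig(t_mat.T)
    pi = vl[:, np.argmax(wl.real)].real
    pi = np.abs(pi) / np.abs(pi).sum()
    if n_macro != 2:
        raise NotImplementedError("only 2-macrostate lumping is supported")
    if macro_assignment is None:
        second = evecs[:, 1]
        macro = (second >= 0).astype(int)
        if macro.min() == macro.max():  # pathological split: use median
            macro = (second >= np.median(second)).astype(int)
        full = np.full(n_states, -1, dtype=int)
        full[active] = macro
    else:
        full = np.asarray(macro_assignment, dtype=int).copy()
        if np.any(full[active] < 0) and clustering is not None:
            # microstates never visited by the defining data set: adopt the
            # macrostate of the nearest assigned cluster center
            centers = clustering.cluster_centers_
            assigned = np.where(full >= 0)[0]
            for s in active[full[active] < 0]:
                near = assigned[np.argmin(
                    np.linalg.norm(centers[assigned] - centers[s], axis=1))]
                full[s] = full[near]
        macro = full[active]
    with np.errstate(divide="ignore"):
        its = -lag / np.log(np.clip(np.abs(evals[1:min(6, len(evals))]),
                                    1e-15, 1 - 1e-15))
    return MSMResult(lag=lag, transition_matrix=t_mat, stationary=pi,
                     micro_labels=dtrajs, macro_of_micro=macro,
                     macro_assignment=full, active_set=active,
                     clustering=clustering, implied_timescales=its)


def mfpt(msm: MSMResult):
    """Mean first passage times (in lag-time units of frames) both ways.

    Solves m_i = lag + sum_j T_ij m_j with m = 0 on the target macrostate;
    the source average is weighted by the stationary distribution restricted
    to the source macrostate. Returns (MFPT_{0->1}, MFPT_{1->0}).
    """
    t_mat, pi, macro = msm.transition_matrix, msm.stationary, msm.macro_of_micro
    out = []
    for target in (1, 0):
        src = np.where(macro != target)[0]
        tgt = np.where(macro == target)[0]
        if tgt.size == 0 or src.size == 0:
            raise ValueError("absorbing target macrostate is empty")
        a = np.eye(src.size) - t_mat[np.ix_(src, src)]
        m = np.linalg.solve(a, msm.lag * np.ones(src.size))
        w = pi[src] / pi[src].sum()
        out.append(float(w @ m))
    return out[0], out[1]


def mare_mfpt(ref_pair, cg_pair) -> float:
    """Mean absolute relative error of MFPTs over both directions."""
    ref = np.asarray(ref_pair, dtype=float)
    cg = np.asarray(cg_pair, dtype=float)
    return float(np.mean(np.abs(cg - ref) / ref))


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------


@dataclass
class FidelityReport:
    tica: TICAModel
    d_js: float
    pmf_ref: np.ndarray
    pmf_cg: np.ndarray
    acf_ref: list
    acf_cg: list
    epsilon_acf_components: list
    epsilon_acf: float
    msm_ref: MSMResult | None = None
    msm_cg: MSMResult | None = None
    mfpt_ref: tuple | None = None
    mfpt_cg: tuple | None = None
    mare_mfpt: float | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"d_js": self.d_js, "epsilon_acf": self.epsilon_acf,
               "epsilon_acf_components": self.epsilon_acf_components}
        if self.mare_mfpt is not None:
            out.update(mfpt_ref=list(self.mfpt_ref),
                       mfpt_cg=list(self.mfpt_cg),
                       mare_mfpt=self.mare_mfpt)
        return out


def evaluate_fidelity(
    ref_features,
    cg_features,
    tica_lag: int,
    n_components: int = 2,
    bins: int = 72,
    acf_max_lag: int = 100,
    acf_components: int | None = None,
    kT: float = 1.0,
    msm_lag: int | None = None,
    n_micro: int = 250,
    seed: int = 0,
) -> FidelityReport:
    """Full configurational + dynamical comparison.

    Both inputs are unscaled features; TICA, histogram ranges, k-means
    clusters and macrostate definitions are fitted on the reference only and
    applied unchanged to the generated data. ``acf_components`` limits the
    epsilon_ACF sum (defaults to all fitted components).
    """
    tica = fit_tica(ref_features, tica_lag, n_components)
    tic_ref = project_tica(ref_features, tica)
    tic_cg = project_tica(cg_features, tica)
    tic_ref = tic_ref if isinstance(tic_ref, list) else [tic_ref]
    tic_cg = tic_cg if isinstance(tic_cg, list) else [tic_cg]
    ref_all = np.vstack(tic_ref)[:, :2]
    cg_all = np.vstack(tic_cg)[:, :2]
    ranges = shared_range(ref_all, cg_all)
    h_ref = hist2d(ref_all, bins, ranges)
    h_cg = hist2d(cg_all, bins, ranges)
    d_js = jsd_2d(h_ref, h_cg)
    pmf_ref, _ = pmf_2d(ref_all, bins, kT, ranges)
    pmf_cg, _ = pmf_2d(cg_all, bins, kT, ranges)
    k_acf = acf_components or n_components
    acf_ref = [acf([t[:, c] for t in tic_ref], acf_max_lag)
               for c in range(k_acf)]
    acf_cg = [acf([t[:, c] for t in tic_cg], acf_max_lag)
              for c in range(k_acf)]
    eps_comp = [epsilon_acf(a, b) for a, b in zip(acf_ref, acf_cg)]
    report = FidelityReport(
        tica=tica, d_js=d_js, pmf_ref=pmf_ref, pmf_cg=pmf_cg,
        acf_ref=acf_ref, acf_cg=acf_cg,
        epsilon_acf_components=eps_comp, epsilon_acf=float(sum(eps_comp)),
    )
    if msm_lag is not None:
        msm_ref = build_msm(tic_ref, msm_lag, n_micro=n_micro, seed=seed)
        msm_cg = build_msm(tic_cg, msm_lag, n_micro=n_micro,
                           clustering=msm_ref.clustering, seed=seed,
                           macro_assignment=msm_ref.macro_assignment)
        report.msm_ref, report.msm_cg = msm_ref, msm_cg
        report.mfpt_ref = mfpt(msm_ref)
        report.mfpt_cg = mfpt(msm_cg)
        report.mare_mfpt = mare_mfpt(report.mfpt_ref, report.mfpt_cg)
    return report
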