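"""Reference fine-grained simulators with known statistical structure.

Bead-chain systems evolved under either Markovian Langevin dynamics or a
generalized Langevin equation (GLE) with an exponential memory kernel. The
chain potential is

    U = sum bonds  k_b/2 (r - r0)^2
      + sum angles k_a/2 (theta - theta0)^2
      + sum dihedrals  eps (1 - cos 2 phi)

so the slowest motion is hopping of each dihedral between two symmetric wells
separated by a barrier of height 2 eps. Because the potential and temperature
fix the stationary (Boltzmann) distribution analytically, these simulators
come with closed-form/quadrature oracles: the dihedral free-energy profile,
harmonic-coordinate variances, and the Ornstein-Uhlenbeck autocorrelation.

The GLE kernel K(t) = (c^2 / tau_m) exp(-t / tau_m) is realized exactly by a
Markovian embedding with one auxiliary Ornstein-Uhlenbeck force variable per
degree of freedom; only bead coordinates are saved, so the output trajectory
is genuinely non-Markovian in the saved variables while sharing the Langevin
configurational ensemble.

Integrator: BAOAB splitting (velocity Verlet with an exact
Ornstein-Uhlenbeck midpoint substep), chosen for its small configurational
sampling bias at finite time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ChainPotential",
    "LangevinParams",
    "GLEParams",
    "Trajectory",
    "simulate_langevin_chain",
    "simulate_gle_chain",
    "dihedral_reference_profile",
    "analytic_ou_acf",
    "minimum_energy_chain",
    "compute_dihedrals",
    "chain_energy_forces",
]

_CHUNK = 100_000
_BURN_IN = 10_000


@dataclass
class ChainPotential:
    """Bonded bead-chain potential; masses default to 1 per bead."""

    n_beads: int = 4
    bond_k: float = 100.0
    r0: float = 1.0
    angle_k: float = 20.0
    theta0: float = 1.9
    eps: float = 3.0
    masses: np.ndarray | None = None

    def __post_init__(self):
        if self.n_beads < 4:
            raise ValueError("need n_beads >= 4 so a dihedral exists")
        if self.bond_k <= 0:
            raise ValueError("bond_k must be positive")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")
        if self.masses is None:
            self.masses = np.ones(self.n_beads)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (self.n_beads,) or np.any(self.masses <= 0):
                raise ValueError("masses must be positive, one per bead")


@dataclass
class LangevinParams:
    gamma: float = 1.0
    kT: float = 1.0
    dt: float = 0.005
    n_steps: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0 or self.kT < 0 or self.dt <= 0:
            raise ValueError("require gamma > 0, kT >= 0, dt > 0")


@dataclass
class GLEParams(LangevinParams):
    """Adds an exponential memory kernel K(t) = (c2/tau_m) exp(-t/tau_m).

    ``gamma`` keeps an optional residual white-noise friction; the memory
    amplitude ``c2`` is the integrated kernel friction.
    """

    c2: float = 2.0
    tau_m: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if self.tau_m <= 0 or self.c2 < 0:
            raise ValueError("require tau_m > 0 and c2 >= 0")


@dataclass
class Trajectory:
    """Saved frames (frames x sites x 3) with save-interval metadata."""

    coords: np.ndarray
    dt_save: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# Forces (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forces(x, bond_k, r0, angle_k, theta0, eps, f):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    energy = 0.0
    # bonds
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        energy += 0.5 * bond_k * (d - r0) ** 2
        fac = bond_k * (d - r0) / d
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[i + 1, 0] -= fac * dx
        f[i + 1, 1] -= fac * dy
        f[i + 1, 2] -= fac * dz
    # angles
    for i in range(1, n - 1):
        ux = x[i - 1, 0] - x[i, 0]
        uy = x[i - 1, 1] - x[i, 1]
        uz = x[i - 1, 2] - x[i, 2]
        vx = x[i + 1, 0] - x[i, 0]
        vy = x[i + 1, 1] - x[i, 1]
        vz = x[i + 1, 2] - x[i, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        cos_t = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cos_t > 1.0 - 1e-12:
            cos_t = 1.0 - 1e-12
        if cos_t < -1.0 + 1e-12:
            cos_t = -1.0 + 1e-12
        theta = math.acos(cos_t)
        sin_t = math.sqrt(1.0 - cos_t * cos_t)
        energy += 0.5 * angle_k * (theta - theta0) ** 2
        coef = angle_k * (theta - theta0) / sin_t  # = -dU/dtheta * (-1/sin)
        # dtheta/du = -(1/sin) (v/(nu nv) - cos u/nu^2); force = -dU/dtheta*dtheta/dx
        gux = coef * (vx / (nu * nv) - cos_t * ux / (nu * nu))
        guy = coef * (vy / (nu * nv) - cos_t * uy / (nu * nu))
        guz = coef * (vz / (nu * nv) - cos_t * uz / (nu * nu))
        gvx = coef * (ux / (nu * nv) - cos_t * vx / (nv * nv))
        gvy = coef * (uy / (nu * nv) - cos_t * vy / (nv * nv))
        gvz = coef * (uz / (nu * nv) - cos_t * vz / (nv * nv))
        f[i - 1, 0] += gux
        f[i - 1, 1] += guy
        f[i - 1, 2] += guz
        f[i + 1, 0] += gvx
        f[i + 1, 1] += gvy
        f[i + 1, 2] += gvz
        f[i, 0] -= gux + gvx
        f[i, 1] -= guy + gvy
        f[i, 2] -= guz + gvz
    # dihedrals: U = eps (1 - cos 2 phi)
    if eps > 0.0:
        for i in range(n - 3):
            b1x = x[i + 1, 0] - x[i, 0]
            b1y = x[i + 1, 1] - x[i, 1]
            b1z = x[i + 1, 2] - x[i, 2]
            b2x = x[i + 2, 0] - x[i + 1, 0]
            b2y = x[i + 2, 1] - x[i + 1, 1]
            b2z = x[i + 2, 2] - x[i + 1, 2]
            b3x = x[i + 3, 0] - x[i + 2, 0]
            b3y = x[i + 3, 1] - x[i + 2, 1]
            b3z = x[i + 3, 2] - x[i + 2, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            cx = n1y * n2z - n1z * n2y
            cy = n1z * n2x - n1x * n2z
            cz = n1x * n2y - n1y * n2x
            phi = math.atan2(
                (cx * b2x + cy * b2y + cz * b2z) / nb2,
                n1x * n2x + n1y * n2y + n1z * n2z,
            )
            energy += eps * (1.0 - math.cos(2.0 * phi))
            dU = 2.0 * eps * math.sin(2.0 * phi)
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            # dphi/dx0 and dphi/dx3
            g0x = -nb2 / n1sq * n1x
            g0y = -nb2 / n1sq * n1y
            g0z = -nb2 / n1sq * n1z
            g3x = nb2 / n2sq * n2x
            g3y = nb2 / n2sq * n2y
            g3z = nb2 / n2sq * n2z
            c1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            c2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            g1x = -(1.0 + c1) * g0x + c2 * g3x
            g1y = -(1.0 + c1) * g0y + c2 * g3y
            g1z = -(1.0 + c1) * g0z + c2 * g3z
            g2x = c1 * g0x - (1.0 + c2) * g3x
            g2y = c1 * g0y - (1.0 + c2) * g3y
            g2z = c1 * g0z - (1.0 + c2) * g3z
            f[i, 0] -= dU * g0x
            f[i, 1] -= dU * g0y
            f[i, 2] -= dU * g0z
            f[i + 1, 0] -= dU * g1x
            f[i + 1, 1] -= dU * g1y
            f[i + 1, 2] -= dU * g1z
            f[i + 2, 0] -= dU * g2x
            f[i + 2, 1] -= dU * g2y
            f[i + 2, 2] -= dU * g2z
            f[i + 3, 0] -= dU * g3x
            f[i + 3, 1] -= dU * g3y
            f[i + 3, 2] -= dU * g3z
    return energy


def chain_energy_forces(potential: ChainPotential, coords: np.ndarray):
    """Energy and forces of one configuration (python-facing wrapper)."""
    f = np.zeros_like(coords, dtype=np.float64)
    e = _forces(
        np.ascontiguousarray(coords, dtype=np.float64),
        potential.bond_k,
        potential.r0,
        potential.angle_k,
        potential.theta0,
        potential.eps,
        f,
    )
    return e, f


@njit(cache=True)
def _baoab_chunk(
    x, v, f, masses, bond_k, r0, angle_k, theta0, eps,
    gamma, kT, dt, noise, out_x, out_v, save_stride, step0,
):
    n = x.shape[0]
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kT)
    for s in range(noise.shape[0]):
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d] * inv_m
                x[i, d] += 0.5 * dt * v[i, d]
        for i in range(n):
            sd = c2 / math.sqrt(masses[i])
            for d in range(3):
                v[i, d] = c1 * v[i, d] + sd * noise[s, i, d]
                x[i, d] += 0.5 * dt * v[i, d]
        _forces(x, bond_k, r0, angle_k, theta0, eps, f)
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d] * inv_m
        step = step0 + s + 1
        if step > 0 and step % save_stride == 0:
            row = step // save_stride
            for i in range(n):
                for d in range(3):
                    out_x[row, i, d] = x[i, d]
                    out_v[row, i, d] = v[i, d]


@njit(cache=True)
def _gle_chunk(
    x, v, z, f, masses, bond_k, r0, angle_k, theta0, eps,
    gamma, kT, dt, g_amp, tau_m, noise_w, noise_z, out_x, out_v,
    save_stride, step0,
):
    n = x.shape[0]
    c1 = math.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = math.sqrt((1.0 - c1 * c1) * kT)
    cz = math.exp(-dt / tau_m)
    sz = math.sqrt(kT * g_amp / tau_m * (1.0 - cz * cz))
    for s in range(noise_w.shape[0]):
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += 0.5 * dt * (f[i, d] + z[i, d]) * inv_m
                x[i, d] += 0.5 * dt * v[i, d]
        for i in range(n):
            sd = c2 / math.sqrt(masses[i])
            for d in range(3):
                v[i, d] = c1 * v[i, d] + sd * noise_w[s, i, d]
                # exact OU update of the auxiliary force, drift toward -g*v
                z[i, d] = cz * z[i, d] + (1.0 - cz) * (-g_amp * v[i, d]) \
                    + sz * noise_z[s, i, d]
                x[i, d] += 0.5 * dt * v[i, d]
        _forces(x, bond_k, r0, angle_k, theta0, eps, f)
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += 0.5 * dt * (f[i, d] + z[i, d]) * inv_m
        step = step0 + s + 1
        if step > 0 and step % save_stride == 0:
            row = step // save_stride
            for i in range(n):
                for d in range(3):
                    out_x[row, i, d] = x[i, d]
                    out_v[row, i, d] = v[i, d]


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def minimum_energy_chain(potential: ChainPotential) -> np.ndarray:
    """Chain with all bonds at r0, angles at theta0, dihedrals at phi = 0."""
    n = potential.n_beads
    coords = np.zeros((n, 3))
    coords[1] = (potential.r0, 0.0, 0.0)
    if n > 2:
        a = math.pi - potential.theta0
        coords[2] = coords[1] + potential.r0 * np.array(
            [math.cos(a), math.sin(a), 0.0]
        )
    for i in range(3, n):
        # phi = 0 keeps the chain planar: extend using the previous two bonds
        b_prev = coords[i - 1] - coords[i - 2]
        b_prev2 = coords[i - 2] - coords[i - 3]
        b_prev_u = b_prev / np.linalg.norm(b_prev)
        # in-plane unit vector perpendicular to b_prev, pointing away from chain
        perp = b_prev2 - np.dot(b_prev2, b_prev_u) * b_prev_u
        perp /= np.linalg.norm(perp)
        a = math.pi - potential.theta0
        coords[i] = coords[i - 1] + potential.r0 * (
            math.cos(a) * b_prev_u - math.sin(a) * perp
        )
    return coords


def compute_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Dihedral angles of consecutive bead quadruples, (frames, n-3)."""
    x = np.asarray(coords, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    b1 = x[:, 1:-2] - x[:, :-3]
    b2 = x[:, 2:-1] - x[:, 1:-2]
    b3 = x[:, 3:] - x[:, 2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    y = np.einsum("fij,fij->fi", np.cross(n1, n2), b2) / nb2
    c = np.einsum("fij,fij->fi", n1, n2)
    phi = np.arctan2(y, c)
    return phi[0] if single else phi


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


def _prepare_initial(potential, params, initial_coords, jitter, rng):
    if initial_coords is None:
        x = minimum_energy_chain(potential)
        if jitter > 0:
            x = x + jitter * rng.standard_normal(x.shape)
    else:
        x = np.array(initial_coords, dtype=np.float64)
        if x.shape != (potential.n_beads, 3):
            raise ValueError("initial_coords has wrong shape")
        d = np.linalg.norm(np.diff(x, axis=0), axis=1)
        if np.any(d < 1e-8):
            raise ValueError("overlapping initial beads")
    v = np.sqrt(params.kT / potential.masses)[:, None] * rng.standard_normal(
        (potential.n_beads, 3)
    )
    return np.ascontiguousarray(x), np.ascontiguousarray(v)


def _run(kernel_step, potential, params, save_stride, initial_coords, jitter,
         burn_in, return_velocities, n_noise_streams):
    if save_stride < 1 or params.n_steps % save_stride:
        raise ValueError("save_stride must divide n_steps")
    rng = np.random.default_rng(params.seed)
    x, v = _prepare_initial(potential, params, initial_coords, jitter, rng)
    masses = np.ascontiguousarray(potential.masses, dtype=np.float64)
    f = np.zeros_like(x)
    pot = (potential.bond_k, potential.r0, potential.angle_k,
           potential.theta0, potential.eps)
    _forces(x, *pot, f)
    n_frames = params.n_steps // save_stride + 1
    out_x = np.empty((n_frames, potential.n_beads, 3))
    out_v = np.empty_like(out_x)
    state = {"z": np.zeros_like(x)}

    def run_steps(n_total, record):
        done = 0
        while done < n_total:
            m = min(_CHUNK, n_total - done)
            noises = [
                np.ascontiguousarray(rng.standard_normal((m, potential.n_beads, 3)))
                for _ in range(n_noise_streams)
            ]
            # during burn-in, map global step indices to <= 0 so nothing saves
            step0 = done if record else done - n_total
            kernel_step(x, v, state, f, masses, pot, params, noises,
                        out_x, out_v, save_stride, step0)
            done += m

    if burn_in > 0:
        run_steps(burn_in, record=False)
    out_x[0], out_v[0] = x, v
    run_steps(params.n_steps, record=True)
    if not np.all(np.isfinite(out_x)):
        raise FloatingPointError(
            "non-finite coordinates: integration unstable, reduce dt"
        )
    traj = Trajectory(
        coords=out_x,
        dt_save=params.dt * save_stride,
        metadata={"params": params, "potential": potential,
                  "save_stride": save_stride},
    )
    return (traj, out_v) if return_velocities else traj


def simulate_langevin_chain(
    potential: ChainPotential,
    params: LangevinParams,
    save_stride: int = 1,
    initial_coords: np.ndarray | None = None,
    jitter: float = 0.05,
    burn_in: int = _BURN_IN,
    return_velocities: bool = False,
):
    """Markovian Langevin dynamics of the bead chain (BAOAB integrator).

    The stationary distribution converges to exp(-U/kT); runs are
    bit-reproducible for a fixed ``params.seed``.
    """

    def step(x, v, state, f, masses, pot, p, noises, out_x, out_v, stride, s0):
        _baoab_chunk(x, v, f, masses, *pot, p.gamma, p.kT, p.dt,
                     noises[0], out_x, out_v, stride, s0)

    return _run(step, potential, params, save_stride, initial_coords, jitter,
                burn_in, return_velocities, n_noise_streams=1)


def simulate_gle_chain(
    potential: ChainPotential,
    params: GLEParams,
    save_stride: int = 1,
    initial_coords: np.ndarray | None = None,
    jitter: float = 0.05,
    burn_in: int = _BURN_IN,
    return_velocities: bool = False,
):
    """GLE dynamics with exponential memory kernel via Markovian embedding.

    One auxiliary Ornstein-Uhlenbeck force variable per degree of freedom
    gives kernel K(t) = (c2/tau_m) exp(-t/tau_m) with matched colored noise
    (second fluctuation-dissipation theorem). Only coordinates are part of
    the returned trajectory; configurational statistics coincide with the
    Langevin chain at the same (U, kT) while the dynamics differ.
    """

    def step(x, v, state, f, masses, pot, p, noises, out_x, out_v, stride, s0):
        _gle_chunk(x, v, state["z"], f, masses, *pot, p.gamma, p.kT, p.dt,
                   p.c2, p.tau_m, noises[0], noises[1], out_x, out_v,
                   stride, s0)

    return _run(step, potential, params, save_stride, initial_coords, jitter,
                burn_in, return_velocities, n_noise_streams=2)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def dihedral_reference_profile(potential: ChainPotential, kT: float,
                               n_grid: int = 360):
    """Free-energy profile F(phi) = -kT ln p(phi) of the dihedral potential.

    Quadrature of the Boltzmann weight of U(phi) = eps (1 - cos 2 phi) on a
    uniform grid over [-pi, pi); the minimum is shifted to zero. Returns
    ``(phi_grid, free_energy, p_normalized)``.
    """
    if n_grid < 100:
        raise ValueError("n_grid must be >= 100")
    phi = np.linspace(-math.pi, math.pi, n_grid, endpoint=False)
    u = potential.eps * (1.0 - np.cos(2.0 * phi))
    w = np.exp(-u / kT)
    p = w / (w.sum() * (phi[1] - phi[0]))
    free = -kT * np.log(p)
    free -= free.min()
    return phi, free, p


def analytic_ou_acf(gamma: float, lags: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation exp(-gamma * lag) of an OU process."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.exp(-gamma * np.asarray(lags, dtype=float))
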