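"""Coarse-grain mapping, local frame transformation, and feature scaling.

The pipeline fine coordinates -> CG sites -> rigid-motion-invariant features:

1. ``map_to_cg``: each CG site is the mass-weighted mean (center of mass) of
   its group of fine-grained particles.
2. ``local_frame_transform``: translate so reference site j sits at the
   origin, then rotate with the orthonormal right-handed basis built from
   sites (i, j, k) so that k lies on the +x axis and i lies in the xy plane
   with positive y. The flattened result F-hat (frames x 3N) is invariant to
   any rigid rotation + translation of the input, and exactly six of its
   columns are identically zero (all of j; y,z of k; z of i).
3. ``fit_scaler`` / ``apply_scaler``: per-feature affine min-max map of the
   fitting set onto [-0.75, 0.75], exactly invertible for non-constant
   features; constant columns (the six zeros) get an identity map and are
   re-zeroed by the mask downstream.

Note the unnormalized frame vectors (r_jk, r_jk x (r_ji x r_jk), r_jk x r_ji)
do not form a rotation; rows are normalized to unit length here so the
transform is a proper rigid motion, which is what makes the canonical pose
and the fixed feature range well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synthetic import Trajectory

__all__ = [
    "CGMapping",
    "LocalFrame",
    "FeatureScaler",
    "FeatureSeries",
    "map_to_cg",
    "local_frame_transform",
    "zero_dof_mask",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "featurize_trajectory",
    "read_xyz",
    "write_xyz",
    "save_features",
    "load_features",
    "residue_mapping_from_pdb",
]

TARGET_RANGE = 0.75


@dataclass
class CGMapping:
    """Disjoint groups of fine-grained particle indices, one per CG site."""

    groups: list
    masses: np.ndarray

    def __post_init__(self):
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]
        self.masses = np.asarray(self.masses, dtype=float)
        seen = set()
        for g in self.groups:
            if g.size == 0:
                raise ValueError("empty CG group")
            if seen & set(g.tolist()):
                raise ValueError("CG groups must be disjoint")
            seen |= set(g.tolist())
        if np.any(self.masses <= 0):
            raise ValueError("particle masses must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.groups)

    @classmethod
    def identity(cls, n_particles: int) -> "CGMapping":
        return cls([np.array([i]) for i in range(n_particles)],
                   np.ones(n_particles))


@dataclass(frozen=True)
class LocalFrame:
    """Reference CG site indices (i, j, k), 0-based; j is the origin."""

    i: int = 0
    j: int = 1
    k: int = 2

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("reference sites i, j, k must be distinct")


@dataclass
class FeatureScaler:
    """Affine per-feature map sending fitting-set min/max to -/+ 0.75.

    Applied as y = 0.75 * (2 (x - min)/span - 1) so the fitted extremes map
    to exactly +/- 0.75 in floating point. Constant columns get span = 2 and
    a centered offset, i.e. the identity map y = x.
    """

    data_min: np.ndarray
    data_max: np.ndarray

    def __post_init__(self):
        self.data_min = np.asarray(self.data_min, dtype=float)
        self.data_max = np.asarray(self.data_max, dtype=float)
        if np.any(self.data_max < self.data_min):
            raise ValueError("data_max must be >= data_min")

    @property
    def constant(self):
        return self.data_max == self.data_min

    @property
    def span(self):
        return np.where(self.constant, 1.0, self.data_max - self.data_min)

    @property
    def scale(self):
        """Slope dy/dx of the affine map (used to unscale model output)."""
        return np.where(self.constant, 1.0, 2.0 * TARGET_RANGE / self.span)

    def to_dict(self):
        return {"data_min": self.data_min.tolist(),
                "data_max": self.data_max.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["data_min"], dtype=float),
                   np.asarray(d["data_max"], dtype=float))


@dataclass
class FeatureSeries:
    """Frames x 3N feature matrix with its zero mask and scaling state."""

    values: np.ndarray
    zero_mask: np.ndarray
    dt_save: float
    scaler: FeatureScaler | None = None
    scaled: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self):
        return self.values.shape[0]

    @property
    def n_features(self):
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def map_to_cg(fine_coords, mapping: CGMapping):
    """Mass-weighted group means: (frames, particles, 3) -> (frames, N, 3).

    Accepts and returns a :class:`Trajectory` when given one.
    """
    traj = fine_coords if isinstance(fine_coords, Trajectory) else None
    coords = np.asarray(traj.coords if traj else fine_coords, dtype=float)
    n_particles = coords.shape[1]
    out = np.empty((coords.shape[0], mapping.n_sites, 3))
    for s, g in enumerate(mapping.groups):
        if np.any(g >= n_particles) or np.any(g < 0):
            raise IndexError("CG group index out of bounds")
        w = mapping.masses[g]
        total = w.sum()
        if total <= 0:
            raise ValueError("zero total mass in CG group")
        out[:, s] = np.einsum("fpd,p->fd", coords[:, g], w) / total
    if traj is not None:
        return Trajectory(out, traj.dt_save, dict(traj.metadata, cg=True))
    return out


def _frame_bases(coords: np.ndarray, frame: LocalFrame, tol: float = 1e-10):
    """Per-frame orthonormal rows (e1, e2, e3) of the local-frame rotation."""
    r_jk = coords[:, frame.k] - coords[:, frame.j]
    r_ji = coords[:, frame.i] - coords[:, frame.j]
    n_jk = np.linalg.norm(r_jk, axis=1)
    cross = np.cross(r_jk, r_ji)
    n_cross = np.linalg.norm(cross, axis=1)
    bad = (n_jk < tol) | (n_cross < tol * np.maximum(
        n_jk * np.linalg.norm(r_ji, axis=1), 1e-300))
    if np.any(bad):
        raise ValueError(
            f"degenerate local frame (collinear/coincident references) in "
            f"{int(bad.sum())} frame(s)"
        )
    e1 = r_jk / n_jk[:, None]
    e3 = cross / n_cross[:, None]
    e2 = np.cross(e3, e1)  # equals normalized r_jk x (r_ji x r_jk)
    return np.stack([e1, e2, e3], axis=1)  # (frames, 3, 3), rows are basis


def local_frame_transform(cg_coords, frame: LocalFrame = LocalFrame()):
    """Canonical-pose features F-hat: (frames, N, 3) -> (frames, 3N)."""
    coords = np.asarray(
        cg_coords.coords if isinstance(cg_coords, Trajectory) else cg_coords,
        dtype=float,
    )
    if coords.ndim == 2:
        coords = coords[None]
    q = _frame_bases(coords, frame)
    x = coords - coords[:, frame.j][:, None, :]
    transformed = np.einsum("frd,fnd->fnr", q, x)
    return transformed.reshape(coords.shape[0], -1)


def zero_dof_mask(n_sites: int, frame: LocalFrame = LocalFrame()) -> np.ndarray:
    """Boolean mask (length 3N) of the six identically-zero features."""
    if n_sites < 3:
        raise ValueError("need at least 3 CG sites for a local frame")
    mask = np.zeros(3 * n_sites, dtype=bool)
    mask[3 * frame.j: 3 * frame.j + 3] = True      # j at origin
    mask[3 * frame.k + 1: 3 * frame.k + 3] = True  # k on +x axis
    mask[3 * frame.i + 2] = True                   # i in xy plane
    return mask


def fit_scaler(features: np.ndarray) -> FeatureScaler:
    """Per-feature min-max scaler onto [-0.75, 0.75] (fit on training data)."""
    x = np.asarray(features, dtype=float)
    return FeatureScaler(x.min(axis=0), x.max(axis=0))


def apply_scaler(features: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    """Scale to [-0.75, 0.75]; no clipping, so held-out values may exceed it."""
    x = np.asarray(features, dtype=float)
    y = TARGET_RANGE * (2.0 * (x - scaler.data_min) / scaler.span - 1.0)
    return np.where(scaler.constant, x, y)


def invert_scaler(features: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    y = np.asarray(features, dtype=float)
    x = scaler.data_min + scaler.span * (y / TARGET_RANGE + 1.0) / 2.0
    return np.where(scaler.constant, y, x)


def featurize_trajectory(
    traj,
    mapping: CGMapping | None = None,
    frame: LocalFrame = LocalFrame(),
    scaler: FeatureScaler | None = None,
    fit: bool = False,
) -> FeatureSeries:
    """Full pipeline: CG map (optional) -> LFT -> (optional) scaling."""
    coords = traj.coords if isinstance(traj, Trajectory) else np.asarray(traj)
    dt_save = traj.dt_save if isinstance(traj, Trajectory) else 1.0
    if mapping is not None:
        coords = map_to_cg(coords, mapping)
    fhat = local_frame_transform(coords, frame)
    mask = zero_dof_mask(coords.shape[1], frame)
    fhat[:, mask] = 0.0  # exact zeros (kill numerical dust)
    if fit:
        scaler = fit_scaler(fhat)
    values = apply_scaler(fhat, scaler) if scaler is not None else fhat
    return FeatureSeries(values, mask, dt_save, scaler=scaler,
                         scaled=scaler is not None,
                         metadata={"frame": (frame.i, frame.j, frame.k)})


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_xyz(path, traj: Trajectory, names=None, fmt="%.8f"):
    """Multi-frame plain-text XYZ; comment line carries dt_save."""
    coords = traj.coords
    n = coords.shape[1]
    names = names or [f"C{i}" for i in range(n)]
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"{n}\n")
            fh.write(f"frame={f} dt_save={traj.dt_save!r}\n")
            for i in range(n):
                x, y, z = coords[f, i]
                fh.write(f"{names[i]} {fmt % x} {fmt % y} {fmt % z}\n")


def read_xyz(path) -> Trajectory:
    frames = []
    dt_save = 1.0
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        n = int(lines[pos])
        comment = lines[pos + 1]
        for tok in comment.split():
            if tok.startswith("dt_save="):
                dt_save = float(tok.split("=", 1)[1])
        block = np.array(
            [line.split()[1:4] for line in lines[pos + 2: pos + 2 + n]],
            dtype=float,
        )
        frames.append(block)
        pos += 2 + n
    return Trajectory(np.array(frames), dt_save)


def save_features(path, series: FeatureSeries):
    """Binary array container (HDF5) with JSON-encoded metadata attrs."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=series.values)
        fh.create_dataset("zero_mask", data=series.zero_mask)
        fh.attrs["dt_save"] = series.dt_save
        fh.attrs["scaled"] = series.scaled
        fh.attrs["metadata"] = json.dumps(
            {k: v for k, v in series.metadata.items()
             if isinstance(v, (str, int, float, list, tuple))}
        )
        if series.scaler is not None:
            fh.attrs["scaler"] = json.dumps(series.scaler.to_dict())


def load_features(path) -> FeatureSeries:
    import h5py

    with h5py.File(path, "r") as fh:
        scaler = None
        if "scaler" in fh.attrs:
            scaler = FeatureScaler.from_dict(json.loads(fh.attrs["scaler"]))
        return FeatureSeries(
            values=fh["values"][...],
            zero_mask=fh["zero_mask"][...].astype(bool),
            dt_save=float(fh.attrs["dt_save"]),
            scaler=scaler,
            scaled=bool(fh.attrs["scaled"]),
            metadata=json.loads(fh.attrs.get("metadata", "{}")),
        )


def residue_mapping_from_pdb(path) -> CGMapping:
    """One CG site per residue (center of mass), derived from a PDB file."""
    import mdtraj

    top = mdtraj.load_topology(str(path))
    groups = [
        np.array([a.index for a in res.atoms]) for res in top.residues
    ]
    masses = np.array([a.element.mass for a in top.atoms], dtype=float)
    return CGMapping(groups, masses)
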