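"""Synthetic molecular configurations for monolayer exciton models.

Generators for the model systems used throughout the package: uniformly
spaced 2D sheets (monolayers), cubic 3D cells with uniformly random
molecular orientations, and snapshot ensembles with Gaussian positional,
orientational and frequency disorder emulating thermal motion in an MD
trajectory.  Each molecule is reduced to a rigid body carrying a set of
local vibrational modes (frequencies plus transition-dipole vectors in
the molecule frame).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

__all__ = [
    "MonomerModeSet",
    "MolecularConfiguration",
    "SnapshotEnsemble",
    "make_2d_sheet",
    "make_3d_cell",
    "area_spacing_convert",
    "uniform_scale",
    "jitter_ensemble",
    "random_rotations",
    "pfoa_single_mode",
    "pfoa_cf_band_modes",
    "aa_ch_mode",
    "octanoic_ch_mode",
]

#: Default harmonic frequency scale factor for ab initio parameterizations.
DEFAULT_SCALE_FACTOR = 0.9805

_MIN_CENTER_DISTANCE = 0.1  # Å; coincident-molecule guard


@dataclass(frozen=True)
class MonomerModeSet:
    """Local vibrational modes of a single molecule.

    Parameters
    ----------
    mode_labels
        One identifier per mode (e.g. ``"CF-sym"``).
    frequencies
        Per-mode wavenumbers in cm^-1 *after* any harmonic scale factor
        has been applied.
    dipole_vectors
        Per-mode transition-dipole 3-vectors in the molecule frame, in
        debye.  Zero vectors are permitted (dark local modes).
    dipole_origins
        Per-mode dipole positions in the molecule frame, in ångström.
        Defaults to the molecular center.
    scale_factor
        The harmonic scale factor that produced ``frequencies`` (kept
        for provenance; 1.0 means the frequencies were supplied as
        effective values).
    """

    mode_labels: tuple
    frequencies: np.ndarray
    dipole_vectors: np.ndarray
    dipole_origins: np.ndarray = None  # type: ignore[assignment]
    scale_factor: float = 1.0

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        dips = np.asarray(self.dipole_vectors, dtype=float).reshape(-1, 3)
        if self.dipole_origins is None:
            origins = np.zeros_like(dips)
        else:
            origins = np.asarray(self.dipole_origins, dtype=float).reshape(-1, 3)
        labels = tuple(str(l) for l in self.mode_labels)
        if not (len(labels) == freqs.size == dips.shape[0] == origins.shape[0]):
            raise ValueError("mode_labels, frequencies, dipole_vectors and "
                             "dipole_origins must have matching lengths")
        if len(set(labels)) != len(labels):
            raise ValueError("mode_labels must be unique")
        if np.any(freqs <= 0):
            raise ValueError("all mode frequencies must be > 0 cm^-1")
        if not np.all(np.isfinite(dips)):
            raise ValueError("dipole_vectors must be finite")
        if not (0.5 < self.scale_factor < 1.5):
            raise ValueError("scale_factor must lie in (0.5, 1.5)")
        object.__setattr__(self, "mode_labels", labels)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "dipole_vectors", dips)
        object.__setattr__(self, "dipole_origins", origins)

    @classmethod
    def from_harmonic(cls, mode_labels, raw_frequencies, dipole_vectors,
                      dipole_origins=None, scale_factor=DEFAULT_SCALE_FACTOR):
        """Build a mode set from unscaled harmonic frequencies.

        Applies ``scale_factor`` to ``raw_frequencies`` (the usual
        correction for systematic overestimation of harmonic
        wavenumbers).
        """
        raw = np.asarray(raw_frequencies, dtype=float)
        return cls(mode_labels=tuple(mode_labels),
                   frequencies=raw * scale_factor,
                   dipole_vectors=dipole_vectors,
                   dipole_origins=dipole_origins,
                   scale_factor=scale_factor)

    @property
    def n_modes(self) -> int:
        return len(self.mode_labels)

    def mode_indices(self, mode_subset: Optional[Sequence[str]]) -> np.ndarray:
        """Resolve a subset of mode labels to integer indices."""
        if mode_subset is None:
            return np.arange(self.n_modes)
        idx = []
        for label in mode_subset:
            if label not in self.mode_labels:
                raise KeyError(f"unknown mode label {label!r}; known labels: "
                               f"{list(self.mode_labels)}")
            idx.append(self.mode_labels.index(label))
        return np.asarray(idx, dtype=int)

    def to_dict(self) -> dict:
        return {
            "mode_labels": list(self.mode_labels),
            "frequencies": self.frequencies.tolist(),
            "dipole_vectors": self.dipole_vectors.tolist(),
            "dipole_origins": self.dipole_origins.tolist(),
            "scale_factor": self.scale_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MonomerModeSet":
        return cls(mode_labels=tuple(d["mode_labels"]),
                   frequencies=np.asarray(d["frequencies"], dtype=float),
                   dipole_vectors=np.asarray(d["dipole_vectors"], dtype=float),
                   dipole_origins=np.asarray(d["dipole_origins"], dtype=float),
                   scale_factor=float(d["scale_factor"]))


# ---------------------------------------------------------------------------
# Built-in single-dipole monomer surrogates.
#
# These stand in for ab initio monomer parameterizations: one bright local
# mode per surrogate, with the transition dipole in the monolayer plane
# (+x) for an upright amphiphile whose chain axis is the surface normal.
# ---------------------------------------------------------------------------

def pfoa_single_mode() -> MonomerModeSet:
    """Single C–F stretch surrogate for perfluorooctanoate: 1213 cm^-1, 0.5 D."""
    return MonomerModeSet(("CF",), np.array([1213.0]),
                          np.array([[0.5, 0.0, 0.0]]))


def pfoa_cf_band_modes() -> MonomerModeSet:
    """Three-band C–F surrogate spanning the 1100–1280 cm^-1 window.

    Synthetic stand-in for a full normal-mode parameterization: three
    bright C–F stretching modes at the model band centers with mixed
    in-plane polarizations.
    """
    return MonomerModeSet(
        ("CF3-as", "CF2-as", "CF2-ss"),
        np.array([1254.0, 1214.0, 1153.0]),
        np.array([[0.30, 0.10, 0.05],
                  [0.50, 0.00, 0.00],
                  [0.20, 0.25, 0.05]]),
    )


def aa_ch_mode() -> MonomerModeSet:
    """Single C–H stretch surrogate for arachidic acid: 2918 cm^-1, 0.25 D."""
    return MonomerModeSet(("CH2-as",), np.array([2918.0]),
                          np.array([[0.25, 0.0, 0.0]]))


def octanoic_ch_mode() -> MonomerModeSet:
    """Single C–H stretch surrogate for octanoic acid (same band as AA)."""
    return MonomerModeSet(("CH2-as",), np.array([2918.0]),
                          np.array([[0.25, 0.0, 0.0]]))


BUILTIN_MODE_SETS = {
    "pfoa_single": pfoa_single_mode,
    "pfoa_cf_bands": pfoa_cf_band_modes,
    "aa_ch": aa_ch_mode,
    "octanoic_ch": octanoic_ch_mode,
}


@dataclass
class MolecularConfiguration:
    """Rigid-body positions and orientations of N identical molecules.

    ``positions`` are lab-frame molecular centers (Å); ``orientations``
    are proper rotation matrices taking molecule-frame vectors to the
    lab frame.  ``freq_offsets`` holds optional per-molecule, per-mode
    diagonal disorder in cm^-1.
    """

    positions: np.ndarray
    orientations: np.ndarray
    mode_set: MonomerModeSet
    freq_offsets: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(
            -1, 3, 3)
        if self.orientations.shape[0] != self.positions.shape[0]:
            raise ValueError("positions and orientations disagree on the "
                             "number of molecules")
        if self.freq_offsets is not None:
            self.freq_offsets = np.asarray(self.freq_offsets, dtype=float).reshape(
                self.n_molecules, self.mode_set.n_modes)
        self.validate()

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    def validate(self, tol: float = 1e-10) -> None:
        """Check rotation properness and the coincident-molecule guard."""
        R = self.orientations
        eye = np.eye(3)
        gram_err = np.abs(R @ np.transpose(R, (0, 2, 1)) - eye).max()
        if gram_err > tol:
            raise ValueError(f"orientations not orthonormal (max deviation "
                             f"{gram_err:.3e} > {tol:.0e})")
        dets = np.linalg.det(R)
        if np.abs(dets - 1.0).max() > 1e-8:
            raise ValueError("orientations must be proper rotations (det=+1)")
        if self.n_molecules > 1:
            dmin = pdist(self.positions).min()
            if dmin <= _MIN_CENTER_DISTANCE:
                raise ValueError(f"minimum inter-molecular center distance "
                                 f"{dmin:.3g} Å <= {_MIN_CENTER_DISTANCE} Å")

    def min_center_distance(self) -> float:
        """Nearest-neighbor center-of-mass distance (Å)."""
        if self.n_molecules < 2:
            raise ValueError("need at least two molecules for a distance")
        return float(pdist(self.positions).min())

    def local_frequencies(self, mode_indices: Optional[np.ndarray] = None
                          ) -> np.ndarray:
        """(N, M) local-mode frequencies including diagonal disorder."""
        if mode_indices is None:
            mode_indices = np.arange(self.mode_set.n_modes)
        base = self.mode_set.frequencies[mode_indices]
        freqs = np.broadcast_to(base, (self.n_molecules, mode_indices.size)).copy()
        if self.freq_offsets is not None:
            freqs += self.freq_offsets[:, mode_indices]
        return freqs

    def lab_dipoles(self, mode_indices: Optional[np.ndarray] = None
                    ) -> np.ndarray:
        """(N, M, 3) lab-frame transition dipoles (debye)."""
        if mode_indices is None:
            mode_indices = np.arange(self.mode_set.n_modes)
        mu = self.mode_set.dipole_vectors[mode_indices]  # (M, 3)
        return np.einsum("nij,mj->nmi", self.orientations, mu)

    def dipole_positions(self, mode_indices: Optional[np.ndarray] = None
                         ) -> np.ndarray:
        """(N, M, 3) lab-frame dipole origins (Å)."""
        if mode_indices is None:
            mode_indices = np.arange(self.mode_set.n_modes)
        origins = self.mode_set.dipole_origins[mode_indices]  # (M, 3)
        shifted = np.einsum("nij,mj->nmi", self.orientations, origins)
        return self.positions[:, None, :] + shifted

    def copy(self) -> "MolecularConfiguration":
        return MolecularConfiguration(
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            mode_set=self.mode_set,
            freq_offsets=None if self.freq_offsets is None
            else self.freq_offsets.copy(),
            metadata=copy.deepcopy(self.metadata),
        )


@dataclass
class SnapshotEnsemble:
    """Ordered list of configurations emulating MD snapshots."""

    snapshots: list
    seed: int
    disorder_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.snapshots:
            raise ValueError("ensemble must contain at least one snapshot")
        ref = self.snapshots[0]
        for snap in self.snapshots:
            if snap.mode_set is not ref.mode_set:
                raise ValueError("all snapshots must share the same mode_set")
            if snap.n_molecules != ref.n_molecules:
                raise ValueError("all snapshots must share the molecule count")

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @property
    def mode_set(self) -> MonomerModeSet:
        return self.snapshots[0].mode_set

    def __iter__(self):
        return iter(self.snapshots)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n rotation matrices uniform over SO(3), via unit-quaternion sampling.

    Normalized 4D Gaussians are uniform on S^3, hence uniform over
    proper rotations.
    """
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix().reshape(n, 3, 3)


def make_2d_sheet(nx: int, ny: int, area_per_molecule: float,
                  mode_set: MonomerModeSet,
                  orientation_policy: str = "identical",
                  seed: int = 0) -> MolecularConfiguration:
    """Square-lattice monolayer sheet in the z=0 plane.

    ``nx * ny`` molecules are placed on a square lattice with spacing
    ``sqrt(area_per_molecule)``, centered on the origin, with the
    monolayer normal along +z.  ``orientation_policy`` is ``identical``
    (all molecules in the reference orientation, hence all-parallel
    dipoles) or ``random`` (independent uniform rotations about the
    surface normal).
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if area_per_molecule <= 0:
        raise ValueError(f"area_per_molecule must be > 0 Å^2, got "
                         f"{area_per_molecule}")
    spacing = float(np.sqrt(area_per_molecule))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pos = np.zeros((nx * ny, 3))
    pos[:, 0] = (ix.ravel() - (nx - 1) / 2.0) * spacing
    pos[:, 1] = (iy.ravel() - (ny - 1) / 2.0) * spacing
    n = nx * ny
    if orientation_policy == "identical":
        orients = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    elif orientation_policy == "random":
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0.0, 2.0 * np.pi, size=(n, 1))
        orients = Rotation.from_euler("z", angles).as_matrix().reshape(n, 3, 3)
    else:
        raise ValueError(f"unknown orientation_policy {orientation_policy!r}")
    meta = {
        "generator": "make_2d_sheet",
        "nx": nx, "ny": ny,
        "area_per_molecule": float(area_per_molecule),
        "spacing": spacing,
        "orientation_policy": orientation_policy,
        "seed": int(seed),
        "domain_area": float(nx * ny * area_per_molecule),
        "dimensionality": "2D",
    }
    return MolecularConfiguration(pos, orients, mode_set, metadata=meta)


def make_3d_cell(n_per_axis: int, spacing: float, mode_set: MonomerModeSet,
                 seed: int = 0) -> MolecularConfiguration:
    """Cubic cell of ``n_per_axis**3`` molecules with uniform random orientations."""
    if n_per_axis < 1:
        raise ValueError("n_per_axis must be >= 1")
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0 Å, got {spacing}")
    ax = (np.arange(n_per_axis) - (n_per_axis - 1) / 2.0) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    rng = np.random.default_rng(seed)
    orients = random_rotations(pos.shape[0], rng)
    meta = {
        "generator": "make_3d_cell",
        "n_per_axis": n_per_axis,
        "spacing": float(spacing),
        "seed": int(seed),
        "domain_volume": float((n_per_axis * spacing) ** 3),
        "dimensionality": "3D",
    }
    return MolecularConfiguration(pos, orients, mode_set, metadata=meta)


def area_spacing_convert(value: float, direction: str) -> float:
    """Convert mean molecular area (Å^2) <-> square-lattice spacing (Å).

    One molecule per square-lattice site: ``spacing = sqrt(area)``.
    ``direction`` is ``"area_to_spacing"`` or ``"spacing_to_area"``.
    """
    if value <= 0:
        raise ValueError(f"value must be > 0, got {value}")
    if direction == "area_to_spacing":
        return float(np.sqrt(value))
    if direction == "spacing_to_area":
        return float(value) ** 2
    raise ValueError(f"unknown direction {direction!r}; expected "
                     "'area_to_spacing' or 'spacing_to_area'")


def uniform_scale(config: MolecularConfiguration, factor: float
                  ) -> MolecularConfiguration:
    """Scale all molecular centers about the centroid by ``factor``.

    This is the uniform compression/expansion coordinate: every pairwise
    center distance is multiplied by ``factor``.  Orientations, mode set
    and diagonal disorder are unchanged.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    out = config.copy()
    centroid = out.positions.mean(axis=0)
    out.positions = centroid + factor * (out.positions - centroid)
    out.metadata = dict(out.metadata)
    out.metadata["uniform_scale"] = float(factor) * out.metadata.get(
        "uniform_scale", 1.0)
    for key, power in (("domain_area", 2), ("domain_volume", 3)):
        if key in out.metadata:
            out.metadata[key] = out.metadata[key] * factor ** power
    if "area_per_molecule" in out.metadata:
        out.metadata["area_per_molecule"] *= factor ** 2
    if "spacing" in out.metadata:
        out.metadata["spacing"] *= factor
    return out


def _small_rotations(n: int, sigma: float, rng: np.random.Generator
                     ) -> np.ndarray:
    """n small random rotations: uniform axis, Gaussian angle ~ N(0, sigma)."""
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, sigma, size=n)
    return Rotation.from_rotvec(axes * angles[:, None]).as_matrix()


def jitter_ensemble(config: MolecularConfiguration, pos_sigma: float = 0.3,
                    rot_sigma: float = 0.1, freq_sigma: float = 5.0,
                    n_snapshots: int = 25, seed: int = 0) -> SnapshotEnsemble:
    """Snapshot ensemble with Gaussian thermal disorder about ``config``.

    Emulates the positional, orientational and site-frequency disorder
    of an MD trajectory: each snapshot displaces every center by an
    isotropic Gaussian (``pos_sigma``, Å), composes each orientation
    with a small random rotation (uniform axis, Gaussian angle
    ``rot_sigma``, rad), and adds i.i.d. diagonal frequency offsets
    ``~ N(0, freq_sigma)`` (cm^-1).  Defaults emulate modest thermal
    disorder in a condensed monolayer; deterministic per seed.
    """
    if pos_sigma < 0 or rot_sigma < 0 or freq_sigma < 0:
        raise ValueError("disorder sigmas must be >= 0")
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    rng = np.random.default_rng(seed)
    n, m = config.n_molecules, config.mode_set.n_modes
    snapshots = []
    for k in range(n_snapshots):
        snap = config.copy()
        if pos_sigma > 0:
            snap.positions = snap.positions + rng.normal(
                0.0, pos_sigma, size=(n, 3))
        if rot_sigma > 0:
            perturb = _small_rotations(n, rot_sigma, rng)
            snap.orientations = perturb @ snap.orientations
        offsets = rng.normal(0.0, freq_sigma, size=(n, m)) if freq_sigma > 0 \
            else np.zeros((n, m))
        if snap.freq_offsets is not None:
            offsets = offsets + snap.freq_offsets
        snap.freq_offsets = offsets
        snap.metadata = dict(snap.metadata)
        snap.metadata["snapshot_index"] = k
        snap.validate()
        snapshots.append(snap)
    return SnapshotEnsemble(
        snapshots=snapshots, seed=int(seed),
        disorder_params={"pos_sigma": float(pos_sigma),
                         "rot_sigma": float(rot_sigma),
                         "freq_sigma": float(freq_sigma)})
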