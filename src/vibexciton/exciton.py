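"""Transition-dipole-coupling vibrational exciton Hamiltonians.

The Frenkel-type exciton Hamiltonian for N molecules with M local modes
each is a D x D symmetric matrix (D = N*M): local-mode wavenumbers on
the diagonal (including any diagonal disorder) and point-dipole
couplings

    J_ij = K * [mu_i.mu_j - 3 (mu_i.rhat)(mu_j.rhat)] / R^3

off the diagonal, with K the vacuum prefactor in cm^-1 Å^3 D^-2 (see
:mod:`vibexciton.constants`).  Local modes of one molecule are treated
as pre-diagonalized normal modes, so intra-molecular off-diagonal
couplings are zero by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import K_DIPOLE
from .structures import MolecularConfiguration

__all__ = [
    "ExcitonHamiltonian",
    "ExcitonStates",
    "StickSpectrum",
    "dipole_coupling",
    "build_hamiltonian",
    "diagonalize",
    "uncoupled_states",
    "stick_spectrum",
]

logger = logging.getLogger(__name__)

_COINCIDENT_TOL = 1e-8  # Å


@dataclass
class ExcitonHamiltonian:
    """Symmetric exciton Hamiltonian in the local-mode basis (cm^-1)."""

    matrix: np.ndarray
    basis_index: list  # [(molecule_index, mode_label), ...]
    config_ref: dict = field(default_factory=dict)

    def __post_init__(self):
        H = np.asarray(self.matrix, dtype=float)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ValueError("Hamiltonian must be a square matrix")
        if len(self.basis_index) != H.shape[0]:
            raise ValueError("basis_index length must match matrix dimension")
        scale = max(np.abs(H).max(), 1.0)
        if np.abs(H - H.T).max() > 1e-12 * scale:
            raise ValueError("Hamiltonian is not symmetric")
        self.matrix = H

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def to_text(self, matrix_path, basis_path) -> None:
        """Dump the matrix and basis index as plain text for debugging."""
        np.savetxt(matrix_path, self.matrix, fmt="%.12g")
        with open(basis_path, "w", encoding="utf-8") as fh:
            fh.write("basis_index,molecule,mode_label\n")
            for i, (mol, label) in enumerate(self.basis_index):
                fh.write(f"{i},{mol},{label}\n")


@dataclass
class ExcitonStates:
    """Eigenstates of an exciton Hamiltonian (or its uncoupled diagonal).

    ``coefficients[:, k]`` is the k-th eigenvector in the local-mode
    basis; ``state_dipoles[k] = sum_i c_ik mu_i`` in the lab frame and
    ``intensities[k] = |state_dipoles[k]|^2`` (debye^2).
    """

    frequencies: np.ndarray
    coefficients: np.ndarray
    state_dipoles: np.ndarray
    intensities: np.ndarray
    coupled_flag: bool
    basis_index: list = field(default_factory=list)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < -1e-12):
            raise ValueError("intensities must be non-negative")
        self.intensities = np.clip(self.intensities, 0.0, None)

    @property
    def n_states(self) -> int:
        return self.frequencies.size

    def total_intensity(self) -> float:
        """Total oscillator-strength proxy, sum_k |d_k|^2 (debye^2)."""
        return float(self.intensities.sum())

    def dominant_labels(self) -> list:
        """Per-state dominant local-mode label.

        The label whose summed squared coefficients (over molecules)
        dominate state k; used to group states into bands.
        """
        if not self.basis_index:
            raise ValueError("basis_index required for label assignment")
        labels = sorted({label for _, label in self.basis_index})
        lab_to_col = {lab: j for j, lab in enumerate(labels)}
        member = np.array([lab_to_col[label] for _, label in self.basis_index])
        c2 = self.coefficients ** 2  # (D, K)
        weights = np.zeros((len(labels), self.n_states))
        np.add.at(weights, member, c2)
        best = np.argmax(weights, axis=0)
        return [labels[b] for b in best]


@dataclass
class StickSpectrum:
    """Discrete line spectrum: (wavenumber, intensity) pairs, ascending."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    labels: Optional[list] = None

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must match in shape")
        if np.any(self.intensities < 0):
            raise ValueError("stick intensities must be >= 0")

    @property
    def n_lines(self) -> int:
        return self.wavenumbers.size

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"wavenumber_cm1": self.wavenumbers,
                      "intensity_D2": self.intensities}).to_csv(path,
                                                                index=False)


def dipole_coupling(mu_i, mu_j, r_i, r_j) -> float:
    """Vacuum point-dipole coupling J between two transition dipoles, cm^-1.

    ``mu_i``/``mu_j`` are lab-frame dipole vectors in debye at positions
    ``r_i``/``r_j`` in ångström.  J follows the kappa/R^3 form with
    kappa = mu_i.mu_j - 3 (mu_i.rhat)(mu_j.rhat) evaluated on the full
    (unnormalized) dipoles.
    """
    mu_i = np.asarray(mu_i, dtype=float)
    mu_j = np.asarray(mu_j, dtype=float)
    dr = np.asarray(r_j, dtype=float) - np.asarray(r_i, dtype=float)
    R = np.linalg.norm(dr)
    if R < _COINCIDENT_TOL:
        raise ValueError("coincident dipole positions (separation "
                         f"{R:.3g} Å)")
    rhat = dr / R
    kappa_mu2 = mu_i @ mu_j - 3.0 * (mu_i @ rhat) * (mu_j @ rhat)
    return float(K_DIPOLE * kappa_mu2 / R**3)


def build_hamiltonian(config: MolecularConfiguration,
                      mode_subset: Optional[Sequence[str]] = None,
                      include_intramolecular: bool = False,
                      ) -> ExcitonHamiltonian:
    """Assemble the dipole-coupling exciton Hamiltonian for a configuration.

    Every pair of basis modes on *different* molecules is coupled via
    :func:`dipole_coupling` using lab-frame (rotated) dipoles placed at
    the mode-specific dipole origins.  Intra-molecular off-diagonal
    couplings are zero unless ``include_intramolecular`` (monomer modes
    are normal modes, i.e. already diagonal).
    """
    mode_idx = config.mode_set.mode_indices(mode_subset)
    n, m = config.n_molecules, mode_idx.size
    freqs = config.local_frequencies(mode_idx)         # (N, M)
    mu = config.lab_dipoles(mode_idx).reshape(n * m, 3)
    pos = config.dipole_positions(mode_idx).reshape(n * m, 3)
    mol_of = np.repeat(np.arange(n), m)

    D = n * m
    H = np.zeros((D, D))
    # Row-chunked pairwise assembly keeps memory bounded for large D.
    chunk = max(1, min(D, 512))
    for start in range(0, D, chunk):
        stop = min(start + chunk, D)
        dr = pos[None, start:stop, :] - pos[:, None, :]      # (D, c, 3)
        R = np.linalg.norm(dr, axis=-1)
        same_mol = mol_of[:, None] == mol_of[None, start:stop]
        bad = (R < _COINCIDENT_TOL) & ~same_mol
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError("coincident dipole positions between molecules "
                             f"{mol_of[i]} and {mol_of[start + j]}")
        Rsafe = np.where(R < _COINCIDENT_TOL, 1.0, R)
        rhat = dr / Rsafe[..., None]
        dot_mm = mu @ mu[start:stop].T                        # (D, c)
        proj_i = np.einsum("ik,ijk->ij", mu, -rhat)           # mu_i . rhat_ij
        proj_j = np.einsum("jk,ijk->ij", mu[start:stop], -rhat)
        kappa_mu2 = dot_mm - 3.0 * proj_i * proj_j
        J = K_DIPOLE * kappa_mu2 / Rsafe**3
        mask = same_mol if not include_intramolecular \
            else (np.arange(D)[:, None] == np.arange(start, stop)[None, :])
        J[mask] = 0.0
        H[:, start:stop] = J
    H[np.diag_indices(D)] = freqs.ravel()
    H = 0.5 * (H + H.T)  # enforce exact symmetry against roundoff

    labels = [config.mode_set.mode_labels[k] for k in mode_idx]
    basis = [(i, lab) for i in range(n) for lab in labels]
    logger.info("built %dx%d exciton Hamiltonian (K = %.6g cm^-1 Å^3 D^-2, "
                "intramolecular couplings %s)", D, D, K_DIPOLE,
                "on" if include_intramolecular else "off")
    return ExcitonHamiltonian(matrix=H, basis_index=basis,
                              config_ref={"n_molecules": n,
                                          "mode_labels": labels,
                                          **{k: v for k, v in
                                             config.metadata.items()
                                             if np.isscalar(v) or
                                             isinstance(v, str)}})


def _states_from_eig(frequencies, coefficients, mu, coupled, basis):
    """Order states, form state dipoles/intensities, package as ExcitonStates."""
    state_dipoles = coefficients.T @ mu                   # (K, 3)
    intensities = np.einsum("ki,ki->k", state_dipoles, state_dipoles)
    # Stable ordering: ascending frequency, ties broken by descending intensity.
    order = np.lexsort((-intensities, frequencies))
    return ExcitonStates(frequencies=frequencies[order],
                         coefficients=coefficients[:, order],
                         state_dipoles=state_dipoles[order],
                         intensities=intensities[order],
                         coupled_flag=coupled,
                         basis_index=list(basis))


def diagonalize(H: ExcitonHamiltonian, config: MolecularConfiguration
                ) -> ExcitonStates:
    """Diagonalize the exciton Hamiltonian; coupled eigenstates.

    State dipoles are coherent sums of the lab-frame local dipoles,
    ``d_k = sum_i c_ik mu_i``, so intensity redistributes among exciton
    states while the total ``sum_k |d_k|^2 = sum_i |mu_i|^2`` is
    conserved (oscillator-strength sum rule, by orthogonality).
    """
    mode_labels = list(dict.fromkeys(lab for _, lab in H.basis_index))
    mode_idx = config.mode_set.mode_indices(mode_labels)
    mu = config.lab_dipoles(mode_idx).reshape(H.dimension, 3)
    evals, evecs = np.linalg.eigh(H.matrix)
    return _states_from_eig(evals, evecs, mu, True, H.basis_index)


def uncoupled_states(config: MolecularConfiguration,
                     mode_subset: Optional[Sequence[str]] = None
                     ) -> ExcitonStates:
    """Reference states with all inter-molecular couplings switched off.

    Frequencies are the (disorder-shifted) local-mode wavenumbers and
    each state carries its own local dipole; this is the thermally
    broadened but non-interacting baseline I0.
    """
    mode_idx = config.mode_set.mode_indices(mode_subset)
    n, m = config.n_molecules, mode_idx.size
    freqs = config.local_frequencies(mode_idx).ravel()
    mu = config.lab_dipoles(mode_idx).reshape(n * m, 3)
    labels = [config.mode_set.mode_labels[k] for k in mode_idx]
    basis = [(i, lab) for i in range(n) for lab in labels]
    return _states_from_eig(freqs, np.eye(n * m), mu, False, basis)


def stick_spectrum(states: ExcitonStates, with_labels: bool = False
                   ) -> StickSpectrum:
    """Line list (frequency, intensity) from exciton states, ascending.

    Dark (zero-intensity) states are retained.  With ``with_labels``,
    each line is tagged with the state's dominant local-mode label (for
    band grouping across snapshots).
    """
    labels = states.dominant_labels() if with_labels else None
    return StickSpectrum(wavenumbers=states.frequencies.copy(),
                         intensities=states.intensities.copy(),
                         labels=labels)
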