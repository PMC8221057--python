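"""Broadened spectra and spectral analyses for exciton ensembles.

Stick spectra from snapshot ensembles are turned into Gaussian-broadened
spectra on a uniform wavenumber grid (default 0.5 cm^-1 step, the
instrument sampling).  Analyses mirror the standard IRRAS workflow:
difference spectra Delta-I = I - I0 between coupled and uncoupled
models, linear-baseline peak areas, band-center picking, 2D
energy-intensity histograms, the weak-mode fraction, and the
reflectance-absorbance transform RA = -log10(Rm/R0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .exciton import ExcitonStates, StickSpectrum

__all__ = [
    "BroadenedSpectrum",
    "DifferenceSpectrum",
    "HistogramGrid",
    "IRRASTrace",
    "wavenumber_grid",
    "broaden_ensemble",
    "difference_spectrum",
    "integrate_peak_area",
    "find_band_centers",
    "energy_intensity_histogram",
    "weak_mode_fraction",
    "reflectance_absorbance",
]

#: Default experimental windows (cm^-1).
CF_WINDOW = (1100.0, 1280.0)
CH_WINDOW = (2800.0, 3000.0)
DEFAULT_GRID_STEP = 0.5


@dataclass
class BroadenedSpectrum:
    """Intensity on a uniform wavenumber grid (arbitrary units ~ debye^2)."""

    grid: np.ndarray
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be matching 1D arrays")
        steps = np.diff(self.grid)
        if self.grid.size > 1 and (np.any(steps <= 0) or
                                   np.ptp(steps) > 1e-9 * steps.mean()):
            raise ValueError("grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        """Trapezoidal integral over the full grid (intensity · cm^-1)."""
        return float(np.trapezoid(self.values, self.grid))

    def moments(self) -> Tuple[float, float]:
        """Intensity-weighted mean frequency and frequency variance."""
        w = self.values.clip(0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("cannot take moments of a non-positive spectrum")
        mean = float((w * self.grid).sum() / total)
        var = float((w * (self.grid - mean) ** 2).sum() / total)
        return mean, var

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"wavenumber_cm1": self.grid,
                      "intensity": self.values}).to_csv(path, index=False)


@dataclass
class DifferenceSpectrum:
    """Delta-I = I - I0 restricted to an observation window."""

    grid: np.ndarray
    delta: np.ndarray
    window: Tuple[float, float]

    def integral(self) -> float:
        return float(np.trapezoid(self.delta, self.grid))

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"wavenumber_cm1": self.grid,
                      "delta_intensity": self.delta}).to_csv(path, index=False)


@dataclass
class HistogramGrid:
    """2D histogram correlating state energy and intensity."""

    energy_edges: np.ndarray
    intensity_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.energy_edges = np.asarray(self.energy_edges, dtype=float)
        self.intensity_edges = np.asarray(self.intensity_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.energy_edges) <= 0) or \
           np.any(np.diff(self.intensity_edges) <= 0):
            raise ValueError("histogram edges must be increasing")
        if np.any(self.counts < 0):
            raise ValueError("histogram weights must be >= 0")

    def occupied_energy_columns(self) -> int:
        """Number of energy bins holding any weight (delocalization proxy)."""
        return int(np.count_nonzero(self.counts.sum(axis=1)))

    def to_csv(self, path) -> None:
        import pandas as pd
        ne, ni = self.counts.shape
        rows = []
        for i in range(ne):
            for j in range(ni):
                rows.append((self.energy_edges[i], self.energy_edges[i + 1],
                             self.intensity_edges[j],
                             self.intensity_edges[j + 1],
                             self.counts[i, j]))
        pd.DataFrame(rows, columns=["energy_lo", "energy_hi", "intensity_lo",
                                    "intensity_hi", "weight"]
                     ).to_csv(path, index=False)


@dataclass
class IRRASTrace:
    """Reflectivities and the derived reflectance-absorbance."""

    grid: np.ndarray
    Rm: np.ndarray
    R0: np.ndarray
    RA: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.Rm = np.asarray(self.Rm, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)
        if self.RA is None:
            self.RA = reflectance_absorbance(self.Rm, self.R0)


def wavenumber_grid(lo: float, hi: float, step: float = DEFAULT_GRID_STEP
                    ) -> np.ndarray:
    """Uniform wavenumber axis from lo to hi inclusive (cm^-1)."""
    if hi <= lo or step <= 0:
        raise ValueError("need hi > lo and step > 0")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _as_grid(grid) -> np.ndarray:
    if isinstance(grid, (tuple, list)) and len(grid) in (2, 3):
        return wavenumber_grid(*grid)
    return np.asarray(grid, dtype=float)


def _band_table(sticks: Sequence[StickSpectrum], band_assignment: str):
    """Collect per-band frequency samples and intensities across snapshots.

    ``state_index``: the k-th line (ascending frequency) of each
    snapshot belongs to band k — the natural matching when all
    snapshots share one Hamiltonian dimension.
    ``mode_label``: lines are pooled by their dominant local-mode label
    (requires labeled sticks); the band frequency per snapshot is the
    intensity-weighted mean of its lines and the band intensity their sum.

    Returns (freq_samples, intensity_samples) as (n_bands, n_snapshots).
    """
    n_snap = len(sticks)
    if band_assignment == "state_index":
        n_lines = {s.n_lines for s in sticks}
        if len(n_lines) != 1:
            raise ValueError("state_index band assignment requires equal "
                             "line counts across snapshots")
        freqs = np.stack([np.sort(s.wavenumbers) for s in sticks], axis=1)
        order = [np.argsort(s.wavenumbers, kind="stable") for s in sticks]
        intens = np.stack([s.intensities[o] for s, o in zip(sticks, order)],
                          axis=1)
        return freqs, intens
    if band_assignment == "mode_label":
        if any(s.labels is None for s in sticks):
            raise ValueError("mode_label band assignment requires labeled "
                             "stick spectra (stick_spectrum(..., "
                             "with_labels=True))")
        labels = sorted({lab for s in sticks for lab in s.labels})
        freqs = np.zeros((len(labels), n_snap))
        intens = np.zeros((len(labels), n_snap))
        for j, s in enumerate(sticks):
            labs = np.asarray(s.labels)
            for i, lab in enumerate(labels):
                sel = labs == lab
                if not np.any(sel):
                    raise ValueError(f"band {lab!r} missing from snapshot {j}")
                w = s.intensities[sel]
                nu = s.wavenumbers[sel]
                total = w.sum()
                freqs[i, j] = nu.mean() if total <= 0 else (w * nu).sum() / total
                intens[i, j] = total
        return freqs, intens
    raise ValueError(f"unknown band_assignment {band_assignment!r}")


def broaden_ensemble(ensemble_sticks: Sequence[StickSpectrum], grid,
                     band_assignment: str = "state_index",
                     width_scale: float = 2.0,
                     width_floor: float = 1.0,
                     provenance: Optional[dict] = None) -> BroadenedSpectrum:
    """Gaussian-broadened ensemble spectrum on a uniform grid.

    Lines are grouped into bands across snapshots (``band_assignment``);
    each band contributes a Gaussian centered at its ensemble-mean
    frequency whose sigma parameter is ``width_scale`` times the
    across-snapshot (population) standard deviation of the band
    frequency, floored at ``width_floor`` cm^-1, with area equal to the
    ensemble-mean band intensity.  The default ``width_scale=2``
    implements the "2-sigma" ensemble-width convention.
    """
    if len(ensemble_sticks) == 0:
        raise ValueError("ensemble must contain at least one stick spectrum")
    if width_floor < 0 or width_scale <= 0:
        raise ValueError("width_scale must be > 0 and width_floor >= 0")
    axis = _as_grid(grid)
    freqs, intens = _band_table(ensemble_sticks, band_assignment)
    centers = freqs.mean(axis=1)
    sigmas = np.maximum(width_scale * freqs.std(axis=1, ddof=0), width_floor)
    areas = intens.mean(axis=1)
    if np.any(sigmas <= 0):
        raise ValueError("zero band width with zero width_floor")
    values = np.zeros_like(axis)
    norm = areas / (sigmas * np.sqrt(2.0 * np.pi))
    for c, s, a in zip(centers, sigmas, norm):
        if a == 0.0:
            continue
        values += a * np.exp(-0.5 * ((axis - c) / s) ** 2)
    prov = {"band_assignment": band_assignment,
            "width_scale": width_scale, "width_floor": width_floor,
            "n_snapshots": len(ensemble_sticks),
            "n_bands": int(centers.size)}
    if provenance:
        prov.update(provenance)
    return BroadenedSpectrum(grid=axis, values=values, provenance=prov)


def difference_spectrum(I: BroadenedSpectrum, I0: BroadenedSpectrum,
                        window: Tuple[float, float] = CF_WINDOW
                        ) -> DifferenceSpectrum:
    """Delta-I = I - I0 restricted to the observation window."""
    if I.grid.shape != I0.grid.shape or \
            np.abs(I.grid - I0.grid).max() > 1e-9:
        raise ValueError("coupled and uncoupled spectra must share a grid")
    lo, hi = window
    sel = (I.grid >= lo) & (I.grid <= hi)
    if not np.any(sel):
        raise ValueError("window does not overlap the spectrum grid")
    return DifferenceSpectrum(grid=I.grid[sel],
                              delta=I.values[sel] - I0.values[sel],
                              window=(float(lo), float(hi)))


def integrate_peak_area(spectrum: BroadenedSpectrum, lo: float, hi: float,
                        baseline: str = "linear") -> float:
    """Baseline-subtracted trapezoidal peak area between lo and hi.

    With ``baseline='linear'`` the straight line through the spectrum
    values at the two endpoints is subtracted first (the standard
    endpoint-anchored baseline correction for IRRAS band areas).
    """
    grid, vals = spectrum.grid, spectrum.values
    if not (grid[0] <= lo < hi <= grid[-1]):
        raise ValueError(f"window [{lo}, {hi}] outside grid "
                         f"[{grid[0]}, {grid[-1]}]")
    x = np.concatenate([[lo], grid[(grid > lo) & (grid < hi)], [hi]])
    y = np.interp(x, grid, vals)
    if baseline == "linear":
        y = y - (y[0] + (y[-1] - y[0]) * (x - lo) / (hi - lo))
    elif baseline != "none":
        raise ValueError(f"unknown baseline {baseline!r}")
    return float(np.trapezoid(y, x))


def find_band_centers(spectrum: BroadenedSpectrum, n_peaks: int,
                      min_prominence: float = 0.02) -> list:
    """Centers of the ``n_peaks`` most prominent local maxima, cm^-1.

    Prominence threshold is a fraction of the spectrum maximum.  Returns
    centers sorted descending in wavenumber, resolved to the grid step;
    if fewer maxima exist, returns what there is and warns.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    vmax = spectrum.values.max()
    if vmax <= 0:
        warnings.warn("spectrum has no positive signal; no band centers")
        return []
    idx, props = find_peaks(spectrum.values,
                            prominence=min_prominence * vmax)
    if idx.size < n_peaks:
        warnings.warn(f"requested {n_peaks} band centers but found only "
                      f"{idx.size}")
    top = idx[np.argsort(props["prominences"])[::-1][:n_peaks]]
    return sorted((float(spectrum.grid[i]) for i in top), reverse=True)


def _match_states_by_overlap(coupled: ExcitonStates,
                             uncoupled: ExcitonStates) -> np.ndarray:
    """Index of the basis (uncoupled) state dominating each coupled state."""
    return np.argmax(coupled.coefficients ** 2, axis=0)


def energy_intensity_histogram(states_ensemble: Sequence[ExcitonStates],
                               energy_bins, intensity_bins,
                               paired_uncoupled: Optional[
                                   Sequence[ExcitonStates]] = None,
                               weight: str = "count") -> HistogramGrid:
    """Snapshot-averaged 2D histogram of (frequency, intensity).

    Each state contributes one count (or its intensity, with
    ``weight='intensity'``) at (frequency, intensity); weights are
    averaged over snapshots.  With ``paired_uncoupled`` the intensity
    axis instead bins I - I0, matching each coupled state to the basis
    state that dominates its eigenvector.
    """
    if len(states_ensemble) == 0:
        raise ValueError("need at least one snapshot of states")
    if paired_uncoupled is not None and \
            len(paired_uncoupled) != len(states_ensemble):
        raise ValueError("paired ensembles must have equal length")
    e_edges = np.asarray(energy_bins, dtype=float)
    i_edges = np.asarray(intensity_bins, dtype=float)
    counts = np.zeros((e_edges.size - 1, i_edges.size - 1))
    for k, states in enumerate(states_ensemble):
        x = states.frequencies
        if paired_uncoupled is None:
            y = states.intensities
        else:
            u = paired_uncoupled[k]
            # Uncoupled states are basis states; order them back to the basis.
            basis_int = np.empty(u.n_states)
            basis_int[np.argmax(u.coefficients ** 2, axis=0)] = u.intensities
            y = states.intensities - basis_int[
                _match_states_by_overlap(states, u)]
        w = states.intensities if weight == "intensity" else None
        h, _, _ = np.histogram2d(x, y, bins=(e_edges, i_edges), weights=w)
        counts += h
    counts /= len(states_ensemble)
    return HistogramGrid(energy_edges=e_edges, intensity_edges=i_edges,
                         counts=counts)


def weak_mode_fraction(sticks: StickSpectrum, ratio: float = 10.0) -> float:
    """Fraction of lines at least ``ratio``-fold weaker than the brightest.

    The intensity-borrowing fingerprint: coupling spawns many states an
    order of magnitude weaker than the most prominent peak.  Invariant
    under uniform intensity rescaling.
    """
    if sticks.n_lines == 0:
        raise ValueError("empty stick spectrum")
    vmax = sticks.intensities.max()
    if vmax <= 0:
        raise ValueError("weak-mode fraction undefined for an all-dark "
                         "spectrum")
    return float(np.mean(sticks.intensities < vmax / ratio))


def reflectance_absorbance(Rm, R0) -> np.ndarray:
    """Reflectance-absorbance RA = -log10(Rm / R0), elementwise."""
    Rm = np.asarray(Rm, dtype=float)
    R0 = np.asarray(R0, dtype=float)
    if Rm.shape != R0.shape:
        raise ValueError("Rm and R0 must have the same shape")
    if np.any(Rm <= 0) or np.any(R0 <= 0):
        raise ValueError("reflectivities must be positive")
    return -np.log10(Rm / R0)
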