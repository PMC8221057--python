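"""Szyszkowski surface-tension fits and Langmuir surface concentrations.

Soluble-surfactant tensiometry data (bulk concentration C, surface
tension gamma) follow the Szyszkowski equation

    gamma(C) = gamma0 - a * ln(1 + C/b)

with gamma0 the subphase tension and (a, b) fitted parameters.  Through
the Gibbs adsorption relation this implies the Langmuir–Szyszkowski
surface concentration

    Gamma(C) = a / (R T) * C / (b + C)

saturating at a/(R T) (a converted from mN/m to J/m^2).  A linear fit
of integrated band area against Gamma exposes deviations from
Beer–Lambert proportionality, the tensiometric fingerprint of
coupling-induced signal depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .constants import R_GAS

__all__ = [
    "TensiometryDataset",
    "SzyszkowskiFit",
    "SurfaceConcentrationCurve",
    "szyszkowski_gamma",
    "fit_szyszkowski",
    "surface_concentration",
    "synth_tensiometry",
    "cross_section_fit",
]

#: mN/m -> J/m^2
_MN_PER_M_TO_J_PER_M2 = 1e-3

#: Reference subphase tension of water near 21 °C, mN/m.
WATER_GAMMA0 = 72.57
#: Reference laboratory temperature, K (21.1 °C).
ROOM_TEMPERATURE_K = 294.25


@dataclass
class TensiometryDataset:
    """(C, gamma) tensiometry data with the subphase tension gamma0."""

    concentrations: np.ndarray    # mol/L
    surface_tensions: np.ndarray  # mN/m
    gamma0: float = WATER_GAMMA0  # mN/m
    temperature: float = ROOM_TEMPERATURE_K  # K
    errors: Optional[np.ndarray] = None      # mN/m

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.surface_tensions = np.asarray(self.surface_tensions, dtype=float)
        if self.concentrations.shape != self.surface_tensions.shape:
            raise ValueError("concentrations and surface_tensions must match")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0 mol/L")
        if np.any(self.surface_tensions <= 0):
            raise ValueError("surface tensions must be > 0 mN/m")
        # Allow measurement noise above gamma0, but not grossly.
        if np.any(self.surface_tensions > self.gamma0 + 5.0):
            raise ValueError("surface tension far above the subphase value; "
                             "check units")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)

    @property
    def n_points(self) -> int:
        return self.concentrations.size

    def to_csv(self, path) -> None:
        frame = {"concentration_mol_L": self.concentrations,
                 "surface_tension_mN_m": self.surface_tensions}
        if self.errors is not None:
            frame["sd_mN_m"] = self.errors
        pd.DataFrame(frame).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, gamma0: float = WATER_GAMMA0,
                 temperature: float = ROOM_TEMPERATURE_K
                 ) -> "TensiometryDataset":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"no tensiometry rows in {path}")
        cols = list(df.columns)
        err = df[cols[2]].to_numpy() if len(cols) > 2 else None
        return cls(concentrations=df[cols[0]].to_numpy(),
                   surface_tensions=df[cols[1]].to_numpy(),
                   gamma0=gamma0, temperature=temperature, errors=err)


@dataclass
class SzyszkowskiFit:
    """Fitted Szyszkowski parameters with adjusted R^2."""

    a: float            # mN/m
    b: float            # mol/L
    gamma0: float       # mN/m (fixed, not fitted)
    temperature: float  # K
    adjusted_R2: float = np.nan
    covariance: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("fitted a and b must be positive")

    def saturation_gamma(self) -> float:
        """Saturation surface concentration a/(R T), mol/m^2."""
        return self.a * _MN_PER_M_TO_J_PER_M2 / (R_GAS * self.temperature)

    def to_dict(self) -> dict:
        return {"a_mN_m": self.a, "b_mol_L": self.b,
                "gamma0_mN_m": self.gamma0, "temperature_K": self.temperature,
                "adjusted_R2": self.adjusted_R2,
                "covariance": None if self.covariance is None
                else np.asarray(self.covariance).tolist()}


@dataclass
class SurfaceConcentrationCurve:
    """Gamma(C) curve from a Szyszkowski fit."""

    concentrations: np.ndarray  # mol/L
    gamma_surface: np.ndarray   # mol/m^2
    temperature: float

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.gamma_surface = np.asarray(self.gamma_surface, dtype=float)
        if np.any(self.gamma_surface < 0):
            raise ValueError("surface concentration must be >= 0")
        if np.any(np.diff(self.concentrations) > 0) and \
                np.any(np.diff(self.gamma_surface) < -1e-15):
            raise ValueError("Gamma must be nondecreasing in C")

    def to_csv(self, path) -> None:
        pd.DataFrame({"concentration_mol_L": self.concentrations,
                      "surface_concentration_mol_m2": self.gamma_surface}
                     ).to_csv(path, index=False)


def szyszkowski_gamma(gamma0: float, a: float, b: float, C) -> np.ndarray:
    """Szyszkowski surface tension gamma = gamma0 - a ln(1 + C/b), mN/m."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be >= 0")
    return gamma0 - a * np.log1p(C / b)


def fit_szyszkowski(data: TensiometryDataset) -> SzyszkowskiFit:
    """Nonlinear least squares for (a, b) with gamma0 fixed from the data.

    Reports adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) with p = 2
    free parameters.
    """
    C, g = data.concentrations, data.surface_tensions
    if data.n_points < 4:
        raise ValueError("need >= 4 tensiometry points")
    pos = C > 0
    if pos.sum() < 2 or C[pos].max() / C[pos].min() < 10.0:
        raise ValueError("concentrations must span at least one decade")
    if np.ptp(g) < 1e-9:
        raise ValueError("degenerate data: surface tension is constant")

    depression = np.clip(data.gamma0 - g, 1e-9, None)
    b0 = float(np.median(C[pos]))
    a0 = float(depression.max() / max(np.log1p(C.max() / b0), 1e-9))

    def resid(p):
        return szyszkowski_gamma(data.gamma0, p[0], p[1], C) - g

    sol = least_squares(resid, np.array([max(a0, 1e-6), b0]),
                        bounds=([1e-12, 1e-15], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"Szyszkowski fit did not converge: {sol.message}")
    a, b = sol.x
    ss_res = float(sol.fun @ sol.fun)
    ss_tot = float(((g - g.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    n, p = data.n_points, 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    dof = max(n - p, 1)
    try:
        cov = (ss_res / dof) * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        cov = None
    return SzyszkowskiFit(a=float(a), b=float(b), gamma0=data.gamma0,
                          temperature=data.temperature, adjusted_R2=adj,
                          covariance=cov)


def surface_concentration(fit: SzyszkowskiFit, C, T: Optional[float] = None
                          ) -> np.ndarray:
    """Langmuir–Szyszkowski surface concentration Gamma(C), mol/m^2.

    Gamma = a/(R T) * C/(b + C) with a converted from mN/m to J/m^2;
    equivalently the Gibbs adsorption isotherm applied to the fitted
    Szyszkowski curve.
    """
    T = fit.temperature if T is None else T
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be >= 0")
    a_si = fit.a * _MN_PER_M_TO_J_PER_M2
    return (a_si / (R_GAS * T)) * C / (fit.b + C)


def synth_tensiometry(gamma0: float, a: float, b: float, C_grid,
                      noise_sd: float = 0.0, seed: int = 0,
                      temperature: float = ROOM_TEMPERATURE_K
                      ) -> TensiometryDataset:
    """Synthetic tensiometry dataset from the Szyszkowski model plus noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    C = np.asarray(C_grid, dtype=float)
    g = szyszkowski_gamma(gamma0, a, b, C)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sd, size=C.shape)
    err = np.full_like(C, noise_sd) if noise_sd > 0 else None
    return TensiometryDataset(concentrations=C, surface_tensions=g,
                              gamma0=gamma0, temperature=temperature,
                              errors=err)


def cross_section_fit(areas, gammas):
    """OLS of integrated band area on surface concentration.

    Returns (slope, intercept, R^2, residuals).  The slope is the
    effective infrared cross section under Beer–Lambert behavior;
    systematically negative residuals at high Gamma flag
    coupling-induced signal depletion.
    """
    areas = np.asarray(areas, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    if areas.size != gammas.size:
        raise ValueError("areas and gammas must have equal length")
    if areas.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(gammas) <= 0:
        raise ValueError("degenerate design: all surface concentrations equal")
    res = linregress(gammas, areas)
    resid = areas - (res.slope * gammas + res.intercept)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), resid)
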