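"""Concentration-dependence models for viscosity and diffusion.

Mass concentration maps to volume fraction via c[g/L] = 1430*phi (an
empirical protein-density relation).  Relative viscosity laws, all
constrained through eta_r(0) = 1:

* Einstein hard spheres:  eta_r = 1 + 2.5*phi
* quadratic expansion:    eta_r = 1 + 2.5*phi + b*phi²  (b captures
  attractions; for adhesive hard spheres b = 5.9 + 1.9/tau_B)
* Mooney:                 eta_r = exp(S*phi/(1 - K*phi))  (S intrinsic
  viscosity, 2.5 for rigid spheres; K a self-crowding/packing factor)

Diffusion vs concentration is fitted with an effective-cluster model
D(phi) = D0 * eta_r(phi)^-1 * (1 + zeta*phi)^-p where 1 + zeta*phi is the
effective cluster size (zeta = 0: no clustering) and the exponent follows
Stokes–Einstein scaling of a compact cluster: p = 1/3 for translation
(R_h grows with size^(1/3)) and p = 1 for rotation (R_h³).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GRAMS_PER_LITER_PER_PHI",
    "ConcentrationSeries",
    "ViscosityFit",
    "DiffusionFit",
    "phi_from_c",
    "c_from_phi",
    "eta_einstein",
    "eta_quadratic",
    "eta_mooney",
    "fit_eta",
    "fit_cluster_model",
    "generalized_se_ratio",
]

#: c[g/L] = 1430 * phi
GRAMS_PER_LITER_PER_PHI = 1430.0


@dataclass
class ConcentrationSeries:
    """Observable (eta_r or D) vs concentration with uncertainties."""

    phi: np.ndarray
    values: np.ndarray
    se: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.phi < 0) or np.any(self.phi >= 0.45):
            raise ValueError("volume fractions must lie in [0, 0.45)")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    @classmethod
    def from_concentration(cls, c, values, se=None, label=""):
        return cls(phi=phi_from_c(np.asarray(c, dtype=float)), values=values,
                   se=se, label=label)


@dataclass
class ViscosityFit:
    model: str                  # einstein | quadratic | mooney
    params: dict
    covariance: Optional[np.ndarray]
    residual: float

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        if self.model == "einstein":
            return eta_einstein(phi)
        if self.model == "quadratic":
            return eta_quadratic(phi, self.params["b"])
        return eta_mooney(phi, self.params["S"], self.params["K"])


@dataclass
class DiffusionFit:
    d0: float
    zeta: float
    exponent: float
    kind: str
    covariance: Optional[np.ndarray]
    at_bound: bool = False
    ledger: dict = field(default_factory=dict)

    def cluster_size(self, phi):
        return 1.0 + self.zeta * np.asarray(phi, dtype=float)

    def __call__(self, phi, eta_r: Callable):
        phi = np.asarray(phi, dtype=float)
        return self.d0 / eta_r(phi) / self.cluster_size(phi) ** self.exponent


def phi_from_c(c):
    """Volume fraction from mass concentration in g/L."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    phi = c / GRAMS_PER_LITER_PER_PHI
    if np.any(phi >= 1):
        warnings.warn("volume fraction >= 1 is outside the physical range")
    return phi if phi.ndim else float(phi)


def c_from_phi(phi):
    """Mass concentration in g/L from volume fraction (exact inverse)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("volume fraction must be nonnegative")
    c = phi * GRAMS_PER_LITER_PER_PHI
    return c if c.ndim else float(c)


def eta_einstein(phi):
    """Hard-sphere dilute limit eta_r = 1 + 2.5*phi."""
    return 1.0 + 2.5 * np.asarray(phi, dtype=float)


def eta_quadratic(phi, b):
    """eta_r = 1 + 2.5*phi + b*phi² (Einstein term fixed)."""
    phi = np.asarray(phi, dtype=float)
    return 1.0 + 2.5 * phi + b * phi ** 2


def eta_mooney(phi, S, K):
    """Mooney law eta_r = exp(S*phi/(1 - K*phi)); requires K*phi < 1."""
    phi = np.asarray(phi, dtype=float)
    if np.any(K * phi >= 1):
        raise ValueError("Mooney pole: K*phi must stay below 1")
    return np.exp(S * phi / (1.0 - K * phi))


def fit_eta(series: ConcentrationSeries, model: str = "quadratic",
            max_c_gL: Optional[float] = None) -> ViscosityFit:
    """Weighted least squares of a viscosity law with the unity intercept
    built in.  ``max_c_gL`` restricts the fit to lower concentrations (the
    quadratic expansion is a low-phi model)."""
    phi, y = series.phi, series.values
    se = series.se
    if max_c_gL is not None:
        keep = phi <= phi_from_c(max_c_gL)
        phi, y = phi[keep], y[keep]
        se = se[keep] if se is not None else None
    if np.any(y < 1.0 - 1e-9):
        warnings.warn("relative viscosities below 1 in the fit data")
    if model == "einstein":
        resid = float(np.sum((y - eta_einstein(phi)) ** 2))
        return ViscosityFit("einstein", {}, None, resid)
    if model == "quadratic":
        if len(phi) < 3:
            raise ValueError("quadratic fit needs at least three points")
        w = 1.0 / se ** 2 if se is not None and np.all(se > 0) else \
            np.ones_like(phi)
        x = phi ** 2
        resp = y - 1.0 - 2.5 * phi
        b = float(np.sum(w * x * resp) / np.sum(w * x * x))
        var_b = 1.0 / np.sum(w * x * x)
        resid = float(np.sum(w * (resp - b * x) ** 2))
        return ViscosityFit("quadratic", {"b": b}, np.array([[var_b]]), resid)
    if model == "mooney":
        if len(phi) < 4:
            raise ValueError("mooney fit needs at least four points")
        sig = se if se is not None and np.all(se > 0) else None
        popt, pcov = curve_fit(eta_mooney, phi, y, p0=(2.5, 2.0), sigma=sig,
                               bounds=([0, 0], [50, 1 / max(phi.max(), 1e-9)]),
                               maxfev=20000)
        resid = float(np.sum((eta_mooney(phi, *popt) - y) ** 2))
        return ViscosityFit("mooney", {"S": popt[0], "K": popt[1]}, pcov,
                            resid)
    raise ValueError(f"unknown model {model!r}")


def fit_cluster_model(series: ConcentrationSeries, eta_r: Callable,
                      kind: str = "translational",
                      exponent: Optional[float] = None) -> DiffusionFit:
    """Fit D(phi) = D0 * eta_r(phi)^-1 * (1 + zeta*phi)^-p with zeta
    bounded at 0.  Default exponents: p = 1/3 translational, p = 1
    rotational; both configurable."""
    if eta_r is None:
        raise ValueError("an eta_r(phi) model is required")
    if exponent is None:
        exponent = 1.0 / 3.0 if kind == "translational" else 1.0
    phi, y = series.phi, series.values
    sig = series.se if series.se is not None and np.all(series.se > 0) \
        else None

    def model(p, d0, zeta):
        return d0 / eta_r(p) / (1.0 + zeta * p) ** exponent

    d0_guess = float(y[np.argmin(phi)]) if len(y) else 1.0
    popt, pcov = curve_fit(model, phi, y, p0=(d0_guess, 1.0), sigma=sig,
                           bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
    d0, zeta = popt
    return DiffusionFit(d0=float(d0), zeta=float(zeta), exponent=exponent,
                        kind=kind, covariance=pcov,
                        at_bound=bool(zeta < 0.01),  # optimizer tolerance
                        # around the zeta >= 0 bound; zeta this small changes
                        # D by < 0.3% over the physical phi range
                        ledger={"exponent": exponent})


def generalized_se_ratio(d: float, d0: float, eta: float, eta0: float
                         ) -> float:
    """(D/D0)/(eta0/eta): unity when the generalized Stokes–Einstein
    relation holds; below one signals excess slow-down (clustering)."""
    if min(d, d0, eta, eta0) <= 0:
        raise ValueError("all inputs must be positive")
    return (d / d0) / (eta0 / eta)
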