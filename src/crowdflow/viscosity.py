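"""Green–Kubo shear viscosity from replicate stress series.

The shear viscosity is eta = (V/k_BT) * ∫ <P_ab(0) P_ab(t)> dt over the
off-diagonal (and optionally deviatoric normal-difference) pressure
channels.  Finite runs never reach the tau -> infinity limit, so the
estimate follows a replica protocol: the running integral eta(tau) is
computed per replica, the cross-replica standard deviation sigma(tau) is
fitted to a power law A*tau^b as a noise-growth diagnostic, a
double-exponential saturation curve weighted by 1/sigma(tau) extrapolates
the mean integral to tau -> infinity, and tau_max is increased until the
extrapolated value stops changing within its uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .constants import BAR_TO_WORKING, thermal_energy
from .core import TimeSeries, raw_autocorr_sums

__all__ = [
    "StressSeries",
    "StressACF",
    "RunningIntegral",
    "ViscosityEstimate",
    "stress_acf_mean",
    "green_kubo_integral",
    "build_running_integral",
    "fit_sigma_power",
    "extrapolate_viscosity",
    "select_tau_max",
    "relative_viscosity",
    "DEFAULT_TAU_MAX_CANDIDATES",
]

#: Default tau_max candidates in ns (25–200 ps); stable estimates are
#: typically reached near 100 ps.
DEFAULT_TAU_MAX_CANDIDATES = (0.025, 0.05, 0.075, 0.1, 0.15, 0.2)


@dataclass
class StressSeries:
    """Off-diagonal/deviatoric pressure channels from one replica.

    channels: (n_channels, n_samples) in bar, uniformly sampled every
    ``dt`` ns; ``volume`` in Å³, ``temperature`` in K.
    """

    dt: float
    channels: np.ndarray
    volume: float
    temperature: float
    replica_id: int = 0

    def __post_init__(self):
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("stress channels must be finite")
        if self.dt <= 0 or self.volume <= 0 or self.temperature <= 0:
            raise ValueError("dt, volume and temperature must be positive")


@dataclass
class StressACF:
    """Channel-averaged raw stress ACFs, per replica and pooled."""

    lags: np.ndarray             # ns
    per_replica: np.ndarray      # (R, K) bar²
    mean: np.ndarray
    sigma: np.ndarray
    volume: float
    temperature: float
    dt: float


@dataclass
class RunningIntegral:
    """Green–Kubo running integrals eta(tau) per replica plus cross-replica
    mean and standard deviation, all in cP on a shared tau grid (ns)."""

    taus: np.ndarray
    eta_per_replica: np.ndarray  # (R, K)
    mean: np.ndarray
    sigma: np.ndarray


@dataclass
class ViscosityEstimate:
    eta: float                   # cP
    uncertainty: float           # cP, bootstrap over replicas
    tau_max: float               # ns
    power_law: tuple             # (A, b) for sigma(tau)
    double_exp: tuple            # (eta_inf, alpha, tau1, tau2)
    n_replicas: int
    converged: bool = True
    ledger: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("viscosity estimate must be positive")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be nonnegative")


def _check_homogeneous(replicas: Sequence[StressSeries]):
    r0 = replicas[0]
    for r in replicas[1:]:
        if not (np.isclose(r.dt, r0.dt) and np.isclose(r.volume, r0.volume)
                and np.isclose(r.temperature, r0.temperature)):
            raise ValueError("replicas must share dt, volume and temperature")


def stress_acf_mean(replicas: Sequence[StressSeries], max_lag: float
                    ) -> StressACF:
    """Raw (no mean removal) ACF of every channel, averaged over channels
    per replica; pooled mean and cross-replica sigma.

    A nonzero mean shear stress is a data-quality problem, not something to
    subtract silently; it is reported via a warning entry in the result's
    pooled mean metadata by the caller if needed.
    """
    _check_homogeneous(replicas)
    dt = replicas[0].dt
    kmax = int(round(max_lag / dt))
    n = replicas[0].channels.shape[1]
    if not 1 <= kmax < n:
        raise ValueError("max_lag must resolve to 1 <= lags < n_samples")
    counts = n - np.arange(kmax + 1)
    per = np.empty((len(replicas), kmax + 1))
    for i, rep in enumerate(replicas):
        sums = raw_autocorr_sums(rep.channels, kmax)
        per[i] = (sums / counts).mean(axis=0)
    mean = per.mean(axis=0)
    sigma = per.std(axis=0, ddof=1) if len(replicas) > 1 else np.zeros_like(mean)
    return StressACF(lags=np.arange(kmax + 1) * dt, per_replica=per,
                     mean=mean, sigma=sigma, volume=replicas[0].volume,
                     temperature=replicas[0].temperature, dt=dt)


def green_kubo_integral(acf: np.ndarray, dt: float, volume: float,
                        temperature: float) -> np.ndarray:
    """Running integral eta(tau) in cP from a raw stress ACF in bar².

    eta(tau) = (V/k_BT) * ∫_0^tau C(t') dt' by the trapezoid rule, with the
    bar² -> working pressure² conversion folded in.
    """
    if volume <= 0 or temperature <= 0:
        raise ValueError("volume and temperature must be positive")
    c_work = np.asarray(acf, dtype=float) * BAR_TO_WORKING ** 2
    integral = cumulative_trapezoid(c_work, dx=dt, initial=0.0)
    return volume / thermal_energy(temperature) * integral


def build_running_integral(replicas: Sequence[StressSeries], max_lag: float
                           ) -> RunningIntegral:
    """ACF + integral per replica; grid shared across replicas."""
    acf = stress_acf_mean(replicas, max_lag)
    etas = np.array([
        green_kubo_integral(acf.per_replica[i], acf.dt, acf.volume,
                            acf.temperature)
        for i in range(len(replicas))
    ])
    mean = etas.mean(axis=0)
    sigma = etas.std(axis=0, ddof=1) if len(replicas) > 1 else np.zeros_like(mean)
    return RunningIntegral(taus=acf.lags, eta_per_replica=etas, mean=mean,
                           sigma=sigma)


def fit_sigma_power(integrals: RunningIntegral,
                    tau_max: Optional[float] = None) -> tuple:
    """Least-squares fit of log sigma(tau) = log A + b log tau over
    (0, tau_max]; returns (A, b)."""
    if integrals.eta_per_replica.shape[0] < 2:
        raise ValueError("need at least two replicas for sigma(tau)")
    mask = integrals.taus > 0
    if tau_max is not None:
        mask &= integrals.taus <= tau_max
    sig = integrals.sigma[mask]
    if np.all(sig == 0):
        raise ValueError("sigma(tau) identically zero; replicas identical")
    tau = integrals.taus[mask][sig > 0]
    sig = sig[sig > 0]
    b, loga = np.polyfit(np.log(tau), np.log(sig), 1)
    return float(np.exp(loga)), float(b)


def _dexp(tau, eta_inf, alpha, t1, t2):
    return eta_inf * (alpha * (1 - np.exp(-tau / t1))
                      + (1 - alpha) * (1 - np.exp(-tau / t2)))


class ExtrapolationError(RuntimeError):
    """Carries the plateau value at tau_max as a fallback diagnostic."""

    def __init__(self, msg, plateau):
        super().__init__(f"{msg} (plateau at tau_max: {plateau:.4g} cP)")
        self.plateau = plateau


def _fit_mean_curve(tau, mean, sigma, n_starts=8, rng=None):
    """Weighted double-exponential saturation fit.

    Weights follow the power-law model of sigma(tau) rather than the raw
    cross-replica sigma (the raw values are noisy and vanish at small tau,
    which would let the first few points dominate).  Both time constants
    are bounded by the fit window — components slower than the window are
    not identifiable — and eta_inf is bounded by three times the plateau,
    since the running integral is a saturating curve.
    """
    rng = rng or np.random.default_rng(0)
    pos = sigma > 0
    if pos.sum() >= 2:
        b, loga = np.polyfit(np.log(tau[pos]), np.log(sigma[pos]), 1)
        w = np.exp(loga) * tau ** b
    else:
        w = np.ones_like(tau)
    w = np.clip(w, max(w.max() * 1e-3, 1e-300), None)
    scale = max(mean[-1], 1e-12)
    best = None
    span = tau[-1]
    tlo, thi = tau[0] / 2, span
    for s in range(n_starts):
        if s == 0:
            t1, t2 = span / 20, span / 2
        else:
            t1, t2 = 10 ** rng.uniform(np.log10(max(tlo, span / 200)),
                                       np.log10(thi), 2)
        p0 = (scale, 0.7, min(t1, t2), max(t1, t2))
        try:
            popt, _ = curve_fit(
                _dexp, tau, mean, p0=p0, sigma=w,
                bounds=([0, 0, tlo, tlo], [scale * 3, 1, thi, thi]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum(((_dexp(tau, *popt) - mean) / w) ** 2))
        if best is None or cost < best[0]:
            best = (cost, popt)
    return best


def extrapolate_viscosity(integrals: RunningIntegral, tau_max: float,
                          n_boot: int = 200, seed: int = 0,
                          max_fit_points: int = 400) -> ViscosityEstimate:
    """Fit the sigma-weighted double-exponential saturation curve to the
    cross-replica mean running integral up to tau_max and extrapolate to
    tau -> infinity; uncertainty by bootstrap over replicas."""
    mask = (integrals.taus > 0) & (integrals.taus <= tau_max)
    tau = integrals.taus[mask]
    if len(tau) < 8:
        raise ValueError("tau_max leaves too few grid points")
    stride = max(1, len(tau) // max_fit_points)
    sel = np.arange(0, len(tau), stride)
    tau = tau[sel]
    etas = integrals.eta_per_replica[:, mask][:, sel]
    mean = etas.mean(axis=0)
    sigma = etas.std(axis=0, ddof=1)
    A, b = fit_sigma_power(integrals, tau_max)

    best = _fit_mean_curve(tau, mean, sigma)
    if best is None:
        raise ExtrapolationError("double-exponential fit did not converge",
                                 plateau=mean[-1])
    _, popt = best
    eta_inf = float(popt[0])

    rng = np.random.default_rng(seed)
    R = etas.shape[0]
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, R, R)
        bm = etas[idx].mean(axis=0)
        bs = etas[idx].std(axis=0, ddof=1)
        fit = _fit_mean_curve(tau, bm, bs, n_starts=2, rng=rng)
        if fit is not None:
            boots.append(fit[1][0])
    unc = float(np.std(boots, ddof=1)) if len(boots) > 2 else float("nan")
    return ViscosityEstimate(
        eta=eta_inf, uncertainty=unc, tau_max=tau_max,
        power_law=(A, b), double_exp=tuple(popt),
        n_replicas=R,
        ledger={"plateau_at_tau_max": float(mean[-1]),
                "n_bootstrap": len(boots)},
    )


def select_tau_max(integrals: RunningIntegral,
                   candidates: Sequence[float] = DEFAULT_TAU_MAX_CANDIDATES,
                   n_boot: int = 100, seed: int = 0) -> ViscosityEstimate:
    """Increase tau_max until the extrapolated eta stops changing within the
    combined uncertainties; returns the first stable estimate, or the
    largest candidate flagged unconverged."""
    candidates = sorted(candidates)
    if len(candidates) < 3:
        raise ValueError("need at least three tau_max candidates")
    ests = [extrapolate_viscosity(integrals, c, n_boot=n_boot, seed=seed)
            for c in candidates]
    for cur, nxt in zip(ests[:-1], ests[1:]):
        if abs(cur.eta - nxt.eta) < cur.uncertainty + nxt.uncertainty:
            return cur
    last = ests[-1]
    last.converged = False
    return last


def relative_viscosity(eta: float, eta_ref: float) -> float:
    """eta / eta_ref (dimensionless)."""
    if eta_ref <= 0:
        raise ValueError("reference viscosity must be positive")
    return eta / eta_ref
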