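"""Colloid-theory interaction strength: centre-of-mass RDFs, second virial
coefficients, Baxter stickiness and dissociation constants.

The chain is: integrate the first peak of a COM pair distribution up to a
recorded r_max to get B2 = -2*pi ∫ (g(r)-1) r² dr, map it onto the
adhesive-hard-sphere stickiness through B2 = 4*V_HS*(1 - 1/(4*tau_B)),
i.e. tau_B = 1/(4 - B2/V_HS), and convert stickiness to a dissociation
constant K_D = tau_B / V_HS (in 1/Å³; divide by N_A per litre for mM).
Smaller tau_B means stickier; 1/tau_B is a clustering propensity.

An independent route relates tau_B to the second-order coefficient of the
relative-viscosity expansion for adhesive hard spheres,
b = 5.9 + 1.9/tau_B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import PER_A3_TO_MM
from .core import Trajectory

__all__ = [
    "RDFCurve",
    "VirialResult",
    "com_rdf",
    "b2_from_rdf",
    "hard_sphere_volume",
    "radius_from_volume",
    "baxter_tau",
    "b2_from_tau",
    "kd_from_tau",
    "tau_from_viscosity_b",
    "viscosity_b_from_tau",
    "virial_chain",
]


@dataclass
class RDFCurve:
    r: np.ndarray               # bin centres, Å
    g: np.ndarray
    bin_width: float
    pair_selection: str = "all"
    n_frames: int = 0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be nonnegative")


@dataclass
class VirialResult:
    b2: float                   # Å³
    r_max: float                # Å
    v_hs: float                 # Å³
    a1: float                   # Å
    a2: Optional[float]         # Å
    tau_b: float
    kd_per_A3: float
    kd_mM: float
    ledger: dict = field(default_factory=dict)


def com_rdf(traj: Trajectory, pairs=None, bins: Optional[np.ndarray] = None,
            bin_width: float = 1.0) -> RDFCurve:
    """Centre-of-mass pair distribution with finite-N normalisation.

    Counts minimum-image pair distances into shells and divides by the
    ideal-gas expectation n_pairs * 4*pi*r²*dr / V (the finite-N pair
    density, which matters for boxes with only a few molecules).  Bins must
    stay below half the box edge.
    """
    L = traj.box.edge_length
    M = traj.n_molecules
    if pairs is None:
        pairs = [(i, j) for i in range(M) for j in range(i + 1, M)]
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    if bins is None:
        bins = np.arange(0.0, L / 2 + 1e-9, bin_width)
    bins = np.asarray(bins, dtype=float)
    if bins[-1] > L / 2 + 1e-9:
        raise ValueError("bins must not extend beyond half the box edge")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    # chunk over frames to bound memory at ~10^7 pair distances at a time
    chunk = max(1, int(1e7) // max(1, len(pairs)))
    counts = np.zeros(len(bins) - 1, dtype=np.int64)
    edges = bins
    for lo in range(0, traj.n_frames, chunk):
        d = (traj.com_positions[lo: lo + chunk, ii, :]
             - traj.com_positions[lo: lo + chunk, jj, :])
        d -= L * np.round(d / L)
        dist = np.linalg.norm(d, axis=-1).ravel()
        c, edges = np.histogram(dist, bins=bins)
        counts += c
    centers = 0.5 * (edges[1:] + edges[:-1])
    shell = 4.0 * np.pi * centers ** 2 * np.diff(edges)
    ideal = len(pairs) * traj.n_frames * shell / L ** 3
    g = counts / ideal
    return RDFCurve(r=centers, g=g, bin_width=float(np.diff(edges).mean()),
                    pair_selection=f"{len(pairs)} pairs",
                    n_frames=traj.n_frames)


def b2_from_rdf(rdf: RDFCurve, r_max: float) -> float:
    """B2 = -2*pi ∫_0^r_max (g(r)-1) r² dr by the trapezoid rule.

    The integrand below the first bin centre is extended with the first
    bin's g value (for molecular RDFs that region is excluded volume with
    g = 0, so the extension is exact there).
    """
    if r_max > rdf.r[-1] + rdf.bin_width / 2:
        raise ValueError("r_max beyond the RDF range")
    mask = rdf.r <= r_max
    r = np.concatenate([[0.0], rdf.r[mask]])
    g = np.concatenate([[rdf.g[0]], rdf.g[mask]])
    integrand = (g - 1.0) * r ** 2
    return float(-2.0 * np.pi * np.trapezoid(integrand, r))


def hard_sphere_volume(a1: float, a2: Optional[float] = None) -> float:
    """(4*pi/3)*a³ for homotypic pairs; (4*pi/3)*((a1+a2)/2)³ for
    heterotypic pairs of unequal spheres."""
    if a1 <= 0 or (a2 is not None and a2 <= 0):
        raise ValueError("radii must be positive")
    a = a1 if a2 is None else 0.5 * (a1 + a2)
    return (4.0 * np.pi / 3.0) * a ** 3


def radius_from_volume(volume: float) -> float:
    """Equivalent sphere radius a = (3V/4pi)^(1/3) from a molecular volume."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def baxter_tau(b2: float, v_hs: float) -> float:
    """Adhesive-hard-sphere stickiness tau_B = 1/(4 - B2/V_HS).

    Raises for B2 >= 4*V_HS (at or beyond the pure hard-sphere limit there
    is no finite stickiness).
    """
    if v_hs <= 0:
        raise ValueError("V_HS must be positive")
    denom = 4.0 - b2 / v_hs
    if denom <= 0:
        raise ValueError("B2 >= 4*V_HS: repulsive limit, no finite stickiness")
    return 1.0 / denom


def b2_from_tau(tau_b: float, v_hs: float) -> float:
    """Inverse map B2 = 4*V_HS*(1 - 1/(4*tau_B))."""
    if tau_b <= 0 or v_hs <= 0:
        raise ValueError("tau_B and V_HS must be positive")
    return 4.0 * v_hs * (1.0 - 1.0 / (4.0 * tau_b))


def kd_from_tau(tau_b: float, v_hs_for_kd: float) -> tuple:
    """Dissociation constant K_D = tau_B / V_HS.

    Returns (K_D in Å⁻³, K_D in mM).  For probe–crowder pairs pass the
    probe's own hard-sphere volume to compare crowder binding to the probe.
    """
    if tau_b <= 0 or v_hs_for_kd <= 0:
        raise ValueError("tau_B and V_HS must be positive")
    kd = tau_b / v_hs_for_kd
    return kd, kd * PER_A3_TO_MM


def tau_from_viscosity_b(b: float) -> float:
    """Stickiness from the quadratic viscosity coefficient:
    tau_B = 1.9/(b - 5.9), the adhesive-hard-sphere second-order relation
    b = 5.9 + 1.9/tau_B."""
    if b <= 5.9:
        raise ValueError("b <= 5.9 is the hard-sphere limit; no stickiness")
    return 1.9 / (b - 5.9)


def viscosity_b_from_tau(tau_b: float) -> float:
    """Inverse: b = 5.9 + 1.9/tau_B."""
    if tau_b <= 0:
        raise ValueError("tau_B must be positive")
    return 5.9 + 1.9 / tau_b


def virial_chain(b2: float, a1: float, a2: Optional[float] = None,
                 v_hs: Optional[float] = None, r_max: float = float("nan"),
                 v_hs_for_kd: Optional[float] = None) -> VirialResult:
    """Full B2 -> tau_B -> K_D chain with the inputs recorded.

    ``v_hs`` defaults to the hard-sphere volume from the radii;
    ``v_hs_for_kd`` defaults to ``v_hs`` (pass the probe volume for
    probe–crowder pairs)."""
    if v_hs is None:
        v_hs = hard_sphere_volume(a1, a2)
    tau = baxter_tau(b2, v_hs)
    vkd = v_hs if v_hs_for_kd is None else v_hs_for_kd
    kd_a3, kd_mm = kd_from_tau(tau, vkd)
    return VirialResult(b2=b2, r_max=r_max, v_hs=v_hs, a1=a1, a2=a2,
                        tau_b=tau, kd_per_A3=kd_a3, kd_mM=kd_mm,
                        ledger={"v_hs_for_kd": vkd})
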