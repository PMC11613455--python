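"""Synthetic-data generators with known ground truth.

These stand in for microsecond MD trajectories of crowded protein
solutions: every estimator in the package can be validated by parameter
recovery against what a generator was told to produce.

Four generators:

* :func:`simulate_brownian_crowd` — overdamped Brownian spheres with an
  optional short-range square well in a periodic cubic box (known free
  diffusion coefficient D0 and stickiness).
* :func:`simulate_rotational_walk` — isotropic rotational Brownian motion
  of a rigid body carrying unit vectors (known D_r).
* :func:`simulate_stress_ou` — stationary Ornstein–Uhlenbeck off-diagonal
  pressure channels whose Green–Kubo integral equals a target viscosity
  exactly in expectation.
* :func:`simulate_contact_timeline` — alternating-renewal contact
  indicators with exponential-mixture on-durations.

Same seed => bit-identical output; each generator derives all randomness
from a single ``numpy.random.default_rng(seed)`` stream (replicas use
``SeedSequence.spawn`` children in order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, signal

from .constants import TEMPERATURE_DEFAULT, thermal_energy, BAR_TO_WORKING
from .core import BoxSpec, OrientationTrajectory, Trajectory, wrap_positions

__all__ = [
    "StabilityError",
    "SquareWell",
    "ou_stationary_variance",
    "CrowdSimConfig",
    "StressSimConfig",
    "ContactSimConfig",
    "simulate_brownian_crowd",
    "simulate_rotational_walk",
    "simulate_stress_ou",
    "simulate_contact_timeline",
]


class StabilityError(RuntimeError):
    """Raised when the overdamped integrator loses particle overlap control."""


@dataclass(frozen=True)
class SquareWell:
    """Smoothed square-well pair potential in k_BT units.

    The hard core is a harmonic repulsion of stiffness ``k_core`` (k_BT/Å²)
    for centre separations below contact sigma = a_i + a_j; the attractive
    well has depth ``epsilon`` (k_BT) over a shell of width ``width`` Å
    beyond contact, with the outer edge smoothed over ``smoothing`` Å so the
    force stays bounded for overdamped integration.  The effective
    stickiness is therefore reported as the B2 of this smoothed potential
    (``b2`` below, by quadrature), not the nominal epsilon.
    """

    epsilon: float = 0.0
    width: float = 3.0
    smoothing: float = 0.5
    k_core: float = 4.0

    def energy(self, r: np.ndarray, sigma: float) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        u = np.zeros_like(r)
        core = r < sigma
        u[core] += 0.5 * self.k_core * (sigma - r[core]) ** 2
        if self.epsilon != 0.0:
            edge0 = sigma + self.width - self.smoothing
            edge1 = sigma + self.width
            flat = r < edge0
            u[flat] -= self.epsilon
            band = (r >= edge0) & (r < edge1)
            t = (edge1 - r[band]) / self.smoothing
            u[band] -= self.epsilon * t * t * (3 - 2 * t)
        return u

    def force_over_r(self, r: np.ndarray, sigma: float) -> np.ndarray:
        """(-dU/dr)/r, so the force vector is this times (r_i - r_j)."""
        r = np.asarray(r, dtype=float)
        f = np.zeros_like(r)
        core = r < sigma
        f[core] += self.k_core * (sigma - r[core])  # repulsive, -dU/dr > 0
        if self.epsilon != 0.0:
            edge0 = sigma + self.width - self.smoothing
            edge1 = sigma + self.width
            band = (r >= edge0) & (r < edge1)
            t = (edge1 - r[band]) / self.smoothing
            # dU/dr = epsilon * 6 t (1 - t) / smoothing  => attractive
            f[band] -= self.epsilon * 6.0 * t * (1 - t) / self.smoothing
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, f / r, 0.0)
        return out

    def b2(self, sigma: float) -> float:
        """Second virial coefficient of the smoothed potential, Å³,
        by quadrature of -2π ∫ (e^{-u} - 1) r² dr."""
        upper = sigma + self.width + 1.0

        def integrand(r):
            return (np.exp(-self.energy(np.array([r]), sigma))[0] - 1.0) * r * r

        val, _ = integrate.quad(integrand, 0.0, upper, limit=400)
        return -2.0 * np.pi * val


@dataclass
class CrowdSimConfig:
    """Study conditions for the Brownian crowd.

    Defaults emulate a moderately crowded protein solution: 30 spheres of
    radius 10 Å at volume fraction ~0.1 with free diffusion
    D0 = 100 Å²/ns, integrated at dt = 1e-3 ns so the RMS free step
    (~0.77 Å) stays below a tenth of the radius.
    """

    n_molecules: int = 30
    radius: float = 10.0
    box_edge: Optional[float] = None     # derived from volume_fraction if None
    volume_fraction: float = 0.1
    d0: float = 100.0
    potential: Optional[SquareWell] = None
    dt: float = 1e-3
    n_steps: int = 100_000
    seed: int = 0
    save_every: int = 1
    temperature: float = TEMPERATURE_DEFAULT

    def __post_init__(self):
        if self.box_edge is None:
            vol = self.n_molecules * (4.0 / 3.0) * np.pi * self.radius ** 3
            self.box_edge = (vol / self.volume_fraction) ** (1.0 / 3.0)
        else:
            vol = self.n_molecules * (4.0 / 3.0) * np.pi * self.radius ** 3
            self.volume_fraction = vol / self.box_edge ** 3
        if self.volume_fraction >= 0.45:
            raise ValueError("volume fraction must stay below 0.45")
        rms_step = np.sqrt(6.0 * self.d0 * self.dt)
        if rms_step >= 0.1 * self.radius:
            raise ValueError(
                f"dt too large: RMS step {rms_step:.3g} Å >= 0.1*radius"
            )


def _initial_placement(rng, n, box_edge, min_dist, max_tries=20000):
    """Random sequential insertion with a minimum pair distance."""
    pos = np.empty((n, 3))
    placed = 0
    for _ in range(max_tries):
        cand = rng.uniform(0, box_edge, size=3)
        if placed:
            d = pos[:placed] - cand
            d -= box_edge * np.round(d / box_edge)
            if np.min(np.linalg.norm(d, axis=1)) < min_dist:
                continue
        pos[placed] = cand
        placed += 1
        if placed == n:
            return pos
    raise RuntimeError("could not place molecules without overlap")


def simulate_brownian_crowd(config: CrowdSimConfig) -> Trajectory:
    """Overdamped Brownian dynamics of (optionally sticky) spheres.

    Update rule per step: ``x += D0*F*dt + sqrt(2*D0*dt)*xi`` with F in
    k_BT/Å (the mobility D0/k_BT absorbs k_BT when forces are expressed in
    thermal units), minimum-image forces and periodic wrapping.  Returns a
    wrapped :class:`Trajectory` with ground-truth metadata attached.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.box_edge
    sigma = 2.0 * cfg.radius
    pot = cfg.potential
    # place with a modest initial clearance (0.95 sigma for soft cores)
    clearance = 0.95 * sigma if pot is not None else 0.5 * sigma
    x = _initial_placement(rng, cfg.n_molecules, L, clearance)

    n_saved = cfg.n_steps // cfg.save_every + 1
    frames = np.empty((n_saved, cfg.n_molecules, 3))
    frames[0] = x
    noise_scale = np.sqrt(2.0 * cfg.d0 * cfg.dt)
    mob = cfg.d0 * cfg.dt  # D0/kBT * dt with forces in kBT/Å
    iu = np.triu_indices(cfg.n_molecules, k=1)
    saved = 1
    for step in range(1, cfg.n_steps + 1):
        if pot is not None:
            d = x[:, None, :] - x[None, :, :]
            d -= L * np.round(d / L)
            r = np.linalg.norm(d, axis=-1)
            rr = r[iu]
            if np.any(rr < 0.5 * sigma):
                raise StabilityError(
                    f"pair distance below 0.5*sigma at step {step}; "
                    "reduce dt or core stiffness"
                )
            fr = pot.force_over_r(r, sigma)
            np.fill_diagonal(fr, 0.0)
            force = np.einsum("ij,ijk->ik", fr, d)
            x = x + mob * force
        x = x + noise_scale * rng.standard_normal(x.shape)
        x = wrap_positions(x, BoxSpec(L))
        if step % cfg.save_every == 0:
            frames[saved] = x
            saved += 1

    times = np.arange(n_saved) * cfg.dt * cfg.save_every
    eta0 = thermal_energy(cfg.temperature) / (6.0 * np.pi * cfg.d0 * cfg.radius)
    gt = {
        "d0": cfg.d0,
        "radius": cfg.radius,
        "volume_fraction": cfg.volume_fraction,
        "epsilon": 0.0 if pot is None else pot.epsilon,
        "eta0_cp": eta0,
        "temperature": cfg.temperature,
        "b2_A3": pot.b2(sigma) if pot is not None else 0.0,
    }
    return Trajectory(
        times=times, com_positions=frames, box=BoxSpec(L), wrapped=True,
        ground_truth=gt, provenance={"generator": "simulate_brownian_crowd",
                                     "seed": cfg.seed},
    )


def _rotation_matrices(rotvecs: np.ndarray) -> np.ndarray:
    """Rodrigues formula for an (n, 3) array of rotation vectors."""
    theta = np.linalg.norm(rotvecs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(theta[:, None] > 0, rotvecs / theta[:, None], 0.0)
    K = np.zeros((len(rotvecs), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    s = np.sin(theta)[:, None, None]
    c = (1 - np.cos(theta))[:, None, None]
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + s * K + c * (K @ K)


def simulate_rotational_walk(dr: float, dt: float, n_steps: int,
                             n_vectors: int = 16, seed: int = 0
                             ) -> OrientationTrajectory:
    """Isotropic rotational Brownian motion of a rigid body.

    The body frame evolves by axis-angle composition of small random
    rotations with angular variance 2*Dr*dt per axis, so
    <P2(cos theta(t))> decays as exp(-6*Dr*t).  Vectors attached to the
    body are rotated rigidly; a handful of vectors suffices because they
    share the body's motion (extra vectors only average orientation noise).
    """
    if dr < 0:
        raise ValueError("Dr must be nonnegative")
    if dr * dt >= 0.05:
        raise ValueError("Dr*dt must stay below 0.05 for small-step accuracy")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal((n_vectors, 3))
    v0 /= np.linalg.norm(v0, axis=1, keepdims=True)
    vectors = np.empty((n_steps + 1, n_vectors, 3))
    vectors[0] = v0
    if dr == 0:
        vectors[:] = v0
    else:
        steps = rng.standard_normal((n_steps, 3)) * np.sqrt(2.0 * dr * dt)
        dR = _rotation_matrices(steps)
        R = np.eye(3)
        for i in range(n_steps):
            R = dR[i] @ R
            vectors[i + 1] = v0 @ R.T
    times = np.arange(n_steps + 1) * dt
    return OrientationTrajectory(times=times, vectors=vectors,
                                 ground_truth={"dr": dr, "seed": seed})


@dataclass
class StressSimConfig:
    """Study conditions for the stress-fluctuation generator.

    Defaults mirror the viscosity protocol: 150 replicas of 1 ns sampled
    every 4 fs, five independent off-diagonal/deviatoric channels, water-like
    target viscosity 0.35 cP with a 1 ps stress relaxation time.
    """

    target_viscosity: float = 0.35      # cP
    tau_c: float = 1e-3                 # ns (1 ps)
    volume: float = 50.0 ** 3           # Å³
    temperature: float = TEMPERATURE_DEFAULT
    dt: float = 4e-6                    # ns (4 fs)
    n_samples: int = 250_000
    n_replicas: int = 150
    n_channels: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.target_viscosity, self.tau_c, self.volume) < 0:
            raise ValueError("viscosity, tau_c and volume must be nonnegative")
        if self.tau_c <= 0 or self.volume <= 0:
            raise ValueError("tau_c and volume must be positive")
        if self.n_replicas < 2:
            raise ValueError("need at least two replicas")


def ou_stationary_variance(config: StressSimConfig) -> float:
    """Target ACF amplitude C0 in bar² so that (V/kT)·C0·tau_c = eta*."""
    e = thermal_energy(config.temperature)
    c0_working = config.target_viscosity * e / (config.volume * config.tau_c)
    return c0_working / BAR_TO_WORKING ** 2


def simulate_stress_ou(config: StressSimConfig) -> list:
    """Stationary OU pressure channels with exponential ACF
    C(t) = C0·exp(-t/tau_c), C0 = eta*·k_BT/(V·tau_c).

    Returns a list of :class:`crowdflow.viscosity.StressSeries`, one per
    replica, each with ``n_channels`` independent channels in bar.
    """
    from .viscosity import StressSeries  # local import to avoid a cycle

    cfg = config
    c0_bar2 = ou_stationary_variance(cfg)
    rho = np.exp(-cfg.dt / cfg.tau_c)
    out = []
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicas)
    for rep, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        if cfg.target_viscosity == 0.0:
            ch = np.zeros((cfg.n_channels, cfg.n_samples))
        else:
            x0 = np.sqrt(c0_bar2) * rng.standard_normal((cfg.n_channels, 1))
            noise = rng.standard_normal((cfg.n_channels, cfg.n_samples))
            s = np.sqrt(c0_bar2 * (1 - rho * rho))
            ch, _ = signal.lfilter([s], [1.0, -rho], noise, axis=1,
                                   zi=rho * x0)
        out.append(StressSeries(dt=cfg.dt, channels=ch, volume=cfg.volume,
                                temperature=cfg.temperature, replica_id=rep))
    return out


@dataclass
class ContactSimConfig:
    """Alternating-renewal contact process per molecule pair.

    On-durations are drawn from the exponential mixture (weights w_i, means
    tau_i); off-durations are exponential with mean chosen to match the
    target stationary occupancy.  Defaults are the three-timescale contact
    kinetics regime (long/intermediate/short survival times spanning ~3
    decades) at low occupancy, where the intermittent contact ACF cleanly
    resolves all three components.
    """

    weights: Sequence[float] = (0.5, 0.3, 0.2)
    taus: Sequence[float] = (100.0, 5.0, 0.3)   # ns, descending
    occupancy: float = 0.05
    dt: float = 0.05                            # ns
    n_frames: int = 40_001
    n_pairs: int = 10_000
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.taus, dtype=float)
        if np.any(w < 0) or w.sum() > 1 + 1e-9:
            raise ValueError("weights must be nonnegative with sum <= 1")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in [0, 1]")
        if np.any(np.diff(t) >= 0) or np.any(t <= 0):
            raise ValueError("survival times must be positive and descending")
        if self.occupancy == 0.0 and w.sum() > 0:
            raise ValueError("occupancy 0 with nonzero weights is degenerate")
        if w.sum() == 0 and self.occupancy > 0:
            raise ValueError("nonzero occupancy needs nonzero mixture weights")


def simulate_contact_timeline(config: ContactSimConfig):
    """Discretised alternating renewal (random-telegraph) process per pair.

    Each pair is assigned one mixture component — the population is
    heterogeneous, with w_i of the pairs having exponential on-durations of
    mean tau_i — and off-durations are exponential with mean
    tau_i*(1-p)/p so every pair has the same stationary occupancy p.
    Component counts are allocated proportionally (deterministic), so the
    realised mixture weights are exact.

    Starts are stationary: a pair begins in contact with probability p, and
    because both dwell distributions are exponential (memoryless), residual
    durations keep their full means.

    The pooled intermittent contact ACF of this population is exactly

        C(t) = p + (1 - p) * sum_i w_i * exp(-t / (tau_i * (1 - p)))

    i.e. each fitted survival time is the telegraph relaxation time
    tau_i*(1-p), within (1-p) of the nominal tau_i; the ground-truth dict
    records both.
    """
    from .contacts import ContactTimeline  # local import to avoid a cycle

    cfg = config
    w = np.asarray(cfg.weights, dtype=float)
    w = w / w.sum() if w.sum() > 0 else np.full_like(w, 1.0 / len(w))
    taus = np.asarray(cfg.taus, dtype=float)
    total_time = (cfg.n_frames - 1) * cfg.dt
    rng = np.random.default_rng(cfg.seed)
    present = np.zeros((cfg.n_frames, cfg.n_pairs), dtype=bool)

    # deterministic proportional allocation of pairs to components
    counts = np.floor(w * cfg.n_pairs).astype(int)
    for k in np.argsort(-(w * cfg.n_pairs - counts)):
        if counts.sum() >= cfg.n_pairs:
            break
        counts[k] += 1
    component = np.repeat(np.arange(len(w)), counts)

    p_occ = cfg.occupancy
    if p_occ >= 1.0:
        present[:] = True
    elif p_occ > 0.0:
        for pair in range(cfg.n_pairs):
            tau_on = taus[component[pair]]
            tau_off = tau_on * (1.0 - p_occ) / p_occ
            start_on = rng.random() < p_occ
            n_draw = max(8, int(3 * total_time / (tau_on + tau_off)) + 8)
            while True:
                ons = rng.exponential(tau_on, size=n_draw)
                offs = rng.exponential(tau_off, size=n_draw)
                segs = np.empty(2 * n_draw)
                if start_on:
                    segs[0::2], segs[1::2] = ons, offs
                else:
                    segs[0::2], segs[1::2] = offs, ons
                edges = np.concatenate([[0.0], np.cumsum(segs)])
                if edges[-1] >= total_time:
                    break
                n_draw *= 2  # rare: redraw with a longer sequence
            first_on = 0 if start_on else 1
            starts = edges[first_on:-1:2]
            ends = edges[first_on + 1::2]
            i0 = np.ceil(starts / cfg.dt).astype(int)
            i1 = np.ceil(ends / cfg.dt).astype(int)
            for a, b in zip(i0, i1):
                if a >= cfg.n_frames:
                    break
                present[a: min(b, cfg.n_frames), pair] = True

    times = np.arange(cfg.n_frames) * cfg.dt
    pairs = [(2 * k, 2 * k + 1) for k in range(cfg.n_pairs)]
    return ContactTimeline(times=times, pairs=pairs, present=present,
                           ground_truth={
                               "weights": tuple(w),
                               "taus": tuple(taus),
                               "acf_taus": tuple(taus * (1.0 - p_occ)),
                               "component_counts": counts.tolist(),
                               "occupancy": p_occ,
                               "seed": cfg.seed,
                           })
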