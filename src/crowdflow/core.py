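"""Shared data model: periodic boxes, trajectories, time series, and
autocorrelation utilities used by every estimator module.

Trajectories store molecular centre-of-mass positions (and optionally atom
positions) in Å on a uniform time grid in ns, inside a periodic cubic box.
Only cubic boxes are supported; every finite-size correction downstream
assumes a single edge length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "BoxSpec",
    "Trajectory",
    "OrientationTrajectory",
    "TimeSeries",
    "unwrap_positions",
    "wrap_positions",
    "autocorrelation",
    "log_lag_grid",
]

#: relative tolerance for enforcing a uniform time step
_DT_RTOL = 1e-6


@dataclass(frozen=True)
class BoxSpec:
    """Cubic periodic box with edge length in Å."""

    edge_length: float
    periodic: bool = True

    def __post_init__(self):
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")


def _check_times(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("times must be a 1-D array with at least two frames")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    dt = steps[0]
    if np.any(np.abs(steps - dt) > _DT_RTOL * dt):
        raise ValueError("time step must be uniform to 1e-6 relative")
    return dt


@dataclass
class Trajectory:
    """Per-frame molecular COM positions (Å) in a periodic cubic box.

    Parameters
    ----------
    times : (F,) array, ns, uniform spacing.
    com_positions : (F, M, 3) array, Å.
    atom_positions : optional (F, A, 3) array, Å.
    molecule_index : optional (A,) int array mapping atom -> molecule.
    elements : optional length-A sequence of element symbols; hydrogens are
        excluded from heavy-atom contact counts.
    calpha_index : optional mapping molecule -> (n_res,) atom indices of the
        Cα atoms, in residue order.
    ground_truth : generator metadata (known D0, stickiness, ...) attached by
        the synthetic-data module; analysis code treats it as opaque.
    """

    times: np.ndarray
    com_positions: np.ndarray
    box: BoxSpec
    wrapped: bool = True
    atom_positions: Optional[np.ndarray] = None
    molecule_index: Optional[np.ndarray] = None
    elements: Optional[Sequence[str]] = None
    calpha_index: Optional[dict] = None
    ground_truth: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.com_positions = np.asarray(self.com_positions, dtype=float)
        self._dt = _check_times(self.times)
        if self.com_positions.ndim != 3 or self.com_positions.shape[2] != 3:
            raise ValueError("com_positions must have shape (F, M, 3)")
        if self.com_positions.shape[0] != len(self.times):
            raise ValueError("com_positions and times disagree on frame count")
        if self.com_positions.shape[1] < 1:
            raise ValueError("need at least one molecule")
        if not np.all(np.isfinite(self.com_positions)):
            raise ValueError("positions must be finite")
        if self.atom_positions is not None:
            self.atom_positions = np.asarray(self.atom_positions, dtype=float)
            if self.molecule_index is None:
                raise ValueError("atom_positions requires molecule_index")
            self.molecule_index = np.asarray(self.molecule_index, dtype=int)

    @property
    def dt(self) -> float:
        return self._dt

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_molecules(self) -> int:
        return self.com_positions.shape[1]


@dataclass
class OrientationTrajectory:
    """Unit vectors rigidly attached to a molecule's body frame.

    vectors has shape (F, n_vec, 3); every vector has unit norm to 1e-8.
    """

    times: np.ndarray
    vectors: np.ndarray
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self._dt = _check_times(self.times)
        norms = np.linalg.norm(self.vectors, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientation vectors must be unit length")

    @property
    def dt(self) -> float:
        return self._dt


@dataclass
class TimeSeries:
    """Carrier for ACFs, MSDs and running integrals: lags/times plus values
    and an optional SEM of the same length."""

    lags: np.ndarray
    values: np.ndarray
    sem: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")
        if np.any(self.lags < 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be nonnegative and increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.values.shape:
                raise ValueError("sem must match values in length")


class UnwrapAmbiguityError(ValueError):
    """Raised when a per-frame displacement reaches half the box edge."""


def wrap_positions(positions: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Fold positions into [0, L) along every axis."""
    return np.mod(positions, box.edge_length)


def unwrap_positions(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps from COM positions by accumulating
    minimum-image frame-to-frame displacements.

    Already-unwrapped input (``wrapped=False``) is returned unchanged.

    Raises
    ------
    UnwrapAmbiguityError
        If any molecule moves by >= L/2 between consecutive frames; the
        message names the first offending frame and molecule.
    """
    if not traj.wrapped:
        return traj
    L = traj.box.edge_length
    pos = traj.com_positions
    disp = np.diff(pos, axis=0)
    disp -= L * np.round(disp / L)
    bad = np.abs(disp) >= L / 2 - 1e-12
    if np.any(bad):
        f, m, _ = np.argwhere(bad)[0]
        raise UnwrapAmbiguityError(
            f"displacement >= L/2 between frames {f} and {f + 1} for "
            f"molecule {m}; trajectory is under-sampled for unwrapping"
        )
    unwrapped = np.concatenate(
        [pos[:1], pos[:1] + np.cumsum(disp, axis=0)], axis=0
    )
    out = replace(traj)
    out.com_positions = unwrapped
    out.wrapped = False
    out.provenance = dict(traj.provenance, unwrapped=True)
    return out


def autocorrelation(values: np.ndarray, max_lag: int, mode: str = "mean-removed",
                    dt: float = 1.0) -> TimeSeries:
    """Autocorrelation C(k) = (1/(N-k)) * sum_t v(t) v(t+k).

    ``mode='raw'`` correlates the values as given (required for Green–Kubo
    stress integrals); ``mode='mean-removed'`` subtracts the sample mean
    first.  Computed via FFT with zero padding; the direct O(N·K) oracle in
    the test suite pins the contract.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    n = len(v)
    if not (1 <= max_lag < n):
        raise ValueError(f"need 1 <= max_lag < len(values); got {max_lag}, {n}")
    if mode == "mean-removed":
        v = v - v.mean()
    elif mode != "raw":
        raise ValueError("mode must be 'raw' or 'mean-removed'")
    acf = raw_autocorr_sums(v, max_lag) / (n - np.arange(max_lag + 1))
    return TimeSeries(lags=np.arange(max_lag + 1) * dt, values=acf,
                      meta={"mode": mode})


def raw_autocorr_sums(v: np.ndarray, max_lag: int) -> np.ndarray:
    """sum_t v(t) v(t+k) for k = 0..max_lag, via zero-padded FFT.

    1-D input returns a (max_lag+1,) array; 2-D input (rows = independent
    series) returns one row of sums per input row.
    """
    v = np.asarray(v, dtype=float)
    one_d = v.ndim == 1
    if one_d:
        v = v[None, :]
    n = v.shape[1]
    size = next_fast_len(2 * n)
    f = rfft(v, size, axis=1)
    corr = irfft(f * np.conj(f), size, axis=1)[:, : max_lag + 1]
    return corr[0] if one_d else corr


def log_lag_grid(dt: float, max_lag_time: float, points_per_decade: int = 24
                 ) -> np.ndarray:
    """Integer lag multiples of dt, approximately log-spaced.

    Returns unique integer lags k >= 1 with k*dt <= max_lag_time, with about
    ``points_per_decade`` points per decade (all small integers are kept
    where the log grid is denser than the frame grid).
    """
    k_max = int(np.floor(max_lag_time / dt))
    if k_max < 1:
        raise ValueError("max_lag_time shorter than one frame")
    n_dec = np.log10(k_max) if k_max > 1 else 1
    n_pts = max(2, int(np.ceil(points_per_decade * n_dec)))
    lags = np.unique(np.round(np.logspace(0, np.log10(k_max), n_pts)).astype(int))
    return lags[lags >= 1]
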