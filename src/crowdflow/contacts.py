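"""Contact detection, cluster membership, contact-survival kinetics and the
equilibration Z-score criterion.

Two molecules are in contact when the minimum distance between any of
their heavy atoms is below a cutoff (5 Å by default); a per-residue
profile counts crowder heavy atoms within 7 Å of each Cα.  For
sphere-surrogate trajectories without atoms, contact means the
surface-to-surface gap |r_ij| - a_i - a_j is below the cutoff.

The contact autocorrelation is the *intermittent* convention: a contact
may break and reform within the lag, with no history condition, and the
curve is normalised so C(0) = 1.  Survival kinetics are extracted by a
triple-exponential fit over a logarithmic lag grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .core import TimeSeries, Trajectory, log_lag_grid, raw_autocorr_sums

__all__ = [
    "ContactTimeline",
    "ClusterSeries",
    "SurvivalFit",
    "ConvergenceReport",
    "direct_contacts",
    "residue_contact_profile",
    "cluster_with_probe",
    "contact_acf",
    "acf_plateau",
    "fit_triple_exponential",
    "convergence_zscore",
]

_HYDROGEN = {"H", "h", "1H", "2H", "D"}


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails across all starts or the input is
    degenerate (e.g. a non-decaying correlation function)."""


@dataclass
class ContactTimeline:
    """Boolean contact indicator per molecule pair per frame."""

    times: np.ndarray
    pairs: list
    present: np.ndarray          # (F, P) bool
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.times), len(self.pairs)):
            raise ValueError("present must have shape (n_frames, n_pairs)")
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pairs must satisfy i < j, got ({i}, {j})")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class ClusterSeries:
    """Probe-centric cluster membership per frame."""

    times: np.ndarray
    labels: np.ndarray           # (F, M) component label per molecule
    in_cluster: np.ndarray       # (F,) crowders in the probe's cluster
    direct: np.ndarray           # (F,) direct probe contacts

    def __post_init__(self):
        n_other = self.labels.shape[1] - 1
        if np.any(self.direct > self.in_cluster) or np.any(
                self.in_cluster > n_other):
            raise ValueError("invariant direct <= in_cluster <= N-1 violated")


@dataclass
class SurvivalFit:
    """Triple-exponential decomposition of a contact ACF."""

    weights: np.ndarray          # descending-tau order
    taus: np.ndarray             # ns, tau1 > tau2 > tau3
    residual: float
    covariance: Optional[np.ndarray] = None
    degenerate: bool = False
    baseline: float = 0.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.baseline + sum(
            w * np.exp(-t / tau) for w, tau in zip(self.weights, self.taus)
        )


@dataclass
class ConvergenceReport:
    times: np.ndarray
    z: np.ndarray
    window: float
    short_means: np.ndarray
    long_means: np.ndarray
    short_sems: np.ndarray
    long_sems: np.ndarray


# ---------------------------------------------------------------------------
# contact detection

def _min_image_dist(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= L * np.round(d / L)
    return np.linalg.norm(d, axis=-1)


def direct_contacts(traj: Trajectory, cutoff: float = 5.0,
                    radii: Optional[np.ndarray] = None) -> ContactTimeline:
    """Per-frame molecular contact map.

    Atom mode (default when the trajectory carries atoms): contact when the
    minimum heavy-atom distance between two molecules is below ``cutoff``.
    Surrogate mode (``radii`` given, or radii in the generator metadata):
    contact when the surface gap |r_ij| - a_i - a_j is below ``cutoff``.
    """
    L = traj.box.edge_length
    M = traj.n_molecules
    pairs = [(i, j) for i in range(M) for j in range(i + 1, M)]
    present = np.zeros((traj.n_frames, len(pairs)), dtype=bool)

    if traj.atom_positions is not None:
        heavy = np.ones(traj.atom_positions.shape[1], dtype=bool)
        if traj.elements is not None:
            heavy = np.array([e not in _HYDROGEN for e in traj.elements])
        mol_of = traj.molecule_index[heavy]
        for f in range(traj.n_frames):
            ap = traj.atom_positions[f][heavy]
            dist = _min_image_dist(ap, ap, L)
            for k, (i, j) in enumerate(pairs):
                sub = dist[np.ix_(mol_of == i, mol_of == j)]
                present[f, k] = sub.size and sub.min() < cutoff
    else:
        if radii is None:
            radii = traj.ground_truth.get("radius")
        if radii is None:
            raise ValueError(
                "no atom data: surrogate mode needs per-molecule radii"
            )
        radii = np.broadcast_to(np.asarray(radii, dtype=float), (M,))
        iu = np.triu_indices(M, k=1)
        for f in range(traj.n_frames):
            dist = _min_image_dist(traj.com_positions[f],
                                   traj.com_positions[f], L)
            gap = dist - radii[:, None] - radii[None, :]
            present[f] = gap[iu] < cutoff
    return ContactTimeline(times=traj.times, pairs=pairs, present=present)


def residue_contact_profile(traj: Trajectory, probe: int,
                            cutoff: float = 7.0, n_blocks: int = 5
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Time-averaged count of crowder heavy atoms within ``cutoff`` of each
    Cα of the probe molecule.  Returns (mean, sem) per residue, SEM over
    ``n_blocks`` consecutive time blocks.
    """
    if traj.atom_positions is None:
        raise ValueError("residue profile needs atom positions")
    if not traj.calpha_index or probe not in traj.calpha_index:
        raise ValueError("missing Cα index for the probe molecule")
    L = traj.box.edge_length
    ca = np.asarray(traj.calpha_index[probe], dtype=int)
    heavy = np.ones(traj.atom_positions.shape[1], dtype=bool)
    if traj.elements is not None:
        heavy = np.array([e not in _HYDROGEN for e in traj.elements])
    others = heavy & (traj.molecule_index != probe)
    counts = np.empty((traj.n_frames, len(ca)))
    for f in range(traj.n_frames):
        dist = _min_image_dist(traj.atom_positions[f][ca],
                               traj.atom_positions[f][others], L)
        counts[f] = (dist < cutoff).sum(axis=1)
    mean = counts.mean(axis=0)
    blocks = np.array_split(counts, n_blocks, axis=0)
    bmeans = np.array([b.mean(axis=0) for b in blocks])
    sem = bmeans.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return mean, sem


# ---------------------------------------------------------------------------
# clusters

def _components(n: int, edges) -> np.ndarray:
    """Connected components by union-find; each component is labelled by its
    lowest molecule index (deterministic)."""
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            if ri < rj:
                parent[rj] = ri
            else:
                parent[ri] = rj
    return np.array([find(i) for i in range(n)])


def cluster_with_probe(timeline: ContactTimeline, probe: int) -> ClusterSeries:
    """Per-frame connected components of the contact graph, reporting the
    probe's direct degree and its cluster size minus one."""
    mols = sorted({m for p in timeline.pairs for m in p})
    if probe not in mols:
        raise ValueError(f"probe {probe} does not appear in any pair")
    index = {m: k for k, m in enumerate(mols)}
    n = len(mols)
    pk = index[probe]
    pair_idx = np.array([[index[i], index[j]] for i, j in timeline.pairs])
    probe_pairs = np.array([pk in row for row in pair_idx])
    labels = np.empty((timeline.n_frames, n), dtype=int)
    in_cluster = np.empty(timeline.n_frames, dtype=int)
    direct = np.empty(timeline.n_frames, dtype=int)
    for f in range(timeline.n_frames):
        on = timeline.present[f]
        comp = _components(n, pair_idx[on])
        labels[f] = comp
        in_cluster[f] = np.sum(comp == comp[pk]) - 1
        direct[f] = int(np.sum(on & probe_pairs))
    return ClusterSeries(times=timeline.times, labels=labels,
                         in_cluster=in_cluster, direct=direct)


# ---------------------------------------------------------------------------
# survival kinetics

def contact_acf(timeline: ContactTimeline, lags: Optional[np.ndarray] = None,
                n_groups: int = 10, chunk: int = 128) -> TimeSeries:
    """Intermittent contact autocorrelation, pooled over pairs:

    C(k) = [sum_pairs sum_t d(t) d(t+k) / (N-k)] / [sum_pairs sum_t d² / N]

    so C(0) = 1.  ``lags`` is a grid of times (ns), snapped to frame
    multiples; default is a 24-points-per-decade logarithmic grid up to a
    quarter of the span.  SEM is estimated across ``n_groups`` pair groups.
    """
    dt = timeline.dt
    nf = timeline.n_frames
    if lags is None:
        ks = log_lag_grid(dt, (nf - 1) * dt / 4.0)
    else:
        ks = np.unique(np.round(np.asarray(lags, dtype=float) / dt)).astype(int)
        ks = ks[(ks >= 1) & (ks < nf)]
    ks = np.concatenate([[0], ks])
    max_lag = int(ks.max())

    total_on = timeline.present.sum()
    if total_on == 0:
        raise ValueError("timeline has no contacts; ACF normalisation undefined")

    n_pairs = len(timeline.pairs)
    n_groups = min(n_groups, n_pairs)
    bounds = np.linspace(0, n_pairs, n_groups + 1).astype(int)
    norm = nf / (nf - ks).astype(float)
    group_c = np.empty((n_groups, len(ks)))
    for g in range(n_groups):
        num = np.zeros(max_lag + 1)
        denom = 0.0
        for lo in range(bounds[g], bounds[g + 1], chunk):
            hi = min(lo + chunk, bounds[g + 1])
            block = timeline.present[:, lo:hi].T.astype(float)
            num += raw_autocorr_sums(block, max_lag).sum(axis=0)
            denom += block.sum()
        group_c[g] = np.where(denom > 0, num[ks] * norm / max(denom, 1e-300),
                              np.nan)
    weights = np.array([
        timeline.present[:, bounds[g]:bounds[g + 1]].sum()
        for g in range(n_groups)
    ], dtype=float)
    wsum = weights.sum()
    with np.errstate(invalid="ignore"):
        c = np.nansum(np.nan_to_num(group_c) * weights[:, None], axis=0) / wsum
    if n_groups > 1:
        valid = weights > 0
        sem = np.nanstd(group_c[valid], axis=0, ddof=1) / np.sqrt(valid.sum())
    else:
        sem = None
    return TimeSeries(lags=ks * dt, values=c, sem=sem,
                      meta={"convention": "intermittent", "n_pairs": n_pairs})


def acf_plateau(timeline: ContactTimeline) -> float:
    """Long-lag limit of the pooled intermittent ACF,
    sum_i p_i² / sum_i p_i with p_i the per-pair occupancy."""
    p = timeline.present.mean(axis=0)
    tot = p.sum()
    if tot == 0:
        raise ValueError("timeline has no contacts")
    return float((p ** 2).sum() / tot)


def _multi_exp(t, *params):
    n = len(params) // 2
    w, tau = params[:n], params[n:]
    return sum(wi * np.exp(-t / ti) for wi, ti in zip(w, tau))


def fit_triple_exponential(acf: TimeSeries, baseline: float = 0.0,
                           n_components: int = 3,
                           n_starts: int = 12, seed: int = 0) -> SurvivalFit:
    """Weighted nonlinear least squares of sum_i w_i exp(-t/tau_i) to an ACF.

    ``baseline`` (e.g. the occupancy plateau from :func:`acf_plateau`) is
    subtracted before fitting.  Multi-start over log-spaced tau
    initialisations; weights 1/SEM where the ACF carries SEMs.  Components
    are returned in descending-tau order.
    """
    mask = acf.lags > 0
    t = acf.lags[mask]
    y = acf.values[mask] - baseline
    if len(t) < 2 * n_components:
        raise FitError("too few lag points for the requested components")
    if y[-1] > 0.95 * max(y[0], 1e-12):
        raise FitError("correlation does not decay; survival time unresolved "
                       "(tau -> infinity)")
    sigma = None
    if acf.sem is not None:
        sigma = np.clip(acf.sem[mask], np.nanmax(acf.sem[mask]) * 1e-3, None)
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(t[0]), np.log10(t[-1])
    best = None
    for s in range(n_starts):
        if s == 0:
            tau0 = np.logspace(lo, hi, n_components + 2)[1:-1][::-1]
        else:
            tau0 = np.sort(10 ** rng.uniform(lo - 0.5, hi + 0.5,
                                             n_components))[::-1]
        w0 = np.full(n_components, max(y[0], 0.1) / n_components)
        p0 = np.concatenate([w0, tau0])
        bounds = ([0.0] * n_components + [t[0] / 100] * n_components,
                  [2.0] * n_components + [t[-1] * 100] * n_components)
        try:
            popt, pcov = curve_fit(_multi_exp, t, y, p0=p0, sigma=sigma,
                                   bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = _multi_exp(t, *popt) - y
        cost = float(np.sum((resid / (sigma if sigma is not None else 1.0))
                            ** 2))
        if best is None or cost < best[0]:
            best = (cost, popt, pcov)
    if best is None:
        raise FitError("triple-exponential fit failed across all starts")
    cost, popt, pcov = best
    w, tau = popt[:n_components], popt[n_components:]
    order = np.argsort(tau)[::-1]
    w, tau = w[order], tau[order]
    # re-order covariance consistently
    perm = np.concatenate([order, order + n_components])
    pcov = pcov[np.ix_(perm, perm)]
    degenerate = bool(np.any(tau[:-1] / tau[1:] < 2.0) or np.any(w < 0.01))
    return SurvivalFit(weights=w, taus=tau, residual=cost, covariance=pcov,
                       degenerate=degenerate, baseline=baseline)


# ---------------------------------------------------------------------------
# convergence

def convergence_zscore(series: TimeSeries, window: float = 400.0,
                       replicates: Optional[Sequence[np.ndarray]] = None
                       ) -> ConvergenceReport:
    """Equilibration criterion: Z(t) = |a_w(t) - a_max(t)| /
    (SEM(a_w) + SEM(a_max)) where a_w averages [t, t+window] and a_max
    averages [t, end].

    SEMs come from replicate series when provided, otherwise from block
    averaging with block length window/10.  Z around 1 indicates the
    short-time average is within one standard error of the long-time one.
    """
    t = series.lags
    span = t[-1] - t[0]
    if window >= span:
        raise ValueError("window must be shorter than the series span")
    dt = t[1] - t[0]
    wlen = max(2, int(round(window / dt)))
    blk = max(2, wlen // 10)
    data = (np.asarray(replicates, dtype=float) if replicates is not None
            else series.values[None, :])
    n = data.shape[1]
    idx = np.arange(0, n - wlen)

    def _sem(seg2d):
        if seg2d.shape[0] > 1:  # across replicates
            means = seg2d.mean(axis=1)
            return means.std(ddof=1) / np.sqrt(len(means))
        v = seg2d[0]
        nb = len(v) // blk
        if nb < 2:
            return v.std(ddof=1) / np.sqrt(len(v))
        bm = v[: nb * blk].reshape(nb, blk).mean(axis=1)
        return bm.std(ddof=1) / np.sqrt(nb)

    zs = np.empty(len(idx))
    sm = np.empty(len(idx))
    lm = np.empty(len(idx))
    ss = np.empty(len(idx))
    ls = np.empty(len(idx))
    for k, i in enumerate(idx):
        short = data[:, i: i + wlen]
        longer = data[:, i:]
        sm[k], lm[k] = short.mean(), longer.mean()
        ss[k], ls[k] = _sem(short), _sem(longer)
        denom = ss[k] + ls[k]
        zs[k] = abs(sm[k] - lm[k]) / denom if denom > 0 else 0.0
    return ConvergenceReport(times=t[idx], z=zs, window=window,
                             short_means=sm, long_means=lm,
                             short_sems=ss, long_sems=ls)
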