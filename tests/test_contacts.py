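import networkx as nx
import numpy as np
import pytest

from crowdflow import (
    BoxSpec,
    ClusterSeries,
    ContactSimConfig,
    ContactTimeline,
    TimeSeries,
    Trajectory,
    acf_plateau,
    cluster_with_probe,
    contact_acf,
    convergence_zscore,
    direct_contacts,
    fit_triple_exponential,
    residue_contact_profile,
    simulate_contact_timeline,
)
from crowdflow.contacts import FitError


def _two_frame_traj(**kwargs):
    com = np.zeros((2, 3, 3))
    com[:, 1, 0] = 30.0
    com[:, 2, 0] = 60.0
    return Trajectory(times=[0.0, 1.0], com_positions=com, box=BoxSpec(200.0),
                      **kwargs)


# ---------------------------------------------------------------------------
# contact detection

def test_direct_contacts_atom_mode_with_hydrogen_exclusion():
    # molecules 0 and 1: nearest heavy atoms 6 Å apart (no contact at 5 Å),
    # but molecule 0 carries a hydrogen only 2 Å from molecule 1's heavy atom
    atoms = np.array([
        [0.0, 0.0, 0.0],     # mol 0 heavy
        [30.0, 0.0, 0.0],    # mol 0 hydrogen, 4 Å from mol 1's heavy atom
        [34.0, 0.0, 0.0],    # mol 1 heavy
        [60.0, 0.0, 0.0],    # mol 2 heavy, far away
    ])
    traj = _two_frame_traj(
        atom_positions=np.broadcast_to(atoms, (2, 4, 3)).copy(),
        molecule_index=[0, 0, 1, 2],
        elements=["C", "H", "N", "C"],
    )
    tl = direct_contacts(traj, cutoff=5.0)
    assert tl.pairs == [(0, 1), (0, 2), (1, 2)]
    assert not tl.present.any()
    # counting the hydrogen would create the (0, 1) contact
    traj.elements = ["C", "C", "N", "C"]
    tl2 = direct_contacts(traj, cutoff=5.0)
    assert tl2.present[:, 0].all()
    assert not tl2.present[:, 1].any() and not tl2.present[:, 2].any()


def test_direct_contacts_surrogate_mode_gap_and_min_image():
    com = np.zeros((2, 2, 3))
    com[:, 1, 0] = 95.0    # minimum image distance 5 in a 100 Å box
    traj = Trajectory(times=[0.0, 1.0], com_positions=com, box=BoxSpec(100.0))
    # radii 1.5 each: gap = 5 - 3 = 2 < 3 => contact
    tl = direct_contacts(traj, cutoff=3.0, radii=1.5)
    assert tl.present.all()
    # radii 0.5 each: gap = 4 > 3 => no contact
    tl = direct_contacts(traj, cutoff=3.0, radii=0.5)
    assert not tl.present.any()


def test_direct_contacts_surrogate_needs_radii():
    traj = _two_frame_traj()
    with pytest.raises(ValueError, match="radii"):
        direct_contacts(traj)


def test_residue_contact_profile_counts():
    # probe molecule 0 with three Cα; one crowder heavy atom within 7 Å of
    # the first Cα only => profile (1, 0, 0)
    atoms = np.array([
        [0.0, 0.0, 0.0],     # Cα residue 1
        [10.0, 0.0, 0.0],    # Cα residue 2
        [20.0, 0.0, 0.0],    # Cα residue 3
        [3.0, 0.0, 0.0],     # crowder heavy atom, 3 Å from residue 1
        [0.0, 40.0, 0.0],    # crowder hydrogen near nothing
    ])
    com = np.zeros((6, 2, 3))
    com[:, 1, 1] = 40.0
    traj = Trajectory(
        times=np.arange(6.0), com_positions=com, box=BoxSpec(200.0),
        atom_positions=np.broadcast_to(atoms, (6, 5, 3)).copy(),
        molecule_index=[0, 0, 0, 1, 1],
        elements=["C", "C", "C", "C", "H"],
        calpha_index={0: [0, 1, 2]},
    )
    mean, sem = residue_contact_profile(traj, probe=0, cutoff=7.0, n_blocks=3)
    assert np.allclose(mean, [1.0, 0.0, 0.0])
    assert np.allclose(sem, 0.0)


def test_residue_profile_requires_atoms():
    with pytest.raises(ValueError):
        residue_contact_profile(_two_frame_traj(), probe=0)


# ---------------------------------------------------------------------------
# clusters

def test_cluster_with_probe_matches_networkx(rng):
    n_mol, n_frames = 12, 40
    pairs = [(i, j) for i in range(n_mol) for j in range(i + 1, n_mol)]
    present = rng.random((n_frames, len(pairs))) < 0.12
    tl = ContactTimeline(times=np.arange(n_frames) * 0.1, pairs=pairs,
                         present=present)
    cs = cluster_with_probe(tl, probe=0)
    for f in range(n_frames):
        g = nx.Graph()
        g.add_nodes_from(range(n_mol))
        g.add_edges_from(p for p, on in zip(pairs, present[f]) if on)
        comp = next(c for c in nx.connected_components(g) if 0 in c)
        assert cs.in_cluster[f] == len(comp) - 1
        assert cs.direct[f] == g.degree[0]
        # labels are the lowest member index of each component
        for c in nx.connected_components(g):
            assert all(cs.labels[f, m] == min(c) for m in c)


def test_cluster_probe_must_exist():
    tl = ContactTimeline(times=[0.0, 1.0], pairs=[(0, 1)],
                         present=np.zeros((2, 1), dtype=bool))
    with pytest.raises(ValueError):
        cluster_with_probe(tl, probe=5)


def test_cluster_series_invariant():
    with pytest.raises(ValueError):
        ClusterSeries(times=np.arange(2.0), labels=np.zeros((2, 3), int),
                      in_cluster=np.array([1, 1]), direct=np.array([2, 0]))


# ---------------------------------------------------------------------------
# contact ACF

def brute_force_acf(present, ks):
    """Direct evaluation of the pooled intermittent ACF."""
    nf = present.shape[0]
    d = present.astype(float)
    denom = d.sum()
    out = []
    for k in ks:
        num = (d[: nf - k] * d[k:]).sum()
        out.append(num / (nf - k) * nf / denom)
    return np.array(out)


def test_contact_acf_matches_brute_force(rng):
    nf, npair = 300, 7
    present = rng.random((nf, npair)) < 0.3
    tl = ContactTimeline(times=np.arange(nf) * 0.5,
                         pairs=[(2 * i, 2 * i + 1) for i in range(npair)],
                         present=present)
    lags = np.array([0.5, 1.0, 2.5, 10.0, 40.0])
    acf = contact_acf(tl, lags=lags, n_groups=1)
    ks = np.round(acf.lags / 0.5).astype(int)
    want = brute_force_acf(present, ks)
    assert np.allclose(acf.values, want, rtol=1e-10)
    assert acf.values[0] == pytest.approx(1.0)


def test_contact_acf_empty_timeline_raises():
    tl = ContactTimeline(times=np.arange(10.0), pairs=[(0, 1)],
                         present=np.zeros((10, 1), dtype=bool))
    with pytest.raises(ValueError, match="no contacts"):
        contact_acf(tl)


def test_acf_plateau_formula():
    # two pairs with occupancies 0.5 and 0.1 over 10 frames
    present = np.zeros((10, 2), dtype=bool)
    present[:5, 0] = True
    present[:1, 1] = True
    tl = ContactTimeline(times=np.arange(10.0), pairs=[(0, 1), (2, 3)],
                         present=present)
    assert acf_plateau(tl) == pytest.approx((0.25 + 0.01) / 0.6)


# ---------------------------------------------------------------------------
# survival fits

def test_triple_exponential_recovery_on_exact_curve():
    taus = np.array([100.0, 5.0, 0.3])
    weights = np.array([0.5, 0.3, 0.2])
    p = 0.05
    t = np.concatenate([[0.0], np.logspace(np.log10(0.05), np.log10(400), 60)])
    y = p + (1 - p) * sum(w * np.exp(-t / tau)
                          for w, tau in zip(weights, taus))
    fit = fit_triple_exponential(TimeSeries(lags=t, values=y), baseline=p)
    assert np.allclose(fit.taus, taus, rtol=0.05)
    assert np.allclose(fit.weights, (1 - p) * weights, rtol=0.05)
    assert not fit.degenerate
    # the fitted object evaluates back onto the curve
    assert np.allclose(fit(t), y, atol=1e-3)


def test_fit_flags_degenerate_closely_spaced_components():
    t = np.concatenate([[0.0], np.logspace(-1, 2, 40)])
    y = 0.6 * np.exp(-t / 10.0) + 0.4 * np.exp(-t / 9.0)
    fit = fit_triple_exponential(TimeSeries(lags=t, values=y))
    assert fit.degenerate


def test_fit_raises_on_nondecaying_acf():
    t = np.linspace(0, 10, 30)
    with pytest.raises(FitError, match="does not decay"):
        fit_triple_exponential(TimeSeries(lags=t, values=np.ones_like(t)))


def test_single_component_telegraph_recovery():
    """Renewal-theory oracle: one exponential on-time component at occupancy
    p decays with relaxation time tau*(1-p)."""
    cfg = ContactSimConfig(weights=(1.0,), taus=(5.0,), occupancy=0.5,
                           dt=0.05, n_frames=8001, n_pairs=2000, seed=17)
    tl = simulate_contact_timeline(cfg)
    acf = contact_acf(tl)
    fit = fit_triple_exponential(acf, baseline=0.5, n_components=1)
    assert fit.taus[0] == pytest.approx(5.0 * 0.5, rel=0.10)


# ---------------------------------------------------------------------------
# convergence Z-score

def test_convergence_zscore_white_noise_calibration():
    """For stationary white noise the windowed mean matches the long mean
    within combined SEs most of the time: the median Z stays below 1."""
    fracs = []
    for seed in range(40):
        rng = np.random.default_rng(seed)
        ts = TimeSeries(lags=np.arange(1200) * 1.0,
                        values=rng.standard_normal(1200))
        rep = convergence_zscore(ts, window=120.0)
        fracs.append(np.mean(rep.z < 1.0))
    assert np.mean(fracs) > 0.6


def test_convergence_zscore_flags_drift():
    t = np.arange(1000) * 1.0
    ts = TimeSeries(lags=t, values=0.01 * t)  # steady drift, no noise
    rep = convergence_zscore(ts, window=100.0)
    assert rep.z[0] > 3.0


def test_convergence_zscore_with_replicates(rng):
    t = np.arange(500) * 1.0
    reps = rng.standard_normal((6, 500))
    ts = TimeSeries(lags=t, values=reps.mean(axis=0))
    rep = convergence_zscore(ts, window=50.0, replicates=reps)
    assert np.isfinite(rep.z).all()
    assert rep.window == 50.0


def test_convergence_zscore_window_validation():
    ts = TimeSeries(lags=np.arange(10.0), values=np.zeros(10))
    with pytest.raises(ValueError):
        convergence_zscore(ts, window=20.0)
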