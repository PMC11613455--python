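import numpy as np
import pytest

from crowdflow import (
    ContactSimConfig,
    CrowdSimConfig,
    SquareWell,
    StabilityError,
    StressSimConfig,
    cluster_with_probe,
    compute_msd,
    direct_contacts,
    fit_Dt,
    ou_stationary_variance,
    simulate_brownian_crowd,
    simulate_contact_timeline,
    simulate_rotational_walk,
    simulate_stress_ou,
    stress_acf_mean,
    unwrap_positions,
)


# ---------------------------------------------------------------------------
# SquareWell potential

def test_square_well_energy_profile():
    sw = SquareWell(epsilon=2.0, width=3.0, smoothing=0.5, k_core=4.0)
    sigma = 20.0
    r = np.array([19.0, 20.5, 22.4, 23.5])
    u = sw.energy(r, sigma)
    # harmonic core minus well depth inside contact
    assert u[0] == pytest.approx(0.5 * 4.0 * 1.0 ** 2 - 2.0)
    # flat well region
    assert u[1] == pytest.approx(-2.0)
    assert u[2] == pytest.approx(-2.0)
    # beyond the smoothed edge
    assert u[3] == 0.0


def test_square_well_force_is_minus_gradient():
    sw = SquareWell(epsilon=1.5, width=3.0)
    sigma = 20.0
    r = np.linspace(18.0, 24.0, 1201)
    u = sw.energy(r, sigma)
    f_num = -np.gradient(u, r)  # -dU/dr
    f = sw.force_over_r(r, sigma) * r
    interior = slice(5, -5)
    assert np.allclose(f[interior], f_num[interior], atol=0.05)


def test_square_well_b2_limits():
    # no well: B2 is close to (slightly below) the hard-core value because
    # the harmonic core is soft
    hard = 2.0 * np.pi / 3.0 * 20.0 ** 3
    b2_repulsive = SquareWell(epsilon=0.0).b2(20.0)
    assert 0.8 * hard < b2_repulsive < hard
    # attraction lowers B2 monotonically
    b2_weak = SquareWell(epsilon=1.0).b2(20.0)
    b2_strong = SquareWell(epsilon=3.0).b2(20.0)
    assert b2_strong < b2_weak < b2_repulsive


# ---------------------------------------------------------------------------
# Brownian crowd

def test_crowd_determinism_bit_identical():
    cfg = CrowdSimConfig(n_molecules=8, n_steps=500, seed=7,
                         potential=SquareWell(epsilon=1.0))
    a = simulate_brownian_crowd(cfg)
    b = simulate_brownian_crowd(CrowdSimConfig(
        n_molecules=8, n_steps=500, seed=7,
        potential=SquareWell(epsilon=1.0)))
    assert np.array_equal(a.com_positions, b.com_positions)
    c = simulate_brownian_crowd(CrowdSimConfig(
        n_molecules=8, n_steps=500, seed=8,
        potential=SquareWell(epsilon=1.0)))
    assert not np.array_equal(a.com_positions, c.com_positions)


def test_crowd_free_diffusion_propagator():
    """Without a potential the generator is an exact free random walk:
    per-step displacement variance is 2*D0*dt per axis and the MSD slope
    recovers D0."""
    cfg = CrowdSimConfig(n_molecules=20, n_steps=5000, seed=3,
                         volume_fraction=0.05)
    traj = simulate_brownian_crowd(cfg)
    un = unwrap_positions(traj)
    steps = np.diff(un.com_positions, axis=0)
    var = steps.var()
    assert var == pytest.approx(2 * cfg.d0 * cfg.dt, rel=0.01)
    msd = compute_msd(un, max_lag=2.0)
    d, se, _ = fit_Dt(msd, window=(0.2, 1.5))
    # within 4 standard errors of the per-molecule slope spread, and sane
    assert abs(d - cfg.d0) < 4 * se
    assert d == pytest.approx(cfg.d0, rel=0.15)


def test_crowd_ground_truth_metadata():
    pot = SquareWell(epsilon=2.0)
    cfg = CrowdSimConfig(n_molecules=6, n_steps=200, seed=1, potential=pot)
    traj = simulate_brownian_crowd(cfg)
    gt = traj.ground_truth
    assert gt["d0"] == cfg.d0
    assert gt["epsilon"] == 2.0
    assert gt["b2_A3"] == pytest.approx(pot.b2(2 * cfg.radius))
    # eta0 consistent with Stokes-Einstein at D0, R
    from crowdflow import stokes_einstein_dt
    assert stokes_einstein_dt(gt["eta0_cp"], cfg.radius) == pytest.approx(
        cfg.d0, rel=1e-12)


def test_crowd_save_every_thins_frames():
    cfg = CrowdSimConfig(n_molecules=6, n_steps=1000, seed=2, save_every=10)
    traj = simulate_brownian_crowd(cfg)
    assert traj.n_frames == 101
    assert traj.dt == pytest.approx(cfg.dt * 10)


def test_crowd_config_validation():
    with pytest.raises(ValueError, match="volume fraction"):
        CrowdSimConfig(volume_fraction=0.5)
    with pytest.raises(ValueError, match="dt too large"):
        CrowdSimConfig(dt=0.1)


def test_crowd_stability_error_without_core():
    # a deep well with the core repulsion disabled collapses pairs
    pot = SquareWell(epsilon=8.0, width=6.0, k_core=0.0)
    cfg = CrowdSimConfig(n_molecules=10, volume_fraction=0.3, n_steps=20000,
                         seed=0, potential=pot)
    with pytest.raises(StabilityError):
        simulate_brownian_crowd(cfg)


# ---------------------------------------------------------------------------
# rotational walk

def test_rotational_determinism_and_rigidity():
    a = simulate_rotational_walk(dr=0.05, dt=0.01, n_steps=300, seed=5)
    b = simulate_rotational_walk(dr=0.05, dt=0.01, n_steps=300, seed=5)
    assert np.array_equal(a.vectors, b.vectors)
    # unit norms and rigid-body motion: pairwise dots are invariant
    norms = np.linalg.norm(a.vectors, axis=-1)
    assert np.allclose(norms, 1.0, atol=1e-10)
    gram0 = a.vectors[0] @ a.vectors[0].T
    gram_last = a.vectors[-1] @ a.vectors[-1].T
    assert np.allclose(gram0, gram_last, atol=1e-9)


def test_rotational_dr_zero_is_static():
    t = simulate_rotational_walk(dr=0.0, dt=0.01, n_steps=50, seed=1)
    assert np.array_equal(t.vectors[0], t.vectors[-1])


def test_rotational_p2_matches_exponential():
    from crowdflow import p2_acf
    dr = 0.05
    walk = simulate_rotational_walk(dr=dr, dt=0.01, n_steps=20000, seed=11)
    acf = p2_acf(walk, max_lag=3.0)
    theory = np.exp(-6 * dr * acf.lags)
    assert np.allclose(acf.values, theory, atol=0.05)
    assert acf.values[0] == pytest.approx(1.0, abs=1e-9)


def test_rotational_validation():
    with pytest.raises(ValueError):
        simulate_rotational_walk(dr=-1.0, dt=0.01, n_steps=10)
    with pytest.raises(ValueError):
        simulate_rotational_walk(dr=10.0, dt=0.01, n_steps=10)


# ---------------------------------------------------------------------------
# OU stress generator

def test_ou_variance_matches_target():
    cfg = StressSimConfig(n_replicas=4, n_samples=250_000, seed=9)
    reps = simulate_stress_ou(cfg)
    c0 = ou_stationary_variance(cfg)
    pooled = np.concatenate([r.channels.ravel() for r in reps])
    assert pooled.var() == pytest.approx(c0, rel=0.05)
    # C0 is defined so that (V/kT) * C0 * tau_c = eta*
    from crowdflow import BAR_TO_WORKING, thermal_energy
    eta = (cfg.volume / thermal_energy(cfg.temperature)
           * c0 * BAR_TO_WORKING ** 2 * cfg.tau_c)
    assert eta == pytest.approx(cfg.target_viscosity, rel=1e-12)


def test_ou_acf_is_exponential_within_noise():
    cfg = StressSimConfig(n_replicas=12, n_samples=50_000, seed=4)
    reps = simulate_stress_ou(cfg)
    acf = stress_acf_mean(reps, max_lag=5 * cfg.tau_c)
    theory = ou_stationary_variance(cfg) * np.exp(-acf.lags / cfg.tau_c)
    bound = 4.0 * acf.sigma / np.sqrt(len(reps)) + 1e-12
    assert np.all(np.abs(acf.mean - theory) < bound)


def test_ou_replicas_are_independent():
    cfg = StressSimConfig(n_replicas=3, n_samples=2000, seed=0)
    reps = simulate_stress_ou(cfg)
    assert not np.array_equal(reps[0].channels, reps[1].channels)
    # determinism across calls
    reps2 = simulate_stress_ou(cfg)
    for a, b in zip(reps, reps2):
        assert np.array_equal(a.channels, b.channels)


def test_ou_zero_viscosity_gives_silent_channels():
    cfg = StressSimConfig(target_viscosity=0.0, n_replicas=2, n_samples=100)
    reps = simulate_stress_ou(cfg)
    for r in reps:
        assert np.all(r.channels == 0.0)


def test_stress_config_validation():
    with pytest.raises(ValueError):
        StressSimConfig(target_viscosity=-1.0)
    with pytest.raises(ValueError):
        StressSimConfig(tau_c=0.0)
    with pytest.raises(ValueError):
        StressSimConfig(n_replicas=1)


# ---------------------------------------------------------------------------
# contact timeline generator

def test_contact_determinism():
    cfg = ContactSimConfig(n_frames=501, n_pairs=50, seed=3)
    a = simulate_contact_timeline(cfg)
    b = simulate_contact_timeline(ContactSimConfig(n_frames=501, n_pairs=50,
                                                   seed=3))
    assert np.array_equal(a.present, b.present)


def test_contact_occupancy_recovered():
    cfg = ContactSimConfig(taus=(10.0, 2.0, 0.3), occupancy=0.2,
                           n_frames=4001, n_pairs=1000, seed=2)
    tl = simulate_contact_timeline(cfg)
    assert tl.present.mean() == pytest.approx(0.2, rel=0.10)


def test_contact_component_counts_are_proportional():
    cfg = ContactSimConfig(weights=(0.5, 0.3, 0.2), n_frames=11, n_pairs=10,
                           seed=0)
    tl = simulate_contact_timeline(cfg)
    assert tl.ground_truth["component_counts"] == [5, 3, 2]
    assert tl.ground_truth["acf_taus"] == tuple(
        t * (1 - cfg.occupancy) for t in cfg.taus)


def test_contact_trivial_occupancies():
    none = simulate_contact_timeline(
        ContactSimConfig(weights=(0.0, 0.0, 0.0), occupancy=0.0,
                         n_frames=101, n_pairs=20))
    assert not none.present.any()
    full = simulate_contact_timeline(
        ContactSimConfig(occupancy=1.0, n_frames=101, n_pairs=20))
    assert full.present.all()


def test_contact_config_validation():
    with pytest.raises(ValueError):
        ContactSimConfig(weights=(-0.1, 0.6, 0.5))
    with pytest.raises(ValueError):
        ContactSimConfig(occupancy=1.5)
    with pytest.raises(ValueError):
        ContactSimConfig(taus=(1.0, 2.0, 3.0))
    with pytest.raises(ValueError):
        ContactSimConfig(occupancy=0.0)


# ---------------------------------------------------------------------------
# stickiness shows up in the contact graph

def test_sticky_crowd_clusters_more_than_hard_crowd():
    kw = dict(n_molecules=15, volume_fraction=0.2, n_steps=5000,
              save_every=10)
    means = {}
    for eps in (0.0, 3.0):
        vals = []
        for seed in (21, 22):
            pot = SquareWell(epsilon=eps, width=6.0)
            traj = simulate_brownian_crowd(
                CrowdSimConfig(potential=pot, seed=seed, **kw))
            tl = direct_contacts(traj, cutoff=2.0)
            cs = cluster_with_probe(tl, probe=0)
            vals.append(cs.in_cluster.mean())
        means[eps] = np.mean(vals)
    assert means[3.0] > 1.5 * means[0.0]
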