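import numpy as np
import pytest

from crowdflow import (
    BoxSpec,
    Dr_from_tau,
    ETA_TIP3P_SALTWATER,
    EWALD_XI_CUBIC,
    MSDCurve,
    TimeSeries,
    Trajectory,
    compute_msd,
    finite_size_correction_r,
    finite_size_correction_t,
    fit_Dt,
    fit_p2,
    hydrodynamic_radius,
    p2_acf,
    stokes_einstein_dt,
    thermal_energy,
    translational_pipeline,
    water_model_rescale,
    wrap_positions,
)


def brute_force_msd(pos, kmax):
    """O(F²) oracle: average squared displacement over all origins."""
    F = len(pos)
    out = np.zeros(kmax + 1)
    for k in range(1, kmax + 1):
        d = pos[k:] - pos[:-k]
        out[k] = (d ** 2).sum(axis=1).mean()
    return out


# ---------------------------------------------------------------------------
# MSD

def test_compute_msd_matches_brute_force(rng):
    F, M = 120, 3
    pos = np.cumsum(rng.standard_normal((F, M, 3)), axis=0)
    traj = Trajectory(times=np.arange(F) * 0.1, com_positions=pos,
                      box=BoxSpec(1e5), wrapped=False)
    msd = compute_msd(traj, max_lag=5.0)
    for m in range(M):
        want = brute_force_msd(pos[:, m, :], 50)
        assert np.allclose(msd.per_molecule[m], want, rtol=1e-8, atol=1e-8)
    assert np.allclose(msd.msd, msd.per_molecule.mean(axis=0))


def test_compute_msd_rejects_wrapped():
    pos = np.zeros((3, 1, 3))
    traj = Trajectory(times=np.arange(3.0), com_positions=pos,
                      box=BoxSpec(10.0), wrapped=True)
    with pytest.raises(ValueError, match="wrapped"):
        compute_msd(traj)


def test_msd_curve_validation():
    with pytest.raises(ValueError):
        MSDCurve(lags=np.arange(3.0), msd=np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError):
        MSDCurve(lags=np.arange(3.0), msd=np.array([0.0, -1.0, 3.0]))


def test_fit_Dt_exact_line():
    t = np.arange(0, 20.0, 0.1)
    d_true, c_true = 42.0, 7.0
    msd = MSDCurve(lags=t, msd=np.where(t > 0, 6 * d_true * t + c_true, 0.0))
    d, se, c = fit_Dt(msd, window=(2.0, 10.0))
    assert d == pytest.approx(d_true, rel=1e-12)
    assert c == pytest.approx(c_true, rel=1e-9)


def test_fit_Dt_window_validation():
    t = np.arange(0, 5.0, 1.0)
    msd = MSDCurve(lags=t, msd=6.0 * t)
    with pytest.raises(ValueError, match="five"):
        fit_Dt(msd, window=(2.0, 4.0))


def test_fit_Dt_recovers_random_walk(random_walk_traj):
    msd = compute_msd(random_walk_traj, max_lag=8.0)
    d, se, _ = fit_Dt(msd, window=(1.0, 6.0))
    d0 = random_walk_traj.ground_truth["d0"]
    assert abs(d - d0) < 4 * se
    assert 0 < se < 0.3 * d0


# ---------------------------------------------------------------------------
# corrections

def test_finite_size_correction_t_values():
    # correction magnitude: kT*xi/(6*pi*eta*L)
    d = finite_size_correction_t(100.0, eta_cp=0.347, box_edge=100.0,
                                 temperature=298.0)
    expect = 100.0 + thermal_energy(298.0) * EWALD_XI_CUBIC / (
        6 * np.pi * 0.347 * 100.0)
    assert d == pytest.approx(expect, rel=1e-12)
    # vanishes as L -> infinity
    far = finite_size_correction_t(100.0, 0.347, 1e9)
    assert far == pytest.approx(100.0, rel=1e-6)


def test_finite_size_correction_t_size_term():
    base = finite_size_correction_t(10.0, 1.0, 80.0)
    with_size = finite_size_correction_t(10.0, 1.0, 80.0, r_p=20.0,
                                         include_size_term=True)
    assert with_size < base          # the R_p term subtracts
    with pytest.raises(ValueError):
        finite_size_correction_t(10.0, 1.0, 80.0, include_size_term=True)


def test_water_model_rescale_reference_value():
    # TIP3P-like pure-water viscosity ratio: 622.5 -> 233.6 Å²/ns
    assert water_model_rescale(622.5) == pytest.approx(233.6, abs=0.05)
    with pytest.raises(ValueError):
        water_model_rescale(1.0, eta_model_water=0.0)


def test_finite_size_correction_r_formula():
    dr = finite_size_correction_r(0.05, eta_cp=ETA_TIP3P_SALTWATER,
                                  box_edge=120.0)
    expect = 0.05 + thermal_energy(298.0) / (
        6.0 * ETA_TIP3P_SALTWATER * 120.0 ** 3)
    assert dr == pytest.approx(expect, rel=1e-12)


# ---------------------------------------------------------------------------
# rotational fits

def test_fit_p2_on_exact_double_exponential():
    t = np.arange(0, 20.0, 0.05)
    a, tau_s, tau_f = 0.7, 10.0, 1.0
    y = a * np.exp(-t / tau_s) + (1 - a) * np.exp(-t / tau_f)
    est = fit_p2(TimeSeries(lags=t, values=y))
    assert est.amplitude == pytest.approx(a, abs=0.01)
    assert est.tau_slow == pytest.approx(tau_s, rel=0.02)
    assert est.tau_fast == pytest.approx(tau_f, rel=0.02)
    # amplitude-weighted overall time: 0.7*10 + 0.3*1 = 7.3
    assert est.tau_overall == pytest.approx(7.3, rel=0.01)
    assert est.dr_pbc == pytest.approx(1.0 / (6 * 7.3), rel=0.01)


def test_Dr_from_tau():
    assert Dr_from_tau(2.0) == pytest.approx(1.0 / 12.0)
    with pytest.raises(ValueError):
        Dr_from_tau(0.0)


def test_p2_acf_static_body_is_unity():
    # rigid body that never rotates: P2 ACF stays at 1 for all lags
    atoms = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0]])
    traj = Trajectory(
        times=np.arange(5.0),
        com_positions=np.zeros((5, 1, 3)),
        box=BoxSpec(100.0),
        atom_positions=np.broadcast_to(atoms, (5, 4, 3)).copy(),
        molecule_index=[0, 0, 0, 0],
        calpha_index={0: [0, 1, 2, 3]},
    )
    acf = p2_acf(traj, probe=0, n_vectors=64, max_lag=3.0)
    assert np.allclose(acf.values, 1.0, atol=1e-8)


def test_p2_acf_rejects_collinear_reference():
    atoms = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    traj = Trajectory(
        times=np.arange(3.0),
        com_positions=np.zeros((3, 1, 3)),
        box=BoxSpec(100.0),
        atom_positions=np.broadcast_to(atoms, (3, 3, 3)).copy(),
        molecule_index=[0, 0, 0],
        calpha_index={0: [0, 1, 2]},
    )
    with pytest.raises(ValueError, match="collinear"):
        p2_acf(traj, probe=0)


# ---------------------------------------------------------------------------
# Stokes-Einstein radii

def test_hydrodynamic_radius_round_trips():
    # translational: a 20 Å sphere in 1 cP water diffuses at 218.27/20
    d = stokes_einstein_dt(1.0, 20.0)
    assert hydrodynamic_radius(d, 1.0) == pytest.approx(20.0, rel=1e-12)
    # rotational
    dr = thermal_energy(298.0) / (8 * np.pi * 1.0 * 20.0 ** 3)
    assert hydrodynamic_radius(dr, 1.0, kind="rotational") == pytest.approx(
        20.0, rel=1e-12)
    with pytest.raises(ValueError):
        hydrodynamic_radius(d, 1.0, kind="bogus")


# ---------------------------------------------------------------------------
# pipeline + audit

def test_translational_pipeline_replay_audit(random_walk_traj):
    # wrap the walk into a box so the pipeline has to unwrap it
    L = 500.0
    wrapped = Trajectory(
        times=random_walk_traj.times,
        com_positions=wrap_positions(random_walk_traj.com_positions,
                                     BoxSpec(L)),
        box=BoxSpec(L), wrapped=True,
        ground_truth=random_walk_traj.ground_truth)
    est = translational_pipeline(wrapped, eta_cp=0.347, window=(1.0, 6.0),
                                 rescale=(0.334, 0.89))
    assert est.d_corrected > est.d_pbc
    assert est.d_final == pytest.approx(est.d_corrected * 0.334 / 0.89)
    d_corr, d_final = est.replay()
    assert d_corr == pytest.approx(est.d_corrected, rel=1e-12)
    assert d_final == pytest.approx(est.d_final, rel=1e-12)
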