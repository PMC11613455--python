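# Methods

This document records the physical models, estimators, numerical choices,
and known limitations of the `crowdflow` package. Units throughout:
length Å, time ns, viscosity cP, temperature K, pressure bar.

## Units and constants

The working energy unit is chosen so that Stokes–Einstein expressions are
unit-clean: `thermal_energy(T)` returns k_BT in cP·Å³/ns, so

    D_t = thermal_energy(T) / (6π · η[cP] · R[Å])   →  Å²/ns
    D_r = thermal_energy(T) / (8π · η[cP] · R[Å]³)  →  1/ns

At 298 K, `thermal_energy(298) = 4114.33` and k_BT/(6π·1 cP·1 Å) =
218.27 Å²/ns. Green–Kubo integrals take stress in bar and convert
internally (1 bar² · Å³ · ns / k_BT → cP).

## Green–Kubo viscosity (`viscosity`, `synth.simulate_stress_ou`)

η = (V/k_BT) ∫₀^∞ ⟨P_αβ(0) P_αβ(t)⟩ dt, averaged over the independent
off-diagonal/deviatoric pressure channels. The estimator:

1. Per replica, per channel: FFT autocorrelation with the unbiased 1/(N−k)
   normalisation; channels averaged; cumulative trapezoidal integral gives
   the running integral η(τ).
2. Across replicas: mean curve and cross-replica σ(τ). σ grows as a power
   law A·τ^b on the plateau approach; the fitted power law (not raw σ,
   which vanishes at small τ and would dominate the weights) provides the
   weights for the extrapolation fit.
3. Extrapolation: η(τ) = η∞ − α·[w exp(−τ/τ₁) + (1−w) exp(−τ/τ₂)] by
   multi-start weighted least squares. Identifiability bounds: fitted time
   constants are capped at the fit window (slower components cannot be
   resolved) and η∞ at 3× the plateau value. Without these bounds the fit
   can drift to large η∞ with huge uncertainty on an already-saturated
   curve.
4. τ_max selection: candidates are scanned in increasing order and the
   first pair of consecutive estimates agreeing within combined bootstrap
   uncertainties is accepted (first-stable-pair protocol); otherwise the
   largest candidate is returned flagged `converged=False`.
5. Uncertainty: bootstrap over replicas (resample replica indices, refit).

The synthetic stress generator is an Ornstein–Uhlenbeck process per
channel, generated by `scipy.signal.lfilter` from the exact AR(1)
recursion, with stationary variance chosen so the closed-form Green–Kubo
integral equals the target viscosity: η = (V/k_BT)·C₀·τ_c. Replicas use
`SeedSequence.spawn` for independence.

## Translational diffusion (`diffusion`)

MSD via the FFT decomposition MSD(k) = S₁(k) − 2·S₂(k) (O(N log N)),
averaged over molecules; trajectories must be unwrapped first
(`unwrap_positions` inverts minimum-image jumps; round-trip tested).

`fit_Dt` fits MSD = 6·D·t + c over a time window with a free intercept
(absorbs short-time behaviour). Standard error: neighbouring MSD lags
share time origins and are strongly correlated, so a residual-based SE on
the pooled curve is ~100× too small. Instead each molecule's MSD is fitted
independently and SE(D) is the standard error of the per-molecule slopes
(molecules are the independent statistical units).

Finite-size (periodic-boundary) correction, cubic box:

    D = D_PBC + k_BT·ξ/(6π·η·L),  ξ = 2.837297

with an optional higher-order solute-size term −4πR_p²/(3L³) (off by
default). The viscosity entering the correction is the *suspension*
viscosity of the crowded system, η₀·η_r(φ) (Einstein η_r = 1 + 2.5φ for
hard spheres), not the bare solvent viscosity — using the system's own
viscosity is what makes the corrected D recover the dilute-limit D₀ on
hard-sphere crowds.

Water-model rescale (applied after the PBC correction, never before):
D ← D · η_model/η_exp with defaults η_TIP3P = 0.334 cP, η_exp = 0.89 cP
(e.g. 622.5 Å²/ns → 233.6 Å²/ns for pure model water).

## Rotational diffusion (`diffusion.p2_acf`, `fit_p2`)

P2 orientational ACF of body-fixed unit vectors. Rather than correlating
P2(cosθ) directly, the second-moment identity is used: with unit vectors
u(t), ⟨P2(u(0)·u(t))⟩ = (3⟨(u(0)·u(t))²⟩ − 1)/2, and the square expands
into autocorrelations of the 6 independent quadratic components
(x², y², z², xy, xz, yz with weights 1,1,1,2,2,2), each computable by FFT.

For trajectories with atomic coordinates the body frame per frame is
obtained by Kabsch superposition onto the reference frame
(`scipy.spatial.transform.Rotation.align_vectors`); collinear reference
geometries are rejected.

`fit_p2` fits a double exponential a·exp(−t/τ_slow) + (1−a)·exp(−t/τ_fast)
with time constants bounded by the fit window (same identifiability
argument as the viscosity fit; unbounded slow components occasionally sent
τ_overall → ∞). τ_overall = a·τ_slow + (1−a)·τ_fast and
D_r = 1/(6·τ_overall). Finite-size correction: D_r = D_r,PBC + k_BT/(6ηL³)
(leading order; the prefactor is exposed as an argument).

The synthetic rotational walk composes small random rotations with angular
variance 2·D_r·dt per axis, giving exactly ⟨P2⟩ = exp(−6 D_r t); rigidity
is preserved by construction (Gram matrix invariance tested).

## Contact and cluster kinetics (`contacts`, `synth.simulate_contact_timeline`)

Contacts: two molecules are in contact when the minimum heavy-atom
distance is below the cutoff (default 5 Å; hydrogens excluded), or in
surrogate (sphere) mode when the surface gap is below the cutoff. Distances
use the minimum image convention.

Clusters: connected components of the contact graph (union–find,
deterministic lowest-index labels). `ClusterSeries` tracks the probe's
cluster size, direct contacts, and in-cluster partners, with the invariant
direct ≤ in-cluster ≤ N−1.

The contact ACF is the pooled intermittent autocorrelation
C(k) = [Σ_pairs Σ_t δδ(t+k)/(N−k)] / [Σ_pairs Σ_t δ²/N] (C(0)=1), with
SEM over pair groups. For an alternating renewal (telegraph) process with
exponential on-times (mean τ) and occupancy p, the ACF decays with time
constant τ(1−p) to the plateau Σp_i²/Σp_i — a (1−p) bias relative to the
bare on-time that matters at high occupancy. Survival fits therefore take
an explicit `baseline` (recommended: the global occupancy, the true
renewal plateau; the empirical plateau estimator is biased upward when
pairs complete few on/off cycles).

The synthetic timeline assigns each pair ONE mixture component (w_i of
pairs are τ_i-pairs) with off-times matched to a common stationary
occupancy. This makes the pooled ACF exactly
C(t) = p + (1−p)·Σ w_i exp(−t/(τ_i(1−p))), with amplitudes w_i. (Redrawing
the component per interval would instead length-bias the amplitudes to
w_iτ_i/Στ̄, burying fast components.)

Convergence diagnostics: block Z-scores comparing early/late window means
against combined SEMs; calibrated so white noise gives |Z| < 1 most of the
time and drifts flag |Z| > 3.

## Colloid-theory interaction strength (`colloid`)

RDF: minimum-image COM pair histogram, normalised by the finite-N ideal
count n_pairs·4πr²Δr/V; frames are processed in chunks to bound memory.

Second virial coefficient: B2 = −2π ∫₀^{r_max} (g(r)−1) r² dr (trapezoid).
r_max must cut the integral where g has reached 1 (for a square-well pair
potential: just past the well edge plus the force-smoothing zone);
extending into noisy large-r bins adds O(r³)-amplified noise.

Baxter adhesive-hard-sphere chain:

    B2 = 4·V_HS·(1 − 1/(4τ_B))   ⇔   τ_B = 1/(4 − B2/V_HS)
    K_D[Å⁻³] = τ_B / V_probe;   K_D[mM] = K_D[Å⁻³] · 10³⁰/N_A
    heterotypic V_HS = (4π/3)·((a₁+a₂)/2)³

τ_B is only defined for net-attractive pairs (B2 < 4·V_HS). The
viscosity route: η_r = 1 + 2.5φ + bφ² with b = 5.9 + 1.9/τ_B, so
τ_B = 1.9/(b − 5.9) (e.g. b = 63.4 → τ_B = 0.033).

## Concentration models (`models`)

φ = c[g/L]/1430. Viscosity laws: Einstein 1 + 2.5φ; quadratic
1 + 2.5φ + bφ²; Mooney exp(Sφ/(1−Kφ)). Cluster model:
D(φ) = D₀·η_r(φ)⁻¹·(1+ζφ)^−p with p = 1/3 (translational, cluster radius
~ cube root of size) or p = 1 (rotational); ζ ≥ 0 enforced, near-zero ζ
flagged `at_bound`. Generalized Stokes–Einstein ratio
(D/D₀)/(η₀/η): unity when viscosity alone explains the slow-down, below
unity when transient clusters add hydrodynamic size.

## Synthetic generators: scope and limitations

- The Brownian crowd is overdamped Langevin dynamics of spheres with an
  optional square-well attraction (harmonic core repulsion, linear force
  smoothing over 0.5 Å at the discontinuities). No hydrodynamic
  interactions: the hard-sphere slow-down is ≈(1−2φ), not the full
  hydrodynamic result, and generated "viscosity" effects enter only
  through the Einstein relation used in the analysis, not the dynamics.
- Euler–Maruyama sampling of exp(−βU) is biased when the RMS step
  √(2D₀dt) approaches the 0.5 Å force-smoothing zone; B2-from-RDF studies
  use smaller D₀·dt so the well population is faithful.
- Statistical error of B2 from a dilute crowd is governed by the number of
  pair encounters: (encounter decorrelation time)/(T · pairs-in-well).
  Small spheres at low φ (higher number density) and large N make the
  estimate feasible at desk scale; per-seed errors remain ~20% and
  multi-seed pooled RDFs are required for a few-percent estimate.
- MSD window dependence: on the hard-sphere crowd, slopes fitted in the
  10–50 ns window run a few percent above the 2–10 ns window (lags
  approaching half the trajectory have few independent origins and large,
  correlated fluctuations). The two windows agree within 2× combined
  standard errors; quantitative estimates should use the 2–10 ns window.
- The stress generator is a single-timescale OU process; real stress ACFs
  have fast molecular components. It is an oracle for the estimator (the
  closed-form η is exact), not a water model.
- The contact generator is stationary by construction; it cannot produce
  equilibration transients (the Z-score diagnostic is validated on
  injected drifts instead).
- `StabilityError` is raised when the integrator detects per-step moves
  beyond half the box, which happens for deep wells with weak cores at
  large dt.

## Numerical choices

- All ACFs/MSDs use FFT correlation with explicit unbiased normalisation;
  direct O(N²) sums are kept in the test suite as oracles.
- Nonlinear fits use `scipy.optimize.curve_fit` with multi-start
  initialisation over log-spaced time constants and explicit bounds;
  degenerate component separation is flagged rather than silently merged.
- All generators take integer seeds (< 2³¹) and are deterministic given
  the seed; replicated generators spawn child seeds via
  `numpy.random.SeedSequence.spawn`.
- Logarithmic lag grids (24 points/decade) keep long-lag fits from being
  dominated by the dense short-lag region.
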