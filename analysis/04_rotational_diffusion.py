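#!/usr/bin/env python
"""Rotational diffusion from the P2 orientational autocorrelation.

Simulates a rigid-body rotational walk at known Dr, computes the P2 ACF,
fits the bounded double exponential, and reports Dr = 1/(6 tau_overall)
with the finite-size correction shown for a typical box.
"""

import json
from pathlib import Path

import crowdflow as cf

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

DR_TRUE = 0.05
walk = cf.simulate_rotational_walk(dr=DR_TRUE, dt=0.01, n_steps=200_000,
                                   n_vectors=16, seed=3)
acf = cf.p2_acf(walk, max_lag=20.0)
fit = cf.fit_p2(acf, window=(0.0, 20.0))
dr_pbc = cf.Dr_from_tau(fit.tau_overall)
dr_corr = cf.finite_size_correction_r(dr_pbc, eta_cp=0.35, box_edge=100.0)

(OUT / "rotational_diffusion.json").write_text(json.dumps({
    "tau_overall_ns": fit.tau_overall,
    "amplitude": fit.amplitude,
    "tau_fast_ns": fit.tau_fast,
    "tau_slow_ns": fit.tau_slow,
    "dr_pbc_per_ns": dr_pbc,
    "dr_corrected_per_ns": dr_corr,
    "dr_true_per_ns": DR_TRUE,
}, indent=2) + "\n")

print(f"tau_overall = {fit.tau_overall:.3f} ns -> "
      f"Dr = {dr_pbc:.4f} /ns (true {DR_TRUE}); "
      f"finite-size corrected (L=100 A, eta=0.35 cP): {dr_corr:.4f}")
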