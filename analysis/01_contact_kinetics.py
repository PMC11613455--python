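#!/usr/bin/env python
"""Contact survival kinetics on the synthetic three-timescale generator.

Generates the contact timeline, pools the intermittent contact ACF over
pairs, fits the baseline-subtracted triple exponential, and writes a
contact-kinetics summary table.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import crowdflow as cf

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = cf.ContactSimConfig(seed=5)
timeline = cf.simulate_contact_timeline(cfg)
acf = cf.contact_acf(timeline)
fit = cf.fit_triple_exponential(acf, baseline=cfg.occupancy)
recovered = fit.taus / (1.0 - cfg.occupancy)

rows = [
    {"component": i + 1,
     "weight": float(fit.weights[i]),
     "tau_acf_ns": float(fit.taus[i]),
     "tau_survival_ns": float(recovered[i]),
     "tau_true_ns": cfg.taus[i]}
    for i in range(3)
]
table = pd.DataFrame(rows)
table.to_csv(OUT / "contact_kinetics.csv", index=False)

# equilibration diagnostic on the uniformly sampled mean-occupancy trace
occupancy_trace = cf.TimeSeries(lags=timeline.times,
                                values=timeline.present.mean(axis=1))
report = cf.convergence_zscore(occupancy_trace)
(OUT / "contact_kinetics.json").write_text(json.dumps({
    "occupancy": cfg.occupancy,
    "n_pairs": cfg.n_pairs,
    "plateau_estimate": cf.acf_plateau(timeline),
    "fit_residual": fit.residual,
    "degenerate": fit.degenerate,
    "zscore_max": float(np.max(np.abs(report.z))),
}, indent=2) + "\n")

print(table.to_string(index=False))
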