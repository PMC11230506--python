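"""Two-site nucleotide binding and the GDP -> GTP chase.

Simulates association of a fluorescent nucleotide to the two-site G-protein
scheme, fits the one-phase association form, then runs a 10x unlabeled-GTP
chase and compares exchange half-times for an open (access2 = 1) versus a
restricted (access2 = 0.1, intermediate-like) canonical site."""

import numpy as np

from gpcrkit.kinetics import (AssayProtocol, TwoSiteModel, exchange_summary,
                              fit_association, simulate_assay)

model = TwoSiteModel(kon1=1e5, koff1=0.01, ktrans=0.0, access2=0.0,
                     protein=1e-9, labeled=1e-7)
trace = simulate_assay(model, AssayProtocol(duration=800.0, n_samples=400))
fit = fit_association(trace, "one_phase")
kobs_expected = model.kon1 * model.labeled + model.koff1
print(f"one-phase fit: k_obs = {fit.params['k1']:.4f} 1/s "
      f"(pseudo-first-order prediction {kobs_expected:.4f} 1/s)")

rates = dict(kon1=1e5, koff1=0.005, ktrans=0.003, koff2=5e-4,
             protein=2e-7, labeled=1e-7)
chase = AssayProtocol(duration=40_000.0, n_samples=1_000,
                      events=((5_000.0, "unlabeled", 1e-6),))
for access in (1.0, 0.1):
    out = exchange_summary(TwoSiteModel(access2=access, **rates), chase)
    print(f"access2 = {access}: exchange t1/2 = {out['t_half']:.0f} s")
print("restricting the canonical site slows exchange — the kinetic "
      "signature of the intermediate complex")
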