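"""Accelerated sampling on a 1-D double well, reweighted back to the exact
free-energy profile.

Runs the staged protocol (plain MD for statistics, boosted equilibration
with adaptive parameters, three production replicas), reweights the boosted
histogram with the second-order cumulant expansion and compares it with the
quadrature reference.  The printed maximum deviation is the end-to-end error
of sampling + boosting + reweighting; well under the ~0.6 kcal/mol thermal
energy at 310 K means the boost was fully corrected for."""

import numpy as np

from gpcrkit.gamd import GaMDProtocol, run_protocol
from gpcrkit.potentials import make_double_well
from gpcrkit.reweight import CVSeries, cumulant_reweight_pmf

model = make_double_well(a=1.0, b=1.0)   # barrier a*b^4 = 1 kcal/mol
protocol = GaMDProtocol(dt=0.01, n_cmd=50_000, n_equil=100_000,
                        n_production=200_000, stats_cadence=10_000,
                        mode="single", replicas=3)
traj = run_protocol(model, protocol, seed=1)
prod = traj.combined_production()
params = traj.final_params["total"]
print(f"boost parameters: E = {params.e:.3f} kcal/mol, k0 = {params.k0:.3f}")

edges = np.arange(-1.8, 1.81, 0.1)
fes = cumulant_reweight_pmf(CVSeries("x", "A", prod.coords[:, 0]), prod.dv,
                            bin_sizes=0.1, cutoff=50, edges=[edges])
ref = model.reference_pmf(edges)
sel = (~fes.mask) & (ref <= 3.0)
err = np.nanmax(np.abs(fes.free_energy[sel] - ref[sel]))
print(f"{prod.n_frames} production frames over 3 replicas")
print(f"max |reweighted - exact| on bins below 3 kcal/mol: {err:.3f} kcal/mol")
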