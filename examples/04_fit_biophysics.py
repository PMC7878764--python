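"""Fit synthetic stopped-flow, chemical-denaturation and melt data.

Generates noisy curves at the package's reference study conditions
(5% range noise, three averaged replicates) and recovers the generating
parameters with the fitting models.
"""

import numpy as np

from ccpo import biophys as bp

RC = bp.REFERENCE_CONDITIONS
noise, nrep = RC["noise_fraction"], RC["n_replicates"]

# stopped-flow refolding: y = a exp(-k t) + b t + c
p = RC["kinetics"]
t = np.arange(0.0, p["t_max_s"], p["dt_s"])
trace = bp.simulate_kinetic_trace(p["k"], p["a"], p["b"], p["c"], t,
                                  noise_sd=noise * p["a"], seed=7,
                                  n_replicates=nrep)
fit = bp.fit_kinetics(trace)
print(f"kinetics: true k = {p['k']} /s, fitted k = {fit.k:.2f} /s "
      f"(+/- {fit.stderr['k']:.2f})")

# chemical denaturation: two-state sigmoid in Gdn-HCl
p = RC["chem_denaturation"]
conc = np.arange(0.0, p["conc_max_M"] + 1e-9, p["dconc_M"])
curve = bp.simulate_chem_denaturation(p["dG_fold"], p["m"], p["B"], p["C"],
                                      p["D"], conc, noise_sd=noise * p["C"],
                                      seed=7, n_replicates=nrep)
cfit = bp.fit_chem_denaturation(curve)
print(f"denaturation: dG_fold = {cfit.dG_fold:.1f} kJ/mol (true {p['dG_fold']}), "
      f"midpoint = {cfit.midpoint_M:.2f} M (true {p['dG_fold']/p['m']:.2f})")

# thermal melts followed by CD at 222 nm
temp_C = np.arange(0.0, 90.5, 1.0)
p = RC["melt_two_state"]
span = float(np.ptp(bp.simulate_thermal_curve(p, temp_C, "two-state").mre222))
melt = bp.simulate_thermal_curve(p, temp_C, "two-state",
                                 noise_sd=noise * span, seed=7, n_replicates=nrep)
mfit = bp.fit_thermal_two_state(melt)
print(f"two-state melt: Tm = {mfit.Tm_C:.1f} C (true {p['Tm_C']}), "
      f"dH = {mfit.dH:.0f} kJ/mol (true {p['dH']})")

p = RC["melt_three_state"]
span = float(np.ptp(bp.simulate_thermal_curve(p, temp_C, "three-state").mre222))
melt3 = bp.simulate_thermal_curve(p, temp_C, "three-state",
                                  noise_sd=noise * span, seed=7, n_replicates=nrep)
m3 = bp.fit_thermal_three_state(melt3)
print(f"three-state melt: Tm1 = {m3.Tm1_C:.1f} C, Tm2 = {m3.Tm2_C:.1f} C "
      f"(true {p['Tm1_C']}, {p['Tm2_C']}); enthalpies are only weakly "
      "determined by a single melt")

# helicity from MRE at 222 nm for a 391-residue chain
helicity = bp.helical_content(-33_000.0, 391)
print(f"helical content at MRE222 = -33,000: {helicity:.0f} %")
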