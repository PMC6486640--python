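"""Simulate the wild-type ATPase mechanism and read off its phases.

Builds the lumped proximal/distal mechanism with the published best-fit
rate constants, simulates phosphate release at 2 µM dimer + 1 mM ATP, and
fits the lag + burst + linear model to the resulting trace.
"""

import numpy as np

import uvrkin as uk

variant, params = uk.variant_preset("wild_type_apo")
network = uk.build_mechanism(variant, params)
print("states:", " -> ".join(network.states))

cond = uk.ExperimentCondition(enzyme_total=2.0, atp_total=1000.0)
t = np.concatenate([[0.0], np.geomspace(1e-3, 10.0, 500)])
traj = uk.simulate(network, cond, t)

trace = uk.KineticTrace(times=t, signal=traj.cumulative_pi, condition=cond)
fit = uk.fit_burst_linear(trace)
kcat = uk.kcat_from_slope(fit.linear_rate, active_sites=4,
                          enzyme_total=cond.enzyme_total)

print(f"burst rate       : {fit.k_burst:.2f} s^-1   (fast first-turnover phase)")
print(f"lag rate         : {fit.k_lag:.1f} s^-1   (steps before Pi release)")
print(f"burst amplitude  : {fit.burst_amplitude:.2f} uM   "
      f"(~{fit.burst_amplitude / cond.enzyme_total:.1f} Pi per dimer)")
print(f"steady-state kcat: {kcat:.3f} s^-1 per site (slope / 4 x [dimer])")
print()
print("The burst counts the sites that hydrolyze ATP rapidly in the first")
print("turnover (the distal pair); the much slower linear phase shows that")
print("a post-chemistry step (ADP release) limits catalytic cycling.")
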