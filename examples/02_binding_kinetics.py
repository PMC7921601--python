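"""Two-step binding mechanism: colocalization kinetics and stoichiometry.

Simulates a population of client molecules captured by small chaperone
species (step 1) that then accrete further chaperone subunits (step 2),
samples the bound-client fraction over a 10-hour incubation, and fits the
one-phase association model used for colocalization kinetics.
"""

import numpy as np

from smstoich import (
    BindingKineticsConfig,
    colocalized_fraction_kinetics,
    simulate_complex_population,
)

cfg = BindingKineticsConfig(
    k_bind=1.0,  # client capture rate, 1/h
    k_accrete=0.3,  # subunit accretion rate, 1/h
    k_off=0.05,  # subunit loss rate, 1/h
    plateau_bound_fraction=0.5,  # equilibrium bound-client fraction
    molar_ratio=2.0,  # chaperone:client, as in the kinetics experiments
)
timepoints = [0, 0.25, 0.5, 0.75, 1, 4, 8, 10]

snapshots = simulate_complex_population(cfg, timepoints, n_clients=500, seed=2)

print("time (h)  bound fraction  mean chaperone subunits per complex")
for snap in snapshots:
    n_ch = [c.n_chaperone for c in snap.complexes]
    mean_ch = np.mean(n_ch) if n_ch else 0.0
    print(f"{snap.time:7.2f}  {snap.bound_fraction:14.3f}  {mean_ch:20.2f}")

fractions = [100.0 * s.bound_fraction for s in snapshots]
fit = colocalized_fraction_kinetics(timepoints, fractions)
print()
print(f"one-phase association fit: plateau = {fit.plateau:.1f} %, "
      f"k = {fit.k:.2f} /h")
print("The bound fraction rises with one-phase kinetics toward its")
print("equilibrium plateau while existing complexes keep growing: the")
print("signature of capture followed by subunit accretion.")
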