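"""Canonical (TST) and microcanonical (RRKM) rate constants.

Shows the Eyring expression with path degeneracy and Eckart tunneling,
the Beyer-Swinehart direct count of harmonic states, and an RRKM rate
for the first barrier of a three-step unimolecular toy network.
"""

from mechkit.kinetics import (
    beyer_swinehart,
    eckart_correction,
    rrkm_rate,
    tst_rate,
)
from mechkit.synthfix import make_toy_network

T = 298.15
print(f"TST, zero barrier, {T} K: k = {tst_rate(0.0, T).value:.4e} s^-1 "
      "(= k_B T / h)")
k = tst_rate(15.0, T, sigma=2.0)
print(f"TST, 15 kcal/mol barrier, sigma=2: k = {k.value:.4e} {k.units}")

kappa = eckart_correction(10.0, 8.0, 1500.0, 300.0)
print(f"Eckart transmission (10/8 kcal/mol, 1500i cm^-1, 300 K): "
      f"kappa = {kappa:.3f}")

counts = beyer_swinehart([100.0], 350.0, grain=10.0)
print(f"sum of states, one 100 cm^-1 mode up to 350 cm^-1: "
      f"W = {counts.sum_of_states(350.0):.0f}")
counts = beyer_swinehart([100.0, 100.0], 250.0, grain=10.0)
print(f"sum of states, two 100 cm^-1 modes up to 250 cm^-1: "
      f"W = {counts.sum_of_states(250.0):.0f}")

net = make_toy_network("vcn_like")
well, ts = net.wells["R"], net.transition_states["TS1"]
for E in (100.0, 120.0, 150.0):
    k = rrkm_rate(well, ts, E)
    print(f"RRKM k(E={E:.0f} kcal/mol) over the first barrier: "
          f"{k.value:.3e} s^-1")
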