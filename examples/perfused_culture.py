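"""Perfused bioreactor culture: mechanical stimulation sustains the biomass.

Runs the 30-day perfused scenario (100 mPa traction and a 50 um/s inlet
flow at the fluid interface, saturated external oxygen, low growth rate)
and contrasts it with the oxygen picture.  The perfusion stress makes the
stress state anisotropic throughout the bar from the first time step
(the xi flag is 0 everywhere), which recruits quiescent cells into the
active pools, and the through-flow keeps oxygen pinned at its external
value, so consumption never limits the culture.
"""

import numpy as np

import chondrosim as cs

cfg = cs.scenario_presets()["perfused-IC1-kg1-csat"]
rec = cs.run_simulation(cfg)

m = rec.midpoint
print(f"scenario: {cfg.name}  (T_b = {cfg.T_b:g} dyne/cm^2, "
      f"V(L)·n = {cfg.V_b:g} cm/s)")
print(f"xi after t=0: min {rec.xi_grid[1:].min():g}, "
      f"max {rec.xi_grid[1:].max():g}  (0 = anisotropic everywhere)")
print(f"oxygen at midpoint, day 30: {m['c'][-1]:.4e} g/cm^3 "
      f"(external value {cfg.c_ext:.4e})")
cells = m["phi_n"] + m["phi_v"] + m["phi_q"]
print(f"total cell fraction at L/2: day 0 {cells[0]:.3e} -> "
      f"day 30 {cells[-1]:.3e}")
print(f"ECM fraction at L/2:        day 0 {m['phi_ECM'][0]:.3e} -> "
      f"day 30 {m['phi_ECM'][-1]:.3e}")
print()
print("Perfusion keeps the construct anisotropic and oxygen-rich: the")
print("cell population holds steady and ECM accumulates, unlike the")
print("static culture where the same growth rate leads to extinction.")
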