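"""Structural checks of the numerical scheme.

Runs the verification battery: kinetic closure (sum of production terms
vanishes), the Mohr identity behind the stress gate, discrete mass
conservation and the maximum principle of the exponential-fitting
transport step, Darcy consistency of the poroelastic step, and
manufactured-solution convergence orders (both solvers are second order
in the mesh size).
"""

from chondrosim.verify import run_verification

for name, (ok, detail) in run_verification(fast=True).items():
    print(f"[{'ok' if ok else 'FAIL'}] {name}: {detail}")
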