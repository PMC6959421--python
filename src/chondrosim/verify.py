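"""Self-contained verification battery: model invariants and solver checks.

These are the structural guarantees of the scheme — kinetic closure,
Mohr-circle consistency of the stress indicator, discrete conservation and
positivity of the transport steps, Darcy consistency at steady state, and
manufactured-solution convergence orders — runnable from the CLI
(``chondrosim verify``) or programmatically.
"""

from __future__ import annotations

import numpy as np

from .constitutive import stress_decomposition
from .fem import (bernoulli, build_mesh, convergence_order,
                  solve_adr_step, solve_poroelastic_step)
from .kinetics import CellFractions, GrowthCoefficients, population_production
from .parameters import ModelParameters, derived_parameters


def check_kinetic_closure(n_states: int = 1000, seed: int = 0,
                          production=population_production) -> tuple[bool, str]:
    """Σ Q = 0 over randomized admissible states, to machine precision."""
    rng = np.random.default_rng(seed)
    p = ModelParameters()
    worst = 0.0
    for _ in range(n_states):
        phis = rng.dirichlet(np.ones(5))[:4] * rng.uniform(0.0, 0.9)
        fr = CellFractions(*phis)
        c = rng.uniform(0.0, p.c_sat)
        Q = production(fr, c, float(rng.integers(2)),
                       float(rng.integers(2)), p)
        total = Q.Q_n + Q.Q_v + Q.Q_q + Q.Q_ECM + Q.Q_fl
        scale = max(abs(Q.Q_n), abs(Q.Q_v), abs(Q.Q_q), abs(Q.Q_ECM), 1e-30)
        worst = max(worst, abs(total) / scale)
    return worst < 1e-12, f"max relative closure defect {worst:.2e}"


def check_mohr_identity(n_states: int = 1000, seed: int = 1) -> tuple[bool, str]:
    """r equals |σ_I − σ_II| / (2 μ) on randomized stress states."""
    rng = np.random.default_rng(seed)
    p = ModelParameters()
    worst = 0.0
    for _ in range(n_states):
        fr = CellFractions(*(rng.uniform(0, 0.2, size=4)))
        g = GrowthCoefficients(*(rng.normal(0, 0.05, size=4)))
        u_x = rng.normal(0, 1e-3)
        pres = rng.normal(0, 1.0)
        ss = stress_decomposition(u_x, pres, fr, g, p)
        mohr = abs(ss.sigma_I - ss.sigma_II) / (2.0 * p.mu)
        worst = max(worst, abs(mohr - ss.r) / max(ss.r, 1e-30))
    return worst < 1e-10, f"max relative Mohr defect {worst:.2e}"


def check_adr_conservation() -> tuple[bool, str]:
    """Lumped mass is conserved by the pure-diffusion step with flux-free ends."""
    mesh = build_mesh(0.01, 80)
    rng = np.random.default_rng(2)
    phi = rng.uniform(0.0, 0.1, mesh.N + 1)
    m = mesh.lumped_mass()
    before = float(m @ phi)
    out = solve_adr_step(mesh, phi, 1e-9, np.zeros(mesh.N),
                         np.zeros(mesh.N + 1), np.zeros(mesh.N + 1), 600.0)
    after = float(m @ out)
    rel = abs(after - before) / before
    return rel < 1e-12, f"relative mass defect per step {rel:.2e}"


def check_maximum_principle() -> tuple[bool, str]:
    """Nutrient step output stays inside [0, c_sat] at high Péclet number."""
    p = ModelParameters()
    mesh = build_mesh(p.L, 100)
    c_prev = np.full(mesh.N + 1, p.c0)
    vel = np.full(mesh.N, -5e-3)
    out = solve_adr_step(mesh, c_prev, 7.7e-6, vel,
                         np.full(mesh.N + 1, 1e-4), np.zeros(mesh.N + 1),
                         600.0, bc="dirichlet_right", dirichlet_value=p.c_sat)
    lo, hi = float(out.min()), float(out.max())
    ok = lo >= 0.0 and hi <= p.c_sat * (1 + 1e-12)
    return ok, f"range [{lo:.3e}, {hi:.3e}] within [0, {p.c_sat:g}]"


def check_darcy_consistency() -> tuple[bool, str]:
    """Steady uniform state: recovered Darcy flux is constant and equals V_b."""
    p = ModelParameters()
    dp = derived_parameters(p)
    mesh = build_mesh(p.L, 60)
    fr = CellFractions(*(np.full(mesh.N + 1, 0.002) for _ in range(4)))
    g = GrowthCoefficients(*(np.zeros(mesh.N + 1) for _ in range(4)))
    sol = solve_poroelastic_step(mesh, np.zeros(mesh.N + 1), fr, g, dp,
                                 dt=1e12, T_b=0.0, V_b=-p.V_b)
    spread = float(np.ptp(sol.V)) / p.V_b
    err = abs(sol.V.mean() + p.V_b) / p.V_b
    ok = spread < 1e-10 and err < 1e-10
    return ok, f"V spread {spread:.2e}, mismatch with V_b {err:.2e}"


def check_sg_central_limit() -> tuple[bool, str]:
    """The exponential-fitting flux reduces to central differencing as Pe → 0."""
    d = bernoulli(1e-8) - bernoulli(-1e-8) + 1e-8   # B(-x) - B(x) = x
    near = abs(bernoulli(1e-8) - (1.0 - 0.5e-8))
    ok = abs(d) < 1e-15 and near < 1e-12
    return ok, f"identity defect {abs(d):.1e}, B(1e-8) vs central {near:.1e}"


def _adr_manufactured_error(N: int) -> float:
    # steady diffusion-reaction with cos profile: flux-free ends are exact
    L, D, rho = 0.01, 1e-6, 1.0
    mesh = build_mesh(L, N)
    x = mesh.nodes
    exact = np.cos(np.pi * x / L)
    source = (D * (np.pi / L) ** 2 + rho) * exact
    out = solve_adr_step(mesh, exact * 0.0, D, np.zeros(mesh.N),
                         np.full(mesh.N + 1, rho), source, dt=1e12)
    return float(np.sqrt(mesh.lumped_mass() @ (out - exact) ** 2 / L))


def _poro_manufactured_error(N: int) -> float:
    p = ModelParameters()
    dp = derived_parameters(p)
    L = p.L
    mesh = build_mesh(L, N)
    x = mesh.nodes
    phi = np.full(mesh.N + 1, 0.005)
    fr = CellFractions(phi, phi, phi, phi)
    K = float(np.mean(np.asarray(
        [dp.K_ref * (1 - 4 * 0.005) ** 2 / (4 * 0.005)])))
    dt = 100.0
    u_exact = 1e-5 * np.sin(np.pi * x / (2 * L))
    p_exact = 0.5 * np.sin(np.pi * x / L)
    # choose the growth offset so the total stress is exactly constant
    phi_s = 4 * 0.005
    T_const = 0.3
    u_x = 1e-5 * (np.pi / (2 * L)) * np.cos(np.pi * x / (2 * L))
    S_g = dp.H_A * phi_s * u_x - p_exact - T_const
    # park the whole offset in g_n (phi_n * g_n * H_A = S_g)
    g = GrowthCoefficients(g_n=S_g / (dp.H_A * phi), g_v=np.zeros_like(x),
                           g_q=np.zeros_like(x), g_ECM=np.zeros_like(x))
    # mass equation: (u_x - u_prev_x)/dt = (K p_x)_x  =>  u_prev = u - dt*K*(p_x - p_x(0))
    p_x = 0.5 * (np.pi / L) * np.cos(np.pi * x / L)
    u_prev = u_exact - dt * K * (p_x - p_x[0])
    T_b = T_const
    V_b = -K * p_x[-1]
    sol = solve_poroelastic_step(mesh, u_prev, fr, g, dp, dt, T_b, V_b)
    return float(np.sqrt(mesh.lumped_mass() @ (sol.u - u_exact) ** 2 / L)
                 / np.sqrt(mesh.lumped_mass() @ u_exact ** 2 / L))


def check_convergence_orders(fast: bool = True) -> tuple[bool, str]:
    sizes = [16, 32, 64] if fast else [16, 32, 64, 128]
    adr = convergence_order(_adr_manufactured_error, sizes)
    poro = convergence_order(_poro_manufactured_error, sizes)
    ok = (adr["order"] or 0) >= 1.9 and (poro["order"] or 0) >= 1.9
    return ok, (f"ADR order {adr['order']:.2f}, poroelastic order "
                f"{poro['order']:.2f}")


def run_verification(fast: bool = True) -> dict[str, tuple[bool, str]]:
    return {
        "kinetic closure (sum Q = 0)": check_kinetic_closure(),
        "Mohr identity r = |tau_max|/mu": check_mohr_identity(),
        "discrete mass conservation": check_adr_conservation(),
        "discrete maximum principle": check_maximum_principle(),
        "Darcy consistency at steady state": check_darcy_consistency(),
        "Scharfetter-Gummel central limit": check_sg_central_limit(),
        "manufactured-solution orders": check_convergence_orders(fast),
    }
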