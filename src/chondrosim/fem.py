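"""Finite-element discretization on the bar (0, L).

Two solvers operate on a shared uniform P1 mesh:

* a poroelastic saddle-point step — equal-order P1/P1 for displacement and
  pressure, backward Euler in time; stable here because the pressure block
  is Darcy-elliptic rather than a Lagrange multiplier;
* an advection–diffusion–reaction step with Scharfetter–Gummel exponential
  fitting on the element fluxes and lumped (trapezoidal) mass, which makes
  the system matrix an M-matrix and the update positivity-preserving at
  any Péclet number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.linalg import solve_banded

from .constitutive import growth_stress_source, permeability
from .kinetics import CellFractions, GrowthCoefficients
from .parameters import DerivedParameters


class MeshError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class Mesh1D:
    """Uniform partition of [0, L] into N elements."""

    N: int
    nodes: np.ndarray   # shape (N+1,)
    h: np.ndarray       # element sizes, shape (N,)

    @property
    def L(self) -> float:
        return float(self.nodes[-1])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[:-1] + self.nodes[1:])

    def lumped_mass(self) -> np.ndarray:
        """Trapezoidal dual-cell sizes; sums to L."""
        m = np.zeros(self.N + 1)
        m[:-1] += 0.5 * self.h
        m[1:] += 0.5 * self.h
        return m


def build_mesh(L: float, N: int) -> Mesh1D:
    if not L > 0:
        raise MeshError("L must be positive")
    if N < 2:
        raise MeshError("need at least 2 elements")
    nodes = np.linspace(0.0, L, N + 1)
    return Mesh1D(N=N, nodes=nodes, h=np.diff(nodes))


def nodal_to_element(values: np.ndarray) -> np.ndarray:
    """Midpoint (average) value of a P1 field on each element."""
    values = np.asarray(values, dtype=float)
    return 0.5 * (values[:-1] + values[1:])


def element_to_nodal(values: np.ndarray) -> np.ndarray:
    """Average adjacent element values back to nodes (copied at the ends)."""
    values = np.asarray(values, dtype=float)
    out = np.empty(values.size + 1)
    out[0] = values[0]
    out[-1] = values[-1]
    out[1:-1] = 0.5 * (values[:-1] + values[1:])
    return out


def bernoulli(x):
    """Bernoulli edge function B(x) = x / (eˣ − 1), with B(0) = 1.

    Evaluated by a Taylor branch near zero and saturated asymptotics for
    |x| beyond the overflow range; satisfies B(−x) − B(x) = x exactly in
    exact arithmetic.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise SolverError("bernoulli argument must be finite")
    out = np.empty_like(x)
    small = np.abs(x) < 1.0e-8
    # B(x) ~ 1 - x/2 + x^2/12 near the removable singularity
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs * xs / 12.0
    big_pos = x > 700.0
    big_neg = x < -700.0
    mid = ~(small | big_pos | big_neg)
    xm = x[mid]
    out[mid] = xm / np.expm1(xm)
    out[big_pos] = 0.0
    out[big_neg] = -x[big_neg]
    return out if out.ndim else float(out)


@dataclass
class PoroelasticSolution:
    u: np.ndarray    # nodal displacement (cm)
    p: np.ndarray    # nodal pressure (dyne·cm⁻²)
    V: np.ndarray    # elementwise Darcy flux phi_fl * w (cm·s⁻¹)
    v_s: np.ndarray  # nodal solid velocity (u - u_prev)/dt (cm·s⁻¹)


def solve_poroelastic_step(mesh: Mesh1D, u_prev: np.ndarray,
                           fr: CellFractions, g: GrowthCoefficients,
                           dp: DerivedParameters, dt: float,
                           T_b: float, V_b: float) -> PoroelasticSolution:
    """One backward-Euler step of the quasi-static poroelastic system.

    Solves the coupled weak equations: vanishing divergence of the total
    axial stress with traction T_b at x = L, and conservation of mixture
    volume with Darcy flux V_b at x = L, under u(0) = 0, p(0) = 0.

    ``fr`` and ``g`` carry nodal fields; coefficients are sampled at
    element midpoints.
    """
    if dt <= 0:
        raise SolverError("dt must be positive")
    n = mesh.N + 1
    u_prev = np.asarray(u_prev, dtype=float)
    phi_s_e = nodal_to_element(np.asarray(fr.phi_s, dtype=float))
    phi_fl_e = 1.0 - phi_s_e
    K_e = permeability(phi_fl_e, dp)
    ku = dp.H_A * phi_s_e / mesh.h   # elastic element conductances
    kp = K_e / mesh.h                # Darcy element conductances

    # growth stress enters the momentum residual as ∫ S_g v'_i dx = ∓S_g_e
    S_g_e = nodal_to_element(growth_stress_source(fr, g, dp))
    f_u = np.zeros(n)
    f_u[:-1] -= S_g_e
    f_u[1:] += S_g_e
    f_u[-1] += T_b

    # f_p = (∫ φ'_j φ_i) u_prev / dt, with the half-sum structure of P1
    f_p = np.zeros(n)
    f_p[0] = (-0.5 * u_prev[0] + 0.5 * u_prev[1]) / dt
    f_p[-1] = (-0.5 * u_prev[-2] + 0.5 * u_prev[-1]) / dt
    f_p[1:-1] = (0.5 * u_prev[2:] - 0.5 * u_prev[:-2]) / dt
    f_p[-1] -= V_b

    # interleaved unknowns z = [u_0, p_0, u_1, p_1, ...]: bandwidth (3, 3)
    m2 = 2 * n
    ab = np.zeros((7, m2))          # solve_banded layout, ab[3 + i - j, j]
    rhs = np.empty(m2)
    rhs[0::2] = f_u
    rhs[1::2] = f_p

    def put(i, j, val):
        ab[3 + i - j, j] += val

    iu = 2 * np.arange(n)           # momentum rows / u columns
    ip = iu + 1                     # mass rows / p columns

    # momentum rows: A_u u − C p
    diag_u = np.zeros(n)
    diag_u[:-1] += ku
    diag_u[1:] += ku
    put(iu, iu, diag_u)
    put(iu[:-1], iu[1:], -ku)
    put(iu[1:], iu[:-1], -ku)
    # −C: interior diagonal cancels; sub/super are ±1/2
    put(iu[0], ip[0], 0.5)
    put(iu[-1], ip[-1], -0.5)
    put(iu[:-1], ip[1:], 0.5)       # −C[i, i+1] = +1/2
    put(iu[1:], ip[:-1], -0.5)      # −C[i, i−1] = −1/2

    # mass rows: (Cᵀ u)/dt + A_p p
    put(ip[0], iu[0], -0.5 / dt)
    put(ip[-1], iu[-1], 0.5 / dt)
    put(ip[:-1], iu[1:], 0.5 / dt)
    put(ip[1:], iu[:-1], -0.5 / dt)
    diag_p = np.zeros(n)
    diag_p[:-1] += kp
    diag_p[1:] += kp
    put(ip, ip, diag_p)
    put(ip[:-1], ip[1:], -kp)
    put(ip[1:], ip[:-1], -kp)

    # Dirichlet u(0) = 0, p(0) = 0: overwrite rows 0 and 1 with identity
    for row in (0, 1):
        lo = max(0, row - 3)
        hi = min(m2 - 1, row + 3)
        cols = np.arange(lo, hi + 1)
        ab[3 + row - cols, cols] = 0.0
        ab[3, row] = 1.0
        rhs[row] = 0.0

    sol = solve_banded((3, 3), ab, rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("poroelastic solve produced non-finite values")
    u, p = sol[0::2], sol[1::2]
    V = -K_e * np.diff(p) / mesh.h
    v_s = (u - u_prev) / dt
    return PoroelasticSolution(u=u, p=p, V=V, v_s=v_s)


BCKind = Literal["flux_free", "dirichlet_right"]


def solve_adr_step(mesh: Mesh1D, field_prev: np.ndarray, D: np.ndarray,
                   vel: np.ndarray, reaction: np.ndarray, source: np.ndarray,
                   dt: float, bc: BCKind = "flux_free",
                   dirichlet_value: float = 0.0) -> np.ndarray:
    """One backward-Euler Scharfetter–Gummel step of an ADR equation.

    Discretizes ∂φ/∂t + ∂(vel·φ − D·∂φ/∂x)/∂x + reaction·φ = source with
    exponential-fitting element fluxes
    J_e = (D/h)·[B(−Pe)·φ_left − B(Pe)·φ_right], Pe = vel·h/D,
    lumped mass, and two boundary treatments: "flux_free" ends impose a
    vanishing diffusive flux — material may still leave with the advective
    field (upwind outflow; an inflowing velocity carries nothing in) —
    while "dirichlet_right" pins the value at x = L strongly and leaves
    the left end flux-free.  When vel = 0 a flux-free end is exactly
    conservative.  With nonnegative data and reaction the matrix is an
    M-matrix and the output is nonnegative.
    """
    if dt <= 0:
        raise SolverError("dt must be positive")
    D = np.broadcast_to(np.asarray(D, dtype=float), (mesh.N,)).copy()
    if np.any(D <= 0):
        raise SolverError("diffusivity must be positive on every element")
    vel = np.broadcast_to(np.asarray(vel, dtype=float), (mesh.N,))
    reaction = np.broadcast_to(np.asarray(reaction, dtype=float), (mesh.N + 1,))
    source = np.broadcast_to(np.asarray(source, dtype=float), (mesh.N + 1,))
    field_prev = np.asarray(field_prev, dtype=float)

    Pe = vel * mesh.h / D
    w = D / mesh.h
    b_minus = w * bernoulli(-Pe)   # multiplies the left node of each face
    b_plus = w * bernoulli(Pe)     # multiplies the right node

    m = mesh.lumped_mass()
    n = mesh.N + 1
    lower = np.zeros(n)  # sub-diagonal entries, lower[i] couples node i to i-1
    main = m / dt + m * reaction
    upper = np.zeros(n)
    # face e sits between nodes e and e+1; J_e enters node e with +, node e+1 with −
    main[:-1] += b_minus
    upper[:-1] += -b_plus           # row e, col e+1
    main[1:] += b_plus
    lower[1:] += -b_minus           # row e+1, col e

    rhs = m * (field_prev / dt + source)

    # advective passage through flux-free ends: outflow is upwinded on the
    # boundary node, inflow carries zero external concentration
    v_left = vel[0]
    if v_left < 0.0:          # pointing out of the domain at x = 0
        main[0] += -v_left
    v_right = vel[-1]
    if bc == "flux_free" and v_right > 0.0:   # outflow at x = L
        main[-1] += v_right

    if bc == "dirichlet_right":
        main[-1] = 1.0
        lower[-1] = 0.0
        rhs[-1] = dirichlet_value
    elif bc != "flux_free":
        raise SolverError(f"unknown boundary condition {bc!r}")

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = main
    ab[2, :-1] = lower[1:]
    out = solve_banded((1, 1), ab, rhs)
    if not np.all(np.isfinite(out)):
        raise SolverError("ADR solve produced non-finite values")
    return out


def convergence_order(solve_on_mesh: Callable[[int], float],
                      mesh_sizes: list[int]) -> dict:
    """Observed order of accuracy from a sequence of refinements.

    ``solve_on_mesh(N)`` must return the discrete error norm on an
    N-element mesh.  Returns the least-squares slope of log(error) against
    log(h); errors at rounding level are flagged "exact" instead.
    """
    if len(mesh_sizes) < 3:
        raise SolverError("need at least 3 mesh sizes")
    errors = np.array([solve_on_mesh(int(N)) for N in mesh_sizes], dtype=float)
    hs = 1.0 / np.asarray(mesh_sizes, dtype=float)
    if np.all(errors < 1e-12):
        return {"order": None, "errors": errors, "exact": True}
    slope = np.polyfit(np.log(hs), np.log(np.maximum(errors, 1e-300)), 1)[0]
    return {"order": float(slope), "errors": errors, "exact": False}
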