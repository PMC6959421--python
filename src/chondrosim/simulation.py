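"""Outer time loop and the nonlinear block Gauss–Seidel fixed point.

Each backward-Euler step is linearized by sweeping three blocks in
sequence — poroelasticity, oxygen transport, population transport — and
feeding every block's output straight into the next until the full state
stops changing.  Scenario presets cover the static and perfused bioreactor
cultures with low/high growth rate, saturated/threshold external oxygen
and the two seeding densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constitutive import effective_diffusion, stress_decomposition
from .fem import (Mesh1D, build_mesh, element_to_nodal, nodal_to_element,
                  solve_adr_step, solve_poroelastic_step)
from .kinetics import (CellFractions, GrowthCoefficients,
                       ecm_synthesis_rate, heaviside_gate, monod_factor,
                       population_production)
from .parameters import ModelParameters, ParameterError, derived_parameters

logger = logging.getLogger(__name__)

DAY = 86400.0

#: seeding amplitudes of the two initial-condition presets
IC_PRESETS = {
    "IC1": {"A_n": 0.005, "A_v": 0.001, "A_q": 0.001, "A_ECM": 0.001},
    "IC2": {"A_n": 0.05, "A_v": 0.01, "A_q": 0.01, "A_ECM": 0.01},
}


@dataclass
class ScenarioConfig:
    """Fully resolved description of one simulation run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    N: int = 100                      # mesh elements
    dt: float = 600.0                 # time step (s)
    T_end: float = 30 * DAY           # culture horizon (s)
    A_n: float = 0.005                # seeding amplitudes at the scaffold wall
    A_v: float = 0.001
    A_q: float = 0.001
    A_ECM: float = 0.001
    T_b: float = 0.0                  # boundary traction at x = L (dyne·cm⁻²)
    V_b: float = 0.0                  # boundary Darcy flux at x = L (cm·s⁻¹)
    c_ext: float = 6.4e-6             # external oxygen at x = L (g·cm⁻³)
    fixed_point_tol: float = 1.0e-8   # relative sup-norm stopping test
    max_inner_iters: int = 50
    sample_every: int = 6             # record every this many steps
    abort_on_nonconvergence: bool = False
    name: str = "custom"

    @property
    def L_d(self) -> float:
        """Decay length of the exponential seeding profile (L/5)."""
        return self.params.L / 5.0

    @property
    def n_steps(self) -> int:
        return int(round(self.T_end / self.dt))

    def validate(self) -> None:
        if self.dt <= 0 or self.T_end < self.dt:
            raise ParameterError("require dt > 0 and T_end >= dt")
        amps = (self.A_n, self.A_v, self.A_q, self.A_ECM)
        if any(a < 0 for a in amps):
            raise ParameterError("seeding amplitudes must be nonnegative")
        if sum(amps) >= 1.0:
            raise ParameterError("seeding amplitudes must sum below 1")
        if self.c_ext < 0:
            raise ParameterError("c_ext must be nonnegative")
        if self.N < 2:
            raise ParameterError("need at least 2 mesh elements")


def scenario_presets() -> dict[str, ScenarioConfig]:
    """The 16 named scenario combinations: {static, perfused} × {IC1, IC2}
    × {kg1, kg2} × {csat, cthr}."""
    base = ModelParameters()
    out: dict[str, ScenarioConfig] = {}
    for mech in ("static", "perfused"):
        for ic in ("IC1", "IC2"):
            for kg_name, kg in (("kg1", ModelParameters.K_G_LOW),
                                ("kg2", ModelParameters.K_G_HIGH)):
                for c_name in ("csat", "cthr"):
                    name = f"{mech}-{ic}-{kg_name}-{c_name}"
                    params = base.with_updates(k_g=kg)
                    # V(L)·n = -V_b: the perfusion inlet at the fluid
                    # interface drives fluid INTO the construct (this is
                    # what lets the flow deliver oxygen; the fluid leaves
                    # through the p = 0 face at the scaffold wall)
                    out[name] = ScenarioConfig(
                        params=params,
                        T_b=params.T_b if mech == "perfused" else 0.0,
                        V_b=-params.V_b if mech == "perfused" else 0.0,
                        c_ext=params.c_sat if c_name == "csat" else params.c_thr,
                        name=name,
                        **IC_PRESETS[ic],
                    )
    return out


@dataclass
class SimulationState:
    """All nodal fields at one time level."""

    time: float
    mesh: Mesh1D
    u: np.ndarray
    p: np.ndarray
    c: np.ndarray
    phi_n: np.ndarray
    phi_v: np.ndarray
    phi_q: np.ndarray
    phi_ECM: np.ndarray
    g_n: np.ndarray
    g_v: np.ndarray
    g_q: np.ndarray
    g_ECM: np.ndarray
    r: np.ndarray
    xi: np.ndarray

    @property
    def fractions(self) -> CellFractions:
        return CellFractions(self.phi_n, self.phi_v, self.phi_q, self.phi_ECM)

    @property
    def growth(self) -> GrowthCoefficients:
        return GrowthCoefficients(self.g_n, self.g_v, self.g_q, self.g_ECM)

    @property
    def phi_fl(self) -> np.ndarray:
        return 1.0 - (self.phi_n + self.phi_v + self.phi_q + self.phi_ECM)

    def copy(self) -> "SimulationState":
        arrays = {k: getattr(self, k).copy()
                  for k in ("u", "p", "c", "phi_n", "phi_v", "phi_q",
                            "phi_ECM", "g_n", "g_v", "g_q", "g_ECM",
                            "r", "xi")}
        return SimulationState(time=self.time, mesh=self.mesh, **arrays)

    def pack(self) -> np.ndarray:
        """Concatenated primary unknowns (u, p, φ's, c) for convergence tests."""
        return np.concatenate([self.u, self.p, self.phi_n, self.phi_v,
                               self.phi_q, self.phi_ECM, self.c])


def strain_at_nodes(mesh: Mesh1D, u: np.ndarray) -> np.ndarray:
    """Nodal ∂u/∂x from element gradients (end values copied)."""
    return element_to_nodal(np.diff(u) / mesh.h)


def make_initial_state(cfg: ScenarioConfig) -> SimulationState:
    """Exponential seeding profiles, uniform initial oxygen, relaxed solid."""
    cfg.validate()
    mesh = build_mesh(cfg.params.L, cfg.N)
    x = mesh.nodes
    prof = np.exp(-x / cfg.L_d)
    zeros = np.zeros_like(x)
    state = SimulationState(
        time=0.0, mesh=mesh,
        u=zeros.copy(), p=zeros.copy(),
        c=np.full_like(x, cfg.params.c0),
        phi_n=cfg.A_n * prof, phi_v=cfg.A_v * prof,
        phi_q=cfg.A_q * prof, phi_ECM=cfg.A_ECM * prof,
        g_n=zeros.copy(), g_v=zeros.copy(), g_q=zeros.copy(),
        g_ECM=zeros.copy(),
        r=zeros.copy(), xi=np.ones_like(x),
    )
    return postprocess_state(state, cfg.params)


def postprocess_state(state: SimulationState,
                      p: ModelParameters) -> SimulationState:
    """Clamp rounding-level negatives, refresh r and xi from the stress."""
    for name in ("phi_n", "phi_v", "phi_q", "phi_ECM", "c"):
        f = getattr(state, name)
        if np.any(f > 1.0 + 1e-8) and name != "c":
            raise ParameterError(f"{name} exceeds 1")
        f[(f < 0) & (f > -1e-14)] = 0.0
    u_x = strain_at_nodes(state.mesh, state.u)
    ss = stress_decomposition(u_x, state.p, state.fractions, state.growth,
                              p)
    state.r = np.asarray(ss.r, dtype=float)
    state.xi = np.asarray(ss.xi, dtype=float)
    return state


def _field_list(state: SimulationState) -> list[np.ndarray]:
    return [state.u.copy(), state.p.copy(), state.phi_n.copy(),
            state.phi_v.copy(), state.phi_q.copy(), state.phi_ECM.copy(),
            state.c.copy()]


#: absolute floors (CGS) under which a field counts as numerically zero;
#: they stop solver rounding noise on physically-zero fields (e.g. the
#: pressure of a static culture) from stalling the inner loop
_FIELD_FLOORS = (1e-12,   # u (cm)
                 1e-8,    # p (dyne·cm⁻²)
                 1e-12, 1e-12, 1e-12, 1e-12,   # volume fractions
                 1e-12)   # c (g·cm⁻³)


def _relative_change(new: list[np.ndarray], old: list[np.ndarray]) -> float:
    """Sup-norm change per field, relative to that field's own magnitude."""
    worst = 0.0
    for a, b, floor in zip(new, old, _FIELD_FLOORS):
        norm = max(float(np.max(np.abs(a))), floor)
        worst = max(worst, float(np.max(np.abs(a - b))) / norm)
    return worst


def _population_sweep(mesh: Mesh1D, prev: SimulationState, fr: CellFractions,
                      c: np.ndarray, H_r: np.ndarray, H_c: np.ndarray,
                      vel_e: np.ndarray, dt: float,
                      p: ModelParameters) -> CellFractions:
    """Gauss–Seidel update of the four solid fractions.

    Each pool solves a scalar ADR equation whose diagonal (removal) terms
    sit in the reaction coefficient and whose incoming transitions, taken
    at the newest available iterate, form the source; this keeps every
    source nonnegative so the positivity of the flux scheme applies.
    """
    mono = monod_factor(c, p.K_sat)
    qui = p.k_qui * (1.0 - H_c)
    D = p.D_eta if p.D_eta > 0 else 1e-30  # strictly positive for the solver
    common = dict(mesh=mesh, D=D, vel=vel_e, dt=dt, bc="flux_free")

    phi_fl = fr.phi_fl
    phi_n = solve_adr_step(
        field_prev=prev.phi_n,
        reaction=1.0 / p.tau_m + qui - phi_fl * mono * p.k_g,
        source=fr.phi_q * p.beta_qn * H_r,
        **common)
    phi_v = solve_adr_step(
        field_prev=prev.phi_v,
        reaction=p.beta_vq * (1.0 - H_r) + qui + p.k_apo,
        source=fr.phi_q * p.beta_qv * H_r,
        **common)
    phi_q = solve_adr_step(
        field_prev=prev.phi_q,
        reaction=(p.beta_qn + p.beta_qv) * H_r + qui + p.k_apo,
        source=phi_n / p.tau_m + phi_v * p.beta_vq * (1.0 - H_r),
        **common)
    phi_ECM = solve_adr_step(
        field_prev=prev.phi_ECM,
        reaction=np.full(mesh.N + 1, p.k_deg),
        source=ecm_synthesis_rate(phi_v, fr.phi_ECM, c, p),
        **common)
    return CellFractions(phi_n, phi_v, phi_q, phi_ECM)


def fixed_point_iteration(state_k: SimulationState, cfg: ScenarioConfig
                          ) -> tuple[SimulationState, int, bool]:
    """Advance one time step by the block Gauss–Seidel fixed point.

    Starting from the converged state at level k, each sweep solves the
    poroelastic block, then the oxygen block, then the population block
    with stress/oxygen gates from the current iterate, then refreshes the
    growth strains and the fluid fraction.  If a node's stress gate starts
    oscillating between sweeps it is frozen at its first-sweep value so
    the inner loop terminates.
    """
    p = cfg.params
    dp = derived_parameters(p)
    mesh = state_k.mesh
    dt = cfg.dt
    cur = state_k.copy()
    U_old = _field_list(cur)

    H_r_first = None
    H_r_prev = None
    flips = None
    converged = False
    iters = 0

    for m in range(cfg.max_inner_iters):
        iters = m + 1
        fr = cur.fractions
        # --- block 1: poroelasticity -------------------------------------
        poro = solve_poroelastic_step(mesh, state_k.u, fr, cur.growth, dp,
                                      dt, cfg.T_b, cfg.V_b)
        u, pres = poro.u, poro.p
        v_s_e = nodal_to_element(poro.v_s)

        # --- block 2: oxygen transport -----------------------------------
        phi_fl = np.clip(fr.phi_fl, 1e-6, 1.0)
        phi_fl_e = nodal_to_element(phi_fl)
        w_e = poro.V / phi_fl_e
        vel_c = w_e + v_s_e
        D_c_e = effective_diffusion(phi_fl_e, p)
        demand = (p.R_n * fr.phi_n + p.R_v * fr.phi_v + p.R_q * fr.phi_q)
        c = solve_adr_step(mesh, state_k.c, D_c_e, vel_c,
                           reaction=demand / (cur.c + p.K_half),
                           source=np.zeros(mesh.N + 1), dt=dt,
                           bc="dirichlet_right", dirichlet_value=cfg.c_ext)

        # --- gates from the current iterate ------------------------------
        u_x = strain_at_nodes(mesh, u)
        ss = stress_decomposition(u_x, pres, fr, cur.growth, p)
        H_r = heaviside_gate(np.asarray(ss.r) - dp.r_bar)
        H_c = heaviside_gate(c - p.c_thr)
        if H_r_first is None:
            H_r_first = H_r.copy()
            flips = np.zeros_like(H_r, dtype=int)
        else:
            flips += (H_r != H_r_prev).astype(int)
            H_r = np.where(flips >= 2, H_r_first, H_r)
        H_r_prev = H_r.copy()

        # --- block 3: populations, growth strains, fluid closure ---------
        fr_new = _population_sweep(mesh, state_k, fr, c, H_r, H_c,
                                   v_s_e, dt, p)
        Q = population_production(fr_new, c, H_r, H_c, p)
        g_new = GrowthCoefficients(
            g_n=state_k.g_n + dt * Q.Q_n,
            g_v=state_k.g_v + dt * Q.Q_v / 3.0,
            g_q=state_k.g_q + dt * Q.Q_q / 3.0,
            g_ECM=state_k.g_ECM + dt * Q.Q_ECM / 3.0,
        )

        cur.u, cur.p, cur.c = u, pres, c
        cur.phi_n, cur.phi_v = fr_new.phi_n, fr_new.phi_v
        cur.phi_q, cur.phi_ECM = fr_new.phi_q, fr_new.phi_ECM
        cur.g_n, cur.g_v = g_new.g_n, g_new.g_v
        cur.g_q, cur.g_ECM = g_new.g_q, g_new.g_ECM

        U_new = _field_list(cur)
        resid = _relative_change(U_new, U_old)
        logger.debug("t=%.0f sweep %d residual %.3e", state_k.time, iters, resid)
        U_old = U_new
        if resid < cfg.fixed_point_tol:
            converged = True
            break

    if not converged:
        msg = f"fixed point not converged at t={state_k.time:.0f}s after {iters} sweeps"
        if cfg.abort_on_nonconvergence:
            raise RuntimeError(msg)
        logger.warning(msg)

    cur.time = state_k.time + dt
    return postprocess_state(cur, p), iters, converged


@dataclass
class TimeSeriesRecord:
    """Midpoint time series plus optional x–t grids for c and xi."""

    times: np.ndarray                 # sample times (s)
    midpoint: dict[str, np.ndarray]   # field name -> series at x = L/2
    x: np.ndarray                     # node coordinates
    c_grid: np.ndarray | None         # (n_samples, n_nodes)
    xi_grid: np.ndarray | None
    sweeps: np.ndarray                # inner iterations per recorded step
    all_converged: bool
    config: ScenarioConfig

    @property
    def days(self) -> np.ndarray:
        return self.times / DAY

    def series(self, name: str) -> np.ndarray:
        return self.midpoint[name]


_MIDPOINT_FIELDS = ("phi_n", "phi_v", "phi_q", "phi_ECM", "phi_fl",
                    "c", "u", "p", "r", "xi")


def _sample(state: SimulationState) -> dict[str, float]:
    i = state.mesh.N // 2
    vals = {}
    for name in _MIDPOINT_FIELDS:
        f = state.phi_fl if name == "phi_fl" else getattr(state, name)
        vals[name] = float(f[i])
    return vals


def run_simulation(cfg: ScenarioConfig, store_grids: bool = True,
                   callback=None) -> TimeSeriesRecord:
    """Advance the scenario from 0 to T_end, sampling the midpoint fields.

    ``callback(step, state)``, if given, is invoked after every accepted
    step (used for custom probes and for progress reporting).
    """
    cfg.validate()
    state = make_initial_state(cfg)
    times = [0.0]
    rows = [_sample(state)]
    c_grids = [state.c.copy()] if store_grids else None
    xi_grids = [state.xi.copy()] if store_grids else None
    sweeps = [0]
    all_conv = True

    for k in range(cfg.n_steps):
        state, iters, conv = fixed_point_iteration(state, cfg)
        all_conv &= conv
        if callback is not None:
            callback(k, state)
        if (k + 1) % cfg.sample_every == 0 or k + 1 == cfg.n_steps:
            times.append(state.time)
            rows.append(_sample(state))
            sweeps.append(iters)
            if store_grids:
                c_grids.append(state.c.copy())
                xi_grids.append(state.xi.copy())

    midpoint = {name: np.array([r[name] for r in rows])
                for name in _MIDPOINT_FIELDS}
    return TimeSeriesRecord(
        times=np.array(times), midpoint=midpoint, x=state.mesh.nodes.copy(),
        c_grid=np.array(c_grids) if store_grids else None,
        xi_grid=np.array(xi_grids) if store_grids else None,
        sweeps=np.array(sweeps), all_converged=all_conv, config=cfg,
    )


def extinction_time_days(rec: TimeSeriesRecord, fraction: float = 0.01
                         ) -> float | None:
    """First sample time (days) at which both phi_n and phi_v at the bar
    midpoint have fallen below ``fraction`` of their initial values."""
    n0 = rec.midpoint["phi_n"][0]
    v0 = rec.midpoint["phi_v"][0]
    below = (rec.midpoint["phi_n"] < fraction * n0) & \
            (rec.midpoint["phi_v"] < fraction * v0)
    idx = np.nonzero(below)[0]
    return float(rec.days[idx[0]]) if idx.size else None
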