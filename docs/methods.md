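# Methods

## Model

The construct is modeled as a fully saturated biphasic mixture on a fixed
1D domain (0, L): the spatial domain does not grow, the amount of each
species at a point does. The solid phase collects three chondrocyte pools
(proliferating n, ECM-secreting v, quiescent q) and extracellular matrix;
the fluid fraction is eliminated through the saturation condition and
recovered by post-processing, φ_fl = 1 − Σφ_η. All species share the
density of water (intrinsic incompressibility) and the mixture is closed:
the fluid production term is defined as minus the sum of the solid ones,
so total mass is conserved identically — dying cells and degraded matrix
become fluid, growth consumes it.

Kinematics are infinitesimal. Growth enters through the strain
decomposition ε = ε_elastic + ε_growth: each pool carries a scalar growth
coefficient g integrating its net production rate, deposited isotropically
(factor 1/3 per direction) for the v, q and ECM species and uniaxially
along the polarization axis for proliferating cells. In 1D the
polarization direction is fixed to the bar axis; the eigenvector dynamics
of the general 3D picture is out of scope here.

### Mechanotransduction gate

The total stress splits into an isotropic part and a deviatoric part
proportional to φ_s u_x − g_n φ_n. Its normalized magnitude
r = |φ_s u_x − g_n φ_n| equals |τ_max|/μ, the Mohr-circle radius over the
shear modulus — an identity the test suite asserts on randomized states.
The binary flag ξ = 1 marks the isotropic regime r ≤ r̄, with
r̄ = (10 mPa)/μ taken from the level of hydrodynamic shear known to
modulate chondrocyte metabolism.

The gate orientation on the v↔q exchange deserves a note, because the
design space is genuinely open and the two orientations produce opposite
long-time behavior. We gate the exchanges so that *mechanical stimulation
activates quiescent cells*: under anisotropic stress (H_r = 1, e.g. under
perfusion loading) quiescent cells are recruited into both active pools
(q→n and q→v), while in a mechanically quiet isotropic environment
secreting cells drift back to quiescence (v→q). This orientation is the
one that reproduces the experimentally anchored regime picture this class
of models targets: static low-growth cultures exhaust their active pools
in about ten days; static high-growth cultures plateau; perfused cultures
sustain cellularity and ECM production precisely because the flow-induced
stress keeps recruiting cells — the documented chondrogenic effect of
perfusion. The opposite orientation (isotropy feeding the secreting pool)
makes the secreting fraction immortal in static culture, kills ECM
production under perfusion, and is incompatible with all of the above, so
we rejected it. The q→n channel is always anisotropy-gated, and low
oxygen (c < c_thr) adds a quiescence drain k_qui to all three pools.

The Heaviside gates are right-continuous (H(z) = 1 for z ≥ 0): the
threshold state counts as isotropic for ξ and as active for the
oxygen gate.

### Boundary conditions and the perfusion sign

The scaffold wall x = 0 is mechanically fixed (u = 0) with zero pressure;
the fluid interface x = L carries the applied traction T_b and Darcy flux
V_b. For the transported species the "flux-free" conditions are zero
*diffusive* flux: material still passes with the advective field, which we
impose as an upwinded outflow on the boundary node (an inflowing velocity
carries zero external concentration, which keeps the matrix an M-matrix).
With zero velocity this is exactly conservative.

In the perfused presets the inlet at the fluid interface drives fluid
*into* the construct, V(L)·n = −|V_b|, with the flow leaving through the
zero-pressure wall face. This is the orientation under which perfusion
delivers oxygen — the concentration field equilibrates at the external
value throughout the bar — and it is the only one that reproduces the
sustained perfused cultures; an outflow orientation instead advects
oxygen out of the construct and starves it, which contradicts the
intended physics of a perfusion bioreactor.

## Parameters

All computation is CGS (cm, g, s; stresses in dyne·cm⁻² = 0.1 Pa, so
10 mPa = 0.1 dyne·cm⁻²). Key defaults:

| symbol | meaning | default | units |
|---|---|---|---|
| c0, c_sat, c_thr | initial / saturation / threshold O₂ | 5e-6, 6.4e-6, 1.6e-6 | g·cm⁻³ |
| K_eq, D_c_s, D_c_fl | Maxwell diffusivity inputs | 0.1, 0.75e-5, 1e-5 | —, cm²·s⁻¹ |
| R_n = R_v, R_q, K_half | O₂ uptake rates, half-saturation | 3.9e-8, 1e-8, 3.2e-6 | g·cm⁻³·s⁻¹, g·cm⁻³ |
| k_g | max specific growth rate | 1e-7 (low) / 1e-5 (high) | s⁻¹ |
| K_sat | Monod constant | 1.927e-6 | g·cm⁻³ |
| τ_m | mitotic hand-off time | 1.728e5 | s |
| β (all three) | q↔n, q↔v transition rates | 1e-5 | s⁻¹ |
| k_apo, k_qui, k_deg | apoptosis, quiescence, ECM decay | 3.858e-7, 3.858e-7, 7.7e-7 | s⁻¹ |
| E, k_GAG, φ_ECM,max | ECM synthesis law | 20, 8.61e-11, 0.1 | —, cm⁶(cell·s·g)⁻¹, — |
| λ, μ | Lamé parameters of the solid | 5.1937e3, 1.8248e3 | dyne·cm⁻² |
| R_cell, μ_fl | cell radius, fluid viscosity | 5e-4, 1.002e-2 | cm, g·cm⁻¹·s⁻¹ |
| D_η | cell/ECM motility diffusivity | 1e-9 (0 allowed) | cm²·s⁻¹ |
| T_b, V_b (perfused) | interface traction, inlet speed | 1.0, 5e-3 | dyne·cm⁻², cm·s⁻¹ |

Derived: H_A = λ+2μ ≈ 8.84e3, H_B = 3λ+2μ ≈ 1.92e4 dyne·cm⁻²,
K_ref = ⅔R²/μ_fl ≈ 1.66e-5 cm³·s·g⁻¹, V_cell = 4πR³/3 ≈ 5.236e-10 cm³,
r̄ ≈ 5.48e-5. The single tabulated transition rate is exposed as three
independently configurable β's defaulting to the common value. An
apoptosis oxygen threshold c_apo is carried in the parameter set for
completeness but enters no equation. The Lamé values are stress-valued
(dyne·cm⁻²), the only dimensionally consistent reading of the
constitutive law.

The bar length is nowhere pinned by the physics we target; the default
L = 0.01 cm is the scale of a scaffold pore, and the acceptance-level
extinction result is insensitive to it because the midpoint kinetics are
local (oxygen is never limiting in the static scenarios at this scale).
The time step dt = 600 s resolves the fastest kinetic time (τ_m ≈ 2 days)
by ~300×; sampling is hourly. The initial displacement is zero
(unstressed reference, consistent with zero initial growth strains).

## Scenarios (what the generator emulates)

`scenario_presets()` builds the 2×2×2×2 matrix
{static, perfused} × {IC1, IC2} × {kg1, kg2} × {csat, cthr}. Seeding
profiles are exponential, φ_η(x,0) = A_η exp(−x/L_d) with L_d = L/5,
emulating cells colonizing from the scaffold wall: IC1 = (0.005, 0.001,
0.001, 0.001) for (n, v, q, ECM), IC2 ten times denser. Static cultures
apply T_b = V_b = 0; perfused ones 100 mPa and 50 μm/s. External oxygen
is held at either the saturation or the threshold value.

What the scenarios do *not* emulate: real scaffold geometry (a single 1D
pore stands in for a 3D network), nutrient species other than oxygen,
viscoelasticity, separate proteoglycan/collagen phases, and discrete-cell
effects at seeding (the continuum treatment starts from a pre-paved cell
layer). Passing tests therefore demonstrate internal consistency and the
qualitative regime structure, not quantitative agreement with any
particular bioreactor.

## Numerics

Backward Euler in time; each step is solved by a nonlinear block
Gauss–Seidel fixed point sweeping (1) the poroelastic block, (2) the
oxygen block, (3) the population block, each consuming the newest
iterates of the others.

* **Poroelastic step**: equal-order P1/P1 elements for (u, p) on the
  shared uniform mesh. No inf-sup stabilization is needed because after
  time discretization the pressure solves a Darcy-elliptic problem rather
  than acting as a Lagrange multiplier. Assembled as a bandwidth-3
  interleaved banded system; coefficients (H_A φ_s, K(φ_fl)) are sampled
  at element midpoints from nodal averages. The Darcy flux is recovered
  elementwise as −K ∂p/∂x and the solid velocity as (u−u_prev)/dt.
* **Transport steps**: finite-volume form of P1 with lumped (trapezoidal)
  mass and Scharfetter–Gummel exponential-fitting fluxes
  J = (D/h)[B(−Pe)φ_L − B(Pe)φ_R], B(x) = x/(eˣ−1) evaluated with a
  Taylor branch near 0 and saturated asymptotics beyond |x| = 700. Lumping
  plus the Bernoulli weights make the system matrix an M-matrix, which is
  what guarantees nonnegative fractions and the discrete maximum
  principle for oxygen at any Péclet number; the flux reduces to central
  differencing as Pe → 0, so no accuracy is lost in diffusion-dominated
  regimes (both solvers measure order ≈ 2 on manufactured solutions).
* **Population coupling**: the four fractions are updated sequentially;
  removal terms sit on the diagonal (reaction), incoming transitions use
  the newest iterate as a nonnegative source. The converged fixed point
  therefore satisfies the fully coupled backward-Euler system, which is
  how the uniform-culture run reproduces an independently coded implicit
  ODE solve to <1e-3 over 30 days. The only negative diagonal entry is
  the contact-inhibited growth term; at k_g dt ≤ 6e-3 it cannot threaten
  the M-matrix structure.
* **Gates**: H_r and H_c are evaluated from the current iterate (lagged
  gating keeps every inner block linear). If a node's stress gate starts
  flip-flopping between sweeps it is frozen at its first-sweep value for
  the remainder of the step, guaranteeing inner-loop termination near the
  gating threshold.
* **Convergence test**: per-field relative sup-norm of the sweep update,
  default tolerance 1e-8, at most 50 sweeps (2–4 typical). Each field is
  measured against its own magnitude with a tiny unit-aware floor
  (1e-12 cm for u, 1e-8 dyne·cm⁻² for p, 1e-12 for fractions and
  concentration) so that solver rounding noise on physically zero fields
  — the pressure of a static culture is ~1e-13 — cannot stall the loop.
* **Degenerate inputs**: φ_fl is clamped to [1e-6, 1−1e-6] inside the
  permeability; fractions more negative than −1e-14 are an error while
  rounding-level negatives are clamped to zero; D_η = 0 falls back to a
  vanishing diffusivity so the advective structure is preserved.

## Verification surface

The suite checks, among others: exact kinetic closure ΣQ = 0; the Mohr
identity behind r; conservation of the lumped species integrals under
closed kinetics; positivity and the oxygen maximum principle along full
runs; Darcy consistency (V ≡ V_b, linear pressure) at steady state
against the closed form to 1e-10; the Pe = 20 boundary layer against the
exponential profile; second-order convergence of both solvers; agreement
of the uniform culture with an independent stiff/implicit ODE oracle; and
first-order temporal self-convergence. Problem sizes in the tests
(N = 8–100, dt = 600–7200 s, horizons of 1–30 days) were chosen as the
smallest that exercise each property cleanly.

## Known limitations

* The fixed point is first-order accurate in time; stiff transients at
  gate switches are resolved only to O(dt).
* Near the gating threshold the dynamics are genuinely discontinuous;
  the per-step gate freeze makes the inner loop terminate but the
  computed switching times inherit an O(dt) uncertainty. A smoothed
  (logistic) gate would regularize this; we keep the binary gate because
  the regime structure, not the switching instant, is the target.
* Strains in the high-growth scenarios reach a few percent by day 30,
  stretching the infinitesimal-strain assumption.
* The 1D uniaxial reduction cannot represent polarization reorientation
  or genuinely multiaxial stress states.
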