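"""Physical and kinetic parameters of the cartilage-growth mixture model.

All quantities are expressed in CGS units (cm, g, s, dyne·cm⁻²).  The
defaults are the values used for the bioreactor simulation scenarios;
stresses quoted in the tissue-engineering literature in mPa convert as
1 mPa = 0.01 dyne·cm⁻².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace, asdict


class ParameterError(ValueError):
    """Raised when a parameter set violates a physical constraint."""


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the poroelastic mixture model.

    Concentrations are in g·cm⁻³, rates in s⁻¹, diffusivities in cm²·s⁻¹,
    moduli in dyne·cm⁻², lengths in cm.
    """

    # oxygen
    c0: float = 5.0e-6            # initial O2 concentration
    c_sat: float = 6.4e-6         # O2 saturation concentration
    c_thr: float = 1.6e-6         # O2 threshold concentration (quiescence gate)
    c_apo: float = 3.2e-7         # O2 apoptosis concentration (tabulated, unused)
    K_eq: float = 0.1             # solid/fluid local mass-equilibrium coefficient
    D_c_s: float = 0.75e-5        # O2 diffusivity in the solid phase
    D_c_fl: float = 1.0e-5        # O2 diffusivity in the fluid phase
    # perfusion boundary data (defaults are the perfused-bioreactor values)
    V_b: float = 50.0e-4          # inlet velocity of perfusion fluid (cm·s⁻¹)
    T_b: float = 1.0              # stress due to perfusion fluid (100 mPa in CGS)
    mu_fl: float = 1.002e-2       # fluid dynamic viscosity at 20 °C (g·cm⁻¹·s⁻¹)
    # oxygen consumption
    R_n: float = 3.9e-8           # consumption rate of proliferating cells
    R_v: float = 3.9e-8           # consumption rate of ECM-secreting cells
    R_q: float = 1.0e-8           # consumption rate of quiescent cells
    K_half: float = 3.2e-6        # Michaelis-Menten half-saturation constant
    # population exchange
    beta_qn: float = 1.0e-5       # quiescent -> proliferating transition rate
    beta_qv: float = 1.0e-5       # quiescent -> secreting transition rate
    beta_vq: float = 1.0e-5       # secreting -> quiescent transition rate
    k_apo: float = 3.858e-7       # apoptosis rate
    k_qui: float = 3.858e-7       # quiescence rate (active below c_thr)
    k_deg: float = 7.7e-7         # ECM degradation rate
    k_g: float = 1.0e-7           # maximum specific cell growth rate (default: low regime)
    E: float = 20.0               # ECM expansion coefficient (dimensionless)
    k_GAG: float = 8.61e-11       # GAG synthesis rate, cm⁶·(cell·s·g)⁻¹
    K_sat: float = 1.927e-6       # Monod saturation constant
    D_eta: float = 1.0e-9         # cell/ECM diffusivity
    # mechanics
    lam: float = 5.1937e3         # Lamé first parameter of cells and ECM
    mu: float = 1.8248e3          # Lamé shear modulus of cells and ECM
    phi_ECM_max: float = 0.1      # maximum ECM volume fraction
    R_cell: float = 5.0e-4        # cell radius
    tau_m: float = 1.728e5        # mitotic characteristic time (s)
    L: float = 0.01               # bar length (cm)
    shear_threshold: float = 0.1  # shear stress gating ECM secretion (10 mPa in CGS)

    # reference growth rates of the two simulated regimes
    K_G_LOW = 1.0e-7
    K_G_HIGH = 1.0e-5
    K_G_REF = 5.8e-6

    def __post_init__(self) -> None:
        positive = (
            "c0", "c_sat", "c_thr", "c_apo", "K_eq", "D_c_s", "D_c_fl",
            "mu_fl", "R_n", "R_v", "R_q", "K_half", "beta_qn", "beta_qv",
            "beta_vq", "k_apo", "k_qui", "k_deg", "k_g", "E", "k_GAG",
            "K_sat", "lam", "mu", "R_cell", "tau_m", "L", "shear_threshold",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.D_eta < 0:
            raise ParameterError("D_eta must be nonnegative")
        if not 0 < self.phi_ECM_max < 1:
            raise ParameterError("phi_ECM_max must lie in (0, 1)")
        if not self.c_apo < self.c_thr < self.c_sat:
            raise ParameterError("oxygen levels must satisfy c_apo < c_thr < c_sat")

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class DerivedParameters:
    """Closed-form constants derived from :class:`ModelParameters`."""

    H_A: float       # aggregate modulus, lam + 2 mu
    H_B: float       # bulk-like modulus, 3 lam + 2 mu
    K_ref: float     # reference permeability, (2/3) R_cell^2 / mu_fl
    V_cell: float    # single-cell volume, (4/3) pi R_cell^3
    r_bar: float     # dimensionless isotropy threshold, shear_threshold / mu
    C_F_cell: float  # Stokes-drag friction prefactor, (3/2) mu_fl / R_cell^2

    # convenience back-references used by the FEM layer
    params: ModelParameters = field(repr=False, default=None)


def derived_parameters(p: ModelParameters) -> DerivedParameters:
    """Compute the derived moduli, permeability and gating threshold.

    H_A = λ + 2μ is the aggregate (confined-compression) modulus and
    H_B = 3λ + 2μ the bulk-like modulus weighting isotropic growth strains.
    K_ref comes from Stokes drag on spheres of radius R_cell, and r_bar is
    the shear threshold normalized by the shear modulus.
    """
    if not isinstance(p, ModelParameters):
        raise TypeError("expected ModelParameters")
    return DerivedParameters(
        H_A=p.lam + 2.0 * p.mu,
        H_B=3.0 * p.lam + 2.0 * p.mu,
        K_ref=(2.0 / 3.0) * p.R_cell**2 / p.mu_fl,
        V_cell=(4.0 / 3.0) * math.pi * p.R_cell**3,
        r_bar=p.shear_threshold / p.mu,
        C_F_cell=1.5 * p.mu_fl / p.R_cell**2,
        params=p,
    )
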