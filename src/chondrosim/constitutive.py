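"""Constitutive closures: permeability, effective diffusivity, 1D stress.

The bar is in a uniaxial stress state; the total axial stress combines the
elastic response of the solid fraction, the pore pressure and the
accumulated growth strains.  The deviatoric part of the stress feeds the
force-isotropy indicator r that gates the population kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import CellFractions, GrowthCoefficients
from .parameters import DerivedParameters, ModelParameters, ParameterError, derived_parameters

#: fluid fractions are kept this far away from the singular limit phi_fl = 1
PHI_FL_CLAMP = 1.0e-6


@dataclass
class StressState:
    """Principal decomposition of the 1D total stress at one point."""

    T_xx: np.ndarray | float      # total axial stress
    sigma_I: np.ndarray | float   # axial principal total stress
    sigma_II: np.ndarray | float  # lateral principal stress (= sigma_III)
    tau_max: np.ndarray | float   # Mohr-circle radius
    r: np.ndarray | float         # anisotropy indicator |tau_max| / mu
    xi: np.ndarray | float        # 1 where isotropic (r <= r_bar), else 0


def permeability(phi_fl, p: ModelParameters | DerivedParameters):
    """Darcy permeability K_ref · φ_fl² / (1 − φ_fl), from Stokes drag.

    φ_fl is clamped into [ε, 1−ε] before evaluation; fractions at or above
    1 outside the clamp tolerance are rejected as unphysical.
    """
    dp = p if isinstance(p, DerivedParameters) else derived_parameters(p)
    phi = np.asarray(phi_fl, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1.0 + 1e-12):
        raise ParameterError("phi_fl must lie in [0, 1)")
    phi = np.clip(phi, PHI_FL_CLAMP, 1.0 - PHI_FL_CLAMP)
    out = dp.K_ref * phi**2 / (1.0 - phi)
    return out if out.ndim else float(out)


def effective_diffusion(phi_fl, p: ModelParameters):
    """Maxwell volume-averaged oxygen diffusivity of the two-phase construct.

    Interpolates between K_eq·D_c_s in the pure solid and D_c_fl in the
    pure fluid; k = K_eq · D_c_s / D_c_fl is the phase diffusivity ratio.
    """
    phi = np.asarray(phi_fl, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1.0 + 1e-12):
        raise ParameterError("phi_fl must lie in [0, 1]")
    k = p.K_eq * p.D_c_s / p.D_c_fl
    denom = 3.0 + phi * (k - 1.0)
    if np.any(denom <= 0):
        raise ParameterError("Maxwell denominator nonpositive; check K_eq, D_c_s, D_c_fl")
    out = p.D_c_fl * (3.0 * k - 2.0 * phi * (k - 1.0)) / denom
    return out if out.ndim else float(out)


def growth_stress_source(fr: CellFractions, g: GrowthCoefficients,
                         dp: DerivedParameters):
    """Stress offset carried by the growth strains.

    H_A·φ_n·g_n + H_B·(φ_v·g_v + φ_q·g_q + φ_ECM·g_ECM); subtracting it
    from the elastic stress expresses that deposited mass is stress-free.
    """
    iso = fr.phi_v * g.g_v + fr.phi_q * g.g_q + fr.phi_ECM * g.g_ECM
    return dp.H_A * fr.phi_n * g.g_n + dp.H_B * iso


def total_stress_1d(u_x, pres, fr: CellFractions, g: GrowthCoefficients,
                    dp: DerivedParameters):
    """Total axial stress T_xx = H_A·φ_s·u_x − p − growth offset."""
    return dp.H_A * fr.phi_s * u_x - pres - growth_stress_source(fr, g, dp)


def stress_decomposition(u_x, pres, fr: CellFractions, g: GrowthCoefficients,
                         p: ModelParameters) -> StressState:
    """Principal stresses, maximum shear and the isotropy indicator.

    In uniaxial conditions the lateral principal stresses coincide, the
    Mohr radius is μ·(φ_s·u_x − g_n·φ_n) and the anisotropy indicator
    reduces to r = |φ_s·u_x − g_n·φ_n| = |tau_max| / μ.  The binary flag
    xi marks the isotropic regime r <= r_bar (boundary inclusive).
    """
    dp = derived_parameters(p)
    iso = fr.phi_v * g.g_v + fr.phi_q * g.g_q + fr.phi_ECM * g.g_ECM
    e_dev = fr.phi_s * u_x - g.g_n * fr.phi_n   # deviatoric strain measure
    sigma_I = dp.H_A * e_dev - pres - dp.H_B * iso
    sigma_II = p.lam * e_dev - pres - dp.H_B * iso
    tau_max = 0.5 * (sigma_I - sigma_II)
    r = np.abs(e_dev)
    xi = np.where(r <= dp.r_bar, 1.0, 0.0)
    T_xx = sigma_I
    if np.ndim(r) == 0:
        r, xi = float(r), float(xi)
    return StressState(T_xx=T_xx, sigma_I=sigma_I, sigma_II=sigma_II,
                       tau_max=tau_max, r=r, xi=xi)
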