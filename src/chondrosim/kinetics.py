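"""Pointwise cell-population kinetics and growth-strain updates.

The solid phase of the mixture carries three chondrocyte pools —
proliferating (n), ECM-secreting (v) and quiescent (q) — plus extracellular
matrix (ECM).  Mass exchange among the pools and with the interstitial
fluid is gated by two binary indicators: H_r (1 where the local stress
state is anisotropic) and H_c (1 where oxygen exceeds the activity
threshold).  All functions are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .parameters import ModelParameters, derived_parameters


class KineticsError(ValueError):
    pass


@dataclass
class CellFractions:
    """Volume fractions of the solid constituents; the fluid closes to 1."""

    phi_n: np.ndarray | float
    phi_v: np.ndarray | float
    phi_q: np.ndarray | float
    phi_ECM: np.ndarray | float

    @property
    def phi_s(self):
        return self.phi_n + self.phi_v + self.phi_q + self.phi_ECM

    @property
    def phi_fl(self):
        """Saturation closure: the fluid fills the remaining volume."""
        return 1.0 - self.phi_s

    def validate(self) -> None:
        for name in ("phi_n", "phi_v", "phi_q", "phi_ECM"):
            val = np.asarray(getattr(self, name), dtype=float)
            if np.any(val < 0) or np.any(val > 1):
                raise KineticsError(f"{name} outside [0, 1]")
        if np.any(np.asarray(self.phi_s) > 1.0 + 1e-12):
            raise KineticsError("solid fractions sum above 1")


@dataclass
class GrowthCoefficients:
    """Accumulated growth strains; zero in the unstressed initial state."""

    g_n: np.ndarray | float = 0.0
    g_v: np.ndarray | float = 0.0
    g_q: np.ndarray | float = 0.0
    g_ECM: np.ndarray | float = 0.0


class ProductionRates(NamedTuple):
    Q_n: np.ndarray | float
    Q_v: np.ndarray | float
    Q_q: np.ndarray | float
    Q_ECM: np.ndarray | float
    Q_fl: np.ndarray | float


def heaviside_gate(z):
    """Right-continuous Heaviside step: 0 for z < 0, 1 for z >= 0."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise KineticsError("gate argument must be finite")
    out = np.where(z < 0.0, 0.0, 1.0)
    return out if out.ndim else float(out)


def monod_factor(c, K_sat):
    """Saturating nutrient modulation c / (K_sat + c), in [0, 1)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise KineticsError("concentration must be nonnegative")
    if not np.all(np.asarray(K_sat) > 0):
        raise KineticsError("K_sat must be positive")
    out = c / (K_sat + c)
    return out if out.ndim else float(out)


def oxygen_consumption(fr: CellFractions, c, p: ModelParameters):
    """Michaelis–Menten oxygen sink of the three cell pools (g·cm⁻³·s⁻¹, <= 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise KineticsError("concentration must be nonnegative")
    demand = p.R_n * fr.phi_n + p.R_v * fr.phi_v + p.R_q * fr.phi_q
    out = -demand * c / (c + p.K_half)
    return out if np.ndim(out) else float(out)


def ecm_synthesis_rate(phi_v, phi_ECM, c, p: ModelParameters):
    """GAG-driven ECM synthesis, clamped to zero once phi_ECM hits its ceiling."""
    V_cell = derived_parameters(p).V_cell
    headroom = np.maximum(0.0, 1.0 - np.asarray(phi_ECM) / p.phi_ECM_max)
    return (phi_v / V_cell) * c * p.E * p.k_GAG * headroom


def population_production(fr: CellFractions, c, H_r, H_c,
                          p: ModelParameters) -> ProductionRates:
    """Net volume-fraction production rates of the five mixture species.

    Mechanotransduction enters through the anisotropy gate H_r: where the
    stress state is anisotropic (H_r = 1) quiescent cells are recruited
    into both active pools (q→n and q→v), while in a mechanically quiet,
    isotropic environment (H_r = 0) secreting cells drift back to
    quiescence (v→q).  Low oxygen (H_c = 0) adds the k_qui quiescence
    drain to all three cell pools.  The fluid term closes the balance,
    Q_fl = -(Q_n + Q_v + Q_q + Q_ECM): dying cells and degraded matrix
    return to fluid, and growth consumes it.
    """
    fr.validate()
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise KineticsError("concentration must be nonnegative")
    H_r = np.asarray(H_r, dtype=float)
    H_c = np.asarray(H_c, dtype=float)

    mono = c / (p.K_sat + c)
    qui = p.k_qui * (1.0 - H_c)

    Q_n = (-fr.phi_n / p.tau_m
           + fr.phi_q * p.beta_qn * H_r
           + fr.phi_n * fr.phi_fl * mono * p.k_g
           - qui * fr.phi_n)
    Q_v = (-fr.phi_v * p.beta_vq * (1.0 - H_r)
           + fr.phi_q * p.beta_qv * H_r
           - qui * fr.phi_v
           - p.k_apo * fr.phi_v)
    Q_q = (fr.phi_n / p.tau_m
           - fr.phi_q * p.beta_qn * H_r
           + fr.phi_v * p.beta_vq * (1.0 - H_r)
           - fr.phi_q * p.beta_qv * H_r
           - qui * fr.phi_q
           - p.k_apo * fr.phi_q)
    Q_ECM = ecm_synthesis_rate(fr.phi_v, fr.phi_ECM, c, p) - p.k_deg * fr.phi_ECM
    Q_fl = -(Q_n + Q_v + Q_q + Q_ECM)
    return ProductionRates(Q_n, Q_v, Q_q, Q_ECM, Q_fl)


def growth_step(g: GrowthCoefficients, Q: ProductionRates,
                dt: float) -> GrowthCoefficients:
    """One Euler update of the growth strains driven by mass production.

    Proliferation deposits mass along the polarization axis, so g_n
    integrates the full rate Q_n; the isotropically growing species pick up
    one third of their production rate (the trace is spread over three
    directions).
    """
    if dt <= 0:
        raise KineticsError("dt must be positive")
    return GrowthCoefficients(
        g_n=g.g_n + dt * Q.Q_n,
        g_v=g.g_v + dt * Q.Q_v / 3.0,
        g_q=g.g_q + dt * Q.Q_q / 3.0,
        g_ECM=g.g_ECM + dt * Q.Q_ECM / 3.0,
    )


def kinetics_rhs(y: np.ndarray, c: float, H_r: float, H_c: float,
                 p: ModelParameters) -> np.ndarray:
    """Right-hand side [Q_n, Q_v, Q_q, Q_ECM] for a well-mixed (0D) culture.

    Convenience wrapper used to couple the kinetics to an ODE integrator
    when spatial transport is switched off.
    """
    fr = CellFractions(*y)
    Q = population_production(fr, c, H_r, H_c, p)
    return np.array([Q.Q_n, Q.Q_v, Q.Q_q, Q.Q_ECM])
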