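"""Coarse-grained Cdc42/Bni1 polarity dynamics on the cell surface.

Minimal two-species description of the polarization machinery: membrane
Cdc42 (density rho_C) is delivered along actin cables (density rho_A,
proportional to active Bni1) and detaches at rate k_D,

    d/dt (r rho_C) - D d/ds (r d/ds rho_C) = r [k_X rho_A - k_D rho_C],

while active Bni1 (rho_Ba) is recruited by Cdc42 and activated through the
cell-wall-integrity (CWI) pathway at a rate proportional to the local wall
expansion rate,

    d/dt (r rho_Ba) = r [k_R rho_C + k_CWI rho_0 - k_I rho_Ba],
    k_CWI = A_CWI (eps_s_dot + eps_phi_dot),

with rho_0 the uniform inactive-Bni1 pool.  The actin-cable density is
rho_A = c_A rho_Ba with c_A = 1 in scaled units (only products of c_A with
k_X and k_s are identifiable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AxisymShape, cell_areas

__all__ = ["PolarityParams", "PolarityFields", "cwi_activation_rate",
           "cdc42_rhs", "bni1_rhs", "assembly_rate", "diffusion_operator",
           "total_cdc42"]


@dataclass
class PolarityParams:
    """Kinetic parameters of the coarse-grained polarity model.

    D : Cdc42 membrane diffusivity (μm²/s).
    k_D : Cdc42 membrane detachment rate (1/s); sets the time scale 1/k_D
        and, with D, the length scale (D/k_D)^1/2 of the polarity cap.
    k_X : actin-mediated Cdc42 delivery rate (1/s per cable-density unit).
    k_R : Bni1 recruitment rate by Cdc42 (1/s per Cdc42-density unit).
    k_I : Bni1 inactivation rate (1/s).
    A_CWI : dimensionless mechanical-feedback strength.
    rho_0 : uniform inactive-Bni1 pool density.
    c_A : actin-cable density per active Bni1 (1 in scaled units).
    """

    D: float = 0.04
    k_D: float = 0.2
    k_X: float = 0.2
    k_R: float = 0.03
    k_I: float = 0.2
    A_CWI: float = 5000.0
    rho_0: float = 1.0
    c_A: float = 1.0

    def __post_init__(self):
        if self.k_D <= 0:
            raise ValueError("k_D must be strictly positive")
        for name in ("D", "k_X", "k_R", "k_I", "A_CWI", "rho_0", "c_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def length_scale(self) -> float:
        return float(np.sqrt(self.D / self.k_D))


@dataclass
class PolarityFields:
    """Continuum surface densities along arclength."""

    rho_C: np.ndarray
    rho_Ba: np.ndarray
    rho_0: float = 1.0
    c_A: float = 1.0

    @property
    def rho_A(self) -> np.ndarray:
        return self.c_A * self.rho_Ba

    def copy(self) -> "PolarityFields":
        return PolarityFields(np.array(self.rho_C), np.array(self.rho_Ba),
                              self.rho_0, self.c_A)


def cwi_activation_rate(eps_s_dot, eps_phi_dot, A_CWI: float) -> np.ndarray:
    """CWI-mediated Bni1 activation rate, A_CWI (eps_s + eps_phi), floored at 0.

    Transiently negative numerical strain rates would otherwise produce an
    unphysical negative activation.
    """
    return np.maximum(A_CWI * (np.asarray(eps_s_dot) + np.asarray(eps_phi_dot)), 0.0)


def diffusion_operator(shape: AxisymShape, D: float):
    """Conservative finite-volume surface diffusion on the arclength grid.

    Returns ``(apply, areas)`` where ``apply(rho)`` gives the per-node rate
    d(rho)/dt from diffusion alone.  Fluxes through the faces midway between
    nodes make the scheme discretely mass-conserving (no-flux at both ends);
    on-axis poles are regular because the face radius vanishes there.
    """
    s, r = shape.s, shape.r
    ds = np.diff(s)
    r_face = 0.5 * (r[1:] + r[:-1])
    a = cell_areas(shape)
    coeff = 2.0 * np.pi * D * r_face / ds

    def apply(rho: np.ndarray) -> np.ndarray:
        flux = coeff * (rho[1:] - rho[:-1])      # toward increasing s
        div = np.zeros_like(rho)
        div[:-1] += flux
        div[1:] -= flux
        return div / a

    return apply, a


def cdc42_rhs(shape: AxisymShape, rho_C, rho_A, params: PolarityParams) -> np.ndarray:
    """Time derivative of (r rho_C): diffusion + delivery - detachment."""
    apply_diff, _ = diffusion_operator(shape, params.D)
    rho_C = np.asarray(rho_C, float)
    drho = apply_diff(rho_C) + params.k_X * np.asarray(rho_A, float) - params.k_D * rho_C
    return shape.r * drho


def bni1_rhs(shape: AxisymShape, rho_C, rho_Ba, k_CWI, params: PolarityParams) -> np.ndarray:
    """Time derivative of (r rho_Ba): recruitment + CWI activation - decay."""
    rate = (params.k_R * np.asarray(rho_C, float)
            + np.asarray(k_CWI, float) * params.rho_0
            - params.k_I * np.asarray(rho_Ba, float))
    return shape.r * rate


def assembly_rate(rho_A, k_s: float) -> np.ndarray:
    """Wall assembly (thickness deposition) rate G = k_s rho_A."""
    return k_s * np.asarray(rho_A, float)


def total_cdc42(shape: AxisymShape, rho_C) -> float:
    """Total Cdc42 on the surface, ∫ 2π r rho_C ds (cell-area quadrature)."""
    return float(np.sum(cell_areas(shape) * np.asarray(rho_C, float)))
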