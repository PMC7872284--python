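"""Mechanics of the turgor-pressurized viscous cell-wall shell.

The wall is a thin viscous fluid shell with spatially graded viscosity,
inflated by constant turgor pressure P.  Because inertia is negligible the
mechanics is quasistatic: at any instant the tensions follow algebraically
from the geometry (normal and tangential force balance),

    sigma_ss * kappa_phi = P / 2,
    sigma_ss * kappa_s + sigma_phiphi * kappa_phi = P,

the strain rates follow from the constitutive law of a viscous shell,

    sigma_ss     = 4 mu h (eps_s_dot + eps_phi_dot / 2),
    sigma_phiphi = 4 mu h (eps_s_dot / 2 + eps_phi_dot),

and the surface velocity field (u tangential, v_n normal) follows from the
axisymmetric-shell kinematics

    eps_s_dot   = du/ds + v_n kappa_s,
    eps_phi_dot = u cos(theta)/r + v_n kappa_phi.

Wall material mass obeys  d/dt(r h) + d/ds(r h u) = r G  with G the local
assembly (thickness-deposition) rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (AxisymShape, GeometryError, VISCOSITY_CAP, curvatures,
                       fd_matrix, reparametrize)

__all__ = [
    "MechanicsParams", "WallFields", "MechanicsError",
    "solve_tensions", "strain_rates_from_tensions", "viscosity_profile",
    "surface_velocities", "update_thickness", "thickness_flux_audit",
    "advance_shape", "solve_wall_fields",
]


class MechanicsError(RuntimeError):
    """Raised when the quasistatic mechanics solve fails."""


@dataclass
class MechanicsParams:
    """Physical parameters of the wall-mechanics block.

    Units: lengths μm, times s, pressures MPa (so tensions are MPa·μm = N/m).

    P : turgor pressure.
    rho_w : wall density; only enters the dimensionless mechanics group
        (it is absorbed into k_s in the mass balance).
    mu0 : apex (minimum) wall viscosity, MPa·s.
    lambda_A : decay length of the actin-cable density from the tip, μm;
        sets the width of the soft-wall zone, μ = μ0 exp(s²/λ_A²).
    k_s : wall-assembly rate per unit actin-cable density (μm/s per
        cable-density unit).
    """

    P: float = 0.2
    rho_w: float = 1.0
    mu0: float = 2800.0
    lambda_A: float = 0.5
    k_s: float = 1.0e-6

    def __post_init__(self):
        for name in ("P", "rho_w", "mu0", "lambda_A", "k_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class WallFields:
    """Mechanical fields on the shape's node grid."""

    sigma_ss: np.ndarray
    sigma_phiphi: np.ndarray
    eps_s_dot: np.ndarray
    eps_phi_dot: np.ndarray
    u: np.ndarray
    v_n: np.ndarray
    mu: np.ndarray
    G: np.ndarray

    @property
    def expansion_rate(self) -> np.ndarray:
        """Local wall expansion rate, eps_s_dot + eps_phi_dot."""
        return self.eps_s_dot + self.eps_phi_dot


def solve_tensions(shape: AxisymShape, P: float):
    """Tensions from normal/tangential force balance (purely geometric + P)."""
    kphi, ks = shape.kappa_phi, shape.kappa_s
    if np.any(kphi <= 0):
        raise MechanicsError("kappa_phi <= 0: geometry outside model validity")
    sigma_ss = P / (2.0 * kphi)
    sigma_phiphi = (P - sigma_ss * ks) / kphi
    return sigma_ss, sigma_phiphi


def strain_rates_from_tensions(sigma_ss, sigma_phiphi, mu, h):
    """Invert the viscous-shell constitutive law for the strain rates."""
    denom = 6.0 * np.asarray(mu) * np.asarray(h)
    eps_s = (2.0 * sigma_ss - sigma_phiphi) / denom
    eps_phi = (2.0 * sigma_phiphi - sigma_ss) / denom
    return eps_s, eps_phi


def viscosity_profile(s, mu0: float, lambda_A: float, center: float = 0.0):
    """Graded wall viscosity mu0 * exp((s-center)²/λ_A²), capped at mu0*1e6.

    ``center`` is the arclength of the soft-zone center (the polarization
    cap); it is 0 whenever the cap sits at the tip.
    """
    if lambda_A <= 0:
        raise ValueError("lambda_A must be positive")
    x = (np.asarray(s, dtype=float) - center) / lambda_A
    return mu0 * np.exp(np.minimum(x * x, np.log(VISCOSITY_CAP)))


def _translation_mode(shape: AxisymShape):
    """Rigid z-translation: u = -sin(theta), v_n = cos(theta) (strain-free)."""
    return -np.sin(shape.theta), np.cos(shape.theta)


def surface_velocities(shape: AxisymShape, eps_s_dot, eps_phi_dot):
    """Solve the kinematic relations for (u, v_n).

    Eliminating v_n gives a linear first-order ODE in u,

        du/ds = eps_s_dot - (kappa_s/kappa_phi) * eps_phi_dot
                + (kappa_s cos(theta) / (kappa_phi r)) * u,

    which is singular at on-axis poles (regularity requires u = 0 there).
    For a closed generating curve (poles at both ends) the null direction of
    the discrete operator is the rigid z-translation mode (u = -sin theta,
    v_n = cos theta), which satisfies both pole conditions.  The solve uses a
    truncated-SVD least-squares, whose minimal-norm solution suppresses the
    translation component: the physical velocity field is localized in the
    soft tip zone, so any added translation only increases ||u|| over the
    rigid remainder of the cell.

    For an open curve that does not start at a pole the ODE is integrated
    directly with u(0) = 0.
    """
    eps_s = np.asarray(eps_s_dot, dtype=float)
    eps_p = np.asarray(eps_phi_dot, dtype=float)
    s, r, th = shape.s, shape.r, shape.theta
    ks, kphi = shape.kappa_s, shape.kappa_phi
    n = s.size
    closed_start = r[0] <= 1e-9 * max(1.0, r.max())
    closed_end = r[-1] <= 1e-9 * max(1.0, r.max())

    q = eps_s - (ks / kphi) * eps_p
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ks * np.cos(th) / (kphi * r)

    if not closed_start:
        # open curve: integrating-factor solution from u(0) = 0
        P_int = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(s))])
        ef = np.exp(-P_int)
        integ = np.concatenate([[0.0], np.cumsum(0.5 * (q[1:] * ef[1:] + q[:-1] * ef[:-1]) * np.diff(s))])
        u = integ / ef
        v_n = (eps_p - u * np.cos(th) / r) / kphi
        return u, v_n

    D = fd_matrix(s)
    A = D - np.diag(np.where(np.isfinite(p), p, 0.0))
    rows = slice(1, n - 1)
    M = A[rows, 1:n - 1]                       # u_0 = u_{n-1} = 0
    rhs = q[rows]
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=1e-8)
    u = np.zeros(n)
    u[1:n - 1] = sol

    v_n = np.empty(n)
    interior = slice(1, n - 1)
    v_n[interior] = (eps_p[interior] - u[interior] * np.cos(th[interior]) / r[interior]) / kphi[interior]
    # pole values by even extrapolation from the interior (v_n is an even
    # function of arclength about an on-axis pole); interior values rely only
    # on the algebraic kappa_phi, keeping the apex free of FD noise feedback.
    # A non-pole distal end (truncated rigid wall) uses the regular formula.
    m = min(7, n // 4)
    ends = [(0, slice(1, m))] if closed_start else []
    if closed_end:
        ends.append((n - 1, slice(n - m, n - 1)))
    else:
        v_n[-1] = (eps_p[-1] - u[-1] * np.cos(th[-1]) / r[-1]) / kphi[-1]
    for i, sl in ends:
        x = s[sl] - s[i]
        A2 = np.column_stack([np.ones_like(x), x * x])
        coef, *_ = np.linalg.lstsq(A2, v_n[sl], rcond=None)
        v_n[i] = coef[0]

    if not np.all(np.isfinite(u)) or not np.all(np.isfinite(v_n)):
        raise MechanicsError("velocity solve produced non-finite values")
    return u, v_n


def update_thickness(shape: AxisymShape, u, G, dt: float):
    """One explicit conservative step of d/dt(r h) + d/ds(r h u) = r G.

    Finite-volume flux form on the node-centered cells of the current
    (static) grid; the discrete total d/dt ∫ r h ds equals
    ∫ r G ds minus the boundary flux to machine precision.  On-axis pole
    cells use the regular limit dh/dt = G - 2 d(hu)/ds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s, r, h = shape.s, shape.r, np.array(shape.h)
    u = np.asarray(u, float)
    G = np.asarray(G, float)
    n = s.size
    f = r * h * u
    F = 0.5 * (f[1:] + f[:-1])                 # face fluxes
    w = _cell_widths(s)
    rh = r * h
    new_rh = rh.copy()
    new_rh[1:-1] -= dt * (F[1:] - F[:-1]) / w[1:-1]
    new_rh[1:-1] += dt * r[1:-1] * G[1:-1]
    h_new = h.copy()
    pos = r > 0
    h_new[pos] = new_rh[pos] / r[pos]
    D = fd_matrix(s)
    dhu = D @ (h * u)
    for i in (0, n - 1):
        if r[i] <= 1e-9 * max(1.0, r.max()):
            h_new[i] = h[i] + dt * (G[i] - 2.0 * dhu[i])
        else:
            # boundary cell of an open curve: one-sided flux
            Fb = f[i]
            Fin = F[0] if i == 0 else F[-1]
            sgn = 1.0 if i == 0 else -1.0
            h_new[i] = (rh[i] - sgn * dt * (Fin - Fb) / w[i] + dt * r[i] * G[i]) / r[i]
    if np.any(h_new <= 0):
        raise MechanicsError("thickness became non-positive: timestep too large")
    return h_new


def _cell_widths(s: np.ndarray) -> np.ndarray:
    w = np.zeros(s.size)
    d = np.diff(s)
    w[:-1] += 0.5 * d
    w[1:] += 0.5 * d
    return w


def thickness_flux_audit(shape: AxisymShape, h_old, h_new, u, G, dt: float) -> float:
    """Relative residual of the discrete wall-mass balance over one step.

    Compares the change of ∫ r h ds (trapezoid) against the deposited mass
    ∫ r G ds dt minus the net boundary flux, normalized by the wall mass.
    """
    s, r = shape.s, shape.r
    w = _cell_widths(s)
    lhs = np.sum(w * r * (np.asarray(h_new) - np.asarray(h_old)))
    f = r * np.asarray(h_old) * np.asarray(u)
    rhs = dt * (np.sum(w * r * np.asarray(G)) - (f[-1] - f[0]))
    scale = max(np.sum(w * r * np.asarray(h_old)), 1e-300)
    # pole cells are updated by the regular limit rather than the flux form;
    # their weight r*w vanishes at machine level so they do not contribute.
    return abs(lhs - rhs) / scale


def advance_shape(shape: AxisymShape, u, v_n, dt: float,
                  n_nodes: int | None = None) -> AxisymShape:
    """Advect the nodes by dt (u ŝ + v_n n̂), then reparametrize.

    Returns the new shape with recomputed curvatures; thickness is carried
    by material interpolation inside ``reparametrize``.
    """
    th = shape.theta
    u = np.asarray(u, float)
    v_n = np.asarray(v_n, float)
    r = shape.r + dt * (u * np.cos(th) + v_n * np.sin(th))
    z = shape.z + dt * (-u * np.sin(th) + v_n * np.cos(th))
    r = np.maximum(r, 0.0)
    if shape.r[0] == 0.0:
        r[0] = 0.0
    if shape.r[-1] == 0.0:
        r[-1] = 0.0
    seg = np.hypot(np.diff(r), np.diff(z))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    moved = AxisymShape(s=s, r=r, z=z, theta=np.array(th),
                        kappa_s=np.array(shape.kappa_s),
                        kappa_phi=np.array(shape.kappa_phi), h=np.array(shape.h))
    return reparametrize(moved, n_nodes or shape.n_nodes)


def _deflate_translation(shape: AxisymShape, u, v_n, mu):
    """Remove the rigid z-translation component by anchoring the solid wall.

    The kinematic solve determines (u, v_n) only up to a strain-free rigid
    translation along the axis.  Where the graded viscosity makes the wall
    solid-like (mu >> mu_min) the physical velocity vanishes, so the
    translation amplitude is fit over that region and subtracted.  Shapes
    without a rigid region (e.g. a uniformly viscous sphere) are returned
    unchanged; there the minimal-norm gauge of the solver already applies.
    """
    mu = np.asarray(mu, float)
    rigid = mu > 1e3 * mu.min()
    if np.count_nonzero(rigid) < 4:
        return u, v_n
    um, vm = _translation_mode(shape)
    num = float(np.sum(u[rigid] * um[rigid] + v_n[rigid] * vm[rigid]))
    den = float(np.sum(um[rigid] ** 2 + vm[rigid] ** 2))
    if den <= 0:
        return u, v_n
    w = num / den
    return u - w * um, v_n - w * vm


def solve_wall_fields(shape: AxisymShape, params: MechanicsParams,
                      rho_A=None, mu=None, cap_center: float = 0.0) -> WallFields:
    """Full quasistatic mechanics solve on a shape.

    mu defaults to the graded profile mu0 exp((s-cap_center)²/λ_A²); the wall
    assembly rate is G = k_s ρ_A (zero if no actin profile is given).
    """
    if mu is None:
        mu = viscosity_profile(shape.s, params.mu0, params.lambda_A, center=cap_center)
    sig_s, sig_p = solve_tensions(shape, params.P)
    eps_s, eps_p = strain_rates_from_tensions(sig_s, sig_p, mu, shape.h)
    u, v_n = surface_velocities(shape, eps_s, eps_p)
    u, v_n = _deflate_translation(shape, u, v_n, mu)
    G = params.k_s * np.asarray(rho_A, float) if rho_A is not None else np.zeros_like(shape.s)
    return WallFields(sigma_ss=sig_s, sigma_phiphi=sig_p, eps_s_dot=eps_s,
                      eps_phi_dot=eps_p, u=u, v_n=v_n, mu=np.asarray(mu, float), G=G)
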