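"""Axisymmetric cell-surface geometry.

The cell outline is a generating curve in the (r, z) plane, parametrized by
arclength ``s`` measured from the apex (tip) of the mating projection.  The
surface is the curve revolved about the growth axis z.  ``theta`` is the angle
between the outward normal and the growth axis, so the generating curve obeys

    dr/ds = cos(theta),    dz/ds = -sin(theta),

with z decreasing from the tip toward the cell body.  The two principal
curvatures are the meridional curvature ``kappa_s = d(theta)/ds`` and the
azimuthal curvature ``kappa_phi = sin(theta)/r`` (with the regular umbilic
limit ``kappa_phi -> kappa_s`` at an on-axis pole).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "AxisymShape",
    "GeometryError",
    "make_sphere",
    "make_projection",
    "curvatures",
    "reparametrize",
    "enclosed_volume",
    "wall_volume",
    "surface_area",
    "cell_areas",
    "fd_matrix",
    "VISCOSITY_CAP",
    "truncation_length",
]

#: factor by which the wall viscosity may exceed its apex value before the
#: wall is treated as rigid (solid-like limit of the graded-viscosity wall).
VISCOSITY_CAP = 1.0e6


class GeometryError(ValueError):
    """Raised for degenerate or infeasible axisymmetric geometries."""


@dataclass
class AxisymShape:
    """Axisymmetric cell outline sampled at nodes ordered from the apex.

    Attributes
    ----------
    s : ndarray
        Arclength from the apex (μm), strictly increasing, ``s[0] == 0``.
    r : ndarray
        Local radius (μm); 0 at an on-axis pole.
    z : ndarray
        Axial coordinate (μm), decreasing from tip toward body.
    theta : ndarray
        Angle between outward normal and growth axis (rad).
    kappa_s, kappa_phi : ndarray
        Principal curvatures (μm⁻¹).
    h : ndarray
        Local wall thickness (μm), strictly positive.
    """

    s: np.ndarray
    r: np.ndarray
    z: np.ndarray
    theta: np.ndarray
    kappa_s: np.ndarray
    kappa_phi: np.ndarray
    h: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.s.size

    @property
    def length(self) -> float:
        """Total arclength of the generating curve."""
        return float(self.s[-1])

    def copy(self) -> "AxisymShape":
        return AxisymShape(*(np.array(getattr(self, f)) for f in
                             ("s", "r", "z", "theta", "kappa_s", "kappa_phi", "h")))

    def validate(self, tol: float = 1e-2) -> None:
        """Check the structural invariants of the parametrization.

        ``tol`` bounds the generating-curve consistency residual
        |dr/ds - cos(theta)|, which is only met to discretization accuracy.
        """
        if not np.all(np.diff(self.s) > 0) or self.s[0] != 0.0:
            raise GeometryError("arclength must be strictly increasing from 0")
        if abs(self.r[0]) > 1e-9 or abs(self.theta[0]) > 1e-6:
            raise GeometryError("apex must sit on the axis with theta = 0")
        if np.any(self.h <= 0):
            raise GeometryError("wall thickness must be positive")
        if np.any(self.r[1:-1] <= 0):
            raise GeometryError("radius vanishes away from the poles")
        drds = fd_matrix(self.s) @ self.r
        resid = np.max(np.abs(drds - np.cos(self.theta)))
        if resid > tol:
            raise GeometryError(f"generating-curve consistency violated ({resid:.2e})")


def _fornberg_weights(x0: float, x: np.ndarray, m: int) -> np.ndarray:
    """Finite-difference weights for the m-th derivative at x0 on nodes x."""
    n = x.size
    c = np.zeros((n, m + 1))
    c1, c4 = 1.0, x[0] - x0
    c[0, 0] = 1.0
    for i in range(1, n):
        mn = min(i, m)
        c2, c5 = 1.0, c4
        c4 = x[i] - x0
        for j in range(i):
            c3 = x[i] - x[j]
            c2 *= c3
            if j == i - 1:
                for k in range(mn, 0, -1):
                    c[i, k] = c1 * (k * c[i - 1, k - 1] - c5 * c[i - 1, k]) / c2
                c[i, 0] = -c1 * c5 * c[i - 1, 0] / c2
            for k in range(mn, 0, -1):
                c[j, k] = (c4 * c[j, k] - k * c[j, k - 1]) / c3
            c[j, 0] = c4 * c[j, 0] / c3
        c1 = c2
    return c[:, m]


def fd_matrix(s: np.ndarray, order: int = 4) -> np.ndarray:
    """First-derivative differentiation matrix on nodes ``s``.

    Fourth-order stencils in the interior, one-sided at the boundaries
    (the Methods-style method-of-lines discretization).
    """
    n = s.size
    half = order // 2
    width = order + 1
    D = np.zeros((n, n))
    for i in range(n):
        lo = min(max(i - half, 0), n - width)
        idx = np.arange(lo, lo + width)
        D[i, idx] = _fornberg_weights(s[i], s[idx], 1)
    return D


def _pole_flags(shape_or_r, tol: float = 1e-9):
    r = shape_or_r.r if isinstance(shape_or_r, AxisymShape) else np.asarray(shape_or_r)
    scale = max(1.0, float(np.max(r)))
    return r[0] <= tol * scale, r[-1] <= tol * scale


def _extend(s: np.ndarray, fields: dict, start_pole: bool, end_pole: bool, k: int = 6):
    """Mirror a few nodes across on-axis poles for spline/FD regularity.

    ``fields`` maps name -> (values, parity) where parity is the reflection
    rule: 'even' f(-x)=f(x), 'odd' f(-x)=-f(x), or 'theta' for the normal
    angle (odd at the apex, theta -> 2*pi - theta across the distal pole).
    """
    L = s[-1]
    pre = s[1:k + 1][::-1]
    post = s[-2:-k - 2:-1]
    s_ext = np.concatenate([
        (-pre) if start_pole else np.empty(0),
        s,
        (2 * L - post) if end_pole else np.empty(0),
    ])
    out = {}
    for name, (f, parity) in fields.items():
        a = f[1:k + 1][::-1]
        b = f[-2:-k - 2:-1]
        if parity == "even":
            left, right = a, b
        elif parity == "odd":
            left, right = -a, -b
        elif parity == "theta":
            left, right = -a, 2 * np.pi - b
        else:               # pragma: no cover
            raise ValueError(parity)
        out[name] = np.concatenate([
            left if start_pole else np.empty(0),
            f,
            right if end_pole else np.empty(0),
        ])
    n_pre = k if start_pole else 0
    return s_ext, out, n_pre


def _finish(s, r, z, theta, h, kappa_s=None) -> AxisymShape:
    shape = AxisymShape(s=s, r=r, z=z, theta=theta,
                        kappa_s=np.zeros_like(s), kappa_phi=np.zeros_like(s), h=h)
    if kappa_s is not None:
        shape.kappa_s = kappa_s
        shape.kappa_phi = _kappa_phi(shape)
        return shape
    return curvatures(shape)


def _kappa_phi(shape: AxisymShape) -> np.ndarray:
    """sin(theta)/r with the umbilic limit at on-axis poles."""
    s, r, theta, ks = shape.s, shape.r, shape.theta, shape.kappa_s
    kphi = np.empty_like(r)
    interior = slice(1, -1)
    if np.any(r[interior] <= 0):
        raise GeometryError("radius vanishes away from the poles")
    kphi[interior] = np.sin(theta[interior]) / r[interior]
    for i in (0, -1):
        if r[i] <= 1e-9 * max(1.0, r.max()):
            kphi[i] = ks[i]
        else:
            kphi[i] = np.sin(theta[i]) / r[i]
    return kphi


def curvatures(shape: AxisymShape) -> AxisymShape:
    """Recompute principal curvatures from (s, theta, r).

    kappa_s by fourth-order finite differences of theta; kappa_phi as
    sin(theta)/r with the apex regularity limit kappa_phi = kappa_s at poles.
    On-axis poles are handled by parity (mirror) extension of theta, so the
    stencils see a smooth odd/even continuation instead of a boundary.
    """
    out = shape.copy()
    sp, ep = _pole_flags(out)
    if sp or ep:
        s_ext, f, n_pre = _extend(out.s, {"theta": (out.theta, "theta")}, sp, ep)
        ks_ext = fd_matrix(s_ext) @ f["theta"]
        out.kappa_s = ks_ext[n_pre:n_pre + out.n_nodes]
    else:
        out.kappa_s = fd_matrix(out.s) @ out.theta
    # pole values from a local odd polynomial fit of theta: pointwise FD at a
    # pole has O(1/ds) gain on node-level noise, which destabilizes the
    # Lagrangian apex under the mechanics feedback; the least-squares fit
    # averages over several nodes at the same formal accuracy.
    m = min(9, out.n_nodes // 4)
    if sp and m >= 3:
        x = out.s[1:m]
        A = np.column_stack([x, x ** 3])
        coef, *_ = np.linalg.lstsq(A, out.theta[1:m], rcond=None)
        out.kappa_s[0] = coef[0]
    if ep and m >= 3:
        x = out.s[-m:-1] - out.s[-1]
        A = np.column_stack([x, x ** 3])
        coef, *_ = np.linalg.lstsq(A, out.theta[-m:-1] - np.pi, rcond=None)
        out.kappa_s[-1] = coef[0]
    out.kappa_phi = _kappa_phi(out)
    return out


def make_sphere(radius: float, thickness: float, n_nodes: int = 200) -> AxisymShape:
    """Full spherical generating curve (half great circle) of given radius."""
    if radius <= 0 or thickness <= 0:
        raise GeometryError("radius and thickness must be positive")
    if n_nodes < 16:
        raise GeometryError("need at least 16 nodes")
    s = np.linspace(0.0, np.pi * radius, n_nodes)
    psi = s / radius
    r = radius * np.sin(psi)
    z = radius * np.cos(psi)
    r[0] = r[-1] = 0.0
    theta = psi
    h = np.full(n_nodes, float(thickness))
    ks = np.full(n_nodes, 1.0 / radius)
    return _finish(s, r, z, theta, h, kappa_s=ks)


def make_projection(body_radius: float, tube_radius: float, tube_length: float,
                    thickness: float, n_nodes: int = 200,
                    fillet_radius: float | None = None) -> AxisymShape:
    """Pre-grown mating-projection outline: spherical cap, cylindrical tube,
    circular fillet flaring into a spherical body, closed at the rear pole.

    theta is continuous (C¹ generating curve); kappa_s jumps at the
    piece junctions, as for any arc-spline profile.
    """
    a, Rb, L = float(tube_radius), float(body_radius), float(tube_length)
    if a <= 0 or Rb <= 0 or L < 0 or thickness <= 0:
        raise GeometryError("all dimensions must be positive")
    if a >= Rb:
        raise GeometryError("tube radius must be smaller than body radius")
    rf = a if fillet_radius is None else float(fillet_radius)
    sin_tm = (a + rf) / (Rb + rf)
    if sin_tm >= 1.0:
        raise GeometryError("fillet cannot meet the body sphere tangentially")
    theta_m = np.arcsin(sin_tm)

    s_cap = a * np.pi / 2           # hemispherical cap: theta 0 -> pi/2
    s_tube = L                      # cylinder: theta = pi/2
    s_fil = rf * (np.pi / 2 - theta_m)  # fillet: theta pi/2 -> theta_m
    s_body = Rb * (np.pi - theta_m)     # body sphere: theta theta_m -> pi
    total = s_cap + s_tube + s_fil + s_body

    def piecewise(sv: np.ndarray):
        r = np.empty_like(sv)
        z = np.empty_like(sv)
        th = np.empty_like(sv)
        ks = np.empty_like(sv)
        # running z anchors for each piece
        z_cap0 = 0.0                        # apex at z = 0
        z_tube0 = z_cap0 - a                # z at end of cap
        z_fil0 = z_tube0 - L
        z_body_c = z_fil0 - rf * np.cos(theta_m) - Rb * np.cos(theta_m) + rf * 0.0
        for i, sq in enumerate(sv):
            if sq <= s_cap:
                psi = sq / a
                th[i] = psi
                r[i] = a * np.sin(psi)
                z[i] = z_tube0 + a * np.cos(psi)
                ks[i] = 1.0 / a
            elif sq <= s_cap + s_tube:
                th[i] = np.pi / 2
                r[i] = a
                z[i] = z_tube0 - (sq - s_cap)
                ks[i] = 0.0
            elif sq <= s_cap + s_tube + s_fil:
                sig = sq - s_cap - s_tube
                psi = sig / rf                     # turned angle
                th[i] = np.pi / 2 - psi
                r[i] = a + rf * (1.0 - np.cos(psi))
                z[i] = z_fil0 - rf * np.sin(psi)
                ks[i] = -1.0 / rf
            else:
                sig = sq - s_cap - s_tube - s_fil
                th[i] = theta_m + sig / Rb
                r[i] = Rb * np.sin(th[i])
                z[i] = z_body_c + Rb * np.cos(th[i])
                ks[i] = 1.0 / Rb
        return r, z, th, ks

    s = np.linspace(0.0, total, int(n_nodes))
    r, z, theta, ks = piecewise(s)
    r[0] = r[-1] = 0.0
    theta[0], theta[-1] = 0.0, np.pi
    h = np.full(s.size, float(thickness))
    return _finish(s, r, z, theta, h, kappa_s=ks)


def surface_area(shape: AxisymShape) -> float:
    """Area of the surface of revolution, ∫ 2π r ds."""
    return float(np.trapezoid(2.0 * np.pi * shape.r, shape.s))


def enclosed_volume(shape: AxisymShape) -> float:
    """Volume enclosed by the surface, ∫ π r² sin(theta) ds."""
    return float(np.trapezoid(np.pi * shape.r ** 2 * np.sin(shape.theta), shape.s))


def wall_volume(shape: AxisymShape) -> float:
    """Total cell-wall material volume, ∫ 2π r h ds."""
    return float(np.trapezoid(2.0 * np.pi * shape.r * shape.h, shape.s))


def cell_areas(shape: AxisymShape) -> np.ndarray:
    """Surface area of the node-centered cells (half-segments at the ends).

    Segment areas use the trapezoid rule on 2πr, so ``cell_areas.sum()``
    equals ``surface_area`` to machine precision.
    """
    s, r = shape.s, shape.r
    seg = 0.5 * (r[1:] + r[:-1]) * np.diff(s) * 2.0 * np.pi
    a = np.zeros(s.size)
    a[:-1] += 0.5 * seg
    a[1:] += 0.5 * seg
    return a


def _is_simple(r: np.ndarray, z: np.ndarray) -> bool:
    try:
        from shapely.geometry import LineString
    except Exception:       # pragma: no cover - shapely is an env dependency
        return True
    return LineString(np.column_stack([r, z])).is_simple


def reparametrize(shape: AxisymShape, n_nodes: int | None = None) -> AxisymShape:
    """Redistribute nodes at uniform arclength spacing.

    The generating curve is spline-interpolated in (r, z), the arclength is
    re-measured on a dense sampling, and theta is recovered from the tangent.
    Wall thickness is interpolated and rescaled so the total wall volume
    ∫ 2π r h ds is preserved.
    """
    n = shape.n_nodes if n_nodes is None else int(n_nodes)
    s_old = shape.s
    if not _is_simple(shape.r, shape.z):
        raise GeometryError("generating curve self-intersects")
    sp, ep = _pole_flags(shape)
    s_ext, f, _ = _extend(s_old, {"r": (shape.r, "odd"), "z": (shape.z, "even"),
                                  "h": (shape.h, "even")}, sp, ep)
    cr = CubicSpline(s_ext, f["r"])
    cz = CubicSpline(s_ext, f["z"])
    ch = CubicSpline(s_ext, f["h"])
    # re-measure arclength on a dense sampling of the spline
    sd = np.linspace(0.0, s_old[-1], 8 * s_old.size)
    dr, dz = cr(sd, 1), cz(sd, 1)
    speed = np.hypot(dr, dz)
    arc = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(sd))])
    total = arc[-1]
    s_new = np.linspace(0.0, total, n)
    sd_of_arc = np.interp(s_new, arc, sd)
    r = cr(sd_of_arc)
    z = cz(sd_of_arc)
    h = ch(sd_of_arc)
    sp_d = np.hypot(cr(sd_of_arc, 1), cz(sd_of_arc, 1))
    theta = np.arctan2(-cz(sd_of_arc, 1) / sp_d, cr(sd_of_arc, 1) / sp_d)
    theta = np.where(theta < 0, theta + 2 * np.pi, theta)   # keep in [0, pi]+eps
    theta = np.clip(theta, 0.0, np.pi)
    # pole bookkeeping
    if sp:
        r[0], theta[0] = 0.0, 0.0
    if ep:
        r[-1], theta[-1] = 0.0, np.pi
    r = np.maximum(r, 0.0)
    out = _finish(s_new, r, z, theta, np.maximum(h, 1e-12))
    vol_old = wall_volume(shape)
    vol_new = wall_volume(out)
    if vol_new > 0 and vol_old > 0:
        out.h *= vol_old / vol_new
    return out


def truncation_length(lambda_A: float) -> float:
    """Arclength beyond which μ(s)/μ0 exceeds the rigid-wall cap."""
    return float(lambda_A) * np.sqrt(np.log(VISCOSITY_CAP))


def truncate(shape: AxisymShape, L_max: float) -> AxisymShape:
    """Restrict the generating curve to the active region s <= L_max.

    Far from the tip the graded viscosity makes the wall solid-like; the
    truncated domain keeps the deformable part, with the distal boundary
    treated as rigidly anchored (u = 0, h fixed).  The last node is placed
    exactly at L_max by interpolation.
    """
    if L_max >= shape.length:
        return shape.copy()
    if L_max <= 0:
        raise GeometryError("truncation length must be positive")
    keep = shape.s < L_max
    n = int(np.sum(keep))
    if n < 8:
        raise GeometryError("truncation leaves too few nodes")
    fields = {}
    for name in ("r", "z", "theta", "kappa_s", "kappa_phi", "h"):
        v = getattr(shape, name)
        fields[name] = np.concatenate([v[keep], [np.interp(L_max, shape.s, v)]])
    s = np.concatenate([shape.s[keep], [L_max]])
    return AxisymShape(s=s, **fields)
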