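"""Operator-splitting driver: stochastic polarity on a growing cell.

The molecular polarization dynamics (seconds) is far faster than wall
expansion (hours), so the coupled problem is advanced by splitting: run the
SSA for a short segment on the frozen geometry, azimuthally average the
cable counts into a density profile rho_A(s), build the wall assembly rate
G = k_s rho_A and the viscosity profile mu = mu0 exp((s - s_cap)²/λ_A²)
(λ_A re-fitted from the cable profile each segment, the soft zone centered
on the current cap), advance the mechanics by one large step dt_mech, remap
the molecule counts onto the deformed mesh by material band identity, and
continue the SSA with the new frozen strain-rate field.

Because dt_mech may greatly exceed the SSA segment length (the profile
statistics equilibrate in seconds while the shape is quasi-static), hours
of growth are simulated with seconds of biochemical sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .continuum import (_filtered_fields, _mechanics_transport, _stability_dt,
                        ContinuumConfig)
from .geometry import AxisymShape, make_sphere
from .metrics import cap_position
from .polarity import PolarityFields
from .stochastic import (SpeciesState, StochasticRates, SurfaceMesh,
                         band_average, build_surface_mesh, initial_state,
                         ssa_run)
from .wall_mechanics import MechanicsParams, solve_wall_fields, viscosity_profile

__all__ = ["CouplingConfig", "LambdaFit", "NoActinError", "azimuthal_average",
           "fit_lambda_A", "growth_step", "remap_counts",
           "run_coupled_stochastic", "recenter_on_cap", "CoupledTrajectory"]


class NoActinError(RuntimeError):
    """All-zero actin profile: growth is arrested."""


@dataclass
class LambdaFit:
    lambda_A: float
    amplitude: float
    center: float
    used_fallback: bool = False

    def __float__(self):
        return float(self.lambda_A)


@dataclass
class CouplingConfig:
    """Splitting cadence and run settings for the coupled simulation.

    dt_mech : mechanics step (s); may be much larger than t_ssa_per_step.
    t_ssa_per_step : SSA duration per mechanics step (s); long enough for
        the profile statistics to track the slowly moving geometry.
    t_polarize : initial SSA phase on the static sphere during which the
        cap forms by spontaneous symmetry breaking (the axis is then
        re-centered on the cap).
    """

    # k_s here is per molecules/μm² of cables (the stochastic density scale),
    # calibrated so assembly balances tip expansion at a typical cap density.
    mechanics: MechanicsParams = field(
        default_factory=lambda: MechanicsParams(k_s=7.0e-8))
    rates: StochasticRates = field(default_factory=lambda: StochasticRates(A_CWI=2.0e6))
    n_cdc42: int = 400
    n_actin: int = 120
    radius: float = 2.0
    thickness: float = 0.1
    Ns: int = 16
    Nphi: int = 8
    n_nodes: int = 120
    dt_mech: float = 50.0
    t_ssa_per_step: float = 50.0
    n_steps: int = 120
    t_polarize: float = 10.0       # cap equilibration (tip_cap) or SSB phase
    init: str = "tip_cap"          # "tip_cap" | "uniform" (spontaneous SSB)
    averaging_snapshots: int = 5
    lambda_min: float = 0.25
    lambda_max: float = 2.0
    filter_sigma: float = 1.5


def azimuthal_average(state: SpeciesState, mesh: SurfaceMesh):
    """Rotationally collapsed band densities of Cdc42 and cables.

    Returns (s, rho_cdc42, rho_cables) with densities in molecules/μm²;
    band density is (sum of counts)/(sum of patch areas), so the total
    molecule number is recovered by sum(density * band_area).
    """
    s, rho_c = band_average(mesh, state.n_GDP + state.n_GTP)
    _, rho_a = band_average(mesh, state.n_cable)
    return s, rho_c, rho_a


def fit_lambda_A(s, rho_A, s_cut: float | None = None,
                 center: float | None = None) -> LambdaFit:
    """Decay length of the actin-cable density from its peak.

    Least-squares fit of a * exp(-(s - s0)²/λ²) over s <= s_cut (default:
    down to 5% of the peak).  Falls back to the half-maximum width divided
    by sqrt(ln 2) if the fit fails to converge.  Raises NoActinError on an
    all-zero profile.
    """
    s = np.asarray(s, float)
    y = np.asarray(rho_A, float)
    if not np.any(y > 0):
        raise NoActinError("actin-cable profile is identically zero")
    if center is None:
        # locate the peak on a smoothed copy (noise shifts the raw argmax and
        # would bias the fitted width); snap to the tip when the peak sits
        # within one sample of it
        ds = float(np.median(np.diff(s))) if s.size > 1 else 1.0
        s0 = cap_position(s, y, smoothing_width=2 * ds)
        if s0 <= s[0] + 1.5 * ds:
            s0 = s[0]
    else:
        s0 = float(center)
    peak = float(np.max(y))
    if s_cut is None:
        above = np.where(y >= 0.05 * peak)[0]
        s_cut = s[above[-1]] if above.size else s[-1]
    sel = s <= max(s_cut, s0 + np.median(np.diff(s)) if s.size > 1 else s_cut)
    try:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda x, a, lam: a * np.exp(-((x - s0) / lam) ** 2),
                s[sel], y[sel],
                p0=[peak, max(0.3 * (s[sel][-1] - s0 + 1e-6), 1e-3)],
                maxfev=2000)
        lam = abs(float(popt[1]))
        if not np.isfinite(lam) or lam <= 0 or lam > (s[-1] - s[0]):
            raise RuntimeError("fit diverged")     # flat/degenerate profile
        return LambdaFit(lam, float(popt[0]), s0)
    except Exception:
        half = np.where(y >= 0.5 * peak)[0]
        width = (s[half[-1]] - s0) if half.size else float(np.median(np.diff(s)))
        lam = max(abs(width), float(np.median(np.diff(s)))) / np.sqrt(np.log(2.0))
        return LambdaFit(lam, peak, s0, used_fallback=True)


def _coupled_fields(shape: AxisymShape, rho_A_nodes, mech: MechanicsParams,
                    lam: float, center: float, filter_sigma: float):
    from scipy.ndimage import gaussian_filter1d
    mu = viscosity_profile(shape.s, mech.mu0, lam, center=center)
    wf = solve_wall_fields(shape, mech, rho_A=rho_A_nodes, mu=mu)
    if filter_sigma > 0:
        wf.u = gaussian_filter1d(wf.u, filter_sigma)
        wf.v_n = gaussian_filter1d(wf.v_n, filter_sigma, mode="nearest")
    return wf


def growth_step(shape: AxisymShape, rho_A_profile, mech_params: MechanicsParams,
                dt_mech: float, lambda_bounds=(0.25, 2.0),
                filter_sigma: float = 1.5, center: float | None = None):
    """One mechanics step driven by an averaged cable-density profile.

    rho_A_profile is (s_bands, rho_A).  Builds G = k_s rho_A and the
    cap-centered viscosity profile with λ_A fitted from the profile, then
    advances tensions -> strain rates -> velocities -> shape + thickness.
    Returns (new_shape, strain_field, info) where strain_field is
    (band s, eps_s+eps_phi) for the next SSA segment and info carries the
    λ fit and the material positions of the old nodes.

    ``center`` fixes the soft-zone center (0 for the tip-anchored profile of
    the feedback regime); by default it sits at the cable-profile peak.

    With no actin anywhere, growth is arrested: the shape is returned
    unchanged and the strain field is zero.
    """
    s_b = np.asarray(rho_A_profile[0], float)
    rho_b = np.asarray(rho_A_profile[1], float)
    try:
        fit = fit_lambda_A(s_b, rho_b)
    except NoActinError:
        zero = np.zeros_like(s_b)
        return shape.copy(), (s_b, zero), {
            "lambda_fit": None, "arrested": True, "material_s": shape.s.copy()}
    lam = float(np.clip(fit.lambda_A, *lambda_bounds))
    if center is None:
        center = fit.center

    def fields_fn(sh, ra):
        return _coupled_fields(sh, ra, mech_params, lam, center, filter_sigma)

    cfg = ContinuumConfig(mechanics=mech_params, filter_sigma=filter_sigma)
    # substep the mechanics below the explicit stability limit of the
    # grid-scale interface mode; the cable profile stays frozen throughout.
    pos = shape.s.copy()                # material positions of the old nodes
    remaining = float(dt_mech)
    tip_v = None
    audit = None
    while remaining > 1e-12:
        rho_nodes = np.interp(shape.s, s_b, rho_b)
        wf = fields_fn(shape, rho_nodes)
        if tip_v is None:
            tip_v = float(wf.v_n[0])
        dt = min(remaining,
                 _stability_dt(shape, wf.mu, mech_params.P, filter_sigma),
                 0.5 * np.median(np.diff(shape.s)) / max(np.max(np.abs(wf.u)), 1e-300),
                 0.05 / max(np.max(np.abs(wf.expansion_rate)), 1e-300))
        pol = PolarityFields(np.zeros(shape.n_nodes), rho_nodes)  # rho_A carrier
        new, _, audit = _mechanics_transport(shape, pol, wf, cfg, dt,
                                             fields_fn=fields_fn)
        pos = np.interp(pos, shape.s, audit["material_s"])
        shape = new
        remaining -= dt
    wf_new = fields_fn(shape, np.interp(shape.s, s_b, rho_b))
    eps_bands = np.interp(s_b, shape.s, wf_new.expansion_rate)
    info = {"lambda_fit": fit, "lambda_used": lam, "center": center,
            "arrested": False, "material_s": pos,
            "wall_audit": audit, "tip_v": tip_v}
    return shape, (s_b, eps_bands), info


def remap_counts(old_mesh: SurfaceMesh, new_mesh: SurfaceMesh,
                 state: SpeciesState, material_s=None) -> SpeciesState:
    """Carry membrane counts band-to-band by material identity.

    ``material_s`` maps old arclength to post-growth arclength (pairs of
    arrays, e.g. old node positions and their moved positions); identity if
    omitted.  Each old band's counts land in the new band containing its
    material midpoint (ties toward the tip); cytosol pools are untouched.
    Per-species totals are conserved exactly.
    """
    if (old_mesh.n_bands != new_mesh.n_bands
            or old_mesh.n_phi != new_mesh.n_phi
            or old_mesh.n_patches != new_mesh.n_patches):
        raise ValueError("meshes must share band/azimuth topology")
    if material_s is None:
        s_new_of_band = old_mesh.band_s
    else:
        s_old_nodes, s_moved = material_s
        s_new_of_band = np.interp(old_mesh.band_s, s_old_nodes, s_moved)
    edges = np.linspace(0.0, new_mesh.band_s[-1] + 0.5 *
                        (new_mesh.band_s[-1] - new_mesh.band_s[-2]),
                        new_mesh.n_bands + 1)
    band_map = np.clip(np.searchsorted(edges, s_new_of_band, side="left") - 1,
                       0, new_mesh.n_bands - 1)

    out = SpeciesState(np.zeros(new_mesh.n_patches, dtype=np.int64),
                       np.zeros(new_mesh.n_patches, dtype=np.int64),
                       np.zeros(new_mesh.n_patches, dtype=np.int64),
                       int(state.N_cyt), int(state.N_mono))

    def patches_of(mesh, band):
        return np.where(mesh.band_of == band)[0]

    for i_old in range(old_mesh.n_bands):
        i_new = int(band_map[i_old])
        p_old = patches_of(old_mesh, i_old)
        p_new = patches_of(new_mesh, i_new)
        if p_old.size == p_new.size:
            pairs = zip(p_old, p_new)
        elif p_new.size == 1:               # collapse into a polar patch
            pairs = ((p, p_new[0]) for p in p_old)
        else:                               # polar patch spreading to a ring:
            pairs = ((p_old[0], p_new[0]),)  # keep counts in one azimuth cell
        for po, pn in pairs:
            out.n_GDP[pn] += state.n_GDP[po]
            out.n_GTP[pn] += state.n_GTP[po]
            out.n_cable[pn] += state.n_cable[po]
    return out


def recenter_on_cap(mesh: SurfaceMesh, state: SpeciesState, radius: float,
                    weight: str = "n_GTP") -> SpeciesState:
    """Rotate a spherical-geometry state so the cap sits at the apex.

    After spontaneous symmetry breaking on the sphere the cap points in a
    random direction; the axisymmetric growth description assumes it at
    s = 0.  Counts move to the patch containing their rotated centroid,
    conserving totals exactly.  Only meaningful on a sphere.
    """
    w = getattr(state, weight).astype(float)
    if w.sum() == 0:
        w = (state.n_GDP + state.n_GTP).astype(float)
    psi = mesh.s_mid / radius
    vec = np.column_stack([np.sin(psi) * np.cos(mesh.phi_mid),
                           np.sin(psi) * np.sin(mesh.phi_mid),
                           np.cos(psi)])
    direction = (w / max(w.sum(), 1.0)) @ vec
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        return state.copy()
    zhat = direction / nrm
    # rotation taking zhat -> (0,0,1)
    axis = np.cross(zhat, [0.0, 0.0, 1.0])
    sin_a = np.linalg.norm(axis)
    cos_a = zhat[2]
    if sin_a < 1e-12:
        R = np.eye(3) if cos_a > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        k = axis / sin_a
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + sin_a * K + (1 - cos_a) * (K @ K)
    rot = vec @ R.T
    psi_new = np.arccos(np.clip(rot[:, 2], -1.0, 1.0))
    phi_new = np.arctan2(rot[:, 1], rot[:, 0]) % (2 * np.pi)
    s_new = psi_new * radius

    L = mesh.band_s[-1] + 0.5 * (mesh.band_s[-1] - mesh.band_s[-2])
    band_new = np.clip((s_new / (L / mesh.n_bands)).astype(int), 0, mesh.n_bands - 1)
    out = SpeciesState(np.zeros_like(state.n_GDP), np.zeros_like(state.n_GTP),
                       np.zeros_like(state.n_cable), int(state.N_cyt),
                       int(state.N_mono))
    polar = np.array([np.sum(mesh.band_of == i) == 1 for i in range(mesh.n_bands)])
    for p in range(mesh.n_patches):
        b = band_new[p]
        if polar[b]:
            q = int(np.where(mesh.band_of == b)[0][0])
        else:
            j = int(phi_new[p] / (2 * np.pi) * mesh.n_phi) % mesh.n_phi
            q = int(np.where(mesh.band_of == b)[0][j])
        out.n_GDP[q] += state.n_GDP[p]
        out.n_GTP[q] += state.n_GTP[p]
        out.n_cable[q] += state.n_cable[p]
    return out


@dataclass
class CoupledTrajectory:
    times: list = field(default_factory=list)
    tip_z: list = field(default_factory=list)
    cap_position: list = field(default_factory=list)
    polarization_index: list = field(default_factory=list)
    lambda_A: list = field(default_factory=list)
    shapes: list = field(default_factory=list)
    profiles: list = field(default_factory=list)    # (s, rho_cdc42, rho_cables)
    final_state: SpeciesState | None = None
    final_mesh: SurfaceMesh | None = None


def _segment_seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(x % (2 ** 31)) for x in ss.generate_state(n, dtype=np.uint64)]


def _index_on_mesh(mesh: SurfaceMesh, counts, window: float, cap: float) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    mask = np.abs(mesh.s_mid - cap) <= window
    f_win = counts[mask].sum() / total
    f_uni = mesh.area[mask].sum() / mesh.total_area
    return max(0.0, (f_win - f_uni) / (1.0 - f_uni)) if f_uni < 1 else 0.0


def run_coupled_stochastic(config: CouplingConfig, seed: int,
                           grow: bool = True) -> CoupledTrajectory:
    """Full coupled run: polarize on the sphere, re-center the axis on the
    emergent cap, then alternate SSA segments with mechanics steps.

    With ``grow=False`` the geometry is frozen (dt_mech effectively
    infinite) and the run reduces to a fixed-geometry experiment with the
    same seed chain.  Deterministic for fixed config and seed.
    """
    cfg = config
    shape = make_sphere(cfg.radius, cfg.thickness, cfg.n_nodes)
    mesh = build_surface_mesh(shape, cfg.Ns, cfg.Nphi, D_mem=cfg.rates.D_mem)
    seeds = _segment_seeds(seed, cfg.n_steps + 2)
    traj = CoupledTrajectory()

    # phase 1: establish the cap on the static sphere.  "uniform" relies on
    # spontaneous symmetry breaking (viable at full copy numbers) and then
    # re-centers the axis on the emergent cap; "tip_cap" starts from a
    # pre-formed cap at the apex and briefly equilibrates it.
    state = initial_state(mesh, cfg.n_cdc42, cfg.n_actin, cfg.init, seeds[0])
    tr = ssa_run(state, mesh, replace(cfg.rates, A_CWI=0.0),
                 max(cfg.t_polarize, 1e-6), seeds[1],
                 snapshot_times=np.array([max(cfg.t_polarize, 1e-6)]))
    if cfg.init == "uniform":
        state = recenter_on_cap(mesh, tr.final_state, cfg.radius)
    else:
        state = tr.final_state

    t = cfg.t_polarize
    # initial strain field of the starting shape, so the CWI channel is live
    # from the first segment (the wall is already under turgor at t = 0)
    strain = None
    if grow and cfg.rates.A_CWI > 0:
        s_b0, _, rho_a0 = azimuthal_average(state, mesh)
        if np.any(rho_a0 > 0):
            _, strain, _ = growth_step(
                shape, (s_b0, rho_a0), cfg.mechanics, 0.0,
                lambda_bounds=(cfg.lambda_min, cfg.lambda_max),
                filter_sigma=cfg.filter_sigma, center=0.0)
    tip_z0 = float(shape.z[0])
    z_far0 = float(shape.z[-1])
    window = 1.0
    # Soft-zone center: tip-anchored in the feedback regime (CWI nucleation
    # keeps delivery at the tip, the regime of the tip-centered viscosity
    # profile); without feedback it tracks the wandering cap (exponentially
    # smoothed, since wall properties respond to time-integrated delivery).
    feedback_on = cfg.rates.A_CWI > 0
    center_ema = 0.0
    for k in range(cfg.n_steps):
        snap = np.linspace(0, cfg.t_ssa_per_step, cfg.averaging_snapshots + 1)[1:]
        tr = ssa_run(state, mesh, cfg.rates, cfg.t_ssa_per_step, seeds[k + 2],
                     strain_field=strain, snapshot_times=snap)
        state = tr.final_state
        # time + azimuthal average of the segment for the mechanics input
        rho_a = np.zeros(mesh.n_bands)
        rho_c = np.zeros(mesh.n_bands)
        for i in range(snap.size):
            _, dc = band_average(mesh, tr.n_GDP[i] + tr.n_GTP[i])
            _, da = band_average(mesh, tr.n_cable[i])
            rho_a += da / snap.size
            rho_c += dc / snap.size
        s_b = mesh.band_s
        cap = cap_position(s_b, rho_c, smoothing_width=s_b[1] - s_b[0])
        idx = _index_on_mesh(mesh, state.n_GDP + state.n_GTP, window,
                             cap if np.isfinite(cap) else 0.0)
        lam_rec = np.nan
        if grow:
            if feedback_on:
                center = 0.0
            else:
                cap_a = cap_position(s_b, rho_a, smoothing_width=s_b[1] - s_b[0])
                if np.isfinite(cap_a):
                    center_ema = 0.7 * center_ema + 0.3 * cap_a
                center = center_ema
            new_shape, strain, info = growth_step(
                shape, (s_b, rho_a), cfg.mechanics, cfg.dt_mech,
                lambda_bounds=(cfg.lambda_min, cfg.lambda_max),
                filter_sigma=cfg.filter_sigma, center=center)
            if not info["arrested"]:
                lam_rec = info["lambda_used"]
                new_mesh = build_surface_mesh(new_shape, cfg.Ns, cfg.Nphi,
                                              D_mem=cfg.rates.D_mem)
                state = remap_counts(mesh, new_mesh, state,
                                     material_s=(shape.s, info["material_s"]))
                shape, mesh = new_shape, new_mesh
            t += cfg.dt_mech
        else:
            t += cfg.t_ssa_per_step
        traj.times.append(t)
        # tip displacement relative to the (rigid) distal pole
        traj.tip_z.append((float(shape.z[0]) - float(shape.z[-1]))
                          - (tip_z0 - z_far0))
        traj.cap_position.append(float(cap))
        traj.polarization_index.append(float(idx))
        traj.lambda_A.append(float(lam_rec))
        if k % max(cfg.n_steps // 10, 1) == 0 or k == cfg.n_steps - 1:
            traj.shapes.append(shape.copy())
            traj.profiles.append((s_b.copy(), rho_c.copy(), rho_a.copy()))
    traj.final_state = state
    traj.final_mesh = mesh
    return traj
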