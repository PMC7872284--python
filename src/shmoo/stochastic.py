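"""Spatial stochastic (reaction-diffusion master equation) polarity model.

Four species on a structured axisymmetric surface mesh: membrane Cdc42-GDP
and Cdc42-GTP, membrane actin cables, plus well-mixed cytosolic pools of
Cdc42-GDP and actin monomers.  Reactions per membrane patch (area A_p,
cytosol volume V):

    R1  direct binding        beta2 (A_p/V) N_cyt            -> GDP_p
    R2  actin delivery        beta1 n_cab N_cyt / V          -> GDP_p
    R3  dissociation          beta3 n_GDP                    -> cytosol
    R4  activation            k_act n_GDP n_GTP / A_p        GDP -> GTP
    R5  inactivation          k_inact n_GTP                  GTP -> GDP
    R6a cable nucleation      A_on n_GTP N_mono / V          monomer -> cable
    R6b CWI nucleation        A_CWI max(eps, 0) N_mono A_p/A_tot
    R7  cable disassembly     A_off n_cab                    cable -> monomer
    D   hops of membrane Cdc42 (GDP and GTP) to each neighbor at D_mem/l².

R4 is autocatalytic (GTP-assisted activation), giving the positive feedback
required for spontaneous symmetry breaking; R6b is the mechanical-feedback
channel, driven by the local wall expansion rate eps = eps_s + eps_phi.

Sampling is a statistically exact direct-method SSA over all patches and
channels, with the cytosol-proportional channels factored so that pool
updates are O(1); the event loop is compiled with numba when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AxisymShape, enclosed_volume

try:                                    # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:                     # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = ["StochasticRates", "SurfaceMesh", "SpeciesState", "StochasticTrajectory",
           "build_surface_mesh", "single_patch_mesh", "propensities", "ssa_run",
           "initial_state", "run_fixed_geometry_experiment", "band_average",
           "cap_azimuth"]


@dataclass
class StochasticRates:
    """Kinetic constants of the stochastic polarity network.

    The printed literature values: beta2 = 0.28 μm/s, beta3 = 1/s,
    activation 0.2 μm²/s, inactivation 1/s, A_on = 0.197 μm³/s,
    A_off = 2.70 1/s, membrane diffusion 0.0053 μm²/s.  beta1 (actin-mediated
    delivery) is a declared assumption: its default makes cable delivery at a
    polarized cap dominate direct binding by an order of magnitude, the
    regime in which the limited cytosolic pool drives winner-take-all cap
    formation.  A_CWI = 0 disables the mechanical-feedback channel.
    """

    beta1: float = 0.05
    beta2: float = 0.28
    beta3: float = 1.0
    k_act: float = 0.2
    k_inact: float = 1.0
    A_on: float = 0.197
    A_off: float = 2.70
    D_mem: float = 0.0053
    A_CWI: float = 0.0

    def __post_init__(self):
        for name in ("beta1", "beta2", "beta3", "k_act", "k_inact",
                     "A_on", "A_off", "D_mem", "A_CWI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SurfaceMesh:
    """Structured (arclength band x azimuth) membrane patches.

    Pole bands collapse to a single on-axis patch, so interior patches have
    4 neighbors and polar patches Nphi.  Adjacency is CSR-encoded with a
    per-directed-edge hop rate D_mem/l² per molecule.
    """

    area: np.ndarray            # patch areas (μm²)
    s_mid: np.ndarray           # band-midpoint arclength per patch
    phi_mid: np.ndarray         # azimuthal midpoint per patch (rad)
    band_of: np.ndarray         # band index per patch
    nbr_ptr: np.ndarray
    nbr_idx: np.ndarray
    hop: np.ndarray             # D_mem / l_edge² per directed edge
    n_bands: int
    n_phi: int
    band_s: np.ndarray          # band midpoint arclength (n_bands)
    band_area: np.ndarray       # total band area (n_bands)
    cytosol_volume: float

    @property
    def n_patches(self) -> int:
        return self.area.size

    @property
    def total_area(self) -> float:
        return float(self.area.sum())


@dataclass
class SpeciesState:
    """Integer molecule counts per patch plus cytosolic pools."""

    n_GDP: np.ndarray
    n_GTP: np.ndarray
    n_cable: np.ndarray
    N_cyt: int
    N_mono: int

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.n_GDP.copy(), self.n_GTP.copy(),
                            self.n_cable.copy(), int(self.N_cyt), int(self.N_mono))

    @property
    def total_cdc42(self) -> int:
        return int(self.n_GDP.sum() + self.n_GTP.sum() + self.N_cyt)

    @property
    def total_actin(self) -> int:
        return int(self.n_cable.sum() + self.N_mono)

    def validate(self):
        for arr in (self.n_GDP, self.n_GTP, self.n_cable):
            if np.any(arr < 0):
                raise ValueError("negative molecule count")
        if self.N_cyt < 0 or self.N_mono < 0:
            raise ValueError("negative pool count")


@dataclass
class StochasticTrajectory:
    times: np.ndarray
    n_GDP: np.ndarray           # (n_snap, n_patches)
    n_GTP: np.ndarray
    n_cable: np.ndarray
    N_cyt: np.ndarray
    N_mono: np.ndarray
    final_state: SpeciesState
    seed: int


def build_surface_mesh(shape: AxisymShape, Ns: int, Nphi: int,
                       cytosol_volume: float | None = None,
                       D_mem: float = 0.0053) -> SurfaceMesh:
    """Equal-arclength bands, each split into Nphi equal-area patches.

    Band areas integrate 2*pi*r ds on the shape's own grid, so the total
    patch area equals the surface-of-revolution area independent of (Ns,
    Nphi).  Bands whose inner edge touches an on-axis pole become single
    polar patches.
    """
    if Ns < 4 or Nphi < 4:
        raise ValueError("need Ns, Nphi >= 4")
    s, r = shape.s, shape.r
    if shape.length <= 0 or np.all(r == 0):
        raise ValueError("degenerate shape")
    # cumulative area on the fine shape grid
    seg = 0.5 * (r[1:] + r[:-1]) * np.diff(s) * 2.0 * np.pi
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    edges = np.linspace(0.0, shape.length, Ns + 1)
    cum_e = np.interp(edges, s, cum)
    band_area = np.diff(cum_e)
    band_s = 0.5 * (edges[1:] + edges[:-1])
    # band centroid radius for azimuthal hop lengths
    r_bar = band_area / (2.0 * np.pi * np.diff(edges))

    start_pole = r[0] <= 1e-9 * max(1.0, r.max())
    end_pole = r[-1] <= 1e-9 * max(1.0, r.max())
    polar = [start_pole] + [False] * (Ns - 2) + [end_pole]

    areas, s_mid, phi_mid, band_of = [], [], [], []
    index = {}
    for i in range(Ns):
        if polar[i]:
            index[i] = [len(areas)]
            areas.append(band_area[i])
            s_mid.append(band_s[i])
            phi_mid.append(0.0)
            band_of.append(i)
        else:
            index[i] = list(range(len(areas), len(areas) + Nphi))
            for j in range(Nphi):
                areas.append(band_area[i] / Nphi)
                s_mid.append(band_s[i])
                phi_mid.append(2.0 * np.pi * (j + 0.5) / Nphi)
                band_of.append(i)

    npatch = len(areas)
    nbrs = [[] for _ in range(npatch)]
    hops = [[] for _ in range(npatch)]
    ds_band = np.diff(band_s)

    def link(p, q, length):
        nbrs[p].append(q)
        hops[p].append(D_mem / length ** 2)

    for i in range(Ns):
        pi = index[i]
        if not polar[i]:
            lphi = max(2.0 * np.pi * r_bar[i] / Nphi, 1e-9)
            for j in range(Nphi):
                link(pi[j], pi[(j + 1) % Nphi], lphi)
                link(pi[j], pi[(j - 1) % Nphi], lphi)
        if i + 1 < Ns:
            pj = index[i + 1]
            ell = max(ds_band[i], 1e-9)
            if polar[i] and not polar[i + 1]:
                for q in pj:
                    link(pi[0], q, ell)
                    link(q, pi[0], ell)
            elif polar[i + 1] and not polar[i]:
                for q in pi:
                    link(q, pj[0], ell)
                    link(pj[0], q, ell)
            elif not polar[i] and not polar[i + 1]:
                for j in range(Nphi):
                    link(pi[j], pj[j], ell)
                    link(pj[j], pi[j], ell)
            else:                           # two adjacent polar bands
                link(pi[0], pj[0], ell)
                link(pj[0], pi[0], ell)

    nbr_ptr = np.zeros(npatch + 1, dtype=np.int64)
    for p in range(npatch):
        nbr_ptr[p + 1] = nbr_ptr[p] + len(nbrs[p])
    nbr_idx = np.array([q for lst in nbrs for q in lst], dtype=np.int64)
    hop = np.array([h for lst in hops for h in lst], dtype=np.float64)

    V = cytosol_volume if cytosol_volume is not None else enclosed_volume(shape)
    return SurfaceMesh(np.array(areas), np.array(s_mid), np.array(phi_mid),
                       np.array(band_of, dtype=np.int64), nbr_ptr, nbr_idx, hop,
                       Ns, Nphi, band_s, band_area, float(V))


def single_patch_mesh(area: float, cytosol_volume: float) -> SurfaceMesh:
    """Well-mixed limit: one membrane patch, no diffusion (test oracle use)."""
    one = np.array([0], dtype=np.int64)
    return SurfaceMesh(np.array([float(area)]), np.array([0.0]), np.array([0.0]),
                       one.copy(), np.array([0, 0], dtype=np.int64),
                       np.empty(0, dtype=np.int64), np.empty(0),
                       1, 1, np.array([0.0]), np.array([float(area)]),
                       float(cytosol_volume))


def _strain_per_patch(mesh: SurfaceMesh, strain_field) -> np.ndarray:
    """Positive part of eps_s + eps_phi sampled at each patch's band midpoint."""
    if strain_field is None:
        return np.zeros(mesh.n_patches)
    s_f, eps = strain_field
    eps_band = np.interp(mesh.band_s, np.asarray(s_f, float), np.asarray(eps, float))
    return np.maximum(eps_band[mesh.band_of], 0.0)


def propensities(state: SpeciesState, mesh: SurfaceMesh, rates: StochasticRates,
                 strain_field=None):
    """Per-patch reaction propensities and per-edge hop propensities.

    Returns a dict with 'reactions' of shape (n_patches, 8) in the order
    [R1, R2, R3, R4, R5, R6a, R6b, R7], plus 'hop_GDP' and 'hop_GTP' per
    directed edge.
    """
    state.validate()
    V = mesh.cytosol_volume
    A = mesh.area
    eps = _strain_per_patch(mesh, strain_field)
    R = np.empty((mesh.n_patches, 8))
    R[:, 0] = rates.beta2 * (A / V) * state.N_cyt
    R[:, 1] = rates.beta1 * state.n_cable * state.N_cyt / V
    R[:, 2] = rates.beta3 * state.n_GDP
    R[:, 3] = rates.k_act * state.n_GDP * state.n_GTP / A
    R[:, 4] = rates.k_inact * state.n_GTP
    R[:, 5] = rates.A_on * state.n_GTP * state.N_mono / V
    R[:, 6] = rates.A_CWI * eps * state.N_mono * (A / mesh.total_area)
    R[:, 7] = rates.A_off * state.n_cable
    src = np.repeat(np.arange(mesh.n_patches), np.diff(mesh.nbr_ptr))
    return {
        "reactions": R,
        "hop_GDP": mesh.hop * state.n_GDP[src],
        "hop_GTP": mesh.hop * state.n_GTP[src],
    }


@njit(cache=True)
def _ssa_core(n_gdp, n_gtp, n_cab, pools, area, Vcyt, c6b,
              beta1, beta2, beta3, k_act, k_inact, A_on, A_off,
              nbr_ptr, nbr_idx, hop, hsum, t0, snap_times,
              out_gdp, out_gtp, out_cab, out_cyt, out_mono, seed):
    np.random.seed(seed)
    n = area.size
    b2V = beta2 / Vcyt
    b1V = beta1 / Vcyt
    aonV = A_on / Vcyt

    c1 = np.empty(n)
    gN = np.empty(n)
    gM = np.empty(n)
    loc = np.empty(n)
    for p in range(n):
        c1[p] = b2V * area[p]

    def _loc(p):
        return (beta3 * n_gdp[p] + k_act * n_gdp[p] * n_gtp[p] / area[p]
                + k_inact * n_gtp[p] + A_off * n_cab[p]
                + (n_gdp[p] + n_gtp[p]) * hsum[p])

    SN = 0.0
    SM = 0.0
    SL = 0.0
    for p in range(n):
        gN[p] = c1[p] + b1V * n_cab[p]
        gM[p] = aonV * n_gtp[p] + c6b[p]
        loc[p] = _loc(p)
        SN += gN[p]
        SM += gM[p]
        SL += loc[p]

    t = t0
    k = 0
    K = snap_times.size
    events = 0
    while True:
        if events % 4096 == 0:      # refresh running sums against FP drift
            SN = 0.0
            SM = 0.0
            SL = 0.0
            for p in range(n):
                SN += gN[p]
                SM += gM[p]
                SL += loc[p]
        a0 = pools[0] * SN + pools[1] * SM + SL
        if a0 <= 0.0:
            while k < K:
                for p in range(n):
                    out_gdp[k, p] = n_gdp[p]
                    out_gtp[k, p] = n_gtp[p]
                    out_cab[k, p] = n_cab[p]
                out_cyt[k] = pools[0]
                out_mono[k] = pools[1]
                k += 1
            break
        tnew = t - np.log(np.random.random()) / a0
        while k < K and snap_times[k] <= tnew:
            for p in range(n):
                out_gdp[k, p] = n_gdp[p]
                out_gtp[k, p] = n_gtp[p]
                out_cab[k, p] = n_cab[p]
            out_cyt[k] = pools[0]
            out_mono[k] = pools[1]
            k += 1
        if k >= K:
            break
        t = tnew
        events += 1

        x = np.random.random() * a0
        if x < pools[0] * SN:                   # membrane binding (R1/R2)
            y = x / pools[0]
            p = 0
            acc = gN[0]
            while acc < y and p < n - 1:
                p += 1
                acc += gN[p]
            pools[0] -= 1
            n_gdp[p] += 1
            dl = _loc(p) - loc[p]
            loc[p] += dl
            SL += dl
        elif x < pools[0] * SN + pools[1] * SM:  # cable nucleation (R6a/R6b)
            y = (x - pools[0] * SN) / pools[1]
            p = 0
            acc = gM[0]
            while acc < y and p < n - 1:
                p += 1
                acc += gM[p]
            pools[1] -= 1
            n_cab[p] += 1
            dg = b1V
            gN[p] += dg
            SN += dg
            dl = _loc(p) - loc[p]
            loc[p] += dl
            SL += dl
        else:                                   # local membrane channels
            y = x - pools[0] * SN - pools[1] * SM
            p = 0
            acc = loc[0]
            while acc < y and p < n - 1:
                p += 1
                acc += loc[p]
            y -= acc - loc[p]                   # offset within patch p
            a_r3 = beta3 * n_gdp[p]
            a_r4 = k_act * n_gdp[p] * n_gtp[p] / area[p]
            a_r5 = k_inact * n_gtp[p]
            a_r7 = A_off * n_cab[p]
            q = -1
            if y < a_r3:                        # dissociation
                n_gdp[p] -= 1
                pools[0] += 1
            elif y < a_r3 + a_r4:               # activation
                n_gdp[p] -= 1
                n_gtp[p] += 1
            elif y < a_r3 + a_r4 + a_r5:        # inactivation
                n_gtp[p] -= 1
                n_gdp[p] += 1
            elif y < a_r3 + a_r4 + a_r5 + a_r7:  # disassembly
                n_cab[p] -= 1
                pools[1] += 1
                gN[p] -= b1V
                SN -= b1V
            else:                               # diffusion hop
                y -= a_r3 + a_r4 + a_r5 + a_r7
                gdp_hop = n_gdp[p] * hsum[p]
                if y < gdp_hop:
                    species = 0
                    y2 = y / max(n_gdp[p], 1)
                else:
                    species = 1
                    y2 = (y - gdp_hop) / max(n_gtp[p], 1)
                e = nbr_ptr[p]
                acc2 = hop[e]
                while acc2 < y2 and e < nbr_ptr[p + 1] - 1:
                    e += 1
                    acc2 += hop[e]
                q = nbr_idx[e]
                if species == 0:
                    n_gdp[p] -= 1
                    n_gdp[q] += 1
                else:
                    n_gtp[p] -= 1
                    n_gtp[q] += 1
                dgM = aonV * n_gtp[q] + c6b[q] - gM[q]
                gM[q] += dgM
                SM += dgM
                dl = _loc(q) - loc[q]
                loc[q] += dl
                SL += dl
            dgM = aonV * n_gtp[p] + c6b[p] - gM[p]
            gM[p] += dgM
            SM += dgM
            dl = _loc(p) - loc[p]
            loc[p] += dl
            SL += dl
    return t


def ssa_run(state0: SpeciesState, mesh: SurfaceMesh, rates: StochasticRates,
            t_end: float, seed: int, strain_field=None,
            snapshot_times=None, t0: float = 0.0) -> StochasticTrajectory:
    """Exact SSA sample of the surface RDME; bit-reproducible per seed.

    ``strain_field`` is an optional (s, eps_s+eps_phi) pair feeding the CWI
    nucleation channel; ``snapshot_times`` defaults to 20 evenly spaced
    times ending at t_end.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    state0.validate()
    if snapshot_times is None:
        snapshot_times = np.linspace(t0, t_end, 21)[1:]
    snap = np.asarray(snapshot_times, dtype=np.float64)
    K = snap.size
    n = mesh.n_patches
    n_gdp = state0.n_GDP.astype(np.int64).copy()
    n_gtp = state0.n_GTP.astype(np.int64).copy()
    n_cab = state0.n_cable.astype(np.int64).copy()
    pools = np.array([state0.N_cyt, state0.N_mono], dtype=np.int64)
    eps = _strain_per_patch(mesh, strain_field)
    c6b = rates.A_CWI * eps * mesh.area / mesh.total_area
    hsum = np.zeros(n)
    for p in range(n):
        hsum[p] = mesh.hop[mesh.nbr_ptr[p]:mesh.nbr_ptr[p + 1]].sum()
    out_gdp = np.zeros((K, n), dtype=np.int64)
    out_gtp = np.zeros((K, n), dtype=np.int64)
    out_cab = np.zeros((K, n), dtype=np.int64)
    out_cyt = np.zeros(K, dtype=np.int64)
    out_mono = np.zeros(K, dtype=np.int64)
    _ssa_core(n_gdp, n_gtp, n_cab, pools, mesh.area,
              mesh.cytosol_volume, c6b,
              rates.beta1, rates.beta2, rates.beta3, rates.k_act,
              rates.k_inact, rates.A_on, rates.A_off,
              mesh.nbr_ptr, mesh.nbr_idx, mesh.hop, hsum, float(t0), snap,
              out_gdp, out_gtp, out_cab, out_cyt, out_mono, int(seed))
    final = SpeciesState(n_gdp, n_gtp, n_cab, int(pools[0]), int(pools[1]))
    if final.total_cdc42 != state0.total_cdc42 or final.total_actin != state0.total_actin:
        raise RuntimeError("species conservation violated in SSA")  # pragma: no cover
    return StochasticTrajectory(snap, out_gdp, out_gtp, out_cab, out_cyt,
                                out_mono, final, int(seed))


# ---------------------------------------------------------------------------
# initial conditions and experiment drivers

def initial_state(mesh: SurfaceMesh, n_cdc42: int, n_actin: int, mode: str,
                  seed: int, cap_width: float = 0.5) -> SpeciesState:
    """Deterministic-seed initial conditions.

    'uniform' : 50% Cdc42 cytosolic, the rest thrown area-uniformly on the
        membrane split GDP/GTP; 70% of actin as monomers, the rest thrown as
        cables (the spontaneous-symmetry-breaking start).
    'tip_cap' : membrane Cdc42-GTP and cables concentrated within
        ``cap_width`` of the tip; the polarized start of the fixed-geometry
        runs.
    """
    rng = np.random.default_rng(seed)
    w = mesh.area / mesh.total_area
    z = np.zeros(mesh.n_patches, dtype=np.int64)
    if mode == "uniform":
        n_mem = n_cdc42 // 2
        gdp = rng.multinomial(n_mem // 2, w)
        gtp = rng.multinomial(n_mem - n_mem // 2, w)
        cab = rng.multinomial(int(0.3 * n_actin), w)
        return SpeciesState(gdp.astype(np.int64), gtp.astype(np.int64),
                            cab.astype(np.int64),
                            n_cdc42 - n_mem, n_actin - int(cab.sum()))
    if mode == "tip_cap":
        mask = mesh.s_mid <= cap_width
        if not np.any(mask):
            mask = mesh.s_mid <= np.min(mesh.s_mid) + 1e-9
        wc = np.where(mask, mesh.area, 0.0)
        wc = wc / wc.sum()
        gtp = rng.multinomial(n_cdc42 // 2, wc)
        cab = rng.multinomial(int(0.5 * n_actin), wc)
        return SpeciesState(z.copy(), gtp.astype(np.int64), cab.astype(np.int64),
                            n_cdc42 - n_cdc42 // 2, n_actin - int(cab.sum()))
    raise ValueError(f"unknown initial mode {mode!r}")


def band_average(mesh: SurfaceMesh, counts: np.ndarray):
    """Azimuthally averaged band densities: (sum counts)/(sum areas)."""
    dens = np.zeros(mesh.n_bands)
    for i in range(mesh.n_bands):
        sel = mesh.band_of == i
        dens[i] = counts[sel].sum() / mesh.band_area[i]
    return mesh.band_s, dens


def cap_azimuth(mesh: SurfaceMesh, counts: np.ndarray) -> float:
    """Circular-mean azimuth of a membrane count distribution."""
    c = np.sum(counts * np.cos(mesh.phi_mid))
    s = np.sum(counts * np.sin(mesh.phi_mid))
    return float(np.arctan2(s, c) % (2.0 * np.pi))


def run_fixed_geometry_experiment(shape: AxisymShape, rates: StochasticRates,
                                  n_realizations: int, t_end: float,
                                  seeds, strain_field=None,
                                  n_cdc42: int = 5000, n_actin: int = 1000,
                                  Ns: int = 24, Nphi: int = 12,
                                  n_snapshots: int = 10, cap_width: float = 0.5):
    """Polarization-cap fate on a fixed shape (averaged over realizations).

    Starts each realization from a tip-concentrated cap, runs the SSA with
    the given (frozen) strain field, and returns averaged Cdc42 and cable
    density profiles vs arclength plus per-realization cap-position series.
    """
    from .metrics import cap_position as _cap

    seeds = list(seeds)
    if len(seeds) != n_realizations:
        raise ValueError("need one seed per realization")
    mesh = build_surface_mesh(shape, Ns, Nphi, D_mem=rates.D_mem)
    snap = np.linspace(0.0, t_end, n_snapshots + 1)[1:]
    prof_c = np.zeros((n_snapshots, mesh.n_bands))
    prof_a = np.zeros((n_snapshots, mesh.n_bands))
    cap_series = np.zeros((n_realizations, n_snapshots))
    for rdx, seed in enumerate(seeds):
        st = initial_state(mesh, n_cdc42, n_actin, "tip_cap", seed,
                           cap_width=cap_width)
        tr = ssa_run(st, mesh, rates, t_end, seed, strain_field=strain_field,
                     snapshot_times=snap)
        for k in range(n_snapshots):
            cd = tr.n_GDP[k] + tr.n_GTP[k]
            _, dc = band_average(mesh, cd)
            _, da = band_average(mesh, tr.n_cable[k])
            prof_c[k] += dc / n_realizations
            prof_a[k] += da / n_realizations
            cap_series[rdx, k] = _cap(mesh.band_s, dc.astype(float),
                                      smoothing_width=mesh.band_s[1] - mesh.band_s[0])
    return {"s": mesh.band_s, "cdc42": prof_c, "cables": prof_a,
            "times": snap, "cap_positions": cap_series, "mesh": mesh}
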