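"""Surface RDME sampler: mesh construction, propensities, exactness."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from shmoo.geometry import make_sphere
from shmoo.stochastic import (SpeciesState, StochasticRates, band_average,
                              build_surface_mesh, cap_azimuth, initial_state,
                              propensities, single_patch_mesh, ssa_run)


@pytest.fixture(scope="module")
def sphere_mesh(sphere):
    return build_surface_mesh(sphere, 12, 8)


class TestBuildSurfaceMesh:
    def test_total_area_matches_sphere(self, sphere_mesh):
        assert sphere_mesh.total_area == pytest.approx(16 * np.pi, rel=1e-3)

    def test_equal_patch_areas_within_band(self, sphere_mesh):
        for i in range(sphere_mesh.n_bands):
            areas = sphere_mesh.area[sphere_mesh.band_of == i]
            assert np.allclose(areas, areas[0])

    def test_interior_patches_have_four_neighbors(self, sphere_mesh):
        deg = np.diff(sphere_mesh.nbr_ptr)
        interior = (sphere_mesh.band_of > 1) & (sphere_mesh.band_of
                                                < sphere_mesh.n_bands - 2)
        assert np.all(deg[interior] == 4)

    def test_refinement_leaves_total_area_unchanged(self, sphere):
        a1 = build_surface_mesh(sphere, 12, 8).total_area
        a2 = build_surface_mesh(sphere, 24, 16).total_area
        assert abs(a2 - a1) / a1 < 1e-4

    def test_azimuthal_adjacency_is_cyclic(self, sphere_mesh):
        m = sphere_mesh
        ring = np.where(m.band_of == 3)[0]
        p = ring[0]
        nbrs = m.nbr_idx[m.nbr_ptr[p]:m.nbr_ptr[p + 1]]
        assert ring[1] in nbrs and ring[-1] in nbrs


class TestPropensities:
    def test_empty_state_all_zero(self, sphere_mesh):
        st = SpeciesState(np.zeros(sphere_mesh.n_patches, dtype=np.int64),
                          np.zeros(sphere_mesh.n_patches, dtype=np.int64),
                          np.zeros(sphere_mesh.n_patches, dtype=np.int64), 0, 0)
        pr = propensities(st, sphere_mesh, StochasticRates())
        assert np.all(pr["reactions"] == 0)
        assert np.all(pr["hop_GDP"] == 0)

    def test_cwi_channel_off_without_feedback(self, sphere_mesh):
        st = initial_state(sphere_mesh, 100, 30, "uniform", 0)
        pr = propensities(st, sphere_mesh, StochasticRates(A_CWI=0.0))
        assert np.all(pr["reactions"][:, 6] == 0)

    def test_activation_substitution(self):
        mesh = single_patch_mesh(area=1.0, cytosol_volume=10.0)
        st = SpeciesState(np.array([10]), np.array([5]), np.array([0]), 0, 0)
        pr = propensities(st, mesh, StochasticRates(k_act=0.2))
        assert pr["reactions"][0, 3] == pytest.approx(10.0)

    def test_negative_counts_rejected(self, sphere_mesh):
        st = initial_state(sphere_mesh, 100, 30, "uniform", 0)
        st.n_GDP[0] = -1
        with pytest.raises(ValueError):
            propensities(st, sphere_mesh, StochasticRates())


class TestSsaRun:
    def test_zero_molecules_no_events(self, sphere_mesh):
        st = SpeciesState(np.zeros(sphere_mesh.n_patches, dtype=np.int64),
                          np.zeros(sphere_mesh.n_patches, dtype=np.int64),
                          np.zeros(sphere_mesh.n_patches, dtype=np.int64), 0, 0)
        tr = ssa_run(st, sphere_mesh, StochasticRates(), 5.0, seed=1)
        assert np.all(tr.n_GDP == 0) and tr.N_cyt[-1] == 0

    def test_species_totals_conserved(self, sphere_mesh):
        st = initial_state(sphere_mesh, 600, 150, "uniform", 7)
        tr = ssa_run(st, sphere_mesh, StochasticRates(), 20.0, seed=7)
        cdc = tr.n_GDP.sum(axis=1) + tr.n_GTP.sum(axis=1) + tr.N_cyt
        act = tr.n_cable.sum(axis=1) + tr.N_mono
        assert np.all(cdc == 600)
        assert np.all(act == 150)

    def test_identical_seed_bit_identical(self, sphere_mesh):
        st = initial_state(sphere_mesh, 400, 100, "uniform", 5)
        tr1 = ssa_run(st, sphere_mesh, StochasticRates(), 10.0, seed=99)
        tr2 = ssa_run(st, sphere_mesh, StochasticRates(), 10.0, seed=99)
        assert np.array_equal(tr1.n_GDP, tr2.n_GDP)
        assert np.array_equal(tr1.n_GTP, tr2.n_GTP)
        assert np.array_equal(tr1.n_cable, tr2.n_cable)

    def test_two_patch_hopping_reaches_half_half(self):
        """Single molecule hopping between two patches: analytic stationary
        occupancy is 50/50 (symmetric rates)."""
        from shmoo.stochastic import SurfaceMesh
        hop_rate = 2.0
        mesh = SurfaceMesh(
            area=np.array([1.0, 1.0]), s_mid=np.array([0.0, 1.0]),
            phi_mid=np.array([0.0, 0.0]), band_of=np.array([0, 1]),
            nbr_ptr=np.array([0, 1, 2]), nbr_idx=np.array([1, 0]),
            hop=np.array([hop_rate, hop_rate]), n_bands=2, n_phi=1,
            band_s=np.array([0.0, 1.0]), band_area=np.array([1.0, 1.0]),
            cytosol_volume=1.0)
        # a single membrane GDP molecule, all reactions switched off
        rates = StochasticRates(beta1=0, beta2=0, beta3=0, k_act=0,
                                k_inact=0, A_on=0, A_off=0, D_mem=0)
        st = SpeciesState(np.array([1, 0]), np.array([0, 0]),
                          np.array([0, 0]), 0, 0)
        snaps = np.linspace(1.0, 2000.0, 2000)
        tr = ssa_run(st, mesh, rates, 2000.0, seed=11, snapshot_times=snaps)
        frac = tr.n_GDP[:, 0].mean()
        # binomial CI for n=2000 correlated-ish samples; generous 4-sigma
        # bound with the effective sample size of the hop process
        assert abs(frac - 0.5) < 0.05

    def test_single_patch_means_match_ode_oracle(self):
        """Well-mixed limit vs the mass-action ODE of the same network."""
        A, V = 4.0, 20.0
        mesh = single_patch_mesh(A, V)
        rates = StochasticRates(beta1=0.01, A_CWI=0.0)
        N_c, N_a = 2000, 400
        st = SpeciesState(np.array([200]), np.array([300]), np.array([50]),
                          N_c - 500, N_a - 50)

        def ode(t, y):
            gdp, gtp, cab, cyt, mono = y
            r1 = rates.beta2 * (A / V) * cyt
            r2 = rates.beta1 * cab * cyt / V
            r3 = rates.beta3 * gdp
            r4 = rates.k_act * gdp * gtp / A
            r5 = rates.k_inact * gtp
            r6 = rates.A_on * gtp * mono / V
            r7 = rates.A_off * cab
            return [r1 + r2 - r3 - r4 + r5, r4 - r5, r6 - r7,
                    r3 - r1 - r2, r7 - r6]

        T = 15.0
        sol = solve_ivp(ode, [0, T], [200, 300, 50, N_c - 500, N_a - 50],
                        rtol=1e-9, atol=1e-9)
        n_seeds = 80
        finals = np.zeros((n_seeds, 5))
        for i in range(n_seeds):
            tr = ssa_run(st, mesh, rates, T, seed=1000 + i,
                         snapshot_times=np.array([T]))
            finals[i] = [tr.n_GDP[-1, 0], tr.n_GTP[-1, 0], tr.n_cable[-1, 0],
                         tr.N_cyt[-1], tr.N_mono[-1]]
        mean = finals.mean(axis=0)
        se = finals.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        z = np.abs(mean - sol.y[:, -1]) / np.maximum(se, 1e-9)
        assert np.all(z < 5.0), (mean, sol.y[:, -1], z)


class TestAveraging:
    def test_uniform_counts_give_count_over_area(self, sphere_mesh):
        counts = np.full(sphere_mesh.n_patches, 3)
        s, dens = band_average(sphere_mesh, counts)
        for i in range(sphere_mesh.n_bands):
            n_in_band = np.sum(sphere_mesh.band_of == i)
            expect = 3 * n_in_band / sphere_mesh.band_area[i]
            assert dens[i] == pytest.approx(expect)

    def test_rotational_collapse(self, sphere_mesh):
        ring = np.where(sphere_mesh.band_of == 4)[0]
        c1 = np.zeros(sphere_mesh.n_patches, dtype=int)
        c1[ring] = 2
        c2 = np.zeros_like(c1)
        c2[ring[0]] = 2 * ring.size
        _, d1 = band_average(sphere_mesh, c1)
        _, d2 = band_average(sphere_mesh, c2)
        assert np.allclose(d1, d2)

    def test_total_molecules_recovered(self, sphere_mesh):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 10, sphere_mesh.n_patches)
        _, dens = band_average(sphere_mesh, counts)
        assert np.sum(dens * sphere_mesh.band_area) == pytest.approx(counts.sum())

    def test_cap_azimuth_of_single_patch(self, sphere_mesh):
        ring = np.where(sphere_mesh.band_of == 4)[0]
        counts = np.zeros(sphere_mesh.n_patches)
        counts[ring[2]] = 5
        assert cap_azimuth(sphere_mesh, counts) == pytest.approx(
            sphere_mesh.phi_mid[ring[2]])
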