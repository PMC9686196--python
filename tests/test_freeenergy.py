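"""WHAM reconstruction, polar FEL assembly, LJ energetics, decomposition."""

import numpy as np
import pytest

from nanofacet import synthgen
from nanofacet.freeenergy import (
    EnergyProfile,
    LJParams,
    PMFProfile,
    assemble_polar_fel,
    average_pmfs,
    decompose_thermo,
    lj_energy_profile,
    lj_pair_energy,
    wham,
)
from nanofacet.synthgen import (
    KB_KJ_PER_MOL_K,
    UmbrellaSpec,
    UmbrellaWindow,
    sample_umbrella_windows,
)


WELL = dict(depth=20.0, center=2.3, width=0.15)


@pytest.fixture(scope="module")
def well_campaign():
    """Default umbrella campaign over a known single-well potential."""
    spec = UmbrellaSpec(
        "gaussian_well",
        synthgen.default_window_centers(2.0, 3.0),
        potential_params=WELL,
        seed=5,
    )
    return spec, sample_umbrella_windows(spec)


class TestWham:
    def test_flat_potential_recovers_flat_pmf(self):
        rng = np.random.default_rng(0)
        k = 10_000.0
        sigma = np.sqrt(KB_KJ_PER_MOL_K * 300 / k)
        windows = [
            UmbrellaWindow(center=c, force_constant=k,
                           samples=rng.normal(c, sigma, 10_000))
            for c in synthgen.default_window_centers(0.0, 0.5)
        ]
        pmf = wham(windows, 300.0)
        # flat to 0.2 kJ/mol over the window-covered range (outside the
        # outermost centers only one-sided tails sample the coordinate)
        covered = (pmf.xi >= 0.0) & (pmf.xi <= 0.5)
        dev = pmf.delta_g[covered] - pmf.delta_g[covered].mean()
        assert np.sqrt(np.mean(dev**2)) <= 0.2

    def test_known_well_recovered_below_half_kj(self, well_campaign):
        spec, windows = well_campaign
        pmf = wham(windows, spec.temperature)
        u = spec.potential()
        truth = u(pmf.xi) - u(pmf.xi[-1])
        rmse = np.sqrt(np.mean((pmf.delta_g - truth) ** 2))
        assert rmse <= 0.5

    def test_single_unbiased_window_is_histogram_estimate(self):
        rng = np.random.default_rng(4)
        samples = rng.normal(1.0, 0.05, 50_000)
        window = UmbrellaWindow(center=1.0, force_constant=1e-9,
                                samples=samples)
        pmf = wham([window], 300.0, bin_width=0.01, min_counts=100)
        kbt = KB_KJ_PER_MOL_K * 300
        hist, edges = np.histogram(samples, bins=np.arange(
            samples.min(), samples.max() + 0.01, 0.01))
        centers = 0.5 * (edges[1:] + edges[:-1])
        keep = hist >= 100
        ref = -kbt * np.log(hist[keep].astype(float))
        ref -= ref[-1]
        common = np.isin(np.round(centers[keep], 6), np.round(pmf.xi, 6))
        np.testing.assert_allclose(
            pmf.delta_g, ref[common][: len(pmf.delta_g)], atol=0.2)

    def test_gap_between_windows_named(self):
        rng = np.random.default_rng(1)
        k = 10_000.0
        sigma = np.sqrt(KB_KJ_PER_MOL_K * 300 / k)
        windows = [
            UmbrellaWindow(center=c, force_constant=k,
                           samples=rng.normal(c, sigma, 2000))
            for c in (1.0, 1.02, 2.0, 2.02)
        ]
        with pytest.raises(ValueError, match="1.02 and 2"):
            wham(windows, 300.0)

    def test_shift_invariance_of_window_labels(self, well_campaign):
        spec, windows = well_campaign
        pmf = wham(windows, spec.temperature)
        shifted = [
            UmbrellaWindow(center=w.center + 0.5, force_constant=w.force_constant,
                           samples=w.samples + 0.5)
            for w in windows
        ]
        pmf_shifted = wham(shifted, spec.temperature)
        np.testing.assert_allclose(pmf_shifted.xi - 0.5, pmf.xi, atol=1e-9)
        np.testing.assert_allclose(pmf_shifted.delta_g, pmf.delta_g, atol=1e-6)

    def test_duplicated_windows_change_nothing(self, well_campaign):
        spec, windows = well_campaign
        pmf = wham(windows, spec.temperature)
        pmf_dup = wham(windows + windows, spec.temperature)
        np.testing.assert_allclose(pmf_dup.delta_g, pmf.delta_g, atol=0.05)

    def test_replica_average(self, well_campaign):
        spec, _ = well_campaign
        pmfs = []
        for seed in (11, 12, 13):
            s = UmbrellaSpec("gaussian_well", spec.window_centers,
                             potential_params=WELL, seed=seed,
                             n_samples_per_window=3000)
            pmfs.append(wham(sample_umbrella_windows(s), s.temperature))
        avg = average_pmfs(pmfs)
        assert avg.std is not None
        assert avg.std.max() > 0
        assert abs(avg.delta_g[-1]) < 1e-9


class TestPolarFel:
    @staticmethod
    def _pmf_from(f, xi):
        return PMFProfile(xi=xi, delta_g=f(xi) - f(xi)[-1])

    def test_identical_pmfs_flagged_degenerate(self):
        xi = np.linspace(2.0, 3.0, 60)
        f = lambda x: -10 * np.exp(-((x - 2.3) ** 2) / 0.02)
        fel = assemble_polar_fel({t: self._pmf_from(f, xi)
                                  for t in (0.0, 18.2, 36.5, 54.7)})
        assert fel.degenerate_theta

    def test_planted_minimum_found_at_547(self):
        xi = np.linspace(2.0, 3.0, 120)
        pmfs = {}
        for theta, depth in ((0.0, 8.0), (18.2, 5.0), (36.5, 5.5),
                             (54.7, 14.0)):
            f = lambda x, d=depth: -d * np.exp(-((x - 2.25) ** 2) / 0.02)
            pmfs[theta] = self._pmf_from(f, xi)
        fel = assemble_polar_fel(pmfs)
        assert fel.min_theta == 54.7
        assert 2.0 < fel.min_xi < 2.5
        assert not fel.degenerate_theta

    def test_shifted_grids_interpolate_to_analytic_values(self):
        f = lambda x: 3.0 * (x - 2.5) ** 2
        xi_a = np.linspace(2.0, 3.0, 101)
        xi_b = np.linspace(2.05, 3.05, 101)
        fel = assemble_polar_fel({
            0.0: PMFProfile(xi=xi_a, delta_g=f(xi_a)),
            54.7: PMFProfile(xi=xi_b, delta_g=f(xi_b)),
        })
        for row in fel.delta_g:
            np.testing.assert_allclose(row, f(fel.xi), atol=1e-3)

    def test_disjoint_ranges_rejected(self):
        xi = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="disjoint"):
            assemble_polar_fel({
                0.0: PMFProfile(xi=xi, delta_g=np.zeros(20)),
                54.7: PMFProfile(xi=xi + 5, delta_g=np.zeros(20)),
            })

    def test_single_orientation_rejected(self):
        xi = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="two orientations"):
            assemble_polar_fel({0.0: PMFProfile(xi=xi, delta_g=np.zeros(20))})


class TestLJ:
    def test_zero_crossing_and_minimum(self):
        eps, sigma = 0.5, 0.3
        assert lj_pair_energy(np.array([sigma]), eps, sigma)[0] == (
            pytest.approx(0.0, abs=1e-12))
        r_min = 2 ** (1 / 6) * sigma
        assert lj_pair_energy(np.array([r_min]), eps, sigma)[0] == (
            pytest.approx(-eps, rel=1e-12))

    @pytest.fixture()
    def params(self):
        return LJParams(epsilon={"Au": 0.8, "SITE": 0.4},
                        sigma={"Au": 0.26, "SITE": 0.35})

    def test_combining_rules(self, params):
        eps, sigma = params.pair("Au", "SITE")
        assert eps == pytest.approx(np.sqrt(0.8 * 0.4))
        assert sigma == pytest.approx(0.305)

    def test_profile_zero_beyond_cutoff(self, small_particle, params):
        r_out = np.linalg.norm(small_particle.positions, axis=1).max()
        configs = [
            (xi, np.array([[0.0, 0.0, r_out + xi]]))
            for xi in (1.1, 1.5, 2.0)
        ]
        profile = lj_energy_profile(configs, small_particle, params)
        np.testing.assert_array_equal(profile.energy, 0.0)

    def test_matches_no_cutoff_quadratic_oracle(self, small_particle, params):
        rng = np.random.default_rng(6)
        r_out = np.linalg.norm(small_particle.positions, axis=1).max()
        sites = rng.normal(0, 0.2, size=(12, 3)) + [0, 0, r_out + 0.45]
        profile = lj_energy_profile(
            [(0.5, sites), (5.0, sites + [0, 0, 30.0])],
            small_particle,
            LJParams(epsilon=params.epsilon, sigma=params.sigma, cutoff=3.0),
        )
        eps, sigma = params.pair("Au", "SITE")
        oracle = 0.0
        for s in sites:
            r = np.linalg.norm(small_particle.positions - s, axis=1)
            oracle += lj_pair_energy(r, eps, sigma).sum()
        # truncation bound: pairs beyond 3 nm contribute < 4 eps (sigma/r)^6
        n_pairs = len(sites) * len(small_particle)
        bound = n_pairs * 4 * eps * (sigma / 3.0) ** 6
        assert abs(profile.energy[0] - oracle) <= bound + 1e-9

    def test_overlapping_sites_rejected(self, small_particle, params):
        configs = [(0.0, small_particle.positions[:1].copy())]
        with pytest.raises(ValueError, match="overlapping"):
            lj_energy_profile(configs, small_particle, params)


class TestDecompose:
    def test_equal_curves_give_zero_entropy(self):
        xi = np.linspace(2.0, 3.0, 50)
        g = -8 * np.exp(-((xi - 2.2) ** 2) / 0.05)
        thermo = decompose_thermo(
            PMFProfile(xi=xi, delta_g=g - g[-1]),
            EnergyProfile(xi=xi, energy=g - g[-1]),
            particle_radius=2.0,
        )
        np.testing.assert_allclose(thermo.t_delta_s, 0.0, atol=1e-12)
        np.testing.assert_allclose(thermo.xi_star, xi - 2.0)

    def test_identity_holds_pointwise(self, rng):
        xi = np.linspace(2.0, 3.0, 80)
        dg = rng.normal(size=80)
        dh = rng.normal(size=80)
        thermo = decompose_thermo(
            PMFProfile(xi=np.sort(xi), delta_g=dg),
            EnergyProfile(xi=np.sort(xi), energy=dh),
            particle_radius=1.98,
        )
        np.testing.assert_allclose(
            thermo.delta_g - thermo.delta_h + thermo.t_delta_s, 0.0,
            atol=1e-12)
        assert abs(thermo.delta_g[-1]) < 1e-12
        assert abs(thermo.delta_h[-1]) < 1e-12

    def test_facet_gap_is_enthalpic_when_entropy_matches(self):
        # two orientations, same TdS, different DH wells -> DG gap equals
        # DH gap pointwise
        xi = np.linspace(2.0, 3.0, 60)
        tds = -3.0 * np.exp(-((xi - 2.2) ** 2) / 0.03)
        tds -= tds[-1]
        out = {}
        for name, depth in (("111", 15.0), ("100", 9.0)):
            dh = -depth * np.exp(-((xi - 2.2) ** 2) / 0.04)
            dh -= dh[-1]
            dg = dh - tds
            out[name] = decompose_thermo(
                PMFProfile(xi=xi, delta_g=dg),
                EnergyProfile(xi=xi, energy=dh),
                particle_radius=2.0,
            )
        dg_gap = out["111"].delta_g - out["100"].delta_g
        dh_gap = out["111"].delta_h - out["100"].delta_h
        np.testing.assert_allclose(dg_gap, dh_gap, atol=1e-10)
        np.testing.assert_allclose(
            out["111"].t_delta_s, out["100"].t_delta_s, atol=1e-10)

    def test_disjoint_support_rejected(self):
        xi = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="disjoint"):
            decompose_thermo(
                PMFProfile(xi=xi, delta_g=np.zeros(10)),
                EnergyProfile(xi=xi + 10, energy=np.zeros(10)),
                particle_radius=1.0,
            )
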