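import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axdiam.scheme import AcquisitionScheme, PGSE, b_to_gradient_strength
from axdiam.signal import (
    DIAMETER_SCALE,
    VoxelParams,
    add_rician_noise,
    compose_voxel_signal,
    extra_axonal_radial_diffusivity,
    hindered_compartment_signal,
    poisson_diameter_distribution,
    restricted_compartment_signal,
    restricted_perpendicular_attenuation,
    rician_expected_magnitude,
)

from oracles import rician_mean_quadrature


def make_params(**kw):
    defaults = dict(
        orientations=[0.0, 0.0, 1.0],
        fractions=[0.3],
        d_intra_axial=1.5,
        d_extra_radial_min=0.5,
        slope=-0.003,
        d_extra_axial=1.5,
        lambda_poisson=2.0,
        sigma_rician=0.05,
        s0=1.0,
    )
    defaults.update(kw)
    return VoxelParams(**defaults)


class TestExtraAxonalRadialDiffusivity:
    @pytest.mark.parametrize(
        "d0, slope, delta, expected",
        [(0.5, 0.123, 15.0, 0.5), (0.5, 0.0, 60.0, 0.5), (0.5, -0.004, 60.0, 0.32)],
    )
    def test_linear_form(self, d0, slope, delta, expected):
        assert extra_axonal_radial_diffusivity(d0, slope, delta, 15.0) == pytest.approx(
            expected
        )

    def test_delta_below_min_rejected(self):
        with pytest.raises(ValueError):
            extra_axonal_radial_diffusivity(0.5, 0.0, 10.0, 15.0)

    def test_negative_prediction_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipping"):
            out = extra_axonal_radial_diffusivity(0.1, -0.01, 60.0, 15.0)
        assert out == 0.0


class TestCylinderAttenuation:
    def test_zero_diameter_is_unity(self):
        assert restricted_perpendicular_attenuation(0.0, 1.0, 300.0, 5.0, 30.0) == 1.0

    def test_zero_gradient_is_unity(self):
        assert restricted_perpendicular_attenuation(3.0, 1.0, 0.0, 5.0, 30.0) == 1.0

    def test_monotone_in_diameter_and_gradient(self):
        diams = np.array([0.5, 1.0, 2.0, 3.0, 5.0])
        att = restricted_perpendicular_attenuation(diams, 1.0, 300.0, 5.0, 30.0)
        assert np.all(np.diff(att) < 0)
        gs = [100.0, 200.0, 400.0]
        vals = [restricted_perpendicular_attenuation(4.0, 1.0, g, 5.0, 30.0) for g in gs]
        assert vals[0] > vals[1] > vals[2]

    def test_motional_narrowing_plateau_in_delta(self):
        """At fixed b the perpendicular attenuation relaxes monotonically with
        Delta toward a plateau (gradient weakens as Delta grows)."""
        deltas = np.array([15.0, 25.0, 40.0, 60.0, 100.0])
        vals = []
        for D in deltas:
            g = b_to_gradient_strength(4.0, 5.0, D)
            vals.append(restricted_perpendicular_attenuation(3.0, 1.0, float(g), 5.0, D))
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] - vals[-2] < vals[1] - vals[0]

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            restricted_perpendicular_attenuation(-1.0, 1.0, 100.0, 5.0, 30.0)


class TestPoissonDiameterDistribution:
    def test_single_admissible_bin(self):
        dist = poisson_diameter_distribution(2.0, grid_step=1.0, truncation=0.5)
        assert dist.weights.size == 1
        assert dist.weights[0] == pytest.approx(1.0)

    def test_count_weighted_mean_equals_lambda(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for lam in (0.5, 2.0, 4.5):
                dist = poisson_diameter_distribution(lam, grid_step=1.0)
                # within one grid step (truncation shaves the far tail)
                assert dist.mean == pytest.approx(lam, abs=1.0)
            assert poisson_diameter_distribution(2.0, grid_step=1.0).mean == pytest.approx(
                2.0, abs=1e-3
            )
            assert poisson_diameter_distribution(0.5, grid_step=0.25).mean == pytest.approx(
                0.5, abs=1e-6
            )

    def test_volume_weighted_mean_exceeds_count_mean(self):
        count = poisson_diameter_distribution(2.0, grid_step=1.0)
        vol = poisson_diameter_distribution(2.0, grid_step=1.0, weighting="volume")
        # brute-force recomputation of the volume-weighted mean
        w = count.weights * count.diameter_grid**2
        w = w / w.sum()
        expected = float(w @ count.diameter_grid)
        assert vol.mean == pytest.approx(expected, abs=1e-12)
        assert vol.mean > 2.0

    def test_truncation_warning_and_renormalization(self):
        with pytest.warns(RuntimeWarning, match="renormalized"):
            dist = poisson_diameter_distribution(5.0, grid_step=1.0, truncation=6.0)
        assert dist.weights.sum() == pytest.approx(1.0)

    @given(lam=st.floats(0.2, 3.4))
    @settings(max_examples=25, deadline=None)
    def test_weights_are_a_distribution(self, lam):
        dist = poisson_diameter_distribution(lam, grid_step=1.0)
        assert np.all(dist.weights >= 0)
        assert dist.weights.sum() == pytest.approx(1.0, abs=1e-10)


class TestRestrictedCompartment:
    def test_b0_gives_unity(self, tiny_scheme):
        p = make_params()
        sig = restricted_compartment_signal(p, 0, tiny_scheme)
        np.testing.assert_allclose(sig[tiny_scheme.b0_mask], 1.0)
        assert np.all(sig > 0) and np.all(sig <= 1.0)

    def test_parallel_gradient_stick_limit(self):
        scheme = AcquisitionScheme(
            [0.0, 3.0], [[0, 0, 0], [0, 0, 1.0]], [30.0, 30.0], 5.0, PGSE
        )
        p = make_params(lambda_poisson=1e-6)
        sig = restricted_compartment_signal(p, 0, scheme)
        assert sig[1] == pytest.approx(np.exp(-3.0 * 1.5), rel=1e-6)

    def test_two_population_symmetry(self):
        scheme_x = AcquisitionScheme(
            [0.0, 4.0], [[0, 0, 0], [1.0, 0, 0]], [30.0, 30.0], 5.0, PGSE
        )
        scheme_z = AcquisitionScheme(
            [0.0, 4.0], [[0, 0, 0], [0, 0, 1.0]], [30.0, 30.0], 5.0, PGSE
        )
        p = make_params(
            orientations=[[1.0, 0, 0], [0, 0, 1.0]], fractions=[0.25, 0.25]
        )
        pop2_along_x = restricted_compartment_signal(p, 1, scheme_x)
        pop1_along_z = restricted_compartment_signal(p, 0, scheme_z)
        np.testing.assert_allclose(pop2_along_x, pop1_along_z, rtol=1e-12)

    def test_pop_index_out_of_range(self, tiny_scheme):
        with pytest.raises(IndexError):
            restricted_compartment_signal(make_params(), 1, tiny_scheme)


class TestHinderedCompartment:
    def test_b0_is_unity(self, tiny_scheme):
        sig = hindered_compartment_signal(make_params(), tiny_scheme)
        np.testing.assert_allclose(sig[tiny_scheme.b0_mask], 1.0)

    def test_parallel_decay_independent_of_slope(self):
        scheme = AcquisitionScheme(
            [0.0, 3.0], [[0, 0, 0], [0, 0, 1.0]], [60.0, 60.0], 5.0, PGSE
        )
        for slope in (0.0, -0.005):
            p = make_params(slope=slope)
            sig = hindered_compartment_signal(p, scheme)
            assert sig[1] == pytest.approx(np.exp(-3.0 * 1.5), rel=1e-9)

    def test_perpendicular_forced_arithmetic(self):
        scheme = AcquisitionScheme(
            [0.0, 3.0], [[0, 0, 0], [1.0, 0, 0]], [15.0, 15.0], 5.0, PGSE
        )
        p = make_params(d_extra_radial_min=0.4, slope=0.0)
        sig = hindered_compartment_signal(p, scheme)
        assert sig[1] == pytest.approx(np.exp(-1.2), rel=1e-9)


class TestComposeVoxelSignal:
    def test_zero_restricted_fraction_is_pure_hindered(self, tiny_scheme):
        p = make_params(fractions=[0.0])
        np.testing.assert_allclose(
            compose_voxel_signal(p, tiny_scheme),
            hindered_compartment_signal(p, tiny_scheme),
            rtol=1e-12,
        )

    def test_full_restricted_fraction_is_pure_restricted(self, tiny_scheme):
        p = make_params(fractions=[1.0])
        np.testing.assert_allclose(
            compose_voxel_signal(p, tiny_scheme),
            restricted_compartment_signal(p, 0, tiny_scheme),
            rtol=1e-12,
        )

    def test_independent_recomputation(self, tiny_scheme):
        """Compartment-by-compartment recomputation from the public ops."""
        p = make_params(lambda_poisson=2.0, fractions=[0.3], d_intra_axial=1.5)
        dist = poisson_diameter_distribution(2.0, grid_step=1.0)
        g = tiny_scheme.gradient_strength
        expected = np.zeros(tiny_scheme.n_meas)
        for m in range(tiny_scheme.n_meas):
            if tiny_scheme.b0_mask[m]:
                expected[m] = 1.0
                continue
            cos = float(tiny_scheme.bvecs[m] @ [0, 0, 1.0])
            g_perp = g[m] * np.sqrt(1 - cos**2)
            perp = sum(
                w
                * restricted_perpendicular_attenuation(
                    DIAMETER_SCALE * d, 1.5, g_perp,
                    tiny_scheme.small_delta[m], tiny_scheme.big_delta[m],
                )
                for d, w in zip(dist.diameter_grid, dist.weights)
            )
            restricted = np.exp(-tiny_scheme.bvals[m] * 1.5 * cos**2) * perp
            d_perp = 0.5 + (-0.003) * (tiny_scheme.big_delta[m] - 15.0)
            hind = np.exp(
                -tiny_scheme.bvals[m] * (d_perp + (1.5 - d_perp) * cos**2)
            )
            expected[m] = 0.3 * restricted + 0.7 * hind
        np.testing.assert_allclose(
            compose_voxel_signal(p, tiny_scheme), expected, rtol=1e-10
        )

    def test_steam_t1_decay_applied(self, tiny_steam_scheme):
        p = make_params(t1=1500.0)
        base = make_params(t1=np.inf)
        sig = compose_voxel_signal(p, tiny_steam_scheme)
        ref = compose_voxel_signal(base, tiny_steam_scheme)
        np.testing.assert_allclose(
            sig, ref * np.exp(-tiny_steam_scheme.mixing_time / 1500.0), rtol=1e-12
        )

    def test_two_tensor_reduction(self, tiny_scheme):
        """slope=0, single population, lambda->0 reduces to two tensors."""
        p = make_params(lambda_poisson=1e-8, slope=0.0)
        b = tiny_scheme.bvals
        cos2 = (tiny_scheme.bvecs @ np.array([0, 0, 1.0])) ** 2
        stick = np.exp(-b * 1.5 * cos2)
        zeppelin = np.exp(-b * (0.5 + (1.5 - 0.5) * cos2))
        expected = 0.3 * stick + 0.7 * zeppelin
        expected[tiny_scheme.b0_mask] = 1.0
        np.testing.assert_allclose(
            compose_voxel_signal(p, tiny_scheme), expected, rtol=1e-6
        )

    def test_antipodal_symmetry(self, tiny_scheme):
        p = make_params(orientations=[[0.36, -0.48, 0.8]])
        flipped = make_params(orientations=[[-0.36, 0.48, -0.8]])
        np.testing.assert_allclose(
            compose_voxel_signal(p, tiny_scheme),
            compose_voxel_signal(flipped, tiny_scheme),
            rtol=1e-12,
        )

    def test_overfull_fractions_rejected(self, tiny_scheme):
        with pytest.raises(ValueError):
            VoxelParams(
                orientations=[[0, 0, 1.0], [1.0, 0, 0]],
                fractions=[0.7, 0.6],
                d_intra_axial=1.5,
                d_extra_radial_min=0.5,
                slope=0.0,
                d_extra_axial=1.5,
                lambda_poisson=2.0,
            )


class TestRician:
    def test_rayleigh_mean_at_zero_signal(self):
        assert rician_expected_magnitude(0.0, 2.0) == pytest.approx(
            2.0 * np.sqrt(np.pi / 2), rel=1e-12
        )

    def test_high_snr_limit(self):
        assert rician_expected_magnitude(100.0, 1.0) == pytest.approx(100.0, rel=1e-4)

    @pytest.mark.parametrize("nu, sigma", [(1.0, 1.0), (0.3, 0.1), (2.0, 0.5)])
    def test_matches_quadrature(self, nu, sigma):
        assert rician_expected_magnitude(nu, sigma) == pytest.approx(
            rician_mean_quadrature(nu, sigma), abs=1e-6
        )

    def test_monotone_in_nu(self):
        nus = np.linspace(0, 5, 50)
        vals = rician_expected_magnitude(nus, 0.5)
        assert np.all(np.diff(vals) > 0)

    def test_noise_determinism(self, rng):
        s = np.linspace(0.1, 1.0, 20)
        a = add_rician_noise(s, 0.1, 77)
        b = add_rician_noise(s, 0.1, 77)
        np.testing.assert_array_equal(a, b)

    def test_small_sigma_limit(self):
        s = np.linspace(0.5, 1.0, 10)
        out = add_rician_noise(s, 1e-9, 0)
        np.testing.assert_allclose(out, s, atol=1e-7)

    def test_sample_mean_matches_analytic(self, rng):
        sigma, s = 0.5, 0.8
        draws = add_rician_noise(np.full(100_000, s), sigma, rng)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - rician_expected_magnitude(s, sigma)) < 3 * se
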