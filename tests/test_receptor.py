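import numpy as np
import pytest

from conftest import rnl_matrix_oracle
from crypsis.receptor import (
    NoiseModel,
    QuantumCatchVector,
    catch_vector,
    maxwell_coordinates,
    quantum_catch,
    receptor_noise,
    rnl_distance,
    von_kries_adapt,
    weber_contrast,
)
from crypsis.receptor import AdaptedCatch
from crypsis.spectra import CANONICAL_GRID, Spectrum
from crypsis.visual import VisualSystem, build_stomatopod_system, pigment_template


def make_flat(value, kind="reflectance"):
    wl = CANONICAL_GRID.wavelengths
    return Spectrum(wl, np.full(len(wl), float(value)), kind=kind)


class TestQuantumCatch:
    def test_unit_integrand_over_full_range(self):
        # R = S = I = 1 over 300-800 nm integrates to 500 (nm units)
        from crypsis.visual import ReceptorSensitivity

        wl = CANONICAL_GRID.wavelengths
        flat_curve = Spectrum(wl, np.ones(len(wl)), kind="sensitivity")
        r = ReceptorSensitivity(name="flat", lambda_max=300, curve=flat_curve)
        q = quantum_catch(r, make_flat(1.0), make_flat(1.0, "irradiance"), (300, 800))
        assert q == pytest.approx(500.0, rel=1e-12)

    def test_linearity_in_reflectance(self, fish, irradiance_1m):
        s = make_flat(0.8)
        half = make_flat(0.4)
        r = fish.receptors[0]
        q1 = quantum_catch(r, s, irradiance_1m, fish.integration_range)
        q2 = quantum_catch(r, half, irradiance_1m, fish.integration_range)
        assert q2 == pytest.approx(q1 / 2, rel=1e-12)

    def test_gaussian_closed_form(self):
        # Gaussian sensitivity (peak 500, sigma 50), S=I=1: integral over the
        # full grid approaches sigma*sqrt(2*pi)
        wl = CANONICAL_GRID.wavelengths
        r = pigment_template(500, shape="gaussian", sigma=50)
        s = make_flat(1.0)
        i = make_flat(1.0, kind="irradiance")
        sys3 = VisualSystem(
            receptors=[r], integration_range=(300, 800), abundances=[1.0], weber_fraction=0.05
        )
        q = quantum_catch(r, s, i, sys3.integration_range)
        assert q == pytest.approx(50 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_grid_mismatch_rejected(self, fish, irradiance_1m):
        s = Spectrum([300, 500, 800], [1, 1, 1])
        with pytest.raises(ValueError, match="grid"):
            quantum_catch(fish.receptors[0], s, irradiance_1m, fish.integration_range)


class TestCatchVector:
    def test_flat_ratios_match_integrated_sensitivities(self, fish):
        s = make_flat(1.0)
        i = make_flat(1.0, kind="irradiance")
        cv = catch_vector(fish, s, i)
        wl = CANONICAL_GRID.wavelengths
        lo, hi = fish.integration_range
        m = (wl >= lo) & (wl <= hi)
        areas = np.array([np.trapezoid(r.curve.values[m], wl[m]) for r in fish.receptors])
        np.testing.assert_allclose(cv.values / cv.values[0], areas / areas[0], rtol=1e-12)

    def test_zero_reflectance(self, fish, irradiance_1m):
        cv = catch_vector(fish, make_flat(0.0), irradiance_1m)
        np.testing.assert_array_equal(cv.values, 0.0)

    def test_stomatopod_order(self, irradiance_1m):
        sys12 = build_stomatopod_system()
        cv = catch_vector(sys12, make_flat(0.5), irradiance_1m)
        assert len(cv.values) == 12
        assert np.all(cv.values > 0)


class TestWeberContrast:
    def test_self_contrast_zero(self, fish, irradiance_1m):
        q = catch_vector(fish, make_flat(0.5), irradiance_1m)
        w = weber_contrast(q, q)
        np.testing.assert_array_equal(w.values, 0.0)

    @pytest.mark.parametrize("factor,expected", [(2.0, 1.0), (0.5, -0.5)])
    def test_scaling(self, fish, factor, expected):
        qb = QuantumCatchVector(fish, [1.0, 2.0, 3.0], "bg")
        qs = QuantumCatchVector(fish, factor * qb.values, "stim")
        w = weber_contrast(qs, qb)
        np.testing.assert_allclose(w.values, expected)

    def test_zero_background_names_receptor(self, fish):
        qb = QuantumCatchVector(fish, [1.0, 0.0, 3.0], "bg")
        qs = QuantumCatchVector(fish, [1.0, 1.0, 1.0], "stim")
        with pytest.raises(ValueError, match="MWS"):
            weber_contrast(qs, qb)

    def test_invariant_to_joint_rescaling(self, fish):
        rng = np.random.default_rng(5)
        qb = QuantumCatchVector(fish, rng.uniform(1, 5, 3))
        qs = QuantumCatchVector(fish, rng.uniform(1, 5, 3))
        w1 = weber_contrast(qs, qb).values
        w2 = weber_contrast(
            QuantumCatchVector(fish, 7.3 * qs.values),
            QuantumCatchVector(fish, 7.3 * qb.values),
        ).values
        np.testing.assert_allclose(w1, w2, rtol=1e-12)


class TestVonKries:
    def test_self_adaptation(self, fish, irradiance_1m):
        bg = make_flat(0.3)
        q = catch_vector(fish, bg, irradiance_1m)
        a = von_kries_adapt(q, bg, irradiance_1m, fish)
        np.testing.assert_allclose(a.von_kries, 1.0, rtol=1e-12)
        np.testing.assert_allclose(a.normalised, 1 / 3, rtol=1e-12)

    def test_irradiance_scale_cancels(self, fish, irradiance_1m):
        wl = irradiance_1m.wavelengths
        scaled = Spectrum(wl, 3.7 * irradiance_1m.values, kind="irradiance")
        stim = make_flat(0.6)
        bg = make_flat(0.3)
        a1 = von_kries_adapt(catch_vector(fish, stim, irradiance_1m), bg, irradiance_1m, fish)
        a2 = von_kries_adapt(catch_vector(fish, stim, scaled), bg, scaled, fish)
        np.testing.assert_allclose(a1.von_kries, a2.von_kries, rtol=1e-12)
        np.testing.assert_allclose(a1.normalised, a2.normalised, rtol=1e-12)

    def test_long_wavelength_boost_shifts_toward_L(self, fish, irradiance_1m):
        wl = CANONICAL_GRID.wavelengths
        bg = make_flat(0.3)
        vals = np.where(wl > 550, 0.36, 0.30)
        stim = Spectrum(wl, vals)
        a = von_kries_adapt(catch_vector(fish, stim, irradiance_1m), bg, irradiance_1m, fish)
        n_s, n_m, n_l = a.normalised
        assert n_l > 1 / 3 > n_s


class TestMaxwell:
    def test_achromatic_centre(self):
        pt = maxwell_coordinates(AdaptedCatch([1, 1, 1], [1 / 3, 1 / 3, 1 / 3]))
        assert pt.x == pytest.approx(0.0, abs=1e-12)
        assert pt.y == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "n,expected",
        [
            ((0, 0, 1), (1 / np.sqrt(2), -np.sqrt(2 / 3) / 2)),
            ((0, 1, 0), (0.0, np.sqrt(2 / 3))),
            ((1, 0, 0), (-1 / np.sqrt(2), -np.sqrt(2 / 3) / 2)),
        ],
    )
    def test_vertices(self, n, expected):
        pt = maxwell_coordinates(AdaptedCatch(np.array(n, dtype=float), np.array(n, dtype=float)))
        assert pt.x == pytest.approx(expected[0], abs=1e-12)
        assert pt.y == pytest.approx(expected[1], abs=1e-12)
        assert pt.saturation == pytest.approx(np.sqrt(2 / 3), abs=1e-12)

    def test_all_simplex_points_inside_triangle(self):
        rng = np.random.default_rng(11)
        verts = np.array(
            [
                [-1 / np.sqrt(2), -np.sqrt(2 / 3) / 2],
                [0.0, np.sqrt(2 / 3)],
                [1 / np.sqrt(2), -np.sqrt(2 / 3) / 2],
            ]
        )
        for _ in range(200):
            n = rng.dirichlet([1, 1, 1])
            pt = maxwell_coordinates(AdaptedCatch(n, n))
            # the projection is affine: the point must equal the same convex
            # combination of the three vertices (order S, M, L)
            expected = n[0] * verts[0] + n[1] * verts[1] + n[2] * verts[2]
            assert pt.x == pytest.approx(expected[0], abs=1e-9)
            assert pt.y == pytest.approx(expected[1], abs=1e-9)

    def test_non_trichromatic_rejected(self):
        with pytest.raises(ValueError, match="trichromat"):
            maxwell_coordinates(AdaptedCatch([1, 1], [0.5, 0.5]))


class TestReceptorNoise:
    def test_published_ratio(self, fish):
        n = receptor_noise(fish)
        assert n.e[0] == pytest.approx(0.05 * np.sqrt(2), rel=1e-9)
        assert n.e[1] == pytest.approx(0.05)
        assert n.e[2] == pytest.approx(0.05)

    def test_equal_abundances(self, grid):
        sys3 = VisualSystem(
            receptors=[pigment_template(420), pigment_template(480), pigment_template(520)],
            integration_range=(340, 700),
            abundances=[1, 1, 1],
            weber_fraction=0.05,
        )
        np.testing.assert_allclose(receptor_noise(sys3).e, 0.05)

    def test_zero_abundance_rejected(self, fish):
        with pytest.raises(ValueError):
            VisualSystem(
                receptors=fish.receptors,
                integration_range=fish.integration_range,
                abundances=[0, 2, 2],
                weber_fraction=0.05,
            )


class TestRnlDistance:
    def test_identity(self, fish, fish_noise):
        q = QuantumCatchVector(fish, [1.0, 2.0, 3.0])
        assert rnl_distance(q, q, fish_noise) == 0.0

    def test_uniform_scaling_is_achromatic(self, fish, fish_noise):
        q = QuantumCatchVector(fish, [1.0, 2.0, 3.0])
        q2 = QuantumCatchVector(fish, 4.2 * q.values)
        assert rnl_distance(q, q2, fish_noise) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value(self, fish, fish_noise):
        # df = (0, 0, ln 2) with e = (0.05*sqrt(2), 0.05, 0.05) gives ~10.74
        a = QuantumCatchVector(fish, [1.0, 1.0, 2.0])
        b = QuantumCatchVector(fish, [1.0, 1.0, 1.0])
        d = rnl_distance(a, b, fish_noise)
        assert d == pytest.approx(10.74, abs=0.01)
        assert d == pytest.approx(rnl_matrix_oracle([0, 0, np.log(2)], fish_noise.e), rel=1e-10)

    def test_matches_matrix_oracle_on_random_pairs(self, fish, fish_noise):
        rng = np.random.default_rng(3)
        for _ in range(100):
            qa = QuantumCatchVector(fish, rng.uniform(0.1, 10, 3))
            qb = QuantumCatchVector(fish, rng.uniform(0.1, 10, 3))
            d = rnl_distance(qa, qb, fish_noise)
            oracle = rnl_matrix_oracle(np.log(qa.values / qb.values), fish_noise.e)
            assert d == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    def test_symmetry_and_triangle_inequality(self, fish, fish_noise):
        rng = np.random.default_rng(9)
        for _ in range(300):
            qa, qb, qc = (QuantumCatchVector(fish, rng.uniform(0.1, 10, 3)) for _ in range(3))
            dab = rnl_distance(qa, qb, fish_noise)
            dba = rnl_distance(qb, qa, fish_noise)
            assert dab == pytest.approx(dba, rel=1e-12)
            dac = rnl_distance(qa, qc, fish_noise)
            dcb = rnl_distance(qc, qb, fish_noise)
            assert dab <= dac + dcb + 1e-9

    def test_zero_catch_rejected(self, fish, fish_noise):
        qa = QuantumCatchVector(fish, [0.0, 1.0, 1.0])
        qb = QuantumCatchVector(fish, [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            rnl_distance(qa, qb, fish_noise)

    def test_linear_form_agrees_for_small_contrasts(self, fish, fish_noise):
        qa = QuantumCatchVector(fish, [1.001, 2.0, 3.0])
        qb = QuantumCatchVector(fish, [1.0, 2.0, 3.0])
        d_log = rnl_distance(qa, qb, fish_noise, signal_form="log")
        d_lin = rnl_distance(qa, qb, fish_noise, signal_form="linear")
        assert d_log == pytest.approx(d_lin, rel=1e-3)
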