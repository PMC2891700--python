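import io

import numpy as np
import pytest

from cgfold.bonded import (CoordinateHistogram, CosineSeries, InversionError,
                           TorsionLibrary, backbone_angle_potential,
                           build_torsion_library, fit_cosine_series,
                           fit_polynomial, invert_angle, invert_bond,
                           invert_torsion, read_potential, write_potential)
from cgfold.fixtures import bonded_histogram, sample_bonded
from cgfold.units import KB

T = 300.0
KT = KB * T

_STANDARD = ("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
             "LEU LYS MET PHE PRO SER THR TRP TYR VAL").split()


class TestInvertBond:
    def test_r_squared_density_gives_flat_potential(self, rng):
        # p(r) ∝ r^2 on [0.3, 0.5]: volume factor cancels exactly
        u = rng.uniform(0.3 ** 3, 0.5 ** 3, size=400_000)
        samples = u ** (1 / 3)
        hist = CoordinateHistogram.from_samples("bond", samples, T,
                                                bin_width=0.005,
                                                range_=(0.3, 0.5))
        pot = invert_bond(hist)
        v = pot.values[pot.supported]
        assert np.nanmax(v) - np.nanmin(v) < 0.25  # kJ/mol, statistical

    def test_harmonic_recovery(self):
        # generate-and-recover oracle: 1e6 Boltzmann samples of a known well
        k_true, r0_true = 1000.0, 0.38
        pot_fn = lambda r: 0.5 * k_true * (r - r0_true) ** 2
        hist = bonded_histogram("bond", pot_fn, T, 1_000_000, seed=7,
                                domain=(0.30, 0.46))
        inv = invert_bond(hist)
        fit = fit_polynomial(inv, order=2)
        k_fit = 2 * fit.coefficients[2]
        r0_fit = -fit.coefficients[1] / k_fit
        assert k_fit == pytest.approx(k_true, rel=0.05)
        assert abs(r0_fit - r0_true) < 0.002

    def test_single_occupied_bin(self):
        hist = CoordinateHistogram("bond", np.array([0.3, 0.32, 0.34, 0.36]),
                                   np.array([0.0, 50.0, 0.0]), T)
        pot = invert_bond(hist)
        assert pot.values[1] == 0.0
        assert not np.isfinite(pot.values[0])
        assert not np.isfinite(pot.values[2])

    def test_all_zero_histogram_raises(self):
        hist = CoordinateHistogram("bond", np.array([0.3, 0.32, 0.34]),
                                   np.zeros(2), T)
        with pytest.raises(InversionError, match="all-zero"):
            invert_bond(hist)

    def test_wrong_kind_raises(self):
        hist = CoordinateHistogram("angle", np.array([10.0, 12, 14]),
                                   np.array([1.0, 1.0]), T)
        with pytest.raises(InversionError):
            invert_bond(hist)

    def test_count_rescaling_invariance(self, rng):
        edges = np.linspace(0.3, 0.5, 30)
        counts = rng.integers(1, 1000, size=29).astype(float)
        a = invert_bond(CoordinateHistogram("bond", edges, counts, T))
        b = invert_bond(CoordinateHistogram("bond", edges, counts * 17.5, T))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestInvertAngle:
    def test_sin_density_gives_flat(self, rng):
        # p(theta) ∝ sin(theta): inverse-CDF sampling via arccos(uniform)
        samples = np.degrees(np.arccos(rng.uniform(-1, 1, size=400_000)))
        hist = CoordinateHistogram.from_samples("angle", samples, T,
                                                range_=(0.0, 180.0))
        pot = invert_angle(hist)
        mid = pot.supported & (pot.grid > 15) & (pot.grid < 165)
        assert np.nanmax(pot.values[mid]) - np.nanmin(pot.values[mid]) < 0.15

    def test_harmonic_angle_recovery(self):
        k_true, th0 = 0.05, 100.0   # kJ/mol/deg^2
        pot_fn = lambda th: 0.5 * k_true * (th - th0) ** 2
        hist = bonded_histogram("angle", pot_fn, T, 500_000, seed=11,
                                domain=(60.0, 140.0))
        inv = invert_angle(hist)
        fit = fit_polynomial(inv, order=2)
        th0_fit = -fit.coefficients[1] / (2 * fit.coefficients[2])
        assert abs(th0_fit - th0) < 1.0

    def test_uniform_density_gives_kt_log_sin_shape(self, rng):
        samples = rng.uniform(5.0, 175.0, size=2_000_000)
        hist = CoordinateHistogram.from_samples("angle", samples, T,
                                                range_=(5.0, 175.0))
        pot = invert_angle(hist)
        # V = kT ln(sin) shape: minimum at 90 deg, symmetric, increasing edges
        expected = KT * (np.log(np.sin(np.radians(90.0)))
                         - np.log(np.sin(np.radians(30.0))))
        i90 = np.argmin(np.abs(pot.grid - 90))
        i30 = np.argmin(np.abs(pot.grid - 30))
        i150 = np.argmin(np.abs(pot.grid - 150))
        assert pot.values[i30] - pot.values[i90] == pytest.approx(
            -expected, abs=0.05)
        assert pot.values[i30] == pytest.approx(pot.values[i150], abs=0.05)


class TestInvertTorsion:
    def test_uniform_gives_zero(self, rng):
        samples = rng.uniform(-180, 180, size=1_000_000)
        hist = CoordinateHistogram.from_samples("torsion", samples, T)
        pot = invert_torsion(hist)
        assert np.nanmax(pot.values) < 0.2

    def test_cosine_well_closed_form(self, rng):
        # p ∝ exp(cos phi) with kT = 1: V = -cos phi + const, range 2 kJ/mol
        T1 = 1.0 / KB
        pot_fn = lambda phi: -np.cos(np.radians(phi))
        hist = bonded_histogram("torsion", pot_fn, T1, 2_000_000, seed=3)
        pot = invert_torsion(hist)
        v = pot.values[pot.supported]
        assert np.nanmax(v) - np.nanmin(v) == pytest.approx(2.0, abs=0.08)

    def test_two_well_minima_recovered(self):
        # wells where 2*phi = 120 (mod 360): phi = 60 and phi = -120
        pot_fn = lambda phi: 4.0 * (1 - np.cos(np.radians(2 * phi - 120)))
        hist = bonded_histogram("torsion", pot_fn, T, 500_000, seed=5)
        pot = invert_torsion(hist)
        v = np.where(pot.supported, pot.values, np.inf)
        order = np.argsort(v)
        found = []
        for i in order:
            if all(abs(pot.grid[i] - f) > 60 for f in found):
                found.append(pot.grid[i])
            if len(found) == 2:
                break
        for f, t in zip(sorted(found), (-120.0, 60.0)):
            assert abs(f - t) < 7.5  # within 1.5 bins

    def test_periodic_endpoints(self):
        series = CosineSeries(np.array([0.3, 1.0, 0.0, 0.25, 0.0]))
        assert series(-180.0) == pytest.approx(series(180.0), abs=1e-12)


class TestFitPolynomial:
    def test_exact_quartic_recovered(self):
        from cgfold.bonded import InvertedPotential
        coefs = np.array([0.5, -1.2, 3.0, 0.4, 2.2])
        x = np.linspace(-1, 1, 41)
        y = np.polynomial.polynomial.polyval(x, coefs)
        pot = InvertedPotential("bond", x, y - y.min(), T, "none")
        fit = fit_polynomial(pot, order=4)
        shifted = coefs.copy()
        shifted[0] -= y.min()
        np.testing.assert_allclose(fit.coefficients, shifted, atol=1e-9)

    def test_bimodal_flags_table_fallback(self):
        from cgfold.bonded import InvertedPotential
        x = np.linspace(-1, 1, 81)
        y = 10 * (x ** 2 - 0.5) ** 2   # double well
        pot = InvertedPotential("bond", x, y - y.min(), T, "none")
        fit = fit_polynomial(pot, order=2, residual_threshold=0.25)
        assert fit.use_table
        fit4 = fit_polynomial(pot, order=4, residual_threshold=0.25)
        assert not fit4.use_table

    def test_underdetermined_raises(self):
        from cgfold.bonded import InvertedPotential
        pot = InvertedPotential("bond", np.array([0.1, 0.2, 0.3]),
                                np.array([0.0, np.nan, np.nan]), T, "none")
        with pytest.raises(InversionError, match="underdetermined"):
            fit_polynomial(pot, order=2)


class TestFitCosineSeries:
    def _pot(self, fn):
        from cgfold.bonded import InvertedPotential
        grid = np.arange(-177.5, 180.0, 5.0)
        return InvertedPotential("torsion", grid, fn(grid), T, "none")

    def test_pure_cos_phi(self):
        fit = fit_cosine_series(self._pot(
            lambda p: np.cos(np.radians(p))))
        np.testing.assert_allclose(fit.coefficients,
                                   [0, 1, 0, 0, 0], atol=1e-10)

    def test_mixed_harmonics(self):
        fit = fit_cosine_series(self._pot(
            lambda p: 0.5 + 0.25 * np.cos(np.radians(3 * p))))
        np.testing.assert_allclose(fit.coefficients,
                                   [0.5, 0, 0, 0.25, 0], atol=1e-10)

    def test_series_matches_table_within_residual(self):
        pot_fn = lambda phi: 3.0 * (1 - np.cos(np.radians(2 * phi)))
        hist = bonded_histogram("torsion", pot_fn, T, 300_000, seed=9)
        inv = invert_torsion(hist)
        fit = fit_cosine_series(inv)
        sup = inv.supported
        rms = np.sqrt(np.mean((fit(inv.grid[sup]) - inv.values[sup]) ** 2))
        assert rms == pytest.approx(fit.rms_residual, rel=1e-9)


class TestTorsionLibrary:
    def _full_coeff_rows(self):
        return [(a, b, 0.1, 1.0, 0.0, 0.2, 0.0)
                for a in _STANDARD for b in _STANDARD]

    def test_full_library_has_400_entries(self):
        lib = build_torsion_library(
            {(a, b): np.array([0.1, 1.0, 0.0, 0.2, 0.0])
             for a in _STANDARD for b in _STANDARD})
        assert len(lib) == 400
        assert lib.check_complete() == []

    def test_scale_applied_to_min_shifted_potential(self):
        lib = build_torsion_library({("ALA", "ALA"): [0.0, 1.0, 0, 0, 0]},
                                    scale=0.54)
        series = lib[("ALA", "ALA")]
        grid = np.linspace(-180, 180, 721)
        base = CosineSeries(np.array([0.0, 1.0, 0, 0, 0]))
        scaled = series(grid) - series(grid).min()
        ref = 0.54 * (base(grid) - base(grid).min())
        np.testing.assert_allclose(scaled, ref, atol=1e-12)
        assert series.coefficients[1] == pytest.approx(0.54)

    def test_scale_one_is_identity_up_to_shift(self):
        lib = build_torsion_library({("GLY", "PRO"): [0.3, 0.5, 0, 0, 0.1]},
                                    scale=1.0)
        series = lib[("GLY", "PRO")]
        np.testing.assert_allclose(series.coefficients[1:],
                                   [0.5, 0, 0, 0.1], atol=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            build_torsion_library({("ALA", "ALA"): [0, 1, 0, 0, 0]}, scale=0)

    def test_fallback_entry_logged(self):
        lib = build_torsion_library({("ALA", "ALA"): [0, 1, 0, 0, 0]},
                                    fallback_key=("ALA", "ALA"))
        _ = lib[("TRP", "GLY")]
        assert ("TRP", "GLY") in lib.missing_pairs

    def test_round_trip_file(self, tmp_path):
        lib = build_torsion_library(
            {("ALA", "GLY"): [0.2, 0.8, -0.1, 0.05, 0.0]}, scale=0.54)
        path = tmp_path / "torsions.txt"
        lib.write(path)
        again = TorsionLibrary.read(path, scale=1.0, prescaled=False)
        # file stores post-scale coefficients; reading with scale=1 keeps them
        grid = np.linspace(-180, 180, 100)
        np.testing.assert_allclose(again[("ALA", "GLY")](grid),
                                   lib[("ALA", "GLY")](grid), atol=1e-6)


class TestBackboneAnglePotential:
    def test_bimodal_pool_quartic_brackets_wells(self):
        pot_fn = lambda th: 8.0 * (((th - 105.0) / 15.0) ** 2 - 1.0) ** 2
        hist = bonded_histogram("angle", pot_fn, T, 400_000, seed=21,
                                domain=(60.0, 150.0))
        fit = backbone_angle_potential(hist)
        assert fit.order == 4
        grid = np.linspace(70, 140, 701)
        v = fit(grid)
        # two local minima bracketing 90 and 120
        d = np.diff(np.sign(np.diff(v)))
        minima = grid[1:-1][d > 0]
        assert len(minima) == 2
        assert 80 < minima[0] < 100
        assert 110 < minima[1] < 130

    def test_single_well_near_harmonic(self):
        pot_fn = lambda th: 0.08 * (th - 100.0) ** 2
        hist = bonded_histogram("angle", pot_fn, T, 400_000, seed=22,
                                domain=(80.0, 120.0))
        fit = backbone_angle_potential(hist)
        # quartic reduces to near-harmonic: it agrees with a harmonic fit
        # over the well to within a small fraction of the sampled depth
        inv = invert_angle(hist)
        fit2 = fit_polynomial(inv, order=2)
        grid = np.linspace(85, 115, 301)
        depth = fit2(grid).max() - fit2(grid).min()
        rms = np.sqrt(np.mean((fit(grid) - fit2(grid)) ** 2))
        assert rms < 0.1 * depth

    def test_determinism(self):
        pot_fn = lambda th: 0.05 * (th - 95.0) ** 2
        h1 = bonded_histogram("angle", pot_fn, T, 100_000, seed=4,
                              domain=(70.0, 120.0))
        h2 = bonded_histogram("angle", pot_fn, T, 100_000, seed=4,
                              domain=(70.0, 120.0))
        f1 = backbone_angle_potential(h1)
        f2 = backbone_angle_potential(h2)
        np.testing.assert_array_equal(f1.coefficients, f2.coefficients)


class TestReBoltzmannization:
    def test_full_loop_consistency(self):
        # invert -> sample the recovered potential -> re-invert
        k_true, r0 = 800.0, 0.40
        pot_fn = lambda r: 0.5 * k_true * (r - r0) ** 2
        h1 = bonded_histogram("bond", pot_fn, T, 400_000, seed=31,
                              domain=(0.30, 0.50))
        inv1 = invert_bond(h1)
        fit1 = fit_polynomial(inv1, order=2)
        h2 = bonded_histogram("bond", lambda r: fit1(r), T, 400_000, seed=32,
                              domain=(0.30, 0.50))
        inv2 = invert_bond(h2)
        fit2 = fit_polynomial(inv2, order=2)
        k1 = 2 * fit1.coefficients[2]
        k2 = 2 * fit2.coefficients[2]
        assert k2 == pytest.approx(k1, rel=0.08)


class TestPotentialSerialization:
    def test_round_trip(self, tmp_path):
        pot_fn = lambda r: 0.5 * 500 * (r - 0.4) ** 2
        hist = bonded_histogram("bond", pot_fn, T, 50_000, seed=2,
                                domain=(0.3, 0.5))
        pot = invert_bond(hist)
        buf = io.StringIO()
        write_potential(pot, buf)
        buf.seek(0)
        again = read_potential(buf)
        assert again.kind == "bond"
        assert again.temperature == T
        np.testing.assert_allclose(again.grid, pot.grid, atol=1e-6)
        finite = np.isfinite(pot.values)
        np.testing.assert_allclose(again.values[finite], pot.values[finite],
                                   rtol=1e-6)
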