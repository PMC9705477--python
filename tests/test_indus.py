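"""Hydration volumes, coarse water counting, UWHAM unbiasing."""

import warnings

import numpy as np
import pytest

from oracles import binned_wham, double_well_beta_f

from coacerlab import synth
from coacerlab.errors import InputError, ParameterError
from coacerlab.indus import (
    FreeEnergyProfile,
    IndusParams,
    MolecularFrame,
    UmbrellaWindow,
    coarse_count,
    hydration_volume,
    mean_per_water_cost,
    more_hydrophobic,
    parse_nstar_schedule,
    per_water_profile,
    sample_model_biased,
    sharp_count,
    uwham_unbias,
)


def _unbias_quiet(windows, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return uwham_unbias(windows, **kw)


class TestHydrationVolume:
    def test_single_atom_sphere_volume(self):
        frame = MolecularFrame([[1, 1, 1]], np.empty((0, 3)))
        vol = hydration_volume(frame, [0], 0.55)
        analytic = 4 / 3 * np.pi * 0.55**3
        assert analytic == pytest.approx(0.697, abs=0.001)
        assert vol.monte_carlo_volume(400_000, seed=1) == pytest.approx(
            analytic, rel=0.01
        )

    def test_coincident_atoms_union_is_single_sphere(self):
        frame = MolecularFrame([[1, 1, 1], [1, 1, 1]], np.empty((0, 3)))
        vol = hydration_volume(frame, [0, 1], 0.55)
        assert vol.monte_carlo_volume(400_000, seed=2) == pytest.approx(
            4 / 3 * np.pi * 0.55**3, rel=0.01
        )

    def test_disjoint_spheres_add(self):
        frame = MolecularFrame([[1, 1, 1], [3, 1, 1]], np.empty((0, 3)))
        vol = hydration_volume(frame, [0, 1], 0.55)
        assert vol.monte_carlo_volume(800_000, seed=3) == pytest.approx(
            2 * 4 / 3 * np.pi * 0.55**3, rel=0.01
        )

    def test_empty_index_set_rejected(self):
        frame = MolecularFrame([[1, 1, 1]], np.empty((0, 3)))
        with pytest.raises(InputError):
            hydration_volume(frame, [], 0.55)


class TestCounting:
    def test_sharp_count_trivials(self):
        frame = MolecularFrame([[1, 1, 1]], np.empty((0, 3)))
        vol = hydration_volume(frame, [0], 0.55)
        assert sharp_count(frame, vol) == 0
        frame2 = MolecularFrame([[1, 1, 1]], [[1, 1, 1]])
        assert sharp_count(frame2, hydration_volume(frame2, [0], 0.55)) == 1

    def test_poisson_mean_count_matches_density_times_union_volume(self):
        density = 20.0
        counts = []
        for seed in range(100):
            frame = synth.gen_solvated_frame(
                [[2, 2, 2], [2.6, 2, 2]], density, (5, 5, 5), seed=seed
            )
            vol = hydration_volume(frame, [0, 1], 0.55)
            counts.append(sharp_count(frame, vol))
        union = vol.monte_carlo_volume(400_000, seed=0)
        expected = density * union
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_coarse_contribution_boundaries(self):
        frame = MolecularFrame([[2, 2, 2]], [[2, 2, 2]])
        vol = hydration_volume(frame, [0], 0.55)
        assert coarse_count(frame, vol) == pytest.approx(1.0)
        far = MolecularFrame([[2, 2, 2]], [[2 + 0.55 + 0.03, 2, 2]])
        assert coarse_count(far, vol) == 0.0

    def test_coarse_equals_sharp_away_from_surface(self, rng):
        for _ in range(20):
            frame = synth.gen_solvated_frame(
                [[2, 2, 2]], 10.0, (4, 4, 4), seed=rng.integers(1 << 31)
            )
            vol = hydration_volume(frame, [0], 0.55)
            d = np.linalg.norm(frame.water_oxygen_positions - [2, 2, 2], axis=1)
            if np.any(np.abs(d - 0.55) <= 0.02):
                continue  # only exact far from the smoothing shell
            assert coarse_count(frame, vol) == pytest.approx(
                sharp_count(frame, vol), abs=1e-9
            )

    def test_coarse_minus_sharp_bounded_by_surface_waters(self):
        for seed in range(100):
            frame = synth.gen_solvated_frame(
                [[2, 2, 2], [2.4, 2.2, 2]], 15.0, (4, 4, 4), seed=seed
            )
            vol = hydration_volume(frame, [0, 1], 0.55)
            d = np.min(
                np.linalg.norm(
                    frame.water_oxygen_positions[:, None]
                    - vol.centers_nm[None],
                    axis=2,
                ),
                axis=1,
            )
            n_surface = np.count_nonzero(np.abs(d - 0.55) <= 0.02)
            diff = abs(coarse_count(frame, vol) - sharp_count(frame, vol))
            assert diff <= n_surface + 1e-9

    def test_coarse_converges_to_sharp_as_kernel_shrinks(self):
        frame = synth.gen_solvated_frame([[2, 2, 2]], 25.0, (4, 4, 4), seed=5)
        vol = hydration_volume(frame, [0], 0.55)
        target = sharp_count(frame, vol)
        diffs = [
            abs(coarse_count(frame, vol, sigma_nm=s, rc_nm=2 * s) - target)
            for s in (0.02, 0.005, 0.00125)
        ]
        assert diffs[-1] <= diffs[0] and diffs[-1] < 0.05

    def test_kernel_truncation_must_exceed_width(self):
        frame = MolecularFrame([[1, 1, 1]], [[1, 1, 1]])
        vol = hydration_volume(frame, [0], 0.55)
        with pytest.raises(ParameterError):
            coarse_count(frame, vol, sigma_nm=0.02, rc_nm=0.01)


class TestUwham:
    def test_single_unbiased_window_reduces_to_histogram(self, rng):
        samples = rng.choice([3.0, 4.0, 5.0], size=3000, p=[0.2, 0.5, 0.3])
        window = UmbrellaWindow(nstar=0.0, kappa_kt=0.0, samples=samples)
        profile = _unbias_quiet([window])
        counts = np.array([(samples == v).sum() for v in (3, 4, 5)])
        expected = -np.log(counts / counts.sum())
        np.testing.assert_allclose(
            profile.beta_f, expected - expected.min(), atol=1e-9
        )

    def test_two_identical_windows_match_pooled_single_window(self, rng):
        samples = rng.normal(10, 2, size=4000).clip(0).round()
        w = lambda s: UmbrellaWindow(nstar=10.0, kappa_kt=0.5, samples=s)
        two = _unbias_quiet([w(samples[:2000]), w(samples[2000:])])
        one = _unbias_quiet([w(samples)])
        np.testing.assert_allclose(two.beta_f, one.beta_f, atol=1e-6)

    def test_double_well_recovered_with_overlapping_ladder(self, double_well):
        """κ=0.5 kBT windows every integer resolve the landscape to 0.1 kBT."""
        n, f_true = double_well
        lookup = dict(zip(n, f_true))
        for seed in (1, 2, 3):
            windows = synth.gen_umbrella_windows(
                double_well, 0.5, "{-9..1..54}", 5000, seed=seed
            )
            profile = _unbias_quiet(windows)
            errs = [
                abs(bf - lookup[int(g)])
                for g, bf in zip(profile.n_grid, profile.beta_f)
                if lookup.get(int(g), np.inf) <= 8.0
            ]
            assert max(errs) <= 0.1

    def test_agrees_with_binned_wham_oracle(self, double_well):
        windows = synth.gen_umbrella_windows(
            double_well, 0.5, "{-9..1..54}", 5000, seed=1
        )
        profile = _unbias_quiet(windows)
        centers, f_oracle = binned_wham(windows)
        oracle = dict(zip(np.round(centers).astype(int), f_oracle))
        n, f_true = double_well
        lookup = dict(zip(n, f_true))
        errs = [
            abs(bf - oracle[int(g)])
            for g, bf in zip(profile.n_grid, profile.beta_f)
            if int(g) in oracle and lookup.get(int(g), np.inf) <= 8.0
        ]
        assert max(errs) <= 0.05

    def test_invariant_under_window_permutation(self, double_well, rng):
        windows = synth.gen_umbrella_windows(
            double_well, 0.5, "{-9..1..54}", 2000, seed=4
        )
        base = _unbias_quiet(windows)
        shuffled = [windows[i] for i in rng.permutation(len(windows))]
        perm = _unbias_quiet(shuffled)
        np.testing.assert_array_equal(base.n_grid, perm.n_grid)
        np.testing.assert_allclose(base.beta_f, perm.beta_f, atol=1e-6)

    def test_dropping_redundant_window_changes_little(self, double_well):
        windows = synth.gen_umbrella_windows(
            double_well, 0.5, "{-9..1..54}", 5000, seed=6
        )
        base = _unbias_quiet(windows)
        # drop one interior window whose support neighbours fully cover
        reduced = _unbias_quiet(windows[:20] + windows[21:])
        common = np.intersect1d(base.n_grid, reduced.n_grid)
        fb = dict(zip(base.n_grid, base.beta_f))
        fr = dict(zip(reduced.n_grid, reduced.beta_f))
        errs = [abs(fb[c] - fr[c]) for c in common if fb[c] <= 8.0]
        assert max(errs) < 0.1

    def test_disconnected_window_chain_rejected(self, rng):
        w1 = UmbrellaWindow(5.0, 10.0, rng.normal(5, 0.3, 500).clip(0))
        w2 = UmbrellaWindow(40.0, 10.0, rng.normal(40, 0.3, 500).clip(0))
        with pytest.raises(InputError):
            uwham_unbias([w1, w2])

    def test_sample_model_biased_delegates_to_generator(self, double_well):
        params = IndusParams(kappa_kt=5.0)
        window = sample_model_biased(double_well, params, 12.0, 500, seed=9)
        assert window.nstar == 12.0
        assert window.kappa_kt == 5.0
        assert window.n_equilibration_discarded == 0
        assert len(window.samples) == 500

    def test_negative_nstar_pushes_toward_empty_volume(self, double_well):
        windows = synth.gen_umbrella_windows(double_well, 10.0, [-9.0], 500, 0)
        assert windows[0].samples.min() >= 0
        assert windows[0].samples.max() <= 2


class TestPerWater:
    def test_quadratic_profile_has_linear_per_water_cost(self):
        n0, s = 20, 2.0
        grid = np.arange(0, 31)
        beta_f = (grid - n0) ** 2 / (2 * s)
        profile = FreeEnergyProfile(grid, beta_f - beta_f.min(), n0)
        x, y = per_water_profile(profile)
        expected = (n0 - grid[grid < n0]) / (2 * s)
        np.testing.assert_allclose(y, expected, rtol=1e-12)
        np.testing.assert_allclose(x, grid[grid < n0] / n0)

    def test_flat_profile_costs_nothing_per_water(self):
        grid = np.arange(0, 21)
        profile = FreeEnergyProfile(grid, np.zeros(21), n0=10)
        x, y = per_water_profile(profile)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_monotone_boundary_profile_rejected(self):
        grid = np.arange(0, 10)
        profile = FreeEnergyProfile(grid, grid.astype(float), n0=0)
        with pytest.raises(InputError):
            per_water_profile(profile)

    def test_lower_cost_profile_classified_more_hydrophobic(self):
        grid = np.arange(0, 31)
        shallow = FreeEnergyProfile(grid, (grid - 20) ** 2 / 40.0, 20)
        steep = FreeEnergyProfile(grid, (grid - 20) ** 2 / 10.0, 20)
        assert more_hydrophobic(shallow, steep)
        assert mean_per_water_cost(shallow) < mean_per_water_cost(steep)


def test_schedule_parser_rejects_malformed_strings():
    assert parse_nstar_schedule("{0..5..20}") == [0, 5, 10, 15, 20]
    with pytest.raises(ParameterError):
        parse_nstar_schedule("0..5..20")
    with pytest.raises(ParameterError):
        parse_nstar_schedule("{0..-5..20}")
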