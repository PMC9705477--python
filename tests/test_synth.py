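"""Generators: determinism, analytic moments, documented failure modes."""

import numpy as np
import pytest
from scipy import stats

from coacerlab import synth
from coacerlab.constants import stokes_einstein_diffusivity
from coacerlab.errors import ParameterError
from coacerlab.indus import parse_nstar_schedule, sharp_count, hydration_volume


GENERATORS = [
    lambda seed: synth.gen_brownian_tracks(
        0.3052, n_particles=3, n_frames=50, seed=seed
    ).x_um,
    lambda seed: synth.gen_echo_decay(
        2.4e-9, np.linspace(0, 80, 16), noise_sd=0.02, seed=seed
    ).attenuation,
    lambda seed: synth.gen_coalescence_series(
        28.47, 4.2e-3, 10e-6, noise_sd=0.01, seed=seed
    ).aspect,
    lambda seed: synth.gen_turbidity_profile(
        [(0, 80)], np.linspace(0, 200, 100), noise_sd=0.02, seed=seed
    ).od600,
    lambda seed: synth.gen_umbrella_windows(
        {n: 0.0 for n in range(40)}, 1.0, [20.0], 200, seed=seed
    )[0].samples,
    lambda seed: synth.gen_solvated_frame(
        [[1, 1, 1]], 10.0, (2, 2, 2), seed=seed
    ).water_oxygen_positions,
    lambda seed: synth.gen_chain_ensemble(
        n_beads=10, n_frames=5, seed=seed
    ).frames,
]


@pytest.mark.parametrize("gen", GENERATORS)
def test_generators_deterministic_given_seed(gen):
    """Same parameters and seed must reproduce byte-identical data."""
    a, b = gen(42), gen(42)
    np.testing.assert_array_equal(np.asarray(a), np.asarray(b))
    c = gen(43)
    assert not np.array_equal(np.asarray(a), np.asarray(c))


class TestBrownianTracks:
    def test_stokes_einstein_diffusivity_matches_hand_value(self):
        # kB*295.15 / (6*pi*0.3052 Pa s*1e-6 m) evaluated by hand
        d = stokes_einstein_diffusivity(0.3052, 1e-6, 295.15)
        assert d == pytest.approx(7.08e-16, rel=5e-3)

    def test_single_step_variance_is_2dt_per_axis(self):
        dt, eta = 0.02, 0.3052
        d = stokes_einstein_diffusivity(eta, 1e-6, 295.15)
        tracks = synth.gen_brownian_tracks(
            eta, frame_interval_s=dt, n_frames=2, n_particles=4000, seed=0
        )
        x = tracks.x_um.reshape(4000, 2) * 1e-6
        var = np.var(np.diff(x, axis=1))
        expected = 2 * d * dt
        se = expected * np.sqrt(2 / 4000)  # SE of a variance estimate
        assert abs(var - expected) < 3 * se

    def test_localization_noise_inflates_msd_offset(self):
        noise = 0.05e-6
        tracks = synth.gen_brownian_tracks(
            30.0, frame_interval_s=1.0, n_frames=2, n_particles=8000,
            noise_sd_m=noise, seed=1,
        )
        d = stokes_einstein_diffusivity(30.0, 1e-6, 295.15)
        xy = np.column_stack([tracks.x_um, tracks.y_um]).reshape(8000, 2, 2)
        sq = np.sum((xy[:, 1] - xy[:, 0]) ** 2, axis=1) * 1e-12
        expected = 4 * d * 1.0 + 4 * noise**2
        assert np.mean(sq) == pytest.approx(expected, rel=0.1)

    @pytest.mark.parametrize("bad", [
        dict(viscosity_pa_s=-1.0),
        dict(viscosity_pa_s=1.0, probe_radius_m=0.0),
        dict(viscosity_pa_s=1.0, temperature_k=-5.0),
        dict(viscosity_pa_s=1.0, n_frames=1),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            synth.gen_brownian_tracks(**bad)


class TestEchoDecay:
    def test_zero_diffusion_gives_unit_attenuation(self):
        decay = synth.gen_echo_decay(0.0, np.linspace(0, 80, 16))
        np.testing.assert_allclose(decay.attenuation, 1.0)

    def test_zero_gradient_entry_gives_unit_attenuation(self):
        decay = synth.gen_echo_decay(2.4e-9, np.array([0.0, 40.0, 80.0]))
        assert decay.attenuation[0] == 1.0

    def test_log_attenuation_quadratic_in_gradient(self):
        g = np.linspace(5, 80, 16)
        decay = synth.gen_echo_decay(2.4e-9, g)
        y = -np.log(decay.attenuation)
        assert np.all(np.diff(y) > 0)
        ratio = y / g**2
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_nonpositive_diffusion_time_rejected(self):
        with pytest.raises(ParameterError):
            synth.gen_echo_decay(
                1e-9, np.linspace(0, 80, 4), delta_s=3e-3, big_delta_s=1e-3
            )


class TestCoalescence:
    def test_decay_time_matches_hand_evaluation(self):
        # tau = 0.95 * 28.47 * 1e-5 / 4.20e-3 = 0.0644 s
        series = synth.gen_coalescence_series(28.47, 4.20e-3, 10e-6)
        assert series.ground_truth.params["tau"][0] == pytest.approx(
            0.0644, rel=1e-3
        )

    def test_initial_aspect_equals_a0_without_noise(self):
        series = synth.gen_coalescence_series(1.0, 1e-3, 10e-6, a0=0.37)
        assert series.aspect[0] == 0.37

    def test_doubling_tension_halves_decay_time(self):
        t1 = synth.gen_coalescence_series(1.0, 1e-3, 1e-5)
        t2 = synth.gen_coalescence_series(1.0, 2e-3, 1e-5)
        assert t1.ground_truth.params["tau"][0] == pytest.approx(
            2 * t2.ground_truth.params["tau"][0]
        )

    @pytest.mark.parametrize("a0", [0.0, 1.0, -0.2, 1.5])
    def test_aspect_amplitude_outside_unit_interval_rejected(self, a0):
        with pytest.raises(ParameterError):
            synth.gen_coalescence_series(1.0, 1e-3, 1e-5, a0=a0)


class TestTurbidity:
    def test_no_windows_gives_flat_zero_curve(self):
        curve = synth.gen_turbidity_profile([], np.linspace(0, 100, 50))
        np.testing.assert_array_equal(curve.od600, 0.0)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ParameterError):
            synth.gen_turbidity_profile(
                [(0, 80), (50, 120)], np.linspace(0, 200, 50)
            )

    def test_hysteresis_shifts_heating_and_cooling_apart(self):
        grid = np.linspace(0, 70, 400)
        heat = synth.gen_turbidity_profile(
            [(20, 50)], grid, sharpness=1.0, ramp="heating", hysteresis_shift=4.0
        )
        cool = synth.gen_turbidity_profile(
            [(20, 50)], grid, sharpness=1.0, ramp="cooling", hysteresis_shift=4.0
        )
        # heating curve edge sits ~4 units above the cooling curve edge
        mid = 0.5 * heat.od600.max()
        t_heat = grid[np.argmax(heat.od600 >= mid)]
        t_cool = grid[np.argmax(cool.od600 >= mid)]
        assert t_heat - t_cool == pytest.approx(4.0, abs=0.5)


class TestUmbrellaSampling:
    def test_stiff_spring_pins_samples_to_nearest_integer(self):
        f_model = {n: 0.0 for n in range(41)}
        (w,) = synth.gen_umbrella_windows(f_model, 1e3, [20.0], 500, seed=0)
        np.testing.assert_array_equal(w.samples, 20.0)

    def test_flat_landscape_sampling_matches_discretized_gaussian(self):
        f_model = {n: 0.0 for n in range(41)}
        kappa, nstar, n_samp = 1.0, 20.0, 20000
        (w,) = synth.gen_umbrella_windows(f_model, kappa, [nstar], n_samp, seed=3)
        grid = np.arange(41)
        p = np.exp(-0.5 * kappa * (grid - nstar) ** 2)
        p /= p.sum()
        keep = p * n_samp >= 5
        observed = np.array([(w.samples == n).sum() for n in grid[keep]])
        expected = p[keep] * n_samp
        # fold in the tail mass so counts total n_samp
        observed = np.append(observed, n_samp - observed.sum())
        expected = np.append(expected, n_samp - expected.sum())
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01

    def test_schedule_string_parses_inclusive_range(self):
        sched = parse_nstar_schedule("{-9..3..54}")
        assert len(sched) == 22
        assert sched[0] == -9 and sched[1] == -6 and sched[-1] == 54

    def test_empty_schedule_rejected(self):
        with pytest.raises(ParameterError):
            synth.gen_umbrella_windows({0: 0.0, 1: 0.0}, 1.0, [], 10, 0)


class TestSolvatedFrame:
    def test_zero_density_gives_no_waters(self):
        frame = synth.gen_solvated_frame([[1, 1, 1]], 0.0, (2, 2, 2))
        assert len(frame.water_oxygen_positions) == 0

    def test_water_count_is_poisson_with_mean_density_times_volume(self):
        counts = [
            len(
                synth.gen_solvated_frame(
                    [[2, 2, 2]], 5.0, (4, 4, 4), seed=s
                ).water_oxygen_positions
            )
            for s in range(200)
        ]
        mean = 5.0 * 64
        se = np.sqrt(mean / 200)
        assert abs(np.mean(counts) - mean) < 3 * se

    def test_in_shell_count_matches_sphere_volume_arithmetic(self):
        # 33 waters/nm^3 * (4/3) pi 0.55^3 = 23.0 expected in one shell
        density, rv = 33.0, 0.55
        counts = []
        for s in range(150):
            frame = synth.gen_solvated_frame(
                [[3, 3, 3]], density, (6, 6, 6), seed=s
            )
            vol = hydration_volume(frame, [0], rv)
            counts.append(sharp_count(frame, vol))
        expected = density * 4 / 3 * np.pi * rv**3
        se = np.sqrt(expected / 150)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_solute_outside_box_rejected(self):
        with pytest.raises(ParameterError):
            synth.gen_solvated_frame([[5, 1, 1]], 1.0, (2, 2, 2))


class TestChainEnsemble:
    def test_two_beads_end_to_end_is_bond_length(self):
        from coacerlab.chain import end_to_end

        ens = synth.gen_chain_ensemble(n_beads=2, bond_length_nm=0.4, n_frames=20)
        for frame in ens.frames:
            assert end_to_end(frame, (0, 1)) == pytest.approx(0.4)

    def test_freely_jointed_mean_square_end_to_end(self):
        from coacerlab.chain import end_to_end

        n, b = 50, 0.38
        ens = synth.gen_chain_ensemble(
            n_beads=n, bond_length_nm=b, n_frames=2000, seed=5
        )
        dee2 = np.array(
            [end_to_end(f, (0, n - 1)) ** 2 for f in ens.frames]
        )
        expected = (n - 1) * b**2
        se = np.std(dee2) / np.sqrt(len(dee2))
        assert abs(dee2.mean() - expected) < 3 * se

    def test_self_avoiding_respects_hardcore_distance(self):
        ens = synth.gen_chain_ensemble(
            "self_avoiding", n_beads=15, bond_length_nm=0.4, n_frames=10, seed=2
        )
        for frame in ens.frames:
            d = np.linalg.norm(frame[:, None] - frame[None, :], axis=2)
            iu = np.triu_indices(15, k=2)
            assert np.all(d[iu] >= 0.9 * 0.4 - 1e-9)
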