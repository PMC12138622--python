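"""Generator contracts: determinism, calibration recovery, validation."""

import numpy as np
import pytest

from kpbiofilm import dynamics as dyn
from kpbiofilm import synthetic_data as synth
from kpbiofilm.errors import ConfigurationError, ParameterError

KP_40_60 = synth.CompositionSpec(kombucha_fraction=0.60, proteinoid_fraction=0.40)
KP_25_75 = synth.CompositionSpec(kombucha_fraction=0.75, proteinoid_fraction=0.25)


class TestCompositionSpec:
    def test_fraction_and_label_consistency(self):
        with pytest.raises(ConfigurationError):
            synth.CompositionSpec(0.5, 0.4)
        with pytest.raises(ConfigurationError):
            synth.CompositionSpec(1.0, 0.0, label="P")
        synth.CompositionSpec(1.0, 0.0, label="K")  # valid pure Kombucha

    def test_chaos_mapping_ordering(self):
        assert synth.default_chaos_level(KP_40_60) == 0.0
        assert synth.default_chaos_level(KP_25_75) == pytest.approx(0.9)
        assert synth.default_chaos_level(synth.CompositionSpec(1.0, 0.0, "K")) == pytest.approx(0.9)


class TestSinusoidResponse:
    def test_output_amplitude_matches_gain(self):
        cfg = synth.GeneratorConfig(seed=1)
        _, out = synth.generate_sinusoid_response(KP_40_60, cfg)
        amp = (out.potential.max() - out.potential.min()) / 2
        assert amp == pytest.approx(229.08, rel=0.01)

    def test_noiseless_regular_output_is_exact_scaled_sinusoid(self):
        cfg = synth.GeneratorConfig(seed=2, noise_sd=0.0, chaos_level=0.0)
        v_in, v_out = synth.generate_sinusoid_response(KP_40_60, cfg)
        # reconstruct analytically: gain-scaled, phase-lagged copy of the drive
        amp_ratio = cfg.output_gain
        t = v_in.time
        phase_in = np.arctan2(v_in.potential[0] / cfg.input_amplitude,
                              np.cos(np.arcsin(np.clip(v_in.potential[0] / cfg.input_amplitude, -1, 1))))
        omega = 2 * np.pi * cfg.input_frequency
        # cross-check via least squares rather than phase bookkeeping
        X = np.column_stack([np.sin(omega * t), np.cos(omega * t)])
        resid = v_out.potential - X @ np.linalg.lstsq(X, v_out.potential, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-9 * cfg.input_amplitude * amp_ratio

    def test_same_seed_is_bit_identical(self):
        cfg = synth.GeneratorConfig(seed=7)
        a = synth.generate_sinusoid_response(KP_25_75, cfg)
        b = synth.generate_sinusoid_response(KP_25_75, cfg)
        np.testing.assert_array_equal(a[1].potential, b[1].potential)
        np.testing.assert_array_equal(a[0].potential, b[0].potential)

    def test_invalid_config_names_the_field(self):
        with pytest.raises(ConfigurationError, match="sampling_rate"):
            synth.GeneratorConfig(sampling_rate=0.03, input_frequency=0.02)
        with pytest.raises(ConfigurationError, match="noise_sd"):
            synth.GeneratorConfig(noise_sd=-1.0)
        with pytest.raises(ConfigurationError, match="chaos_level"):
            synth.GeneratorConfig(chaos_level=1.5)

    def test_chaotic_component_strength_rises_with_chaos_level(self):
        t_resid = []
        for level in (0.0, 0.3, 0.9):
            cfg = synth.GeneratorConfig(seed=3, chaos_level=level)
            _, out = synth.generate_sinusoid_response(KP_40_60, cfg)
            t = out.time
            omega = 2 * np.pi * cfg.input_frequency
            X = np.column_stack([np.sin(omega * t), np.cos(omega * t)])
            resid = out.potential - X @ np.linalg.lstsq(X, out.potential, rcond=None)[0]
            t_resid.append(resid.std())
        assert t_resid[0] < t_resid[1] < t_resid[2]


class TestIVGenerator:
    def test_degenerate_hysteresis_closes_the_loop(self):
        params = synth.IVGeneratorParams(
            target_mean=0.0, target_sd=1.0, hysteresis_strength=0.0,
            n_sweeps=1, n_points_per_sweep=200, noise_scale=0.0,
        )
        sweep = synth.generate_iv_sweeps(params, seed=0)
        # pure conductor: i proportional to v, zero enclosed loop area
        g = sweep.current[10] / sweep.voltage[10]
        np.testing.assert_allclose(sweep.current, g * sweep.voltage, atol=1e-12)

    def test_hysteresis_opens_a_pinched_loop(self):
        params = synth.IVGeneratorParams(
            target_mean=0.0, target_sd=1.0, hysteresis_strength=2.0,
            n_sweeps=2, n_points_per_sweep=400, noise_scale=0.0,
        )
        sweep = synth.generate_iv_sweeps(params, seed=0)
        # forward and reverse currents differ away from v = 0
        cyc = sweep.current[400:800]
        v = sweep.voltage[400:800]
        up, down = cyc[:200], cyc[200:][::-1]
        assert np.max(np.abs(up - down)) > 0.01
        # pinched: current vanishes with voltage
        assert np.all(np.abs(cyc[np.abs(v) < 1e-9]) < 1e-12)

    def test_unattainable_moment_targets_rejected(self):
        with pytest.raises(ParameterError):
            synth.IVGeneratorParams(target_mean=0.0, target_sd=1.0,
                                    target_skewness=1.0, target_kurtosis=1.5)

    def test_asymmetric_voltage_range_rejected(self):
        with pytest.raises(ParameterError):
            synth.IVGeneratorParams(target_mean=0.0, target_sd=1.0, v_range=(-1.0, 2.0))

    def test_determinism(self):
        params = synth.IVGeneratorParams(target_mean=-0.15, target_sd=3.25)
        a = synth.generate_iv_sweeps(params, seed=4)
        b = synth.generate_iv_sweeps(params, seed=4)
        np.testing.assert_array_equal(a.current, b.current)


class TestFleishman:
    @pytest.mark.parametrize(
        "skew,kurt", [(0.0, 3.0), (0.4, 4.53), (-0.39, 2.80), (1.0, 6.0)]
    )
    def test_sample_moments_recover_targets(self, skew, kurt):
        rng = np.random.default_rng(0)
        x = synth.moment_shaped_sample(rng, 200_000, mean=1.0, sd=2.0,
                                       skewness=skew, kurtosis=kurt)
        from scipy import stats as sps

        assert x.mean() == pytest.approx(1.0, abs=0.05)
        assert x.std() == pytest.approx(2.0, abs=0.05)
        assert sps.skew(x) == pytest.approx(skew, abs=0.08)
        assert sps.kurtosis(x, fisher=False) == pytest.approx(kurt, abs=0.25)

    def test_infeasible_pair_raises(self):
        with pytest.raises(ParameterError):
            synth.fleishman_coefficients(0.0, -2.5)


class TestSpectrumGenerator:
    def test_noiseless_round_trip_is_exact(self):
        from kpbiofilm import impedance as imp

        params = synth.SpectrumGeneratorParams(noise_fraction=0.0)
        spec = synth.generate_impedance_spectrum(params, seed=0)
        cs = imp.conductivity_from_capacitance(spec)
        np.testing.assert_allclose(cs.sigma, synth.design_sigma_profile(params), rtol=1e-9)

    def test_determinism_with_noise(self):
        params = synth.SpectrumGeneratorParams(noise_fraction=0.05)
        a = synth.generate_impedance_spectrum(params, seed=9)
        b = synth.generate_impedance_spectrum(params, seed=9)
        np.testing.assert_array_equal(a.capacitance, b.capacitance)

    def test_invalid_targets(self):
        with pytest.raises(ParameterError):
            synth.SpectrumGeneratorParams(baseline_sigma=-0.1)
        with pytest.raises(ParameterError):
            synth.SpectrumGeneratorParams(spike_band=(1.0, 2.0))  # outside grid


class TestSphereImages:
    def test_single_disk_ground_truth_diameter(self):
        spec = synth.ImageFixtureSpec(
            canvas_size=(600, 600), pixel_size=4.34, sphere_diameters=(1800.0,),
        )
        img, truth = synth.generate_sphere_image(spec, seed=0)
        assert len(truth) == 1
        assert truth.particles[0].equivalent_diameter == 1800.0
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_zero_spheres_is_pure_noise(self):
        spec = synth.ImageFixtureSpec(canvas_size=(64, 64), sphere_diameters=())
        img, truth = synth.generate_sphere_image(spec, seed=1)
        assert len(truth) == 0
        assert img.std() > 0

    def test_fifty_nanospheres_counted(self):
        spec = synth.ImageFixtureSpec(
            canvas_size=(256, 256), pixel_size=1.0,
            sphere_diameters=tuple([23.5] * 50),
        )
        _, truth = synth.generate_sphere_image(spec, seed=2)
        assert len(truth) == 50

    def test_overlap_flagged(self):
        spec = synth.ImageFixtureSpec(
            canvas_size=(128, 128), pixel_size=1.0,
            sphere_diameters=(30.0, 30.0),
            sphere_centers=((60.0, 60.0), (60.0, 70.0)),
        )
        _, truth = synth.generate_sphere_image(spec, seed=0)
        assert all(p.flag == "overlap" for p in truth.particles)

    def test_sphere_must_fit(self):
        with pytest.raises(ParameterError):
            synth.ImageFixtureSpec(canvas_size=(50, 50), pixel_size=1.0,
                                   sphere_diameters=(100.0,))


class TestCompositionDynamicsOrdering:
    def test_regular_versus_chaotic_trace(self):
        cfg = synth.GeneratorConfig(seed=5)
        _, lo = synth.generate_sinusoid_response(KP_40_60, cfg)
        _, hi = synth.generate_sinusoid_response(KP_25_75, cfg)
        h_lo = dyn.shannon_entropy(lo).H
        h_hi = dyn.shannon_entropy(hi).H
        assert h_lo < h_hi
        le_lo = dyn.largest_lyapunov(lo, dyn.EmbeddingConfig(tau=12, m=2, theiler_window=50))
        le_hi = dyn.largest_lyapunov(hi, dyn.EmbeddingConfig(tau=1, m=3, theiler_window=12),
                                     fit_range=(0, 4))
        assert le_lo <= 0.0
        assert le_hi > 0.0
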