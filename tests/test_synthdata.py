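import numpy as np
import pytest
from scipy import stats

from spikecodec.detection import noise_sigma
from spikecodec.synthdata import (
    GeometryConfig,
    NeuronSpec,
    TARGET_BASE_COORDS,
    WaveformParams,
    bandpass_filter,
    default_electrode_positions,
    estimate_snr,
    make_surrogate_library,
    mean_snr,
    place_noise_neurons,
    place_target_neurons,
    sample_spike_train,
    synthesize_recording,
    template_shape,
    waveform_at_site,
)
from spikecodec.workbench import simulate_condition


def single_site_geometry(**kw):
    return GeometryConfig(electrode_positions=default_electrode_positions()[9:10], **kw)


class TestNoiseNeuronPlacement:
    def test_positions_inside_hollow_cylinder(self):
        geom = GeometryConfig()
        neurons = place_noise_neurons(geom, seed=0)
        assert len(neurons) == round(geom.noise_density_per_cm3 * geom.cylinder_volume_cm3)
        for n in neurons:
            r = np.hypot(n.position[0], n.position[1])
            assert geom.cylinder_inner_um <= r <= geom.cylinder_outer_um
            assert abs(n.position[2]) <= geom.cylinder_halfheight_um
            assert 1.0 <= n.mean_rate <= 50.0

    def test_zero_expected_count_gives_empty_list(self):
        geom = GeometryConfig(noise_density_per_cm3=1.0)  # << 1 expected in the shell
        assert place_noise_neurons(geom, seed=0) == []

    def test_nonpositive_density_rejected(self):
        geom = GeometryConfig()
        geom.noise_density_per_cm3 = 0.0
        with pytest.raises(ValueError):
            place_noise_neurons(geom, seed=0)

    def test_radial_distribution_uniform_in_volume(self):
        """Monte-Carlo radii follow the annular CDF (r^2-r_in^2)/(r_out^2-r_in^2)."""
        geom = GeometryConfig(noise_density_per_cm3=3e5 * 10_000 / 41)  # ~10k neurons
        neurons = place_noise_neurons(geom, seed=42)
        r = np.array([np.hypot(n.position[0], n.position[1]) for n in neurons])
        u = (r**2 - geom.cylinder_inner_um**2) / (
            geom.cylinder_outer_um**2 - geom.cylinder_inner_um**2
        )
        counts, _ = np.histogram(u, bins=10, range=(0, 1))
        chi2 = np.sum((counts - len(u) / 10) ** 2 / (len(u) / 10))
        assert chi2 < stats.chi2.ppf(0.999, df=9)

    def test_reproducible_for_fixed_seed(self):
        geom = GeometryConfig()
        a = place_noise_neurons(geom, seed=5)
        b = place_noise_neurons(geom, seed=5)
        assert all(np.array_equal(x.position, y.position) for x, y in zip(a, b))


class TestTargetNeuronPlacement:
    def test_printed_coordinates_at_unit_scale(self):
        neurons = place_target_neurons(snr_scale=1.0, seed=0)
        expected = [(10, 20, -2), (-2, 18, 20), (-20, -5, -10), (16, -13, 15)]
        for n, e in zip(neurons, expected):
            assert np.allclose(n.position, e)
            assert 1.0 <= n.mean_rate <= 10.0

    def test_coordinates_scale_linearly(self):
        n2 = place_target_neurons(snr_scale=2.0, seed=0)
        assert np.allclose(n2[0].position, (20, 40, -4))

    def test_mean_xy_distance_medium_condition(self):
        # direct arithmetic on the printed coordinates, scaled by 1.5
        neurons = place_target_neurons(snr_scale=1.5, seed=0)
        d = np.mean([np.hypot(n.position[0], n.position[1]) for n in neurons])
        assert d == pytest.approx(30.64, abs=0.05)

    def test_wrong_coordinate_count_rejected(self):
        with pytest.raises(ValueError):
            place_target_neurons(base_coords=np.zeros((3, 3)), snr_scale=1.0)


class TestSpikeTrains:
    def test_zero_rate_gives_empty_train(self):
        assert sample_spike_train(0.0, duration=10.0, seed=0).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_spike_train(-1.0, duration=10.0)

    def test_times_increasing_within_duration_and_refractory(self):
        t = sample_spike_train(30.0, gamma_shape=2.0, duration=50.0, refractory_floor=1e-3, seed=1)
        assert np.all(np.diff(t) >= 1e-3 - 1e-12)
        assert np.all((t >= 0) & (t < 50.0))

    def test_count_matches_nominal_rate(self):
        counts = [
            sample_spike_train(10.0, duration=300.0, seed=s).size for s in range(8)
        ]
        # mean count 3000, SE of the mean over 8 runs ~ sqrt(3000/2)/sqrt(8)
        assert abs(np.mean(counts) - 3000) < 3 * np.sqrt(3000.0 / 2 / 8)

    def test_long_run_rate_convergence(self):
        t = sample_spike_train(5.0, duration=1000.0, seed=3)
        assert abs(t.size / 1000.0 - 5.0) / 5.0 < 0.05


class TestSurrogateWaveforms:
    neuron = NeuronSpec(np.array([0.0, 0.0, 0.0]), WaveformParams(), mean_rate=5.0)

    def test_amplitude_follows_point_source_decay(self):
        p = self.neuron.waveform_params
        w1 = waveform_at_site(self.neuron, np.array([p.r0_um, 0, 0]))
        w2 = waveform_at_site(self.neuron, np.array([2 * p.r0_um, 0, 0]))
        assert np.ptp(w1) == pytest.approx(p.amp_ref, rel=1e-12)
        assert np.allclose(w2 * 2, w1)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            waveform_at_site(self.neuron, np.zeros(3))

    def test_different_parameters_give_different_shapes(self):
        a = template_shape(WaveformParams(theta1_ms=0.08, balance=0.3))
        b = template_shape(WaveformParams(theta1_ms=0.2, balance=0.9))
        cc = np.dot(a, b) / np.linalg.norm(a) / np.linalg.norm(b)
        assert cc < 0.999


class TestRecordingSynthesis:
    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            synthesize_recording(single_site_geometry(), [], [], duration=0.0)

    def test_pure_thermal_noise_variance(self, rng):
        sigma = 0.8
        rec = synthesize_recording(
            single_site_geometry(), [], [], duration=8.0, thermal_sigma=sigma, seed=2
        )
        # oracle: empirically filter white noise with the same bandpass
        ref = bandpass_filter(rng.normal(0, sigma, rec.samples.shape[1]))
        assert rec.samples[0].std() == pytest.approx(ref.std(), rel=0.05)

    def test_single_neuron_matches_template_superposition(self, clean_recording):
        rec = clean_recording
        starts = np.round(rec.true_spike_times[0] * rec.fs).astype(int)
        tmpl = rec.templates[0, 0]
        for s in starts[1:-1]:
            seg = rec.samples[0, s : s + tmpl.size]
            assert np.allclose(seg, tmpl, atol=0.02 * np.ptp(tmpl))

    def test_synthesis_is_additive_in_neuron_sets(self):
        geom = single_site_geometry()
        t = place_target_neurons(seed=3)
        kw = dict(duration=4.0, thermal_sigma=0.0, seed=7)
        rA = synthesize_recording(geom, [t[0]], [], **kw)
        rB = synthesize_recording(geom, [t[1]], [], **kw)
        rAB = synthesize_recording(geom, [t[0], t[1]], [], **kw)
        assert np.allclose(rA.samples + rB.samples, rAB.samples, atol=1e-12)


class TestSNR:
    def test_scale_invariance(self, short_recording):
        rec = short_recording
        base = estimate_snr(rec, 0, 0)
        scaled = type(rec)(
            samples=rec.samples * 3.7,
            fs=rec.fs,
            true_spike_times=rec.true_spike_times,
            neuron_ids=rec.neuron_ids,
            templates=rec.templates,
            band=rec.band,
            duration=rec.duration,
            target_ids=rec.target_ids,
        )
        assert estimate_snr(scaled, 0, 0) == pytest.approx(base, rel=1e-9)

    def test_ratio_definition(self, short_recording):
        rec = short_recording
        x = rec.samples[0]
        starts = np.round(rec.true_spike_times[0] * rec.fs).astype(int)
        wins = x[starts[:, None] + np.arange(64)[None, :]]
        expected = np.ptp(wins.mean(axis=0)) / noise_sigma(x)
        assert estimate_snr(rec, 0, 0) == pytest.approx(expected)

    def test_snr_decreases_with_target_distance_scale(self):
        snrs = [
            mean_snr(simulate_condition(lvl, duration=15.0, seed=9), 0)
            for lvl in ("high", "medium", "low")
        ]
        assert snrs[0] > snrs[1] > snrs[2]


class TestSurrogateLibrary:
    def test_frozen_library_is_deterministic(self):
        a = make_surrogate_library()
        b = make_surrogate_library()
        assert np.array_equal(a, b)

    def test_column_norms_positive(self):
        lib = make_surrogate_library(n_waveforms=80)
        assert np.all(np.linalg.norm(lib, axis=0) > 0)

    def test_energy_concentrates_in_leading_components(self):
        # pinned on the frozen library: top 4 singular values carry > 80%
        s = np.linalg.svd(make_surrogate_library(), compute_uv=False)
        assert np.sum(s[:4] ** 2) / np.sum(s**2) > 0.80

    def test_too_few_waveforms_rejected(self):
        with pytest.raises(ValueError):
            make_surrogate_library(n_waveforms=10)
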