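"""Synthetic PPG generator: determinism, ground truth, presets, modulation."""
import numpy as np
import pytest

import ppgdtw as pp


class TestSimulate:
    def test_onset_count_and_spacing(self):
        spec = pp.SimulationSpec(duration_s=10.0, hr_bpm=60.0)
        res = pp.simulate(spec)
        assert len(res.beat_times) == 10
        assert np.allclose(np.diff(res.beat_times), 1.0)

    def test_same_seed_is_bit_identical(self):
        spec = pp.SimulationSpec(duration_s=15.0, hr_bpm=70.0, noise_sd=0.05, seed=123)
        a, b = pp.simulate(spec), pp.simulate(spec)
        np.testing.assert_array_equal(a.stream.samples, b.stream.samples)
        assert a.truth_list() == b.truth_list()

    def test_amplitude_modulation_range(self):
        spec = pp.SimulationSpec(duration_s=60.0, hr_bpm=60.0, am_depth=0.3, resp_rate_hz=0.25)
        res = pp.simulate(spec)
        peaks = np.array([res.noiseless[p.index] for p in res.truth["SYS"]])
        # the modulator is sampled at the beat onsets, so the attainable range
        # is set by sin(2*pi*f_r*t_k) at those instants, not by +/-1
        s = np.sin(2 * np.pi * spec.resp_rate_hz * res.beat_times)
        expected = (1 + 0.3 * s.max()) / (1 + 0.3 * s.min())
        assert peaks.max() / peaks.min() == pytest.approx(expected, rel=0.02)

    def test_amplitude_modulation_full_swing_when_incommensurate(self):
        spec = pp.SimulationSpec(duration_s=120.0, hr_bpm=60.0, am_depth=0.3, resp_rate_hz=0.21)
        res = pp.simulate(spec)
        peaks = np.array([res.noiseless[p.index] for p in res.truth["SYS"]])
        assert peaks.max() / peaks.min() == pytest.approx(1.3 / 0.7, rel=0.05)

    def test_constant_rate_without_fm(self):
        spec = pp.SimulationSpec(duration_s=30.0, hr_bpm=75.0, fm_depth=0.0)
        res = pp.simulate(spec)
        ibis = np.diff([p.timestamp for p in res.truth["EP"]]) * 1000
        assert np.allclose(ibis, 60000 / 75.0, atol=2 * 1000 / spec.fs)

    def test_truth_ordering_per_beat(self):
        spec = pp.SimulationSpec(duration_s=20.0, hr_bpm=80.0, fm_depth=0.2)
        res = pp.simulate(spec)
        for ep, ms, sy in zip(res.truth["EP"], res.truth["MS"], res.truth["SYS"]):
            assert ep.index < ms.index < sy.index

    def test_truth_relocation_requires_matching_length(self):
        res = pp.simulate(pp.SimulationSpec(duration_s=10.0))
        with pytest.raises(ValueError):
            res.truth_for(np.zeros(10))

    def test_schedule_validation(self):
        P = pp.presets()
        with pytest.raises(ValueError):
            pp.SimulationSpec(duration_s=10.0, morphology_schedule=[(0.0, P["classic"]), (20.0, P["classic"])])
        with pytest.raises(ValueError):
            pp.SimulationSpec(duration_s=0.0)
        with pytest.raises(ValueError):
            pp.SimulationSpec(duration_s=10.0, hr_bpm=250.0)


class TestPresets:
    @pytest.mark.parametrize("name", sorted(pp.presets()))
    def test_one_systolic_peak_per_beat(self, name):
        spec = pp.SimulationSpec(duration_s=10.0, morphology_schedule=[(0.0, pp.presets()[name])])
        res = pp.simulate(spec)
        assert len(res.truth["SYS"]) == len(res.beat_times)
        # the systolic peak is the unique global max of each beat
        for sy, ep in zip(res.truth["SYS"], res.truth["EP"]):
            assert res.noiseless[sy.index] >= res.noiseless[ep.index]

    def test_pairwise_distinct_morphologies(self):
        P = pp.presets()
        names = sorted(P)
        units = {}
        for n in names:
            spec = pp.SimulationSpec(duration_s=5.0, morphology_schedule=[(0.0, P[n])])
            units[n] = pp.make_prime_template(spec).samples
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                dist, _ = pp.dtw_full(units[a], units[b])
                assert dist > 0

    def test_notch_preset_has_two_minima_per_cycle(self):
        spec = pp.SimulationSpec(duration_s=5.0, morphology_schedule=[(0.0, pp.presets()["prominent_notch"])])
        y = pp.make_prime_template(spec).samples
        interior = pp.detect_candidates(np.concatenate([y, y, y]))
        per_cycle = len(interior) / 3
        assert per_cycle >= 1.5  # onset + dicrotic notch


class TestPrimeTemplate:
    def test_fiducial_ordering(self, classic_template):
        t = classic_template
        assert t.onset_idx < t.ms_idx < t.sys_idx < len(t.samples)

    def test_zero_distance_to_first_simulated_cycle(self, classic_spec, classic_noiseless, classic_template):
        ep0 = classic_noiseless.truth["EP"][0].index
        ep1 = classic_noiseless.truth["EP"][1].index
        cycle = classic_noiseless.noiseless[ep0:ep1]
        dist, _ = pp.dtw_full(cycle, classic_template.samples)
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self, classic_spec):
        a = pp.make_prime_template(classic_spec)
        b = pp.make_prime_template(classic_spec)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert (a.onset_idx, a.ms_idx, a.sys_idx) == (b.onset_idx, b.ms_idx, b.sys_idx)

    def test_bandpassed_variant_is_annotated_and_consistent(self, classic_spec):
        t = pp.make_prime_template(classic_spec, bandpass=(0.5, 5.0))
        assert t.onset_idx < t.ms_idx < t.sys_idx < len(t.samples)


def test_noise_sd_for_snr_scaling():
    x = np.sin(np.linspace(0, 20 * np.pi, 5000))
    sd = pp.noise_sd_for_snr(x, 20.0)
    assert sd == pytest.approx(np.sqrt(0.5) / 10, rel=1e-3)
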