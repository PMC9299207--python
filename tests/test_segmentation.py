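"""Boosted endpoint search, likelihood fusion and fiducial mapping."""
import numpy as np
import pytest

import ppgdtw as pp
from ppgdtw.segmentation import map_fiducial_indices
from ppgdtw.spring import normalize


class TestEndpointLikelihood:
    @pytest.mark.parametrize(
        "p_c,p_d,expected",
        [(0.8, 0.5, 0.4), (1.0, 0.37, 0.37), (0.37, 1.0, 0.37), (0.0, 0.9, 0.0), (1.0, 1.0, 1.0)],
    )
    def test_product_identities(self, p_c, p_d, expected):
        assert pp.endpoint_likelihood(p_c, p_d) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.endpoint_likelihood(1.2, 0.5)
        with pytest.raises(ValueError):
            pp.endpoint_likelihood(0.5, -0.1)


class TestMapFiducials:
    def test_identity_cycle_maps_identically(self, classic_template):
        y = classic_template.samples
        _, path = pp.dtw_full(y, y)
        rel = pp.map_fiducials(y, classic_template, path)
        assert rel == classic_template.fiducial_indices

    def test_two_x_stretch_doubles_indices(self, classic_template):
        y = classic_template.samples
        stretched = np.repeat(y, 2)
        _, path = pp.dtw_full(stretched, y)
        rel = pp.map_fiducials(stretched, classic_template, path)
        for label in ("MS", "SYS"):
            assert abs(rel[label] - 2 * classic_template.fiducial_indices[label]) <= 1
        assert rel["EP"] == 0

    def test_tie_resolves_to_earliest(self):
        # template [0, 1]; cycle has a 3-sample plateau aligned to template end
        tmpl = pp.AnnotatedTemplate(np.array([0.0, 0.5, 1.0]), 10.0, 0, 1, 2)
        cyc = np.array([0.0, 0.5, 1.0, 1.0, 1.0])
        _, path = pp.dtw_full(cyc, tmpl.samples)
        rel = pp.map_fiducials(cyc, tmpl, path)
        assert rel["SYS"] == 2  # earliest of the equal-cost plateau

    def test_malformed_path_rejected(self, classic_template):
        y = classic_template.samples
        _, path = pp.dtw_full(y[:-5], y[:-5])  # does not reach template end
        with pytest.raises(ValueError):
            map_fiducial_indices(y[:-5], classic_template.fiducial_indices, path, y)


class TestSegmentStream:
    def test_noiseless_recovery_is_exact(self, classic_noiseless, classic_template):
        cycles = pp.segment_stream(classic_noiseless.stream, classic_template)
        assert len(cycles) in (59, 60)
        truth = {lab: np.array([p.index for p in classic_noiseless.truth[lab]]) for lab in ("EP", "MS", "SYS")}
        for c in cycles:
            for lab in ("EP", "MS", "SYS"):
                err = np.abs(truth[lab] - c.fiducials[lab].index).min()
                assert err <= 1, f"{lab} off by {err} in cycle {c.start_idx}"

    def test_cycles_share_boundaries_and_are_ordered(self, classic_noiseless, classic_template):
        cycles = pp.segment_stream(classic_noiseless.stream, classic_template)
        for a, b in zip(cycles, cycles[1:]):
            assert a.start_idx < a.end_idx
            assert a.end_idx == b.start_idx
            assert a.fiducials["EP"].index == a.start_idx

    def test_accepted_endpoints_are_candidates(self, classic_noiseless, classic_template):
        cycles = pp.segment_stream(classic_noiseless.stream, classic_template)
        cands = set(pp.detect_candidates(classic_noiseless.stream.samples).tolist())
        assert all(c.end_idx in cands for c in cycles)

    def test_notch_minima_never_accepted(self):
        spec = pp.SimulationSpec(
            duration_s=30.0, hr_bpm=60.0,
            morphology_schedule=[(0.0, pp.presets()["prominent_notch"])],
        )
        res = pp.simulate(spec)
        tmpl = pp.make_prime_template(spec)
        cycles = pp.segment_stream(res.stream, tmpl)
        onsets = np.array([p.index for p in res.truth["EP"]])
        assert len(cycles) >= 25
        for c in cycles:
            assert np.abs(onsets - c.end_idx).min() <= 1  # never the dicrotic notch

    def test_gap_triggers_abandon_and_restart(self, classic_template):
        # splice a flat gap of 1.5 cycles into an otherwise periodic stream
        y = classic_template.samples
        flat = np.full(450, y.min())
        x = np.concatenate([np.tile(y, 10), flat, np.tile(y, 10)])
        stream = pp.SignalStream(x, 300.0)
        cycles = pp.segment_stream(stream, classic_template)
        # no cycle may span the interior of the gap region
        gap = (3000 + 50, 3450 - 50)
        for c in cycles:
            assert not (c.start_idx > gap[0] and c.end_idx < gap[1])
        assert any(c.start_idx >= 3450 - 1 for c in cycles)  # search resumed after the gap

    def test_literal_reset_policy_runs_on_notch_free_morphology(self):
        # the literal rule hands the start to *any* candidate before l_alpha, so it
        # only terminates when cycles contain a single minimum (no dicrotic notch)
        spec = pp.SimulationSpec(
            duration_s=60.0, hr_bpm=60.0,
            morphology_schedule=[(0.0, pp.presets()["fused_diastolic"])],
        )
        res = pp.simulate(spec)
        cfg = pp.RunConfig(reset_policy="literal")
        cycles = pp.segment_stream(res.stream, pp.make_prime_template(spec), cfg)
        assert len(cycles) >= 50

    def test_literal_reset_stalls_on_notched_morphology(self, classic_noiseless, classic_template):
        # with a dicrotic notch every cycle, the naive reset rule never settles;
        # this is why score gating is the default
        cfg = pp.RunConfig(reset_policy="literal")
        cycles = pp.segment_stream(classic_noiseless.stream, classic_template, cfg)
        gated = pp.segment_stream(classic_noiseless.stream, classic_template, pp.RunConfig())
        assert len(gated) > len(cycles)

    def test_boost_off_never_improves_endpoint_f1(self):
        cfg = pp.RunConfig()
        specs = pp.make_cohort(seed=202, n_subjects=3, duration_s=60.0)
        for spec in specs:
            subj = pp.prepare_subject(spec, cfg)
            on = pp.run_subject(subj, cfg, boost=True)
            off = pp.run_subject(subj, cfg, boost=False)
            truth_ep = sorted(p for p in subj.truth if p.label == "EP")

            def ep_f1(pred):
                p = sorted(x for x in pred if x.label == "EP")
                return pp.classification_metrics(pp.match_events(p, truth_ep, cfg.tolerance_ms))[2]

            assert ep_f1(on) >= ep_f1(off)

    def test_too_short_stream_rejected(self, classic_template):
        s = pp.SignalStream(np.sin(np.arange(300) / 10.0), 300.0)
        with pytest.raises(ValueError):
            pp.segment_stream(s, classic_template)


class TestBootstrapTemplate:
    def test_bootstrap_spans_one_plausible_cycle(self, classic_noiseless):
        t = pp.bootstrap_template(classic_noiseless.stream)
        assert t.onset_idx == 0 and t.onset_idx < t.ms_idx < t.sys_idx < len(t.samples)
        assert 0.7 * 300 <= len(t.samples) <= 1.3 * 300 + 1
        # bootstrapped template segments its own stream competently
        cycles = pp.segment_stream(classic_noiseless.stream, t)
        assert len(cycles) >= 55

    def test_bootstrap_needs_candidates(self):
        fs = 300.0
        tone = pp.SignalStream(np.sin(2 * np.pi * 1.0 * np.arange(int(10 * fs)) / fs), fs)
        t = pp.bootstrap_template(tone)  # a tone bootstraps trivially
        assert t.sys_idx > t.ms_idx


class TestCyclesToFiducials:
    def test_final_endpoint_emitted_once(self, classic_noiseless, classic_template):
        cycles = pp.segment_stream(classic_noiseless.stream, classic_template)
        pts = pp.cycles_to_fiducials(cycles, classic_noiseless.stream)
        eps = [p.index for p in pts if p.label == "EP"]
        assert len(eps) == len(set(eps)) == len(cycles) + 1
        assert sorted(eps) == eps
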