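"""DBA consensus, annotation transfer, template selection and eviction."""
import numpy as np
import pytest

import ppgdtw as pp
from ppgdtw.template import dba_objective


@pytest.fixture()
def prime(classic_template):
    return classic_template


class TestDbaConsensus:
    def test_identical_inputs_are_a_fixed_point(self, prime):
        y = prime.samples
        consensus = pp.dba_consensus([y.copy() for _ in range(5)])
        np.testing.assert_allclose(consensus, y, atol=1e-12)

    def test_single_cycle_returned_unchanged(self, prime):
        np.testing.assert_allclose(pp.dba_consensus([prime.samples]), prime.samples)

    def test_objective_non_increasing_across_iterations(self, prime):
        rng = np.random.default_rng(8)
        cycles = [prime.samples + rng.normal(0, 0.05, prime.samples.size) for _ in range(4)]
        objs = []
        for it in range(1, 6):
            avg = pp.dba_consensus(cycles, max_iter=it, tol=0.0)
            objs.append(dba_objective(cycles, avg))
        for a, b in zip(objs, objs[1:]):
            assert b <= a + 1e-9

    def test_average_no_worse_than_cross_distance(self, prime):
        y = prime.samples
        shifted = np.roll(y, 12)
        consensus = pp.dba_consensus([y, shifted])
        cross, _ = pp.dtw_full(y, shifted)
        assert dba_objective([y, shifted], consensus) <= 2 * cross + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pp.dba_consensus([])


class TestAnnotateConsensus:
    def test_identity_preserves_annotations(self, prime):
        t = pp.annotate_consensus(prime.samples.copy(), prime)
        assert (t.onset_idx, t.ms_idx, t.sys_idx) == (prime.onset_idx, prime.ms_idx, prime.sys_idx)
        assert t.usage_count == 0 and t.id != prime.id

    def test_two_x_stretch_doubles_indices(self, prime):
        t = pp.annotate_consensus(np.repeat(prime.samples, 2), prime)
        assert abs(t.ms_idx - 2 * prime.ms_idx) <= 1
        assert abs(t.sys_idx - 2 * prime.sys_idx) <= 1

    def test_flat_consensus_rejected(self, prime):
        with pytest.raises(ValueError):
            pp.annotate_consensus(np.zeros(100), prime)


class TestSelectOptimal:
    def test_single_template_wins(self, prime):
        ens = pp.TemplateEnsemble(prime=prime)
        assert pp.select_optimal({prime.id: [0.3, 0.4]}, ens) == prime.id
        assert prime.usage_count == 1

    def test_argmin_of_mean_cost(self, prime):
        other = pp.AnnotatedTemplate(prime.samples.copy(), prime.fs, 0, prime.ms_idx, prime.sys_idx, id="other")
        ens = pp.TemplateEnsemble(prime=prime, templates=[prime, other])
        assert pp.select_optimal({prime.id: [0.10], "other": [0.07]}, ens) == "other"

    def test_exact_tie_favors_prime(self, prime):
        other = pp.AnnotatedTemplate(prime.samples.copy(), prime.fs, 0, prime.ms_idx, prime.sys_idx, id="a-first")
        ens = pp.TemplateEnsemble(prime=prime, templates=[prime, other])
        assert pp.select_optimal({prime.id: [0.2], "a-first": [0.2]}, ens) == prime.id

    def test_empty_rejected(self, prime):
        ens = pp.TemplateEnsemble(prime=prime)
        with pytest.raises(ValueError):
            pp.select_optimal({}, ens)


class TestUpdateEnsemble:
    def _cycles_for(self, prime, n=6, seed=0):
        rng = np.random.default_rng(seed)
        return [prime.samples + rng.normal(0, 0.02, prime.samples.size) for _ in range(n)]

    def test_grows_below_capacity(self, prime):
        ens = pp.TemplateEnsemble(prime=prime, k=3)
        added = pp.update_ensemble(ens, self._cycles_for(prime), {prime.id: [0.1]}, y_opt=prime.id)
        assert added is not None and len(ens.templates) == 2

    def test_full_and_prime_optimal_means_no_change(self, prime):
        other = pp.AnnotatedTemplate(prime.samples.copy(), prime.fs, 0, prime.ms_idx, prime.sys_idx, id="b")
        ens = pp.TemplateEnsemble(prime=prime, k=2, templates=[prime, other])
        added = pp.update_ensemble(ens, self._cycles_for(prime), {}, y_opt=prime.id)
        assert added is None and [t.id for t in ens.templates] == [prime.id, "b"]

    def test_full_evicts_least_frequently_used(self, prime):
        other = pp.AnnotatedTemplate(prime.samples.copy(), prime.fs, 0, prime.ms_idx, prime.sys_idx, id="b")
        prime.usage_count = 5
        other.usage_count = 1
        ens = pp.TemplateEnsemble(prime=prime, k=2, templates=[prime, other])
        added = pp.update_ensemble(ens, self._cycles_for(prime), {}, y_opt=prime.id if False else "b")
        # y_opt is "b" (not prime) -> swap triggered; LFU among non-optimal is prime? no:
        # evictable excludes y_opt ("b"), so prime (usage 5) is evicted as the only option
        assert added is not None
        assert prime.id not in [t.id for t in ens.templates]
        assert len(ens.templates) == 2

    def test_empty_region_is_a_noop(self, prime):
        ens = pp.TemplateEnsemble(prime=prime, k=3)
        assert pp.update_ensemble(ens, [], {}, y_opt=prime.id) is None
        assert len(ens.templates) == 1


class TestEnsembleInvariants:
    def test_size_never_exceeds_k(self):
        cfg = pp.RunConfig(k=2, region_seconds=15.0)
        spec = pp.make_cohort(seed=77, n_subjects=1, duration_s=60.0)[0]
        subj = pp.prepare_subject(spec, cfg)
        ens = pp.TemplateEnsemble(prime=subj.template, k=cfg.k)
        pp.segment_stream_dynamic(subj.stream, ens, cfg)
        assert 1 <= len(ens.templates) <= 2

    def test_k1_is_bit_identical_to_single_template(self):
        cfg = pp.RunConfig()
        spec = pp.make_cohort(seed=42, n_subjects=1, duration_s=60.0)[0]
        subj = pp.prepare_subject(spec, cfg)
        st = pp.segment_stream(subj.stream, subj.template, cfg)
        ens = pp.TemplateEnsemble(prime=subj.template, k=1)
        dt = pp.segment_stream_dynamic(subj.stream, ens, cfg)
        assert len(st) == len(dt)
        for a, b in zip(st, dt):
            assert (a.start_idx, a.end_idx) == (b.start_idx, b.end_idx)
            assert {l: p.index for l, p in a.fiducials.items()} == {l: p.index for l, p in b.fiducials.items()}
            assert a.dtw_distance == b.dtw_distance
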