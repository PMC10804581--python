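import numpy as np
import pytest

from ttmpath import (GroundTruth, Posterior, block_scenario, generate_corpus,
                     recovery_report, standard_scenario, time_resolved_error,
                     validate_corpus, write_event_log, read_event_log)
import io


def tiny_truth(**kw):
    k, t, a = 2, 2, 4
    phi_act = np.zeros((k, t, a))
    phi_act[0, :, :2] = 0.5
    phi_act[1, :, 2:] = 0.5
    defaults = dict(n_topics=k, n_activities=a, n_timestamps=t,
                    phi_act=phi_act, phi_time=np.full((k, t), 0.5),
                    n_processes=5, los=2, tokens_per_day=3)
    defaults.update(kw)
    return GroundTruth(**defaults)


class TestGenerateCorpus:
    def test_seed_determinism(self):
        truth = standard_scenario("chemo-like", n_processes=5)
        a = generate_corpus(truth, seed=9)
        b = generate_corpus(truth, seed=9)
        assert a.corpus == b.corpus
        np.testing.assert_array_equal(a.z_true, b.z_true)

    def test_generated_corpora_are_valid(self):
        for mode in ("day-timestamp", "model-faithful"):
            sim = generate_corpus(tiny_truth(), mode=mode, seed=0)
            assert validate_corpus(sim.corpus) == []
            assert sim.z_true.shape[0] == sim.corpus.n_tokens
            assert sim.theta_true.shape == (sim.corpus.n_days, 2)

    def test_event_log_round_trip(self):
        # vocabulary ids may be renumbered (first-seen order on read), but
        # the decoded log must be identical
        def decoded(corpus):
            return [
                (p.patient_id, d.timestamp,
                 tuple(corpus.vocabulary.code(a) for a in d.tokens))
                for p in corpus.processes for d in p.days
            ]

        sim = generate_corpus(tiny_truth(), seed=1)
        buf = io.StringIO()
        write_event_log(sim.corpus, buf)
        buf.seek(0)
        assert decoded(read_event_log(buf)) == decoded(sim.corpus)

    def test_single_topic_activity_frequencies_converge(self):
        """With K=1 the empirical activity distribution at each timestamp
        must approach the generating distribution (law of large numbers)."""
        a = 5
        phi = np.array([[[0.5, 0.2, 0.1, 0.1, 0.1],
                         [0.1, 0.1, 0.1, 0.2, 0.5]]])
        truth = GroundTruth(1, a, 2, phi, np.array([[0.5, 0.5]]),
                            n_processes=700, los=2, tokens_per_day=8)
        sim = generate_corpus(truth, seed=3)
        assert (sim.z_true == 0).all()
        for t in (1, 2):
            tokens = [tok for p in sim.corpus.processes for d in p.days
                      if d.timestamp == t for tok in d.tokens]
            freq = np.bincount(tokens, minlength=a) / len(tokens)
            assert 0.5 * np.abs(freq - phi[0, t - 1]).sum() < 0.05

    def test_model_faithful_mode_single_token_days(self):
        sim = generate_corpus(tiny_truth(), mode="model-faithful", seed=0)
        assert all(d.n_tokens == 1 for p in sim.corpus.processes
                   for d in p.days)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            bad = tiny_truth()
            object.__setattr__(bad, "phi_act", bad.phi_act * 2)
            generate_corpus(bad)
        with pytest.raises(ValueError, match="los"):
            generate_corpus(tiny_truth(los=(3, 2)))
        with pytest.raises(ValueError, match="n_timestamps"):
            generate_corpus(tiny_truth(los=9))


class TestRecoveryReport:
    def test_truth_scores_zero(self):
        sim = generate_corpus(tiny_truth(n_processes=30), seed=5)
        post = Posterior(sim.theta_true, sim.phi_time_true,
                         sim.phi_act_true)
        report = recovery_report(sim, post)
        assert report.max_tv_phi_act == pytest.approx(0.0, abs=1e-12)
        assert report.max_tv_phi_time == pytest.approx(0.0, abs=1e-12)
        assert report.theta_mae == pytest.approx(0.0, abs=1e-12)

    def test_permuted_truth_scores_zero(self):
        sim = generate_corpus(tiny_truth(n_processes=30), seed=5)
        post = Posterior(sim.theta_true[:, ::-1], sim.phi_time_true[::-1],
                         sim.phi_act_true[::-1])
        report = recovery_report(sim, post)
        assert report.permutation == (1, 0)
        assert report.max_tv_phi_act == pytest.approx(0.0, abs=1e-12)

    def test_moved_mass_equals_tv(self):
        sim = generate_corpus(tiny_truth(n_processes=30), seed=5)
        phi = sim.phi_act_true.copy()
        phi[0, :, 0] -= 0.1
        phi[0, :, 1] += 0.1
        report = recovery_report(
            sim, Posterior(sim.theta_true, sim.phi_time_true, phi))
        assert report.tv_phi_act[0] == pytest.approx(0.1)
        assert report.tv_phi_act[1] == pytest.approx(0.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        sim = generate_corpus(tiny_truth(n_processes=5), seed=0)
        with pytest.raises(ValueError):
            recovery_report(sim, Posterior(sim.theta_true[:, :1],
                                           sim.phi_time_true[:1],
                                           sim.phi_act_true[:1]))

    def test_time_resolved_error_broadcasts_lda_estimate(self):
        sim = generate_corpus(tiny_truth(n_processes=30), seed=5)
        exact = time_resolved_error(sim, sim.phi_act_true)
        assert exact == pytest.approx(0.0, abs=1e-12)
        flat = sim.phi_act_true.mean(axis=1)
        assert time_resolved_error(sim, flat) >= 0.0


class TestScenarios:
    @pytest.mark.parametrize("name,k", [("radiotherapy-like", 4),
                                        ("surgery-like", 4),
                                        ("chemo-like", 3)])
    def test_presets_shape(self, name, k):
        truth = standard_scenario(name)
        assert truth.n_topics == k
        assert truth.n_activities == 37
        truth.validate()
        # each topic concentrates its separation mass on its own block
        blocks = np.linspace(0, 37, k + 1).astype(int)
        for j in range(k):
            own = truth.phi_act[j, :, blocks[j]:blocks[j + 1]].sum(axis=1)
            assert (own >= 0.8 - 1e-9).all()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            standard_scenario("dialysis-like")

    def test_time_drift_moves_mass_within_block(self):
        truth = block_scenario(n_topics=2, los=(6, 6), n_processes=5,
                               time_drift=0.8)
        tv = 0.5 * np.abs(truth.phi_act[0, 0] - truth.phi_act[0, -1]).sum()
        assert tv >= 0.3
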