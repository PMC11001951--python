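"""Generator correctness: cohort moments, label-stream coupling, emission
round trips, missingness, and session structure."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dyadgaze import metrics as gm
from dyadgaze import synthetic as syn
from dyadgaze.errors import ConfigurationError
from dyadgaze.geometry import GazeLabel


class TestCohort:
    def test_empty_cohort(self, preset):
        cfg = preset.cohort.model_copy(update={"n_participants": 0})
        assert syn.generate_cohort(cfg) == []

    def test_same_seed_identical(self, preset):
        a = syn.generate_cohort(preset.cohort)
        b = syn.generate_cohort(preset.cohort)
        assert a == b

    def test_different_seed_differs(self, preset):
        a = syn.generate_cohort(preset.cohort)
        b = syn.generate_cohort(preset.cohort.model_copy(update={"seed": 9}))
        assert a != b

    def test_large_cohort_matches_configured_moments(self, preset):
        """Monte-Carlo check against the configured population values."""
        cfg = preset.cohort.model_copy(update={"n_participants": 100_000,
                                               "seed": 5})
        cohort = syn.generate_cohort(cfg)
        aq = np.array([p.aq for p in cohort])
        assert abs(aq.mean() - cfg.aq_mean) < 0.05
        assert abs(np.mean([p.discomfort for p in cohort]) - 0.30) < 0.01
        assert aq.min() >= cfg.aq_range[0] and aq.max() <= cfg.aq_range[1]

    def test_adolescents_get_adolescent_instrument(self, preset):
        cfg = preset.cohort.model_copy(update={"n_participants": 500, "seed": 2})
        for p in syn.generate_cohort(cfg):
            assert (p.aq_instrument == "adolescent") == (p.age < 18)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(Exception, match="truncation|ordered"):
            syn.CohortConfig(aq_mean=19.5, aq_sd=0.1, aq_range=(40.0, 50.0))

    def test_aq_linked_discomfort(self, preset):
        cfg = preset.cohort.model_copy(update={
            "n_participants": 20_000, "seed": 3,
            "aq_discomfort_association": 0.3})
        cohort = syn.generate_cohort(cfg)
        aq = np.array([p.aq for p in cohort])
        disc = np.array([p.discomfort for p in cohort])
        assert aq[disc].mean() > aq[~disc].mean() + 1.0


class TestLabelStreams:
    def run(self, p, q, m, n=100_000, seed=0, **kw):
        rng = np.random.default_rng(seed)
        return syn.generate_label_streams(p, q, m, n, 30.0, rng, **kw)

    def test_target_marginals_and_overlap(self):
        """p = 0.6, q = 0.5, overlap 0.3 -> conditionals 0.5/0.5; empirical
        joint within MC error at n = 1e5."""
        a, b = self.run(0.6, 0.5, 0.3)
        assert abs(a.mean() - 0.6) < 0.015
        assert abs(b.mean() - 0.5) < 0.01
        assert abs((a & b).mean() - 0.3) < 0.01

    def test_independence_when_overlap_is_product(self):
        a, b = self.run(0.5, 0.4, 0.2)
        joint = (a & b).mean()
        assert abs(joint - a.mean() * b.mean()) < 0.01

    def test_nesting_at_upper_bound(self):
        """overlap = min(p, q) with p < q: self EYE implies other EYE."""
        a, b = self.run(0.3, 0.6, 0.3)
        assert not (a & ~b).any()

    def test_mean_dwell_matches_persistence(self):
        a, _ = self.run(0.5, 0.5, 0.25, n=200_000, seed=1)
        changes = np.flatnonzero(np.diff(a.astype(int)))
        runs = np.diff(changes)
        eye_runs = runs[::2] if a[changes[0] + 1] else runs[1::2]
        assert abs(eye_runs.mean() - 30.0) < 1.5

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            self.run(0.6, 0.5, 0.55)
        with pytest.raises(ConfigurationError, match="overlap"):
            self.run(0.9, 0.9, 0.5)  # below the Frechet lower bound

    def test_exact_mode_quantised_counts(self):
        a, b = self.run(0.558, 0.52, 0.272, n=5400, exact=True)
        assert a.sum() == round(0.558 * 5400)
        assert (a & b).sum() == round(0.272 * 5400)
        assert b.sum() == round(0.52 * 5400)

    def test_deterministic_under_seed(self):
        a1, b1 = self.run(0.6, 0.5, 0.3, n=1000, seed=42)
        a2, b2 = self.run(0.6, 0.5, 0.3, n=1000, seed=42)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)


class TestEmission:
    layout = syn.default_layout()

    def test_zero_noise_labels_recovered_exactly(self, rng):
        cfg = syn.StreamConfig(noise_sd_cm=0.0, missing_rate=0.0,
                               timestamp_jitter_sd_s=0.0)
        labels = rng.random(2000) < 0.5
        stream = syn.emit_gaze_samples(labels, self.layout, cfg, rng)
        partner = syn.emit_gaze_samples(np.zeros(2000, dtype=bool), self.layout,
                                        cfg, rng, person="experimenter")
        cls = gm.classify_stream(stream, partner)
        got_eye = cls.labels == int(GazeLabel.EYE)
        np.testing.assert_array_equal(got_eye, labels)
        assert not (cls.labels == int(GazeLabel.MISSING)).any()

    def test_default_noise_label_recovery_rate(self, rng):
        """With default noise the 1 cm safety margins keep label recovery
        essentially perfect (>= 99.9% per frame)."""
        cfg = syn.StreamConfig(missing_rate=0.0, timestamp_jitter_sd_s=0.0)
        labels = rng.random(20_000) < 0.5
        stream = syn.emit_gaze_samples(labels, self.layout, cfg, rng)
        partner = syn.emit_gaze_samples(np.zeros(20_000, dtype=bool),
                                        self.layout, cfg, rng,
                                        person="experimenter")
        cls = gm.classify_stream(stream, partner)
        got_eye = cls.labels == int(GazeLabel.EYE)
        assert (got_eye == labels).mean() >= 0.999

    def test_missing_rate_one_invalidates_everything(self, rng):
        cfg = syn.StreamConfig(missing_rate=1.0)
        stream = syn.emit_gaze_samples(np.ones(100, dtype=bool), self.layout,
                                       cfg, rng)
        assert not stream.valid.any()
        assert np.isnan(stream.left_dir).all()

    def test_missing_fraction_within_binomial_interval(self, rng):
        """n = 21600 frames at rate .103: the empirical missing count lies
        in the exact central 99% binomial interval."""
        cfg = syn.StreamConfig()
        n = 21_600
        stream = syn.emit_gaze_samples(np.zeros(n, dtype=bool), self.layout,
                                       cfg, rng)
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.103)
        assert lo <= (~stream.valid).sum() <= hi

    def test_timestamps_strictly_increasing_with_jitter(self, rng):
        cfg = syn.StreamConfig()
        stream = syn.emit_gaze_samples(np.zeros(5000, dtype=bool), self.layout,
                                       cfg, rng)
        assert (np.diff(stream.timestamps) > 0).all()


class TestSession:
    def test_frame_count_per_trial(self, small_session, small_stream_config):
        rate = small_stream_config.sampling_rate_hz
        sess = small_session.session
        for trial in sess.manifest.trials:
            n = sess.participant_stream.window(trial.start, trial.end).sum()
            expected = small_stream_config.round_length_s * rate
            assert abs(n - expected) <= 1

    def test_condition_sequence_guess_first(self, small_session):
        conds = [t.condition for t in small_session.session.manifest.trials]
        assert conds == ["GUESS", "DESCRIBE", "GUESS", "DESCRIBE"]

    def test_word_events_capped(self, small_session):
        for trial in small_session.session.manifest.trials:
            assert trial.word_events
            for ev in trial.word_events:
                assert ev.end - ev.onset <= 20.0 + 1e-9
                assert trial.start <= ev.onset < trial.end

    def test_same_seed_bit_identical(self, participant_meta, preset,
                                     small_stream_config):
        a = syn.generate_session(participant_meta, preset.effects,
                                 small_stream_config, seed=21)
        b = syn.generate_session(participant_meta, preset.effects,
                                 small_stream_config, seed=21)
        np.testing.assert_array_equal(a.session.participant_stream.timestamps,
                                      b.session.participant_stream.timestamps)
        np.testing.assert_array_equal(a.session.participant_stream.left_dir,
                                      b.session.participant_stream.left_dir)
        assert a.session.manifest == b.session.manifest

    def test_zero_noise_pipeline_recovers_preset_bases(
            self, participant_meta, preset, clean_stream_config):
        """Reference participant (AQ at the mean, no discomfort), no
        residual SDs: measured condition means equal the preset bases up
        to one-frame quantisation."""
        effects = preset.effects.model_copy(update={
            "guess": preset.effects.guess.model_copy(
                update={"eye_sd": 0.0, "mutual_sd": 0.0}),
            "describe": preset.effects.describe.model_copy(
                update={"eye_sd": 0.0, "mutual_sd": 0.0})})
        synth = syn.generate_session(participant_meta, effects,
                                     clean_stream_config, seed=4)
        _trials, conds, _ = gm.analyze_session(synth.session)
        n = clean_stream_config.round_length_s * 60
        quant = 100 / n  # one frame in percent
        # effects are centred at the cohort references, so the participant's
        # own generative targets (not the cohort bases) are the ground truth
        for cond in ("GUESS", "DESCRIBE"):
            assert conds[cond].eye_gaze_pct == pytest.approx(
                synth.targets[f"eye_{cond}"], abs=quant)
            assert conds[cond].mutual_pct == pytest.approx(
                synth.targets[f"mutual_{cond}"], abs=quant)
        # the describing condition has no discomfort shift, so its targets
        # for the reference participant are the printed bases themselves
        assert synth.targets["eye_DESCRIBE"] == pytest.approx(37.1)
        assert synth.targets["mutual_DESCRIBE"] == pytest.approx(21.2)

    def test_generative_truth_recovery_at_scale(self, participant_meta, preset):
        """Stochastic mode at ~1e5 frames per condition: pipeline estimates
        within one percentage point of the generative targets."""
        cfg = syn.StreamConfig(round_length_s=900.0, inter_round_gap_s=1.0,
                               include_calibration=False,
                               timestamp_jitter_sd_s=0.0)
        effects = preset.effects.model_copy(update={
            "guess": preset.effects.guess.model_copy(
                update={"eye_sd": 0.0, "mutual_sd": 0.0}),
            "describe": preset.effects.describe.model_copy(
                update={"eye_sd": 0.0, "mutual_sd": 0.0})})
        synth = syn.generate_session(participant_meta, effects, cfg, seed=6)
        _trials, conds, _ = gm.analyze_session(synth.session)
        for cond in ("GUESS", "DESCRIBE"):
            assert conds[cond].eye_gaze_pct == pytest.approx(
                synth.targets[f"eye_{cond}"], abs=1.0)
            assert conds[cond].mutual_pct == pytest.approx(
                synth.targets[f"mutual_{cond}"], abs=1.0)


class TestTargets:
    def test_no_clamping_for_preset_over_aq_range(self, preset):
        """Deterministic effect injection stays feasible across the whole
        configured AQ range and both discomfort groups."""
        from dyadgaze.session_io import ParticipantMeta
        effects = preset.effects.model_copy(update={
            "guess": preset.effects.guess.model_copy(
                update={"eye_sd": 0.0, "mutual_sd": 0.0}),
            "describe": preset.effects.describe.model_copy(
                update={"eye_sd": 0.0, "mutual_sd": 0.0})})
        participants = [
            ParticipantMeta(id=f"S{i}_{d}", age=25, sex=0, aq=float(aq),
                            discomfort=bool(d))
            for i, aq in enumerate(np.linspace(*preset.cohort.aq_range, 40))
            for d in (0, 1)]
        targets = syn.assign_behaviour_targets(participants, effects,
                                               np.random.default_rng(0))
        assert targets.attrs["clip_counts"] == {"eye": 0, "mutual": 0}

    def test_centred_effects_preserve_cohort_means(self, preset):
        """With effects centred at the cohort references, a large cohort's
        mean behaviour equals the configured bases."""
        cfg = preset.cohort.model_copy(update={"n_participants": 2000, "seed": 8})
        participants = syn.generate_cohort(cfg)
        targets = syn.assign_behaviour_targets(participants, preset.effects,
                                               np.random.default_rng(3))
        assert targets["eye_GUESS"].mean() == pytest.approx(55.8, abs=0.5)
        assert targets["eye_DESCRIBE"].mean() == pytest.approx(37.1, abs=0.5)
        assert targets["mutual_GUESS"].mean() == pytest.approx(27.2, abs=0.5)
        assert targets["mutual_DESCRIBE"].mean() == pytest.approx(21.2, abs=0.5)

    def test_between_participant_sds_match_printed_totals(self, preset):
        """Injected effects plus residual SDs reproduce the reported
        between-participant SDs (17.6 / 16.9 / 12.2 / 11.7)."""
        cfg = preset.cohort.model_copy(update={"n_participants": 5000, "seed": 9})
        participants = syn.generate_cohort(cfg)
        targets = syn.assign_behaviour_targets(participants, preset.effects,
                                               np.random.default_rng(4))
        assert targets["eye_GUESS"].std() == pytest.approx(17.6, abs=0.8)
        assert targets["eye_DESCRIBE"].std() == pytest.approx(16.9, abs=0.8)
        assert targets["mutual_GUESS"].std() == pytest.approx(12.2, abs=0.8)
        assert targets["mutual_DESCRIBE"].std() == pytest.approx(11.7, abs=0.8)

    def test_preset_serialises_and_round_trips(self, preset, tmp_path):
        import yaml
        path = tmp_path / "preset.yaml"
        path.write_text(yaml.safe_dump(preset.model_dump()))
        loaded = syn.StudyPreset.model_validate(
            yaml.safe_load(path.read_text()))
        assert loaded == preset
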