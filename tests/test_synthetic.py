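"""Synthetic study generator: determinism, design balance, forward models."""

import numpy as np
import pytest

from audsurp.features import FEATURE_ORDER
from audsurp.synthetic import (GroundTruth, SyntheticConfig, condition_shifts,
                               generate_trial_features,
                               simulate_behavioral_responses,
                               simulate_pupil_session, simulate_pupil_traces,
                               synthesize_audio_trial)


class TestDesign:
    def test_all_control_when_fraction_one(self):
        cfg = SyntheticConfig.music(n_subjects=1, n_trials_per_session=8,
                                    control_fraction=1.0, seed=0)
        records, feats = generate_trial_features(cfg, GroundTruth())
        assert all(r.is_control for r in records)
        # no injected shifts: all channels stationary around the trial mean
        for f in feats:
            for k in FEATURE_ORDER:
                assert abs(f.channels[k].mean()) < 5.0

    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig.music(n_subjects=1, n_trials_per_session=12, seed=3)
        r1, f1 = generate_trial_features(cfg, GroundTruth())
        r2, f2 = generate_trial_features(cfg, GroundTruth())
        assert r1 == r2
        for a, b in zip(f1, f2):
            for k in FEATURE_ORDER:
                assert (a.channels[k] == b.channels[k]).all()

    def test_music_levels_from_printed_values(self):
        cfg = SyntheticConfig.music(n_subjects=1, n_trials_per_session=64, seed=1)
        records, _ = generate_trial_features(cfg, GroundTruth())
        loud = {r.loudness for r in records if not r.is_control}
        pitch = {r.pitch for r in records if not r.is_control}
        assert loud == {2.0, 6.0} and pitch == {2.0, 6.0}

    def test_nature_levels_from_printed_values(self):
        cfg = SyntheticConfig.nature(n_subjects=1, n_trials_per_session=64, seed=1)
        records, _ = generate_trial_features(cfg, GroundTruth())
        assert {r.loudness for r in records if not r.is_control} == {2.0, 8.0}
        assert {r.pitch for r in records if not r.is_control} == {0.0, 3.0}
        assert records[0].duration == 6.0

    def test_control_fraction_exact_for_even_counts(self):
        cfg = SyntheticConfig.music(n_subjects=3, n_trials_per_session=32, seed=2)
        records, _ = generate_trial_features(cfg, GroundTruth())
        for s in range(3):
            ctrl = [r for r in records if r.subject_id == s and r.is_control]
            assert len(ctrl) == 16

    def test_onsets_inside_their_quadrant(self):
        cfg = SyntheticConfig.music(n_subjects=2, n_trials_per_session=64, seed=4)
        records, _ = generate_trial_features(cfg, GroundTruth())
        for r in records:
            if not r.is_control:
                lo, hi = (r.quadrant - 1) / 4 * 5.0, r.quadrant / 4 * 5.0
                assert lo <= r.t0 <= hi

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig.music(control_fraction=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig.music(trial_duration=-1.0)
        with pytest.raises(ValueError):
            SyntheticConfig.music(n_trials_per_session=0)


class TestShifts:
    def test_shift_monotone_in_condition_level(self):
        """Mean envelope in the token window grows with the loudness level
        (averaged over >= 50 trials per level)."""
        cfg = SyntheticConfig.music(n_subjects=2, n_trials_per_session=128, seed=9)
        truth = GroundTruth()
        records, feats = generate_trial_features(cfg, truth)
        by_level = {2.0: [], 6.0: []}
        for r, f in zip(records, feats):
            if r.is_control:
                continue
            t = f.time
            win = (t >= r.t0) & (t < r.t0 + cfg.token_duration)
            if not win.any():  # onset at the very end of the trial
                continue
            bg = ~win
            by_level[r.loudness].append(f.channels["envelope"][win].mean()
                                        - f.channels["envelope"][bg].mean())
        assert len(by_level[2.0]) >= 50 and len(by_level[6.0]) >= 50
        assert np.mean(by_level[6.0]) > np.mean(by_level[2.0]) > 0.5

    def test_condition_to_channel_mapping(self):
        truth = GroundTruth()
        from audsurp.trials import TrialRecord

        r = TrialRecord(0, 0, 0, False, 6.0, 2.0, 0, 1, 2, 1.5, 5.0)
        s = condition_shifts(r, truth)
        idx = {k: i for i, k in enumerate(FEATURE_ORDER)}
        assert s[idx["envelope"]] > 0 and s[idx["pitch"]] > 0
        assert s[idx["spec_high"]] > 0  # timbre differs
        r2 = TrialRecord(1, 0, 0, False, 6.0, 2.0, 1, 1, 2, 1.5, 5.0)
        assert condition_shifts(r2, truth)[idx["spec_high"]] == 0.0

    def test_negative_truth_parameters_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(weight_matrix_true=-np.eye(6))
        with pytest.raises(ValueError):
            GroundTruth(pupil_feature_gains=-np.ones(6))
        with pytest.raises(ValueError):
            GroundTruth(behavioral_lapse_rate=1.5)


class TestBehavioralForwardModel:
    def test_full_lapse_gives_coin_flips(self, small_music_study):
        config, _, records, feats = small_music_study
        truth = GroundTruth(behavioral_lapse_rate=1.0)
        resp, _, alphas, _ = simulate_behavioral_responses(
            records, feats, truth, config, rng=np.random.default_rng(0))
        is_dev = np.array([not r.is_control for r in records])
        # response rate near 0.5 for both trial types
        assert abs(resp.mean() - 0.5) < 0.12
        assert abs(resp[is_dev].mean() - resp[~is_dev].mean()) < 0.25

    def test_identity_truth_hits_exceed_false_alarms(self):
        """Identity weights + large injected shifts: hit rate > FA rate on a
        20-trial sample, in most of 10 seeds (Monte-Carlo check)."""
        wins = 0
        for seed in range(10):
            cfg = SyntheticConfig.music(n_subjects=1, n_trials_per_session=20,
                                        seed=seed)
            truth = GroundTruth(weight_matrix_true=np.eye(6))
            records, feats = generate_trial_features(cfg, truth)
            resp, _, _, _ = simulate_behavioral_responses(
                records, feats, truth, cfg, rng=np.random.default_rng(seed))
            dev = np.array([not r.is_control for r in records])
            wins += resp[dev].mean() > resp[~dev].mean()
        assert wins >= 7

    def test_control_false_alarm_rate_tracks_alpha(self):
        cfg = SyntheticConfig.music(n_subjects=2, n_trials_per_session=100,
                                    control_fraction=1.0, seed=6)
        truth = GroundTruth()
        records, feats = generate_trial_features(cfg, truth)
        resp, _, alphas, _ = simulate_behavioral_responses(
            records, feats, truth, cfg, rng=np.random.default_rng(1))
        lapse = truth.behavioral_lapse_rate
        expect = np.mean([(1 - lapse) * a.max() + lapse * 0.5 for a in alphas])
        assert resp.mean() == pytest.approx(expect, abs=0.07)


class TestPupilSimulation:
    def test_zero_gains_leave_noise_and_drift_only(self, small_music_study):
        config, _, records, _ = small_music_study
        truth = GroundTruth(pupil_feature_gains=np.zeros(6), pupil_noise_sd=0.01)
        recs = [r for r in records if not r.is_control][:4]
        traces = simulate_pupil_traces(recs, truth, config,
                                       np.random.default_rng(0))
        for tr in traces:
            good = tr.pupil[~tr.blink]
            assert np.ptp(good) < 1.0  # drift amplitude only, no response

    def test_noise_free_peak_lands_at_kernel_latency(self, small_music_study):
        config, _, records, _ = small_music_study
        truth = GroundTruth(pupil_noise_sd=1e-9)
        r = next(r for r in records if not r.is_control and r.quadrant == 2)
        session, onsets = simulate_pupil_session([r], truth, config,
                                                 np.random.default_rng(0))
        # suppress drift by removing a slow moving average
        x = session.pupil.copy()
        x[session.blink] = np.nan
        t = (session.time_ms - onsets[0]) / 1000.0
        sel = (t > r.t0) & (t < r.t0 + 3.0) & ~session.blink
        peak_t = t[sel][np.nanargmax(x[sel])]
        assert peak_t - r.t0 == pytest.approx(truth.pupil_kernel_latency,
                                              abs=0.35)

    def test_thousand_samples_per_second(self, small_music_study):
        config, _, records, _ = small_music_study
        traces = simulate_pupil_traces(records[:2], GroundTruth(), config,
                                       np.random.default_rng(0))
        tr = traces[0]
        assert np.allclose(np.diff(tr.time_ms), 1.0)
        assert tr.time_ms[0] == -1000.0
        assert tr.pupil.size == int((1 + config.trial_duration + 2) * 1000)


class TestAudio:
    def test_control_trial_is_background_only(self):
        cfg = SyntheticConfig.music(seed=0)
        from audsurp.trials import TrialRecord

        ctrl = TrialRecord(0, 0, 0, True, 2.0, 2.0, 0, 0, None, None, 5.0)
        wave = synthesize_audio_trial(ctrl, cfg)
        assert wave.sample_rate == 16000
        assert wave.duration == pytest.approx(5.0, abs=1e-3)

    def test_deviant_token_raises_local_energy(self):
        cfg = SyntheticConfig.music(seed=0)
        from audsurp.trials import TrialRecord

        dev = TrialRecord(1, 0, 0, False, 6.0, 2.0, 0, 1, 2, 1.5, 5.0)
        ctrl = TrialRecord(1, 0, 0, True, 6.0, 2.0, 0, 1, None, None, 5.0)
        wd = synthesize_audio_trial(dev, cfg)
        wc = synthesize_audio_trial(ctrl, cfg)
        seg = slice(int(1.5 * 16000), int(2.7 * 16000))
        assert np.abs(wd.samples[seg]).mean() > np.abs(wc.samples[seg]).mean()

    def test_token_overrunning_trial_rejected(self):
        cfg = SyntheticConfig.music(seed=0)
        from audsurp.trials import TrialRecord

        late = TrialRecord(2, 0, 0, False, 2.0, 2.0, 0, 1, 4, 4.5, 5.0)
        with pytest.raises(ValueError):
            synthesize_audio_trial(late, cfg)
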