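"""ROC/AUROC, cross-validation, cross-correlation, d' and the RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from audsurp.evaluation import (DPRIME_CLAMP, BehavioralDataset,
                                baseline_models, cross_weight_ttest,
                                dprime_table, loso_behavioral_eval,
                                max_crosscorr, pdr_crosscorr_eval,
                                quadrant_models, rm_anova_effects,
                                score_trials_roc)
from audsurp.integration import IntegrationConfig
from audsurp.targets import Outcome
from audsurp.trials import TrialRecord

CFG = IntegrationConfig()


def make_records(n_dev, n_ctrl, subject=0, duration=5.0):
    out = []
    for i in range(n_dev):
        q = i % 4 + 1
        out.append(TrialRecord(i, subject, 0, False, 2.0, 2.0, 0, 1, q,
                               (q - 1) / 4 * duration + 0.2, duration))
    for i in range(n_ctrl):
        out.append(TrialRecord(n_dev + i, subject, 0, True, 2.0, 2.0, 0, 0,
                               None, None, duration))
    return out


class TestRoc:
    def test_perfect_separation(self):
        records = make_records(5, 5)
        alphas = [np.full(50, 1.0 if not r.is_control else 0.0) for r in records]
        assert score_trials_roc(alphas, records, CFG).auroc == pytest.approx(1.0)

    def test_constant_alpha_is_chance(self):
        records = make_records(5, 5)
        alphas = [np.full(50, 0.4) for _ in records]
        assert score_trials_roc(alphas, records, CFG).auroc == pytest.approx(0.5)

    def test_shuffled_labels_average_to_chance(self, rng):
        records = make_records(20, 20)
        scores = rng.uniform(0, 1, 40)
        alphas = [np.full(50, s) for s in scores]
        aurocs = []
        for _ in range(100):
            perm = rng.permutation(40)
            aurocs.append(score_trials_roc([alphas[i] for i in perm], records,
                                           CFG).auroc)
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.05)

    def test_needs_both_classes(self):
        records = make_records(3, 0)
        with pytest.raises(ValueError):
            score_trials_roc([np.zeros(50)] * 3, records, CFG)

    def test_window_restricted_variant_ignores_out_of_window_peaks(self):
        records = make_records(1, 1)
        a_dev = np.zeros(50)
        a_dev[45] = 1.0  # peak far outside the quadrant-1 deviance window
        a_ctrl = np.zeros(50)
        roc = score_trials_roc([a_dev, a_ctrl], records, CFG, window_only=True)
        assert roc.auroc == pytest.approx(0.5)
        roc2 = score_trials_roc([a_dev, a_ctrl], records, CFG)
        assert roc2.auroc == pytest.approx(1.0)


def small_dataset(seed=0, n_subjects=2):
    from audsurp.synthetic import (GroundTruth, SyntheticConfig,
                                   generate_trial_features,
                                   simulate_behavioral_responses)

    cfg = SyntheticConfig.music(n_subjects=n_subjects,
                                n_trials_per_session=32, seed=seed)
    truth = GroundTruth()
    records, feats = generate_trial_features(cfg, truth)
    resp, rts, _, sp = simulate_behavioral_responses(records, feats, truth, cfg)
    return BehavioralDataset.build(records, feats, resp, rts,
                                   cfg.integration_config(), sparsified=sp)


class TestLoso:
    def test_fold_count_equals_subjects(self):
        ds = small_dataset(n_subjects=3)
        folds, W = loso_behavioral_eval(ds)
        assert len(folds) == 3
        assert W.shape == (6, 6) and (W >= 0).all()

    def test_deterministic_across_runs(self):
        ds = small_dataset()
        f1, _ = loso_behavioral_eval(ds)
        f2, _ = loso_behavioral_eval(ds)
        for s in f1:
            assert f1[s]["roc"].auroc == f2[s]["roc"].auroc

    def test_single_subject_rejected(self):
        ds = small_dataset(n_subjects=1)
        with pytest.raises(ValueError):
            loso_behavioral_eval(ds)

    def test_uniform_baseline_on_identity_data_matches_identity_model(self):
        ds = small_dataset()
        uni = baseline_models(ds, "uniform")
        import audsurp.evaluation as ev

        for subj, auroc in uni.items():
            want = ev._eval_weights(ds, np.eye(6), ds.index(subject=subj)).auroc
            assert auroc == pytest.approx(want)

    def test_unknown_baseline_kind_and_bad_repeats(self):
        ds = small_dataset()
        with pytest.raises(ValueError):
            baseline_models(ds, "bogus")
        with pytest.raises(ValueError):
            baseline_models(ds, "random", repeats=0)


class TestCrosscorr:
    def test_self_correlation_is_one_at_zero_lag(self, rng):
        a = rng.normal(size=500)
        c, lag = max_crosscorr(a, a, fs=100.0)
        assert c == pytest.approx(1.0) and lag == 0.0

    def test_shifted_copy_found_at_its_lag(self, rng):
        a = np.zeros(500)
        a[100:110] = 1.0
        b = np.roll(a, 100)  # 1 s later at 100 Hz
        c, lag = max_crosscorr(a, b, fs=100.0)
        assert c == pytest.approx(1.0) and lag == pytest.approx(1.0)

    def test_scaling_invariance(self, rng):
        a, b = rng.normal(size=300), rng.normal(size=300)
        c1, _ = max_crosscorr(a, b, 100.0)
        c2, _ = max_crosscorr(3.7 * a, 0.2 * b, 100.0)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_independent_noise_rarely_exceeds_point_two(self):
        high = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            c, _ = max_crosscorr(r.normal(size=1000), r.normal(size=1000), 100.0)
            high += c > 0.2
        assert high <= 5

    def test_zero_energy_defined_as_zero(self):
        c, lag = max_crosscorr(np.zeros(100), np.ones(100), 100.0)
        assert c == 0.0

    def test_frame_output_per_condition(self, rng):
        model = {("a",): rng.normal(size=100), ("b",): rng.normal(size=100)}
        emp = {k: v.copy() for k, v in model.items()}
        df = pdr_crosscorr_eval(model, emp, fs=100.0)
        assert len(df) == 2
        np.testing.assert_allclose(df["max_corr"], 1.0)


class TestQuadrantModels:
    def test_outputs_per_quadrant_with_replicates(self):
        ds = small_dataset(seed=2, n_subjects=2)
        out = quadrant_models(ds, n_passes=3, rng=np.random.default_rng(0))
        assert set(out) == {1, 2, 3, 4}
        for q in out:
            assert out[q]["weights"].shape == (6, 6)
            assert out[q]["weights_all"].shape[0] == 3

    def test_empty_quadrant_rejected(self):
        records = make_records(4, 4)
        records = [r for r in records if r.quadrant != 3]
        ds = BehavioralDataset(records, [np.zeros((50, 6))] * len(records),
                               [np.zeros(50)] * len(records),
                               [Outcome.MISS] * len(records), CFG)
        with pytest.raises(ValueError):
            quadrant_models(ds, n_passes=1)


class TestDprime:
    def _trials(self, hit, fa, n=100):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n):
            rows.append({"subject_id": 0, "is_control": 0, "loudness": 2.0,
                         "pitch": 2.0, "timbre_bg": 0, "timbre_fg": 0,
                         "response": int(rng.random() < hit)})
            rows.append({"subject_id": 0, "is_control": 1, "loudness": 2.0,
                         "pitch": 2.0, "timbre_bg": 0, "timbre_fg": 0,
                         "response": int(rng.random() < fa)})
        return pd.DataFrame(rows)

    def test_extreme_rates_clamped_to_printed_bound(self):
        df = self._trials(1.0, 0.0)
        out = dprime_table(df)
        assert out.hit_rate.iloc[0] == 0.99 and out.fa_rate.iloc[0] == 0.01
        assert out.dprime.iloc[0] == pytest.approx(2 * norm.ppf(0.99), abs=1e-4)
        assert out.dprime.iloc[0] == pytest.approx(4.6527, abs=1e-3)

    def test_equal_rates_give_zero(self):
        df = self._trials(0.5, 0.5, n=4000)
        assert abs(dprime_table(df).dprime.iloc[0]) < 0.15

    def test_antisymmetry(self):
        lo, hi = DPRIME_CLAMP
        d = lambda h, f: norm.ppf(np.clip(h, lo, hi)) - norm.ppf(np.clip(f, lo, hi))
        assert d(0.8, 0.3) == pytest.approx(-d(0.3, 0.8))

    def test_subject_without_controls_rejected(self):
        df = self._trials(0.5, 0.5)
        with pytest.raises(ValueError):
            dprime_table(df[df.is_control == 0])


class TestRmAnova:
    def _dprime_frame(self, effect=0.0, noise=0.05, n_subj=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            base = float(s) if noise == 0 else rng.normal(1.0, 0.2)
            for lo in (0, 1):
                for p in (0, 1):
                    for tb in (0, 1):
                        for tf in (0, 1):
                            rows.append({
                                "subject_id": s, "loudness": lo, "pitch": p,
                                "timbre_bg": tb, "timbre_fg": tf,
                                "dprime": base + effect * p
                                + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_fifteen_effects_reported(self):
        tab = rm_anova_effects(self._dprime_frame())
        assert len(tab) == 15

    def test_planted_pitch_effect_dominates(self):
        tab = rm_anova_effects(self._dprime_frame(effect=0.8))
        top = tab.loc[tab.F.idxmax(), "effect"]
        assert top == "pitch"
        assert tab.loc[tab.effect == "pitch", "p"].iloc[0] < 0.001

    def test_zero_between_condition_variance_gives_zero_f(self):
        tab = rm_anova_effects(self._dprime_frame(effect=0.0, noise=0.0))
        assert (tab.F == 0.0).all()

    def test_missing_cells_rejected(self):
        df = self._dprime_frame().iloc[:-1]
        with pytest.raises(Exception):
            rm_anova_effects(df)


def test_cross_weight_ttest_all_zero_is_not_significant():
    mats = [np.eye(6) for _ in range(8)]
    tab = cross_weight_ttest(mats)
    assert (tab.p_bonferroni == 1.0).all()
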