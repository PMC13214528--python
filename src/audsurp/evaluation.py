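"""Model evaluation: ROC/AUROC, cross-validation, baselines and statistics.

Trial-level discrimination is scored by comparing the model output
alpha(t) against thresholds between 0 and 1: a trial counts as detected at
threshold theta if alpha crosses theta anywhere in the trial (a
window-restricted variant confines deviant-trial crossings to
[t0, t0 + delta_t]).  The behavioral model is evaluated by leave-one-subject-out
cross-validation against a uniform (identity-weight) and a shuffled-onset
random baseline; the pupil model by the maximum normalised
cross-correlation between model output and binarised condition-averaged
pupil responses within a +-3 s lag window.  Behavioral sensitivity is
summarised by d' per factorial deviant condition and a four-way
repeated-measures ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .drex import DrexParams, compute_surprisal_sets
from .features import FEATURE_ORDER
from .integration import (IntegrationConfig, SurprisalIntegrationModel,
                          boost_surprisal, combined_alpha,
                          normalize_and_sparsify, reduce_weight_matrix)
from .targets import Outcome, behavioral_target_signal, classify_outcome
from .trials import TrialRecord

__all__ = [
    "RocResult",
    "BehavioralDataset",
    "score_trials_roc",
    "loso_behavioral_eval",
    "baseline_models",
    "max_crosscorr",
    "pdr_crosscorr_eval",
    "quadrant_models",
    "dprime_table",
    "rm_anova_effects",
    "cross_weight_ttest",
    "DPRIME_CLAMP",
]

DPRIME_CLAMP = (0.01, 0.99)


@dataclass
class RocResult:
    thresholds: np.ndarray
    hit_rates: np.ndarray
    fa_rates: np.ndarray
    auroc: float


def _trial_scores(alphas, records, config: IntegrationConfig,
                  window_only: bool = False):
    """Max alpha per trial: inside the deviance window for deviants,
    anywhere for controls."""
    scores, labels = [], []
    for a, r in zip(alphas, records):
        a = np.asarray(a, dtype=float)
        if r.is_control or not window_only:
            scores.append(float(a.max()))
        else:
            tau = (np.arange(a.size) + 0.5) / config.frame_rate
            win = (tau >= r.t0) & (tau < r.t0 + config.delta_t)
            scores.append(float(a[win].max()) if win.any() else 0.0)
        labels.append(0 if r.is_control else 1)
    return np.array(scores), np.array(labels)


def score_trials_roc(alphas, records, config: IntegrationConfig,
                     thresholds: np.ndarray | None = None,
                     window_only: bool = False,
                     augment_scores: bool = False) -> RocResult:
    """ROC over alpha thresholds in [0, 1]; AUROC by the trapezoid rule.

    The default threshold grid is 0..1 in steps of 0.01; with
    ``augment_scores`` every distinct trial score is added, making the
    curve resolution independent.
    """
    scores, labels = _trial_scores(alphas, records, config, window_only)
    if labels.min() == labels.max():
        raise ValueError("ROC needs both deviant and control trials")
    if thresholds is None:
        thresholds = np.arange(0.0, 1.01, 0.01)
        if augment_scores:
            thresholds = np.union1d(thresholds, scores)
    hit = np.array([(scores[labels == 1] >= th).mean() for th in thresholds])
    fa = np.array([(scores[labels == 0] >= th).mean() for th in thresholds])
    # sort points by FA then hit; pad with the (0,0) and (1,1) endpoints
    pts = np.array(sorted(zip(fa, hit)))
    fa_c = np.concatenate(([0.0], pts[:, 0], [1.0]))
    hit_c = np.concatenate(([0.0], pts[:, 1], [1.0]))
    auroc = float(np.trapezoid(hit_c, fa_c))
    return RocResult(np.asarray(thresholds), hit, fa, auroc)


@dataclass
class BehavioralDataset:
    """Sparsified surprisals + behavioral targets, grouped by subject."""

    records: list[TrialRecord]
    sparsified: list[np.ndarray]  # (frames, 6) per trial
    targets: list[np.ndarray]
    outcomes: list[Outcome]
    config: IntegrationConfig

    subjects: np.ndarray = field(init=False)

    def __post_init__(self):
        self.subjects = np.array([r.subject_id for r in self.records])

    @classmethod
    def build(cls, records, feature_sets, responses, rts,
              config: IntegrationConfig,
              drex_params: DrexParams | None = None,
              sparsified: list[np.ndarray] | None = None
              ) -> "BehavioralDataset":
        """Surprisal -> pooled normalise/sparsify -> outcome-based targets."""
        if sparsified is None:
            surp = compute_surprisal_sets(feature_sets, drex_params)
            sparsified = [s.stack(FEATURE_ORDER)
                          for s in normalize_and_sparsify(surp, config)]
        outcomes, targets = [], []
        for r, s, resp, rt in zip(records, sparsified, responses, rts):
            o = classify_outcome(r, bool(resp), rt, config)
            outcomes.append(o)
            targets.append(behavioral_target_signal(r, o, s, config).y)
        return cls(list(records), sparsified, targets, outcomes, config)

    def subject_ids(self):
        return sorted(set(self.subjects))

    def index(self, subject=None, exclude=None):
        idx = np.arange(len(self.records))
        if subject is not None:
            idx = idx[self.subjects[idx] == subject]
        if exclude is not None:
            idx = idx[self.subjects[idx] != exclude]
        return idx


def _fit_subject(ds: BehavioralDataset, idx, targets=None) -> np.ndarray:
    targets = targets if targets is not None else [ds.targets[i] for i in idx]
    model = SurprisalIntegrationModel([ds.sparsified[i] for i in idx],
                                      targets, ds.config)
    return model.fit().weights


def _avg_train_weights(ds: BehavioralDataset, held_out,
                       shuffle_rng: np.random.Generator | None = None
                       ) -> np.ndarray:
    Ws = []
    for subj in ds.subject_ids():
        if subj == held_out:
            continue
        idx = ds.index(subject=subj)
        targets = None
        if shuffle_rng is not None:
            perm = shuffle_rng.permutation(len(idx))
            targets = [ds.targets[idx[p]] for p in perm]
        Ws.append(_fit_subject(ds, idx, targets))
    return np.mean(Ws, axis=0)


def _eval_weights(ds: BehavioralDataset, W, idx,
                  label_perm: np.ndarray | None = None) -> RocResult:
    """Score trials under weights ``W``; ``label_perm`` reassigns each
    trial's deviant/control/onset label to another trial of the subject
    (the shuffled-onset null)."""
    alphas = [combined_alpha(boost_surprisal(ds.sparsified[i], W, ds.config))
              for i in idx]
    lab_idx = idx if label_perm is None else idx[label_perm]
    return score_trials_roc(alphas, [ds.records[i] for i in lab_idx], ds.config)


def loso_behavioral_eval(ds: BehavioralDataset):
    """Leave-one-subject-out: per-subject weights averaged across the
    training subjects, applied to the held-out subject's trials.

    Returns ``(folds, mean_weights)`` where ``folds`` maps held-out subject
    to its :class:`RocResult` and fold weight matrix.
    """
    subjects = ds.subject_ids()
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    folds = {}
    all_W = []
    for held in subjects:
        W = _avg_train_weights(ds, held)
        folds[held] = {"roc": _eval_weights(ds, W, ds.index(subject=held)),
                       "weights": W}
        all_W.append(W)
    return folds, np.mean(all_W, axis=0)


def baseline_models(ds: BehavioralDataset, kind: str, repeats: int = 10,
                    rng: np.random.Generator | None = None):
    """Uniform (identity-weight) or shuffled-onset random baseline, LOSO.

    The random baseline shuffles deviant-onset labels across trials: each
    training subject's deviance targets are permuted before fitting, and
    the held-out subject's trial labels are permuted the same way when
    scoring, so the model is both trained and assessed under decoupled
    stimulus/label timing (a permutation null whose AUROC expectation is
    chance).  This is repeated ``repeats`` times (default 10, per the
    behavioral protocol) and AUROCs are averaged.  Returns a dict held-out
    subject -> mean AUROC.
    """
    if kind not in ("uniform", "random"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = rng or np.random.default_rng(0)
    out = {}
    k = len(FEATURE_ORDER)
    for held in ds.subject_ids():
        idx = ds.index(subject=held)
        if kind == "uniform":
            out[held] = _eval_weights(ds, np.eye(k), idx).auroc
        else:
            aurocs = []
            for _ in range(repeats):
                W = _avg_train_weights(ds, held, rng)
                perm = rng.permutation(idx.size)
                aurocs.append(_eval_weights(ds, W, idx, perm).auroc)
            out[held] = float(np.mean(aurocs))
    return out


def max_crosscorr(a: np.ndarray, b: np.ndarray, fs: float,
                  max_lag_s: float = 3.0):
    """Max of C(tau) = sum a(t) b(t+tau) / sqrt(sum a^2 sum b^2), |tau|<=3 s.

    Normalisation by the zero-lag autocorrelations makes the metric
    invariant to positive rescaling of either signal.  Zero-energy inputs
    return 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0, 0.0
    full = np.correlate(b, a, mode="full") / denom
    lags = (np.arange(full.size) - (a.size - 1)) / fs
    sel = np.abs(lags) <= max_lag_s
    i = int(np.argmax(full[sel]))
    return float(full[sel][i]), float(lags[sel][i])


def pdr_crosscorr_eval(model_alphas: dict, empirical_pdr: dict, fs: float,
                       max_lag_s: float = 3.0) -> pd.DataFrame:
    """Per-condition max normalised cross-correlation (model vs PDR).

    Both dicts map a condition key to a signal on a common grid at ``fs``.
    """
    rows = []
    for key in model_alphas:
        c, lag = max_crosscorr(model_alphas[key], empirical_pdr[key], fs,
                               max_lag_s)
        rows.append({"condition": key, "max_corr": c, "lag_s": lag})
    return pd.DataFrame(rows)


def quadrant_models(ds: BehavioralDataset, n_passes: int = 10,
                    rng: np.random.Generator | None = None):
    """Four per-quadrant models, balanced by bootstrapped control quarters.

    Each pass randomly partitions the control trials into four quarters
    (every control used exactly once per pass); quadrant q's model trains
    on its deviant trials plus one quarter.  Weights and in-sample AUROCs
    are averaged over ``n_passes`` passes.
    """
    rng = rng or np.random.default_rng(0)
    ctrl_idx = np.array([i for i, r in enumerate(ds.records) if r.is_control])
    dev_by_q = {q: np.array([i for i, r in enumerate(ds.records)
                             if r.quadrant == q]) for q in (1, 2, 3, 4)}
    if any(v.size == 0 for v in dev_by_q.values()):
        raise ValueError("every quadrant needs at least one deviant trial")
    acc: dict[int, dict] = {q: {"weights": [], "auroc": []} for q in (1, 2, 3, 4)}
    for _ in range(n_passes):
        quarters = np.array_split(rng.permutation(ctrl_idx), 4)
        for q in (1, 2, 3, 4):
            idx = np.concatenate([dev_by_q[q], quarters[q - 1]])
            model = SurprisalIntegrationModel(
                [ds.sparsified[i] for i in idx],
                [ds.targets[i] for i in idx], ds.config)
            W = model.fit().weights
            acc[q]["weights"].append(W)
            acc[q]["auroc"].append(_eval_weights(ds, W, idx).auroc)
    return {q: {"weights": np.mean(acc[q]["weights"], axis=0),
                "weights_all": np.array(acc[q]["weights"]),
                "auroc": float(np.mean(acc[q]["auroc"]))}
            for q in (1, 2, 3, 4)}


# -- behavioral statistics ---------------------------------------------------

def dprime_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x factorial condition hit rates and d'.

    Conditions are the 2 loudness x 2 pitch x 2 timbre-background x 2
    timbre-foreground cells; the false-alarm rate comes from each
    subject's control trials and is constant across that subject's cells.
    Rates of 0/1 are clamped to 0.01/0.99 before the inverse-normal
    transform, bounding |d'| at 2 * Phi^-1(0.99) ~= 4.6527.
    """
    lo, hi = DPRIME_CLAMP
    rows = []
    for subj, g in trials.groupby("subject_id"):
        ctrl = g[g["is_control"] == 1]
        if ctrl.empty:
            raise ValueError(f"subject {subj} has no control trials")
        fa = float(np.clip(ctrl["response"].mean(), lo, hi))
        dev = g[g["is_control"] == 0]
        for key, cell in dev.groupby(["loudness", "pitch", "timbre_bg",
                                      "timbre_fg"]):
            hit = float(np.clip(cell["response"].mean(), lo, hi))
            rows.append({"subject_id": subj, "loudness": key[0],
                         "pitch": key[1], "timbre_bg": key[2],
                         "timbre_fg": key[3], "hit_rate": hit, "fa_rate": fa,
                         "dprime": stats.norm.ppf(hit) - stats.norm.ppf(fa)})
    return pd.DataFrame(rows)


def rm_anova_effects(dprime: pd.DataFrame) -> pd.DataFrame:
    """Four-way repeated-measures ANOVA on d' (15 effects: mains and all
    interactions), via the within-subject sums-of-squares decomposition."""
    from statsmodels.stats.anova import AnovaRM

    factors = ["loudness", "pitch", "timbre_bg", "timbre_fg"]
    resid = dprime["dprime"] - dprime.groupby("subject_id")["dprime"] \
        .transform("mean")
    if np.abs(resid).max() < 1e-12:
        # no within-subject variation at all: every effect is exactly null
        from itertools import combinations

        effects = [":".join(c) for k in range(1, 5)
                   for c in combinations(factors, k)]
        return pd.DataFrame({"effect": effects, "F": 0.0, "p": 1.0})
    res = AnovaRM(dprime, depvar="dprime", subject="subject_id",
                  within=factors).fit()
    tab = res.anova_table.rename(columns={"F Value": "F", "Pr > F": "p"})
    tab.index.name = "effect"
    tab = tab.reset_index()[["effect", "F", "p"]]
    # a zero effect sum of squares yields 0/0 upstream; report F = 0
    tab["F"] = tab["F"].fillna(0.0)
    tab["p"] = tab["p"].fillna(1.0)
    return tab


def cross_weight_ttest(weight_matrices: list[np.ndarray]) -> pd.DataFrame:
    """Group-level test of the reduced cross-feature weights against zero.

    One-sample two-sided t-test per off-diagonal entry of the reduced 3x3
    (loudness, pitch, timbre) matrix across subjects, Bonferroni-corrected
    over the six entries.
    """
    attrs = ("loudness", "pitch", "timbre")
    reduced = np.array([reduce_weight_matrix(W) for W in weight_matrices])
    rows = []
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            vals = reduced[:, a, b]
            if np.allclose(vals, vals[0]):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_1samp(vals, 0.0)
            rows.append({"from": attrs[b], "to": attrs[a], "mean": vals.mean(),
                         "t": float(t), "p": float(p),
                         "p_bonferroni": min(1.0, float(p) * 6)})
    return pd.DataFrame(rows)
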