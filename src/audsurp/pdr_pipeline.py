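"""End-to-end pupil-dilation-response (PDR) modeling pipeline.

Glues the preprocessing, target and integration stages into the
condition-level PDR analysis: clean and normalise a session recording,
average epochs within the 32 deviant condition cells (plus grouped
4-control averages), build peak-anchored deviance targets, fit the
integration model per subject on condition-averaged surprisal, and score
the fit by maximum normalised cross-correlation against the binarised
empirical PDR (with a shuffled-onset baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integration import (IntegrationConfig, SurprisalIntegrationModel,
                          boost_surprisal, combined_alpha)
from .pupil import binarize_trace, clean_and_interpolate, session_z_and_baseline
from .targets import ConditionAverage, condition_average_pdr, pdr_target_signal
from .evaluation import max_crosscorr

__all__ = ["PdrSubjectData", "prepare_pdr_subject", "fit_pdr_subject",
           "pdr_condition_eval"]

EVAL_RATE = 100.0  # Hz grid for model-vs-PDR cross-correlation


@dataclass
class PdrSubjectData:
    subject_id: int
    averages: list[ConditionAverage]  # 32 condition cells + control groups
    surprisal: list[np.ndarray]  # condition-averaged sparsified surprisal
    targets: list[np.ndarray]
    config: IntegrationConfig


def prepare_pdr_subject(session_trace, onsets_ms, records,
                        sparsified_by_trial: dict[int, np.ndarray],
                        config: IntegrationConfig,
                        rng: np.random.Generator) -> PdrSubjectData:
    """Clean, z-score, epoch and condition-average one subject's session.

    ``sparsified_by_trial`` maps trial_id to its (frames, 6) normalised
    sparsified surprisal; each condition average pairs the mean of its
    member trials' surprisal with the PDR-peak target.
    """
    trial_dur = records[0].duration
    cleaned = clean_and_interpolate(session_trace)
    epochs, time_s = session_z_and_baseline(cleaned, onsets_ms, trial_dur)
    order = np.argsort(onsets_ms)
    epoch_by_id = {records[order[i]].trial_id: epochs[i]
                   for i in range(len(records))}
    averages = condition_average_pdr(epoch_by_id, time_s, records, rng)
    n_frames = next(iter(sparsified_by_trial.values())).shape[0]
    surp, targ = [], []
    for avg in averages:
        surp.append(np.mean([sparsified_by_trial[t] for t in avg.trial_ids],
                            axis=0))
        targ.append(pdr_target_signal(avg, config, n_frames).y)
    return PdrSubjectData(records[0].subject_id, averages, surp, targ, config)


def fit_pdr_subject(data: PdrSubjectData, shuffle_rng=None):
    """Fit the integration model on one subject's condition averages.

    With ``shuffle_rng`` the deviance targets are permuted across condition
    averages first (the shuffled-onset baseline).
    """
    targets = data.targets
    if shuffle_rng is not None:
        targets = [data.targets[i]
                   for i in shuffle_rng.permutation(len(data.targets))]
    model = SurprisalIntegrationModel(data.surprisal, targets, data.config)
    return model.fit()


def pdr_condition_eval(data: PdrSubjectData, weights: np.ndarray,
                       max_lag_s: float = 3.0) -> dict:
    """Max cross-correlation per deviant condition cell, keyed by condition.

    Model alpha(t) (10 Hz) is linearly interpolated to 100 Hz; the
    empirical condition-averaged PDR is mean-pooled to 100 Hz over the
    trial span and binarised at 90% of its peak.
    """
    out = {}
    frame_rate = data.config.frame_rate
    for avg, s in zip(data.averages, data.surprisal):
        if avg.key is None:
            continue
        alpha = combined_alpha(boost_surprisal(s, weights, data.config))
        t_model = (np.arange(alpha.size) + 0.5) / frame_rate
        t_out = np.arange(0.0, t_model[-1], 1.0 / EVAL_RATE)
        alpha_up = np.interp(t_out, t_model, alpha)
        in_trial = (avg.time >= 0) & (avg.time < t_model[-1])
        pdr = avg.trace[in_trial]
        hop = int(round(1000.0 / EVAL_RATE))
        n = (pdr.size // hop) * hop
        pdr_ds = pdr[:n].reshape(-1, hop).mean(axis=1)
        m = min(pdr_ds.size, alpha_up.size)
        c, _ = max_crosscorr(alpha_up[:m], binarize_trace(pdr_ds[:m]),
                             EVAL_RATE, max_lag_s)
        out[avg.key] = c
    return out
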