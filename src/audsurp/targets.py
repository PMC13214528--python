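"""Binary deviance targets y(t) from behavioral outcomes and pupil responses.

The regression target marks the deviance window: y(t) = 1 for
t0 <= t < t0 + delta_t and 0 elsewhere, where t0 is the ground-truth
deviant onset (hits), the peak of the summed surprisal (false alarms), or
the peak of the condition-averaged pupil dilation response within one
second after the deviant onset (PDR targets).  Misses and correct
rejections train as all-zero "control" targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .integration import IntegrationConfig
from .trials import TrialRecord

__all__ = [
    "Outcome",
    "TargetSignal",
    "ConditionAverage",
    "classify_outcome",
    "step_target",
    "behavioral_target_signal",
    "condition_key",
    "condition_average_pdr",
    "pdr_target_signal",
]


class Outcome(str, Enum):
    HIT = "hit"
    MISS = "miss"
    FALSE_ALARM = "false_alarm"
    CORRECT_REJECTION = "correct_rejection"


@dataclass(frozen=True)
class TargetSignal:
    y: np.ndarray  # binary, on the 10 Hz frame grid
    t0: float | None
    delta_t: float
    provenance: str  # behavior_tp | behavior_fa | control | pdr

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("target must be binary")
        object.__setattr__(self, "y", y)


def classify_outcome(trial: TrialRecord, responded: bool,
                     rt_s: float | None = None,
                     config: IntegrationConfig | None = None) -> Outcome:
    """Partition a trial into hit / miss / false alarm / correct rejection.

    A response counts only if it falls within the post-sound response
    window (keypresses are timed from trial start; late presses are
    ignored).
    """
    config = config or IntegrationConfig()
    if responded and rt_s is not None:
        responded = rt_s <= trial.duration + config.response_window
    if trial.is_control:
        return Outcome.FALSE_ALARM if responded else Outcome.CORRECT_REJECTION
    return Outcome.HIT if responded else Outcome.MISS


def step_target(n_frames: int, t0: float | None, delta_t: float,
                frame_rate: float = 10.0, provenance: str = "control"
                ) -> TargetSignal:
    """y(t) = 1 on [t0, t0 + delta_t), frames timestamped at bin centers."""
    y = np.zeros(n_frames)
    if t0 is not None:
        tau = (np.arange(n_frames) + 0.5) / frame_rate
        y[(tau >= t0) & (tau < t0 + delta_t)] = 1.0
    return TargetSignal(y=y, t0=t0, delta_t=delta_t, provenance=provenance)


def behavioral_target_signal(trial: TrialRecord, outcome: Outcome,
                             sparsified: np.ndarray,
                             config: IntegrationConfig) -> TargetSignal:
    """Target for one trial given its outcome.

    Hits anchor t0 at the true deviant onset; false alarms anchor it at the
    peak of the summed (normalised, sparsified) surprisal, earliest frame
    winning ties; misses and correct rejections yield all-zero targets.
    """
    n = sparsified.shape[0]
    if outcome is Outcome.HIT:
        if trial.t0 is None:
            raise ValueError(f"trial {trial.trial_id}: hit without onset")
        return step_target(n, trial.t0, config.delta_t, config.frame_rate,
                           "behavior_tp")
    if outcome is Outcome.FALSE_ALARM:
        total = sparsified.sum(axis=1)
        t0 = (int(np.argmax(total)) + 0.5) / config.frame_rate
        return step_target(n, t0, config.delta_t, config.frame_rate,
                           "behavior_fa")
    return step_target(n, None, config.delta_t, config.frame_rate, "control")


def condition_key(trial: TrialRecord) -> tuple:
    """(loudness, pitch, timbre same/different, quadrant) — the 32-cell grid."""
    return (trial.loudness, trial.pitch, int(trial.timbre_different),
            trial.quadrant)


@dataclass
class ConditionAverage:
    key: tuple | None  # None for grouped-control averages
    trace: np.ndarray  # averaged cleaned PDR epoch
    time: np.ndarray  # seconds relative to sound onset
    n_trials: int
    deviant_onset: float | None  # mean onset of the averaged trials
    subject_id: int
    trial_ids: tuple[int, ...] = ()


def condition_average_pdr(epochs: dict[int, np.ndarray], time: np.ndarray,
                          records: list[TrialRecord], rng: np.random.Generator,
                          control_group_size: int = 4
                          ) -> list[ConditionAverage]:
    """Average cleaned pupil epochs per condition cell; group controls by 4.

    ``epochs`` maps trial_id to a baseline-corrected z-scored epoch on the
    common ``time`` grid.  Deviant trials are averaged within each of the
    32 cells (2 loudness x 2 pitch x 2 timbre x 4 quadrants); control
    trials are partitioned at random into clusters of ``control_group_size``
    whose averages serve as a matched control set.
    """
    by_id = {r.trial_id: r for r in records}
    cells: dict[tuple, list[int]] = {}
    controls: list[int] = []
    for tid in epochs:
        r = by_id[tid]
        if r.is_control:
            controls.append(tid)
        else:
            cells.setdefault(condition_key(r), []).append(tid)
    out: list[ConditionAverage] = []
    subject = records[0].subject_id if records else -1
    for key in sorted(cells):
        tids = cells[key]
        trace = np.mean([epochs[t] for t in tids], axis=0)
        onset = float(np.mean([by_id[t].t0 for t in tids]))
        out.append(ConditionAverage(key, trace, time, len(tids), onset,
                                    subject, tuple(tids)))
    controls = list(rng.permutation(controls))
    for start in range(0, len(controls) - control_group_size + 1,
                       control_group_size):
        group = controls[start:start + control_group_size]
        trace = np.mean([epochs[t] for t in group], axis=0)
        out.append(ConditionAverage(None, trace, time, len(group), None,
                                    subject, tuple(group)))
    return out


def pdr_target_signal(avg: ConditionAverage, config: IntegrationConfig,
                      n_frames: int, peak_window: float = 1.0) -> TargetSignal:
    """Target from the PDR peak within one second after the deviant onset.

    t0 is the time of the maximum of the averaged trace inside
    [onset, onset + peak_window] (earliest maximum wins); grouped-control
    averages yield all-zero targets.  A window extending past the trace is
    truncated.
    """
    if avg.key is None or avg.deviant_onset is None:
        return step_target(n_frames, None, config.delta_t, config.frame_rate,
                           "control")
    t, x = avg.time, avg.trace
    lo = avg.deviant_onset
    sel = (t >= lo) & (t <= lo + peak_window)
    if not sel.any():
        raise ValueError("averaged trace does not cover the peak window")
    t0 = float(t[sel][np.argmax(x[sel])])
    return step_target(n_frames, t0, config.delta_t, config.frame_rate, "pdr")
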