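"""Pupillometry preprocessing: cleaning, normalisation, epoching, binarising.

The pipeline mirrors standard pupillometry practice for deviance
paradigms: right-eye traces at 1000 Hz, blink and off-fixation samples
(gaze more than 2 visual degrees from fixation) marked missing and filled
by shape-preserving piecewise-cubic (PCHIP) interpolation, z-scoring
against all cleaned samples of the recording session, and trial-by-trial
baseline correction using the one-second pre-stimulus mean.  No low-pass
filtering is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PupilTrace",
    "clean_and_interpolate",
    "session_z_and_baseline",
    "epoch_trials",
    "binarize_trace",
]

SAMPLE_RATE = 1000  # Hz


@dataclass
class PupilTrace:
    """1000 Hz pupil-diameter trace with gaze position and blink flags."""

    time_ms: np.ndarray
    pupil: np.ndarray
    gaze_x_deg: np.ndarray
    gaze_y_deg: np.ndarray
    blink: np.ndarray
    session_id: int = 0
    trial_id: int = -1

    def __post_init__(self):
        n = {len(self.time_ms), len(self.pupil), len(self.gaze_x_deg),
             len(self.gaze_y_deg), len(self.blink)}
        if len(n) != 1:
            raise ValueError("trace columns must share one length")
        dt = np.diff(self.time_ms)
        if dt.size and not np.allclose(dt, 1.0):
            raise ValueError("trace must be uniformly sampled at 1 ms")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.time_ms, "pupil": self.pupil,
            "gaze_x_deg": self.gaze_x_deg, "gaze_y_deg": self.gaze_y_deg,
            "blink": self.blink.astype(int)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "PupilTrace":
        return cls(time_ms=df["time_ms"].to_numpy(dtype=float),
                   pupil=df["pupil"].to_numpy(dtype=float),
                   gaze_x_deg=df["gaze_x_deg"].to_numpy(dtype=float),
                   gaze_y_deg=df["gaze_y_deg"].to_numpy(dtype=float),
                   blink=df["blink"].to_numpy().astype(bool), **kw)


def _blink_fallback(pupil: np.ndarray, margin_ms: int = 50) -> np.ndarray:
    """Mark zero/negative-diameter runs as blinks, dilated by +-50 ms.

    Fallback for recordings without an explicit blink column; the margin is
    a standard artifact guard, not derived from the study procedure.
    """
    bad = pupil <= 0
    if not bad.any():
        return bad
    idx = np.flatnonzero(bad)
    out = np.zeros_like(bad)
    for i in idx:
        out[max(0, i - margin_ms):i + margin_ms + 1] = True
    return out


def clean_and_interpolate(trace: PupilTrace,
                          gaze_limit_deg: float = 2.0) -> PupilTrace:
    """Repair blink and off-fixation samples; valid samples pass unchanged.

    Samples flagged as blinks, or with gaze farther than ``gaze_limit_deg``
    from fixation, are replaced by PCHIP interpolation over the valid
    samples; leading/trailing gaps take the nearest valid value.
    """
    blink = trace.blink.astype(bool)
    if not blink.any():  # no annotation: fall back to dropout detection
        blink = _blink_fallback(trace.pupil)
    gaze_dist = np.hypot(trace.gaze_x_deg, trace.gaze_y_deg)
    missing = blink | (gaze_dist > gaze_limit_deg)
    if missing.all():
        raise ValueError(f"trial {trace.trial_id}: no valid pupil samples")
    if not missing.any():
        return trace
    t = trace.time_ms
    good = ~missing
    interp = PchipInterpolator(t[good], trace.pupil[good], extrapolate=False)
    pupil = trace.pupil.copy()
    pupil[missing] = interp(t[missing])
    # edges: nearest valid value
    first, last = np.flatnonzero(good)[[0, -1]]
    pupil[:first] = pupil[first]
    pupil[last + 1:] = pupil[last]
    return replace(trace, pupil=pupil, blink=missing)


def epoch_trials(session: PupilTrace, onsets_ms: np.ndarray,
                 trial_duration_s: float, pre_s: float = 1.0,
                 post_s: float = 2.0):
    """Cut per-trial epochs spanning [-pre, duration + post] around onsets.

    Returns ``(epochs, time_s)``: a (n_trials, n_samples) array and the
    epoch time axis in seconds relative to sound onset.  Epochs running
    past the recording are truncated (and reported via the returned mask of
    full-length epochs in ``epochs`` being NaN-padded).
    """
    n_pre = int(round(pre_s * SAMPLE_RATE))
    n_total = int(round((pre_s + trial_duration_s + post_s) * SAMPLE_RATE))
    t0_rec = session.time_ms[0]
    epochs = np.full((len(onsets_ms), n_total), np.nan)
    for i, onset in enumerate(np.sort(np.asarray(onsets_ms, dtype=float))):
        start = int(round(onset - t0_rec)) - n_pre
        if start < 0 or start >= session.pupil.size:
            raise ValueError(f"onset {onset} outside recording")
        stop = min(start + n_total, session.pupil.size)
        epochs[i, : stop - start] = session.pupil[start:stop]
    time_s = (np.arange(n_total) - n_pre) / SAMPLE_RATE
    return epochs, time_s


def session_z_and_baseline(session: PupilTrace, onsets_ms: np.ndarray,
                           trial_duration_s: float, pre_s: float = 1.0,
                           post_s: float = 2.0):
    """z-score against the whole session, epoch, and baseline-correct.

    The z-transform uses the mean/SD of *all* cleaned session samples; each
    epoch then subtracts its own mean over the 1 s pre-stimulus window.
    Returns ``(epochs, time_s)``.
    """
    mu, sd = float(np.mean(session.pupil)), float(np.std(session.pupil))
    if sd == 0:
        raise ValueError("session has zero variance; z-transform undefined")
    z = replace(session, pupil=(session.pupil - mu) / sd)
    epochs, time_s = epoch_trials(z, onsets_ms, trial_duration_s, pre_s, post_s)
    base = np.nanmean(epochs[:, time_s < 0], axis=1, keepdims=True)
    return epochs - base, time_s


def binarize_trace(trace: np.ndarray, threshold_frac: float = 0.9) -> np.ndarray:
    """1 where the trace reaches ``threshold_frac`` of its epoch maximum."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        trace = np.nan_to_num(trace, nan=np.nanmin(trace))
    return (trace >= threshold_frac * trace.max()).astype(float)
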