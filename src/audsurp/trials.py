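"""Trial metadata records and table I/O shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TrialRecord", "records_to_frame", "records_from_frame"]


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the deviant-detection task.

    ``condition`` holds (loudness dB, pitch semitones, timbre background,
    timbre foreground); ``quadrant`` (1..4) and ``t0`` (deviant onset,
    seconds) are ``None`` on control trials.
    """

    trial_id: int
    subject_id: int
    session_id: int
    is_control: bool
    loudness: float
    pitch: float
    timbre_bg: int
    timbre_fg: int
    quadrant: int | None
    t0: float | None
    duration: float

    def __post_init__(self):
        if self.is_control:
            if self.t0 is not None or self.quadrant is not None:
                raise ValueError("control trials carry no deviant onset")
        else:
            if self.t0 is None or self.quadrant is None:
                raise ValueError("deviant trials need an onset and quadrant")
            q = self.quadrant
            lo, hi = (q - 1) / 4 * self.duration, q / 4 * self.duration
            if not lo <= self.t0 <= hi:
                raise ValueError(f"onset {self.t0} outside quadrant {q} "
                                 f"[{lo}, {hi}]")

    @property
    def timbre_different(self) -> bool:
        return self.timbre_bg != self.timbre_fg


def records_to_frame(records, responses=None, rts=None) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "trial_id": r.trial_id, "subject_id": r.subject_id,
            "session_id": r.session_id, "is_control": int(r.is_control),
            "loudness": r.loudness, "pitch": r.pitch,
            "timbre_bg": r.timbre_bg, "timbre_fg": r.timbre_fg,
            "quadrant": -1 if r.quadrant is None else r.quadrant,
            "t0_s": float("nan") if r.t0 is None else r.t0,
            "duration_s": r.duration,
            "response": -1 if responses is None else int(responses[i]),
            "rt_s": float("nan") if rts is None else rts[i],
        })
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in df.itertuples(index=False):
        ctrl = bool(row.is_control)
        out.append(TrialRecord(
            trial_id=int(row.trial_id), subject_id=int(row.subject_id),
            session_id=int(row.session_id), is_control=ctrl,
            loudness=float(row.loudness), pitch=float(row.pitch),
            timbre_bg=int(row.timbre_bg), timbre_fg=int(row.timbre_fg),
            quadrant=None if ctrl else int(row.quadrant),
            t0=None if ctrl else float(row.t0_s),
            duration=float(row.duration_s)))
    return out
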