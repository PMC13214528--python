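"""Synthetic study generator: stimuli, responses and pupil traces.

Emulates the deviant-detection experiments end to end with known ground
truth, so every downstream stage (surprisal, integration, targets,
pupillometry, evaluation) is exercisable and parameter recovery is
testable.  Two experiments are modelled:

* Music — 5 s scenes of overlapping 1.2 s tokens; deviants 2 or 6 dB
  louder, 2 or 6 semitones higher, same or different instrument;
* Nature — 6 s scenes of 1.3-1.5 s tokens; deviants 2 or 8 dB, 0 or 3
  semitones, same or different species.

Deviants appear in half the trials, at a uniform time within one of four
equal trial quadrants.  Feature streams are generated directly as
piecewise-stationary Gaussian channels with condition-dependent additive
mean shifts (the generator's native path), or trials can be rendered to
audio and passed through the acoustic-feature front end.  Behavioral
responses come from the full surprisal + integration forward model run
with a known weight matrix; pupil traces are deviance impulses convolved
with a gamma kernel peaking ~1 s after the deviant, plus drift, noise and
blink gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drex import DrexParams, SurprisalSet, compute_surprisal_sets
from .features import FEATURE_ORDER, FeatureSet, Waveform
from .integration import IntegrationConfig, boost_surprisal, combined_alpha, \
    normalize_and_sparsify
from .trials import TrialRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_trial_features",
    "synthesize_audio_trial",
    "forward_alphas",
    "simulate_behavioral_responses",
    "simulate_pupil_session",
    "simulate_pupil_traces",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters; defaults follow the Music experiment."""

    experiment: str = "music"
    n_subjects: int = 8
    n_trials_per_session: int = 128
    n_sessions: int = 1
    trial_duration: float = 5.0
    token_duration: float = 1.2
    loudness_levels: tuple[float, float] = (2.0, 6.0)  # dB
    pitch_levels: tuple[float, float] = (2.0, 6.0)  # semitones
    timbre_levels: tuple[int, int] = (0, 1)
    control_fraction: float = 0.5
    sample_rate_audio: int = 16000
    feature_rate: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.control_fraction <= 1.0:
            raise ValueError("control_fraction must lie in [0, 1]")
        if min(self.trial_duration, self.token_duration) <= 0:
            raise ValueError("durations must be positive")
        if self.n_subjects < 1 or self.n_trials_per_session < 1:
            raise ValueError("at least one subject and one trial required")

    @classmethod
    def music(cls, **kw) -> "SyntheticConfig":
        return cls(experiment="music", **kw)

    @classmethod
    def nature(cls, **kw) -> "SyntheticConfig":
        defaults = dict(experiment="nature", trial_duration=6.0,
                        token_duration=1.4, loudness_levels=(2.0, 8.0),
                        pitch_levels=(0.0, 3.0))
        defaults.update(kw)
        return cls(**defaults)

    def integration_config(self, **kw) -> IntegrationConfig:
        return IntegrationConfig.for_experiment(self.experiment, **kw)


def _default_gains() -> dict[str, float]:
    # feature-shift per condition unit, in units of the background noise SD
    return {"envelope_per_db": 1.5, "pitch_per_semitone": 2.0,
            "spec_low_per_semitone": 1.0, "timbre_spec_high": 4.0,
            "timbre_scale": 4.0, "timbre_rate": 4.0}


@dataclass(frozen=True)
class GroundTruth:
    """Known generative parameters, the reference for recovery tests.

    ``weight_matrix_true`` drives the forward behavioral model; the
    optional per-quadrant list enables time-dependent interactions.  The
    pupil kernel is a gamma density peaking at ``(shape - 1) * scale``
    seconds after the deviant (defaults peak at 1.0 s).
    """

    weight_matrix_true: np.ndarray = field(
        default_factory=lambda: 4.0 * np.eye(len(FEATURE_ORDER)))
    weight_matrix_by_quadrant: tuple | None = None
    behavioral_lapse_rate: float = 0.05
    pupil_kernel_shape: float = 3.0
    pupil_kernel_scale: float = 0.5
    pupil_feature_gains: np.ndarray = field(
        default_factory=lambda: np.full(len(FEATURE_ORDER), 0.15))
    pupil_noise_sd: float = 0.5
    noise_sd: float = 1.0  # feature-channel noise, z units
    noise_channel_corr: float = 0.5  # shared background fluctuation across channels
    feature_shift_gains: dict = field(default_factory=_default_gains)

    def __post_init__(self):
        W = np.asarray(self.weight_matrix_true, dtype=float)
        if np.any(W < 0):
            raise ValueError("true weights must be nonnegative")
        object.__setattr__(self, "weight_matrix_true", W)
        gains = np.asarray(self.pupil_feature_gains, dtype=float)
        if np.any(gains < 0):
            raise ValueError("pupil gains must be nonnegative")
        object.__setattr__(self, "pupil_feature_gains", gains)
        if not 0.0 <= self.behavioral_lapse_rate <= 1.0:
            raise ValueError("lapse rate must lie in [0, 1]")
        if self.pupil_kernel_latency <= 0:
            raise ValueError("kernel peak latency must be positive")

    @property
    def pupil_kernel_latency(self) -> float:
        return (self.pupil_kernel_shape - 1.0) * self.pupil_kernel_scale

    def weight_for_trial(self, record: TrialRecord) -> np.ndarray:
        if self.weight_matrix_by_quadrant is None or record.quadrant is None:
            return self.weight_matrix_true
        return np.asarray(self.weight_matrix_by_quadrant[record.quadrant - 1],
                          dtype=float)


def condition_shifts(record: TrialRecord, truth: GroundTruth) -> np.ndarray:
    """Additive per-channel mean shift implied by a trial's condition.

    Loudness maps to the envelope; pitch to the pitch and low-spectral
    channels; a timbre change to the high-spectral, scale and rate
    channels.  Shifts are linear in the condition level, so magnitude is
    monotone in level.
    """
    g = truth.feature_shift_gains
    shift = np.zeros(len(FEATURE_ORDER))
    if record.is_control:
        return shift
    idx = {n: i for i, n in enumerate(FEATURE_ORDER)}
    shift[idx["envelope"]] = g["envelope_per_db"] * record.loudness
    shift[idx["pitch"]] = g["pitch_per_semitone"] * record.pitch
    shift[idx["spec_low"]] = g["spec_low_per_semitone"] * record.pitch
    if record.timbre_different:
        for name in ("spec_high", "scale", "rate"):
            shift[idx[name]] = g[f"timbre_{name}"]
    return shift


def _balanced_conditions(config: SyntheticConfig, n: int,
                         rng: np.random.Generator) -> list[tuple]:
    """Tile the loudness x pitch x timbre x quadrant grid over n deviants.

    Balanced assignment keeps every factorial cell populated (as in the
    study's design); the tiled list is shuffled so cell order is random.
    """
    from itertools import product

    cells = list(product(config.loudness_levels, config.pitch_levels,
                         config.timbre_levels, config.timbre_levels))
    offset = {c: int(rng.integers(4)) for c in cells}
    count = {c: 0 for c in cells}
    conds: list[tuple] = []
    while len(conds) < n:
        rng.shuffle(cells)
        for c in cells:
            q = (offset[c] + count[c]) % 4 + 1  # rotate quadrants per cell
            count[c] += 1
            conds.append((*c, q))
    return conds[:n]


def _make_records(config: SyntheticConfig, rng: np.random.Generator
                  ) -> list[TrialRecord]:
    records = []
    tid = 0
    for subj in range(config.n_subjects):
        for sess in range(config.n_sessions):
            n = config.n_trials_per_session
            n_ctrl = int(round(n * config.control_fraction))
            is_ctrl = np.zeros(n, dtype=bool)
            is_ctrl[:n_ctrl] = True
            rng.shuffle(is_ctrl)
            conds = iter(_balanced_conditions(config, n - n_ctrl, rng))
            for k in range(n):
                if is_ctrl[k]:
                    loud = float(rng.choice(config.loudness_levels))
                    pitch = float(rng.choice(config.pitch_levels))
                    tb = int(rng.choice(config.timbre_levels))
                    tf = int(rng.choice(config.timbre_levels))
                    q, t0 = None, None
                else:
                    loud, pitch, tb, tf, q = next(conds)
                    loud, pitch, tb, tf, q = (float(loud), float(pitch),
                                              int(tb), int(tf), int(q))
                    lo = (q - 1) / 4 * config.trial_duration
                    t0 = float(lo + rng.uniform(0, config.trial_duration / 4))
                records.append(TrialRecord(
                    trial_id=tid, subject_id=subj, session_id=sess,
                    is_control=is_ctrl[k], loudness=loud, pitch=pitch,
                    timbre_bg=tb, timbre_fg=tf, quadrant=q, t0=t0,
                    duration=config.trial_duration))
                tid += 1
    return records


def generate_trial_features(config: SyntheticConfig,
                            truth: GroundTruth | None = None,
                            rng: np.random.Generator | None = None):
    """Generate trial records and their 10 Hz feature streams.

    Background channels are stationary Gaussian within a trial, with
    per-trial means drawn from a subject-level prior (so trials share a
    subject's acoustic context).  Because the background is a stream of
    overlapping tokens that drive every acoustic dimension at once, channel
    noise shares a common per-frame component
    (``truth.noise_channel_corr``).  Deviant trials add the condition's
    mean shift over [t0, t0 + token_duration], clipped at the trial end.
    Deterministic under ``config.seed`` when no generator is supplied.
    """
    truth = truth or GroundTruth()
    rng = rng or np.random.default_rng(config.seed)
    records = _make_records(config, rng)
    n_frames = int(round(config.trial_duration * config.feature_rate))
    time = (np.arange(n_frames) + 0.5) / config.feature_rate
    subj_mu = {s: rng.normal(0.0, 1.0, len(FEATURE_ORDER))
               for s in range(config.n_subjects)}
    feature_sets = []
    rho = truth.noise_channel_corr
    for r in records:
        mu = subj_mu[r.subject_id] + rng.normal(0.0, 0.3, len(FEATURE_ORDER))
        common = rng.normal(0.0, 1.0, (n_frames, 1))
        idio = rng.normal(0.0, 1.0, (n_frames, len(FEATURE_ORDER)))
        x = mu[None, :] + truth.noise_sd * (np.sqrt(rho) * common
                                            + np.sqrt(1.0 - rho) * idio)
        if not r.is_control:
            win = (time >= r.t0) & (time < r.t0 + config.token_duration)
            x[win] += condition_shifts(r, truth)[None, :]
        feature_sets.append(FeatureSet(
            time=time,
            channels={n: x[:, i] for i, n in enumerate(FEATURE_ORDER)}))
    return records, feature_sets


# -- audio path --------------------------------------------------------------

_PENTATONIC = np.array([0, 2, 4, 7, 9])


def _harmonic_token(f0: float, dur: float, fs: int, amp: float,
                    bright: bool, rng: np.random.Generator) -> np.ndarray:
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    tone = np.zeros(n)
    for k in range(1, 7):
        w = (1.0 / k) if not bright else (1.0 if k % 2 else 0.15)
        tone += w * np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
    return amp * tone * np.hanning(n)


def synthesize_audio_trial(record: TrialRecord, config: SyntheticConfig,
                           rng: np.random.Generator | None = None) -> Waveform:
    """Render a trial as a 16 kHz scene of overlapping harmonic tokens.

    Background tokens are drawn from a pentatonic pitch set around 220 Hz;
    the deviant token is raised by the condition's dB / semitone amounts
    and, when the foreground timbre differs, given a brighter
    (odd-harmonic) spectral envelope.  Control trials contain background
    only.
    """
    rng = rng or np.random.default_rng(config.seed + record.trial_id)
    fs = config.sample_rate_audio
    if config.experiment == "nature":
        token_dur = float(rng.uniform(1.3, 1.5))
    else:
        token_dur = config.token_duration
    if record.t0 is not None and record.t0 + token_dur > record.duration:
        raise ValueError("deviant token would exceed the trial duration")
    n = int(round(record.duration * fs))
    x = np.zeros(n)
    hop = 0.6 * token_dur
    onset = 0.0
    while onset < record.duration:
        f0 = 220.0 * 2.0 ** (rng.choice(_PENTATONIC) / 12.0)
        tok = _harmonic_token(f0, min(token_dur, record.duration - onset),
                              fs, 0.25, bright=False, rng=rng)
        i0 = int(round(onset * fs))
        x[i0:i0 + tok.size] += tok
        onset += hop
    if record.t0 is not None:
        f0 = 220.0 * 2.0 ** ((rng.choice(_PENTATONIC) + record.pitch) / 12.0)
        amp = 0.25 * 10.0 ** (record.loudness / 20.0)
        tok = _harmonic_token(f0, token_dur, fs, amp,
                              bright=record.timbre_different, rng=rng)
        i0 = int(round(record.t0 * fs))
        x[i0:i0 + tok.size] += tok
    return Waveform(x, fs)


# -- behavioral forward model ------------------------------------------------

def forward_alphas(records, feature_sets, truth: GroundTruth,
                   config: SyntheticConfig,
                   drex_params: DrexParams | None = None):
    """Run the surprisal + integration forward model with the true weights.

    Returns ``(alphas, sparsified)``: per-trial combined deviance
    probability alpha(t) under ``truth.weight_matrix_true`` (per-quadrant
    matrices when configured), and the pooled normalised-sparsified
    surprisal arrays, reusable for training.
    """
    icfg = config.integration_config()
    surp = compute_surprisal_sets(feature_sets, drex_params)
    sparse_sets = normalize_and_sparsify(surp, icfg)
    sparsified = [s.stack(FEATURE_ORDER) for s in sparse_sets]
    alphas = [combined_alpha(boost_surprisal(s, truth.weight_for_trial(r), icfg))
              for r, s in zip(records, sparsified)]
    return alphas, sparsified


def simulate_behavioral_responses(records, feature_sets, truth: GroundTruth,
                                  config: SyntheticConfig,
                                  drex_params: DrexParams | None = None,
                                  rng: np.random.Generator | None = None,
                                  alphas=None, sparsified=None):
    """Draw detection responses from the forward model.

    Detection probability is the trial's maximum alpha(t), mixed with a
    lapse process (probability ``behavioral_lapse_rate`` of a fair guess).
    Detected deviants get a keypress shortly after the deviant; false
    alarms a keypress shortly after the sound.  Returns
    ``(responses, rts, alphas, sparsified)``.
    """
    if len(records) != len(feature_sets or alphas):
        raise ValueError("one feature set per trial required")
    rng = rng or np.random.default_rng(config.seed + 1)
    if alphas is None or sparsified is None:
        alphas, sparsified = forward_alphas(records, feature_sets, truth,
                                            config, drex_params)
    lapse = truth.behavioral_lapse_rate
    responses, rts = [], []
    for r, a in zip(records, alphas):
        p = (1.0 - lapse) * float(np.max(a)) + lapse * 0.5
        hit = bool(rng.random() < p)
        responses.append(hit)
        if not hit:
            rts.append(np.nan)
        elif r.t0 is not None:
            rts.append(r.t0 + 1.0)  # fixed motor latency after the deviant
        else:
            rts.append(r.duration + 0.5)
    return np.array(responses), np.array(rts), alphas, sparsified


# -- pupil -------------------------------------------------------------------

def _gamma_kernel(truth: GroundTruth, fs: int, dur_s: float = 4.0) -> np.ndarray:
    from scipy.stats import gamma as gamma_dist

    t = np.arange(int(dur_s * fs)) / fs
    k = gamma_dist.pdf(t, truth.pupil_kernel_shape,
                       scale=truth.pupil_kernel_scale)
    return k / k.max()


def simulate_pupil_session(records, truth: GroundTruth,
                           config: SyntheticConfig,
                           rng: np.random.Generator | None = None,
                           fs: int = 1000):
    """One continuous pupil recording covering the given trials.

    Layout per trial: 1 s pre-stimulus + trial + 2 s post + 2 s gap (a 5 s
    inter-trial interval).  The trace is baseline drift plus, on deviant
    trials, a gamma-kernel response at the deviant onset scaled by the
    summed feature gains, plus Gaussian noise.  Blink gaps (2-10 per
    trial, 50-400 ms) zero the diameter and set the blink flag; gaze
    jitters around fixation with occasional >2 degree excursions.
    Returns ``(PupilTrace, onsets_ms)``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    dur = config.trial_duration
    slot = int(round((1.0 + dur + 2.0 + 2.0) * fs))
    n = slot * len(records)
    t = np.arange(n) / fs
    drift = 0.3 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    pupil = 5.0 + drift + rng.normal(0.0, truth.pupil_noise_sd, n)
    kernel = _gamma_kernel(truth, fs)
    onsets_ms = []
    blink = np.zeros(n, dtype=bool)
    gaze_x = rng.normal(0.0, 0.4, n)
    gaze_y = rng.normal(0.0, 0.4, n)
    for i, r in enumerate(records):
        sound_on = i * slot + int(1.0 * fs)
        onsets_ms.append(sound_on)
        if r.t0 is not None:
            amp = float(truth.pupil_feature_gains
                        @ (condition_shifts(r, truth) / truth.noise_sd))
            i0 = sound_on + int(round(r.t0 * fs))
            seg = min(kernel.size, n - i0)
            pupil[i0:i0 + seg] += amp * kernel[:seg]
        for _ in range(int(rng.integers(2, 11))):
            b0 = i * slot + int(rng.uniform(0, slot - 400))
            blink[b0:b0 + int(rng.uniform(50, 400))] = True
        if rng.random() < 0.1:  # brief off-fixation excursion
            g0 = i * slot + int(rng.uniform(0, slot - 200))
            gaze_x[g0:g0 + 200] += 3.0
    pupil[blink] = 0.0
    from .pupil import PupilTrace

    trace = PupilTrace(time_ms=np.arange(n, dtype=float), pupil=pupil,
                       gaze_x_deg=gaze_x, gaze_y_deg=gaze_y, blink=blink,
                       session_id=records[0].session_id if records else 0)
    return trace, np.asarray(onsets_ms, dtype=float)


def simulate_pupil_traces(records, truth: GroundTruth, config: SyntheticConfig,
                          rng: np.random.Generator | None = None,
                          fs: int = 1000):
    """Per-trial pupil traces (1 s pre-stimulus included), via the session."""
    session, onsets = simulate_pupil_session(records, truth, config, rng, fs)
    dur = config.trial_duration
    slot = int(round((1.0 + dur + 2.0 + 2.0) * fs))
    n_epoch = int(round((1.0 + dur + 2.0) * fs))
    from .pupil import PupilTrace

    out = []
    for i, r in enumerate(records):
        s = i * slot
        sl = slice(s, s + n_epoch)
        out.append(PupilTrace(
            time_ms=np.arange(-int(1.0 * fs), n_epoch - int(1.0 * fs),
                              dtype=float),
            pupil=session.pupil[sl], gaze_x_deg=session.gaze_x_deg[sl],
            gaze_y_deg=session.gaze_y_deg[sl], blink=session.blink[sl],
            session_id=r.session_id, trial_id=r.trial_id))
    return out
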