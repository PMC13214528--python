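"""Bayesian online regularity tracking (D-REX style) and per-feature surprisal.

The model treats each acoustic feature channel as a sequence of observations
drawn from a Gaussian whose mean and variance may change abruptly at unknown
times.  It maintains a posterior over *contexts* -- run lengths since the
last statistical change -- under a constant hazard rate ``H`` (the per-step
prior probability of a change).  Each context carries conjugate
normal--inverse-gamma sufficient statistics, so its posterior-predictive
distribution is a Student-t.  The surprisal of an observation is

    S(t) = -log2  sum_c  b_{t-1}(c) * p_c(x_t)

the negative log of the belief-weighted predictive density, in bits.  After
scoring ``x_t`` the beliefs are propagated: each context grows by one with
probability ``1 - H`` and a fresh (run-length zero, prior statistics)
context is spawned with probability ``H``.

Only first-order temporal dependence (``D = 1``) is implemented: the
predictive for ``x_t`` depends on past samples solely through the sufficient
statistics of each hypothesised context.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "DrexParams",
    "ContextBeliefs",
    "SurprisalSet",
    "prior_from_first_quadrant",
    "predictive_log_density",
    "run_drex",
    "compute_surprisal_set",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class DrexParams:
    """Parameters of the run-length filter.

    ``mu0, kappa0, a0, b0`` are the normal--inverse-gamma prior: mean
    ``mu0`` with pseudo-count ``kappa0`` and variance with shape ``a0`` /
    rate ``b0`` (so the prior predictive is a Student-t with ``2*a0``
    degrees of freedom).  ``hazard`` is the per-step change probability.
    """

    hazard: float = 0.5
    temporal_dependence: int = 1
    mu0: float = 0.0
    kappa0: float = 1.0
    a0: float = 1.0
    b0: float = 1.0
    max_contexts: int = 50
    belief_floor: float = 1e-6
    variance_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.hazard < 1.0:
            raise ValueError("hazard must lie strictly inside (0, 1)")
        if self.temporal_dependence != 1:
            raise NotImplementedError("only temporal dependence D=1 is implemented")
        if min(self.kappa0, self.a0, self.b0) <= 0:
            raise ValueError("kappa0, a0 and b0 must be positive")
        if self.max_contexts < 2:
            raise ValueError("max_contexts must be at least 2")


@dataclass
class ContextBeliefs:
    """Run-length hypotheses with beliefs and per-context sufficient stats.

    ``n``, ``mean`` and ``m2`` (sum of squared deviations) describe the
    observations attributed to each context; run length 0 carries the bare
    prior.  Beliefs are kept normalised to 1.
    """

    run_lengths: np.ndarray
    log_beliefs: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    m2: np.ndarray

    @property
    def beliefs(self) -> np.ndarray:
        return np.exp(self.log_beliefs)

    @classmethod
    def initial(cls) -> "ContextBeliefs":
        z = np.zeros(1)
        return cls(run_lengths=np.zeros(1, dtype=int), log_beliefs=z.copy(),
                   n=z.copy(), mean=z.copy(), m2=z.copy())


def prior_from_first_quadrant(series: np.ndarray, params: DrexParams | None = None,
                              n_quadrants: int = 4) -> DrexParams:
    """Set the data-driven part of the prior from the trial's first quadrant.

    ``mu0`` is the mean of the first quarter of the frames and ``b0`` is set
    from their variance (``b0 = a0 * var``), so the prior predictive scale
    tracks the local signal statistics.  A variance floor guards constant
    segments.
    """
    params = params or DrexParams()
    series = np.asarray(series, dtype=float)
    n_first = max(2, series.size // n_quadrants)
    if series.size < 2:
        raise ValueError("need at least two frames to initialize the prior")
    seg = series[:n_first]
    var = max(float(np.var(seg)), params.variance_floor)
    return replace(params, mu0=float(np.mean(seg)), b0=params.a0 * var)


def _posterior_params(beliefs: ContextBeliefs, p: DrexParams):
    """Conjugate NIG posterior parameters for every context."""
    n, mean, m2 = beliefs.n, beliefs.mean, beliefs.m2
    kappa = p.kappa0 + n
    mu = (p.kappa0 * p.mu0 + n * mean) / kappa
    a = p.a0 + 0.5 * n
    b = p.b0 + 0.5 * m2 + 0.5 * p.kappa0 * n * (mean - p.mu0) ** 2 / kappa
    return mu, kappa, a, b


def _student_t_logpdf(x: float, df: np.ndarray, loc: np.ndarray,
                      scale2: np.ndarray) -> np.ndarray:
    z2 = (x - loc) ** 2 / scale2
    return (gammaln((df + 1) / 2) - gammaln(df / 2)
            - 0.5 * np.log(df * np.pi * scale2)
            - (df + 1) / 2 * np.log1p(z2 / df))


def predictive_log_density(beliefs: ContextBeliefs, params: DrexParams,
                           x: float) -> np.ndarray:
    """log2 posterior-predictive (Student-t) density at ``x``, per context."""
    if not np.isfinite(x):
        raise ValueError("observation must be finite")
    mu, kappa, a, b = _posterior_params(beliefs, params)
    scale2 = b * (kappa + 1.0) / (a * kappa)
    return _student_t_logpdf(float(x), 2.0 * a, mu, scale2) / _LN2


def run_drex(series: np.ndarray, params: DrexParams,
             return_trajectory: bool = False):
    """Filter one feature channel, emitting surprisal in bits per frame.

    Returns ``(surprisal, trajectory)`` where ``trajectory`` is the final
    :class:`ContextBeliefs` (or the full per-frame list when
    ``return_trajectory``).  All mixture arithmetic is done in log space;
    the output is finite for any finite input.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")

    ln_h, ln_1mh = np.log(params.hazard), np.log1p(-params.hazard)
    beliefs = ContextBeliefs.initial()
    surprisal = np.empty(series.size)
    trajectory: list[ContextBeliefs] = []

    for t, x in enumerate(series):
        lp = predictive_log_density(beliefs, params, x) * _LN2  # nats
        joint = beliefs.log_beliefs + lp
        ln_mix = logsumexp(joint)
        surprisal[t] = -ln_mix / _LN2

        # absorb x into every surviving context, then branch: grow vs reset
        n_new = beliefs.n + 1.0
        delta = x - beliefs.mean
        mean_new = beliefs.mean + delta / n_new
        m2_new = beliefs.m2 + delta * (x - mean_new)

        run_lengths = np.concatenate(([0], beliefs.run_lengths + 1))
        log_b = np.concatenate(([ln_h + ln_mix], joint + ln_1mh))
        n = np.concatenate(([0.0], n_new))
        mean = np.concatenate(([0.0], mean_new))
        m2 = np.concatenate(([0.0], m2_new))
        log_b -= logsumexp(log_b)

        # bounded memory: drop negligible-belief contexts, cap their count
        keep = log_b >= (np.log(params.belief_floor) if params.belief_floor > 0
                         else -np.inf)
        keep[0] = True  # the reset context is always viable a priori
        if keep.sum() > params.max_contexts:
            order = np.argsort(log_b)[::-1]
            cutoff = np.zeros_like(keep)
            cutoff[order[: params.max_contexts]] = True
            keep &= cutoff
        if not keep.all():
            run_lengths, log_b = run_lengths[keep], log_b[keep]
            n, mean, m2 = n[keep], mean[keep], m2[keep]
            log_b -= logsumexp(log_b)

        beliefs = ContextBeliefs(run_lengths, log_b, n, mean, m2)
        if return_trajectory:
            trajectory.append(beliefs)

    return surprisal, (trajectory if return_trajectory else beliefs)


def run_drex_batch(series: np.ndarray, params: DrexParams,
                   mu0: np.ndarray | None = None,
                   b0: np.ndarray | None = None) -> np.ndarray:
    """Vectorised filter over many independent equal-length series.

    ``series`` is ``(n_series, n_frames)``; ``mu0``/``b0`` override the
    prior per series (as :func:`prior_from_first_quadrant` would).  Returns
    the ``(n_series, n_frames)`` surprisal array, identical (to numerical
    round-off) to running :func:`run_drex` on each row.  Contexts live in
    fixed-width arrays whose slots carry their own sufficient statistics;
    pruned slots are parked at zero belief.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("series must be a non-empty 2-D array")
    B, T = X.shape
    mu0 = np.full(B, params.mu0) if mu0 is None else np.asarray(mu0, float)
    b0 = np.full(B, params.b0) if b0 is None else np.asarray(b0, float)
    ln_h, ln_1mh = np.log(params.hazard), np.log1p(-params.hazard)
    ln_floor = np.log(params.belief_floor) if params.belief_floor > 0 else -np.inf

    log_b = np.zeros((B, 1))
    n = np.zeros((B, 1))
    mean = np.zeros((B, 1))
    m2 = np.zeros((B, 1))
    out = np.empty((B, T))
    for t in range(T):
        x = X[:, [t]]
        kappa = params.kappa0 + n
        mu = (params.kappa0 * mu0[:, None] + n * mean) / kappa
        a = params.a0 + 0.5 * n
        b = (b0[:, None] + 0.5 * m2
             + 0.5 * params.kappa0 * n * (mean - mu0[:, None]) ** 2 / kappa)
        scale2 = b * (kappa + 1.0) / (a * kappa)
        lp = _student_t_logpdf(x, 2.0 * a, mu, scale2)
        joint = log_b + lp
        ln_mix = logsumexp(joint, axis=1, keepdims=True)
        out[:, t] = -ln_mix[:, 0] / _LN2

        n_new = n + 1.0
        delta = x - mean
        mean_g = mean + delta / n_new
        m2_g = m2 + delta * (x - mean_g)
        zeros = np.zeros((B, 1))
        log_b = np.hstack([ln_h + ln_mix, joint + ln_1mh])
        n = np.hstack([zeros, n_new])
        mean = np.hstack([zeros, mean_g])
        m2 = np.hstack([zeros, m2_g])
        log_b -= logsumexp(log_b, axis=1, keepdims=True)

        dead = log_b < ln_floor
        dead[:, 0] = False
        if dead.any():
            log_b = np.where(dead, -np.inf, log_b)
            log_b -= logsumexp(log_b, axis=1, keepdims=True)
        if log_b.shape[1] > params.max_contexts:
            key = log_b.copy()
            key[:, 0] = np.inf  # the reset slot always survives
            order = np.argsort(-key, axis=1, kind="stable")[:, : params.max_contexts]
            order.sort(axis=1)  # preserve run-length ordering of survivors
            log_b = np.take_along_axis(log_b, order, axis=1)
            n = np.take_along_axis(n, order, axis=1)
            mean = np.take_along_axis(mean, order, axis=1)
            m2 = np.take_along_axis(m2, order, axis=1)
            log_b -= logsumexp(log_b, axis=1, keepdims=True)
    return out


@dataclass
class SurprisalSet:
    """Per-feature surprisal channels on the 10 Hz feature grid."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    params: dict[str, DrexParams] = field(default_factory=dict)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def stack(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        order = order or self.feature_names
        return np.column_stack([self.channels[k] for k in order])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.time, **self.channels})


def compute_surprisal_set(features, params: DrexParams | None = None) -> SurprisalSet:
    """Run the filter independently on each feature channel of a trial.

    The prior of every channel is re-initialised from that channel's first
    time quadrant, so surprisal adapts to the local acoustic statistics.
    """
    params = params or DrexParams()
    channels: dict[str, np.ndarray] = {}
    used: dict[str, DrexParams] = {}
    for name, series in features.channels.items():
        try:
            p = prior_from_first_quadrant(series, params)
            s, _ = run_drex(series, p)
        except ValueError as exc:  # re-raise with channel context
            raise ValueError(f"channel {name!r}: {exc}") from exc
        channels[name] = s
        used[name] = p
    return SurprisalSet(time=np.asarray(features.time, dtype=float),
                        channels=channels, params=used)


def compute_surprisal_sets(feature_sets, params: DrexParams | None = None
                           ) -> list[SurprisalSet]:
    """Batched :func:`compute_surprisal_set` over equal-length trials.

    Stacks every (trial, channel) series through :func:`run_drex_batch`;
    falls back to the per-trial path when trial lengths differ.
    """
    params = params or DrexParams()
    lengths = {len(f.time) for f in feature_sets}
    if len(lengths) != 1:
        return [compute_surprisal_set(f, params) for f in feature_sets]
    names = list(feature_sets[0].channels)
    X = np.vstack([f.channels[name] for f in feature_sets for name in names])
    n_first = max(2, X.shape[1] // 4)
    seg = X[:, :n_first]
    mu0 = seg.mean(axis=1)
    b0 = params.a0 * np.maximum(seg.var(axis=1), params.variance_floor)
    S = run_drex_batch(X, params, mu0=mu0, b0=b0)
    out = []
    k = len(names)
    for i, f in enumerate(feature_sets):
        chans = {name: S[i * k + j] for j, name in enumerate(names)}
        pr = {name: replace(params, mu0=float(mu0[i * k + j]),
                            b0=float(b0[i * k + j])) for j, name in enumerate(names)}
        out.append(SurprisalSet(time=np.asarray(f.time, dtype=float),
                                channels=chans, params=pr))
    return out
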