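"""Cross-feature integration: boosted surprisal and constrained regression.

Raw per-feature surprisals are first min-max normalised to [0, 1] per
feature over a whole trial collection and sparsified by zeroing values
below the feature's 70th percentile.  A 6x6 nonnegative weight matrix
``W`` then couples the features:

    s'_i(t) = s_i(t) * ( w_ii + sum_{j != i} w_ij * max_{|tau| <= T} s_j(t + tau) )

with an interaction window of T = 100 ms, and each boosted surprisal maps
to a per-feature deviance probability

    alpha_i(t) = 2 / (1 + exp(-s'_i(t))) - 1        (= tanh(s'_i(t) / 2))

whose average over the six features is the model output alpha(t), the
probability of a deviant event at time t.

``W`` is learned by maximum likelihood against a binary deviance target
y(t): each feature row is fit independently (six bound-constrained
optimisations over its six nonnegative weights) under the Bernoulli
log-likelihood sum_t [ y log alpha_i + (1 - y) log(1 - alpha_i) ].

The module follows the Model/Results idiom: build a
:class:`SurprisalIntegrationModel` from sparsified surprisal trials and
their targets, call :meth:`~SurprisalIntegrationModel.fit`, and read the
weights, likelihoods and standard errors off the returned
:class:`SurprisalIntegrationResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .drex import SurprisalSet
from .features import FEATURE_ORDER

ATTRIBUTE_GROUPS: dict[str, tuple[str, ...]] = {
    "loudness": ("envelope",),
    "pitch": ("pitch", "spec_low"),
    "timbre": ("spec_high", "scale", "rate"),
}

__all__ = [
    "ATTRIBUTE_GROUPS",
    "IntegrationConfig",
    "normalize_and_sparsify",
    "boost_surprisal",
    "alpha_map",
    "reduce_weight_matrix",
    "SurprisalIntegrationModel",
    "SurprisalIntegrationResults",
]


@dataclass(frozen=True)
class IntegrationConfig:
    """Integration and target-construction parameters.

    ``delta_t`` is the deviance-labelling window: 1.2 s for the Music
    experiment (token length) and 1.4 s for Nature (tokens 1.3-1.5 s).
    """

    interaction_window: float = 0.1  # seconds, each side
    sparsify_percentile: float = 70.0
    delta_t: float = 1.2
    alpha_floor: float = 1e-9
    frame_rate: float = 10.0
    response_window: float = 2.0  # post-sound keypress window, seconds

    def __post_init__(self):
        if self.interaction_window < 0 or self.delta_t <= 0:
            raise ValueError("window lengths must be positive")
        if not 0 <= self.sparsify_percentile <= 100:
            raise ValueError("percentile must lie in [0, 100]")

    @classmethod
    def for_experiment(cls, experiment: str, **kw) -> "IntegrationConfig":
        dt = {"music": 1.2, "nature": 1.4}[experiment]
        return cls(delta_t=dt, **kw)

    @property
    def window_frames(self) -> int:
        return int(round(self.interaction_window * self.frame_rate))


def normalize_and_sparsify(surprisals: list[SurprisalSet],
                           config: IntegrationConfig) -> list[SurprisalSet]:
    """Pooled per-feature min-max scaling, then percentile thresholding.

    Minimum, maximum and the sparsification percentile are computed per
    feature over *all* trials jointly, so a single trial keeps its rank
    relative to the collection.
    """
    if not surprisals:
        raise ValueError("empty trial collection")
    names = surprisals[0].feature_names
    out = [SurprisalSet(time=s.time, channels={}, params=s.params)
           for s in surprisals]
    for name in names:
        pooled = np.concatenate([s.channels[name] for s in surprisals])
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:
            raise ValueError(f"feature {name!r} is constant across the "
                             "collection; min-max scaling undefined")
        cut = np.percentile((pooled - lo) / (hi - lo), config.sparsify_percentile)
        for s, o in zip(surprisals, out):
            z = (s.channels[name] - lo) / (hi - lo)
            o.channels[name] = np.where(z < cut, 0.0, z)
    return out


def _windowed_max(s: np.ndarray, half_width: int) -> np.ndarray:
    """Per-column running max over +-half_width frames, clipped at edges."""
    if half_width == 0:
        return s
    return ndimage.maximum_filter1d(s, size=2 * half_width + 1, axis=0,
                                    mode="nearest")


def boost_surprisal(s: np.ndarray, W: np.ndarray,
                    config: IntegrationConfig) -> np.ndarray:
    """Apply the cross-feature boost to a (frames, features) surprisal array."""
    s = np.asarray(s, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != (s.shape[1], s.shape[1]):
        raise ValueError(f"weight matrix {W.shape} does not match "
                         f"{s.shape[1]} channels")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    m = _windowed_max(s, config.window_frames)
    cross = W.copy()
    np.fill_diagonal(cross, 0.0)
    return s * (np.diag(W)[None, :] + m @ cross.T)


def alpha_map(s_boosted: np.ndarray) -> np.ndarray:
    """Per-feature deviance probability alpha_i = 2 sigma(s') - 1 = tanh(s'/2)."""
    return np.tanh(np.asarray(s_boosted, dtype=float) / 2.0)


def combined_alpha(s_boosted: np.ndarray) -> np.ndarray:
    """alpha(t): average of the per-feature probabilities."""
    return alpha_map(s_boosted).mean(axis=1)


def reduce_weight_matrix(W: np.ndarray,
                         feature_order=FEATURE_ORDER) -> np.ndarray:
    """Collapse the 6x6 matrix to 3x3 perceptual attributes by block means.

    Attribute order: loudness, pitch, timbre.  Diagonal blocks average all
    their entries, including within-group off-diagonals.
    """
    idx = {name: i for i, name in enumerate(feature_order)}
    groups = [np.array([idx[f] for f in ATTRIBUTE_GROUPS[a]])
              for a in ("loudness", "pitch", "timbre")]
    R = np.empty((3, 3))
    for a, ga in enumerate(groups):
        for b, gb in enumerate(groups):
            R[a, b] = W[np.ix_(ga, gb)].mean()
    return R


def _row_design(trials: list[np.ndarray], row: int,
                config: IntegrationConfig) -> np.ndarray:
    """Stack per-frame regressors for one feature row across trials.

    Column ``row`` multiplies w_ii (coefficient s_i(t)); column j != row
    multiplies w_ij (coefficient s_i(t) * windowed-max of s_j).
    """
    blocks = []
    for s in trials:
        m = _windowed_max(s, config.window_frames)
        X = s[:, [row]] * m
        X[:, row] = s[:, row]
        blocks.append(X)
    return np.vstack(blocks)


def _neg_loglike_and_grad(w, X, y, floor):
    sp = X @ w
    a = np.tanh(sp / 2.0)
    a = np.clip(a, floor, 1.0 - floor)
    ll = y @ np.log(a) + (1.0 - y) @ np.log1p(-a)
    # d ll / d s' = [y/a - (1-y)/(1-a)] * (1 - a^2)/2
    dl_ds = (y / a - (1.0 - y) / (1.0 - a)) * (1.0 - a * a) / 2.0
    return -ll, -(X.T @ dl_ds)


class SurprisalIntegrationModel:
    """Nonnegative cross-feature weight model of deviance detection.

    Parameters
    ----------
    surprisals
        One ``(frames, 6)`` array per trial of *normalised, sparsified*
        surprisal (see :func:`normalize_and_sparsify`).
    targets
        One binary array per trial, same frame count, marking the deviance
        window (1 inside [t0, t0 + delta_t), else 0).
    config
        Integration parameters; defaults follow the Music experiment.
    """

    def __init__(self, surprisals: list[np.ndarray], targets: list[np.ndarray],
                 config: IntegrationConfig | None = None,
                 feature_names=FEATURE_ORDER):
        if len(surprisals) != len(targets):
            raise ValueError("one target per trial required")
        self.config = config or IntegrationConfig()
        self.feature_names = tuple(feature_names)
        self.surprisals = [np.asarray(s, dtype=float) for s in surprisals]
        self.targets = [np.asarray(y, dtype=float) for y in targets]
        for s, y in zip(self.surprisals, self.targets):
            if s.shape != (y.size, len(self.feature_names)):
                raise ValueError("surprisal/target shape mismatch")
        y_all = np.concatenate(self.targets)
        self._n_pos = int(y_all.sum())
        self._n_frames = y_all.size

    @classmethod
    def from_trials(cls, surprisal_sets: list[SurprisalSet],
                    target_signals, config=None) -> "SurprisalIntegrationModel":
        """Build from sparsified :class:`SurprisalSet` objects and targets."""
        s = [ss.stack(FEATURE_ORDER) for ss in surprisal_sets]
        y = [np.asarray(t.y, dtype=float) if hasattr(t, "y") else
             np.asarray(t, dtype=float) for t in target_signals]
        return cls(s, y, config)

    def fit(self, maxiter: int = 500, tol: float = 1e-6,
            start: np.ndarray | None = None) -> "SurprisalIntegrationResults":
        """Six independent bound-constrained (w >= 0) ML fits, one per row.

        Starts from the uniform model (w_ii = 1, w_ij = 0) unless ``start``
        is given.  Degenerate targets (no positive frames) are legal; the
        likelihood then drives the row toward zero and the result is
        flagged.
        """
        k = len(self.feature_names)
        W = np.zeros((k, k))
        loglike = np.zeros(k)
        converged = np.zeros(k, dtype=bool)
        bse = np.full((k, k), np.nan)
        y = np.concatenate(self.targets)
        for i in range(k):
            X = _row_design(self.surprisals, i, self.config)
            w0 = np.eye(k)[i] if start is None else np.asarray(start[i], float)
            res = optimize.minimize(
                _neg_loglike_and_grad, w0, args=(X, y, self.config.alpha_floor),
                jac=True, method="L-BFGS-B", bounds=[(0.0, None)] * k,
                options={"maxiter": maxiter, "ftol": tol})
            W[i] = res.x
            loglike[i] = -res.fun
            converged[i] = bool(res.success)
            bse[i] = self._row_bse(res.x, X, y)
        return SurprisalIntegrationResults(self, W, loglike, converged, bse)

    def _row_bse(self, w, X, y, eps: float = 1e-5) -> np.ndarray:
        """SEs from the observed information (central-difference Hessian).

        Entries at the nonnegativity boundary have one-sided curvature only;
        their SEs are nominal.
        """
        k = w.size
        H = np.zeros((k, k))
        floor = self.config.alpha_floor
        for j in range(k):
            hi, lo = w.copy(), w.copy()
            hi[j] = w[j] + eps
            lo[j] = max(w[j] - eps, 0.0)  # forward difference at the bound
            _, g_hi = _neg_loglike_and_grad(hi, X, y, floor)
            _, g_lo = _neg_loglike_and_grad(lo, X, y, floor)
            H[j] = (g_hi - g_lo) / (hi[j] - lo[j])
        H = (H + H.T) / 2.0
        try:
            cov = np.linalg.pinv(H)
            var = np.diag(cov)
            return np.where(var > 0, np.sqrt(var), np.nan)
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)


@dataclass
class SurprisalIntegrationResults:
    """Fitted weights with likelihoods, convergence flags and SEs."""

    model: SurprisalIntegrationModel
    weights: np.ndarray  # (6, 6); row i = weights of feature i's boost
    loglike: np.ndarray  # per feature row
    converged: np.ndarray
    bse: np.ndarray
    extra: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return self.weights

    def predict(self, surprisals: list[np.ndarray] | np.ndarray):
        """Combined alpha(t) per trial under the fitted weights."""
        single = isinstance(surprisals, np.ndarray)
        trials = [surprisals] if single else surprisals
        alphas = [combined_alpha(boost_surprisal(s, self.weights,
                                                 self.model.config))
                  for s in trials]
        return alphas[0] if single else alphas

    def reduced_weights(self) -> np.ndarray:
        return reduce_weight_matrix(self.weights, self.model.feature_names)

    @property
    def degenerate(self) -> np.ndarray:
        """Rows whose fitted weights collapsed to ~0 (all-negative targets)."""
        return self.weights.max(axis=1) < 1e-8

    def summary(self) -> str:
        names = self.model.feature_names
        lines = ["Surprisal integration model (nonnegative weights)",
                 f"  trials: {len(self.model.surprisals)}   frames: "
                 f"{self.model._n_frames}   positive frames: {self.model._n_pos}",
                 f"  total log-likelihood: {self.loglike.sum():.3f}", ""]
        hdr = "row (i)    " + "".join(f"{n:>10}" for n in names)
        lines += [hdr, "-" * len(hdr)]
        for i, name in enumerate(names):
            w = "".join(f"{v:10.4f}" for v in self.weights[i])
            flag = "" if self.converged[i] else "  [not converged]"
            lines.append(f"{name:<11}{w}{flag}")
        lines += ["", "reduced (loudness, pitch, timbre):"]
        for row in self.reduced_weights():
            lines.append("  " + "".join(f"{v:10.4f}" for v in row))
        return "\n".join(lines)

    def plot_weights(self, ax=None, reduced: bool = False):
        """Heatmap of the fitted weight matrix (or its 3x3 reduction)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3.5))
        if reduced:
            M, labels = self.reduced_weights(), ("loudness", "pitch", "timbre")
        else:
            M, labels = self.weights, self.model.feature_names
        im = ax.imshow(M, cmap="viridis")
        ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
        ax.set_yticks(range(len(labels)), labels)
        ax.set_xlabel("boosting feature j")
        ax.set_ylabel("boosted feature i")
        ax.figure.colorbar(im, ax=ax, label="weight")
        return ax

    def to_json(self, path, config_note: str = "") -> None:
        payload = {
            "feature_order": list(self.model.feature_names),
            "weights": self.weights.tolist(),
            "loglike": self.loglike.tolist(),
            "converged": self.converged.tolist(),
            "config": {"interaction_window": self.model.config.interaction_window,
                       "sparsify_percentile": self.model.config.sparsify_percentile,
                       "delta_t": self.model.config.delta_t},
            "note": config_note,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
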