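"""Discrete-time survival primitives.

The follow-up horizon is divided into three left-inclusive bins,
[0, 24), [24, 48) and [48, 108) months. A model predicts a conditional
progression probability (hazard) h_j per bin; the probability of surviving
through bin j is prod_{i<=j} (1 - h_i), and the likelihood of progressing in
bin j is h_j * prod_{i<j} (1 - h_i).

Each subject's outcome is encoded into per-bin survival-credit indicators
s_j and event indicators e_j. A subject with an event in bin j contributes
ln h_j in bin j and ln(1 - h_i) for every earlier bin; a censored subject
contributes ln(1 - h_j) for every bin whose midpoint the censoring time
reaches (half-interval credit). The training objective is the negative of
that log-likelihood, summed over bins and subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # hazard clipping before logs


@dataclass(frozen=True)
class TimeBins:
    """Left-inclusive time intervals over the follow-up horizon (months)."""

    edges: tuple = (0.0, 24.0, 48.0, 108.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or (np.diff(e) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges, dtype=float))

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges, dtype=float)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def horizon(self) -> float:
        return float(self.edges[-1])


DEFAULT_BINS = TimeBins()


def discretize_outcome(
    times, events, bins: TimeBins = DEFAULT_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Encode outcomes into (survival-credit s, event e) indicator arrays.

    Event at t in bin j: s_i = 1 for i < j, s_j = 0, e_j = 1. Censored at c:
    s_j = 1 for every bin whose midpoint <= c, e = 0 (half-interval credit).
    Events at or beyond the horizon are treated as censored at the horizon.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    events = np.atleast_1d(np.asarray(events, dtype=bool))
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    n, k = len(times), bins.n_bins
    s = np.zeros((n, k), dtype=float)
    e = np.zeros((n, k), dtype=float)
    edges = np.asarray(bins.edges, dtype=float)
    mids = bins.midpoints
    ev = events & (times < bins.horizon)
    cens_time = np.where(ev, times, np.minimum(times, bins.horizon))
    for j in range(k):
        in_bin = ev & (times >= edges[j]) & (times < edges[j + 1])
        e[in_bin, j] = 1.0
        s[ev & (times >= edges[j + 1]), j] = 1.0  # survived past bin j before event
        s[~ev & (mids[j] <= cens_time), j] = 1.0
    return s, e


def survival_loss(
    hazards: np.ndarray, s: np.ndarray, e: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> float:
    """Negative discrete-time survival log-likelihood (sum over subjects).

    -sum_j [ sum_{events in j} ln h_j + sum_{survivors of j} ln(1 - h_j) ],
    where a subject is a survivor of bin j iff s_j = 1. Hazards are clipped
    to [EPS, 1 - EPS] before taking logs.
    """
    h = np.asarray(hazards, dtype=float)
    if h.shape != np.shape(s) or h.shape != np.shape(e):
        raise ValueError("hazards and encodings must share a shape")
    h = np.clip(h, EPS, 1.0 - EPS)
    ll = e * np.log(h) + s * np.log1p(-h)
    if sample_weight is not None:
        ll = ll * np.asarray(sample_weight, dtype=float)[:, None]
    return float(-ll.sum())


def survival_loss_grad(
    hazards: np.ndarray, s: np.ndarray, e: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of :func:`survival_loss` with respect to the hazards."""
    h = np.clip(np.asarray(hazards, dtype=float), EPS, 1.0 - EPS)
    grad = -e / h + s / (1.0 - h)
    if sample_weight is not None:
        grad = grad * np.asarray(sample_weight, dtype=float)[:, None]
    return grad


def hazards_to_survival(
    hazards: np.ndarray, bins: TimeBins = DEFAULT_BINS,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Monthly survival curves from per-bin hazards.

    S at bin end j is prod_{i<=j} (1 - h_i); inside bin j the curve follows
    constant-hazard (geometric) interpolation,
    S(t) = S(t_{j-1}) * (1 - h_j)^{(t - t_{j-1}) / w_j}. S(0) = 1 and the
    curve is non-increasing.
    """
    h = np.atleast_2d(np.asarray(hazards, dtype=float))
    if (h < 0).any() or (h > 1).any():
        raise ValueError("hazards must lie in [0, 1]")
    if grid is None:
        grid = np.arange(0.0, bins.horizon + 1.0)
    edges = np.asarray(bins.edges, dtype=float)
    widths = bins.widths
    s_ends = np.cumprod(1.0 - h, axis=1)
    s_starts = np.concatenate([np.ones((h.shape[0], 1)), s_ends[:, :-1]], axis=1)
    out = np.empty((h.shape[0], len(grid)))
    for i, t in enumerate(grid):
        t = min(float(t), bins.horizon)
        j = int(np.clip(np.searchsorted(edges, t, side="right") - 1, 0, bins.n_bins - 1))
        frac = (t - edges[j]) / widths[j]
        base = 1.0 - h[:, j]
        with np.errstate(divide="ignore"):
            out[:, i] = s_starts[:, j] * np.where(
                base > 0.0, base**frac, np.where(frac == 0.0, 1.0, 0.0)
            )
    return out if np.asarray(hazards).ndim == 2 else out[0]


def event_bin_likelihood(hazards: np.ndarray) -> np.ndarray:
    """Likelihood of progressing in each bin: h_j * prod_{i<j} (1 - h_i)."""
    h = np.atleast_2d(np.asarray(hazards, dtype=float))
    surv = np.cumprod(1.0 - h, axis=1)
    prev = np.concatenate([np.ones((h.shape[0], 1)), surv[:, :-1]], axis=1)
    out = h * prev
    return out if np.asarray(hazards).ndim == 2 else out[0]


def inverse_propensity_weights(s: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Per-subject weights 1 / (frequency of the subject's encoded pattern)."""
    patterns = np.concatenate([s, e], axis=1)
    _, inverse, counts = np.unique(
        patterns, axis=0, return_inverse=True, return_counts=True
    )
    freq = counts[inverse] / len(s)
    w = 1.0 / freq
    return w / w.mean()
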