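"""Censoring-aware model evaluation.

Implements the concordance index at fixed horizons, the inverse probability
of censoring weighted (IPCW) Brier score and its trapezoidal integral over
the three bin ends, truncation of predictions to the training follow-up
range with shape-preserving (PCHIP) interpolation, and bootstrap bands
around mean predicted curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .classical import kaplan_meier

logger = logging.getLogger(__name__)

MONTH_GRID = np.arange(0.0, 109.0)
EVAL_TIMES = (24.0, 48.0, 108.0)


def concordance_index(times, events, risk) -> float:
    """Censored concordance index.

    Comparable pairs are (i, j) with an observed event for i and
    t_i < t_j; a pair is concordant when risk_i > risk_j; risk ties count
    one half. Raises when no pair is comparable.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    risk = np.asarray(risk, dtype=float)
    concordant = 0.0
    comparable = 0
    for i in np.flatnonzero(events):
        later = times > times[i]
        comparable += int(later.sum())
        concordant += float((risk[later] < risk[i]).sum())
        concordant += 0.5 * float((risk[later] == risk[i]).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable


@dataclass(frozen=True)
class CensoringDistribution:
    """Kaplan-Meier estimate G(t) of the censoring survival function."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t, left: bool = False) -> np.ndarray:
        """G(t); ``left=True`` evaluates the left limit G(t-)."""
        t = np.asarray(t, dtype=float)
        side = "left" if left else "right"
        idx = np.searchsorted(self.times, t, side=side) - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)


def censoring_survival(times, events) -> CensoringDistribution:
    """Product-limit estimate of the censoring distribution.

    The censoring indicator is the flipped event indicator; at tied times
    events are taken to precede censorings, so subjects with an event at t
    leave the at-risk set before the censoring hazard at t is formed.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    uniq = np.unique(times)
    surv = []
    g = 1.0
    n = len(times)
    for u in uniq:
        here = times == u
        d_event = int((events & here).sum())
        c_cens = int((~events & here).sum())
        at_risk = n - d_event  # events at u occur first
        if c_cens > 0 and at_risk > 0:
            g *= 1.0 - c_cens / at_risk
        n -= int(here.sum())
        surv.append(g)
    return CensoringDistribution(times=uniq, survival=np.array(surv))


def brier_score(
    times, events, curves: np.ndarray, t: float,
    g: CensoringDistribution, grid: np.ndarray = MONTH_GRID,
) -> float:
    """IPCW Brier score at horizon ``t``.

    BS(t) = n^-1 sum_i [ 1{t_i <= t, event} * S_i(t)^2 / G(t_i-)
                        + 1{t_i > t} * (1 - S_i(t))^2 / G(t) ].
    Subjects needing a zero-valued weight are excluded (and logged).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    col = int(np.searchsorted(np.asarray(grid, dtype=float), t))
    if col >= len(grid) or grid[col] != t:
        raise ValueError(f"horizon {t} not on the prediction grid")
    s_hat = np.asarray(curves, dtype=float)[:, col]
    n = len(times)
    total = 0.0
    dropped = 0
    g_t = float(g.at(t))
    for i in range(n):
        if events[i] and times[i] <= t:
            w = float(g.at(times[i], left=True))
            if w <= 0.0:
                dropped += 1
                continue
            total += s_hat[i] ** 2 / w
        elif times[i] > t:
            if g_t <= 0.0:
                dropped += 1
                continue
            total += (1.0 - s_hat[i]) ** 2 / g_t
        # censored at or before t: contributes 0
    if dropped:
        logger.info("brier_score: excluded %d subjects with zero IPCW weight", dropped)
    return total / n


def integrated_brier_score(
    times, events, curves: np.ndarray, g: CensoringDistribution,
    eval_times=EVAL_TIMES, grid: np.ndarray = MONTH_GRID,
) -> float:
    """Trapezoidal integral of BS(t) over the evaluation times, normalized
    by the spanned range."""
    ts = np.sort(np.asarray(eval_times, dtype=float))
    if len(ts) < 2:
        raise ValueError("need at least two evaluation times")
    bs = np.array([brier_score(times, events, curves, t, g, grid) for t in ts])
    return float(np.trapezoid(bs, ts) / (ts[-1] - ts[0]))


def truncate_and_interpolate(
    curves: np.ndarray, train_max_time: float, grid: np.ndarray = MONTH_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Clip predictions to the training follow-up range.

    Grid points beyond the training maximum are replaced by the survival
    value at the boundary, obtained by shape-preserving cubic (PCHIP)
    interpolation of each curve; monotonicity is preserved. Returns the
    adjusted curves and the clipped grid.
    """
    grid = np.asarray(grid, dtype=float)
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if train_max_time <= grid[0]:
        raise ValueError("training follow-up range is empty")
    if train_max_time >= grid[-1]:
        return curves.copy(), grid.copy()
    out = curves.copy()
    beyond = grid > train_max_time
    for i in range(len(out)):
        boundary = float(PchipInterpolator(grid, curves[i])(train_max_time))
        out[i, beyond] = boundary
    clipped = np.minimum(grid, train_max_time)
    return out, clipped


def adjust_eval_times(eval_times, train_max_time: float) -> np.ndarray:
    """Evaluation horizons clipped to the training follow-up range."""
    return np.minimum(np.asarray(eval_times, dtype=float), float(train_max_time))


def bootstrap_mean_band(
    curves: np.ndarray, n_boot: int = 10_000, seed: int = 0, level: float = 0.95,
) -> dict:
    """Bootstrap the mean curve: resample subjects with replacement and take
    pointwise percentiles of the replicate means."""
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    n = len(curves)
    if n < 2:
        raise ValueError("need at least two curves")
    rng = np.random.default_rng(seed)
    means = np.empty((n_boot, curves.shape[1]))
    chunk = max(1, int(2e7 // (n * curves.shape[1])))  # bound peak memory
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        means[start:stop] = curves[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return {
        "mean": curves.mean(axis=0),
        "lower": np.percentile(means, 100 * alpha, axis=0),
        "upper": np.percentile(means, 100 * (1 - alpha), axis=0),
    }


def permutation_null_ci(
    times, events, risk, n_perm: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Mean and SE of the concordance index under permuted risk scores."""
    rng = np.random.default_rng(seed)
    risk = np.asarray(risk, dtype=float)
    vals = []
    for _ in range(n_perm):
        vals.append(concordance_index(times, events, rng.permutation(risk)))
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def evaluate_predictions(
    curves: np.ndarray,
    test_times, test_events,
    train_times, train_events,
    eval_times=EVAL_TIMES, grid: np.ndarray = MONTH_GRID,
) -> dict:
    """Full censoring-aware report for one test fold.

    Concordance per horizon (risk = 1 - S(horizon)) and its mean, IPCW
    Brier score per horizon and the integrated score, with predictions
    truncated to the training follow-up range when the test range exceeds it.
    """
    test_times = np.asarray(test_times, dtype=float)
    test_events = np.asarray(test_events, dtype=bool)
    train_max = float(np.max(train_times))
    curves_adj, _ = truncate_and_interpolate(curves, train_max, grid)
    ts = adjust_eval_times(eval_times, train_max)
    g = censoring_survival(train_times, train_events)
    report = {"n": len(test_times), "events": int(test_events.sum()),
              "censored": int((~test_events).sum())}
    cis, bss = {}, {}
    for t_orig, t in zip(eval_times, ts):
        col = int(np.searchsorted(grid, min(t, grid[-1])))
        risk = 1.0 - curves_adj[:, col]
        try:
            cis[t_orig] = concordance_index(test_times, test_events, risk)
        except ValueError:
            cis[t_orig] = float("nan")
        bss[t_orig] = brier_score(test_times, test_events, curves_adj,
                                  float(grid[col]), g, grid)
    report["ci"] = cis
    report["ci_mean"] = float(np.nanmean(list(cis.values())))
    report["brier"] = bss
    bs_vals = np.array(list(bss.values()))
    ts_arr = np.array(eval_times, dtype=float)
    report["ibs"] = float(np.trapezoid(bs_vals, ts_arr) / (ts_arr[-1] - ts_arr[0]))
    return report


def marginal_km_curves(train_times, train_events, n_subjects: int,
                       grid: np.ndarray = MONTH_GRID) -> np.ndarray:
    """Constant predictor: the training Kaplan-Meier curve for every subject."""
    km = kaplan_meier(train_times, train_events)
    return np.tile(km.on_grid(grid), (n_subjects, 1))
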