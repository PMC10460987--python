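"""Classical survival analysis: Kaplan-Meier estimation with Greenwood
variance, fixed-point-in-time survival difference tests, univariate hazard
ratios (Breslow ties), the elastic-net Cox reference model with a Breslow
baseline, and Benjamini-Hochberg adjustment.

The product-limit estimator is implemented here because the fixed-point test
needs the Greenwood variance on the log(-log) scale directly; lifelines is
used as an independent cross-check in the test-suite, and scikit-survival
provides the penalized Cox coefficient path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MONTH_GRID = np.arange(0, 109, dtype=float)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate with Greenwood variance and log(-log) CI."""

    times: np.ndarray          # distinct observed times, ascending
    survival: np.ndarray       # S(t) at each time (right-continuous step)
    variance: np.ndarray       # Greenwood variance of S(t)
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def _index(self, t: float) -> int:
        return int(np.searchsorted(self.times, t, side="right")) - 1

    def survival_at(self, t: float) -> float:
        i = self._index(t)
        return 1.0 if i < 0 else float(self.survival[i])

    def variance_at(self, t: float) -> float:
        i = self._index(t)
        return 0.0 if i < 0 else float(self.variance[i])

    def ci_at(self, t: float) -> tuple[float, float]:
        i = self._index(t)
        if i < 0:
            return (1.0, 1.0)
        return (float(self.ci_lower[i]), float(self.ci_upper[i]))

    def on_grid(self, grid: np.ndarray = MONTH_GRID) -> np.ndarray:
        idx = np.searchsorted(self.times, grid, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out


def kaplan_meier(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times, with
    the Greenwood variance and a log(-log)-transformed 95% confidence band
    (bounded within [0, 1]).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    uniq = np.unique(t_sorted)
    n_at_risk, d, c = [], [], []
    n = len(times)
    for u in uniq:
        here = t_sorted == u
        n_at_risk.append(n)
        d.append(int((e_sorted & here).sum()))
        c.append(int((~e_sorted & here).sum()))
        n -= int(here.sum())
    n_at_risk = np.array(n_at_risk, dtype=float)
    d = np.array(d, dtype=float)
    c = np.array(c, dtype=float)
    frac = np.where(n_at_risk > 0, 1.0 - d / n_at_risk, 1.0)
    surv = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n_at_risk - d) > 0, d / (n_at_risk * (n_at_risk - d)), np.inf)
    cumsum = np.cumsum(terms)
    with np.errstate(invalid="ignore"):
        var = np.where(surv == 0.0, 0.0, surv**2 * cumsum)
    lo, hi = _loglog_band(surv, cumsum)
    return KMEstimate(
        times=uniq, survival=surv, variance=var, at_risk=n_at_risk,
        events=d, censored=c, ci_lower=lo, ci_upper=hi,
    )


def _loglog_band(surv: np.ndarray, cumsum: np.ndarray, z: float = 1.959963984540054):
    lo = np.empty_like(surv)
    hi = np.empty_like(surv)
    for i, s in enumerate(surv):
        if s <= 0.0 or s >= 1.0:
            lo[i] = hi[i] = s
            continue
        se_theta = np.sqrt(cumsum[i]) / abs(np.log(s))
        lo[i] = s ** np.exp(z * se_theta)
        hi[i] = s ** np.exp(-z * se_theta)
    return lo, hi


def survival_difference_at_time(
    times_a, events_a, times_b, events_b, t: float
) -> dict:
    """Chi-square test of S_A(t) = S_B(t) on the log(-log) scale.

    statistic = (log(-log S_A) - log(-log S_B))^2 / (var_A + var_B), with the
    delta-method variances derived from Greenwood; p from chi-square(1).
    Survival of exactly 0 or 1 in either group leaves the transform
    undefined and is reported as such.
    """
    km_a, km_b = kaplan_meier(times_a, events_a), kaplan_meier(times_b, events_b)
    out = {"t": t, "S_A": km_a.survival_at(t), "S_B": km_b.survival_at(t)}
    if not (0.0 < out["S_A"] < 1.0) or not (0.0 < out["S_B"] < 1.0):
        out.update(statistic=np.nan, p=np.nan, df=1,
                   note="survival at t is 0 or 1; log(-log) undefined")
        return out
    var = []
    for km, s in ((km_a, out["S_A"]), (km_b, out["S_B"])):
        green = km.variance_at(t)
        var.append(green / (s * np.log(s)) ** 2)
    theta_a, theta_b = np.log(-np.log(out["S_A"])), np.log(-np.log(out["S_B"]))
    stat = (theta_a - theta_b) ** 2 / (var[0] + var[1])
    out.update(statistic=float(stat), df=1, p=float(stats.chi2.sf(stat, df=1)))
    return out


def hazard_ratio(group, times, events) -> dict:
    """Univariate Cox hazard ratio between two groups (Breslow ties).

    ``group`` is a boolean/0-1 indicator (1 = the group whose hazard is in
    the numerator). Returns HR, Wald 95% CI, coefficient and its SE.
    """
    group = np.asarray(group, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if set(np.unique(group)) - {0.0, 1.0}:
        raise ValueError("group must be a 0/1 indicator")
    if events.sum() == 0:
        raise ValueError("no events: hazard ratio undefined")
    model = PHReg(times, group.reshape(-1, 1), status=events, ties="breslow")
    try:
        fit = model.fit(disp=False)
        beta = float(fit.params[0])
        se = float(fit.bse[0])
    except Exception as exc:  # complete separation or other failure
        return {"hr": np.nan, "ci": (np.nan, np.nan), "converged": False,
                "note": f"fit failed: {exc}"}
    if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
        return {"hr": np.nan, "ci": (np.nan, np.nan), "converged": False,
                "note": "non-converged (separation)"}
    z = 1.959963984540054
    return {
        "hr": float(np.exp(beta)),
        "ci": (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        "beta": beta, "se": se, "converged": True,
    }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Elastic-net Cox with Breslow baseline


@dataclass
class CoxModel:
    """Penalized Cox model with stored standardization and Breslow baseline."""

    coef: np.ndarray                  # on the standardized feature scale
    feature_names: list
    center: np.ndarray
    scale: np.ndarray
    baseline_times: np.ndarray        # event times of the Breslow baseline
    baseline_cumhaz: np.ndarray       # H0 at those times (non-decreasing)
    penalty: float = 0.0
    l1_ratio: float = 0.5
    val_ci: float = float("nan")

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != list(self.feature_names):
            raise ValueError("feature columns do not match the training space")
        x = (features.to_numpy(dtype=float) - self.center) / self.scale
        return x @ self.coef

    def cumulative_hazard(self, grid: np.ndarray = MONTH_GRID) -> np.ndarray:
        idx = np.searchsorted(self.baseline_times, grid, side="right") - 1
        return np.where(idx >= 0, self.baseline_cumhaz[np.maximum(idx, 0)], 0.0)


def breslow_baseline(times, events, linear_pred) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard.

    H0(t) = sum over event times t_i <= t of d_i / sum_{j at risk} exp(lp_j).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    lp = np.asarray(linear_pred, dtype=float)
    risk = np.exp(lp)
    uniq = np.unique(times[events])
    h0 = []
    total = 0.0
    for u in uniq:
        d = int((events & (times == u)).sum())
        denom = risk[times >= u].sum()
        total += d / denom
        h0.append(total)
    return uniq, np.array(h0)


def fit_cox_elasticnet(
    train_x: pd.DataFrame, train_y: pd.DataFrame,
    val_x: pd.DataFrame, val_y: pd.DataFrame,
    penalties=(0.001, 0.01, 0.1, 1.0),
    l1_ratios=(0.1, 0.5, 0.9),
    eval_times=(24.0, 48.0, 108.0),
) -> CoxModel:
    """Grid search an elastic-net Cox model on validation concordance.

    Features are Z-scored to the training data; each (penalty, l1_ratio)
    pair is fit with scikit-survival's coordinate-descent path and scored by
    the mean concordance index over the evaluation horizons on the
    validation split; failures at a grid point are skipped and logged.
    ``train_y``/``val_y`` carry columns ``time_months`` and ``event``.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    from .evaluation import concordance_index

    center = train_x.to_numpy(dtype=float).mean(axis=0)
    scale = train_x.to_numpy(dtype=float).std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    xt = (train_x.to_numpy(dtype=float) - center) / scale
    xv = (val_x.to_numpy(dtype=float) - center) / scale
    y_train = Surv.from_arrays(
        train_y["event"].to_numpy(dtype=bool), train_y["time_months"].to_numpy(float)
    )

    best = None
    for l1 in l1_ratios:
        for pen in penalties:
            try:
                net = CoxnetSurvivalAnalysis(
                    alphas=[pen], l1_ratio=l1, fit_baseline_model=False
                )
                net.fit(xt, y_train)
                coef = net.coef_[:, 0]
            except Exception as exc:
                logger.warning("coxnet failed at penalty=%s l1=%s: %s", pen, l1, exc)
                continue
            bt, bh = breslow_baseline(
                train_y["time_months"], train_y["event"], xt @ coef
            )
            model = CoxModel(
                coef=coef, feature_names=list(train_x.columns),
                center=center, scale=scale,
                baseline_times=bt, baseline_cumhaz=bh,
                penalty=pen, l1_ratio=l1,
            )
            curves = predict_cox_survival(model, val_x)
            cis = []
            for t in eval_times:
                risk = 1.0 - curves[:, int(t)]
                try:
                    cis.append(concordance_index(
                        val_y["time_months"].to_numpy(float),
                        val_y["event"].to_numpy(bool), risk,
                    ))
                except ValueError:
                    pass
            score = float(np.mean(cis)) if cis else 0.5
            model.val_ci = score
            if best is None or score > best.val_ci:
                best = model
    if best is None:
        raise RuntimeError("all elastic-net grid points failed")
    return best


def predict_cox_survival(
    model: CoxModel, features: pd.DataFrame, grid: np.ndarray = MONTH_GRID
) -> np.ndarray:
    """Per-subject survival curves S(t|x) = exp(-H0(t) e^{x beta})."""
    lp = model.linear_predictor(features)
    h0 = model.cumulative_hazard(grid)
    return np.exp(-np.outer(np.exp(lp), h0))
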