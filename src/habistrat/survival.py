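"""Survival estimation, group tests, Cox models and IPCW model-comparison metrics.

Implements the statistics used to compare risk models on right-censored
endpoints: Kaplan-Meier curves, the log-rank test, Cox proportional hazards
(backed by lifelines, Efron ties), Harrell's concordance, and the
censoring-corrected comparison metrics — Brier score / integrated Brier
score, cumulative/dynamic time-dependent AUC, and continuous NRI / IDI — all
weighted by inverse-probability-of-censoring weights (IPCW).

Conventions fixed here and relied on by the tests:

* KM ties: deaths are processed before censorings at a tied time.
* The censoring survival function G is the reverse Kaplan-Meier (event
  flags flipped) with risk sets {T >= c}; G is right-continuous and left
  limits G(t-) use strict inequality.
* IPCW weights at horizon t: events before t get 1/G(T-), survivors past t
  get 1/G(t), subjects censored before t get 0.
* Risk ties in concordance and AUC count 1/2.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _validate(time, event):
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValueError("all times must be finite and > 0")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event flags must be 0 or 1")
    return time, event.astype(np.int64)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclasses.dataclass
class SurvivalCurve:
    """Right-continuous product-limit step function.

    ``times`` are the distinct event times, ``survival`` the post-step
    values; the curve starts at 1 and the last value is carried forward
    beyond the final event time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """S(t), right-continuous."""
        return self._eval(t, side="right")

    def evaluate_left(self, t) -> np.ndarray:
        """S(t-), the left limit (value strictly before t)."""
        return self._eval(t, side="left")

    def _eval(self, t, side):
        tt = np.atleast_1d(t)
        if len(self.times) == 0:  # no events: S identically 1
            out = np.ones_like(tt, dtype=np.float64)
        else:
            idx = np.searchsorted(self.times, tt, side=side) - 1
            out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if np.ndim(t) else float(out[0])


def kaplan_meier(time, event) -> SurvivalCurve:
    """Product-limit estimator; ties: deaths before censorings."""
    time, event = _validate(time, event)
    t_sorted = np.sort(time)
    n = len(time)
    ev_t = time[event == 1]
    event_times, d = np.unique(ev_t, return_counts=True)
    at_risk = n - np.searchsorted(t_sorted, event_times, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return SurvivalCurve(event_times.astype(np.float64), surv,
                         at_risk.astype(np.int64), d.astype(np.int64))


# ---------------------------------------------------------------------------
# Log-rank test


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """K-sample log-rank test: (chi2, dof, p).

    Observed-minus-expected over pooled event times with the hypergeometric
    covariance; dof = groups - 1.
    """
    time, event = _validate(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    g = len(labels)
    if g < 2:
        raise ValueError("need >= 2 groups")
    for lab in labels:
        if np.sum(group == lab) == 0:
            raise ValueError(f"group {lab} is empty")
    gidx = np.searchsorted(labels, group)
    event_times = np.unique(time[event == 1])
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        d = int(np.sum((time == t) & (event == 1)))
        nj = np.bincount(gidx[at_risk], minlength=g).astype(np.float64)
        dj = np.bincount(gidx[(time == t) & (event == 1)],
                         minlength=g).astype(np.float64)
        O += dj
        E += d * nj / n
        if n > 1:
            c = d * (n - d) / (n - 1.0)
            V += c * (np.diag(nj / n) - np.outer(nj, nj) / n ** 2)
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(Vsub) @ z) if z.size else 0.0
    chi2 = max(chi2, 0.0)
    dof = g - 1
    return chi2, dof, float(stats.chi2.sf(chi2, dof))


# ---------------------------------------------------------------------------
# Cox proportional hazards (lifelines-backed)


def cox_model(data: pd.DataFrame, duration_col: str, event_col: str,
              covariates: Sequence[str]) -> pd.DataFrame:
    """Multivariate Cox PH fit (Efron ties) with HR, 95% CI and p per covariate.

    Raises on constant covariates, on more covariates than events, and on
    separation / non-convergence — never fails silently.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates)
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(f"{n_events} events < {len(covariates)} covariates")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate '{c}' is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(data[[duration_col, event_col] + covariates],
                duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    summ = cph.summary
    out = pd.DataFrame({
        "covariate": summ.index,
        "coef": summ["coef"].to_numpy(),
        "hr": summ["exp(coef)"].to_numpy(),
        "hr_ci_lower": np.exp(summ["coef lower 95%"].to_numpy()),
        "hr_ci_upper": np.exp(summ["coef upper 95%"].to_numpy()),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Concordance


def concordance_index(risk, time, event) -> float:
    """Harrell's C for a scalar risk marker (higher = worse).

    Pairs are comparable when the earlier time is an event; risk ties count
    1/2.  Errors when no pair is comparable.
    """
    time, event = _validate(time, event)
    risk = np.asarray(risk, dtype=np.float64)
    conc = 0.0
    n_pairs = 0
    for i in np.where(event == 1)[0]:
        later = (time > time[i]) | ((time == time[i]) & (event == 0))
        n = int(later.sum())
        if n == 0:
            continue
        n_pairs += n
        conc += np.sum(risk[i] > risk[later]) + 0.5 * np.sum(risk[i] == risk[later])
    if n_pairs == 0:
        raise ValueError("no comparable pairs under censoring")
    return float(conc / n_pairs)


# ---------------------------------------------------------------------------
# IPCW machinery


def censoring_survival(time, event) -> SurvivalCurve:
    """Reverse Kaplan-Meier: KM of the censoring distribution."""
    time, event = _validate(time, event)
    return kaplan_meier(time, 1 - event)


def ipcw_weights(time, event, t: float) -> np.ndarray:
    """Per-subject IPCW weights at horizon t.

    1/G(T-) for events before/at t, 1/G(t) for subjects still at risk past
    t, and 0 for subjects censored at or before t.
    """
    time, event = _validate(time, event)
    G = censoring_survival(time, event)
    return _ipcw_weights_from_curve(time, event, t, G)


# ---------------------------------------------------------------------------
# Brier score and IBS


def _ipcw_weights_from_curve(time, event, t: float,
                             G: SurvivalCurve) -> np.ndarray:
    w = np.zeros(len(time))
    is_case = (event == 1) & (time <= t)
    is_control = time > t
    g_case = np.atleast_1d(G.evaluate_left(time[is_case]))
    g_t = G.evaluate(t)
    if np.any(g_case <= 0) or (is_control.any() and g_t <= 0):
        raise ValueError(
            f"censoring survival reaches 0 before horizon t={t}; "
            "use a smaller horizon")
    w[is_case] = 1.0 / g_case
    if is_control.any():
        w[is_control] = 1.0 / g_t
    return w


def brier_score(surv_prob, time, event, t: float,
                _G: Optional[SurvivalCurve] = None) -> float:
    """IPCW Brier score of predicted survival probabilities at horizon t."""
    time, event = _validate(time, event)
    s = np.asarray(surv_prob, dtype=np.float64)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("predicted survival probabilities must lie in [0,1]")
    G = _G if _G is not None else censoring_survival(time, event)
    w = _ipcw_weights_from_curve(time, event, t, G)
    is_case = (event == 1) & (time <= t)
    is_control = time > t
    sq = np.zeros(len(time))
    sq[is_case] = (0.0 - s[is_case]) ** 2
    sq[is_control] = (1.0 - s[is_control]) ** 2
    return float(np.sum(w * sq) / len(time))


def integrated_brier_score(surv_matrix: np.ndarray, grid, time, event,
                           t_max: Optional[float] = None) -> float:
    """IBS = (1/t_max) * integral of BS(t) dt, trapezoid on the event-time grid.

    ``surv_matrix`` is (n_subjects, n_grid) of predicted S(t) on ``grid``.
    """
    time, event = _validate(time, event)
    grid = np.asarray(grid, dtype=np.float64)
    surv_matrix = np.asarray(surv_matrix, dtype=np.float64)
    if surv_matrix.shape != (len(time), len(grid)):
        raise ValueError("surv_matrix shape must be (n_subjects, n_grid)")
    if t_max is None:
        t_max = float(grid[-1])
    G = censoring_survival(time, event)
    use = np.where(grid <= t_max)[0]
    ts = grid[use]
    bs = np.array([brier_score(surv_matrix[:, j], time, event, float(grid[j]),
                               _G=G) for j in use])
    # BS(0) = 0: no subject can have failed at time 0
    ts = np.concatenate([[0.0], ts])
    bs = np.concatenate([[0.0], bs])
    return float(np.trapezoid(bs, ts) / t_max)


def make_prediction_grid(time, event, t_max: float) -> np.ndarray:
    """Event-time grid for IBS integration, capped at t_max."""
    time, event = _validate(time, event)
    ts = np.unique(time[event == 1])
    ts = ts[ts <= t_max]
    if len(ts) == 0 or ts[-1] < t_max:
        ts = np.concatenate([ts, [t_max]])
    return ts


# ---------------------------------------------------------------------------
# Time-dependent AUC (cumulative/dynamic, IPCW)


def time_dependent_auc(marker, time, event, t: float) -> float:
    """Cumulative/dynamic AUC(t) with IPCW: cases are events with T <= t,
    controls are subjects with T > t; risk ties count 1/2."""
    time, event = _validate(time, event)
    marker = np.asarray(marker, dtype=np.float64)
    is_case = (event == 1) & (time <= t)
    is_control = time > t
    if not is_case.any() or not is_control.any():
        raise ValueError(f"no cases or no controls at t={t}")
    w = ipcw_weights(time, event, t)
    wc = w[is_case]
    wk = w[is_control]
    mc = marker[is_case][:, None]
    mk = marker[is_control][None, :]
    wmat = wc[:, None] * wk[None, :]
    wins = np.sum(wmat * ((mc > mk) + 0.5 * (mc == mk)))
    return float(wins / wmat.sum())


# ---------------------------------------------------------------------------
# NRI / IDI


def _event_masks_weights(time, event, t):
    time, event = _validate(time, event)
    w = ipcw_weights(time, event, t)
    is_event = (event == 1) & (time <= t)
    is_nonevent = time > t
    if not is_event.any() or not is_nonevent.any():
        raise ValueError(f"no events or no non-events at t={t}")
    return is_event, is_nonevent, w


def nri(old_risk, new_risk, time, event, t: float) -> float:
    """Category-free (continuous) NRI at horizon t, IPCW-weighted.

    NRI = P(up|event) - P(down|event) + P(down|non-event) - P(up|non-event),
    with up/down meaning the new model moved the risk up/down.
    """
    old_risk = np.asarray(old_risk, dtype=np.float64)
    new_risk = np.asarray(new_risk, dtype=np.float64)
    is_event, is_nonevent, w = _event_masks_weights(time, event, t)
    up = new_risk > old_risk
    down = new_risk < old_risk

    def wprop(mask, cond):
        return np.sum(w[mask & cond]) / np.sum(w[mask])

    return float((wprop(is_event, up) - wprop(is_event, down))
                 + (wprop(is_nonevent, down) - wprop(is_nonevent, up)))


def idi(old_risk, new_risk, time, event, t: float) -> float:
    """IDI at horizon t: gain in mean risk separation (events vs non-events),
    IPCW-weighted; risks should be event probabilities in [0,1]."""
    old_risk = np.asarray(old_risk, dtype=np.float64)
    new_risk = np.asarray(new_risk, dtype=np.float64)
    is_event, is_nonevent, w = _event_masks_weights(time, event, t)

    def wmean(x, mask):
        return np.sum(w[mask] * x[mask]) / np.sum(w[mask])

    sep_new = wmean(new_risk, is_event) - wmean(new_risk, is_nonevent)
    sep_old = wmean(old_risk, is_event) - wmean(old_risk, is_nonevent)
    return float(sep_new - sep_old)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_ci(metric_fn: Callable[[np.ndarray], float], n: int,
                 B: int = 1000, seed: int = 0,
                 max_failure_rate: float = 0.10,
                 ) -> tuple[float, float, float]:
    """Percentile 95% interval over B seeded patient resamples.

    ``metric_fn`` receives an index array into the n patients and returns a
    scalar; the point estimate uses the identity index.  Errors if more than
    ``max_failure_rate`` of resamples fail.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    point = float(metric_fn(np.arange(n)))
    values = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(metric_fn(idx)))
        except (ValueError, ZeroDivisionError, RuntimeError):
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(f"metric failed on {failures}/{B} bootstrap resamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return point, float(lo), float(hi)
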