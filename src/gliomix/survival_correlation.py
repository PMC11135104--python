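"""Correlation structure of selected features and survival characterization.

Pearson correlation matrices with t-based two-sided p-values, expression
dichotomization at the median or at the density valley between two distinct
KDE peaks, Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde, t as t_dist


@dataclass
class CorrelationResult:
    r: pd.DataFrame          # symmetric, unit diagonal
    p: pd.DataFrame          # two-sided, NaN on the diagonal
    n: pd.DataFrame          # samples used per pair
    flagged: list[str]       # zero-variance features (r undefined)


def pearson_matrix(X: pd.DataFrame) -> CorrelationResult:
    """All-pairs Pearson r with p from t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2.

    Missing values are handled pairwise-complete; zero-variance features
    yield NaN and are listed in ``flagged``.
    """
    cols = list(X.columns)
    m = len(cols)
    arr = X.to_numpy(dtype=float)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    nmat = np.zeros((m, m), dtype=int)
    flagged = []
    for i in range(m):
        xi = arr[:, i]
        ok_i = ~np.isnan(xi)
        if np.nanstd(xi) == 0:
            flagged.append(cols[i])
        r[i, i] = 1.0
        nmat[i, i] = int(ok_i.sum())
        for j in range(i + 1, m):
            xj = arr[:, j]
            ok = ok_i & ~np.isnan(xj)
            n = int(ok.sum())
            nmat[i, j] = nmat[j, i] = n
            if n < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            rij = float(np.corrcoef(xi[ok], xj[ok])[0, 1])
            r[i, j] = r[j, i] = rij
            if abs(rij) >= 1.0:
                pij = 0.0
            else:
                tstat = rij * np.sqrt(n - 2) / np.sqrt(1.0 - rij**2)
                pij = 2.0 * t_dist.sf(abs(tstat), df=n - 2)
            p[i, j] = p[j, i] = pij
    idx = pd.Index(cols)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
        flagged=flagged,
    )


def dichotomize_expression(
    values, prominence_frac: float = 0.05, grid_size: int = 512
) -> tuple[np.ndarray, float, str]:
    """Split samples into low/high expression groups.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a ``grid_size``
    grid; local maxima with prominence at least ``prominence_frac`` times
    the maximum density count as distinct peaks. With two or more peaks the
    cutoff is the density minimum between the two most prominent peaks
    (method 'density_valley'); otherwise the median (method 'median').
    Returns (groups, cutoff, method) with groups 'low' (value <= cutoff)
    and 'high'.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 samples")
    if np.std(v) == 0:
        raise ValueError("constant expression vector")
    kde = gaussian_kde(v, bw_method="silverman")
    # pad the grid by 3 bandwidths so edge peaks keep their full prominence
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_size)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=prominence_frac * dens.max())
    if peaks.size >= 2:
        top2 = peaks[np.argsort(props["prominences"])[::-1][:2]]
        lo, hi = np.sort(top2)
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        cutoff = float(grid[valley])
        method = "density_valley"
    else:
        cutoff = float(np.median(v))
        method = "median"
    groups = np.where(v <= cutoff, "low", "high")
    return groups, cutoff, method


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk/event tallies at event times."""

    times: np.ndarray        # distinct event times, increasing
    at_risk: np.ndarray      # n_i just before each event time
    events: np.ndarray       # d_i at each event time
    survival: np.ndarray     # S(t_i)
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate; censoring removes from the risk set."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty input")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event, label=label or None)
    table = kmf.event_table
    is_event = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[is_event]
    at_risk = table["at_risk"].to_numpy(dtype=float)[is_event]
    events = table["observed"].to_numpy(dtype=float)[is_event]
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(times=times, at_risk=at_risk, events=events, survival=surv, label=label)


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(list(groups))
    uniq = list(dict.fromkeys(groups))
    if len(uniq) != 2:
        raise ValueError("need exactly 2 groups")
    for g in uniq:
        if event[groups == g].sum() == 0:
            warnings.warn(f"group {g!r} has no events; log-rank statistic is fragile")
    m = groups == uniq[0]
    res = _ll_logrank(time[m], time[~m], event_observed_A=event[m], event_observed_B=event[~m])
    return float(res.test_statistic), float(res.p_value)


def survival_by_feature(
    values, time, event, prominence_frac: float = 0.05
) -> dict:
    """Dichotomize one feature and compare the two survival curves.

    Returns cutoff, method, the per-group KM curves and the log-rank
    (statistic, p).
    """
    groups, cutoff, method = dichotomize_expression(values, prominence_frac)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    curves = {
        g: km_estimate(time[groups == g], event[groups == g], label=g)
        for g in ("low", "high")
        if (groups == g).any()
    }
    if len(curves) == 2:
        stat, p = logrank_test(time, event, groups)
    else:
        stat, p = np.nan, np.nan
    return {"cutoff": cutoff, "method": method, "curves": curves,
            "statistic": stat, "p": p}
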