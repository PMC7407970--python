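"""Median-split survival stratification: Kaplan-Meier curves, the two-group
log-rank test, and Cox proportional-hazards regression.

KM and log-rank are implemented directly (they are small, closed-form
procedures); Cox regression delegates to lifelines' ``CoxPHFitter``
(Newton-Raphson partial likelihood with Efron tie handling) behind a tabular
interface.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "median_dichotomize",
    "kaplan_meier",
    "logrank_test",
    "cox_regression",
]


def median_dichotomize(expr) -> pd.Series:
    """Split samples at the median: value > median -> "high", else "low".

    Median-tied samples go to "low" (deterministic rule).  Raises when the
    split would leave a group empty (e.g. constant expression).
    """
    x = pd.Series(expr, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    med = float(np.median(x.to_numpy()))
    groups = pd.Series(np.where(x.to_numpy() > med, "high", "low"), index=x.index)
    if groups.nunique() < 2:
        raise ValueError("median split produced a single group (constant expression?)")
    return groups


def _check_times(time):
    t = np.asarray(time, dtype=float)
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    return t


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit estimator for one sample of (time, event) pairs.

    Returns a right-continuous step table with one row per distinct event
    time: columns time, at_risk, events, survival.  S(0) = 1.
    """
    t = _check_times(time)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n_at_risk = t.size
    i = 0
    while i < t.size:
        ti = t[i]
        d = 0
        removed = 0
        while i < t.size and t[i] == ti:
            d += int(e[i])
            removed += 1
            i += 1
        if d > 0:
            surv *= 1.0 - d / n_at_risk
            rows.append((ti, n_at_risk, d, surv))
        n_at_risk -= removed
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_test(time, event, groups):
    """Two-group log-rank test: (chi2, p) with 1 df.

    Observed-minus-expected events in group 1 at each distinct event time,
    with the hypergeometric variance.
    """
    t = _check_times(time)
    e = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("exactly two non-empty groups required")
    if e.sum() == 0:
        raise ValueError("no events")
    in1 = g == labels[1]
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_regression(data: pd.DataFrame, covariates, mode: str = "univariate",
                   duration_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Cox PH fits; one model per covariate (univariate) or one joint model.

    Returns a table with columns covariate, mode, HR, CI_low, CI_high, p,
    converged.  Constant covariates raise; non-convergence is flagged rather
    than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates)
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be univariate or multivariate")
    df = data[[duration_col, event_col, *covariates]].dropna().copy()
    n_events = int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError("too few events for the number of covariates")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")

    def _fit(cols):
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df[[duration_col, event_col, *cols]],
                        duration_col=duration_col, event_col=event_col)
        except ConvergenceError:
            return None
        return cph

    rows = []
    if mode == "univariate":
        fits = [(c, _fit([c])) for c in covariates]
        for c, cph in fits:
            rows.extend(_rows_from_fit(c, cph, "univariate"))
    else:
        cph = _fit(covariates)
        for c in covariates:
            rows.extend(_rows_from_fit(c, cph, "multivariate"))
    return pd.DataFrame(rows, columns=["covariate", "mode", "HR", "CI_low",
                                       "CI_high", "p", "converged"])


def _rows_from_fit(cov, cph, mode):
    if cph is None:
        return [(cov, mode, np.nan, np.nan, np.nan, np.nan, False)]
    s = cph.summary.loc[cov]
    return [(
        cov, mode,
        float(np.exp(s["coef"])),
        float(np.exp(s["coef lower 95%"])),
        float(np.exp(s["coef upper 95%"])),
        float(s["p"]),
        True,
    )]
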