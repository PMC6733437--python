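"""Survival machinery: Kaplan-Meier, log-rank, binary and multivariate Cox.

The single-binary-covariate Cox fit is implemented as a direct Newton
maximization of the Efron-ties partial likelihood.  For one binary covariate
the risk-set sums reduce to group counts, which lets the same solver run
*batched* across thousands of candidate stratifications at once — the
workhorse of the hazard-ratio-maximizing grid search.  The multivariate model
is delegated to lifelines (which uses the same Efron convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORY_LEVELS, REFERENCE_LEVELS

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SurvivalFit:
    """A hazard ratio with Wald 95% CI and p-value for one stratification."""

    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    n_high: int
    n_low: int
    label: str = ""
    converged: bool = True
    coef: float = field(default=np.nan, repr=False)
    se: float = field(default=np.nan, repr=False)


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p: float
    df: int = 1


def stratify_at_cutoff(scores, cutoff: float, high_risk_side: str) -> np.ndarray:
    """Binary high-risk labels; ties (score == cutoff) go to the low-risk group."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if high_risk_side == "above":
        return (s > cutoff).astype(int)
    if high_risk_side == "below":
        return (s < cutoff).astype(int)
    raise ValueError("high_risk_side must be 'above' or 'below'")


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator evaluated at the distinct event times."""
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return KMCurve(times=np.array([]), survival=np.array([]),
                       at_risk=np.array([], dtype=int))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(t >= ut).sum() for ut in event_times])
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank chi-square test (df=1)."""
    from lifelines.statistics import logrank_test as _lr

    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    res = _lr(ta, tb, event_observed_A=np.asarray(events_a, int),
              event_observed_B=np.asarray(events_b, int))
    return LogRankResult(statistic=float(res.test_statistic),
                         p=float(res.p_value), df=1)


# ---------------------------------------------------------------------------
# Efron partial-likelihood Newton solver for a single binary covariate
# ---------------------------------------------------------------------------

class _EfronData:
    """Time-ordered sufficient statistics reused across candidate labelings."""

    __slots__ = ("order", "n", "risk_start", "d", "event_rows", "tie_slices", "nrisk")

    def __init__(self, times, events):
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        self.n = t.size
        self.order = np.argsort(t, kind="stable")
        ts, es = t[self.order], e[self.order]
        # unique event times -> first sorted index (risk set = rows idx..n-1)
        ev_times = np.unique(ts[es == 1])
        self.risk_start = np.searchsorted(ts, ev_times, side="left")
        self.nrisk = self.n - self.risk_start
        self.d = np.empty(ev_times.size, dtype=int)
        self.tie_slices = []
        self.event_rows = np.flatnonzero(es == 1)
        for i, ut in enumerate(ev_times):
            in_tie = (ts == ut) & (es == 1)
            self.d[i] = int(in_tie.sum())
            self.tie_slices.append(np.flatnonzero(in_tie))


def _batch_cox_binary(times, events, labels, max_iter: int = 60,
                      tol: float = 1e-12, data: _EfronData | None = None):
    """Newton fit of the Efron partial likelihood, one binary covariate.

    ``labels`` is (n,) or (n, m) with one candidate stratification per column.
    Returns ``(coef, se, converged)`` each of shape (m,).  Candidates with an
    empty group, no events, or a diverging estimate are flagged unconverged
    with coef NaN.
    """
    L = np.asarray(labels, dtype=float)
    squeeze = L.ndim == 1
    if squeeze:
        L = L[:, None]
    n, m = L.shape
    if data is None:
        data = _EfronData(times, events)
    Ls = L[data.order]
    ne = data.d.size
    if ne == 0:
        nan = np.full(m, np.nan)
        out = nan, nan, np.zeros(m, dtype=bool)
        return tuple(x[0] if squeeze else x for x in out)

    # suffix sums: G_R[i] = sum of labels over the risk set of event time i
    suffix = np.cumsum(Ls[::-1], axis=0)[::-1]
    G_R = suffix[data.risk_start]                    # (ne, m)
    G_D = np.stack([Ls[rows].sum(axis=0) for rows in data.tie_slices])  # (ne, m)
    deaths_g = G_D.sum(axis=0)                       # (m,)
    nrisk = data.nrisk[:, None].astype(float)
    d = data.d[:, None].astype(float)

    n1 = Ls.sum(axis=0)
    valid = (n1 > 0) & (n1 < n)

    beta = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eb = np.exp(beta)[None, :]
        S0 = nrisk + (eb - 1.0) * G_R
        S1 = eb * G_R
        S0D = d + (eb - 1.0) * G_D
        S1D = eb * G_D
        grad = deaths_g.copy()
        info = np.zeros(m)
        dmax = int(data.d.max())
        for j in range(dmax):
            mask = (data.d > j)[:, None]
            frac = j / d
            den = S0 - frac * S0D
            num = S1 - frac * S1D
            with np.errstate(divide="ignore", invalid="ignore"):
                u = np.where(mask & (den > 0), num / den, 0.0)
            grad -= u.sum(axis=0)
            info += (u * (1.0 - u) * mask).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 1e-12, grad / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.clip(beta + np.where(valid, step, 0.0), -30.0, 30.0)
        converged = valid & (np.abs(grad) < tol * np.maximum(1.0, np.abs(deaths_g))) \
            & (info > 1e-10)
        if converged.all() or np.all(np.abs(step[valid]) < 1e-14):
            break
    # a second pass of the information at the solution for the SE
    eb = np.exp(beta)[None, :]
    S0 = nrisk + (eb - 1.0) * G_R
    S1 = eb * G_R
    S0D = d + (eb - 1.0) * G_D
    S1D = eb * G_D
    info = np.zeros(m)
    for j in range(int(data.d.max())):
        mask = (data.d > j)[:, None]
        frac = j / d
        den = S0 - frac * S0D
        num = S1 - frac * S1D
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(mask & (den > 0), num / den, 0.0)
        info += (u * (1.0 - u) * mask).sum(axis=0)
    ok = valid & converged & (np.abs(beta) < 29.0) & (info > 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(ok, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    coef = np.where(ok, beta, np.nan)
    if squeeze:
        return coef[0], se[0], ok[0]
    return coef, se, ok


def binary_cox_hr(times, events, group, label: str = "") -> SurvivalFit:
    """Univariate Cox HR for high-risk (group=1) vs low-risk (group=0).

    Efron tie handling; 95% CI = exp(coef +/- 1.96*SE); Wald p from coef/SE.
    Complete separation or a degenerate split yields a flagged non-converged
    fit rather than an exception.
    """
    g = np.asarray(group, dtype=int)
    e = np.asarray(events, dtype=int)
    n_high, n_low = int(g.sum()), int((1 - g).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both groups must be nonempty")
    if e.sum() == 0:
        raise ValueError("no events in the data")
    coef, se, ok = _batch_cox_binary(times, events, g)
    if not ok or not np.isfinite(coef):
        return SurvivalFit(hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                           wald_p=np.nan, n_high=n_high, n_low=n_low,
                           label=label, converged=False)
    z = coef / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SurvivalFit(hr=float(np.exp(coef)),
                       ci_low=float(np.exp(coef - Z95 * se)),
                       ci_high=float(np.exp(coef + Z95 * se)),
                       wald_p=p, n_high=n_high, n_low=n_low, label=label,
                       converged=True, coef=float(coef), se=float(se))


def welch_t_test(x, y) -> tuple[float, float]:
    """Two-sided two-sample t-test with Welch (unequal-variance) df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def multivariate_cox(cohort: pd.DataFrame, covariates: dict,
                     time_col: str = "os_time", event_col: str = "event",
                     ) -> list[SurvivalFit]:
    """Multivariate Cox PH over a named covariate specification.

    ``covariates`` maps a display name to either a column name (numeric or
    categorical, expanded against the documented reference levels) or an
    array of per-patient values (e.g. a derived risk-group indicator).  Rows
    missing any covariate are deleted listwise; constant covariates are
    dropped with a warning.  Returns one fit per non-reference level.
    """
    from lifelines import CoxPHFitter

    design = pd.DataFrame({
        time_col: cohort[time_col].to_numpy(float),
        event_col: cohort[event_col].to_numpy(int),
    })
    meta: list[tuple[str, str]] = []  # (design column, display label)
    for name, spec in covariates.items():
        values = cohort[spec] if isinstance(spec, str) and spec in cohort.columns else pd.Series(np.asarray(spec), index=cohort.index)
        col_key = spec if isinstance(spec, str) else name
        if col_key in CATEGORY_LEVELS:
            ref = REFERENCE_LEVELS[col_key]
            for level in CATEGORY_LEVELS[col_key]:
                if level == ref:
                    continue
                dcol = f"{name}[{level}]"
                design[dcol] = (values == level).astype(float).where(values.notna())
                meta.append((dcol, f"{name}: {level} vs {ref}"))
        else:
            design[name] = pd.to_numeric(values, errors="coerce")
            meta.append((name, name))
    design = design.dropna()
    keep: list[tuple[str, str]] = []
    for dcol, lab in meta:
        if design[dcol].nunique() < 2:
            warnings.warn(f"covariate {lab!r} is constant after listwise "
                          "deletion; dropped", stacklevel=2)
            design = design.drop(columns=dcol)
        else:
            keep.append((dcol, lab))
    cph = CoxPHFitter()
    cph.fit(design, duration_col=time_col, event_col=event_col)
    out = []
    for dcol, lab in keep:
        coef = float(cph.params_[dcol])
        se = float(cph.standard_errors_[dcol])
        n1 = int((design[dcol] > 0).sum())
        out.append(SurvivalFit(
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - Z95 * se)),
            ci_high=float(np.exp(coef + Z95 * se)),
            wald_p=float(2.0 * stats.norm.sf(abs(coef / se))),
            n_high=n1, n_low=len(design) - n1, label=lab,
            converged=True, coef=coef, se=se))
    return out


def km_to_frame(curve: KMCurve, group: str = "") -> pd.DataFrame:
    """Tidy one-row-per-step export of a KM curve."""
    return pd.DataFrame({"group": group, "time": curve.times,
                         "survival": curve.survival, "at_risk": curve.at_risk})
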