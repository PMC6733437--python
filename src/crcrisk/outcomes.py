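"""Outcome classification, hybrid clinical scores, subgroups, single-protein risk.

Favorable outcome = alive through the study (event 0); unfavorable =
death/recurrence (event 1).  The Risk Score predicts favorable iff RS >= 0,
and the favorable class is the positive class of the confusion summary.

The hybrid score adds weighted clinical features to the raw protein score:
``Comb = beta* + sum_i w_i * feature_i`` with numeric features entering in
raw units (age in years) and categorical features contributing their level's
weight; RS_H is the z-normalized Comb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CATEGORY_LEVELS, z_normalize
from .risk import FixedWeightRiskScore, compute_beta, grid_values
from .survival import KMCurve, LogRankResult, SurvivalFit, binary_cox_hr, \
    km_estimate, logrank_test, stratify_at_cutoff


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def predict_outcome(rs) -> np.ndarray:
    """Favorable (1) iff RS >= 0; the boundary itself is favorable."""
    rs = np.asarray(rs, float)
    if not np.all(np.isfinite(rs)):
        raise ValueError("RS must be finite")
    return (rs >= 0).astype(int)


def confusion_metrics(predicted_favorable, actual_favorable) -> ConfusionSummary:
    """Confusion counts with favorable as the positive class."""
    p = np.asarray(predicted_favorable, int)
    a = np.asarray(actual_favorable, int)
    if p.size != a.size:
        raise ValueError("length mismatch")
    if p.size == 0:
        raise ValueError("empty input")
    return ConfusionSummary(tp=int(((p == 1) & (a == 1)).sum()),
                            fp=int(((p == 1) & (a == 0)).sum()),
                            tn=int(((p == 0) & (a == 0)).sum()),
                            fn=int(((p == 0) & (a == 1)).sum()))


def outcome_report(cohort: pd.DataFrame, rs) -> ConfusionSummary:
    """Confusion of RS-predicted vs actual favorable/unfavorable outcomes."""
    actual_favorable = (cohort["event"].to_numpy(int) == 0).astype(int)
    return confusion_metrics(predict_outcome(rs), actual_favorable)


# ---------------------------------------------------------------------------
# hybrid clinical combinations
# ---------------------------------------------------------------------------

def _feature_contribution(cohort: pd.DataFrame, name: str, weight) -> np.ndarray:
    col = cohort[name]
    if isinstance(weight, dict):
        contrib = col.map(weight)
    else:
        contrib = pd.to_numeric(col, errors="coerce") * float(weight)
    return contrib.to_numpy(float)


def compute_comb(cohort: pd.DataFrame, base_beta, feature_weights: dict
                 ) -> np.ndarray:
    """Comb = beta* + sum of weighted clinical features (raw units).

    Rows with a missing feature value get NaN (excluded downstream with a
    warning).
    """
    comb = np.asarray(base_beta, float).copy()
    for name, w in feature_weights.items():
        if name not in cohort.columns:
            raise KeyError(f"feature {name!r} not in cohort")
        comb = comb + _feature_contribution(cohort, name, w)
    if np.isnan(comb).any():
        warnings.warn(f"{int(np.isnan(comb).sum())} rows excluded for missing "
                      "clinical features", stacklevel=2)
    return comb


class HybridRiskScore(BaseEstimator):
    """RS_H = z-normalized (beta* + weighted clinical features).

    ``base`` is a fitted :class:`FixedWeightRiskScore` (or subclass) holding
    the protein weights; ``feature_weights`` maps clinical columns to a
    scalar (numeric feature) or a per-level dict (categorical feature).
    """

    def __init__(self, base: FixedWeightRiskScore = None, feature_weights: dict = None):
        self.base = base
        self.feature_weights = feature_weights

    def fit(self, X: pd.DataFrame, y=None):
        if self.base is None or not hasattr(self.base, "w_star_"):
            raise ValueError("base must be a fitted risk-score model")
        beta = compute_beta(X, self.base.w_star_)
        comb = compute_comb(X, beta, self.feature_weights or {})
        keep = ~np.isnan(comb)
        rs_h, params = z_normalize(comb[keep])
        self.znorm_ = params
        self.cutoff_mean_ = 0.0
        self.cutoff_median_ = float(np.median(rs_h))
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        beta = compute_beta(X, self.base.w_star_)
        comb = compute_comb(X, beta, self.feature_weights or {})
        return self.znorm_.transform(comb)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return stratify_at_cutoff(self.transform(X), self.cutoff_mean_, "below")


def hybrid_risk_score(cohort: pd.DataFrame, model: HybridRiskScore
                      ) -> tuple[np.ndarray, SurvivalFit, SurvivalFit]:
    """RS_H plus mean- and median-cutoff Cox fits on the given cohort."""
    rs_h = model.transform(cohort)
    keep = ~np.isnan(rs_h)
    t = cohort["os_time"].to_numpy(float)[keep]
    e = cohort["event"].to_numpy(int)[keep]
    v = rs_h[keep]
    fits = []
    for cut_label, cut in (("mean", float(np.mean(v))), ("median", float(np.median(v)))):
        g = stratify_at_cutoff(v, cut, "below")
        fits.append(binary_cox_hr(t, e, g, label=f"RS_H < {cut_label}"))
    return rs_h, fits[0], fits[1]


def search_clinical_weights(cohort: pd.DataFrame, base_beta, feature: str,
                            precision: float = 0.1, bounds=(-1.0, 1.0),
                            alpha: float = 0.05):
    """Grid-search the weight(s) of one clinical feature added to beta*.

    Numeric features search a scalar weight; categorical features search one
    weight per level (full Cartesian grid).  The objective and tie-breaks are
    those of the protein search.  Returns (best_weights, objective).
    """
    t = cohort["os_time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    beta = np.asarray(base_beta, float)
    vals = grid_values(precision, bounds)
    if feature in CATEGORY_LEVELS:
        levels = CATEGORY_LEVELS[feature]
        onehot = np.stack([(cohort[feature] == lv).to_numpy(float)
                           for lv in levels], axis=1)  # (n, L)
        grids = np.meshgrid(*([vals] * len(levels)), indexing="ij")
        W = np.stack([g.ravel() for g in grids], axis=1)  # (m, L)
        contrib = onehot @ W.T
    else:
        x = pd.to_numeric(cohort[feature], errors="coerce").to_numpy(float)
        W = vals[:, None]
        contrib = x[:, None] * vals[None, :]
    comb = beta[:, None] + contrib  # (n, m)
    # reuse the batched objective machinery on precomputed "beta" columns
    from .survival import _EfronData, _batch_cox_binary
    data = _EfronData(t, e)
    means = comb.mean(axis=0, keepdims=True)
    medians = np.median(comb, axis=0, keepdims=True)
    cm, sm, okm = _batch_cox_binary(t, e, comb < means, data=data)
    cd, sd, okd = _batch_cox_binary(t, e, comb < medians, data=data)
    from scipy import stats as _st
    with np.errstate(invalid="ignore"):
        p_mean = 2.0 * _st.norm.sf(np.abs(cm / sm))
        p_median = 2.0 * _st.norm.sf(np.abs(cd / sd))
    hr_mean, hr_median = np.exp(cm), np.exp(cd)
    obj = np.full(W.shape[0], -np.inf)
    good = okm & okd & (p_mean < alpha) & (p_median < alpha)
    obj[good] = np.minimum(hr_mean[good], hr_median[good])
    if not np.isfinite(obj).any():
        raise ValueError("all clinical-weight candidates were degenerate")
    best = np.max(obj)
    tied = np.flatnonzero(obj == best)
    sums = hr_mean[tied] + hr_median[tied]
    tied = tied[sums == sums.max()]
    idx = tied[0]  # enumeration is lexicographic over the level grids
    w = W[idx]
    if feature in CATEGORY_LEVELS:
        return {lv: float(w[j]) for j, lv in enumerate(CATEGORY_LEVELS[feature])}, float(best)
    return float(w[0]), float(best)


def subgroup_stratify(cohort: pd.DataFrame, predicate, rs, cutoff: float
                      ) -> tuple[tuple[KMCurve, KMCurve], LogRankResult, SurvivalFit]:
    """KM curves, log-rank and Cox HR within a clinical subgroup.

    ``predicate`` is a boolean mask or a callable on the cohort frame; high
    risk is RS strictly below ``cutoff``.  A subgroup entirely on one side of
    the cutoff raises a ValueError (flagged, no fit).
    """
    mask = predicate(cohort) if callable(predicate) else np.asarray(predicate, bool)
    sub = cohort.loc[mask]
    srs = np.asarray(rs, float)[mask]
    if len(sub) == 0:
        raise ValueError("empty subgroup")
    g = stratify_at_cutoff(srs, cutoff, "below")
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("subgroup lies entirely on one side of the cutoff")
    t = sub["os_time"].to_numpy(float)
    e = sub["event"].to_numpy(int)
    km_high = km_estimate(t[g == 1], e[g == 1])
    km_low = km_estimate(t[g == 0], e[g == 0])
    lr = logrank_test(t[g == 1], e[g == 1], t[g == 0], e[g == 0])
    fit = binary_cox_hr(t, e, g, label="RS < cutoff within subgroup")
    return (km_high, km_low), lr, fit


# ---------------------------------------------------------------------------
# single-protein bin regression (risk percentage from one concentration)
# ---------------------------------------------------------------------------

class SingleProteinRisk(BaseEstimator):
    """Bin-wise linear model of high-risk probability vs one protein.

    High risk = OS below the cohort median OS.  The concentrations are cut
    into ``n_bins`` equal-count bins; a least-squares line is fit through
    (bin mean concentration, bin high-risk fraction); ``predict`` clamps the
    line to [0, 100]%.
    """

    def __init__(self, protein: str = "bclxl", n_bins: int = 10):
        self.protein = protein
        self.n_bins = n_bins

    def fit(self, X: pd.DataFrame, y=None):
        conc = X[self.protein].to_numpy(float)
        os_time = X["os_time"].to_numpy(float)
        if len(X) < 5 * self.n_bins:
            raise ValueError(f"need >= {5 * self.n_bins} patients for "
                             f"{self.n_bins} bins (>=5 per bin)")
        high_risk = (os_time < np.median(os_time)).astype(float)
        ranks = pd.qcut(pd.Series(conc).rank(method="first"), self.n_bins,
                        labels=False).to_numpy()
        bin_means = np.array([conc[ranks == b].mean() for b in range(self.n_bins)])
        bin_risk = np.array([high_risk[ranks == b].mean() for b in range(self.n_bins)])
        edges = [float(conc[ranks == b].max()) for b in range(self.n_bins - 1)]
        slope, intercept = np.polyfit(bin_means, bin_risk, 1)
        self.bin_means_ = bin_means
        self.bin_risk_ = bin_risk
        self.bin_edges_ = np.array([float(conc.min()), *edges, float(conc.max())])
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        return self

    def predict(self, concentration) -> np.ndarray:
        """Risk percentage in [0, 100] for given concentration(s) in nM."""
        c = np.atleast_1d(np.asarray(concentration, float))
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        risk = np.clip(self.slope_ * c + self.intercept_, 0.0, 1.0) * 100.0
        return risk if risk.size > 1 else risk


def fit_single_protein_model(cohort: pd.DataFrame, protein: str,
                             n_bins: int = 10) -> SingleProteinRisk:
    return SingleProteinRisk(protein=protein, n_bins=n_bins).fit(cohort)


def predict_single_protein_risk(model: SingleProteinRisk, concentration) -> np.ndarray:
    return model.predict(concentration)
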