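"""Cross-validated linear models predicting OS from protein concentrations.

Six estimators fit ``OS = x0 + x1*Bak + x2*Bax + x3*Bcl2 + x4*BclXL +
x5*Mcl1`` under the OS-sorted five-fold scheme; out-of-fold predictions are
assembled into a per-patient predicted OS, which is then used as a risk
marker (high risk = predicted OS below the mean/median cutoff).

Statistical caveat: censoring is ignored in the regression target — censored
times enter as observed survival.  The predicted OS is a ranking marker, not
a calibrated survival estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import (
    BayesianRidge,
    ElasticNetCV,
    LassoCV,
    LassoLarsCV,
    LinearRegression,
    RidgeCV,
)

from .cohort import PROTEINS
from .cv import FoldAssignment, train_test_pairs
from .survival import SurvivalFit, binary_cox_hr, stratify_at_cutoff

#: method name -> zero-argument estimator factory; penalized methods select
#: their penalty inside each training fold via the CV-selector classes.
REGRESSION_METHODS = {
    "ols": lambda: LinearRegression(),
    "ridge": lambda: RidgeCV(),
    "lasso": lambda: LassoCV(random_state=0),
    "lassolars": lambda: LassoLarsCV(),
    "elasticnet": lambda: ElasticNetCV(l1_ratio=0.5, random_state=0),
    "bayesian_ridge": lambda: BayesianRidge(),
}


def fit_predict_cv(cohort: pd.DataFrame, method: str,
                   folds: FoldAssignment) -> np.ndarray:
    """Out-of-fold predicted OS, one value per patient (no leakage)."""
    if method not in REGRESSION_METHODS:
        raise ValueError(f"unsupported method {method!r}; "
                         f"choose from {sorted(REGRESSION_METHODS)}")
    X = cohort[PROTEINS].to_numpy(float)
    y = cohort["os_time"].to_numpy(float)
    pred = np.full(len(cohort), np.nan)
    for train, test in train_test_pairs(folds):
        est = REGRESSION_METHODS[method]()
        est.fit(X[train], y[train])
        pred[test] = est.predict(X[test])
    return pred


def evaluate_predicted_os(pred: np.ndarray, cohort: pd.DataFrame
                          ) -> tuple[SurvivalFit, SurvivalFit]:
    """HR at the mean and median cutoffs of predicted OS (high risk below)."""
    pred = np.asarray(pred, float)
    if len(pred) != len(cohort):
        raise ValueError("prediction and cohort are not aligned")
    if np.ptp(pred) == 0:
        raise ValueError("degenerate (constant) predictions cannot stratify")
    t = cohort["os_time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    fits = []
    for cut_name, cut in (("mean", float(np.mean(pred))),
                          ("median", float(np.median(pred)))):
        g = stratify_at_cutoff(pred, cut, "below")
        fits.append(binary_cox_hr(t, e, g, label=f"predicted OS < {cut_name}"))
    return fits[0], fits[1]


def regression_report(cohort: pd.DataFrame, folds: FoldAssignment,
                      methods=tuple(REGRESSION_METHODS)) -> pd.DataFrame:
    """One row per method: HR and p at mean and median cutoffs."""
    rows = []
    for m in methods:
        pred = fit_predict_cv(cohort, m, folds)
        fit_mean, fit_median = evaluate_predicted_os(pred, cohort)
        rows.append({"method": m,
                     "hr_mean_cut": fit_mean.hr, "p_mean_cut": fit_mean.wald_p,
                     "hr_median_cut": fit_median.hr,
                     "p_median_cut": fit_median.wald_p})
    return pd.DataFrame(rows)
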