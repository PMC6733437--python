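"""Hazard-ratio-maximizing risk score: beta = X W^T, grid search, RS.

The score for patient j under a weight vector W in [-1, 1]^5 is the inner
product of W with the five protein concentrations.  Each OS-sorted training
fold is searched exhaustively over a one-decimal grid for the W maximizing
the Cox hazard ratio of the below-cutoff stratification (see
:func:`fold_objective`); the five fold optima are averaged componentwise into
W*, and the z-normalized beta* is the Risk Score (RS).  High risk is *below*
the cutoff: the anti-apoptotic proteins carry negative weights, so a low
score means a high anti-apoptotic burden.

Candidate evaluation is vectorized: beta for all patients and all candidates
is one matrix product, and the per-candidate binary Cox fits run batched
through the Efron Newton solver in :mod:`crcrisk.survival`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import PROTEINS, ZNormParams, z_normalize
from .cv import FoldAssignment, make_folds, train_test_pairs
from .survival import SurvivalFit, _EfronData, _batch_cox_binary, \
    binary_cox_hr, stratify_at_cutoff
from scipy import stats


@dataclass(frozen=True)
class GridSearchResult:
    best_weight: np.ndarray
    objective_value: float
    hr_mean_cut: SurvivalFit
    hr_median_cut: SurvivalFit
    candidates_evaluated: int


def compute_beta(cohort: pd.DataFrame, w) -> np.ndarray:
    """Per-patient weighted protein sum beta_j = sum_k w_k * conc_jk."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    w = np.asarray(w, dtype=float)
    return cohort[PROTEINS].to_numpy(float) @ w


def grid_values(precision: float = 0.1, bounds=(-1.0, 1.0)) -> np.ndarray:
    if precision <= 0:
        raise ValueError("precision must be positive")
    lo, hi = bounds
    steps = (hi - lo) / precision
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError("precision must divide the interval evenly")
    vals = lo + precision * np.arange(round(steps) + 1)
    return np.round(vals, 10)


def grid_candidates(precision: float = 0.1, bounds=(-1.0, 1.0)):
    """Lexicographic stream over the full Cartesian weight grid.

    At the default 0.1 precision this is 21^5 = 4,084,101 candidates; the
    first is (-1, -1, -1, -1, -1).
    """
    vals = grid_values(precision, bounds)
    for combo in itertools.product(vals, repeat=5):
        yield np.array(combo)


def n_grid_candidates(precision: float = 0.1, bounds=(-1.0, 1.0)) -> int:
    return len(grid_values(precision, bounds)) ** 5


def _cutoff_labels(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """High-risk-below labels at each candidate's own mean and median."""
    means = B.mean(axis=0, keepdims=True)
    medians = np.median(B, axis=0, keepdims=True)
    return (B < means), (B < medians)


def _wald_p(coef, se):
    with np.errstate(invalid="ignore"):
        return 2.0 * stats.norm.sf(np.abs(coef / se))


def evaluate_candidates(X: np.ndarray, times, events, C: np.ndarray,
                        alpha: float = 0.05, data: _EfronData | None = None):
    """Objective and cutoff HRs for every candidate weight row of ``C``.

    objective = min(HR at mean cut, HR at median cut) when both Wald p-values
    are below ``alpha``, else -inf (degenerate stratifications included).
    Returns (objective, hr_mean, p_mean, hr_median, p_median) arrays.
    """
    if data is None:
        data = _EfronData(times, events)
    B = X @ C.T  # (n, m)
    lab_mean, lab_median = _cutoff_labels(B)
    cm, sm, okm = _batch_cox_binary(times, events, lab_mean, data=data)
    cd, sd, okd = _batch_cox_binary(times, events, lab_median, data=data)
    hr_mean = np.where(okm, np.exp(cm), np.nan)
    hr_median = np.where(okd, np.exp(cd), np.nan)
    p_mean = np.where(okm, _wald_p(cm, sm), np.nan)
    p_median = np.where(okd, _wald_p(cd, sd), np.nan)
    obj = np.full(C.shape[0], -np.inf)
    good = okm & okd & (p_mean < alpha) & (p_median < alpha)
    obj[good] = np.minimum(hr_mean[good], hr_median[good])
    return obj, hr_mean, p_mean, hr_median, p_median


def fold_objective(beta: np.ndarray, times, events, alpha: float = 0.05
                   ) -> tuple[float, SurvivalFit | None, SurvivalFit | None]:
    """Objective for a single beta vector, with the two cutoff fits.

    Degenerate stratifications (an empty group, no convergence) give -inf,
    never an exception.
    """
    beta = np.asarray(beta, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    fits = []
    for cut in (float(np.mean(beta)), float(np.median(beta))):
        g = stratify_at_cutoff(beta, cut, "below")
        if g.sum() == 0 or g.sum() == len(g) or e.sum() == 0:
            fits.append(None)
            continue
        fits.append(binary_cox_hr(t, e, g))
    if any(f is None or not f.converged for f in fits):
        return -np.inf, fits[0], fits[1]
    if all(f.wald_p < alpha for f in fits):
        return float(min(f.hr for f in fits)), fits[0], fits[1]
    return -np.inf, fits[0], fits[1]


def search_fold(train: pd.DataFrame, precision: float = 0.1,
                bounds=(-1.0, 1.0), alpha: float = 0.05,
                chunk_size: int = 50_000) -> GridSearchResult:
    """Exhaustive grid search over weight candidates on one training set.

    Tie-break among equal objectives: larger HR_mean + HR_median sum, then
    lexicographically smallest W (the enumeration order).
    """
    t = train["os_time"].to_numpy(float)
    e = train["event"].to_numpy(int)
    if e.sum() == 0:
        raise ValueError("training set has no events")
    X = train[PROTEINS].to_numpy(float)
    data = _EfronData(t, e)
    vals = grid_values(precision, bounds)
    total = len(vals) ** 5

    best_obj = -np.inf
    best_sum = -np.inf
    best_w = None
    best_fits = (None, None)
    it = itertools.product(vals, repeat=5)
    done = 0
    while done < total:
        chunk = np.array(list(itertools.islice(it, chunk_size)))
        if chunk.size == 0:
            break
        done += len(chunk)
        obj, hrm, pm, hrd, pdn = evaluate_candidates(X, t, e, chunk,
                                                     alpha=alpha, data=data)
        hr_sum = np.where(np.isfinite(obj), hrm + hrd, -np.inf)
        for i in np.flatnonzero(obj > -np.inf):
            if (obj[i] > best_obj
                    or (obj[i] == best_obj and hr_sum[i] > best_sum)):
                # lexicographic order of enumeration settles exact ties
                best_obj, best_sum, best_w = float(obj[i]), float(hr_sum[i]), chunk[i]
                best_fits = (float(hrm[i]), float(hrd[i]))
    if best_w is None:
        raise ValueError("all grid candidates were degenerate or "
                         "non-significant on this training set")
    beta = X @ best_w
    _, fit_mean, fit_median = fold_objective(beta, t, e, alpha=alpha)
    return GridSearchResult(best_weight=best_w, objective_value=best_obj,
                            hr_mean_cut=fit_mean, hr_median_cut=fit_median,
                            candidates_evaluated=total)


class FixedWeightRiskScore(BaseEstimator, TransformerMixin):
    """Risk Score under a fixed weight vector (e.g. the published W*).

    ``fit`` computes beta over the training proteins and stores its
    z-normalization; ``transform`` returns the RS of new patients against the
    training normalization.  ``predict`` labels high risk (1) below the
    chosen cutoff.
    """

    def __init__(self, weights=None, cutoff: str = "mean"):
        self.weights = weights
        self.cutoff = cutoff

    def _proteins(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[PROTEINS].to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(PROTEINS):
            raise ValueError(f"X must have {len(PROTEINS)} protein columns")
        return X

    def _finalize(self, Xp: np.ndarray, w: np.ndarray):
        """Store the weight vector and the training z-normalization."""
        w = np.asarray(w, dtype=float)
        if w.shape != (5,):
            raise ValueError("weights must have 5 components")
        if np.any(np.abs(w) > 1 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")
        rs, params = z_normalize(Xp @ w)
        self.w_star_ = w
        self.znorm_ = params
        self.cutoff_mean_ = 0.0
        self.cutoff_median_ = float(np.median(rs))
        return self

    def fit(self, X, y=None):
        if self.weights is None:
            raise ValueError("weights must be provided")
        return self._finalize(self._proteins(X), self.weights)

    def transform(self, X) -> np.ndarray:
        return self.znorm_.transform(self._proteins(X) @ self.w_star_)

    def predict(self, X) -> np.ndarray:
        cut = self.cutoff_mean_ if self.cutoff == "mean" else self.cutoff_median_
        return stratify_at_cutoff(self.transform(X), cut, "below")

    def get_feature_names_out(self, input_features=None):
        return np.array(["risk_score"])


class RiskScoreCV(FixedWeightRiskScore):
    """Learn the weight vector by per-fold HR-maximizing grid search.

    fit(X, y) expects the protein matrix (or cohort frame) in ``X`` and the
    survival outcome in ``y`` as a (n, 2) array / DataFrame of
    (os_time, event).  The cohort is dealt into ``k`` OS-sorted folds; each
    training set is searched exhaustively; the fold optima W1..Wk are
    averaged into ``w_star_`` and the full-data beta* is z-normalized into
    the Risk Score.  Passing ``injected_fold_weights`` bypasses the search
    (injection mode, used to score with published weights).
    """

    def __init__(self, k: int = 5, precision: float = 0.1,
                 bounds=(-1.0, 1.0), alpha: float = 0.05,
                 injected_fold_weights=None, cutoff: str = "mean"):
        super().__init__(weights=None, cutoff=cutoff)
        self.k = k
        self.precision = precision
        self.bounds = bounds
        self.alpha = alpha
        self.injected_fold_weights = injected_fold_weights

    @staticmethod
    def _survival(y) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(y, pd.DataFrame):
            return y["os_time"].to_numpy(float), y["event"].to_numpy(int)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2): os_time, event")
        return y[:, 0].astype(float), y[:, 1].astype(int)

    def fit(self, X, y):
        Xp = self._proteins(X)
        t, e = self._survival(y)
        frame = pd.DataFrame(Xp, columns=PROTEINS)
        frame["os_time"] = t
        frame["event"] = e
        folds = make_folds(frame, self.k)
        if self.injected_fold_weights is not None:
            fw = np.asarray(self.injected_fold_weights, dtype=float)
            if fw.shape != (self.k, 5):
                raise ValueError(f"injected fold weights must be ({self.k}, 5)")
            self.fold_results_ = None
        else:
            results = []
            for train_idx, _ in train_test_pairs(folds):
                results.append(search_fold(frame.iloc[train_idx],
                                           precision=self.precision,
                                           bounds=self.bounds,
                                           alpha=self.alpha))
            self.fold_results_ = results
            fw = np.vstack([r.best_weight for r in results])
        self.fold_assignment_ = folds
        self.fold_weights_ = fw
        self._finalize(Xp, fw.mean(axis=0))
        # per-Wi and W* full-data evaluation (one row per weight vector)
        rows = []
        for name, w in [*((f"W{i + 1}", fw[i]) for i in range(len(fw))),
                        ("W*", self.w_star_)]:
            beta = Xp @ w
            _, fm, fd = fold_objective(beta, t, e, alpha=self.alpha)
            rows.append({"case": name,
                         **{f"w_{p}": w[j] for j, p in enumerate(PROTEINS)},
                         "hr_mean_cut": fm.hr if fm else np.nan,
                         "p_mean_cut": fm.wald_p if fm else np.nan,
                         "hr_median_cut": fd.hr if fd else np.nan,
                         "p_median_cut": fd.wald_p if fd else np.nan})
        self.full_data_fits_ = pd.DataFrame(rows)
        return self


def run_parameter_optimization(cohort: pd.DataFrame, k: int = 5,
                               precision: float = 0.1,
                               injected_fold_weights=None,
                               alpha: float = 0.05) -> RiskScoreCV:
    """Fit the five-fold grid-search risk-score model on a cohort table."""
    model = RiskScoreCV(k=k, precision=precision, alpha=alpha,
                        injected_fold_weights=injected_fold_weights)
    return model.fit(cohort, cohort[["os_time", "event"]])


def risk_score(cohort: pd.DataFrame, model: FixedWeightRiskScore) -> np.ndarray:
    """RS of a cohort under a fitted model's weights and normalization."""
    return model.transform(cohort)


def serialize_model(model: FixedWeightRiskScore) -> str:
    """Flat text serialization of a fitted risk-score model."""
    lines = ["format = crcrisk-rs-v1"]
    if getattr(model, "fold_weights_", None) is not None:
        for i, row in enumerate(model.fold_weights_):
            lines.append(f"fold_weight_{i + 1} = " + ",".join(f"{v:.10g}" for v in row))
    lines += [
        "w_star = " + ",".join(f"{v:.10g}" for v in model.w_star_),
        f"znorm_center = {model.znorm_.center!r}",
        f"znorm_scale = {model.znorm_.scale!r}",
        f"cutoff_mean = {model.cutoff_mean_!r}",
        f"cutoff_median = {model.cutoff_median_!r}",
    ]
    return "\n".join(lines) + "\n"


def deserialize_model(text: str) -> FixedWeightRiskScore:
    kv = {}
    fold_rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition("=")
        k, v = k.strip(), v.strip()
        if k.startswith("fold_weight_"):
            fold_rows.append([float(x) for x in v.split(",")])
        else:
            kv[k] = v
    if kv.get("format") != "crcrisk-rs-v1":
        raise ValueError("unrecognized model format")
    model = FixedWeightRiskScore(weights=[float(x) for x in kv["w_star"].split(",")])
    model.w_star_ = np.asarray(model.weights, dtype=float)
    model.znorm_ = ZNormParams(center=float(kv["znorm_center"]),
                               scale=float(kv["znorm_scale"]))
    model.cutoff_mean_ = float(kv["cutoff_mean"])
    model.cutoff_median_ = float(kv["cutoff_median"])
    if fold_rows:
        model.fold_weights_ = np.array(fold_rows)
    return model
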