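"""End-to-end analysis orchestration and report artifacts.

``run_analysis`` executes every stage on one cohort — univariate
stratification table (with the composite protein sum/difference factors and
the survivor-vs-deceased t-tests), the six regression baselines, risk-score
fitting (grid search or injected weights), outcome confusion metrics, hybrid
clinical combinations, the multivariate Cox model, and clinical subgroup
stratification — and writes each as a tidy CSV into the output directory.
The pipeline is deterministic given the config (and seed, in synthetic mode).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PROTEINS, read_cohort, summarize_cohort
from .cv import make_folds
from .outcomes import HybridRiskScore, hybrid_risk_score, outcome_report, \
    search_clinical_weights, subgroup_stratify
from .regression import regression_report
from .risk import compute_beta, run_parameter_optimization
from .survival import binary_cox_hr, km_estimate, km_to_frame, \
    multivariate_cox, stratify_at_cutoff, welch_t_test
from .synthetic import default_crc_like_config, generate_cohort

#: univariate factors of the report: label -> column or derived expression
UNIVARIATE_FACTORS = {
    "Age": "age",
    "Bax": "bax",
    "Bak": "bak",
    "Bcl2": "bcl2",
    "BclXL": "bclxl",
    "Mcl1": "mcl1",
    "Bcl2+BclXL+Mcl1+Bax+Bak": ("sum", PROTEINS),
    "Bcl2+BclXL+Mcl1-Bax-Bak": ("anti_minus_pro", None),
}


@dataclass
class AnalysisConfig:
    input_path: str | None = None       # None => synthetic mode
    dialect: str | None = None
    sheet: str | int = 0
    k: int = 5
    precision: float = 1.0              # grid precision of the weight search
    alpha: float = 0.05
    injected_fold_weights: list | None = None  # k rows x 5, bypasses search
    hybrid_features: tuple = ("age",)
    hybrid_weights: dict | None = None  # fixed weights; None => search
    subgroups: tuple = ("age>60", "lvi=yes", "gender=male")
    out_dir: str = "reports"
    seed: int = 0
    synthetic_n: int = 134

    def hash(self) -> str:
        payload = json.dumps(
            {k: (list(map(list, v)) if isinstance(v, (list, tuple)) and k == "injected_fold_weights" and v else v)
             for k, v in sorted(self.__dict__.items())},
            default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _factor_values(cohort: pd.DataFrame, spec) -> np.ndarray:
    if isinstance(spec, str):
        return pd.to_numeric(cohort[spec], errors="coerce").to_numpy(float)
    kind, _ = spec
    X = cohort[PROTEINS].to_numpy(float)
    if kind == "sum":
        return X.sum(axis=1)
    # anti-apoptotic minus pro-apoptotic: (bcl2+bclxl+mcl1) - (bax+bak)
    anti = cohort[["bcl2", "bclxl", "mcl1"]].to_numpy(float).sum(axis=1)
    pro = cohort[["bak", "bax"]].to_numpy(float).sum(axis=1)
    return anti - pro


def univariate_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Median-cutoff stratification HR for each factor (high risk above)."""
    t = cohort["os_time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    rows = []
    for label, spec in UNIVARIATE_FACTORS.items():
        vals = _factor_values(cohort, spec)
        keep = np.isfinite(vals)
        g = stratify_at_cutoff(vals[keep], float(np.median(vals[keep])), "above")
        fit = binary_cox_hr(t[keep], e[keep], g, label=f"{label} > median")
        rows.append({"factor": label, "hr": fit.hr, "ci_low": fit.ci_low,
                     "ci_high": fit.ci_high, "p": fit.wald_p})
    return pd.DataFrame(rows)


def ttest_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Welch t-test per protein: survivors (event 0) vs deceased (event 1)."""
    e = cohort["event"].to_numpy(int)
    rows = []
    for p in PROTEINS:
        x = cohort.loc[e == 0, p].to_numpy(float)
        y = cohort.loc[e == 1, p].to_numpy(float)
        stat, pv = welch_t_test(x, y)
        rows.append({"protein": p, "mean_survived": x.mean(),
                     "mean_deceased": y.mean(), "t": stat, "p": pv})
    return pd.DataFrame(rows)


def _parse_predicate(expr: str):
    """'age>60' / 'lvi=yes' -> (label, callable mask)."""
    if ">" in expr:
        col, val = expr.split(">")
        return expr, lambda c, col=col.strip(), v=float(val): \
            pd.to_numeric(c[col], errors="coerce").to_numpy(float) > v
    col, val = expr.split("=")
    return expr, lambda c, col=col.strip(), v=val.strip(): \
        (c[col] == v).to_numpy()


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline; returns the artifact dict and writes CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"crcrisk {__version__}", f"config_hash {config.hash()}"]

    def stage(name):
        log_lines.append(f"stage {name}")

    if config.input_path is None:
        stage("synthetic cohort")
        cohort = generate_cohort(default_crc_like_config(
            seed=config.seed, n=config.synthetic_n))
    else:
        stage("read cohort")
        cohort = read_cohort(config.input_path, dialect=config.dialect,
                             sheet=config.sheet)
    summary = summarize_cohort(cohort)
    log_lines.append(f"n={summary.n} events={summary.n_events} "
                     f"censored={summary.n_censored}")
    artifacts: dict = {"cohort": cohort}

    stage("univariate table")
    artifacts["table1_univariate"] = univariate_table(cohort)
    artifacts["ttest_panel"] = ttest_table(cohort)

    stage("regression baselines")
    folds = make_folds(cohort, config.k)
    artifacts["table2_regression"] = regression_report(cohort, folds)

    stage("risk score")
    model = run_parameter_optimization(
        cohort, k=config.k, precision=config.precision,
        injected_fold_weights=config.injected_fold_weights,
        alpha=config.alpha)
    artifacts["model"] = model
    artifacts["table3_weights"] = model.full_data_fits_
    rs = model.transform(cohort)
    artifacts["risk_scores"] = pd.DataFrame(
        {"patient_id": cohort["patient_id"], "rs": rs})

    stage("km curves")
    t = cohort["os_time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    km_frames = []
    for cut_name, cut in (("mean", 0.0), ("median", model.cutoff_median_)):
        g = stratify_at_cutoff(rs, cut, "below")
        for lab, mask in (("high", g == 1), ("low", g == 0)):
            if mask.sum():
                km_frames.append(km_to_frame(
                    km_estimate(t[mask], e[mask]), f"RS {cut_name} cut: {lab}"))
    artifacts["km_curves"] = pd.concat(km_frames, ignore_index=True)

    stage("outcome confusion")
    cm = outcome_report(cohort, rs)
    artifacts["confusion_panel"] = pd.DataFrame([{
        "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
        "sensitivity_pct": 100 * cm.sensitivity,
        "specificity_pct": 100 * cm.specificity,
        "accuracy_pct": 100 * cm.accuracy}])

    stage("hybrid combinations")
    base_beta = compute_beta(cohort, model.w_star_)
    hybrid_rows = []
    for feat in config.hybrid_features:
        if feat not in cohort.columns or cohort[feat].isna().all():
            continue
        if config.hybrid_weights and feat in config.hybrid_weights:
            w = config.hybrid_weights[feat]
        else:
            try:
                w, _ = search_clinical_weights(cohort, base_beta, feat,
                                               precision=config.precision,
                                               alpha=config.alpha)
            except ValueError:
                continue
        hmodel = HybridRiskScore(base=model, feature_weights={feat: w}).fit(cohort)
        _, fit_mean, fit_median = hybrid_risk_score(cohort, hmodel)
        hybrid_rows.append({"feature": feat, "weight": json.dumps(w),
                            "hr_mean_cut": fit_mean.hr, "p_mean_cut": fit_mean.wald_p,
                            "hr_median_cut": fit_median.hr,
                            "p_median_cut": fit_median.wald_p})
    artifacts["table4_hybrid"] = pd.DataFrame(hybrid_rows)

    stage("multivariate cox")
    covariates = {"RS<mean": stratify_at_cutoff(rs, 0.0, "below")}
    for col in ("age", "gender", "lvi", "t_stage", "n_stage", "tumor_location"):
        if col in cohort.columns and cohort[col].notna().any():
            covariates[col] = col
    fits = multivariate_cox(cohort, covariates)
    artifacts["multivariate"] = pd.DataFrame(
        [{"covariate": f.label, "hr": f.hr, "ci_low": f.ci_low,
          "ci_high": f.ci_high, "p": f.wald_p} for f in fits])

    stage("subgroups")
    sub_rows = []
    for expr in config.subgroups:
        label, pred = _parse_predicate(expr)
        try:
            _, lr, fit = subgroup_stratify(cohort, pred, rs, 0.0)
        except (ValueError, KeyError):
            continue
        sub_rows.append({"subgroup": label, "hr": fit.hr, "p": fit.wald_p,
                         "logrank_p": lr.p, "n": fit.n_high + fit.n_low})
    artifacts["subgroups"] = pd.DataFrame(sub_rows)

    for name in ("table1_univariate", "ttest_panel", "table2_regression",
                 "table3_weights", "risk_scores", "km_curves",
                 "confusion_panel", "table4_hybrid", "multivariate",
                 "subgroups"):
        df = artifacts[name]
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = log_lines
    return artifacts


def config_from_toml(path: str | Path) -> AnalysisConfig:
    """Load a flat TOML config file."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = AnalysisConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    if cfg.precision not in (1, 1.0, 0.5, 0.2, 0.1):
        raise ValueError("precision must be one of 1, 0.5, 0.2, 0.1")
    return cfg
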