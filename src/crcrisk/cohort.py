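"""Patient cohort tables: reading, validation, summaries, z-normalization.

A cohort is held as a :class:`pandas.DataFrame` with canonical column names.
Mandatory columns are the five Bcl-2 family protein concentrations (nM), the
overall survival time (months) and the event indicator (1 = death/recurrence,
0 = censored).  Clinical covariates (age, gender, lymphovascular invasion,
T/N stage, tumor location) are optional and may contain missing values;
operations that need them delete rows listwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical protein column order (pro-apoptotic Bak/Bax, anti-apoptotic rest)
PROTEINS = ["bak", "bax", "bcl2", "bclxl", "mcl1"]

REQUIRED_COLUMNS = ["patient_id", *PROTEINS, "os_time", "event"]

CLINICAL_COLUMNS = ["age", "gender", "lvi", "t_stage", "n_stage", "tumor_location"]

CATEGORY_LEVELS = {
    "gender": ["female", "male"],
    "lvi": ["no", "yes"],
    "t_stage": ["T2&3", "T4"],
    "n_stage": ["N1", "N2"],
    "tumor_location": ["left", "right", "rectal"],
}

#: reference level per categorical covariate (first level above)
REFERENCE_LEVELS = {k: v[0] for k, v in CATEGORY_LEVELS.items()}

# Accepted header spellings, lower-cased and stripped of separators.
COLUMN_ALIASES = {
    "patientid": "patient_id", "patient": "patient_id", "id": "patient_id",
    "sample": "patient_id", "sampleid": "patient_id",
    "bak": "bak", "bax": "bax",
    "bcl2": "bcl2", "bcl2conc": "bcl2",
    "bclxl": "bclxl", "bcl2l1": "bclxl", "bclx": "bclxl",
    "mcl1": "mcl1",
    "ostime": "os_time", "os": "os_time", "overallsurvival": "os_time",
    "survivaltime": "os_time", "osmonths": "os_time",
    "event": "event", "status": "event", "censor": "event", "death": "event",
    "age": "age", "gender": "gender", "sex": "gender",
    "lvi": "lvi", "lymphovascularinvasion": "lvi",
    "tstage": "t_stage", "t": "t_stage",
    "nstage": "n_stage", "n": "n_stage",
    "tumorlocation": "tumor_location", "location": "tumor_location",
    "tumourlocation": "tumor_location", "sidedness": "tumor_location",
}


class CohortError(ValueError):
    """Raised on schema or validation problems in a cohort table."""


@dataclass(frozen=True)
class ZNormParams:
    """Affine z-normalization parameters: ``z = (x - center) / scale``."""

    center: float
    scale: float

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.center


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_events: int
    n_censored: int
    protein_stats: pd.DataFrame  # index: protein, columns: mean/median/sd


def _canonical_name(raw: str) -> str | None:
    key = "".join(ch for ch in str(raw).lower() if ch.isalnum())
    return COLUMN_ALIASES.get(key)


def _normalize_category(col: str, value):
    if pd.isna(value):
        return np.nan
    s = str(value).strip().lower()
    if col == "gender":
        return {"m": "male", "male": "male", "f": "female", "female": "female"}.get(s, s)
    if col == "lvi":
        return {"y": "yes", "yes": "yes", "1": "yes", "n": "no", "no": "no", "0": "no"}.get(s, s)
    if col == "t_stage":
        return {"t2&3": "T2&3", "t23": "T2&3", "t2": "T2&3", "t3": "T2&3", "t4": "T4"}.get(s, value)
    if col == "n_stage":
        return {"n1": "N1", "n2": "N2"}.get(s, value)
    if col == "tumor_location":
        return s
    return value


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a canonical-column cohort frame; returns it unchanged.

    Raises :class:`CohortError` naming the first violated invariant.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CohortError(f"missing required column: {col!r}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortError(f"duplicate patient_id: {dup!r}")
    for col in PROTEINS + ["os_time"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            raise CohortError(
                f"non-numeric or non-finite value in column {col!r} at row "
                f"{int(np.flatnonzero(bad.to_numpy())[0])}"
            )
    if len(df) and (df[PROTEINS].to_numpy(dtype=float) < 0).any():
        raise CohortError("negative protein concentration")
    if len(df) and (df["os_time"].to_numpy(dtype=float) <= 0).any():
        raise CohortError("os_time must be positive")
    if not df["event"].isin([0, 1]).all():
        raise CohortError("event must be 0 or 1")
    for col, levels in CATEGORY_LEVELS.items():
        if col in df.columns:
            obs = df[col].dropna()
            bad = ~obs.isin(levels)
            if bad.any():
                raise CohortError(
                    f"column {col!r} contains unknown level {obs[bad].iloc[0]!r}; "
                    f"expected one of {levels}"
                )
    return df


def read_cohort(path: str | Path, dialect: str | None = None,
                sheet: str | int = 0) -> pd.DataFrame:
    """Read a cohort table from CSV/TSV or an XLSX sheet.

    Header names are mapped to the canonical schema through the alias table
    (case- and separator-insensitive); unknown columns are kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv")
    if dialect == "csv":
        raw = pd.read_csv(path)
    elif dialect == "tsv":
        raw = pd.read_csv(path, sep="\t")
    elif dialect == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    renames = {}
    for c in raw.columns:
        canon = _canonical_name(c)
        if canon is not None and canon not in renames.values():
            renames[c] = canon
    df = raw.rename(columns=renames)
    if "patient_id" not in df.columns:
        df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(len(df))])
    for col in PROTEINS + ["os_time", "age"]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "event" in df.columns:
        df["event"] = pd.to_numeric(df["event"], errors="coerce").astype("Int64")
    for col in CATEGORY_LEVELS:
        if col in df.columns:
            df[col] = df[col].map(lambda v, c=col: _normalize_category(c, v))
    df["patient_id"] = df["patient_id"].astype(str)
    validate_cohort(df)
    df["event"] = df["event"].astype(int)
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Canonical CSV serialization (round-trips through :func:`read_cohort`)."""
    cols = [c for c in REQUIRED_COLUMNS + CLINICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def summarize_cohort(df: pd.DataFrame) -> CohortSummary:
    """Counts and per-protein moments. sd is NaN for a single-patient cohort."""
    if len(df) == 0:
        raise CohortError("empty cohort")
    n = len(df)
    n_events = int((df["event"] == 1).sum())
    stats = pd.DataFrame({
        "mean": df[PROTEINS].mean(),
        "median": df[PROTEINS].median(),
        "sd": df[PROTEINS].std(ddof=1),  # NaN when n == 1, never fabricated
    })
    return CohortSummary(n=n, n_events=n_events, n_censored=n - n_events,
                         protein_stats=stats)


def z_normalize(values) -> tuple[np.ndarray, ZNormParams]:
    """Center and scale to mean 0 / unit sample standard deviation (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise CohortError("z-normalization needs at least 2 values")
    center = float(np.mean(x))
    scale = float(np.std(x, ddof=1))
    if scale == 0.0 or not np.isfinite(scale):
        raise CohortError("degenerate dispersion: constant vector")
    params = ZNormParams(center=center, scale=scale)
    return params.transform(x), params
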