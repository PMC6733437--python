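# crcrisk

Survival risk stratification for stage III colorectal cancer (CRC) from the
concentrations of five Bcl-2 family proteins — pro-apoptotic **Bak** and
**Bax**, anti-apoptotic **Bcl2**, **BclXL** and **Mcl1** — measured in nM
(e.g. by reverse-phase protein array on FFPE tumour samples). The package is
aimed at biostatisticians and computational biologists who want a tested,
scriptable re-implementation of the hazard-ratio-maximizing "Risk Score"
analysis for such apoptosis-panel cohorts, together with the surrounding
survival statistics, regression baselines, outcome classification and hybrid
clinical scoring.

## The model

For patient *j* with protein concentration row *X<sub>j</sub>* and a weight
vector *W* = (w<sub>Bak</sub>, w<sub>Bax</sub>, w<sub>Bcl2</sub>,
w<sub>BclXL</sub>, w<sub>Mcl1</sub>), each w<sub>k</sub> ∈ [−1, 1], the raw
score is the inner product

> β<sub>j</sub> = X<sub>j</sub> W<sup>T</sup>

Patients are dealt into five folds by ascending overall survival (OS) time
(round-robin, deterministic). On each training set the full one-decimal
Cartesian grid over W (21⁵ = 4,084,101 candidates) is searched exhaustively
for the vector maximizing the Cox proportional-hazards hazard ratio (HR) of
the "β below cutoff" stratification, evaluated at both the mean and the
median of β; a candidate is admissible only when both Wald p-values are
below 0.05, and its objective is min(HR<sub>mean</sub>, HR<sub>median</sub>).
The five fold optima W₁…W₅ are averaged componentwise into **W\***, and the
z-normalized β\* is the **Risk Score (RS)**: mean cutoff 0, median cutoff
stored from the training cohort. Low RS (high anti-apoptotic burden) means
**high risk**; RS ≥ 0 predicts a favorable outcome. A hybrid score
RS<sub>H</sub> adds weighted clinical features (e.g. age with weight −0.2) to
β\* before z-normalization. Cox fits use the Efron tie convention
throughout; the candidate evaluation is a vectorized Newton solver batched
across grid candidates, cross-checked against lifelines.

## Worked example

Cohort tables are CSV/TSV/XLSX with one row per patient. Header names are
matched case- and separator-insensitively through an alias table:
`Bcl-XL`/`BCL2L1` → `bclxl`, `Bcl-2` → `bcl2`, `Mcl-1` → `mcl1`,
`OS`/`survival_time` → `os_time`, `status`/`censor` → `event`,
`sex` → `gender`, `lymphovascular_invasion` → `lvi`, `T`/`N` → `t_stage` /
`n_stage`, `location`/`sidedness` → `tumor_location`. Proteins, `os_time`
(months) and `event` (1 = death/recurrence, 0 = censored) are mandatory;
clinical covariates may be missing.

```sh
$ crcrisk synth --n 134 --seed 1 --out cohort.csv
wrote 134 patients to cohort.csv

$ crcrisk fit-rs --input cohort.csv --precision 0.5 --k 5 --out model.txt
W* = (0.00, 0.10, -0.50, -0.80, -0.70); median RS cutoff = 0.185

$ crcrisk score --input cohort.csv --model model.txt --out scores.csv
scored 134 patients; 54 high risk

$ crcrisk predict-single --input cohort.csv --protein bclxl \
      --concentration 45 --n-bins 5
bclxl = 45.0 nM -> 55.9% risk
```

The fitted weight vector puts its large negative components on the
anti-apoptotic proteins (here BclXL −0.80, Mcl1 −0.70): a patient with high
anti-apoptotic concentrations gets a low score, lands below the RS cutoff,
and is called high risk. `scores.csv` lists per-patient RS and the
high/low-risk group at the mean cutoff (RS < 0). The single-protein
predictor answers the same question from one concentration only, via a
binned linear model of the probability of below-median survival.

The same operations are available as a library, sklearn-style:

```python
from crcrisk import RiskScoreCV, generate_cohort, default_crc_like_config

cohort = generate_cohort(default_crc_like_config(seed=1))
model = RiskScoreCV(precision=0.5).fit(cohort, cohort[["os_time", "event"]])
rs = model.transform(cohort)              # z-scored risk score
high_risk = model.predict(cohort)         # 1 = RS below the mean cutoff
print(model.fold_weights_, model.w_star_)
```

`crcrisk report --config analysis.toml` runs everything — univariate table,
Welch t-tests, six cross-validated regression baselines, the weight search
(or injection of known fold weights), outcome confusion metrics, hybrid
combinations, multivariate Cox and subgroup stratification — and writes each
artifact as a tidy CSV.

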