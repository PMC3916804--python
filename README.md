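# quantpk

Quantitative LC-MS/MS bioanalysis and mouse pharmacokinetics in one
package: calibration-curve back-calculation, regulatory method-validation
statistics, and non-compartmental PK analysis with dose-normalised oral
bioavailability — plus a ground-truthed synthetic-data generator so the
entire chain is testable without any instrument data.

## Who this is for

Bioanalytical scientists and DMPK groups who quantify small molecules in
blood by MRM LC-MS/MS and need the numbers a validation report and a PK
study report contain: per-level accuracy and precision of calibration
standards and quality controls, extraction recovery, matrix factors,
stability panels, cross-matrix validation, and the NCA parameter set
(λz, t½, AUC, CL, Vz, Vss, F) for concentration–time profiles.

## The models

**Calibration.** Instrument response *y* (analyte/internal-standard peak
area ratio) is related to concentration *x* (ng/ml) by the log-log
quadratic (Wagner) curve

```
ln(y) = a (ln x)² + b (ln x) + c
```

fitted by ordinary least squares in (ln x, ln y) space. Back-calculation
solves the quadratic for ln x and keeps the root on the strictly
increasing branch (2a·ln x + b > 0), which is unique because fits that
are not monotone over [LLOQ, ULOQ] are rejected. A straight line in
log-log space (a = 0) and a plain linear model are available.

**Validation statistics.** Accuracy is the mean as percent of nominal
(%Nom), bias is %Nom − 100, precision is the sample-SD coefficient of
variation (%CV). Extraction recovery is 100 × mean(extracted areas) /
mean(reference areas). The internal-standard-normalised matrix factor
(IS-MF) is each matrix lot's area ratio divided by the mean matrix-free
area ratio; reproducibility requires %CV(IS-MF) ≤ 15%. Stability is
judged as percent of a fresh reference, bias against nominal, or
end-vs-start percent difference, all at ±15%.

**NCA.** λz comes from log-linear regression over the terminal window
that maximises adjusted r² (≥ 3 points strictly after Tmax); AUC/AUMC by
linear or linear-up/log-down trapezoid, extrapolated by C_last/λz. For
IV dosing CL = Dose/AUC₀₋∞, Vz = CL/λz, Vss = CL·MRT. Oral
bioavailability is the dose-normalised AUC ratio

```
F (%) = 100 × (AUC_po / D_po) / (AUC_iv / D_iv)
```

Internal units are minutes, µmol/l and µmol/kg; reports use the field's
conventions (t½ and Tmax in h, Cmax in µM, CL in ml/min/kg, V in l/kg).

## Worked example

```python
from quantpk import (AssayTruth, PKTruth, RunConfig, default_study_arms,
                     fit_calibration, make_batch, run_nca, simulate_study)

# a synthetic validation batch: standards 3.910-1000 ng/ml in duplicate,
# seven QC levels in six-fold, blanks, double blanks, SPVS
truth = AssayTruth(analyte_noise_cv=3.0, is_noise_cv=2.0, seed=11)
batch = make_batch(truth, batch_id="val1")
fit = fit_calibration(batch)
print(f"calibration: ln(y) = {fit.coeff_a:+.4f}(ln x)^2 {fit.coeff_b:+.4f} ln x "
      f"{fit.coeff_c:+.4f},  r^2 = {fit.r_squared:.4f}")

# a four-arm PK study (oral 40/20, IV 5/2.5 mg/kg; n=5 mice, 15% CV)
base = PKTruth(residual_cv=15.0, f_true=0.25, seed=11)
study = simulate_study(default_study_arms(base), n_animals=5, seed=11)
summary = run_nca(RunConfig(), profiles=[p for arm in study.values() for p in arm])
for row in summary["bioavailability"]:
    print(f"F = {row['f_pct']:.1f}%  (oral {row['dose_oral_mg_per_kg']:g} mg/kg "
          f"vs IV {row['dose_iv_mg_per_kg']:g} mg/kg)")
```

prints

```
calibration: ln(y) = -0.0070(ln x)^2 +1.0682 ln x -6.1657,  r^2 = 0.9998
F = 22.4%  (oral 40 mg/kg vs IV 5 mg/kg)
F = 26.6%  (oral 20 mg/kg vs IV 2.5 mg/kg)
```

The fitted coefficients recover the generating curve (a = −0.01,
b = 1.1) through 3% area noise; the estimated F values scatter around
the generating 25% — the sparse 8-point sampling schedule slightly
underestimates the oral AUC because the absorption peak falls between
sample points (see `docs/methods.md`).

The same stages are available from the shell:

```sh
quantpk simulate-batch --seed 3 --n-batches 3 --out-dir data/
quantpk validate data/batch*.csv --out-dir report/
quantpk simulate-study --seed 5 --out-dir study/
quantpk nca study/*.csv --out-dir nca/
quantpk bioavailability --auc-oral 287 --dose-oral 40 --auc-iv 222 --dose-iv 5
```

`validate` exits 0 on acceptance, 2 when the assay fails its limits.

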