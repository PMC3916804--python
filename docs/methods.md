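# Methods

## Calibration model

The response model is quadratic in log-log space:
ln(y) = a(ln x)² + b(ln x) + c, with x the nominal concentration
(ng/ml) and y the instrument response — by default the analyte/IS peak
area ratio, since ratio-based quantification cancels extraction and
ionisation variability shared with the internal standard. The model is
linear in (a, b, c), so fitting is ordinary least squares on
(ln x, ln y); r² is the coefficient of determination **in that fitting
space**. (Whether a validation report's printed r² was computed in
transformed or raw space is rarely stated; transformed-space r² is the
quantity the fit actually optimises, so that is what we report.)

Weighting defaults to none: the log transform already stabilises the
multiplicative variance that motivates 1/x or 1/x² weighting in linear
fits. Both weights remain available (`weighting="1/x"` / `"1/x2"`).

**Monotonicity.** A usable calibration must be strictly increasing over
[LLOQ, ULOQ]. The derivative d ln y/d ln x = 2a·ln x + b is linear in
ln x, so positivity at the two range endpoints is necessary and
sufficient; violating fits are rejected at fit time, never silently
inverted.

**Back-calculation.** Solving a·u² + b·u + (c − ln y) = 0 for
u = ln x, the monotone-increasing branch corresponds to
2a·u + b = +√disc, which identifies the root uniquely. For b ≥ 0 the
textbook root (−b + √disc)/(2a) suffers catastrophic cancellation as
a → 0; we use the algebraically identical product-of-roots form
u = 2(ln y − c)/(b + √disc), which is stable and continuous with the
a = 0 line. |a| < 1e-12 falls back to the exact linear solution.
Back-calculated values outside [LLOQ, ULOQ] are **flagged, not
rejected**: dilution QCs legitimately exceed the ULOQ before the
record's `dilution_factor` is applied.

## Validation statistics

All statistics are pure reductions with no hidden state; every
pass/fail flag is the stated inequality on the reported numbers.

- %CV uses the sample (n−1) standard deviation, the convention in
  bioanalytical reporting.
- %Nom = 100·mean/nominal and %Bias = %Nom − 100 exactly, so the two
  columns of any report table are mutually redundant by construction.
- Acceptance limits default to ±15% with ±20% at the LLOQ (the usual
  regulatory convention); all limits live in `RunConfig`, never in code.
- The batch acceptance roll-up (fraction of QCs within limits ≥ 67%
  overall and ≥ 50% per level) is a configurable, flag-only rule;
  guidelines phrase this rule in several ways and the analyst owns the
  final judgement.
- Stock-solution stability compares **raw peak areas** of stored vs
  freshly prepared stocks (after the stated dilution), not
  concentrations — stock tests precede any calibration.
- Cross-matrix validation reports a breach of the 15% limit in its
  `accept` column rather than raising: guidance explicitly allows wider
  limits "if justified", so the breach is surfaced, not adjudicated.
- Printed tables round half-up to 1 decimal (`round_half_up` operates
  on the shortest decimal representation so that a tie like 1.15
  rounds to 1.2 despite binary floating point); all internal
  computation is full precision.

## Non-compartmental analysis

Internal units are minutes, µmol/l and µmol/kg (concentration ng/ml ÷
MW = µmol/l; dose mg/kg × 1000 ÷ MW = µmol/kg); report units convert
at the boundary (h, µM, min·µmol/l, ml/min/kg, l/kg).

**BLQ rules.** Values below the LLOQ before Tmax count as 0; BLQ
embedded between positive points are excluded; trailing BLQ are
excluded. NCA results are therefore invariant to appending BLQ points
after the last positive observation.

**Time-zero anchoring.** When the first sample is after t = 0, IV
profiles are anchored at a log-back-extrapolated C(0) from the first
two declining points (falling back to the first observed value for a
rising pair), and extravascular profiles at C(0) = 0. Without the IV
anchor the first 5 minutes of a bolus profile — about 2.5% of the AUC
at ke = 0.005/min — would be silently dropped.

**λz window.** Auto selection searches every window that ends at the
last positive point, starts strictly after Tmax and has ≥ 3 points,
maximising adjusted r² with ties broken toward more points; windows
with non-declining slope are inadmissible. An explicit (start, stop)
override exists so a reported value can be chased. When no admissible
window exists (a noisy subject whose observed maximum falls late), the
subject is reported as not estimable rather than forced.

**AUC.** Linear trapezoid is the default; linear-up/log-down is exact
on exponentially declining segments and is preferred when integrating
sparse mono-exponential decay. AUC₀₋∞ = AUC_last + C_last/λz;
AUMC₀₋∞ = AUMC_last + C_last·t_last/λz + C_last/λz².

**Disposition parameters.** CL, Vz and Vss are computed for IV dosing
only; for oral routes they are absent with a reason code, because only
CL/F and Vz/F are identifiable without an IV reference. The apparent
oral t½ is reported from the oral profile's own λz, acknowledging
possible flip-flop kinetics (absorption slower than elimination) —
documented, not "corrected". Vz = CL/λz is what a report's "Vd" is
taken to mean here; the identity Vz = CL·t½/ln 2 holds exactly under
that reading.

## Synthetic data

The assay generator emulates a regulatory validation batch: standards
3.910–1000 ng/ml in duplicate, seven QC levels (3.909–800.0 ng/ml) in
six-fold, a 1600 ng/ml dilution QC (factor 2), six blanks, two double
blanks and three SPVS at the mid QC level. Analyte area =
recovery × lot effect × exp(a(ln x)² + b ln x + c) × mean-one lognormal
noise; IS area = nominal IS area × its lot effect × noise. Blanks carry
additive baseline noise in both channels; double blanks have no IS
channel entry at all. Defaults: curve (a, b, c) = (−0.01, 1.1, 7.3)
giving a realistic MRM dynamic range (≈5×10³ counts at LLOQ to
≈1.5×10⁶ at ULOQ), analyte noise CV 5% and IS 3% (the middle of the
0.6–10.8% per-level precision a validated assay shows), extraction
recovery 0.737, matrix-lot lognormal scale 0.05 with analyte/IS
correlation 0.8 — IS normalisation only cancels the correlated part,
which is exactly what makes the IS-MF experiment informative.

The PK generator is a one-compartment model: IV bolus
C(t) = (D/V)e^(−ke·t); first-order oral absorption
C(t) = F·D·ka/(V(ka−ke))·(e^(−ke·t) − e^(−ka·t)), degenerate (and
rejected) at ka = ke. Defaults ke = 0.005/min (t½ ≈ 2.3 h), V = 9 l/kg,
ka = 0.02/min, F = 0.25, MW = 504.85 g/mol are plausible magnitudes for
a lipophilic small molecule; the study design is oral 40/20 mg/kg and
IV 5/2.5 mg/kg, n = 5 animals per arm, sampled at 5 min (IV) or 10 min
(PO) and then 0.5, 1, 3, 5, 7, 12 and 24 h, with LLOQ censoring at
3.910 ng/ml and multiplicative lognormal residuals.

What the generator does **not** emulate: chromatographic drift and
carry-over kinetics, integration errors, two-compartment or
transit-absorption kinetics, between-animal parameter variability
(residual noise only), and blood/plasma partitioning. Passing closure
tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to every pathology of real data.

**Known sampling bias.** On the sparse 8-point schedule the oral
absorption peak (≈92 min at the default ka/ke) falls between the 60 and
180 min samples, so the trapezoid underestimates the oral AUC and hence
F by roughly 3–4% relative (estimated F ≈ 24.2% for a generating 25%).
This is a property of the design, not the estimator; the Monte-Carlo
reference interval for the noisy-study closure test
(`tests/data/f_recovery_mc.json`, central 99% of 400 independent
replicates at n = 5, 15% CV) is computed under exactly these
conditions and captures it.

## Problem sizes

Tests and the acceptance script run at desk scale: batches of 77
records, three batches per validation run, studies of 4 arms × 5
animals × 8 samples, dense grids of 1440 points for closed-form AUC
checks, 150-replicate noise-calibration sweeps, and a 400-replicate
Monte-Carlo reference run (regenerable via
`scripts/make_mc_fixture.py`). The full suite completes in a few
seconds.

## Limitations

- The calibration family is the log-log quadratic and its reductions;
  4PL/5PL response models are out of scope.
- Raw chromatogram handling (peak detection/integration, vendor or
  mzML files) is out of scope; inputs are integrated peak areas.
- No population PK, compartmental fitting to data, protein binding or
  allometric scaling.
- Incurred-sample reanalysis and inter-laboratory designs are not
  implemented.
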