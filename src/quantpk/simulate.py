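"""Ground-truthed synthetic data for every stage of the pipeline.

Two generators, each parameterised by an explicit "truth" record so
that estimators can be closed against the values that generated their
inputs:

* :func:`make_batch` emulates an MRM quantification batch — duplicate
  calibration standards over 3.910-1000 ng/ml, seven QC levels in
  six-fold plus a dilution QC, blanks, double blanks and system
  performance verification samples — with multiplicative lognormal
  area noise and correlated matrix-lot effects on analyte and internal
  standard.
* :func:`simulate_profile` / :func:`simulate_study` emulate
  one-compartment blood kinetics at the study doses (40/20 mg/kg oral,
  5/2.5 mg/kg IV; n=5 mice per arm) with multiplicative residual error
  and LLOQ censoring.

All randomness flows from the truth record's seed through
``numpy.random.default_rng``; identical truths give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .records import BatchRecord, ConcTimeProfile, QuantpkError, Role, Route

__all__ = [
    "AssayTruth",
    "PKTruth",
    "BatchDesign",
    "DEFAULT_BATCH_DESIGN",
    "IV_SAMPLING_MIN",
    "PO_SAMPLING_MIN",
    "make_batch",
    "make_matrix_effect_set",
    "simulate_profile",
    "simulate_study",
    "default_study_arms",
    "StudyArm",
]

#: Sampling schedules in minutes: first sample 5 min (IV) / 10 min (PO)
#: after dosing, then 0.5, 1, 3, 5, 7, 12 and 24 h.
IV_SAMPLING_MIN: Tuple[float, ...] = (5, 30, 60, 180, 300, 420, 720, 1440)
PO_SAMPLING_MIN: Tuple[float, ...] = (10, 30, 60, 180, 300, 420, 720, 1440)

#: Calibration-standard nominal ladder, ng/ml (gravimetric serial
#: dilution from the 1000 ng/ml ULOQ, taken verbatim, not an exact 2x).
STD_NOMINALS: Tuple[float, ...] = (
    3.910, 7.821, 15.64, 31.28, 62.57, 125.0, 250.0, 500.2, 1000.0
)
STD_LABELS = ("STD B", "STD C", "STD D", "STD E", "STD F",
              "STD G", "STD H", "STD I", "STD J")

#: QC nominal ladder, ng/ml (LLOQ through high).
QC_NOMINALS: Tuple[float, ...] = (3.909, 10.01, 20.01, 60.03, 160.1, 400.2, 800.0)
QC_LABELS = ("QC A", "QC B", "QC C", "QC D", "QC E", "QC F", "QC G")


def _cv_to_sigma(cv_pct: float) -> float:
    """Lognormal shape parameter for a mean-one factor with the given CV."""
    if cv_pct < 0:
        raise QuantpkError("noise CV must be >= 0")
    return math.sqrt(math.log1p((cv_pct / 100.0) ** 2))


def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size=None):
    """Mean-one multiplicative lognormal noise factor(s)."""
    if cv_pct == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = _cv_to_sigma(cv_pct)
    z = rng.standard_normal(size)
    return np.exp(sigma * z - 0.5 * sigma * sigma)


@dataclass(frozen=True)
class AssayTruth:
    """Generating parameters of the synthetic MRM assay.

    ``coeff_a/b/c`` define the generating response curve
    exp(a (ln x)^2 + b ln x + c) in analyte-area units; the defaults
    give LLOQ areas of a few thousand counts rising to ~1.5 million at
    the ULOQ, a realistic MRM dynamic range.  Noise CVs default to the
    middle of the precision range a validated assay shows (analyte 5%,
    IS 3%).  ``recovery_true`` is the extraction efficiency applied to
    extracted analyte areas; ``matrix_lot_sigma`` is the lognormal
    scale of per-lot suppression/enhancement factors and
    ``lot_correlation`` how strongly the analyte and IS factors move
    together (IS normalisation only cancels the correlated part).
    """

    coeff_a: float = -0.01
    coeff_b: float = 1.1
    coeff_c: float = 7.3
    response_basis: str = "area_ratio"
    analyte_noise_cv: float = 5.0  # %
    is_noise_cv: float = 3.0  # %
    is_nominal_area: float = 540000.0
    matrix_lot_sigma: float = 0.05
    lot_correlation: float = 0.8
    recovery_true: float = 0.737
    blank_baseline_sd: float = 50.0  # additive area counts on blanks
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.recovery_true <= 1):
            raise QuantpkError("recovery_true must lie in (0, 1]")
        if self.analyte_noise_cv < 0 or self.is_noise_cv < 0:
            raise QuantpkError("noise CVs must be >= 0")
        lo, hi = math.log(min(STD_NOMINALS)), math.log(max(STD_NOMINALS))
        for u in (lo, hi):
            if 2 * self.coeff_a * u + self.coeff_b <= 0:
                raise QuantpkError(
                    "generating curve is not monotone over the design range"
                )

    def curve_area(self, conc) -> np.ndarray:
        """Noise-free analyte area at a concentration (before recovery)."""
        lx = np.log(np.asarray(conc, dtype=float))
        return np.exp(self.coeff_a * lx**2 + self.coeff_b * lx + self.coeff_c)


@dataclass(frozen=True)
class BatchDesign:
    """Composition of one validation batch."""

    std_nominals: Tuple[float, ...] = STD_NOMINALS
    std_labels: Tuple[str, ...] = STD_LABELS
    std_replicates: int = 2
    qc_nominals: Tuple[float, ...] = QC_NOMINALS
    qc_labels: Tuple[str, ...] = QC_LABELS
    qc_replicates: int = 6
    dilution_qc_nominal: Optional[float] = 1600.0
    dilution_qc_label: str = "QC H DIL"
    dilution_factor: float = 2.0
    dilution_qc_replicates: int = 6
    n_blanks: int = 6
    n_double_blanks: int = 2
    n_spvs: int = 3
    spvs_conc: float = 160.1

    def __post_init__(self) -> None:
        if not self.std_nominals and not self.qc_nominals:
            raise QuantpkError("empty batch design")


DEFAULT_BATCH_DESIGN = BatchDesign()


def _lot_factors(rng: np.random.Generator, sigma: float,
                 correlation: float) -> Tuple[float, float]:
    """Correlated lognormal (analyte, IS) lot suppression factors."""
    if sigma == 0:
        return 1.0, 1.0
    z1, z2 = rng.standard_normal(2)
    za = z1
    zi = correlation * z1 + math.sqrt(1.0 - correlation**2) * z2
    return math.exp(sigma * za), math.exp(sigma * zi)


def _spiked_record(truth: AssayTruth, rng: np.random.Generator, *,
                   sample_id: str, batch_id: str, role: Role, label: str,
                   conc: float, nominal: Optional[float], lot: str,
                   lot_a: float, lot_i: float,
                   dilution_factor: float = 1.0,
                   condition_tag: Optional[str] = None,
                   recovery: Optional[float] = None) -> BatchRecord:
    rec_recovery = truth.recovery_true if recovery is None else recovery
    analyte = (
        rec_recovery * lot_a * float(truth.curve_area(conc))
        * float(_lognormal_factor(rng, truth.analyte_noise_cv))
    )
    is_area = (
        truth.is_nominal_area * lot_i
        * float(_lognormal_factor(rng, truth.is_noise_cv))
    )
    return BatchRecord(
        sample_id=sample_id, batch_id=batch_id, role=role,
        level_label=label, nominal_conc=nominal,
        analyte_area=analyte, is_area=is_area, matrix_lot=lot,
        condition_tag=condition_tag, dilution_factor=dilution_factor,
    )


def make_batch(truth: AssayTruth, design: BatchDesign = DEFAULT_BATCH_DESIGN,
               batch_id: str = "batch1", matrix_lot: str = "lot1",
               rng: Optional[np.random.Generator] = None) -> List[BatchRecord]:
    """Generate one validation batch of peak-area records.

    The default design mirrors a regulatory validation batch: the full
    standard ladder in duplicate, seven QC levels in six-fold, a
    six-fold dilution QC above the ULOQ, six blanks, two double blanks
    and three SPVS.  Deterministic for a given truth seed.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    lot_a, lot_i = _lot_factors(rng, truth.matrix_lot_sigma, truth.lot_correlation)
    records: List[BatchRecord] = []

    for label, nominal in zip(design.std_labels, design.std_nominals):
        for rep in range(design.std_replicates):
            records.append(_spiked_record(
                truth, rng, sample_id=f"{batch_id}-{label}-{rep + 1}",
                batch_id=batch_id, role=Role.STD, label=label,
                conc=nominal, nominal=nominal, lot=matrix_lot,
                lot_a=lot_a, lot_i=lot_i,
            ))
    for label, nominal in zip(design.qc_labels, design.qc_nominals):
        for rep in range(design.qc_replicates):
            records.append(_spiked_record(
                truth, rng, sample_id=f"{batch_id}-{label}-{rep + 1}",
                batch_id=batch_id, role=Role.QC, label=label,
                conc=nominal, nominal=nominal, lot=matrix_lot,
                lot_a=lot_a, lot_i=lot_i,
            ))
    if design.dilution_qc_nominal is not None:
        # Measured after dilution into range; the record carries the
        # dilution factor so back-calculation can correct it.
        measured = design.dilution_qc_nominal / design.dilution_factor
        for rep in range(design.dilution_qc_replicates):
            records.append(_spiked_record(
                truth, rng,
                sample_id=f"{batch_id}-{design.dilution_qc_label}-{rep + 1}",
                batch_id=batch_id, role=Role.QC, label=design.dilution_qc_label,
                conc=measured, nominal=design.dilution_qc_nominal,
                lot=matrix_lot, lot_a=lot_a, lot_i=lot_i,
                dilution_factor=design.dilution_factor,
            ))
    for i in range(design.n_blanks):
        # blank: matrix only, neither analyte nor IS spiked; both
        # channels read baseline noise
        records.append(BatchRecord(
            sample_id=f"{batch_id}-BLANK-{i + 1}", batch_id=batch_id,
            role=Role.BLANK,
            analyte_area=abs(rng.normal(0.0, truth.blank_baseline_sd)),
            is_area=abs(rng.normal(0.0, truth.blank_baseline_sd)),
            matrix_lot=matrix_lot,
        ))
    for i in range(design.n_double_blanks):
        records.append(BatchRecord(
            sample_id=f"{batch_id}-DBLANK-{i + 1}", batch_id=batch_id,
            role=Role.DOUBLE_BLANK,
            analyte_area=abs(rng.normal(0.0, truth.blank_baseline_sd)),
            is_area=None, matrix_lot=matrix_lot,
        ))
    for i in range(design.n_spvs):
        records.append(_spiked_record(
            truth, rng, sample_id=f"{batch_id}-SPVS-{i + 1}",
            batch_id=batch_id, role=Role.SPVS, label="SPVS",
            conc=design.spvs_conc, nominal=design.spvs_conc,
            lot=matrix_lot, lot_a=lot_a, lot_i=lot_i,
        ))
    return records


def make_matrix_effect_set(
    truth: AssayTruth, n_lots: int = 10,
    levels: Tuple[float, ...] = (800.0, 10.01),
    n_neat_replicates: int = 6,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[BatchRecord], List[BatchRecord], Dict[str, float]]:
    """With-matrix and matrix-free record sets for the IS-MF experiment.

    Blank matrix from ``n_lots`` sources is "reconstituted" with
    analyte at the given levels plus internal standard; matrix-free
    replicates carry no lot effect.  Samples are spiked after
    extraction, so the extraction recovery does not apply.  Returns the
    two record lists and the true IS-normalised matrix factor per lot
    (analyte lot factor / IS lot factor).
    """
    if n_lots < 1:
        raise QuantpkError("need at least one matrix lot")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    with_matrix: List[BatchRecord] = []
    true_mf: Dict[str, float] = {}
    for k in range(n_lots):
        lot = f"lot{k + 1:02d}"
        lot_a, lot_i = _lot_factors(rng, truth.matrix_lot_sigma,
                                    truth.lot_correlation)
        true_mf[lot] = lot_a / lot_i
        for conc in levels:
            with_matrix.append(_spiked_record(
                truth, rng, sample_id=f"ME-{lot}-{conc:g}", batch_id="ME",
                role=Role.MATRIX_EFFECT, label=f"ME {conc:g}",
                conc=conc, nominal=conc, lot=lot, lot_a=lot_a, lot_i=lot_i,
                condition_tag="with_matrix", recovery=1.0,
            ))
    without_matrix: List[BatchRecord] = []
    for conc in levels:
        for rep in range(n_neat_replicates):
            without_matrix.append(_spiked_record(
                truth, rng, sample_id=f"ME-neat-{conc:g}-{rep + 1}",
                batch_id="ME", role=Role.MATRIX_EFFECT, label=f"ME {conc:g}",
                conc=conc, nominal=conc, lot="neat", lot_a=1.0, lot_i=1.0,
                condition_tag="without_matrix", recovery=1.0,
            ))
    return with_matrix, without_matrix, true_mf


# ---------------------------------------------------------------------------
# Pharmacokinetic simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PKTruth:
    """Generating parameters of a one-compartment blood PK model.

    Defaults are plausible for a lipophilic small molecule with a
    2-4 h half-life and a large volume of distribution: ke such that
    t1/2 ~ 2.3 h, V = 9 l/kg, oral F = 0.25 with first-order
    absorption.  ``residual_cv`` is the multiplicative lognormal
    residual on concentrations (percent).
    """

    model: str = "one_compartment"
    ka: float = 0.02  # 1/min, absorption (PO)
    ke: float = 0.005  # 1/min, elimination
    v: float = 9.0  # l/kg
    f_true: float = 0.25
    dose: float = 40.0  # mg/kg
    mw: float = 504.85  # g/mol
    residual_cv: float = 0.0  # %
    sampling_times: Optional[Tuple[float, ...]] = None  # min; route default if None
    lloq: float = 3.910  # ng/ml
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0 or self.v <= 0:
            raise QuantpkError("rates and volume must be > 0")
        if not (0 < self.f_true <= 1):
            raise QuantpkError("f_true must lie in (0, 1]")
        if self.dose <= 0 or self.mw <= 0:
            raise QuantpkError("dose and mw must be > 0")

    def curve_ng_per_ml(self, times, route: Route) -> np.ndarray:
        """Noise-free blood concentration (ng/ml) at ``times`` minutes."""
        t = np.asarray(times, dtype=float)
        dose_umol = 1000.0 * self.dose / self.mw  # umol/kg
        if route is Route.IV:
            c_um = (dose_umol / self.v) * np.exp(-self.ke * t)
        else:
            if self.ka == self.ke:
                raise QuantpkError(
                    "the oral closed form is degenerate at ka == ke"
                )
            c_um = (
                self.f_true * dose_umol * self.ka
                / (self.v * (self.ka - self.ke))
                * (np.exp(-self.ke * t) - np.exp(-self.ka * t))
            )
        return c_um * self.mw


def simulate_profile(truth: PKTruth, route: Route | str,
                     subject_id: str = "sim1",
                     rng: Optional[np.random.Generator] = None) -> ConcTimeProfile:
    """One animal's concentration-time profile under the truth model.

    Concentrations below the truth LLOQ are censored to 0 (BLQ).
    Deterministic for a given truth seed.
    """
    route = Route(route)
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    times = truth.sampling_times
    if times is None:
        times = IV_SAMPLING_MIN if route is Route.IV else PO_SAMPLING_MIN
    conc = truth.curve_ng_per_ml(times, route)
    conc = conc * np.asarray(
        _lognormal_factor(rng, truth.residual_cv, size=len(times))
    )
    conc = np.where(conc < truth.lloq, 0.0, conc)
    return ConcTimeProfile(
        subject_id=subject_id, route=route, dose=truth.dose, mw=truth.mw,
        times=tuple(times), concentrations=tuple(conc.tolist()),
        lloq=truth.lloq,
    )


@dataclass(frozen=True)
class StudyArm:
    name: str
    route: Route
    truth: PKTruth


def default_study_arms(base: Optional[PKTruth] = None) -> List[StudyArm]:
    """The four-arm crossover-style design: oral 40/20, IV 5/2.5 mg/kg."""
    base = base or PKTruth()
    return [
        StudyArm("PO_high", Route.PO, replace(base, dose=40.0)),
        StudyArm("PO_low", Route.PO, replace(base, dose=20.0)),
        StudyArm("IV_high", Route.IV, replace(base, dose=5.0)),
        StudyArm("IV_low", Route.IV, replace(base, dose=2.5)),
    ]


def simulate_study(arms: Optional[Sequence[StudyArm]] = None,
                   n_animals: int = 5,
                   seed: Optional[int] = None) -> Dict[str, List[ConcTimeProfile]]:
    """Simulate ``n_animals`` profiles per study arm.

    Each animal draws its residuals from an independent stream spawned
    from the study seed (default: the first arm truth's seed), so the
    bundle is reproducible as a whole.
    """
    if arms is None:
        arms = default_study_arms()
    if seed is None:
        seed = arms[0].truth.seed
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(arms) * n_animals)
    study: Dict[str, List[ConcTimeProfile]] = {}
    idx = 0
    for arm in arms:
        profiles = []
        for animal in range(n_animals):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            profiles.append(simulate_profile(
                arm.truth, arm.route,
                subject_id=f"{arm.name}-m{animal + 1}", rng=rng,
            ))
        study[arm.name] = profiles
    return study
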