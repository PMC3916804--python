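"""Stage orchestration: batch validation runs and NCA runs.

These functions tie the modules together the way a study report does:
fit the calibration per batch, back-calculate everything, compute the
validation statistics that the supplied records support, and write
report tables whose columns mirror a standard validation report
(per-level standards, intra/inter-batch QC statistics, recovery,
matrix effect, stability, cross-matrix validation).  The NCA run
produces per-subject and mean-profile parameter tables plus the
dose-normalised bioavailability summary.

Section discovery is tag-driven: records opt into the optional
sections through ``condition_tag`` (``recovery:extracted`` /
``recovery:reference``, ``stability:<condition>`` with
``stability:stock_fresh`` / ``stability:ois_start`` /
``stability:ois_end`` references, ``crossval``) and matrix-effect
records through ``with_matrix`` / ``without_matrix``.
"""

from __future__ import annotations

import json
import logging
import sys
from collections import defaultdict
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationFit,
    check_specificity,
    evaluate_curve,
    fit_calibration,
    record_response,
)
from .config import RunConfig
from .io import read_batch_csv, read_profile_csv
from .nca import NCA, NCAError, bioavailability, mean_profile
from .records import BatchRecord, ConcTimeProfile, QuantpkError, Role, Route
from .validation import (
    StabilityCondition,
    StabilityMode,
    absolute_recovery,
    batch_and_run_statistics,
    cross_validate,
    matrix_factor,
    stability_assessment,
)

__all__ = ["run_validation", "run_nca"]

logger = logging.getLogger("quantpk")

_STOCK_CONDITIONS = {
    StabilityCondition.STOCK_RT,
    StabilityCondition.STOCK_5C,
    StabilityCondition.STOCK_M20C,
}


def _load_batches(batch_files: Sequence[Union[str, Path]]) -> List[BatchRecord]:
    records: List[BatchRecord] = []
    for path in batch_files:
        recs = read_batch_csv(path)
        logger.info("stage=read file=%s records=%d", path, len(recs))
        records.extend(recs)
    return records


def _tag(rec: BatchRecord) -> str:
    return rec.condition_tag or ""


def run_validation(config: RunConfig,
                   batch_files: Sequence[Union[str, Path]] = (),
                   records: Optional[Sequence[BatchRecord]] = None,
                   out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Full validation run over one or more batches of records.

    Returns a summary dict with per-section pass flags; when
    ``out_dir`` is given, writes one CSV per report table plus
    ``summary.json``.
    """
    all_records = list(records) if records is not None else []
    if batch_files:
        all_records.extend(_load_batches(batch_files))
    if not all_records:
        raise QuantpkError("no records supplied to run_validation")

    core = [r for r in all_records if not _tag(r)]
    std = [r for r in core if r.role is Role.STD]
    if not std:
        raise QuantpkError("validation needs at least one batch with standards")

    tables: Dict[str, pd.DataFrame] = {}
    summary: dict = {"sections": {}}

    # --- per-batch calibration fits and back-calculation -------------
    fits: Dict[str, CalibrationFit] = {}
    backcalc: Dict[Tuple[str, str], List[float]] = defaultdict(list)  # QC pools
    std_levels: Dict[Tuple[str, float], List[float]] = defaultdict(list)
    nominals: Dict[str, float] = {}
    batch_ids = sorted({r.batch_id for r in core})
    for batch_id in batch_ids:
        batch_std = [r for r in std if r.batch_id == batch_id]
        if not batch_std:
            logger.warning("stage=calibration batch=%s no standards", batch_id)
            continue
        fit = fit_calibration(
            batch_std, model_kind=config.model_kind,
            response_basis=config.response_basis, weighting=config.weighting,
        )
        fits[batch_id] = fit
        est = fit.to_estimator()
        logger.info("stage=calibration batch=%s r2=%.6f", batch_id, fit.r_squared)
        for rec in core:
            if rec.batch_id != batch_id or rec.role not in (Role.STD, Role.QC):
                continue
            conc = float(est.inverse([record_response(rec, fit.response_basis)])[0])
            conc *= rec.dilution_factor
            label = rec.level_label or f"{rec.nominal_conc:g}"
            nominals[label] = rec.nominal_conc
            if rec.role is Role.STD:
                std_levels[(label, rec.nominal_conc)].append(conc)
            else:
                backcalc[(batch_id, label)].append(conc)

    tables["calibration_fits"] = pd.DataFrame(
        [{"batch": b, **asdict(f)} for b, f in fits.items()]
    )

    from .validation import level_stats as _level_stats

    std_rows = []
    for (label, nominal), values in sorted(std_levels.items(), key=lambda kv: kv[0][1]):
        st = _level_stats(values, nominal)
        std_rows.append({"level": label, "nominal": nominal, "n": st.n,
                         "mean": st.mean, "pct_nom": st.pct_nom,
                         "pct_cv": st.pct_cv, "pct_bias": st.pct_bias})
    tables["calibration_standards"] = pd.DataFrame(std_rows)

    # --- intra/inter-batch QC statistics ------------------------------
    if backcalc:
        lloq_level = min(
            (lvl for (_, lvl) in backcalc), key=lambda lvl: nominals[lvl]
        )
        intra, inter = batch_and_run_statistics(
            backcalc, nominals, limit_pct=config.qc_limit_pct,
            lloq_level=lloq_level, lloq_limit_pct=config.lloq_limit_pct,
        )
        tables["qc_intra_batch"] = intra
        tables["qc_inter_batch"] = inter
        overall_frac = float(intra["accept"].mean()) if len(intra) else 1.0
        per_level_ok = bool(
            (inter.groupby("level")["accept"].mean() >= config.qc_rule_per_level).all()
        )
        summary["sections"]["qc"] = {
            "pass": bool(overall_frac >= config.qc_rule_overall and per_level_ok),
            "fraction_within_limits": overall_frac,
        }

    # --- specificity --------------------------------------------------
    blanks = [r for r in core if r.role is Role.BLANK]
    if blanks and std_levels:
        lloq_nominal = min(n for (_, n) in std_levels)
        lloq_recs = [r for r in std if r.nominal_conc == lloq_nominal]
        rep = check_specificity(
            blanks, lloq_recs,
            analyte_threshold=config.blank_analyte_threshold,
            is_threshold=config.blank_is_threshold,
        )
        tables["specificity"] = pd.DataFrame([
            {"lot": lot,
             "blank_analyte_fraction": rep.analyte_fraction_by_lot[lot],
             "blank_is_fraction": rep.is_fraction_by_lot[lot],
             "analyte_pass": rep.analyte_pass_by_lot[lot],
             "is_pass": rep.is_pass_by_lot[lot]}
            for lot in rep.analyte_fraction_by_lot
        ])
        summary["sections"]["specificity"] = {"pass": rep.all_pass}

    # --- recovery -----------------------------------------------------
    extracted = [r for r in all_records if _tag(r) == "recovery:extracted"]
    reference = [r for r in all_records if _tag(r) == "recovery:reference"]
    if extracted and reference:
        results = absolute_recovery(extracted, reference)
        tables["recovery"] = pd.DataFrame([asdict(r) for r in results])
        summary["sections"]["recovery"] = {
            "mean_recovery_pct": float(np.mean([r.recovery_pct for r in results]))
        }

    # --- matrix effect ------------------------------------------------
    with_m = [r for r in all_records
              if r.role is Role.MATRIX_EFFECT and _tag(r) == "with_matrix"]
    without_m = [r for r in all_records
                 if r.role is Role.MATRIX_EFFECT and _tag(r) == "without_matrix"]
    if with_m and without_m:
        levels = sorted({r.level_label for r in with_m})
        rows = []
        passes = []
        for level in levels:
            res = matrix_factor(
                [r for r in with_m if r.level_label == level],
                [r for r in without_m if r.level_label == level],
                cv_limit_pct=config.mf_cv_limit_pct,
            )
            rows.append({"level": level, "mean_mf": res.mean_mf,
                         "pct_cv_mf": res.pct_cv_mf, "pass": res.passed})
            passes.append(res.passed)
        tables["matrix_effect"] = pd.DataFrame(rows)
        summary["sections"]["matrix_effect"] = {"pass": all(passes)}

    # --- stability ----------------------------------------------------
    stab_rows = []
    stab_recs = [r for r in all_records if _tag(r).startswith("stability:")]
    if stab_recs:
        fresh = [r.analyte_area for r in stab_recs
                 if _tag(r) == "stability:stock_fresh"]
        ois_start = [r for r in stab_recs if _tag(r) == "stability:ois_start"]
        by_cond: Dict[str, List[BatchRecord]] = defaultdict(list)
        for r in stab_recs:
            name = _tag(r).split(":", 1)[1]
            if name in ("stock_fresh", "ois_start"):
                continue
            by_cond[name].append(r)
        first_fit = next(iter(fits.values())) if fits else None
        for name, recs in sorted(by_cond.items()):
            cond = StabilityCondition("on_instrument" if name == "ois_end" else name)
            if cond in _STOCK_CONDITIONS:
                res = stability_assessment(
                    [r.analyte_area for r in recs], StabilityMode.PCT_REFERENCE,
                    cond, reference=fresh, limit_pct=config.stability_limit_pct,
                )
                stab_rows.append({"condition": cond.value, "level": "stock",
                                  "value_pct": res.value, "pct_cv": res.pct_cv,
                                  "mode": res.comparison_mode.value,
                                  "pass": res.passed})
            elif cond is StabilityCondition.ON_INSTRUMENT:
                for nominal in sorted({r.nominal_conc for r in recs}):
                    test = [r for r in recs if r.nominal_conc == nominal]
                    start = [r for r in ois_start if r.nominal_conc == nominal]
                    res = stability_assessment(
                        _backcalc_concs(test, first_fit),
                        StabilityMode.PCT_DIFFERENCE, cond,
                        reference=_backcalc_concs(start, first_fit),
                        limit_pct=config.stability_limit_pct,
                    )
                    stab_rows.append({"condition": cond.value,
                                      "level": f"{nominal:g}",
                                      "value_pct": res.value, "pct_cv": res.pct_cv,
                                      "mode": res.comparison_mode.value,
                                      "pass": res.passed})
            else:
                for nominal in sorted({r.nominal_conc for r in recs}):
                    test = [r for r in recs if r.nominal_conc == nominal]
                    res = stability_assessment(
                        _backcalc_concs(test, first_fit),
                        StabilityMode.PCT_BIAS_VS_NOMINAL, cond,
                        nominal=nominal, limit_pct=config.stability_limit_pct,
                    )
                    stab_rows.append({"condition": cond.value,
                                      "level": f"{nominal:g}",
                                      "value_pct": res.value, "pct_cv": res.pct_cv,
                                      "mode": res.comparison_mode.value,
                                      "pass": res.passed})
        tables["stability"] = pd.DataFrame(stab_rows)
        summary["sections"]["stability"] = {
            "pass": bool(all(r["pass"] for r in stab_rows))
        }

    # --- cross-matrix validation --------------------------------------
    xval = [r for r in all_records if _tag(r) == "crossval"]
    if xval and fits:
        first_fit = next(iter(fits.values()))
        grouped: Dict[str, List[float]] = defaultdict(list)
        xnom: Dict[str, float] = {}
        for r in xval:
            label = r.level_label or f"{r.nominal_conc:g}"
            xnom[label] = r.nominal_conc
            grouped[label].extend(_backcalc_concs([r], first_fit))
        table = cross_validate(grouped, xnom, limit_pct=config.crossval_limit_pct)
        tables["cross_validation"] = table
        summary["sections"]["cross_validation"] = {
            "pass": bool(table["accept"].all())
        }

    summary["pass"] = all(
        sec.get("pass", True) for sec in summary["sections"].values()
    )
    summary["n_records"] = len(all_records)
    summary["batches"] = batch_ids

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("stage=report dir=%s tables=%d", out, len(tables))
    summary["tables"] = tables
    return summary


def _backcalc_concs(recs: Sequence[BatchRecord],
                    fit: Optional[CalibrationFit]) -> List[float]:
    if fit is None:
        raise QuantpkError("stability/cross-validation needs a calibration fit")
    est = fit.to_estimator()
    return [
        float(est.inverse([record_response(r, fit.response_basis)])[0])
        * r.dilution_factor
        for r in recs
    ]


def _nca_row(result) -> dict:
    row = asdict(result)
    row["route"] = result.route.value
    row["lambda_z_window"] = f"{result.lambda_z_window[0]}:{result.lambda_z_window[1]}"
    return row


def run_nca(config: RunConfig,
            profile_files: Sequence[Union[str, Path]] = (),
            profiles: Optional[Sequence[ConcTimeProfile]] = None,
            out_dir: Optional[Union[str, Path]] = None) -> dict:
    """NCA over all profiles, grouped into arms by (route, dose).

    Produces per-subject and mean-profile parameter tables, and a
    bioavailability summary for each oral arm paired with the IV arm
    of the same dose rank (highest with highest, and so on).  With no
    IV arm the bioavailability section is skipped with a logged reason.
    """
    all_profiles = list(profiles) if profiles is not None else []
    for path in profile_files:
        batch = read_profile_csv(path)
        logger.info("stage=read file=%s profiles=%d", path, len(batch))
        all_profiles.extend(batch)
    if not all_profiles:
        raise QuantpkError("no profiles supplied to run_nca")

    arms: Dict[Tuple[str, float], List[ConcTimeProfile]] = defaultdict(list)
    for p in all_profiles:
        arms[(p.route.value, p.dose)].append(p)

    nca = NCA(auc_method=config.auc_method,
              lambda_z_selection=config.lambda_z_selection,
              anchor_time_zero=config.anchor_time_zero)

    subject_rows, mean_rows = [], []
    mean_results: Dict[Tuple[str, float], object] = {}
    for (route, dose), members in sorted(arms.items()):
        for p in members:
            # A noisy profile can lack three declining points after its
            # observed Tmax; report the subject as not estimable.
            try:
                subject_rows.append(_nca_row(nca.fit(p).result_))
            except NCAError as exc:
                logger.warning("stage=nca subject=%s skipped reason=%s",
                               p.subject_id, exc)
                subject_rows.append({"subject_id": p.subject_id,
                                     "route": route, "dose": dose,
                                     "disposition_note": f"not_estimable: {exc}"})
        mp = mean_profile(members)
        res = nca.fit(mp).result_
        mean_results[(route, dose)] = res
        mean_rows.append(_nca_row(res))
        logger.info("stage=nca arm=%s/%g n=%d auc_inf=%.1f",
                    route, dose, len(members), res.auc_inf)

    tables = {
        "nca_subjects": pd.DataFrame(subject_rows),
        "nca_mean": pd.DataFrame(mean_rows),
    }

    po_arms = sorted((d for (r, d) in mean_results if r == "PO"), reverse=True)
    iv_arms = sorted((d for (r, d) in mean_results if r == "IV"), reverse=True)
    f_rows = []
    if po_arms and not iv_arms:
        logger.warning("stage=bioavailability skipped reason=no_iv_arm")
    for dose_po, dose_iv in zip(po_arms, iv_arms):
        res_po = mean_results[("PO", dose_po)]
        res_iv = mean_results[("IV", dose_iv)]
        f = bioavailability(res_po.auc_inf, dose_po, res_iv.auc_inf, dose_iv)
        f_rows.append({
            "dose_oral_mg_per_kg": dose_po, "dose_iv_mg_per_kg": dose_iv,
            "auc_oral": f.auc_oral, "auc_iv": f.auc_iv, "f_pct": f.f_pct,
        })
    if f_rows:
        tables["bioavailability"] = pd.DataFrame(f_rows)

    summary = {
        "arms": {f"{r}/{d:g}": len(m) for (r, d), m in sorted(arms.items())},
        "bioavailability": f_rows,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "nca_summary.json").write_text(json.dumps(summary, indent=2))
    summary["tables"] = tables
    return summary
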