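"""CSV readers and writers for batch and profile data.

Dialect: comma-separated UTF-8 with "." decimals and a header row.
Empty cells mean "absent", which is distinct from 0; concentrations
below the limit of quantification are encoded with the literal token
``BLQ`` (not 0) in profile files, because the BLQ-vs-zero distinction
changes NCA handling.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .records import BatchRecord, ConcTimeProfile, QuantpkError, Role, Route

__all__ = [
    "BATCH_COLUMNS",
    "PROFILE_COLUMNS",
    "read_batch_csv",
    "write_batch_csv",
    "read_profile_csv",
    "write_profile_csv",
]

BATCH_COLUMNS = (
    "sample_id", "batch_id", "role", "level_label", "nominal_conc",
    "analyte_area", "is_area", "matrix_lot", "condition_tag",
    "dilution_factor",
)

PROFILE_COLUMNS = (
    "subject_id", "route", "dose_mg_per_kg", "mw", "time_min",
    "conc_ng_per_ml", "lloq",
)

BLQ_TOKEN = "BLQ"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise QuantpkError(f"{path}: missing required columns {missing}")


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    v = float(value)
    return None if math.isnan(v) else v


def read_batch_csv(path: Union[str, Path]) -> List[BatchRecord]:
    """Read peak-area batch records, validating each row.

    Malformed rows are reported with their file line number; duplicate
    sample ids within a batch are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "batch_id": str},
                     float_precision="round_trip")
    _require_columns(df, ["sample_id", "batch_id", "role", "analyte_area"], path)
    records: List[BatchRecord] = []
    seen = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            key = (str(row["batch_id"]), str(row["sample_id"]))
            if key in seen:
                raise QuantpkError(
                    f"duplicate sample_id {key[1]!r} in batch {key[0]!r}"
                )
            seen.add(key)
            df_factor = _opt_float(row.get("dilution_factor"))
            records.append(BatchRecord(
                sample_id=str(row["sample_id"]),
                batch_id=str(row["batch_id"]),
                role=Role(str(row["role"]).strip()),
                level_label=_opt_str(row.get("level_label")),
                nominal_conc=_opt_float(row.get("nominal_conc")),
                analyte_area=float(row["analyte_area"]),
                is_area=_opt_float(row.get("is_area")),
                matrix_lot=_opt_str(row.get("matrix_lot")),
                condition_tag=_opt_str(row.get("condition_tag")),
                dilution_factor=1.0 if df_factor is None else df_factor,
            ))
        except (ValueError, KeyError) as exc:
            raise QuantpkError(f"{path}, line {line}: {exc}") from exc
    return records


def write_batch_csv(records: Sequence[BatchRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "batch_id": r.batch_id,
            "role": r.role.value,
            "level_label": r.level_label,
            "nominal_conc": r.nominal_conc,
            "analyte_area": repr(r.analyte_area),
            "is_area": None if r.is_area is None else repr(r.is_area),
            "matrix_lot": r.matrix_lot,
            "condition_tag": r.condition_tag,
            "dilution_factor": r.dilution_factor,
        })
    pd.DataFrame(rows, columns=list(BATCH_COLUMNS)).to_csv(path, index=False)


def read_profile_csv(path: Union[str, Path]) -> List[ConcTimeProfile]:
    """Read long-format concentration-time profiles.

    One row per (subject, time); per-subject metadata (route, dose,
    mw, lloq) must be constant within a subject.  ``BLQ`` cells become
    0 ng/ml with BLQ semantics downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "conc_ng_per_ml": str},
                     float_precision="round_trip")
    _require_columns(df, PROFILE_COLUMNS[:6], path)
    profiles: List[ConcTimeProfile] = []
    for subject, grp in df.groupby("subject_id", sort=False):
        meta_cols = ["route", "dose_mg_per_kg", "mw"]
        if "lloq" in grp.columns:
            meta_cols.append("lloq")
        for col in meta_cols:
            if grp[col].nunique() > 1:
                raise QuantpkError(
                    f"{path}: subject {subject!r} has inconsistent {col!r}"
                )
        times = grp["time_min"].astype(float).to_numpy()
        if len(set(times.tolist())) != len(times):
            raise QuantpkError(
                f"{path}: subject {subject!r} has duplicate sampling times"
            )
        order = times.argsort()
        concs = [
            0.0 if str(v).strip().upper() == BLQ_TOKEN else float(v)
            for v in grp["conc_ng_per_ml"].to_numpy()[order]
        ]
        profiles.append(ConcTimeProfile(
            subject_id=str(subject),
            route=Route(str(grp["route"].iloc[0]).strip()),
            dose=float(grp["dose_mg_per_kg"].iloc[0]),
            mw=float(grp["mw"].iloc[0]),
            times=tuple(times[order].tolist()),
            concentrations=tuple(concs),
            lloq=float(grp["lloq"].iloc[0]) if "lloq" in grp.columns else 0.0,
        ))
    return profiles


def write_profile_csv(profiles: Sequence[ConcTimeProfile],
                      path: Union[str, Path]) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append({
                "subject_id": p.subject_id,
                "route": p.route.value,
                "dose_mg_per_kg": p.dose,
                "mw": p.mw,
                "time_min": t,
                "conc_ng_per_ml": BLQ_TOKEN if c == 0 else repr(c),
                "lloq": p.lloq,
            })
    pd.DataFrame(rows, columns=list(PROFILE_COLUMNS)).to_csv(path, index=False)
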