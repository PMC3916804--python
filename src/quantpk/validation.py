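"""Regulatory bioanalytical validation statistics.

Every statistic a method-validation report needs: per-level accuracy
and precision (%Nom, %CV, %Bias), intra- and inter-batch pooling,
absolute extraction recovery, the internal-standard-normalised matrix
factor, the stability panels (stock solution, long-term, freeze-thaw,
on-bench, on-instrument) and cross-matrix validation.  Each function
is a pure reduction over its inputs; every pass/fail decision is the
stated inequality on the reported numbers, with no hidden state.

Conventions: the coefficient of variation uses the sample (n-1)
standard deviation; accuracy is the mean as a percent of nominal
(%Nom) and %Bias = %Nom - 100 exactly.  Acceptance limits default to
the regulatory +/-15% (with +/-20% tolerated at the LLOQ).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import BatchRecord, QuantpkError, Role

__all__ = [
    "LevelStats",
    "RecoveryResult",
    "MatrixEffectResult",
    "StabilityCondition",
    "StabilityMode",
    "StabilityResult",
    "level_stats",
    "batch_and_run_statistics",
    "absolute_recovery",
    "matrix_factor",
    "stability_assessment",
    "cross_validate",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as validation tables print.

    Operates on the shortest decimal representation of the float so
    that a value like 1.15 (binary ~1.14999...96) still rounds up.
    """
    if not math.isfinite(value):
        return value
    import decimal

    q = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(value))).quantize(
            q, rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class LevelStats:
    """Accuracy/precision summary of replicate measurements at one level.

    ``pct_nom`` is 100 * mean / nominal, ``pct_bias = pct_nom - 100``
    and ``pct_cv`` is 100 * sample SD / mean (NaN for n < 2).
    """

    n: int
    mean: float
    pct_nom: float
    pct_cv: float
    pct_bias: float

    def within(self, limit_pct: float) -> bool:
        return abs(self.pct_bias) <= limit_pct


def level_stats(values: Sequence[float], nominal: float) -> LevelStats:
    """Mean, %Nom, %CV and %Bias of replicate concentrations at one level."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise QuantpkError("level_stats requires at least one value")
    if nominal <= 0:
        raise QuantpkError("nominal concentration must be > 0")
    mean = float(np.mean(v))
    pct_nom = 100.0 * mean / nominal
    if v.size >= 2:
        pct_cv = 100.0 * float(np.std(v, ddof=1)) / mean if mean != 0 else math.nan
    else:
        pct_cv = math.nan
    return LevelStats(
        n=int(v.size),
        mean=mean,
        pct_nom=pct_nom,
        pct_cv=pct_cv,
        pct_bias=pct_nom - 100.0,
    )


def batch_and_run_statistics(
    qc_values: Mapping[Tuple[str, str], Sequence[float]],
    nominals: Mapping[str, float],
    limit_pct: float = 15.0,
    lloq_level: Optional[str] = None,
    lloq_limit_pct: float = 20.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Intra-batch and pooled inter-batch accuracy/precision tables.

    Parameters
    ----------
    qc_values : mapping of (batch_id, level_label) -> concentrations
        Back-calculated QC concentrations grouped by batch and level.
    nominals : mapping of level_label -> nominal ng/ml
    limit_pct, lloq_limit_pct : float
        Acceptance limit on |%Bias| (the wider limit applies at
        ``lloq_level``).

    Returns
    -------
    (intra, inter) : DataFrames
        Per-(batch, level) and pooled per-level statistics with an
        ``accept`` flag.  A level absent from a batch is simply absent
        from the intra table, never an error.
    """
    intra_rows: List[dict] = []
    pooled: Dict[str, List[float]] = {}
    for (batch_id, level), values in sorted(qc_values.items()):
        if level not in nominals:
            raise QuantpkError(f"no nominal concentration for level {level!r}")
        if len(values) == 0:
            continue
        st = level_stats(values, nominals[level])
        lim = lloq_limit_pct if level == lloq_level else limit_pct
        intra_rows.append(
            {
                "batch": batch_id,
                "level": level,
                "nominal": nominals[level],
                "n": st.n,
                "mean": st.mean,
                "pct_nom": st.pct_nom,
                "pct_cv": st.pct_cv,
                "pct_bias": st.pct_bias,
                "accept": st.within(lim),
            }
        )
        pooled.setdefault(level, []).extend(float(v) for v in values)

    inter_rows: List[dict] = []
    for level, values in sorted(pooled.items(), key=lambda kv: nominals[kv[0]]):
        st = level_stats(values, nominals[level])
        lim = lloq_limit_pct if level == lloq_level else limit_pct
        inter_rows.append(
            {
                "level": level,
                "nominal": nominals[level],
                "n": st.n,
                "mean": st.mean,
                "pct_nom": st.pct_nom,
                "pct_cv": st.pct_cv,
                "pct_bias": st.pct_bias,
                "accept": st.within(lim),
            }
        )
    return pd.DataFrame(intra_rows), pd.DataFrame(inter_rows)


@dataclass(frozen=True)
class RecoveryResult:
    """Absolute extraction recovery at one concentration level."""

    level: str
    nominal: Optional[float]
    mean_extracted_area: float
    mean_reference_area: float
    recovery_pct: float
    pct_cv: float


def absolute_recovery(
    extracted: Sequence[BatchRecord],
    references: Sequence[BatchRecord],
    use_is_area: bool = False,
) -> List[RecoveryResult]:
    """Extraction efficiency per level, from mean peak areas.

    Recovery is 100 x mean(extracted areas) / mean(reference
    "theoretical" areas); %CV is taken over the extracted replicates.
    Records are matched by ``level_label``.  With ``use_is_area`` the
    internal-standard areas are compared instead (IS recovery).
    """

    def area(rec: BatchRecord) -> float:
        if use_is_area:
            if rec.is_area is None:
                raise QuantpkError(f"sample {rec.sample_id!r} has no IS area")
            return rec.is_area
        return rec.analyte_area

    def by_level(recs: Sequence[BatchRecord]) -> Dict[str, List[BatchRecord]]:
        out: Dict[str, List[BatchRecord]] = {}
        for r in recs:
            out.setdefault(r.level_label or "?", []).append(r)
        return out

    ext, ref = by_level(extracted), by_level(references)
    results: List[RecoveryResult] = []
    for level in ext:
        if level not in ref:
            raise QuantpkError(f"no reference records for level {level!r}")
        e_areas = np.array([area(r) for r in ext[level]], dtype=float)
        r_areas = np.array([area(r) for r in ref[level]], dtype=float)
        if e_areas.size < 2 or r_areas.size < 2:
            raise QuantpkError(
                f"level {level!r}: need >= 2 records per side for recovery"
            )
        mean_ref = float(np.mean(r_areas))
        if mean_ref == 0:
            raise QuantpkError(f"level {level!r}: zero reference mean area")
        mean_ext = float(np.mean(e_areas))
        results.append(
            RecoveryResult(
                level=level,
                nominal=ext[level][0].nominal_conc,
                mean_extracted_area=mean_ext,
                mean_reference_area=mean_ref,
                recovery_pct=100.0 * mean_ext / mean_ref,
                pct_cv=100.0 * float(np.std(e_areas, ddof=1)) / mean_ext,
            )
        )
    results.sort(key=lambda r: (r.nominal is None, r.nominal))
    return results


@dataclass(frozen=True)
class MatrixEffectResult:
    """IS-normalised matrix factors across matrix lots.

    An IS-MF of 1 means no matrix effect; < 1 ionisation suppression,
    > 1 enhancement.  The assay is reproducible when the %CV of the
    factors across lots is within the limit (default 15%).
    """

    mf_by_lot: Dict[str, float]
    mean_mf: float
    pct_cv_mf: float
    cv_limit_pct: float

    @property
    def passed(self) -> bool:
        return self.pct_cv_mf <= self.cv_limit_pct


def matrix_factor(
    with_matrix: Sequence[BatchRecord],
    without_matrix: Sequence[BatchRecord],
    cv_limit_pct: float = 15.0,
) -> MatrixEffectResult:
    """IS-normalised matrix factor per matrix lot.

    Each lot's analyte/IS area ratio in the presence of matrix is
    divided by the mean analyte/IS ratio of the matrix-free replicates.
    """
    if not with_matrix:
        raise QuantpkError("at least one with-matrix lot is required")
    if len(without_matrix) < 2:
        raise QuantpkError("need >= 2 matrix-free replicates")
    neat = np.array([r.response for r in without_matrix], dtype=float)
    neat_mean = float(np.mean(neat))
    if neat_mean == 0:
        raise QuantpkError("zero matrix-free mean response")

    ratios: Dict[str, List[float]] = {}
    for rec in with_matrix:
        lot = rec.matrix_lot or rec.sample_id
        ratios.setdefault(lot, []).append(rec.response)
    mf = {lot: float(np.mean(v)) / neat_mean for lot, v in ratios.items()}
    values = np.array(list(mf.values()), dtype=float)
    mean_mf = float(np.mean(values))
    pct_cv = (
        100.0 * float(np.std(values, ddof=1)) / mean_mf
        if values.size >= 2
        else math.nan
    )
    return MatrixEffectResult(
        mf_by_lot=mf, mean_mf=mean_mf, pct_cv_mf=pct_cv, cv_limit_pct=cv_limit_pct
    )


class StabilityCondition(str, enum.Enum):
    STOCK_RT = "stock_rt"
    STOCK_5C = "stock_5c"
    STOCK_M20C = "stock_m20c"
    LONG_TERM = "long_term"
    FREEZE_THAW = "freeze_thaw"
    ON_BENCH = "on_bench"
    ON_INSTRUMENT = "on_instrument"


class StabilityMode(str, enum.Enum):
    #: 100 x mean test area / mean fresh-reference area (stock solutions)
    PCT_REFERENCE = "pct_reference"
    #: %Bias of measured concentrations against the spiked nominal
    PCT_BIAS_VS_NOMINAL = "pct_bias_vs_nominal"
    #: 100 x (mean end - mean start) / mean start (on-instrument runs)
    PCT_DIFFERENCE = "pct_difference_vs_reference_set"


@dataclass(frozen=True)
class StabilityResult:
    condition: StabilityCondition
    comparison_mode: StabilityMode
    value: float  # % reference, % bias or % difference
    pct_cv: float
    limit_pct: float
    n: int

    @property
    def passed(self) -> bool:
        ref = 100.0 if self.comparison_mode is StabilityMode.PCT_REFERENCE else 0.0
        return abs(self.value - ref) <= self.limit_pct


def stability_assessment(
    test_values: Sequence[float],
    mode: StabilityMode | str,
    condition: StabilityCondition | str,
    reference: Optional[Sequence[float]] = None,
    nominal: Optional[float] = None,
    limit_pct: float = 15.0,
) -> StabilityResult:
    """Stability statistic for one condition.

    ``test_values`` are peak areas (stock-solution tests compare raw
    areas of the stored vs freshly prepared stocks) or measured
    concentrations, depending on the mode; ``reference`` supplies the
    fresh/start set where the mode needs one.
    """
    mode = StabilityMode(mode)
    condition = StabilityCondition(condition)
    test = np.asarray(list(test_values), dtype=float)
    if test.size == 0:
        raise QuantpkError("empty stability test set")
    mean_test = float(np.mean(test))
    pct_cv = (
        100.0 * float(np.std(test, ddof=1)) / mean_test if test.size >= 2 else math.nan
    )

    if mode is StabilityMode.PCT_BIAS_VS_NOMINAL:
        if nominal is None:
            raise QuantpkError("pct_bias_vs_nominal mode needs a nominal")
        value = level_stats(test, nominal).pct_bias
    else:
        if reference is None or len(list(reference)) == 0:
            raise QuantpkError(f"mode {mode.value} needs a reference set")
        mean_ref = float(np.mean(np.asarray(list(reference), dtype=float)))
        if mean_ref == 0:
            raise QuantpkError("zero reference mean")
        if mode is StabilityMode.PCT_REFERENCE:
            value = 100.0 * mean_test / mean_ref
        else:  # PCT_DIFFERENCE: end-of-run vs start-of-run sets
            value = 100.0 * (mean_test - mean_ref) / mean_ref
    return StabilityResult(
        condition=condition,
        comparison_mode=mode,
        value=value,
        pct_cv=pct_cv,
        limit_pct=limit_pct,
        n=int(test.size),
    )


def cross_validate(
    alt_matrix_values: Mapping[str, Sequence[float]],
    nominals: Mapping[str, float],
    limit_pct: float = 15.0,
) -> pd.DataFrame:
    """Accuracy of alternate-matrix QCs against the primary calibration.

    QCs prepared in the alternate matrix (e.g. mouse blood) and
    quantified against the primary-matrix (human blood) curve must show
    |%Bias| within the limit at every level.  Breaches are flagged in
    the ``accept`` column, not raised: regulatory guidance allows wider
    limits when justified, so the judgement is left to the analyst.
    """
    rows = []
    for level, values in alt_matrix_values.items():
        if len(values) == 0:
            raise QuantpkError(f"empty cross-validation level {level!r}")
        if level not in nominals:
            raise QuantpkError(f"no nominal for cross-validation level {level!r}")
        st = level_stats(values, nominals[level])
        rows.append(
            {
                "level": level,
                "nominal": nominals[level],
                "n": st.n,
                "mean": st.mean,
                "pct_nom": st.pct_nom,
                "pct_cv": st.pct_cv,
                "pct_bias": st.pct_bias,
                "accept": st.within(limit_pct),
            }
        )
    if len(rows) < 1:
        raise QuantpkError("cross-validation needs at least one level")
    return pd.DataFrame(rows).sort_values("nominal", ignore_index=True)
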