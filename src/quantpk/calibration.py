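"""Calibration-curve fitting and back-calculation.

LC-MS/MS quantification converts an instrument response (analyte peak
area, or analyte/internal-standard area ratio) into a concentration via
a calibration curve fitted to spiked standards.  The workhorse model
here is the log-log quadratic ("Wagner") curve

    ln(y) = a (ln x)^2 + b (ln x) + c

with response ``y`` and concentration ``x``.  It is linear in its
coefficients, so fitting is ordinary least squares in (ln x, ln y)
space; a straight line in log-log space (``a = 0``) and a plain linear
model are available as alternatives.  Back-calculation inverts the
fitted curve; for the quadratic this means solving for ln x and taking
the root on the monotone-increasing branch, which is unique because
fits that are not strictly increasing over the calibration range are
rejected outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .records import BatchRecord, QuantpkError, Role

__all__ = [
    "CalibrationError",
    "BackCalculationError",
    "WagnerCalibration",
    "CalibrationFit",
    "SpecificityReport",
    "fit_calibration",
    "predict_response",
    "back_calculate",
    "evaluate_curve",
    "check_specificity",
    "record_response",
]

#: |a| below this uses the straight-line inversion (continuity with a -> 0).
LINEAR_FALLBACK_TOL = 1e-12

MODEL_KINDS = ("wagner", "linear_loglog", "linear")
RESPONSE_BASES = ("area", "area_ratio")


class CalibrationError(QuantpkError):
    """Raised when a calibration fit is infeasible or invalid."""


class BackCalculationError(QuantpkError):
    """Raised when a response cannot be mapped back to a concentration."""


class WagnerCalibration(BaseEstimator, RegressorMixin):
    """Log-log quadratic calibration model as a scikit-learn estimator.

    Parameters
    ----------
    model_kind : {"wagner", "linear_loglog", "linear"}
        ``wagner`` fits ln(y) = a (ln x)^2 + b ln x + c; ``linear_loglog``
        fixes a = 0; ``linear`` fits y = b x + c in untransformed space.
    weighting : {None, "1/x", "1/x2"}
        Optional regression weights by nominal concentration.  The log
        transform already stabilises multiplicative variance, so the
        default is unweighted.
    min_levels : int
        Minimum number of distinct nominal concentrations required.

    Attributes
    ----------
    coef_a_, coef_b_, coef_c_ : float
        Fitted coefficients (``coef_a_`` is 0 for the linear kinds).
    lloq_, uloq_ : float
        Lowest and highest nominal concentration among the standards.
    r_squared_ : float
        Coefficient of determination in the fitting space (ln-ln space
        for the log models).
    n_points_ : int
        Number of standards used.

    Examples
    --------
    >>> import numpy as np
    >>> x = np.array([4.0, 8.0, 16.0, 31.0, 62.0, 125.0, 250.0, 500.0, 1000.0])
    >>> cal = WagnerCalibration().fit(x, 10.0 * x)
    >>> float(round(cal.inverse(cal.predict([50.0]))[0], 9))
    50.0
    """

    def __init__(self, model_kind: str = "wagner", weighting: Optional[str] = None,
                 min_levels: int = 6):
        self.model_kind = model_kind
        self.weighting = weighting
        self.min_levels = min_levels

    # -- fitting -----------------------------------------------------

    def fit(self, X, y) -> "WagnerCalibration":
        """Fit the calibration curve to standard concentrations/responses.

        Parameters
        ----------
        X : array-like of shape (n,) or (n, 1)
            Nominal concentrations (ng/ml), all > 0.
        y : array-like of shape (n,)
            Instrument responses (area or area ratio), all > 0.
        """
        if self.model_kind not in MODEL_KINDS:
            raise CalibrationError(f"unknown model kind {self.model_kind!r}")
        x = np.asarray(X, dtype=float).reshape(-1)
        resp = np.asarray(y, dtype=float).reshape(-1)
        if x.size != resp.size:
            raise CalibrationError("X and y must have equal length")
        if np.any(x <= 0):
            raise CalibrationError("all nominal concentrations must be > 0")
        if np.any(resp <= 0):
            raise CalibrationError("all responses must be > 0")
        n_levels = np.unique(x).size
        if n_levels < self.min_levels:
            raise CalibrationError(
                f"calibration needs >= {self.min_levels} distinct levels, "
                f"got {n_levels}"
            )

        w = self._weights(x)
        if self.model_kind == "linear":
            design = np.column_stack([x, np.ones_like(x)])
            target = resp
        else:
            lx = np.log(x)
            target = np.log(resp)
            if self.model_kind == "wagner":
                design = np.column_stack([lx**2, lx, np.ones_like(lx)])
            else:  # linear_loglog
                design = np.column_stack([lx, np.ones_like(lx)])

        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], target * sw, rcond=None)
        if self.model_kind == "wagner":
            a, b, c = beta
        else:
            a, (b, c) = 0.0, beta

        self.coef_a_ = float(a)
        self.coef_b_ = float(b)
        self.coef_c_ = float(c)
        self.lloq_ = float(np.min(x))
        self.uloq_ = float(np.max(x))
        self.n_points_ = int(x.size)

        fitted = design @ beta
        ss_res = float(np.sum(w * (target - fitted) ** 2))
        ss_tot = float(np.sum(w * (target - np.average(target, weights=w)) ** 2))
        self.r_squared_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

        self._check_monotone()
        return self

    def _weights(self, x: np.ndarray) -> np.ndarray:
        if self.weighting is None:
            return np.ones_like(x)
        if self.weighting == "1/x":
            return 1.0 / x
        if self.weighting == "1/x2":
            return 1.0 / x**2
        raise CalibrationError(f"unknown weighting {self.weighting!r}")

    def _check_monotone(self) -> None:
        """Reject fits whose response is not strictly increasing in
        concentration over [lloq, uloq].

        For the log models d ln(y)/d ln(x) = 2a ln(x) + b is linear in
        ln(x), so positivity at both range endpoints suffices.
        """
        if self.model_kind == "linear":
            if self.coef_b_ <= 0:
                raise CalibrationError("linear calibration slope must be > 0")
            return
        for bound in (self.lloq_, self.uloq_):
            if 2.0 * self.coef_a_ * math.log(bound) + self.coef_b_ <= 0:
                raise CalibrationError(
                    "fitted curve is not strictly increasing over "
                    f"[{self.lloq_:g}, {self.uloq_:g}] ng/ml; fit rejected"
                )

    # -- forward and inverse maps ------------------------------------

    def predict(self, X) -> np.ndarray:
        """Predicted response at concentrations ``X`` (ng/ml, > 0)."""
        self._require_fitted()
        x = np.asarray(X, dtype=float).reshape(-1)
        if np.any(x <= 0):
            raise QuantpkError("concentration must be > 0")
        if self.model_kind == "linear":
            return self.coef_b_ * x + self.coef_c_
        lx = np.log(x)
        return np.exp(self.coef_a_ * lx**2 + self.coef_b_ * lx + self.coef_c_)

    def inverse(self, y, with_flags: bool = False):
        """Back-calculate concentrations from responses.

        Solves a u^2 + b u + (c - ln y) = 0 for u = ln(conc) and keeps
        the root on the monotone-increasing branch (2a u + b > 0).  When
        |a| < ``LINEAR_FALLBACK_TOL`` the straight-line solution is used
        to avoid catastrophic cancellation.

        Parameters
        ----------
        y : array-like
            Responses, all > 0.
        with_flags : bool
            Also return a range flag per value: ``"ok"``,
            ``"below_lloq"`` or ``"above_uloq"``.  Out-of-range results
            are flagged, never rejected (dilution QCs legitimately
            exceed the ULOQ before dilution correction).
        """
        self._require_fitted()
        resp = np.asarray(y, dtype=float).reshape(-1)
        if np.any(resp <= 0):
            raise BackCalculationError("response must be > 0")

        if self.model_kind == "linear":
            conc = (resp - self.coef_c_) / self.coef_b_
            if np.any(conc <= 0):
                raise BackCalculationError(
                    "response below the linear calibration intercept"
                )
        else:
            a, b, c = self.coef_a_, self.coef_b_, self.coef_c_
            ly = np.log(resp)
            if abs(a) < LINEAR_FALLBACK_TOL:
                u = (ly - c) / b
            else:
                disc = b * b - 4.0 * a * (c - ly)
                if np.any(disc < 0):
                    raise BackCalculationError(
                        "response not reachable by the fitted curve "
                        "(negative discriminant)"
                    )
                # Monotone-increasing root: 2a u + b = +sqrt(disc).  For
                # b >= 0 the textbook form (-b + sqrt)/(2a) cancels
                # catastrophically as a -> 0; the equivalent product-of-
                # roots form is stable there and continuous with a = 0.
                sqrt_disc = np.sqrt(disc)
                if b >= 0:
                    u = 2.0 * (ly - c) / (b + sqrt_disc)
                else:
                    u = (-b + sqrt_disc) / (2.0 * a)
            conc = np.exp(u)

        if not with_flags:
            return conc
        flags = np.where(
            conc < self.lloq_, "below_lloq",
            np.where(conc > self.uloq_, "above_uloq", "ok"),
        )
        return conc, flags

    def _require_fitted(self) -> None:
        if not hasattr(self, "coef_b_"):
            raise QuantpkError("calibration model is not fitted")


# ---------------------------------------------------------------------------
# Plain-record layer: dataclasses and functions over BatchRecord lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationFit:
    """Serializable summary of a fitted calibration curve."""

    model_kind: str
    coeff_a: float
    coeff_b: float
    coeff_c: float
    response_basis: str
    lloq: float
    uloq: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0 < self.lloq < self.uloq):
            raise CalibrationError("need 0 < lloq < uloq")
        if not (0.0 <= self.r_squared <= 1.0):
            raise CalibrationError("r_squared must lie in [0, 1]")

    def to_estimator(self) -> WagnerCalibration:
        est = WagnerCalibration(model_kind=self.model_kind)
        est.coef_a_ = self.coeff_a
        est.coef_b_ = self.coeff_b
        est.coef_c_ = self.coeff_c
        est.lloq_ = self.lloq
        est.uloq_ = self.uloq
        est.r_squared_ = self.r_squared
        est.n_points_ = self.n_points
        est._check_monotone()
        return est

    @classmethod
    def from_estimator(cls, est: WagnerCalibration,
                       response_basis: str = "area_ratio") -> "CalibrationFit":
        return cls(
            model_kind=est.model_kind,
            coeff_a=est.coef_a_,
            coeff_b=est.coef_b_,
            coeff_c=est.coef_c_,
            response_basis=response_basis,
            lloq=est.lloq_,
            uloq=est.uloq_,
            r_squared=est.r_squared_,
            n_points=est.n_points_,
        )


@dataclass(frozen=True)
class SpecificityReport:
    """Per-lot blank interference relative to the LLOQ response."""

    analyte_fraction_by_lot: dict
    is_fraction_by_lot: dict
    analyte_threshold: float
    is_threshold: float
    analyte_pass_by_lot: dict = field(default_factory=dict)
    is_pass_by_lot: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.analyte_pass_by_lot.values()) and all(
            self.is_pass_by_lot.values()
        )


def record_response(rec: BatchRecord, response_basis: str) -> float:
    """A record's response under the chosen basis."""
    if response_basis == "area":
        return rec.analyte_area
    if response_basis == "area_ratio":
        return rec.response
    raise QuantpkError(f"unknown response basis {response_basis!r}")


def fit_calibration(standards: Sequence[BatchRecord],
                    model_kind: str = "wagner",
                    response_basis: str = "area_ratio",
                    weighting: Optional[str] = None) -> CalibrationFit:
    """Fit a calibration curve to STD-role batch records."""
    stds = [r for r in standards if r.role is Role.STD]
    if not stds:
        raise CalibrationError("no STD-role records supplied")
    x = np.array([r.nominal_conc for r in stds], dtype=float)
    y = np.array([record_response(r, response_basis) for r in stds], dtype=float)
    est = WagnerCalibration(model_kind=model_kind, weighting=weighting).fit(x, y)
    return CalibrationFit.from_estimator(est, response_basis=response_basis)


def predict_response(fit: CalibrationFit, conc) -> np.ndarray:
    """Forward-evaluate the calibration curve at ``conc`` ng/ml."""
    return fit.to_estimator().predict(np.atleast_1d(conc))


def back_calculate(fit: CalibrationFit, response, with_flags: bool = False):
    """Invert the calibration curve for observed responses."""
    return fit.to_estimator().inverse(np.atleast_1d(response), with_flags=with_flags)


def evaluate_curve(fit: CalibrationFit, standards: Sequence[BatchRecord]):
    """Per-nominal-level back-calculation statistics for standards.

    Returns a DataFrame with one row per nominal level (mean, %Nom,
    %CV, %Bias, n) computed on dilution-corrected back-calculated
    concentrations; the duplicate-per-batch structure is preserved in
    the reported n.
    """
    import pandas as pd

    from .validation import level_stats

    stds = [r for r in standards if r.role in (Role.STD, Role.QC)]
    if not stds:
        raise CalibrationError("no quantifiable records supplied")
    est = fit.to_estimator()
    rows = []
    by_level: dict = {}
    for rec in stds:
        conc = float(est.inverse([record_response(rec, fit.response_basis)])[0])
        conc *= rec.dilution_factor
        key = (rec.level_label or f"{rec.nominal_conc:g}", rec.nominal_conc)
        by_level.setdefault(key, []).append(conc)
    for (label, nominal), values in sorted(by_level.items(), key=lambda kv: kv[0][1]):
        st = level_stats(values, nominal)
        rows.append(
            {
                "level": label,
                "nominal": nominal,
                "n": st.n,
                "mean": st.mean,
                "pct_nom": st.pct_nom,
                "pct_cv": st.pct_cv,
                "pct_bias": st.pct_bias,
            }
        )
    return pd.DataFrame(rows)


def check_specificity(blanks: Iterable[BatchRecord],
                      lloq_records: Sequence[BatchRecord],
                      analyte_threshold: float = 0.20,
                      is_threshold: float = 0.05) -> SpecificityReport:
    """Blank interference check against the mean LLOQ response.

    A lot passes when its blank analyte area is below
    ``analyte_threshold`` of the mean LLOQ analyte area and its blank
    IS area is below ``is_threshold`` of the mean IS area of the LLOQ
    records.
    """
    lloqs = list(lloq_records)
    if not lloqs:
        raise QuantpkError("at least one LLOQ record is required")
    mean_analyte = float(np.mean([r.analyte_area for r in lloqs]))
    is_areas = [r.is_area for r in lloqs if r.is_area is not None]
    if mean_analyte <= 0 or not is_areas:
        raise QuantpkError("mean LLOQ analyte and IS responses must be > 0")
    mean_is = float(np.mean(is_areas))
    if mean_is <= 0:
        raise QuantpkError("mean LLOQ IS response must be > 0")

    a_frac: dict = {}
    i_frac: dict = {}
    for rec in blanks:
        lot = rec.matrix_lot or rec.sample_id
        a_frac[lot] = rec.analyte_area / mean_analyte
        i_frac[lot] = (rec.is_area or 0.0) / mean_is
    if not a_frac:
        raise QuantpkError("at least one blank record is required")
    return SpecificityReport(
        analyte_fraction_by_lot=a_frac,
        is_fraction_by_lot=i_frac,
        analyte_threshold=analyte_threshold,
        is_threshold=is_threshold,
        analyte_pass_by_lot={k: v < analyte_threshold for k, v in a_frac.items()},
        is_pass_by_lot={k: v < is_threshold for k, v in i_frac.items()},
    )
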