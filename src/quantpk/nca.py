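"""Non-compartmental pharmacokinetic analysis (NCA).

Estimates the standard NCA parameter set from a blood
concentration-time profile without assuming a compartmental model:
Cmax/Tmax read off the observed points, the terminal elimination rate
constant lambda_z from log-linear regression of the terminal phase,
trapezoidal AUC and AUMC with extrapolation to infinity, and the
derived clearance and volume terms for intravenous dosing.  Oral
bioavailability F is the dose-normalised oral/IV AUC ratio.

Unit conventions follow bioanalytical reporting: concentrations arrive
in ng/ml and are converted to umol/l ("uM") via the molecular weight;
internal time is minutes; half-life and Tmax are reported in hours,
clearance in ml/min/kg and volumes in l/kg.

BLQ (below limit of quantification) handling: values below the LLOQ
before Tmax are set to 0, BLQ values embedded between positive points
are excluded, and trailing BLQ values are excluded.  For IV bolus
profiles whose first sample is after t=0, C(0) is estimated by
log-linear back-extrapolation of the first two points; extravascular
profiles are anchored at C(0)=0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .records import ConcTimeProfile, QuantpkError, Route

__all__ = [
    "NCAError",
    "NCAResult",
    "BioavailabilityResult",
    "NCA",
    "convert_concentration",
    "dose_to_umol_per_kg",
    "fit_lambda_z",
    "auc_trapezoid",
    "compute_nca",
    "bioavailability",
    "mean_profile",
]

LN2 = math.log(2.0)


class NCAError(QuantpkError):
    """Raised when a profile cannot support the requested NCA step."""


def convert_concentration(conc_ng_per_ml, mw: float):
    """ng/ml -> umol/l (numerically equal to uM) via the molar mass."""
    if mw <= 0:
        raise NCAError("molecular weight must be > 0")
    return np.asarray(conc_ng_per_ml, dtype=float) / mw


def dose_to_umol_per_kg(dose_mg_per_kg: float, mw: float) -> float:
    """mg/kg -> umol/kg via the molar mass."""
    if mw <= 0:
        raise NCAError("molecular weight must be > 0")
    return 1000.0 * dose_mg_per_kg / mw


# ---------------------------------------------------------------------------
# BLQ cleaning
# ---------------------------------------------------------------------------


def _clean_blq(times: np.ndarray, concs: np.ndarray,
               lloq: float) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ rules; returns the retained (times, concs)."""
    blq = concs < max(lloq, 0.0) if lloq > 0 else concs <= 0
    positive = ~blq
    if not np.any(positive):
        raise NCAError("profile has no quantifiable concentrations")
    last_pos = int(np.flatnonzero(positive)[-1])
    times, concs, blq = times[: last_pos + 1], concs[: last_pos + 1], blq[: last_pos + 1]
    tmax_idx = int(np.argmax(concs))
    keep = np.ones(times.size, dtype=bool)
    out = concs.copy()
    for i in range(times.size):
        if blq[i]:
            if i < tmax_idx:
                out[i] = 0.0  # pre-Tmax BLQ contributes zero
            else:
                keep[i] = False  # embedded BLQ excluded
    return times[keep], out[keep]


# ---------------------------------------------------------------------------
# Terminal slope
# ---------------------------------------------------------------------------


def fit_lambda_z(
    profile_or_times,
    concentrations=None,
    lloq: float = 0.0,
    selection="auto",
) -> Tuple[float, Tuple[int, int], float]:
    """Terminal elimination rate constant by log-linear regression.

    Parameters
    ----------
    profile_or_times : ConcTimeProfile or array of times (min)
    concentrations : array of concentrations, required with raw times
    selection : "auto" or (start, stop) index pair
        Auto mode searches every window that ends at the last positive
        point, starts strictly after Tmax and spans >= 3 points, and
        keeps the one with the highest adjusted r-squared (ties broken
        toward more points).  An explicit (start, stop) pair (stop
        exclusive, indices into the BLQ-cleaned points) overrides the
        search so a reported value can be chased.

    Returns
    -------
    (lambda_z, (start, stop), r2_adjusted)
        ``lambda_z`` is the positive slope magnitude in 1/min.
    """
    if isinstance(profile_or_times, ConcTimeProfile):
        p = profile_or_times
        t, c = _clean_blq(p.times_array, p.conc_array, p.lloq)
    else:
        t = np.asarray(profile_or_times, dtype=float)
        c = np.asarray(concentrations, dtype=float)
        t, c = _clean_blq(t, c, lloq)
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < 3:
        raise NCAError("lambda_z needs >= 3 positive concentrations")
    logc = np.log(c)
    tmax_idx = int(np.argmax(c))

    def ols(i: int, j: int) -> Tuple[float, float]:
        tt, yy = t[i:j], logc[i:j]
        n = tt.size
        slope, intercept = np.polyfit(tt, yy, 1)
        fitted = slope * tt + intercept
        ss_res = float(np.sum((yy - fitted) ** 2))
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        return slope, r2_adj

    if selection != "auto":
        i, j = selection
        if j - i < 3:
            raise NCAError("explicit lambda_z window needs >= 3 points")
        slope, r2_adj = ols(i, j)
        if slope >= 0:
            raise NCAError("terminal phase is not declining in the window")
        return -slope, (i, j), r2_adj

    stop = t.size
    best: Optional[Tuple[float, int, float]] = None  # (r2_adj, n, slope)
    best_start = None
    for start in range(tmax_idx + 1, stop - 2):
        slope, r2_adj = ols(start, stop)
        if slope >= 0:
            continue
        n = stop - start
        if best is None or r2_adj > best[0] + 1e-12 or (
            abs(r2_adj - best[0]) <= 1e-12 and n > best[1]
        ):
            best = (r2_adj, n, slope)
            best_start = start
    if best is None:
        raise NCAError(
            "no declining terminal window with >= 3 points after Tmax"
        )
    return -best[2], (best_start, stop), best[0]


# ---------------------------------------------------------------------------
# AUC / AUMC
# ---------------------------------------------------------------------------


def auc_trapezoid(times, concentrations, method: str = "linear") -> Tuple[float, float]:
    """Trapezoidal AUC and AUMC over the observed points.

    ``linear`` applies the linear trapezoid everywhere;
    ``linear_up_log_down`` uses the logarithmic trapezoid on declining
    segments with both endpoints positive (exact for exponential decay)
    and the linear rule otherwise.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise NCAError("AUC needs >= 2 points")
    if np.all(c == 0):
        raise NCAError("AUC of an all-zero profile is undefined")
    if method not in ("linear", "linear_up_log_down"):
        raise NCAError(f"unknown AUC method {method!r}")
    auc = aumc = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        dt = t2 - t1
        if method == "linear_up_log_down" and c1 > c2 > 0:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / (k * k)
        else:
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NCAResult:
    """NCA parameter set for one profile (units as reported in PK tables)."""

    subject_id: str
    route: Route
    dose: float  # mg/kg
    cmax: float  # uM
    tmax: float  # h
    lambda_z: float  # 1/min
    apparent_t_half: float  # h
    auc_last: float  # min*umol/l
    auc_inf: float  # min*umol/l
    pct_extrapolated: float  # %
    aumc_inf: float  # min^2*umol/l
    mrt: float  # min
    lambda_z_window: Tuple[int, int]
    lambda_z_r2_adj: float
    cl_total: Optional[float] = None  # ml/min/kg, IV only
    vz: Optional[float] = None  # l/kg, IV only
    vss: Optional[float] = None  # l/kg, IV only
    disposition_note: Optional[str] = None


@dataclass(frozen=True)
class BioavailabilityResult:
    """Dose-normalised oral/IV AUC ratio."""

    f_pct: float
    auc_oral: float
    auc_iv: float
    dose_oral: float
    dose_iv: float


class NCA(BaseEstimator):
    """Non-compartmental analysis as a fitter-style estimator.

    Parameters
    ----------
    auc_method : {"linear", "linear_up_log_down"}
    lambda_z_selection : "auto" or (start, stop)
        Passed to :func:`fit_lambda_z`.
    anchor_time_zero : bool
        Anchor the integral at t=0 when the first sample is later: IV
        profiles get a log-back-extrapolated C(0), extravascular
        profiles get C(0)=0.

    After ``fit(profile)`` the estimates are available as fitted
    attributes (``lambda_z_``, ``auc_inf_``, ``cl_total_``, ...) and
    bundled in ``result_``.
    """

    def __init__(self, auc_method: str = "linear",
                 lambda_z_selection="auto", anchor_time_zero: bool = True):
        self.auc_method = auc_method
        self.lambda_z_selection = lambda_z_selection
        self.anchor_time_zero = anchor_time_zero

    def fit(self, profile: ConcTimeProfile, y=None) -> "NCA":
        t, c_ng = _clean_blq(profile.times_array, profile.conc_array, profile.lloq)
        pos = c_ng > 0
        if np.count_nonzero(pos) < 2:
            raise NCAError(
                f"profile {profile.subject_id!r}: fewer than 2 quantifiable points"
            )
        c = np.asarray(convert_concentration(c_ng, profile.mw))

        obs_pos_t, obs_pos_c = t[pos], c[pos]
        i_cmax = int(np.argmax(obs_pos_c))
        self.cmax_ = float(obs_pos_c[i_cmax])
        self.tmax_h_ = float(obs_pos_t[i_cmax]) / 60.0

        lam, window, r2_adj = fit_lambda_z(
            t, c, lloq=0.0, selection=self.lambda_z_selection
        )
        self.lambda_z_ = lam
        self.lambda_z_window_ = window
        self.lambda_z_r2_adj_ = r2_adj
        self.t_half_h_ = LN2 / lam / 60.0

        ti, ci = t, c
        if self.anchor_time_zero and t[0] > 0:
            if profile.route is Route.IV:
                c0 = self._back_extrapolate_c0(obs_pos_t, obs_pos_c)
            else:
                c0 = 0.0
            ti = np.concatenate([[0.0], t])
            ci = np.concatenate([[c0], c])

        auc_last, aumc_last = auc_trapezoid(ti, ci, method=self.auc_method)
        c_last = float(obs_pos_c[-1])
        t_last = float(obs_pos_t[-1])
        self.auc_last_ = auc_last
        self.auc_inf_ = auc_last + c_last / lam
        self.aumc_inf_ = aumc_last + c_last * t_last / lam + c_last / lam**2
        self.pct_extrapolated_ = 100.0 * (self.auc_inf_ - auc_last) / self.auc_inf_
        self.mrt_ = self.aumc_inf_ / self.auc_inf_

        note = None
        if profile.route is Route.IV:
            dose_umol = dose_to_umol_per_kg(profile.dose, profile.mw)
            cl_l_min_kg = dose_umol / self.auc_inf_  # (umol/kg)/(min*umol/l)
            self.cl_total_ = 1000.0 * cl_l_min_kg  # ml/min/kg
            self.vz_ = cl_l_min_kg / lam  # l/kg
            self.vss_ = cl_l_min_kg * self.mrt_  # l/kg
        else:
            self.cl_total_ = self.vz_ = self.vss_ = None
            note = "disposition_requires_iv_dosing"

        self.result_ = NCAResult(
            subject_id=profile.subject_id,
            route=profile.route,
            dose=profile.dose,
            cmax=self.cmax_,
            tmax=self.tmax_h_,
            lambda_z=self.lambda_z_,
            apparent_t_half=self.t_half_h_,
            auc_last=self.auc_last_,
            auc_inf=self.auc_inf_,
            pct_extrapolated=self.pct_extrapolated_,
            aumc_inf=self.aumc_inf_,
            mrt=self.mrt_,
            lambda_z_window=self.lambda_z_window_,
            lambda_z_r2_adj=self.lambda_z_r2_adj_,
            cl_total=self.cl_total_,
            vz=self.vz_,
            vss=self.vss_,
            disposition_note=note,
        )
        return self

    @staticmethod
    def _back_extrapolate_c0(t: np.ndarray, c: np.ndarray) -> float:
        """IV bolus C(0) from the first two positive points (log-linear);
        falls back to the first observed concentration for a rising pair."""
        if t.size >= 2 and c[0] > c[1] > 0:
            slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
            return float(c[0] * math.exp(-slope * t[0]))
        return float(c[0])


def compute_nca(profile: ConcTimeProfile, auc_method: str = "linear",
                lambda_z_selection="auto",
                anchor_time_zero: bool = True) -> NCAResult:
    """One-call NCA of a profile; see :class:`NCA` for the options."""
    return NCA(
        auc_method=auc_method,
        lambda_z_selection=lambda_z_selection,
        anchor_time_zero=anchor_time_zero,
    ).fit(profile).result_


def bioavailability(auc_oral: float, dose_oral: float,
                    auc_iv: float, dose_iv: float) -> BioavailabilityResult:
    """F(%) = 100 x (AUC_oral/Dose_oral) / (AUC_iv/Dose_iv).

    AUCs must share a unit and doses must share a unit; the ratio is
    invariant under any consistent change of either unit.
    """
    for name, v in (("auc_oral", auc_oral), ("dose_oral", dose_oral),
                    ("auc_iv", auc_iv), ("dose_iv", dose_iv)):
        if v <= 0:
            raise NCAError(f"{name} must be > 0")
    f = 100.0 * (auc_oral / dose_oral) / (auc_iv / dose_iv)
    return BioavailabilityResult(
        f_pct=f, auc_oral=auc_oral, auc_iv=auc_iv,
        dose_oral=dose_oral, dose_iv=dose_iv,
    )


def mean_profile(profiles: Sequence[ConcTimeProfile]) -> ConcTimeProfile:
    """Arithmetic mean concentration per time point across subjects.

    All profiles must share the nominal time grid, route, dose and
    molecular weight.  BLQ values enter the mean as 0, mirroring how
    mean concentration-time figures are usually drawn.
    """
    if not profiles:
        raise NCAError("mean_profile needs at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.times != first.times:
            raise NCAError("profiles do not share a sampling schedule")
        if p.route is not first.route or p.dose != first.dose or p.mw != first.mw:
            raise NCAError("profiles do not share route/dose/mw")
    stack = np.vstack([p.conc_array for p in profiles])
    return first.with_values(
        first.times, np.mean(stack, axis=0),
        subject_id=f"mean_of_{len(profiles)}",
    )
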