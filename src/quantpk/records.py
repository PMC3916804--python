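"""Core record types shared across the package.

A :class:`BatchRecord` is one injected sample from an analytical batch:
its integrated peak areas, its role in the batch design (calibration
standard, quality control, blank, ...) and the metadata needed to place
it in a validation statistic.  A :class:`ConcTimeProfile` is one
animal's blood concentration-time course with its dosing metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Role",
    "Route",
    "BatchRecord",
    "ConcTimeProfile",
    "QuantpkError",
]


class QuantpkError(ValueError):
    """Base class for domain validation errors raised by this package."""


class Role(str, enum.Enum):
    """What a sample is for within a batch."""

    STD = "STD"
    QC = "QC"
    BLANK = "BLANK"
    DOUBLE_BLANK = "DOUBLE_BLANK"
    SPVS = "SPVS"
    STABILITY = "STABILITY"
    MATRIX_EFFECT = "MATRIX_EFFECT"
    UNKNOWN = "UNKNOWN"


class Route(str, enum.Enum):
    PO = "PO"
    IV = "IV"


@dataclass(frozen=True)
class BatchRecord:
    """One sample's peak areas with role, level and lot metadata.

    Parameters
    ----------
    sample_id : str
        Unique within a batch.
    batch_id : str
        Identifier of the analytical run the sample was injected in.
    role : Role
        Sample role in the batch design.
    level_label : str, optional
        Human-readable level name, e.g. ``"QC E"``.
    nominal_conc : float, optional
        Spiked concentration in ng/ml.  Required for STD and QC roles.
    analyte_area : float
        Integrated analyte peak area (response units, >= 0).
    is_area : float, optional
        Internal-standard peak area.  Absent for double blanks, which
        receive neither analyte nor internal standard.
    matrix_lot : str, optional
        Source lot of the biological matrix.
    condition_tag : str, optional
        Free tag: a stability condition or ``with_matrix`` /
        ``without_matrix`` for matrix-effect samples.
    dilution_factor : float
        >= 1; multiplies the back-calculated concentration (dilution
        QCs are measured after dilution into range).
    """

    sample_id: str
    batch_id: str
    role: Role
    analyte_area: float
    is_area: Optional[float] = None
    level_label: Optional[str] = None
    nominal_conc: Optional[float] = None
    matrix_lot: Optional[str] = None
    condition_tag: Optional[str] = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        role = Role(self.role)
        object.__setattr__(self, "role", role)
        if self.analyte_area < 0:
            raise QuantpkError(
                f"sample {self.sample_id!r}: negative analyte area "
                f"{self.analyte_area}"
            )
        if self.is_area is not None and self.is_area < 0:
            raise QuantpkError(
                f"sample {self.sample_id!r}: negative IS area {self.is_area}"
            )
        if role is Role.DOUBLE_BLANK and self.is_area is not None:
            raise QuantpkError(
                f"sample {self.sample_id!r}: double blank must not carry an "
                "internal-standard area"
            )
        if role in (Role.STD, Role.QC):
            if self.nominal_conc is None or self.nominal_conc <= 0:
                raise QuantpkError(
                    f"sample {self.sample_id!r}: role {role.value} requires a "
                    "positive nominal concentration"
                )
        if self.dilution_factor < 1:
            raise QuantpkError(
                f"sample {self.sample_id!r}: dilution factor must be >= 1"
            )

    @property
    def response(self) -> float:
        """Analyte/IS peak-area ratio (requires an IS area)."""
        if self.is_area is None or self.is_area == 0:
            raise QuantpkError(
                f"sample {self.sample_id!r}: area ratio undefined without a "
                "positive IS area"
            )
        return self.analyte_area / self.is_area


@dataclass(frozen=True)
class ConcTimeProfile:
    """One subject's blood concentration-time profile.

    Times are minutes post-dose, strictly increasing.  Concentrations
    are ng/ml; values recorded as 0 at or after the first sample are
    treated as below the limit of quantification (BLQ).
    """

    subject_id: str
    route: Route
    dose: float  # mg/kg
    mw: float  # g/mol
    times: tuple = field(default=())
    concentrations: tuple = field(default=())
    lloq: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise QuantpkError(
                f"profile {self.subject_id!r}: times and concentrations have "
                f"different lengths ({t.size} vs {c.size})"
            )
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise QuantpkError(
                f"profile {self.subject_id!r}: times must be >= 0 and "
                "strictly increasing"
            )
        if np.any(c < 0):
            raise QuantpkError(
                f"profile {self.subject_id!r}: negative concentration"
            )
        if self.dose <= 0:
            raise QuantpkError(f"profile {self.subject_id!r}: dose must be > 0")
        if self.mw <= 0:
            raise QuantpkError(f"profile {self.subject_id!r}: mw must be > 0")
        object.__setattr__(self, "times", tuple(t.tolist()))
        object.__setattr__(self, "concentrations", tuple(c.tolist()))

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def conc_array(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)

    def with_values(self, times: Sequence[float], concentrations: Sequence[float],
                    subject_id: Optional[str] = None) -> "ConcTimeProfile":
        return replace(
            self,
            subject_id=subject_id if subject_id is not None else self.subject_id,
            times=tuple(times),
            concentrations=tuple(concentrations),
        )
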