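"""Run configuration: every acceptance threshold and method option.

Thresholds live here, never hard-coded at call sites, so an audit can
read one record.  Defaults follow regulatory convention: +/-15% QC
accuracy (20% at the LLOQ), matrix-factor CV <= 15%, stability and
cross-matrix limits +/-15%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .records import QuantpkError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # calibration
    model_kind: str = "wagner"
    response_basis: str = "area_ratio"
    weighting: Optional[str] = None
    # acceptance limits (percent)
    qc_limit_pct: float = 15.0
    lloq_limit_pct: float = 20.0
    mf_cv_limit_pct: float = 15.0
    stability_limit_pct: float = 15.0
    crossval_limit_pct: float = 15.0
    # specificity thresholds (fractions of the LLOQ / IS response)
    blank_analyte_threshold: float = 0.20
    blank_is_threshold: float = 0.05
    # batch QC acceptance rule (flag-only): fraction of QCs within
    # limits overall and per level
    qc_rule_overall: float = 0.67
    qc_rule_per_level: float = 0.50
    # NCA options
    lambda_z_selection: str = "auto"
    auc_method: str = "linear"
    anchor_time_zero: bool = True
    # reporting
    rounding_decimals: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("qc_limit_pct", "lloq_limit_pct", "mf_cv_limit_pct",
                     "stability_limit_pct", "crossval_limit_pct"):
            if getattr(self, name) <= 0:
                raise QuantpkError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise QuantpkError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
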