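"""Regenerate tests/data/f_recovery_mc.json (synthetic reference interval).

Runs many independent replicates of the default four-arm PK study
(n=5 animals per arm, 15% residual CV, the standard sparse sampling
schedule) through the full simulate -> NCA -> bioavailability chain
and stores the central 99% interval of the estimated F per arm pair.
The fixed-seed acceptance test asserts containment in this interval.

Usage: python scripts/make_mc_fixture.py [n_replicates]
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

from quantpk import PKTruth, RunConfig, default_study_arms, run_nca, simulate_study

N_ANIMALS = 5
RESIDUAL_CV = 15.0
F_TRUE = 0.25


def estimate_f(seed: int) -> dict:
    base = PKTruth(residual_cv=RESIDUAL_CV, f_true=F_TRUE, seed=seed)
    study = simulate_study(default_study_arms(base), n_animals=N_ANIMALS,
                           seed=seed)
    summary = run_nca(RunConfig(), profiles=[p for v in study.values() for p in v])
    return {
        f"{row['dose_oral_mg_per_kg']:g}": row["f_pct"]
        for row in summary["bioavailability"]
    }


def main() -> None:
    n_rep = int(sys.argv[1]) if len(sys.argv) > 1 else 400
    estimates = {"40": [], "20": []}
    for rep in range(n_rep):
        for arm, f in estimate_f(seed=10_000 + rep).items():
            estimates[arm].append(f)
    out = {
        "conditions": {
            "n_animals": N_ANIMALS,
            "residual_cv_pct": RESIDUAL_CV,
            "f_true": F_TRUE,
            "n_replicates": n_rep,
        },
        "intervals": {
            arm: {
                "lo": float(np.percentile(vals, 0.5)),
                "hi": float(np.percentile(vals, 99.5)),
                "mean": float(np.mean(vals)),
            }
            for arm, vals in estimates.items()
        },
    }
    path = Path(__file__).resolve().parent.parent / "tests" / "data" / "f_recovery_mc.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
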