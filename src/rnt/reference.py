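"""Built-in reference examples and the harness that recomputes them.

Two published chemoradiation trials in stage III non-small-cell lung cancer
(KCSG-LU05-04 and GILT, both comparing chemoradiotherapy with and without
consolidation) serve as worked binary examples, together with two toy rate
pairs and a grid of RNT/NNT values over baseline response rates and rate
differences.  ``run_reference_checks`` recomputes every number from the
package's own estimators and compares against the reference value at its
reported precision (round-half-away-from-zero), returning one row per
check.

GILT reports arm sizes and overall response rates (24.8% and 29.1%) but not
responder counts; the fixture uses 26/105 and 28/96, the unique counts
consistent with the reported rates.
"""

from __future__ import annotations

import math

import pandas as pd

from ._utils import round_half_away
from .binary import BinaryArm, nnt, nnt_ci, nnt_from_rates, rnt_from_rates, rnt_wald_ci

__all__ = ["BINARY_TRIALS", "TOY_CASES", "RNT_NNT_GRID", "run_reference_checks"]

# label, (n_C, responders_C), (n_E, responders_E), expected values at their
# reported precision: NNT (1 d.p.), irregular NNT CI bounds (1 d.p.),
# RNT and its 95% Wald CI (2 d.p.)
BINARY_TRIALS = (
    {
        "label": "KCSG-LU05-04",
        "control": (211, 81),
        "treatment": (209, 90),
        "nnt": 21.4,
        "nntb": 7.1,
        "nnth": 21.2,
        "rnt": 0.28,
        "rnt_ci": (-0.29, 0.86),
    },
    {
        "label": "GILT",
        "control": (105, 26),
        "treatment": (96, 28),
        "nnt": 22.7,
        "nntb": 6.0,
        "nnth": 12.7,
        "rnt": 0.61,
        "rnt_ci": (-1.11, 2.33),
    },
)

#: (p_C, p_E, RNT): the low- and high-response toy pairs that NNT cannot
#: distinguish (both give NNT = 10).
TOY_CASES = ((0.1, 0.2, 5.0), (0.4, 0.5, 0.5))

_BASELINES = (0.8, 0.6, 0.4, 0.2, 0.1, 0.05, 0.01)
_DIFFERENCES = (0.2, 0.15, 0.1, 0.05, 0.01, 0.0)

#: RNT at 2 d.p. by (difference, baseline), plus the NNT column (constant in
#: the baseline); the zero-difference row is RNT 0 everywhere with NNT = inf.
RNT_NNT_GRID = {
    0.2: ((0.25, 0.42, 0.83, 2.50, 6.67, 16.00, 95.24), 5.00),
    0.15: ((0.20, 0.33, 0.68, 2.14, 6.00, 15.00, 93.75), 6.67),
    0.1: ((0.14, 0.24, 0.50, 1.67, 5.00, 13.33, 90.91), 10.00),
    0.05: ((0.07, 0.13, 0.28, 1.00, 3.33, 10.00, 83.33), 20.00),
    0.01: ((0.02, 0.03, 0.06, 0.24, 0.91, 3.33, 50.00), 100.00),
    0.0: ((0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0), math.inf),
}


def run_reference_checks() -> pd.DataFrame:
    """Recompute every reference value; mismatches appear as ``match == False``."""
    rows: list[dict] = []

    def add(case: str, quantity: str, computed: float, expected: float, ndigits: int):
        rounded = round_half_away(computed, ndigits)
        rows.append(
            {
                "case": case,
                "quantity": quantity,
                "computed": rounded,
                "expected": expected,
                "match": rounded == expected,
            }
        )

    for trial in BINARY_TRIALS:
        control = BinaryArm(*trial["control"])
        treatment = BinaryArm(*trial["treatment"])
        label = trial["label"]
        add(label, "NNT", nnt(control, treatment), trial["nnt"], 1)
        nnt_est = nnt_ci(control, treatment)
        add(label, "NNTB", nnt_est.ci.benefit_bound, trial["nntb"], 1)
        add(label, "NNTH", nnt_est.ci.harm_bound, trial["nnth"], 1)
        rnt_est = rnt_wald_ci(control, treatment)
        add(label, "RNT", rnt_est.point, trial["rnt"], 2)
        add(label, "RNT CI lower", rnt_est.ci.lower, trial["rnt_ci"][0], 2)
        add(label, "RNT CI upper", rnt_est.ci.upper, trial["rnt_ci"][1], 2)

    for p_c, p_e, expected in TOY_CASES:
        add(f"toy p_C={p_c}, p_E={p_e}", "RNT", rnt_from_rates(p_c, p_e), expected, 2)

    for diff, (rnt_row, nnt_expected) in RNT_NNT_GRID.items():
        for baseline, expected in zip(_BASELINES, rnt_row):
            case = f"grid baseline={baseline}, diff={diff}"
            add(case, "RNT", rnt_from_rates(baseline, baseline + diff), expected, 2)
        add(f"grid diff={diff}", "NNT", nnt_from_rates(0.5, 0.5 + diff), nnt_expected, 2)

    return pd.DataFrame(rows)
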