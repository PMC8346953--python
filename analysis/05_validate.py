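"""Validate the fitted utilities against out-of-sample risk attitudes.

Measures the CE of each equivariant validation gamble from the held-out
validation sequences, computes CE - EV risk attitudes, and fits the
inflection-anchored linear regression per distribution.  A negative slope
with a sign flip near the fitted inflection corroborates the S-shaped
utilities.  Writes results/validation.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from utiladapt import (
    choice_ratios,
    design_gambles,
    fit_psychometric,
    fit_risk_regression,
    read_trials,
    risk_attitude,
)
from utiladapt.distributions import PRESETS
from utiladapt.psychometrics import PsychometricError
from utiladapt.validation import CENTER_FRACTIONS, ValidationPoint

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = [
        t for t in read_trials(RESULTS / "trials.csv")
        if t.sequence_tag == "validation"
    ]
    adaptation = json.loads((RESULTS / "adaptation.json").read_text())
    inflections = adaptation["inflection_ml"]

    rows, points_by_dist = [], {}
    for lbl in sorted({t.distribution for t in trials}):
        dist = PRESETS[lbl]
        dist_trials = [t for t in trials if t.distribution == lbl]
        for frac, g in zip(CENTER_FRACTIONS, design_gambles(dist)):
            try:
                fit = fit_psychometric(choice_ratios(dist_trials, g), min_repeats=4)
            except PsychometricError:
                continue
            ra = risk_attitude(fit.x0, g)
            infl = inflections.get(lbl)
            points_by_dist.setdefault(lbl, []).append(
                ValidationPoint(gamble=g, ev_ml=g.ev_ml, ce_ml=fit.x0,
                                risk_attitude=ra,
                                ev_minus_inflection=(g.ev_ml - infl
                                                     if infl is not None else np.nan))
            )
            rows.append(dict(distribution=lbl, center_frac=frac,
                             ev_ml=round(g.ev_ml, 6), ce_ml=round(fit.x0, 6),
                             risk_attitude_ml=round(ra, 6),
                             ev_minus_inflection_ml=(round(g.ev_ml - infl, 6)
                                                     if infl is not None else "")))
    pd.DataFrame(rows).to_csv(RESULTS / "validation.csv", index=False)

    print("CE - EV risk attitudes (positive = risk-seeking):")
    for lbl, pts in points_by_dist.items():
        attitudes = ", ".join(f"{p.risk_attitude:+.3f}" for p in pts)
        print(f"  {lbl:5s} [{attitudes}] ml at centers 25/45/65/85%")
        infl = inflections.get(lbl)
        if infl is not None and len(pts) >= 3:
            reg = fit_risk_regression(pts, infl)
            print(f"        regression: beta0 {reg.beta0:+.4f} ml, "
                  f"beta1 {reg.beta1:+.3f}, R^2 {reg.r_squared:.3f}")
    print(f"wrote {RESULTS / 'validation.csv'}")


if __name__ == "__main__":
    main()
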