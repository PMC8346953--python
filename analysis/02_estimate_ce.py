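"""Estimate certainty equivalents from the simulated choices.

Runs the fractile bookkeeping day by day: fits the logistic psychometric
curve to each gamble's safe-ladder choice ratios and assigns the chained
utility levels (0.5; 0.25/0.75; 0.125/0.875).  Writes results/cepoints.csv
and prints the mean normalized CE per utility level and distribution —
the raw material of the utility curves.
"""

from pathlib import Path

import pandas as pd

from utiladapt import read_trials, run_fractile
from utiladapt.distributions import PRESETS
from utiladapt.psychometrics import PsychometricError

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_trials(RESULTS / "trials.csv")
    fractile = [t for t in trials if t.sequence_tag.startswith("fractile")]
    rows = []
    discarded = 0
    days = sorted({t.day_index for t in fractile})
    for day in days:
        day_trials = [t for t in fractile if t.day_index == day]
        dist = PRESETS[day_trials[0].distribution]
        try:
            points = run_fractile(day_trials, dist, min_repeats=4)
        except PsychometricError:
            discarded += 1
            continue
        for p in points:
            rows.append(
                dict(session_id=p.session_id, day_index=day,
                     distribution=p.distribution, step=p.step,
                     utility_level=p.utility_level, ce_ml=round(p.ce_ml, 6),
                     ce_normalized=round(dist.normalize(p.ce_ml), 6),
                     x0=round(p.x0, 6), sigma=round(p.sigma, 6))
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cepoints.csv", index=False)
    print(f"{len(days)} sessions, {discarded} discarded by the 3-level filter, "
          f"{len(df)} CE points")
    table = df.pivot_table(index="utility_level", columns="distribution",
                           values="ce_normalized", aggfunc="mean").round(3)
    print("\nmean normalized CE per utility level:")
    print(table.to_string())
    print(f"\nwrote {RESULTS / 'cepoints.csv'}")


if __name__ == "__main__":
    main()
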