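"""Fit the discrete-choice model per day for all five utility families.

Maximizes the trial-level logit likelihood for each (day, family), scores
each fit by BIC and 10-fold cross-validated held-out likelihood, and
applies the pooled 3-SD ln-parameter outlier rule to the winning family.
Writes results/fits.jsonl and prints the model-selection table.
"""

import dataclasses
from pathlib import Path

import numpy as np

from utiladapt import FAMILIES, crossvalidate, fit_dcm, flag_outliers, read_trials
from utiladapt.dcm import FitError
from utiladapt.distributions import PRESETS
from utiladapt.io import write_fits
from utiladapt.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig.from_yaml(RESULTS / "config.yaml")
    trials = read_trials(RESULTS / "trials.csv")
    fractile = [t for t in trials if t.sequence_tag.startswith("fractile")]
    days = sorted({t.day_index for t in fractile})

    records = []
    for day in days:
        day_trials = [t for t in fractile if t.day_index == day]
        dist = PRESETS[day_trials[0].distribution]
        for family in FAMILIES:
            try:
                fit = fit_dcm(day_trials, family, dist, n_starts=5,
                              seed=cfg.seed + day)
            except FitError:
                continue
            cv = crossvalidate(day_trials, family, dist, seed=cfg.seed + day,
                               n_starts=5)
            records.append((day, dist.label, dataclasses.replace(fit, cv_negll=cv)))
    write_fits(records, RESULTS / "fits.jsonl", meta=f"seed={cfg.seed}")

    print("median BIC / CV held-out -LL per family:")
    table = {}
    for family in FAMILIES:
        fam = [f for _, _, f in records if f.family == family]
        table[family] = (np.median([f.bic for f in fam]),
                         np.median([f.cv_negll for f in fam]))
        print(f"  {family:10s}  BIC {table[family][0]:8.2f}   CV {table[family][1]:7.3f}")
    best = min(table, key=lambda k: table[k][0])
    print(f"selected family: {best}")

    best_fits = [f for _, _, f in records if f.family == best]
    kept, excluded = flag_outliers(best_fits)
    print(f"outlier rule: kept {len(kept)}, excluded {len(excluded)}")
    print(f"wrote {RESULTS / 'fits.jsonl'}")


if __name__ == "__main__":
    main()
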