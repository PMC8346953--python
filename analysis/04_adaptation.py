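"""Measure utility adaptation across the three reward distributions.

From the winning family's daily fits (outliers removed): median utility
curve per distribution, inflection points and curvature ratios, predicted
(rescaled) inflections, sequential SAC and general GAC coefficients, and a
small Monte-Carlo no-adaptation control run through the same estimation
chain.  Writes results/adaptation.json.
"""

import json
from pathlib import Path

import numpy as np

from utiladapt import (
    flag_outliers,
    gac,
    median_curve,
    monte_carlo_no_adaptation,
    rescale_inflection,
    sac,
)
from utiladapt.adaptation import UndefinedGACError
from utiladapt.agent import FractileConfig
from utiladapt.distributions import PRESETS
from utiladapt.io import read_fits
from utiladapt.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig.from_yaml(RESULTS / "config.yaml")
    records = read_fits(RESULTS / "fits.jsonl")
    by_family = {}
    for day, label, fit in records:
        by_family.setdefault(fit.family, []).append((day, label, fit))
    best = min(
        by_family,
        key=lambda fam: np.median([f.bic for _, _, f in by_family[fam]]),
    )
    kept, excluded = flag_outliers([f for _, _, f in by_family[best]])
    kept_ids = {id(f) for f in kept}
    by_dist = {}
    for _, label, fit in by_family[best]:
        if id(fit) in kept_ids:
            by_dist.setdefault(label, []).append(fit)

    order = [lbl for lbl, _ in cfg.blocks if lbl in by_dist]
    curves = {lbl: median_curve(by_dist[lbl]) for lbl in by_dist}
    out = {"best_family": best, "n_excluded": len(excluded)}

    print(f"family: {best} ({len(excluded)} outlier fits removed)")
    out["inflection_ml"], out["curvature_ratio"] = {}, {}
    for lbl in order:
        dist = PRESETS[lbl]
        sm = curves[lbl].shape_metrics(dist)
        out["inflection_ml"][lbl] = sm.inflection_ml
        out["curvature_ratio"][lbl] = sm.curvature_ratio
        infl = "none" if sm.inflection_ml is None else f"{sm.inflection_ml:.3f} ml"
        print(f"  {lbl:5s} params {np.round(curves[lbl].params, 3)} "
              f"inflection {infl}, CR {sm.curvature_ratio:.3f}")

    out["sac"] = {}
    for prev, nxt in zip(order, order[1:]):
        s = sac(curves[nxt], curves[prev])
        out["sac"][f"{prev}->{nxt}"] = s
        print(f"  SAC {prev}->{nxt}: {s:+.3f}")

    out["gac"], out["predicted_inflections"] = {}, {}
    full = PRESETS["full"]
    for lbl in order:
        if lbl == "full":
            continue
        try:
            g = gac(curves[lbl], curves["full"], PRESETS[lbl], full)
        except (UndefinedGACError, KeyError):
            g = None
        out["gac"][lbl] = g
        print(f"  GAC {lbl}: {'undefined' if g is None else f'{g:.3f}'}"
              " (0 = none, 1 = full adaptation)")
        if out["inflection_ml"].get("full") is not None:
            out["predicted_inflections"][lbl] = rescale_inflection(
                out["inflection_ml"]["full"], full, PRESETS[lbl]
            )

    narrow = [PRESETS[lbl] for lbl in order if lbl != "full"]
    mc = monte_carlo_no_adaptation(
        curves["full"], narrow, full, n_reps=20, days_per_dist=3,
        seed=cfg.seed, temperature=cfg.temperature,
        fractile_config=FractileConfig(repeats=cfg.repeats),
    )
    out["monte_carlo_null"] = mc.summary()
    print("Monte-Carlo no-adaptation control (20 reps):")
    for lbl, s in mc.summary().items():
        print(f"  {lbl}: median GAC {s['gac_median']:.3f} "
              f"[{s['gac_p2.5']:.3f}, {s['gac_p97.5']:.3f}]")

    (RESULTS / "adaptation.json").write_text(
        json.dumps(out, indent=2, default=float), encoding="utf-8"
    )
    print(f"wrote {RESULTS / 'adaptation.json'}")


if __name__ == "__main__":
    main()
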