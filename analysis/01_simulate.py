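"""Simulate the multi-week choice dataset.

A partially adapting S-shaped agent (2-parameter Prelec, alpha=2, beta=1;
logit temperature 12) works through a schedule of three reward
distributions — low (0-0.5 ml), full (0-1.0 ml), high (0.5-1.0 ml), five
days each — producing daily three-step fractile elicitation sequences plus
one out-of-sample validation sequence per distribution.  Writes
results/trials.csv and results/config.yaml for the downstream steps.
"""

from pathlib import Path

from utiladapt import FractileConfig, PipelineConfig, generate_validation_session
from utiladapt.agent import build_schedule, day_rng, generate_fractile_session
from utiladapt.io import write_trials
from utiladapt.pipeline import _dist_from_spec

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = PipelineConfig(
    agent_family="prelec2",
    agent_params=(2.0, 1.0),
    temperature=12.0,
    adaptation_mode="partial",
    adaptation_weight=0.6,
    reference="full",
    seed=7,
    blocks=(("low", 5), ("full", 5), ("high", 5)),
    repeats=8,  # ~150-250 trials/day, matching reported session sizes
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    CONFIG.to_yaml(RESULTS / "config.yaml")
    agent = CONFIG.make_agent()
    fcfg = FractileConfig(repeats=CONFIG.repeats)
    schedule = build_schedule(
        [(_dist_from_spec(lbl), n) for lbl, n in CONFIG.blocks]
    )
    trials = []
    degenerate = 0
    for day, dist in schedule:
        sess = generate_fractile_session(agent, dist, day_index=day, config=fcfg)
        degenerate += sess.degenerate
        trials.extend(sess.trials)
    seen = []
    for day, dist in schedule:
        if dist.label in seen:
            continue
        seen.append(dist.label)
        vday = 1000 + day
        trials.extend(
            generate_validation_session(
                agent, dist, day_index=vday, config=fcfg,
                rng=day_rng(CONFIG.seed, vday),
            )
        )
    write_trials(trials, RESULTS / "trials.csv",
                 header_comment=f"config_sha256={CONFIG.sha} seed={CONFIG.seed}")
    print(f"simulated {len(trials)} trials over {len(schedule)} days "
          f"({degenerate} degenerate fractile sessions)")
    print(f"wrote {RESULTS / 'trials.csv'}")


if __name__ == "__main__":
    main()
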