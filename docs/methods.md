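# Methods

## Task and data model

The unit of data is a binary choice trial between a *safe* reward (one
outcome, p = 1) and an *equiprobable two-outcome gamble* (each outcome
p = 0.5), recorded with the chosen side. Trials belong to daily sessions;
each session runs under one *reward distribution* — a fixed range of juice
magnitudes in ml. The canonical ranges are low (0–0.5 ml), high
(0.5–1.0 ml) and full (0–1.0 ml), with an alternate full range
(0.1–1.3 ml); ranges are held fixed for blocks of consecutive days.

Two session types exist. *Fractile* sessions implement three-step bisection
elicitation: the (min, max) gamble is paired against a ladder of safe
rewards in 0.05-ml increments; the certainty equivalent (CE) read off that
block carries utility 0.5; gambles (min, CE) and (CE, max) — their
ladder blocks interwoven in one sequence — yield CEs at utilities 0.25 and
0.75; a third chained step yields 0.125 and 0.875. *Validation* sessions
present four equivariant gambles per range (spread 30% of the range,
centers at 25/45/65/85%) against safe ladders, held out from utility
fitting.

## Simulated agents

An agent is a utility curve plus logit parameters: temperature λ
(default 10; choices are strongly but not perfectly value-guided, and
simulated psychometric curves then show realistic slopes) and side bias θ
(default 0). Choice probabilities are
`expit(λ(EU_left − EU_right) + θ)`; θ > 0 favors the left side. Expected
utility evaluates magnitudes normalized by the agent's *effective anchors*:

- `full` adaptation — the current session's range (the utility re-anchors
  wholesale to whatever is in play);
- `none` — a fixed reference range (narrow-range magnitudes are evaluated
  as segments of one absolute curve);
- `partial(w)` — anchors interpolate linearly,
  `w·current + (1−w)·reference`. This is the device that produces GAC
  values strictly between 0 and 1.

Simulated CEs are read off fitted psychometric inflections (continuous, not
snapped to the 0.05-ml grid). A CE landing within half a ladder step of a
range bound marks the session degenerate and stops the chain — the
counterpart of discarding sessions with fewer than three reliable utility
levels.

Ladder extent is a design choice the task description leaves open: rungs
are the 0.05-ml multiples (anchored at the range minimum) spanning the
gamble's outcome interval plus one rung of margin, clipped to the range.
Each gamble/safe pair repeats a configurable number of times (default 4,
the minimum that survives the elicitation filter; 8 repeats produce
150–500-trial sessions, matching reported day sizes of ~130–320 trials).

Reproducibility: one top-level seed; the stream for day *d* is
`default_rng(SeedSequence([seed, d]))`, so any single session can be
regenerated bit-identically without replaying the schedule.

## Psychometric CE estimation

`P(choose safe) = 1/(1 + exp(−(m − x₀)/σ))` with exactly two free
parameters (no lapse rates). The default objective is binomial maximum
likelihood on per-rung counts — rungs with unequal trial counts are then
weighted correctly; an unweighted least-squares mode on the raw ratios is
available (`method="ls"`). The two agree on noiseless data and differ
negligibly on balanced designs. Filters: at least 3 distinct rungs, each
presented at least 4 times. Initialization at the empirical 50% crossing
with σ at a quarter of the rung span, three jittered restarts; σ is bounded
in [1e−4 ml, 10× span] and a fit at the upper bound (flat ratios) is
reported as degenerate rather than returned. An x₀ more than one ladder
step outside the tested rungs is rejected for fractile chaining.

## Discrete-choice fitting

Trial-level Bernoulli likelihood of left choices under the logit rule, with
probabilities clamped at 1e−12 before the log. Utility parameters are
bounded to keep every family monotone and identifiable: α ∈ [0.05, 20]
(power/Prelec curvature), Prelec β ∈ [0.05, 20], two-sided-power knot
β ∈ [0.01, 0.99], three-parameter-power reference γ ∈ [0, 1] with
loss-weight β ∈ [0, 10] (β defaults to 1 on gains-only data); the Tversky
exponent is bounded below at 0.3, under which the form loses monotonicity.
λ ∈ [0, 1000], θ ∈ [−10, 10].

Optimization is bounded L-BFGS-B from Latin-hypercube multi-starts
(default 10; λ starts drawn below 50), best objective retained. Runs that
terminate on a line-search failure but return a finite optimum are kept as
fallback candidates and flagged `converged=False`. Refits with the same
seed are bit-identical.

BIC = k·ln(n) − 2·LL with k counting utility parameters **plus λ and θ**
(configurable; the convention is not dictated by the estimation itself).
Cross-validation uses seeded 10-fold splits, stratified by sequence tag
when every tag supports 10 folds; each fold refit warm-starts from the
full-session optimum. The outlier rule pools ln-transformed utility
parameters across all supplied fits (days and subjects together) and drops
fits beyond mean ± 3 SD per parameter; a zero-SD pool drops nothing.

### Model recovery and nested families

The Prelec family with α = 1 *is* the power law m^β, and several other
pairs are near-nested. For data generated from the simpler member, the
richer member attains an equal likelihood, so per-session cross-validated
scores differ only by an overfitting penalty of order k/2 log-units —
comparable to CV noise. On generic random gamble/safe trials the
per-session CV winner is therefore close to a coin flip among the
near-equivalent families. On fractile-structured sessions — ladders
concentrated near indifference points, where curve-shape differences move
choice probabilities most — both BIC and CV pick the generating family in
a clear majority of sessions. Model-recovery checks in this package
therefore use fractile-session templates, which are also the task's actual
trial structure.

## Utility families and shape metrics

All families are anchored: U(0) = 0, U(1) = 1 (the Prelec form at m = 0 by
limit, with evaluation clamped at 1e−12; the three-parameter power by
affine rescaling of its raw two-branch form, which is not intrinsically
anchored). The printed source of the two-sided-power CDF is garbled in the
literature this package follows; the standard form with knot β and
curvature α is implemented and verified against its shape contract (α > 1
S-shaped with the inflection at the knot, α < 1 inverse-S). The
1-parameter Tversky form is named but never written in that literature; the
standard form m^γ/(m^γ + (1−m)^γ)^{1/γ} transplanted from probability
weighting to magnitude is used — **a reconstruction**, flagged as such.

Inflections (interior curvature reversals) are found analytically where
tractable: none for pure power curves; the knot β for the two-sided power;
γ for the three-parameter power; for the Prelec family the unique positive
root of βαt^α − t − (α−1) in t = −ln m (bracketed scan + Brent). The
Tversky family uses a sign-change scan of central second differences
(h = 1e−4) refined by Brent. Curvature ratios integrate U over [0, 1] by
composite trapezoid on 10 001 points (exact for the linear curve; ~1e−9
agreement with closed forms for smooth power curves).

## Adaptation metrics

SAC is computed on the normalized domain, so it reduces to the relative
change in curvature ratio — both curves are anchored on [0, 1], making
the areas directly comparable.

GAC embeds the narrow-range utility into normalized full space on the
sub-interval [a, b] with image slots [c, d] = [U_full(a), U_full(b)] — for
the lower half-range [0, U_full(b)], for the upper [U_full(a), 1], exactly
the half-range anchoring rule of the task design. The rescaled template is
U_adapt(x) = c + (d−c)·U_full((x−a)/(b−a)); integrals are trapezoid on
10 001 points over [a, b]. Two degeneracies are reported as *undefined*
rather than 0 or 1: a linear full curve, and — less obviously — a pure
power law compared over a narrow range that shares the full range's
minimum, since m^α is self-similar under rescaling about 0 and the
denominator vanishes. GAC requires the narrow range to be nested in the
full range and refuses otherwise (so a low-vs-high comparison is an error,
not a number).

Inflection points are compared across ranges by preserving relative
position (affine map); a mapped value outside the target range is set to
the nearer bound with a clip flag. The worked identity: 0.3 ml in the full
range (0–1 ml) ↔ 0.15 ml in the low range (0–0.5 ml). The source
literature contains one sentence implying the opposite direction for the
low→full map; relative-position preservation (under which low→full sends
0.3 ml to 0.6 ml) is the self-consistent reading and is what is
implemented.

Median curves are **parameter-wise** medians of daily estimates, not
pointwise medians of curves; for monotone families the two differ little,
but the parameter-wise version is what downstream metrics consume.

The Monte-Carlo control pushes a known agent (non-adapting or fully
adapting, built from the full-range curve) through the whole chain —
fractile simulation, daily Prelec refits, parameter-wise medians, GAC/SAC —
and returns rep-level coefficient draws. Defaults: 1000 reps at 5 days per
narrow range; the test suite and analysis drivers run 20–30 reps at 3–5
days with 8 ladder repeats, sizes chosen to keep the full study
reproducible on a laptop while leaving the medians stable (at these sizes
the non-adapting median GAC sits within ±0.06 of 0 and the fully adapting
one within ±0.05 of 1).

## Validation regression

CE − EV = β₀ + β₁(EV − inflection), unweighted OLS pooled over a
distribution's validation points (a flag on the caller's side can pool
globally instead; per-distribution is the default because inflections are
distribution-specific). β₁ < 0 is the signature of an S-shaped utility;
β₀ is the residual risk attitude at the inflection. CE measurement noise
matters here: near the top of a range the utility is shallow, the
psychometric slope is low, and the SE of a CE from an 8-rung ladder at
λ = 10 is of the same order (~0.05–0.1 ml) as the risk-attitude effects
being measured; low-noise checks of the sign-reversal geometry use higher
temperature and more ladder repeats.

## What the synthetic data do and do not show

The generator reproduces the task's trial structure, the logit choice
rule, the fractile chaining (including its error propagation), the
session-size regime, and controllable ground-truth adaptation. It does not
model satiety or motivation drifts, reaction times, error/timeout trials,
within-session learning, sequential choice dependencies, or probability
distortion (options are valued strictly by expected utility — probability
weighting is deliberately out of scope, as all gambles are at p = 0.5).
Passing recovery tests therefore demonstrate that the estimation chain is
correct and well-conditioned under the task's statistical structure — not
that real subjects satisfy the model's assumptions.

## Interfaces

The library is the interface: the numbered drivers under `analysis/` and
the single-config `pipeline.run_pipeline` cover the end-to-end flow
(simulate → CE → fit → adapt → validate → report), so no separate
command-line binary is shipped. Trial tables are plain CSV (safe options
leave their second outcome columns empty); fits are JSON lines; adaptation
reports are JSON; every artifact records the config hash and seed that
produced it.
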