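# Methods

## Setting

We model continuing decision tasks: an unbounded sequence of trials indexed
by `k`, each presenting a within-trial state sequence, a reward `R_k`
determined by the report and the trial's outcome, and a duration `T_k` that
depends on *when* the report was made. Performance is the stationary reward
rate `ρ = lim Σ R_k / Σ T_k`. All times are measured in token-jump steps
(one step = 200 ms in the primate experiments this emulates); durations are
converted to seconds only at I/O boundaries.

Two opportunity costs organize everything:

- **Commitment cost** `C_com(t) = r_max − r̄_t`: the expected reward given
  up by reporting now instead of with full information. It decays from
  `Δr/2` (at an uninformative start, symmetric payoff) to 0 at the horizon.
- **Deliberation cost** `C_del(t)`: the accumulated opportunity cost of the
  time spent deliberating, built from the agent's reward-rate estimates.

The average-reward-optimal policy maximizes `r_max − (C_com + C_del)`
(equivalently the average-adjusted return). PGD instead reports at their
first crossing, `t_dec = min{t : C_del(t) ≥ C_com(t)}`. The rule needs no
value table: only the learned environment statistics (for `C_com`) and the
agent's own performance history (for `C_del`). In belief space it is a
collapsing boundary `b_t ≥ r_max − C_del(t)`, independent of evidence at
fixed trial time.

## Tokens task

The evidence is an i.i.d. ±1 jump sequence of odd length `t_max` (default
15) with positive-jump probability `p ≥ 1/2` (default 1/2); the sufficient
state is the token difference `N_t`. The exact success probability is the
binomial tail over the `t′ = t_max − t` remaining jumps,

    p⁺(n, t) = Σ_{n′ = ⌈(t′−n)/2⌉}^{t′} C(t′, n′) p^{n′} (1−p)^{t′−n′},

equal to 1 when `⌈(t′−n)/2⌉ ≤ 0`. For `t′ ≤ 60` the sum is accumulated with
exact integer binomial coefficients and compensated summation (machine-exact
for the default horizon); longer horizons (supported up to a few hundred
steps) fall back to the regularized-incomplete-beta tail, which is
overflow-safe. The belief of a correct greedy report is
`b_t = max{p⁺, 1 − p⁺}`; with a payoff matrix `R = (r_{s,a})` the per-action
expected rewards are `[p⁺, 1−p⁺] · R` and `r̄_t` is their maximum. Reward
asymmetry is introduced by scaling the `a = +` column by `(1+γ)` and the
`a = −` column by `(1−γ)`, which biases + reports while preserving the total
diagonal reward; the + reporting boundary then shifts toward negative `n` in
proportion to `γ`. Exact ties (`N_t = 0` under a symmetric payoff) are
broken by a seeded uniform draw.

A sigmoid approximation `p⁺ ≈ 1/(1 + e^{−(at+b)n})` with the published
constants `a = 0.03725, b = 0.3557` (for `t_max = 15`) is provided for
analysis convenience; its worst error before step 12 is below 0.05. The
constants are treated as given inputs — no fitting loss for them is
specified, so the package does not refit them — and all internal
computations use the exact expression.

Deciding at `t` yields duration `T = t + (1−α)(t_max − t) + T_ITI`: the
remaining jumps play out at an interval contracted by `(1−α)`, and a fixed
inter-trial dead time `T_ITI = 7.5` steps follows. The incentive strength
`α` (slow 1/4, fast 3/4) is the context; schedules are periodic
(default block length 300 trials), irregular (uniform block lengths within
configurable bounds), or custom sequences. The experimental sessions this
emulates also included a random 2–3-step set-up wait at the trial start;
that time was excluded from the original analyses and is not simulated.
`T_ITI` is treated as a constant, not scaled by `(1−α)`.

## Performance filtering

Reward history is filtered with the exponential low-pass update
`ρ̂_t = (1−β) ρ̂_{t−1} + β R_t`, `β = 1/(1+τ)`. Because trial rewards are
sparse, the implementation applies the algebraically identical end-of-trial
cumulative form

    ρ̂_k = (1−β)^{T_k} ρ̂_{k−1} + (1 − (1−β)^{T_k}) (R_k / T_k),

which equals `T_k` step-wise updates of the smoothed reward (verified to
1e−12 in the tests). The first trial seeds the filter with its own sample
`R_1/T_1` rather than relaxing from zero. Since the agent is assumed to have
learned the expected reward, the filters are fed `r̄` at the decision state
rather than the realized binary reward, scaled by the subjective reward
factor `K`. Objective performance metrics always use unscaled realized
rewards; `K` affects only the agent's internal costs.

Two filters run in parallel: `τ_long` (default 2×10⁴ steps) estimates the
stationary rate `ρ`; `τ_context` (default 10³ steps) tracks the
context-conditioned rate `ρ_α`. The trial-aware deliberation cost is

    C_del(t) = ρ̂_long t + (ρ̂_context − ρ̂_long) T_prev,

the offset being the context-specific cost deviation of a whole trial, paid
at the trial start (it vanishes in expectation when contexts are evenly
mixed, recovering plain average-reward behaviour). The offset uses the
previous trial's duration in lieu of the context-average duration, the
end-of-trial discrete equivalent of integrating the filter difference
within the trial. A trial-unaware variant `C_del = ρ̂_context · t` and the
stationary `ρ̂_long · t` are also implemented for comparison.

The context filter's integration time is itself modulated by a tracking
cost: with `T_sys` the current trial duration and `T_track` a filtered
duration estimate, `Q = T_sys/T_track` and `τ_eff = τ_context/(1 + Q^ν)`.
The division form (scaling τ *down* with tracking cost) is adopted; the
sensitivity `ν > 1` (default 4) makes adaptation after fast-to-slow context
switches quicker than the reverse, the asymmetry seen in switch-aligned
decision-time averages. Filter defaults were chosen so that `τ_context`
averages over trial noise but not over blocks, and `τ_long` averages over
several block periods, for the default 300-trial blocks.

An optional zero-mean Gaussian perturbation of the cost offset (default
off) is provided as a hook for behavioural noise; it widens the spread of
the survival surfaces without changing their means.

## Average-reward dynamic programming

The episodic optimality equations condition value on trial time:
`Q(n,±|t) = r̄_a(n,t) − ρ(T(t) − t)` (reporting collapses the remainder of
the trial at cost rate ρ), `Q(n,wait|t) = −(ρ + c) + E[V(n±1, t+1)]`, with
the auxiliary deliberation cost rate `c` incurred only before the decision,
the recursion seeded at `t_max` by the best report (never reporting is
always sub-optimal), and the value shift fixed so the start-of-trial value
is zero. Reporting wins exact value ties (waiting at a tie only postpones);
a 1e−12 tolerance guards against floating-point tie noise — at `α = 0`
whole regions of the lattice are analytically tied.

The self-consistent rate solves `ρ = R̄(π_ρ)/T̄(π_ρ)` for the greedy policy
`π_ρ`: bisection on `g(ρ) = R̄ − ρT̄` over `[0, r_max/T_ITI]`, followed by a
fixed-point polish `ρ ← R̄/T̄` that is exact once the policy stabilizes
(`g` is piecewise linear in ρ). `R̄, T̄` are computed by exact probability
flow over the lattice; an independent oracle enumerates all `2^{t_max}`
equiprobable walks (capped at `t_max ≤ 21`) and agrees to better than
1e−10. With `c > 0` the greedy objective and the plain rate differ, so the
rate map can jump across the diagonal at a policy switch with no fixed
point; in that degenerate case the better of the two boundary policies is
returned with its exact rate. A discount-reward value iteration run near
the undiscounted limit (γ = 1 − 10⁻⁵, with the trial-start value solved
exactly per policy iteration rather than by slow fixed-point relaxation)
reproduces the same policies.

The solutions interpolate between wait-for-certainty (report at the first
`b_t = 1` state; optimal at low α, low c) and one-and-done (report after the
first jump, in its direction; optimal at high α or high c), and never report
at ambiguous states mid-trial — the qualitative mismatch with observed
behaviour that motivates PGD. `best_c_fit` chooses the `c` whose policy,
applied to the same walks as an observed log, minimizes the mean absolute
decision-time difference. A constant movement cost on reports (default 0)
is supported.

## Patch-leaving task

`d` patches with fixed richnesses `r_max,s` (sampled once, uniform on (0,1]
by default) share the saturating return profile `r_s(t) = r_max,s(1 −
(λt)^{−1})`, λ = 1/5 by default. Maximizing the average-adjusted return
`r − ρt` gives `t*(r_max) = √(r_max/(λρ))`, which coincides with the PGD
crossing condition `ρt = r_max/(λt)` — the task is constructed so PGD is
optimal — and yields the closed-form optimal rate `ρ* = λμ₁²/(4μ½²)` in the
large-`d` limit (the published leave-time expression `r_max/(λρ)` is
dimensionally inconsistent with this profile; the square-root maximizer,
which reproduces the published ρ*, is used). Decisions live on the integer
grid `1..t_cap` with `t_cap = ⌈4 t*(max richness)⌉` at a reference rate;
the grid induces a finite loss floor. Negative returns at very early leave
times are permitted as the profile dictates; the grid starting at `t = 1`
avoids the `t = 0` divergence.

The PGD learner filters its realized reward through the cumulative update
(τ = 10⁴ steps by default) and reads the current patch's richness directly;
it never references patch labels. The tabular AR-RL learner stores an
average-adjusted return `Q̂(s, t)` per patch *label* (initialized at −1),
trained off-policy from the PGD learner's decisions with the same
learning-rate machinery — a comparison generous to AR-RL, since it
sidesteps exploration. Learning curves report the relative loss
`(ρ* − ρ_policy)/ρ*` of the exactly evaluated current greedy policy. At a
configurable step (default 5×10⁵ of 10⁶) the labels are randomly permuted:
PGD is statistically unaffected, while the AR-RL learner's loss jumps back
by an order of magnitude or more above its pre-permutation floor and must
relearn.

## Behavioural analytics and fitting

**Survival surfaces.** The policy summary is `P(t < t_dec | N_t, t)`,
estimated per lattice cell as the visit-normalized fraction of trials still
undecided — full walks are required so that visits after the report are
counted, removing the visitation bias of raw decision histograms. Unvisited
cells are reported missing, never imputed. Decision times are binned at the
token step. Half-maximum contours summarize context differences: fast-block
contours sit at earlier times than slow-block ones.

**Switch-aligned averages.** Mean decision times in a fixed window (default
20 trials) around each context-switch type, with standard errors over
events; windows are truncated at session edges.

**Reward-rate accounting.** For reaction-time tasks reported in seconds:
`rate = accuracy / (t_response + (1 − accuracy) · penalty + ITI)`. With the
published inputs (accuracy 0.71 at 0.527 s response, accuracy 0.49 at
0.725 s, 1 s penalty and 1 s ITI) this yields 0.391 and 0.219 rewards/s for
the two- and four-choice contexts — matching the published 0.40 and 0.22 to
within one unit of their printed precision. (The accompanying published
claim of a 2.3 rate *ratio* is inconsistent with those same printed rates,
whose ratio is ≈1.8; the accounting here reproduces the rates and leaves
the ratio discrepancy flagged.)

**Fitting.** `PGDBehaviourModel` fits `(τ_long, τ_context, K, ν)` by
minimizing the uniformly weighted squared error between data and model
switch-aligned series. The model series is computed on the *same* α
sequence as the data but with model-generated walks (per-trial walks are
not assumed available to the fitter); walk noise is suppressed by averaging
over repetitions (default 5–8) with fixed per-repetition seeds, making the
objective deterministic. Nelder-Mead operates on log-parameters (all four
positive), with a configurable initial simplex scale (default 0.35 in
log-space) and an iteration cap; non-convergence flags the result rather
than raising. The dependence on `τ_long` is intentionally weak — it is
identified only up to the requirement of averaging over several blocks —
so recovery claims concern `τ_context` and `K`.

**Urgency prediction.** A fitted agent replayed on an α sequence yields
per-trial cost lines `C_del(t) = o_k + ρ̂_long,k t` (the state *entering*
each trial); grouping by context gives mean ± sd curves. Their structure —
a shared slope across contexts (`ρ̂_long` barely moves between blocks when
`T_block ≪ τ_long`) and a context-signed baseline offset, higher in the
fast context — is the model's account of recorded neural urgency. Curves
are in cost units; mapping to firing rates is an affine presentation choice.

## Synthetic sessions and what they do not show

`generate_fixture` emulates alternating-block sessions: periodic blocks of
300 trials, or irregular blocks with lengths uniform on configurable bounds
(default 50–250 trials, echoing the irregular experimenter-driven sessions)
played by a ground-truth PGD agent (defaults `τ_long = 5000`,
`τ_context = 50`, `K = 1.2`, `ν = 4`), with optional lapse noise replacing a
fraction of decision times with uniform draws. Ground truth is embedded in
the log metadata for recovery experiments. These sessions reproduce the
block structure, decision-time relaxation and context-conditioned rates of
real sessions, but not motor latencies, sub-step timing, lapses of
motivation, or the behavioural noise that widens real survival surfaces —
passing recovery tests therefore demonstrates estimator consistency within
the model class, not that real subjects are PGD agents.

## Problem sizes and numerical defaults

Test and acceptance computations use: the full 2¹⁵-walk enumeration for
belief and policy oracles; a 5×5 (α, c) grid for dynamic-programming
self-consistency at tolerance 1e−10; patch runs of 10⁶ steps with d = 300;
periodic sessions of 2400 trials for context-ordering and urgency
structure; a 3×3 (τ_long, T_block) grid with five seeds and burn-in of
three filter timescales for the error-scaling slope; and ten 6000-trial
irregular sessions with eight model repetitions per objective evaluation
for parameter recovery. Bisection tolerance for ρ is 1e−10 with bracket
`[0, r_max/T_ITI]`; filter states are finite by construction; degenerate
inputs (even horizons, off-lattice states, non-positive durations, empty
schedules or grids) raise informative errors rather than propagating NaNs.

## Known limitations

- PGD's commitment cost is assumed already learned; learning `r̄` online
  (e.g. via distributional codes) is out of scope.
- Evidence is Bernoulli; drift-diffusion variants and correlated evidence
  are not modelled.
- The two-filter hierarchy is fixed; the timescale set is not learned.
- Fit quality is assessed on switch-aligned first moments only; matching
  full decision-time distributions would require the noise sources noted
  above.
- The enumeration oracle is exponential in the horizon and capped at
  `t_max = 21`; the DP solver itself scales to long horizons.
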