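# Methods

## Model

The model tracks, per action, the collective strengths `G` (Go/direct
pathway) and `N` (No-Go/indirect pathway), both constrained to be
non-negative.  A single teaching signal, the outcome prediction error
`δ = r − (G − N)/2`, drives both pathways through the piecewise-linear
transform `f_ε` (identity for `δ ≥ 0`, slope `ε` for `δ < 0`):

    ΔG = α f_ε(δ) − λG,    ΔN = α f_ε(−δ) − λN.

The transform's opponency identities, `f_ε(x) − f_ε(−x) = (1+ε)x` and
`f_ε(x) + f_ε(−x) = (1−ε)|x|`, turn the rule pair into a mean-tracking rule
for `Q = (G−N)/2` and a spread-tracking rule for `S = (G+N)/2`.  The model
assumes costs and payoffs of one action arrive as separate events (cost
first), that the error signal is shared by both pathways, and that the
pathways differ only in the sign with which they receive it and in the
asymmetry introduced by `f_ε`.

### Clipping and decay conventions

* Both raw updates are computed from the pre-event weights, then each
  weight is clipped at zero independently.  Simultaneous update from
  pre-values is what makes the two-event trial composition a linear map and
  hence analytically solvable.
* When clipping fires, `(G, N)` is the canonical state; `(Q, S)` is always
  derived from it.  The `(Q, S)` update rule is exact only on clip-free
  stretches, and the tests assert equivalence only there.
* Decay applies on every prediction-error event, including both events of a
  cost-then-payoff trial.  Weights of actions not experienced on an event
  are not decayed: learning (and forgetting) is gated by participation.
  This choice is required for the two-event fixed-point composition to hold
  and leaves unvisited actions' memories intact.

## Equilibrium theory

Stochastic schedules: `Q* = c_Q q` with `c_Q = α_Q/(α_Q+λ)` and
`S* ≈ c_S E|R − c_Q q|` with `c_S = α_S/λ`.  The spread formula replaces
`E|R − Q|` by `E|R − Q*|`; this is a small-`α` approximation with no error
bound.  It is exact for two-point schedules (where `E|R − Q|` does not
depend on `Q` while `|Q| < max(p, n)`), but for wide continuous
distributions the equilibrium fluctuation of `Q` (variance
`≈ α_Q² Var R / (1 − (1−α_Q−λ)²)`) inflates the true stationary spread:
at `α = 0.3` on the symmetric gaussian schedule with `p = n = 20` the
realized terminal weights sit near 18.8 rather than the predicted 17.97
(about 4–5% high).  The package reports the closed-form prediction; the
discrepancy at moderate `α` is an inherent property of the approximation
and is quantified by the ensemble tests.

Mean absolute deviations are evaluated in closed form for two-point and
normal distributions (folded-normal mean) and by adaptive quadrature
(`scipy.integrate.quad`, tolerance 1e−9) for arbitrary frozen continuous
distributions.

Deterministic alternating schedules (cost `−n` then payoff `+p` each
trial): `Q` obeys a linear recursion with per-event multiplier
`1 − α_Q − λ`, solved in closed form.  Two fixed-point values are exposed:

* `Q*_printed = (n(α_Q+λ−1) + p)/(2 − α_Q − λ)`, the widely quoted
  one-line formula, and
* `Q*_exact = α_Q (p − (1−α_Q−λ) n)/(1 − (1−α_Q−λ)²)`, the exact invariant
  point of the two-event composition.

They differ by exactly a factor `c_Q` (`printed = exact / c_Q`) and agree
in the intended regime `α_Q + λ ≈ 0`.  Both are exposed; the exact value is
canonical in tests, and the package does not silently "correct" either
formula.  `S*` is obtained in closed form from the linear `S` recursion
along the periodic `Q` orbit and then verified/refined by iterating the
coupled two-event map to 1e−12.  Closed form rather than bare iteration is
used because the `S` relaxation rate is `λ` per event, so iteration alone
cannot terminate in bounded time as `λ → 0`.

Parameter inversion maps `(α, c_Q, c_S)` to
`ε = (1 − c_S(1/c_Q − 1))/(1 + c_S(1/c_Q − 1))`, `λ = α(1−ε)/(2 c_S)`;
it requires `0 < c_Q < 1` and `c_S(1/c_Q − 1) < 1`.  `check_conditions`
reports the slack of `2λ ≪ α(1+ε)`, the residual of `2λ = α(1−ε)` and the
size of `α`; the "much less than" threshold defaults to a ratio of 0.2 and
is configurable, since no numeric cutoff is canonical.  `balanced_epsilon`
returns the slope `ε = √((2λ/α)² + 1) − 2λ/α` on which `c_Q = c_S`, the
regime in which detuning scales both pathways equally.

## Schedules

Four generators cover the study conditions: `alternating` (fixed `−n` then
`+p`), `fixed_cost_stochastic_payoff` (`−n` then `P ~ N(p, sd²)`; the
payoff sd defaults to `0.2 p`, a declared choice since only "non-vanishing
variance" is specified), `two_point` (`+p` or `−n` with probability 1/2),
and `gaussian` (`N((p−n)/2, (½√(π/2)(p+n))²)`, whose sd is chosen so the
mean absolute deviation equals `(p+n)/2`).  All statistics are available
analytically and are validated against Monte-Carlo moments.  Events within
a trial are delivered and learned from sequentially, cost first.

## Simulation engine

Trajectories record every event.  Default initial weights are `(0, 0)` for
schedule-style runs (overridable; the choice is recorded in run metadata).
Ensemble runs derive per-run generators from a master `SeedSequence`, so
ensembles are bit-reproducible; the ensemble sd uses `ddof=1`.  Time-average
comparisons use the second half of events as the default burn-in.

## Choice experiment

Thalamic activity is `T = D·G − (1 − κ_N·D)·N`; `κ_N = 1` recovers the
unblocked readout, `κ_N = 0` removes dopaminergic inhibition of the No-Go
pathway entirely.  Choice adds independent `N(0, σ²)` noise per option and
takes the argmax unless all noisy activities are negative, in which case no
action is taken and no weights update.  Exact ties (possible only at
`σ = 0`) break uniformly at random.

The simulated lever-pressing experiment uses 180 training and 180 testing
trials, all weights initialized to 0.1, chow payoff fixed at 1, `D = 0.5`
throughout.  Training presents every action once per trial (cost event then
payoff event, even when the cost is zero) and is therefore deterministic;
the trained weights land within 1e−2 of each action's deterministic fixed
point and are shared between dopamine states within a condition.  Blockade
(`κ_N < 1`) applies only during testing.  During testing, executed actions
continue to update their weights, as stated in the protocol; the drift over
180 test trials is small because the weights start at their fixed points.
Within-trial training order (pellet before chow) is irrelevant because the
actions update disjoint weights.

The fit minimizes the normalized summed squared error between simulated
mean choice counts (over 100 replicates) and the measured consumption
table, each condition normalized by its own total — so grams and choice
counts are compared only as per-condition fractions, and the objective is
invariant under per-condition rescaling.  Optimization is Nelder-Mead on
log-transformed magnitudes, logit-transformed `κ_N` and log-transformed
`σ`, with common random numbers (the same base seed for every objective
evaluation) to make the stochastic objective quasi-deterministic.  The
reference fitted values shipped with the package reproduce the qualitative
pattern (pellet preference when free; preference reversal plus reduced
total intake under partial blockade with a lever); exact reproduction of
the reference parameter values is not expected from a stochastic objective,
and the fit is instead validated by parameter recovery on self-generated
synthetic tables (p_pellet, n_lever and κ_N recovered within 15%).

## Comparator architectures

Actor-critic: a situation-level critic with its own Go/No-Go pair supplies
`V = (G_c − N_c)/2`; `δ = r − V` teaches both networks through the same
rules.  With one action the critic mirrors the actor exactly, so the actor
converges to the actor-only solution (asserted to 1e−8).  With two actions
a softmax over `Q(s,a)` (temperature `β`) selects actions; the critic
converges toward the superior action's value and only that action's
weights approach its payoff/cost pair.  Initial weights for the two-action
task default to zero (actors and critic); the conclusions tested are
asymptotic and do not depend on this choice.

OpAL: critic `ΔV = α_V δ`, actor `ΔG = α_G G δ`, `ΔN = −α_N N δ`, no error
transform, no decay; weights are floored at zero.  On alternating
schedules the critic's periodic point is `V* = (p − (1−α_V)n)/(2 − α_V)`,
the within-trial error amplitude is `d = n + V*`, and each trial multiplies
the actor weights by `1 − α² d²` — log-linear collapse, verified to
machine precision, including for heterogeneous rate triples.  For the
large-magnitude regime (`p = n = 20`, `α = 0.3`, actor weights initialized
to 1) `α d > 1`, so the floor is reached within the first trials; the
magnitude-20 setting for that run is an assumption carried over from the
alternating-schedule simulations and is flagged in the test metadata.  A
costless action delivers a single payoff event per trial (see the module
docstring for why a literal zero-cost event is not neutral for OpAL).

## Problem sizes and numerics

Deterministic fixed points and inversions are exact to 1e−9 or better.
Ensemble checks use 500 runs of 200 trials; time-average checks use 4000
trials with half discarded as burn-in; fit validation uses 100 replicate
agents and a 400-evaluation budget for the simplex, which suffices for the
common-random-numbers objective to reach costs below 1e−6 on synthetic
tables.  All randomness flows from explicit seeds or master seed
sequences.

## Known limitations

* Single collective weight per pathway per action: no synapse-level
  vectors, eligibility traces or spiking dynamics.
* The spread equilibrium is a small-`α` approximation (see above); at
  `α = 0.3` it under-predicts continuous-schedule spreads by ~4%.
* The thalamic readout is linear in `G`, `N` and `D`; saturation effects
  of dopamine are not modelled.
* Schedules are stationary; no reversal or correlated payoff-cost noise.
* The synthetic experiment treats one choice as one consumption unit and
  ignores satiety and within-session dynamics, so passing its tests shows
  the choice mechanism reproduces preference patterns, not that the model
  captures real feeding microstructure.
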