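# gonogo — learning the payoffs and costs of actions in the basal ganglia

`gonogo` implements a dual-pathway model of striatal reinforcement learning
in which the direct ("Go") and indirect ("No-Go") basal-ganglia pathways
learn, from one shared outcome prediction error, separate estimates of the
mean payoff and the mean cost of each action.  It is aimed at computational
neuroscientists who want to simulate the model, use its analytic equilibrium
theory, or fit its dopamine-modulated choice rule to effort-based choice
data such as the classic haloperidol lever-pressing experiments.

## The model

Each action carries two non-negative synaptic strengths `G` (Go) and `N`
(No-Go).  A reinforcement `r` (negative values are costs, positive values
payoffs) produces the prediction error

```
δ = r − (G − N)/2
```

which updates both pathways through a piecewise-linear transform
`f_ε(x) = x for x ≥ 0, εx for x < 0` (0 ≤ ε ≤ 1):

```
ΔG = α f_ε(δ) − λG
ΔN = α f_ε(−δ) − λN
```

with learning rate `α` and weight decay `λ`; updates that would drive a
weight negative clip it to zero.  In the variables `Q = (G−N)/2`,
`S = (G+N)/2` the rules track the mean and the mean absolute deviation
(spread) of the reinforcement with effective rates `α_Q = α(1+ε)/2`,
`α_S = α(1−ε)/2`, and settle near

```
Q* = c_Q q,   S* ≈ c_S E|R − c_Q q|,    c_Q = α_Q/(α_Q+λ),  c_S = α_S/λ.
```

When `c_Q ≈ 1` and `c_S = 1` — equivalently `2λ ≪ α(1+ε)` and
`2λ = α(1−ε)` — the weights converge to the payoff and cost magnitudes:
`G* → p`, `N* → n`.  Action selection reads out a thalamic activity
`T = D·G − (1 − κ_N·D)·N`, where `D ∈ [0,1]` is the dopaminergic motivation
level and `κ_N ∈ [0,1]` the coupling of dopamine to the No-Go (D2) pathway;
`κ_N < 1` models D2-antagonist blockade.  Choice adds Gaussian noise to each
option's `T` and takes the argmax, staying inactive if every noisy activity
is negative.

The package also provides the analytic machinery around these rules
(parameter inversion, condition checks, deterministic and stochastic fixed
points, detuning/robustness formulas), schedule generators, single-run and
ensemble simulation, the full lever-pressing experiment with Nelder-Mead
fitting, and two comparator architectures: an actor-critic variant and the
opponent-actor-learning (OpAL) rules, whose multiplicative updates collapse
on cost-then-payoff schedules.

## Worked example

Pick target equilibrium coefficients and invert them into plasticity
parameters:

```
$ gonogo solve-params --alpha 0.3 --cq 0.7 --cs 0.9
{
  "alpha": 0.3,
  "c_Q": 0.7,
  "c_S": 0.9,
  "epsilon": 0.443,
  "lam": 0.093,
  ...
}
```

So a learning rate of 0.3 with near-unit equilibrium coefficients requires a
mild asymmetry `ε = 0.443` between positive and negative prediction errors
and a weak decay `λ = 0.093`.  With these parameters, 200 trials of an
alternating −20/+20 schedule drive `(G, N)` to (22.83, 17.71), i.e. within
~15% of the true payoff/cost magnitudes (`gonogo simulate --kind
alternating --p 20 --n 20 --trials 200 --out run/`).

Simulating the lever-pressing experiment at the fitted parameters
(`p_pellet = 15.51`, `n_lever = 14.51`, `κ_N = 0.7507`, `σ = 1.066`,
learning parameters `α = 0.1`, `ε = 0.6327`, `λ = 0.0204`):

```
$ gonogo salamone --rats 100 --seed 0 --out sal/
option   state condition  amount
pellet control      free  179.98
  chow control      free    0.02
pellet blocked      free  179.99
  chow blocked      free    0.01
pellet control     lever  113.69
  chow control     lever   56.12
pellet blocked     lever   30.23
  chow blocked     lever  105.22
```

The mean choice counts per 180 test trials reproduce the experimental
pattern: with free pellets the model strongly prefers pellets regardless of
D2 blockade; when the pellet requires a lever press, partial blockade
(`κ_N = 0.7507`) reverses the preference toward free chow (30 vs 105) and
reduces total intake (135 vs 170 executed choices), because costs are
weighted more heavily once the No-Go pathway is released from dopaminergic
inhibition.

`gonogo fit --out fitdir/` refits the four experiment parameters to the
measured consumption table (packaged with the library) and `gonogo
equilibria`, `gonogo ensemble` and `gonogo compare` expose the remaining
analyses.

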