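"""Comparator learning architectures: actor-critic and opponent actor learning.

Actor-critic variant
    A situation-level critic with its own Go/No-Go pair (G_c, N_c) supplies
    the prediction V = (G_c - N_c)/2; the single error delta = r - V teaches
    both the critic and the chosen action's actor weights via the same
    dual-pathway rules.  With a single action the actor and critic receive
    identical updates, so the actor converges to exactly the actor-only
    solution.

Opponent actor learning (OpAL)
    A scalar critic V learns by dV = alpha_V delta, and the actor updates are
    multiplicative in the weights themselves: dG = alpha_G G delta,
    dN = -alpha_N N delta (no error transform, no decay).  On a schedule
    that alternates a cost with a payoff, the within-trial error oscillation
    +/- d contracts each actor weight by (1 - alpha^2 d^2) per trial once the
    critic has converged, so both weights collapse to zero — the failure mode
    that motivates the dual-pathway rules, which converge to (p, n) on the
    same schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import ActionSpec
from .core import LearningParams, PathwayWeights, apply_update

__all__ = [
    "CriticState",
    "OpALState",
    "actor_critic_step",
    "run_two_action_task",
    "opal_step",
    "run_opal",
    "opal_alternating_critic_fixed_point",
]


@dataclass(frozen=True)
class CriticState:
    """Situation-level Go/No-Go strengths of the critic; V = (G_c - N_c)/2."""

    G_c: float
    N_c: float

    def __post_init__(self) -> None:
        if self.G_c < 0 or self.N_c < 0:
            raise ValueError(f"critic weights must be non-negative, got {self}")

    @property
    def V(self) -> float:
        return 0.5 * (self.G_c - self.N_c)


@dataclass(frozen=True)
class OpALState:
    """Critic value V and multiplicative actor weights (G, N >= 0)."""

    V: float
    G: float
    N: float

    def __post_init__(self) -> None:
        if self.G < 0 or self.N < 0:
            raise ValueError(f"actor weights must be non-negative, got {self}")


def actor_critic_step(
    actor: PathwayWeights, critic: CriticState, r: float, p: LearningParams
) -> tuple[PathwayWeights, CriticState]:
    """One reinforcement event: delta = r - V_critic teaches actor and critic.

    Both networks apply the dual-pathway rules (error transform, decay,
    clipping at zero) to their own weight pair with the same delta.
    """
    delta = r - critic.V
    new_actor = apply_update(actor, delta, p)
    critic_pair = apply_update(PathwayWeights(critic.G_c, critic.N_c), delta, p)
    return new_actor, CriticState(critic_pair.G, critic_pair.N)


def _softmax_choice(q_values: np.ndarray, beta: float, rng: np.random.Generator) -> int:
    z = beta * q_values
    z = z - z.max()
    probs = np.exp(z)
    probs /= probs.sum()
    return int(rng.choice(len(q_values), p=probs))


def run_two_action_task(
    actions: list[ActionSpec],
    p: LearningParams,
    beta: float,
    n_trials: int,
    rng: np.random.Generator,
    architecture: str = "actor_critic",
) -> pd.DataFrame:
    """Two-action cost-then-payoff task with softmax action selection.

    Each trial samples an action with probability proportional to
    exp(beta Q(s, a)) where Q = (G - N)/2, then delivers that action's cost
    event followed by its payoff event.  ``architecture`` selects how the
    teaching signal is computed: ``actor_only`` uses the chosen action's own
    prediction (delta = r - Q_a), ``actor_critic`` uses the shared critic
    (delta = r - V).  Returns a per-trial record of all weights and V.
    """
    if beta < 0:
        raise ValueError(f"softmax temperature beta must be >= 0, got {beta}")
    if architecture not in ("actor_only", "actor_critic"):
        raise ValueError(f"unknown architecture {architecture!r}")
    actors = [PathwayWeights(0.0, 0.0) for _ in actions]
    critic = CriticState(0.0, 0.0)
    rows = []
    for trial in range(n_trials):
        q_values = np.array([0.5 * (w.G - w.N) for w in actors])
        chosen = _softmax_choice(q_values, beta, rng)
        action = actions[chosen]
        for r in (-action.n, action.p):
            if architecture == "actor_critic":
                actors[chosen], critic = actor_critic_step(
                    actors[chosen], critic, r, p
                )
            else:
                delta = r - 0.5 * (actors[chosen].G - actors[chosen].N)
                actors[chosen] = apply_update(actors[chosen], delta, p)
        row = {"trial": trial, "chosen": chosen, "V": critic.V}
        for i, w in enumerate(actors):
            row[f"G{i}"] = w.G
            row[f"N{i}"] = w.N
        rows.append(row)
    return pd.DataFrame(rows)


def opal_step(
    state: OpALState,
    r: float,
    alpha: float,
    alpha_G: float | None = None,
    alpha_N: float | None = None,
) -> OpALState:
    """One OpAL event: dV = alpha delta, dG = alpha_G G delta, dN = -alpha_N N delta.

    ``alpha`` is the critic rate and the default actor rate; distinct actor
    rates may be passed.  Updates use pre-step values; actor weights are
    floored at zero if a step would cross it.
    """
    a_g = alpha if alpha_G is None else alpha_G
    a_n = alpha if alpha_N is None else alpha_N
    delta = r - state.V
    return OpALState(
        V=state.V + alpha * delta,
        G=max(state.G + a_g * state.G * delta, 0.0),
        N=max(state.N - a_n * state.N * delta, 0.0),
    )


def run_opal(
    p: float,
    n: float,
    alpha: float,
    init: OpALState = OpALState(0.0, 1.0, 1.0),
    n_trials: int = 100,
    alpha_G: float | None = None,
    alpha_N: float | None = None,
) -> pd.DataFrame:
    """Simulate OpAL on the alternating (-n then +p per trial) schedule.

    A costless action (n = 0) delivers a single payoff event per trial — the
    stationary environment in which the OpAL critic converges to p and the
    actor weights stop changing.  (A literal r = 0 cost event would not be
    neutral for OpAL, whose error r - V is negative whenever V > r.)

    Returns a per-event trajectory (trial, event_index, r, delta, V, G, N);
    the first row records the initial state.
    """
    state = init
    trial_events = (-n, p) if n > 0 else (p,)
    rows = [(-1, -1, np.nan, np.nan, state.V, state.G, state.N)]
    for trial in range(n_trials):
        for idx, r in enumerate(trial_events):
            delta = r - state.V
            state = opal_step(state, r, alpha, alpha_G, alpha_N)
            rows.append((trial, idx, r, delta, state.V, state.G, state.N))
    return pd.DataFrame(
        rows, columns=["trial", "event_index", "r", "delta", "V", "G", "N"]
    )


def opal_alternating_critic_fixed_point(p: float, n: float, alpha: float) -> float:
    """Periodic point of the OpAL critic on the alternating schedule.

    The before-trial value V* satisfies the two-event recursion
    V* = (1-a)((1-a)V* - a n) + a p, i.e. V* = (p - (1-a) n)/(2 - a); the
    within-trial error amplitude is then d = n + V*.
    """
    return (p - (1.0 - alpha) * n) / (2.0 - alpha)
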