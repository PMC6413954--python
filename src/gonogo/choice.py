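"""Dopamine-modulated choice and the lever-pressing (effort) experiment.

Basal-ganglia output ("thalamic activity") for an action with weights (G, N)
under dopamine level D and D2-coupling kappa_N is

    T = D G - (1 - kappa_N D) N,

so kappa_N = 1 recovers the unblocked readout T = D G - (1 - D) N, while
kappa_N < 1 models D2-antagonist (haloperidol) blockade releasing the No-Go
pathway from dopaminergic inhibition.  Choice adds independent Gaussian noise
to each option's T and picks the argmax, unless every noisy activity is
negative, in which case the agent stays inactive — this inaction default lets
the model reproduce the reduced total food intake seen under D2 blockade.

The classic experiment modelled here offers a rat a nutritious pellet
(behind a lever press in the effort condition) against freely available lab
chow.  Simulated agents are trained on both options, then tested with and
without partial D2 blockade; the four free parameters (p_pellet, n_lever,
kappa_N, sigma) are fitted to the measured consumption table by Nelder-Mead
simplex on a common-random-numbers objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .analysis import ActionSpec
from .core import LearningParams, PathwayWeights, update_gn

__all__ = [
    "INACTIVE", "OPTIONS", "STATES", "CONDITIONS",
    "ChoiceParams", "ExperimentConfig", "ConsumptionTable", "FitResult",
    "SALAMONE_LEARNING_PARAMS", "SALAMONE_FITTED",
    "load_salamone_table", "thalamic_activity", "select_action",
    "train_actions", "run_test_block", "simulate_consumption",
    "consumption_cost", "fit_experiment",
]

INACTIVE = -1
OPTIONS = ("pellet", "chow")
STATES = ("control", "blocked")
CONDITIONS = ("free", "lever")

#: learning parameters used for the lever-pressing experiment
#: (inverting the equilibrium coefficients at alpha=0.1, c_Q=0.8, c_S=0.9)
SALAMONE_LEARNING_PARAMS = LearningParams(alpha=0.1, epsilon=0.6327, lam=0.0204)

#: reference fitted choice/experiment parameters for the rat data
SALAMONE_FITTED = {
    "p_pellet": 15.511751,
    "n_lever": 14.510517,
    "kappa_N": 0.7507,
    "sigma": 1.066246,
}


@dataclass(frozen=True)
class ChoiceParams:
    """Dopamine level D, D2 coupling kappa_N and decision noise sigma."""

    D: float = 0.5
    kappa_N: float = 1.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"D must lie in [0, 1], got {self.D}")
        if not 0.0 <= self.kappa_N <= 1.0:
            raise ValueError(f"kappa_N must lie in [0, 1], got {self.kappa_N}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol constants of the simulated lever-pressing experiment."""

    n_train: int = 180
    n_test: int = 180
    n_rats: int = 100
    init_weight: float = 0.1
    p_chow: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_train < 0 or self.n_test < 0:
            raise ValueError("trial counts must be non-negative")
        if self.n_rats < 1:
            raise ValueError("n_rats must be >= 1")
        if self.init_weight < 0:
            raise ValueError("init_weight must be non-negative")


@dataclass(frozen=True)
class ConsumptionTable:
    """Amounts (choice counts or grams) indexed by (option, state, condition).

    Only normalized, per-condition fractions are ever compared, so grams and
    simulated choice counts live on a common scale.
    """

    data: dict = field(default_factory=dict)

    @classmethod
    def from_entries(cls, entries: dict) -> "ConsumptionTable":
        table = {}
        for (option, state, condition), amount in entries.items():
            if option not in OPTIONS or state not in STATES or condition not in CONDITIONS:
                raise ValueError(f"unknown table cell {(option, state, condition)}")
            if amount < 0:
                raise ValueError(f"amounts must be non-negative, got {amount}")
            table[(option, state, condition)] = float(amount)
        missing = {
            (o, s, k) for o in OPTIONS for s in STATES for k in CONDITIONS
        } - set(table)
        if missing:
            raise ValueError(f"incomplete consumption table, missing {sorted(missing)}")
        return cls(table)

    def __getitem__(self, key) -> float:
        return self.data[key]

    def condition_total(self, condition: str) -> float:
        return sum(
            self.data[(o, s, condition)] for o in OPTIONS for s in STATES
        )

    def normalized(self, option: str, state: str, condition: str) -> float:
        z = self.condition_total(condition)
        if z <= 0:
            raise ValueError(
                f"normalizer for condition {condition!r} is zero (degenerate table)"
            )
        return self.data[(option, state, condition)] / z

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (o, s, k, self.data[(o, s, k)])
            for k in CONDITIONS for s in STATES for o in OPTIONS
        ]
        return pd.DataFrame(rows, columns=["option", "state", "condition", "amount"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConsumptionTable":
        df = pd.read_csv(path)
        return cls.from_entries(
            {
                (row.option, row.state, row.condition): row.amount
                for row in df.itertuples()
            }
        )


def load_salamone_table() -> ConsumptionTable:
    """Experimental consumption (grams) from the rat lever-pressing study."""
    with resources.files("gonogo.data").joinpath("salamone_consumption.csv").open() as fh:
        df = pd.read_csv(fh)
    return ConsumptionTable.from_entries(
        {(r.option, r.state, r.condition): r.amount for r in df.itertuples()}
    )


def thalamic_activity(w: PathwayWeights, cp: ChoiceParams) -> float:
    """T = D G - (1 - kappa_N D) N; kappa_N = 1 gives the unblocked readout."""
    return cp.D * w.G - (1.0 - cp.kappa_N * cp.D) * w.N


def select_action(T_values, sigma: float, rng: np.random.Generator) -> int:
    """Noisy argmax with an inaction default.

    Adds independent Normal(0, sigma^2) noise to each activity; returns
    ``INACTIVE`` if every noisy value is negative, else the argmax index
    (exact ties broken uniformly at random).
    """
    noisy = np.asarray(T_values, dtype=float)
    if noisy.size == 0:
        raise ValueError("at least one option is required")
    if sigma > 0:
        noisy = noisy + rng.normal(0.0, sigma, size=noisy.shape)
    top = noisy.max()
    if top < 0:
        return INACTIVE
    winners = np.flatnonzero(noisy == top)
    return int(winners[0] if winners.size == 1 else rng.choice(winners))


def _f_eps_vec(delta: np.ndarray, epsilon: float) -> np.ndarray:
    return np.where(delta >= 0.0, delta, epsilon * delta)


def _update_vec(G, N, r, p: LearningParams):
    """Vectorized clipped weight update for one reinforcement event."""
    delta = r - 0.5 * (G - N)
    G2 = np.maximum(G + p.alpha * _f_eps_vec(delta, p.epsilon) - p.lam * G, 0.0)
    N2 = np.maximum(N + p.alpha * _f_eps_vec(-delta, p.epsilon) - p.lam * N, 0.0)
    return G2, N2


def train_actions(
    actions: list[ActionSpec], p: LearningParams, cfg: ExperimentConfig
) -> list[PathwayWeights]:
    """Deterministic training: each trial, every action is experienced once
    (its cost event, then its payoff event), updating only its own weights."""
    weights = [(cfg.init_weight, cfg.init_weight) for _ in actions]
    for _ in range(cfg.n_train):
        for i, action in enumerate(actions):
            G, N = weights[i]
            for r in (-action.n, action.p):
                delta = r - 0.5 * (G - N)
                G, N = update_gn(G, N, delta, p.alpha, p.epsilon, p.lam)
            weights[i] = (G, N)
    return [PathwayWeights(G, N) for G, N in weights]


def _test_block_vec(
    G: np.ndarray,
    N: np.ndarray,
    actions: list[ActionSpec],
    cp: ChoiceParams,
    p: LearningParams,
    n_test: int,
    rng: np.random.Generator,
):
    """Run a testing block for every row of (G, N) in parallel.

    G, N : arrays of shape (n_agents, n_options), modified copies returned.
    Returns (counts[n_agents, n_options], inactive[n_agents], G, N).
    """
    G = G.copy()
    N = N.copy()
    n_agents, n_options = G.shape
    costs = np.array([-a.n for a in actions])
    payoffs = np.array([a.p for a in actions])
    counts = np.zeros((n_agents, n_options), dtype=np.int64)
    inactive = np.zeros(n_agents, dtype=np.int64)
    no_go_gain = 1.0 - cp.kappa_N * cp.D
    for _ in range(n_test):
        T = cp.D * G - no_go_gain * N
        if cp.sigma > 0:
            noisy = T + rng.normal(0.0, cp.sigma, size=T.shape)
        else:
            noisy = T
        top = noisy.max(axis=1)
        choice = np.argmax(noisy, axis=1)
        ties = (noisy == top[:, None]).sum(axis=1)
        for row in np.flatnonzero(ties > 1):
            choice[row] = rng.choice(np.flatnonzero(noisy[row] == top[row]))
        executed = top >= 0
        inactive += ~executed
        for i in range(n_options):
            mask = executed & (choice == i)
            if not mask.any():
                continue
            counts[mask, i] += 1
            for r in (costs[i], payoffs[i]):
                G[mask, i], N[mask, i] = _update_vec(G[mask, i], N[mask, i], r, p)
    return counts, inactive, G, N


def run_test_block(
    weights: list[PathwayWeights],
    actions: list[ActionSpec],
    cp: ChoiceParams,
    p: LearningParams,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
) -> dict:
    """Testing block for a single agent.

    Each trial computes the noisy thalamic activity of every option, selects
    via :func:`select_action`, and — if an action executes — delivers its
    cost-then-payoff events to that action's weights only.  Returns choice
    counts, the inactive-trial count and the final weights.
    """
    G = np.array([[w.G for w in weights]], dtype=float)
    N = np.array([[w.N for w in weights]], dtype=float)
    counts, inactive, G, N = _test_block_vec(G, N, actions, cp, p, cfg.n_test, rng)
    return {
        "counts": counts[0].tolist(),
        "inactive": int(inactive[0]),
        "weights": [PathwayWeights(g, n) for g, n in zip(G[0], N[0])],
    }


def simulate_consumption(
    p_pellet: float,
    n_lever: float,
    kappa_N: float,
    sigma: float,
    learn_params: LearningParams = SALAMONE_LEARNING_PARAMS,
    cfg: ExperimentConfig = ExperimentConfig(),
    seed: int | None = None,
) -> tuple[ConsumptionTable, dict]:
    """Simulate the full experiment and return mean choice counts per cell.

    Two conditions (free pellet / lever pellet) differ only in the pellet
    cost (0 vs n_lever); two dopamine states differ only in kappa_N at test
    (1 in control, ``kappa_N`` under blockade; D = 0.5 throughout).  Training
    is deterministic and shared between states within a condition.  Entries
    are the mean number of choices over ``cfg.n_rats`` replicates.
    """
    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    children = iter(ss.spawn(len(CONDITIONS) * len(STATES)))
    entries = {}
    info: dict = {"inactive": {}, "weights": {}}
    for condition in CONDITIONS:
        n_pellet = 0.0 if condition == "free" else n_lever
        actions = [ActionSpec(p_pellet, n_pellet), ActionSpec(cfg.p_chow, 0.0)]
        trained = train_actions(actions, learn_params, cfg)
        info["weights"][condition] = trained
        G0 = np.tile([w.G for w in trained], (cfg.n_rats, 1))
        N0 = np.tile([w.N for w in trained], (cfg.n_rats, 1))
        for state in STATES:
            cp = ChoiceParams(
                D=0.5, kappa_N=1.0 if state == "control" else kappa_N, sigma=sigma
            )
            rng = np.random.default_rng(next(children))
            counts, inactive, _, _ = _test_block_vec(
                G0, N0, actions, cp, learn_params, cfg.n_test, rng
            )
            means = counts.mean(axis=0)
            for i, option in enumerate(OPTIONS):
                entries[(option, state, condition)] = float(means[i])
            info["inactive"][(state, condition)] = float(inactive.mean())
    return ConsumptionTable.from_entries(entries), info


def consumption_cost(sim: ConsumptionTable, exp: ConsumptionTable) -> float:
    """Normalized summed squared error between two consumption tables.

    Each condition is normalized by its own total before squared differences
    are summed, so the cost is invariant under per-condition rescaling.
    """
    total = 0.0
    for condition in CONDITIONS:
        for state in STATES:
            for option in OPTIONS:
                d = sim.normalized(option, state, condition) - exp.normalized(
                    option, state, condition
                )
                total += d * d
    return total


@dataclass(frozen=True)
class FitResult:
    """Fitted experiment parameters and the simulated table at the optimum."""

    p_pellet: float
    n_lever: float
    kappa_N: float
    sigma: float
    cost: float
    table: ConsumptionTable
    n_evaluations: int
    converged: bool
    message: str

    def params_dict(self) -> dict:
        return {
            "p_pellet": self.p_pellet,
            "n_lever": self.n_lever,
            "kappa_N": self.kappa_N,
            "sigma": self.sigma,
        }

    def to_json(self, path) -> None:
        payload = self.params_dict() | {
            "cost": self.cost,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "message": self.message,
            "table": {
                "|".join(key): value for key, value in sorted(self.table.data.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _pack(p_pellet, n_lever, kappa_N, sigma):
    kappa_N = min(max(kappa_N, 1e-6), 1 - 1e-6)
    return np.array(
        [
            math.log(p_pellet),
            math.log(n_lever),
            math.log(kappa_N / (1.0 - kappa_N)),
            math.log(sigma),
        ]
    )


def _unpack(x):
    return (
        math.exp(x[0]),
        math.exp(x[1]),
        1.0 / (1.0 + math.exp(-x[2])),
        math.exp(x[3]),
    )


def fit_experiment(
    exp: ConsumptionTable,
    learn_params: LearningParams = SALAMONE_LEARNING_PARAMS,
    cfg: ExperimentConfig = ExperimentConfig(),
    seed: int | None = 0,
    x0: dict | None = None,
    maxfev: int = 400,
) -> FitResult:
    """Fit (p_pellet, n_lever, kappa_N, sigma) to a consumption table.

    Derivative-free Nelder-Mead simplex on log/logit-transformed parameters
    keeps kappa_N in (0, 1) and the magnitudes positive.  Every objective
    evaluation reuses the same base seed (common random numbers), which makes
    the stochastic objective quasi-deterministic for the simplex.  The
    control state always uses kappa_N = 1; D is fixed at 0.5.
    """
    start = {"p_pellet": 10.0, "n_lever": 10.0, "kappa_N": 0.8, "sigma": 1.0}
    if x0:
        start.update(x0)

    def objective(x):
        p_pellet, n_lever, kappa_N, sigma = _unpack(x)
        sim, _ = simulate_consumption(
            p_pellet, n_lever, kappa_N, sigma, learn_params, cfg, seed=seed
        )
        try:
            return consumption_cost(sim, exp)
        except ValueError:  # degenerate all-inactive simulation
            return 8.0  # exceeds any attainable normalized squared error

    res = minimize(
        objective,
        _pack(start["p_pellet"], start["n_lever"], start["kappa_N"], start["sigma"]),
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-7},
    )
    p_pellet, n_lever, kappa_N, sigma = _unpack(res.x)
    table, _ = simulate_consumption(
        p_pellet, n_lever, kappa_N, sigma, learn_params, cfg, seed=seed
    )
    return FitResult(
        p_pellet=p_pellet,
        n_lever=n_lever,
        kappa_N=kappa_N,
        sigma=sigma,
        cost=float(res.fun),
        table=table,
        n_evaluations=int(res.nfev),
        converged=bool(res.success),
        message=str(res.message),
    )
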