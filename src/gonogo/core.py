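"""Core plasticity rules of the dual-pathway striatal model.

The model maintains, for each action, two non-negative synaptic strengths:
``G`` (Go / direct pathway, encoding the mean payoff after learning) and
``N`` (No-Go / indirect pathway, encoding the mean cost).  Both learn from a
single outcome prediction error

    delta = r - (G - N) / 2,

which drives the weight updates

    dG = alpha * f_eps(delta)  - lam * G
    dN = alpha * f_eps(-delta) - lam * N,

where ``f_eps`` is a piecewise-linear transform (identity for non-negative
arguments, slope ``eps`` for negative ones).  An update that would push a
weight below zero clips that weight to zero instead.

The change of variables Q = (G - N)/2, S = (G + N)/2 turns the pair of rules
into a mean-tracking rule for Q and a spread-tracking rule for S with
effective rates alpha_Q = alpha (1 + eps)/2 and alpha_S = alpha (1 - eps)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearningParams",
    "PathwayWeights",
    "QSView",
    "ReinforcementEvent",
    "f_eps",
    "prediction_error",
    "apply_update",
    "qs_transform",
    "qs_inverse",
    "qs_update",
]


@dataclass(frozen=True)
class LearningParams:
    """Plasticity constants.

    alpha : learning rate, > 0 (dimensionless).
    epsilon : slope of ``f_eps`` on negative arguments, in [0, 1].
    lam : per-event weight decay rate, >= 0.
    """

    alpha: float
    epsilon: float
    lam: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if not self.lam >= 0:
            raise ValueError(f"lam must be non-negative, got {self.lam}")


@dataclass(frozen=True)
class PathwayWeights:
    """Collective Go and No-Go strengths of one action (both >= 0)."""

    G: float
    N: float

    def __post_init__(self) -> None:
        if self.G < 0 or self.N < 0:
            raise ValueError(f"pathway weights must be non-negative, got {self}")


@dataclass(frozen=True)
class QSView:
    """Mean/spread view of a weight pair: Q = (G-N)/2, S = (G+N)/2."""

    Q: float
    S: float


@dataclass(frozen=True)
class ReinforcementEvent:
    """Instantaneous signed reinforcement; r < 0 is a cost, r > 0 a payoff."""

    r: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.r):
            raise ValueError(f"reinforcement must be finite, got {self.r}")


def f_eps(x, epsilon: float):
    """Piecewise-linear prediction-error transform.

    Returns ``x`` for ``x >= 0`` and ``epsilon * x`` for ``x < 0``.  Accepts
    scalars or arrays.  Satisfies ``f(x) - f(-x) = (1 + eps) x`` and
    ``f(x) + f(-x) = (1 - eps) |x|``.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    arr = np.asarray(x, dtype=float)
    out = np.where(arr >= 0.0, arr, epsilon * arr)
    return out.item() if out.ndim == 0 else out


def _as_r(event) -> float:
    return event.r if isinstance(event, ReinforcementEvent) else float(event)


def prediction_error(event, w: PathwayWeights) -> float:
    """Outcome prediction error delta = r - (G - N)/2."""
    return _as_r(event) - 0.5 * (w.G - w.N)


def update_gn(
    G: float, N: float, delta: float, alpha: float, epsilon: float, lam: float
) -> tuple[float, float]:
    """Scalar weight update with clipping; both raw changes use pre-update values."""
    g = G + alpha * (delta if delta >= 0 else epsilon * delta) - lam * G
    n = N + alpha * (-delta if delta <= 0 else -epsilon * delta) - lam * N
    return (g if g > 0.0 else 0.0, n if n > 0.0 else 0.0)


def apply_update(w: PathwayWeights, delta: float, p: LearningParams) -> PathwayWeights:
    """One plasticity event: dG = a f(d) - lam G, dN = a f(-d) - lam N, clipped at 0."""
    g, n = update_gn(w.G, w.N, delta, p.alpha, p.epsilon, p.lam)
    return PathwayWeights(g, n)


def qs_transform(w: PathwayWeights) -> QSView:
    """Forward change of variables: Q = (G-N)/2, S = (G+N)/2."""
    return QSView(0.5 * (w.G - w.N), 0.5 * (w.G + w.N))


def qs_inverse(qs: QSView) -> PathwayWeights:
    """Inverse change of variables: G = S + Q, N = S - Q.

    Raises ValueError if S < |Q| (which would imply a negative weight).
    """
    if qs.S < abs(qs.Q) - 1e-12:
        raise ValueError(f"S >= |Q| required for a valid weight pair, got {qs}")
    return PathwayWeights(max(qs.S + qs.Q, 0.0), max(qs.S - qs.Q, 0.0))


def qs_update(qs: QSView, delta: float, p: LearningParams) -> QSView:
    """Clip-free update in (Q, S) coordinates.

    Q' = Q + alpha_Q delta - lam Q, S' = S + alpha_S |delta| - lam S with
    alpha_Q = alpha (1+eps)/2 and alpha_S = alpha (1-eps)/2.  Agrees with
    :func:`apply_update` (through :func:`qs_transform`) whenever no clipping
    fires in (G, N) space.
    """
    a_q = 0.5 * p.alpha * (1.0 + p.epsilon)
    a_s = 0.5 * p.alpha * (1.0 - p.epsilon)
    return QSView(
        qs.Q + a_q * delta - p.lam * qs.Q,
        qs.S + a_s * abs(delta) - p.lam * qs.S,
    )
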