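"""Closed-form equilibrium theory for the dual-pathway learning rules.

After learning, the mean estimate Q = (G-N)/2 and spread estimate
S = (G+N)/2 settle near

    Q* = c_Q q,          c_Q = alpha_Q / (alpha_Q + lam)
    S* = c_S E|R - c_Q q|,  c_S = alpha_S / lam,

where q = E[R] is the mean reinforcement of the schedule.  Unbiased coding of
payoff p and cost n (G* -> p, N* -> n) requires c_Q ~ 1 and c_S = 1, i.e.
2 lam << alpha (1 + eps) and 2 lam = alpha (1 - eps); deterministic
cost-then-payoff patterns additionally require alpha << 1.

For deterministic alternating reinforcement (-n then +p each trial) the
module exposes both the commonly printed fixed-point formula

    Q*_printed = (n (alpha_Q + lam - 1) + p) / (2 - alpha_Q - lam)

and the exact invariant point of the two-event composition.  The two differ
by exactly a factor c_Q (exact = printed * c_Q) and agree in the intended
regime alpha_Q + lam ~ 0; both are exposed and the exact value is canonical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate

from .core import LearningParams, QSView, qs_update

__all__ = [
    "EffectiveRates",
    "EquilibriumCoefficients",
    "DistributionStats",
    "ActionSpec",
    "ConditionReport",
    "StochasticEquilibrium",
    "DeterministicFixedPoint",
    "effective_rates",
    "coefficients",
    "solve_parameters",
    "check_conditions",
    "stochastic_equilibrium",
    "discrete_equilibrium",
    "deterministic_fixed_point",
    "balanced_epsilon",
    "detuned_weights",
    "thalamic_detuned",
]


@dataclass(frozen=True)
class EffectiveRates:
    """Effective learning rates alpha_Q = a(1+e)/2 and alpha_S = a(1-e)/2."""

    alpha_Q: float
    alpha_S: float


@dataclass(frozen=True)
class EquilibriumCoefficients:
    """Equilibrium coefficients c_Q = a_Q/(a_Q+lam), c_S = a_S/lam.

    When lam = 0, c_Q = 1 exactly and c_S has no finite value; this is
    reported by ``c_S = None`` together with ``c_S_defined = False``.
    """

    c_Q: float
    c_S: float | None

    @property
    def c_S_defined(self) -> bool:
        return self.c_S is not None


@dataclass(frozen=True)
class DistributionStats:
    """Mean q = E[R] and mean spread s = E|R - q| of a reinforcement distribution."""

    q: float
    s: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"mean spread must be non-negative, got {self.s}")


@dataclass(frozen=True)
class ActionSpec:
    """Payoff magnitude p and cost magnitude n of one action (both >= 0).

    Relates to distribution statistics by q = (p - n)/2 and s = (p + n)/2,
    i.e. p = q + s and -n = q - s.
    """

    p: float
    n: float

    def __post_init__(self) -> None:
        if self.p < 0 or self.n < 0:
            raise ValueError(f"payoff and cost magnitudes must be >= 0, got {self}")

    @property
    def stats(self) -> DistributionStats:
        return DistributionStats(0.5 * (self.p - self.n), 0.5 * (self.p + self.n))

    @classmethod
    def from_stats(cls, stats: DistributionStats) -> "ActionSpec":
        return cls(stats.q + stats.s, stats.s - stats.q)


def effective_rates(p: LearningParams) -> EffectiveRates:
    return EffectiveRates(
        0.5 * p.alpha * (1.0 + p.epsilon), 0.5 * p.alpha * (1.0 - p.epsilon)
    )


def coefficients(p: LearningParams) -> EquilibriumCoefficients:
    rates = effective_rates(p)
    if p.lam == 0:
        return EquilibriumCoefficients(1.0, None)
    return EquilibriumCoefficients(
        rates.alpha_Q / (rates.alpha_Q + p.lam), rates.alpha_S / p.lam
    )


def solve_parameters(alpha: float, c_Q: float, c_S: float) -> tuple[float, float]:
    """Invert the coefficient definitions: (alpha, c_Q, c_S) -> (epsilon, lam).

    epsilon = (1 - c_S (1/c_Q - 1)) / (1 + c_S (1/c_Q - 1)) and
    lam = alpha (1 - epsilon) / (2 c_S).  Requires 0 < c_Q < 1, c_S > 0 and
    c_S (1/c_Q - 1) < 1 so that epsilon stays in (0, 1).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0.0 < c_Q < 1.0:
        raise ValueError(f"c_Q must lie in (0, 1) to give a positive lam, got {c_Q}")
    if c_S <= 0:
        raise ValueError(f"c_S must be positive, got {c_S}")
    t = c_S * (1.0 / c_Q - 1.0)
    if t >= 1.0:
        raise ValueError(
            f"c_S (1/c_Q - 1) = {t:.6g} >= 1 would push epsilon out of (0, 1)"
        )
    epsilon = (1.0 - t) / (1.0 + t)
    lam = alpha * (1.0 - epsilon) / (2.0 * c_S)
    return epsilon, lam


@dataclass(frozen=True)
class ConditionReport:
    """Numeric slack of the parameter conditions for unbiased payoff/cost coding.

    weak_decay_ratio : 2 lam / (alpha (1 + eps)); << 1 required (c_Q ~ 1).
    spread_residual : 2 lam - alpha (1 - eps); = 0 required (c_S = 1).
    alpha : the learning rate itself; << 1 required for deterministic patterns.
    Flags evaluate "<<" against a configurable ratio threshold.
    """

    weak_decay_ratio: float
    spread_residual: float
    alpha: float
    weak_decay_ok: bool
    spread_ok: bool
    alpha_ok: bool
    c_S_defined: bool

    def as_dict(self) -> dict:
        return {
            "weak_decay_ratio": self.weak_decay_ratio,
            "spread_residual": self.spread_residual,
            "alpha": self.alpha,
            "weak_decay_ok": self.weak_decay_ok,
            "spread_ok": self.spread_ok,
            "alpha_ok": self.alpha_ok,
            "c_S_defined": self.c_S_defined,
        }


def check_conditions(p: LearningParams, threshold: float = 0.2) -> ConditionReport:
    """Report how well (alpha, eps, lam) satisfy the unbiased-coding conditions."""
    ratio = 2.0 * p.lam / (p.alpha * (1.0 + p.epsilon))
    residual = 2.0 * p.lam - p.alpha * (1.0 - p.epsilon)
    scale = max(2.0 * p.lam, p.alpha * (1.0 - p.epsilon))
    spread_ok = scale == 0.0 or abs(residual) / scale < threshold
    return ConditionReport(
        weak_decay_ratio=ratio,
        spread_residual=residual,
        alpha=p.alpha,
        weak_decay_ok=ratio < threshold,
        spread_ok=spread_ok,
        alpha_ok=p.alpha < threshold,
        c_S_defined=p.lam > 0,
    )


@dataclass(frozen=True)
class StochasticEquilibrium:
    """Stochastic fixed point in both coordinate systems.

    ``G_approx``/``N_approx`` carry the detuned payoff/cost approximation
    G* ~ (c_Q + c_S) p / 2 - (c_Q - c_S) n / 2 (and symmetrically for N)
    when the schedule derives from an (p, n) action, else None.
    """

    Q_star: float
    S_star: float
    G_star: float
    N_star: float
    G_approx: float | None = None
    N_approx: float | None = None


def _equilibrium(q: float, mean_abs_about: float, p: LearningParams,
                 action: ActionSpec | None) -> StochasticEquilibrium:
    coef = coefficients(p)
    if not coef.c_S_defined:
        raise ValueError("lam = 0 gives no finite spread equilibrium S*")
    q_star = coef.c_Q * q
    s_star = coef.c_S * mean_abs_about
    g_approx = n_approx = None
    if action is not None:
        g_approx, n_approx = detuned_weights(action, coef.c_Q, coef.c_S)
    return StochasticEquilibrium(
        q_star, s_star, s_star + q_star, s_star - q_star, g_approx, n_approx
    )


def stochastic_equilibrium(dist, p: LearningParams) -> StochasticEquilibrium:
    """Equilibrium (Q*, S*, G*, N*) for a reinforcement distribution.

    ``dist`` may be a ``ScheduleSpec`` (closed forms per kind) or a frozen
    scipy.stats continuous distribution (adaptive quadrature for the mean
    absolute deviation about c_Q q).
    """
    from . import schedules  # deferred: schedules imports this module's types

    coef = coefficients(p)
    if not coef.c_S_defined:
        raise ValueError("lam = 0 gives no finite spread equilibrium S*")
    if isinstance(dist, schedules.ScheduleSpec):
        q = schedules.schedule_stats(dist).q
        mad = schedules.schedule_mean_abs(dist, coef.c_Q * q)
        action = ActionSpec(dist.p, dist.n)
        return _equilibrium(q, mad, p, action)
    if hasattr(dist, "pdf"):  # frozen scipy.stats distribution
        q = float(dist.mean())
        center = coef.c_Q * q
        mad, err = integrate.quad(
            lambda x: abs(x - center) * dist.pdf(x),
            *dist.support(), epsabs=1e-9, epsrel=1e-9, limit=200,
        )
        return _equilibrium(q, mad, p, None)
    raise TypeError(f"unsupported distribution object {dist!r}")


def discrete_equilibrium(values, probs, p: LearningParams) -> StochasticEquilibrium:
    """Equilibrium for a finite discrete reinforcement distribution."""
    if len(values) != len(probs):
        raise ValueError("values and probs must have equal length")
    total = sum(probs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to one, got {total}")
    q = sum(v * w for v, w in zip(values, probs))
    coef = coefficients(p)
    if not coef.c_S_defined:
        raise ValueError("lam = 0 gives no finite spread equilibrium S*")
    mad = sum(abs(v - coef.c_Q * q) * w for v, w in zip(values, probs))
    return _equilibrium(q, mad, p, None)


@dataclass(frozen=True)
class DeterministicFixedPoint:
    """Fixed point of the cost-then-payoff two-event trial composition.

    ``Q_star_printed`` follows the commonly printed one-line formula;
    ``Q_star_exact``/``S_star_exact`` solve the exact linear two-step
    recursion (printed = exact / c_Q).  G*, N* derive from the exact pair.
    """

    Q_star_printed: float
    Q_star_exact: float
    S_star_exact: float
    G_star: float
    N_star: float


def deterministic_fixed_point(
    a: ActionSpec, p: LearningParams, tol: float = 1e-12, max_iter: int = 10_000
) -> DeterministicFixedPoint:
    """Fixed point of repeated (cost -n, payoff +p) trials, assuming no clipping.

    Q obeys a linear recursion with per-event multiplier 1 - alpha_Q - lam
    and is solved in closed form.  Given the periodic Q orbit the S map is
    also linear, giving a closed-form S*; the candidate pair is then refined
    by damped iteration of the coupled two-event map to |change| < tol,
    which also verifies that the point is invariant.
    """
    rates = effective_rates(p)
    A = 1.0 - rates.alpha_Q - p.lam
    denom = 2.0 - rates.alpha_Q - p.lam
    q_printed = (a.n * (rates.alpha_Q + p.lam - 1.0) + a.p) / denom
    q_exact = rates.alpha_Q * (a.p - A * a.n) / (1.0 - A * A)

    # |delta| magnitudes on the periodic orbit, then the linear S recursion
    # S'' = (1-lam)^2 S + alpha_S ((1-lam)|d_cost| + |d_payoff|)
    q_after_cost = A * q_exact - rates.alpha_Q * a.n
    d_cost = abs(-a.n - q_exact)
    d_payoff = abs(a.p - q_after_cost)
    shrink = 1.0 - (1.0 - p.lam) ** 2
    if shrink <= 0.0:
        if rates.alpha_S == 0.0:  # eps = 1, lam = 0: S is conserved
            raise ValueError(
                "S has no unique fixed point at eps = 1, lam = 0 (it is conserved)"
            )
        raise ValueError("lam = 0 gives no finite deterministic S*")
    s_exact = rates.alpha_S * ((1.0 - p.lam) * d_cost + d_payoff) / shrink

    qs = QSView(q_exact, s_exact)
    for _ in range(max_iter):
        after_cost = qs_update(qs, -a.n - qs.Q, p)
        after_payoff = qs_update(after_cost, a.p - after_cost.Q, p)
        converged = (
            abs(after_payoff.Q - qs.Q) < tol and abs(after_payoff.S - qs.S) < tol
        )
        qs = after_payoff
        if converged:
            break
    else:
        raise RuntimeError(
            f"fixed-point refinement did not converge within {max_iter} trials "
            f"(last state {qs}); check that the parameters are contractive"
        )
    return DeterministicFixedPoint(
        q_printed, qs.Q, qs.S, qs.S + qs.Q, qs.S - qs.Q
    )


def balanced_epsilon(alpha: float, lam: float) -> float:
    """Slope epsilon for which c_Q = c_S (the balanced-detuning line).

    epsilon = sqrt((2 lam/alpha)^2 + 1) - 2 lam/alpha, in (0, 1].
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    t = 2.0 * lam / alpha
    return math.sqrt(t * t + 1.0) - t


def detuned_weights(a: ActionSpec, c_Q: float, c_S: float) -> tuple[float, float]:
    """Detuned equilibrium weights G* ~ (c_Q+c_S)p/2 - (c_Q-c_S)n/2 and
    N* ~ -(c_Q-c_S)p/2 + (c_Q+c_S)n/2; reduce to (p, n) at c_Q = c_S = 1."""
    g = 0.5 * (c_Q + c_S) * a.p - 0.5 * (c_Q - c_S) * a.n
    n = -0.5 * (c_Q - c_S) * a.p + 0.5 * (c_Q + c_S) * a.n
    return g, n


def thalamic_detuned(
    a: ActionSpec,
    D: float,
    p: LearningParams | None = None,
    *,
    c_Q: float | None = None,
    c_S: float | None = None,
) -> float:
    """Thalamic activity at the detuned equilibrium weights.

    T = p (c_Q/2 - c_S/2 + D c_S) - n (c_Q/2 + c_S/2 - D c_S).  Coefficients
    are taken from ``p`` (requires lam > 0) unless passed explicitly.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"dopamine level D must lie in [0, 1], got {D}")
    if c_Q is None or c_S is None:
        if p is None:
            raise ValueError("either learning params or explicit (c_Q, c_S) required")
        coef = coefficients(p)
        if not coef.c_S_defined:
            raise ValueError("lam = 0 leaves c_S undefined")
        c_Q, c_S = coef.c_Q, coef.c_S
    return a.p * (0.5 * c_Q - 0.5 * c_S + D * c_S) - a.n * (
        0.5 * c_Q + 0.5 * c_S - D * c_S
    )
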