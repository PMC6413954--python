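"""Synthetic reinforcement schedules and their analytic statistics.

Four schedule kinds cover the study conditions used throughout the package:

``alternating``
    Each trial delivers a fixed cost -n followed by a fixed payoff +p.
``fixed_cost_stochastic_payoff``
    Each trial delivers -n followed by P ~ Normal(p, payoff_sd^2).
``two_point``
    One event per trial, +p or -n with probability 1/2 each.
``gaussian``
    One event per trial, drawn from Normal(mu_r, sigma_r^2) with
    mu_r = (p - n)/2 and sigma_r = (1/2) sqrt(pi/2) (p + n), chosen so the
    mean absolute deviation equals (p + n)/2.

All four kinds share the per-event mean q = (p - n)/2; the first three share
the per-event mean spread s = (p + n)/2, while the fixed-cost kind carries a
folded-normal correction from the payoff noise.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .analysis import DistributionStats

__all__ = ["KINDS", "ScheduleSpec", "make_schedule", "schedule_stats",
           "schedule_mean_abs", "schedule_to_csv", "schedule_from_csv"]

KINDS = ("alternating", "fixed_cost_stochastic_payoff", "two_point", "gaussian")

#: trial events for these kinds are (cost, payoff) pairs
PAIRED_KINDS = ("alternating", "fixed_cost_stochastic_payoff")


@dataclass(frozen=True)
class ScheduleSpec:
    """Declarative description of a reinforcement sequence."""

    kind: str
    p: float
    n: float
    n_trials: int = 30
    payoff_sd: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}; choose from {KINDS}")
        if self.p < 0 or self.n < 0:
            raise ValueError("payoff and cost magnitudes must be non-negative")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.payoff_sd is not None and not self.payoff_sd > 0:
            raise ValueError(f"payoff_sd must be positive, got {self.payoff_sd}")

    @property
    def effective_payoff_sd(self) -> float:
        """Payoff noise for the fixed-cost kind; defaults to 0.2 p."""
        if self.payoff_sd is not None:
            return self.payoff_sd
        return 0.2 * self.p

    @property
    def gaussian_mu(self) -> float:
        return 0.5 * (self.p - self.n)

    @property
    def gaussian_sigma(self) -> float:
        return 0.5 * math.sqrt(math.pi / 2.0) * (self.p + self.n)


def make_schedule(spec: ScheduleSpec, rng: np.random.Generator | None = None
                  ) -> list[tuple[float, ...]]:
    """Generate the per-trial reinforcement events of a schedule.

    Returns a list of tuples, one per trial: (cost, payoff) for the paired
    kinds and a single-event tuple otherwise.  Reproducible given
    ``spec.seed`` (a passed ``rng`` takes precedence).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = spec.n_trials
    if spec.kind == "alternating":
        return [(-spec.n, spec.p)] * t
    if spec.kind == "fixed_cost_stochastic_payoff":
        payoffs = rng.normal(spec.p, spec.effective_payoff_sd, size=t)
        return [(-spec.n, float(x)) for x in payoffs]
    if spec.kind == "two_point":
        heads = rng.random(t) < 0.5
        return [(spec.p,) if h else (-spec.n,) for h in heads]
    # gaussian
    draws = rng.normal(spec.gaussian_mu, spec.gaussian_sigma, size=t)
    return [(float(x),) for x in draws]


def _normal_mean_abs(mu: float, sd: float, center: float) -> float:
    """E|X - center| for X ~ Normal(mu, sd^2) (folded-normal mean)."""
    d = mu - center
    if sd == 0:
        return abs(d)
    z = d / sd
    return sd * math.sqrt(2.0 / math.pi) * math.exp(-0.5 * z * z) + d * (
        2.0 * norm.cdf(z) - 1.0
    )


def schedule_mean_abs(spec: ScheduleSpec, center: float) -> float:
    """Analytic E|R - center| of the per-event reinforcement distribution."""
    if spec.kind in ("alternating", "two_point"):
        return 0.5 * abs(spec.p - center) + 0.5 * abs(-spec.n - center)
    if spec.kind == "fixed_cost_stochastic_payoff":
        return 0.5 * abs(-spec.n - center) + 0.5 * _normal_mean_abs(
            spec.p, spec.effective_payoff_sd, center
        )
    return _normal_mean_abs(spec.gaussian_mu, spec.gaussian_sigma, center)


def schedule_stats(spec: ScheduleSpec) -> DistributionStats:
    """Analytic mean q and mean spread s = E|R - q| of the per-event events."""
    q = 0.5 * (spec.p - spec.n)
    return DistributionStats(q, schedule_mean_abs(spec, q))


def schedule_to_csv(events: list[tuple[float, ...]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial", "event_index", "r"])
        for trial, trial_events in enumerate(events):
            for idx, r in enumerate(trial_events):
                writer.writerow([trial, idx, repr(r)])


def schedule_from_csv(path) -> list[tuple[float, ...]]:
    trials: dict[int, list[float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            trials.setdefault(int(row["trial"]), []).append(float(row["r"]))
    return [tuple(trials[t]) for t in sorted(trials)]
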