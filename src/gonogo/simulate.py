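"""Learning-trajectory engine: run the plasticity rules on a schedule.

A trajectory is a pandas DataFrame with one row per reinforcement event and
columns (trial, event_index, r, delta, G, N, Q, S); the first row records the
initial state (event_index -1, no reinforcement).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LearningParams, PathwayWeights, update_gn
from .schedules import ScheduleSpec, make_schedule

__all__ = ["run_learning", "run_ensemble", "EnsembleResult",
           "trajectory_to_csv", "trajectory_from_csv", "write_run_metadata"]

TRAJECTORY_COLUMNS = ["trial", "event_index", "r", "delta", "G", "N", "Q", "S"]


def _resolve_events(spec_or_events, rng):
    if isinstance(spec_or_events, ScheduleSpec):
        return make_schedule(spec_or_events, rng)
    return list(spec_or_events)


def run_learning(
    spec_or_events,
    p: LearningParams,
    init: PathwayWeights | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the weight updates over a schedule, recording every event.

    ``spec_or_events`` is a :class:`ScheduleSpec` or an explicit list of
    per-trial event tuples (an empty list yields the initial state only).
    """
    if init is None:
        init = PathwayWeights(0.0, 0.0)
    events = _resolve_events(spec_or_events, rng)
    G, N = init.G, init.N
    rows = [(-1, -1, math.nan, math.nan, G, N, 0.5 * (G - N), 0.5 * (G + N))]
    for trial, trial_events in enumerate(events):
        for idx, r in enumerate(trial_events):
            delta = r - 0.5 * (G - N)
            G, N = update_gn(G, N, delta, p.alpha, p.epsilon, p.lam)
            rows.append((trial, idx, r, delta, G, N, 0.5 * (G - N), 0.5 * (G + N)))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


@dataclass(frozen=True)
class EnsembleResult:
    """Per-event mean/sd of G and N across runs, plus terminal summaries."""

    summary: pd.DataFrame  # columns: event, mean_G, sd_G, mean_N, sd_N
    n_runs: int
    terminal_G: np.ndarray  # per-run terminal G
    terminal_N: np.ndarray


def run_ensemble(
    spec: ScheduleSpec,
    p: LearningParams,
    init: PathwayWeights | None = None,
    n_runs: int = 500,
    master_seed: int | None = None,
) -> EnsembleResult:
    """Average ``n_runs`` independent simulations of the same schedule.

    Run seeds are spawned from ``master_seed`` via ``SeedSequence`` so the
    whole ensemble is bit-reproducible; sd uses ddof=1 (0 for a single run).
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    children = np.random.SeedSequence(master_seed).spawn(n_runs)
    g_runs, n_runs_arr = [], []
    for child in children:
        traj = run_learning(spec, p, init, rng=np.random.default_rng(child))
        g_runs.append(traj["G"].to_numpy())
        n_runs_arr.append(traj["N"].to_numpy())
    G = np.vstack(g_runs)
    N = np.vstack(n_runs_arr)
    ddof = 1 if n_runs > 1 else 0
    summary = pd.DataFrame(
        {
            "event": np.arange(G.shape[1]) - 1,  # -1 is the initial state
            "mean_G": G.mean(axis=0),
            "sd_G": G.std(axis=0, ddof=ddof),
            "mean_N": N.mean(axis=0),
            "sd_N": N.std(axis=0, ddof=ddof),
        }
    )
    return EnsembleResult(summary, n_runs, G[:, -1].copy(), N[:, -1].copy())


def trajectory_to_csv(traj: pd.DataFrame, path) -> None:
    traj.to_csv(path, index=False)


def trajectory_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_metadata(path, *, params: LearningParams, seed, init: PathwayWeights,
                       extra: dict | None = None) -> None:
    """Persist everything needed to regenerate a run."""
    meta = {
        "alpha": params.alpha,
        "epsilon": params.epsilon,
        "lam": params.lam,
        "seed": seed,
        "init_G": init.G,
        "init_N": init.N,
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
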