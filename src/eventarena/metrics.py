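"""Per-trial trajectory scoring.

The primary behavioral measure is path efficiency (PE): traversed path
length divided by the optimal path length, the Euclidean distance (ED)
from the start to the goal.  PE = 1 means a perfectly direct route.

Naive first-block searches for a new goal are additionally classified
as "lucky shots": trajectories that, although produced without memory,
hug the optimal path so closely that the hidden goal could not have
been missed.  Closeness is measured with the discrete Frechet distance
between the (resampled) trajectory and the straight start-to-goal
segment; trajectories within a fixed cutoff count as lucky.  The
Frechet criterion, unlike a raw PE threshold, is robust to zigzag
paths that accrue large PE while staying on top of the optimal route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import TrialLog

__all__ = [
    "LuckyShotSpec",
    "path_length",
    "path_efficiency",
    "resample_polyline",
    "discrete_frechet",
    "trajectory_frechet",
    "classify_lucky_shot",
    "decompose_block1",
    "summarize_trials",
]


@dataclass(frozen=True)
class LuckyShotSpec:
    """Classification rule for lucky naive searches.

    frechet_cutoff
        Maximal discrete Frechet distance (a.u.) between the trajectory
        and the straight start-to-goal segment for a trial to count as
        lucky; the default 3.5 equals the radius at which a hidden goal
        becomes visible, i.e. a path this close cannot miss the goal.
    pe_equivalent
        The PE value the cutoff empirically corresponds to (reference
        1.15, i.e. within 15% of the optimal path length); informational.
    resample_step
        Arc-length step (a.u.) at which both polylines are resampled
        before the Frechet computation, removing vertex-density
        artifacts.
    """

    frechet_cutoff: float = 3.5
    pe_equivalent: float = 1.15
    resample_step: float = 0.5

    def __post_init__(self) -> None:
        if self.frechet_cutoff <= 0:
            raise ValueError("frechet_cutoff must be positive")
        if self.resample_step <= 0:
            raise ValueError("resample_step must be positive")


def _as_array(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of xy points")
    return arr


def path_length(trajectory) -> float:
    """Traversed path length: sum of consecutive Euclidean segment lengths."""
    arr = _as_array(trajectory)
    if len(arr) < 2:
        raise ValueError("path_length needs at least 2 points")
    return float(np.sum(np.hypot(*np.diff(arr, axis=0).T)))


def path_efficiency(trial: TrialLog) -> float:
    """PE = traversed path length / start-to-goal Euclidean distance.

    The denominator is the full distance to the goal center even though
    trials terminate at the contact radius, so a perfectly direct trial
    scores marginally below 1.
    """
    if not trial.found:
        raise ValueError("path efficiency is defined for found trials only")
    ed = float(np.hypot(trial.goal.x - trial.start.x, trial.goal.y - trial.start.y))
    if ed == 0:
        raise ValueError("start and goal coincide; optimal length is zero")
    return path_length(trial.xy) / ed


def resample_polyline(trajectory, step: float) -> np.ndarray:
    """Resample a polyline at arc-length spacing <= ``step``.

    Output vertices lie exactly on the input polyline; both endpoints
    are preserved.  A step larger than the total length returns the two
    endpoints (or the single input point).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    arr = _as_array(trajectory)
    if len(arr) == 1:
        return arr.copy()
    seg = np.hypot(*np.diff(arr, axis=0).T)
    if np.any(seg == 0):  # drop zero-length segments (repeated vertices)
        keep = np.concatenate([[True], seg > 0])
        arr = arr[keep]
        if len(arr) == 1:
            return np.vstack([arr, arr])
        seg = np.hypot(*np.diff(arr, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return arr[[0, -1]].copy()
    n_seg = max(1, int(np.ceil(total / step)))
    grid = np.linspace(0.0, total, n_seg + 1)
    # keep original vertices where the path turns, so corners and
    # fold-backs survive resampling; collinear vertices are dropped
    d = np.diff(arr, axis=0)
    if len(arr) > 2:
        cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        dot = np.einsum("ij,ij->i", d[:-1], d[1:])
        turning = (np.abs(cross) > 1e-9) | (dot < 0)
        turns = s[1:-1][turning]
    else:
        turns = np.empty(0)
    targets = np.unique(np.concatenate([grid, turns]))
    x = np.interp(targets, s, arr[:, 0])
    y = np.interp(targets, s, arr[:, 1])
    return np.column_stack([x, y])


def discrete_frechet(P, Q) -> float:
    """Discrete Frechet distance between two polylines.

    Dynamic program over the coupling lattice: the minimum over all
    order-preserving couplings of the maximal pointwise distance.
    Symmetric, non-negative, zero for identical sequences.
    """
    P = _as_array(P)
    Q = _as_array(Q)
    if len(P) == 0 or len(Q) == 0:
        raise ValueError("discrete_frechet needs non-empty sequences")
    # pairwise distance matrix
    d = np.hypot(P[:, None, 0] - Q[None, :, 0], P[:, None, 1] - Q[None, :, 1])
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row_prev = ca[i - 1]
        row = ca[i]
        for j in range(1, m):
            row[j] = max(min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j])
    return float(ca[-1, -1])


def trajectory_frechet(trial: TrialLog, spec: LuckyShotSpec = LuckyShotSpec(),
                       *, resample: bool = True) -> float:
    """Frechet distance between a trial's trajectory and its optimal path."""
    optimal = np.array([[trial.start.x, trial.start.y],
                        [trial.goal.x, trial.goal.y]])
    traj = trial.xy
    if resample:
        traj = resample_polyline(traj, spec.resample_step)
        optimal = resample_polyline(optimal, spec.resample_step)
    return discrete_frechet(traj, optimal)


def classify_lucky_shot(trial: TrialLog, spec: LuckyShotSpec = LuckyShotSpec(),
                        *, resample: bool = True) -> bool:
    """True iff a naive (NPA block 1) search could not have missed the goal.

    Only defined for NPA block-1 trials: later blocks reflect memory,
    and the lucky/residual decomposition exists to hold naive-search
    luck constant.
    """
    if trial.phase != "NPA" or trial.block != 1:
        raise ValueError("lucky-shot classification applies to NPA block-1 "
                         "trials only")
    if not trial.found:
        raise ValueError("lucky-shot classification needs a found trial")
    return trajectory_frechet(trial, spec, resample=resample) <= spec.frechet_cutoff


def decompose_block1(block1: pd.DataFrame, spec: LuckyShotSpec = LuckyShotSpec(),
                     *, expected_rooms=None) -> pd.DataFrame:
    """Split naive NPA block-1 PE into a lucky indicator and residual PE.

    ``block1`` must carry one row per room with columns ``room``,
    ``pe`` and ``frechet`` (as produced by :func:`summarize_trials`).
    Lucky trials get ``lucky=1``; their residual PE is imputed with the
    participant's mean non-lucky block-1 PE so the two predictors stay
    orthogonal; non-lucky trials keep their raw PE.
    """
    required = {"room", "pe", "frechet"}
    if not required.issubset(block1.columns):
        raise ValueError(f"block1 table must have columns {sorted(required)}")
    if expected_rooms is not None:
        missing = sorted(set(expected_rooms) - set(block1["room"]))
        if missing:
            raise ValueError(f"block-1 rows missing for rooms: {missing}")
    out = block1[["room", "pe", "frechet"]].copy()
    out["lucky"] = (out["frechet"] <= spec.frechet_cutoff).astype(int)
    nonlucky = out.loc[out["lucky"] == 0, "pe"]
    fill = float(nonlucky.mean()) if len(nonlucky) else 1.0
    out["residual_pe"] = np.where(out["lucky"] == 1, fill, out["pe"])
    return out[["room", "lucky", "residual_pe"]]


def summarize_trials(trials, spec: LuckyShotSpec = LuckyShotSpec()) -> pd.DataFrame:
    """Score a collection of :class:`~eventarena.agent.TrialLog` records.

    Returns one row per trial with identifiers and the derived metrics:
    path length, ED (optimal length), PE, time to goal (from navigation
    onset), Frechet distance to the optimal path, and — for NPA block-1
    trials — the lucky-shot flag.
    """
    rows = []
    for trial in trials:
        ed = float(np.hypot(trial.goal.x - trial.start.x,
                            trial.goal.y - trial.start.y))
        plen = path_length(trial.xy)
        frech = trajectory_frechet(trial, spec)
        lucky = np.nan
        if trial.phase == "NPA" and trial.block == 1 and trial.found:
            lucky = float(frech <= spec.frechet_cutoff)
        rows.append({
            "participant": trial.participant_id,
            "room": trial.room_id,
            "phase": trial.phase,
            "block": trial.block,
            "path_length": plen,
            "ed": ed,
            "pe": plen / ed,
            "time_to_goal": trial.time_to_goal,
            "frechet": frech,
            "lucky": lucky,
            "found": trial.found,
        })
    return pd.DataFrame(rows)
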