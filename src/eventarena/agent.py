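"""Synthetic navigator: trajectory-level and cohort-level data generation.

The generator emulates the statistical structure the analysis stage
assumes, with a known ground truth so that recovery can be tested:

* per-room memory precision of the old goal location (OPA) that
  improves multiplicatively over 12 training blocks, with lognormal
  between-room and between-participant spread;
* naive search behavior on the first new-goal (NPA) block — a spiral
  sweep by default, with a tunable probability of a near-direct
  "lucky" heading that is independent of goal proximity;
* a tunable coupling between a room's OPA precision and the memory
  spread after one-shot NPA learning (block 2), the quantity the
  mixed-model stage tries to recover;
* an optional per-trial "activity" covariate coupled to subsequent
  performance.

Two generation modes are provided.  ``simulate_participant`` integrates
trajectories step by step (constant speed, bounded turn rate, Gaussian
heading noise, no backing up) and yields full ``TrialLog`` polylines for
the scoring stage.  ``simulate_cohort`` draws per-trial path lengths
from the same aiming geometry without timestep integration; it is the
generator of choice for Monte-Carlo calibration at cohort scale, where
thousands of replicate cohorts are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (ArenaGeometry, Location, ParticipantConfig,
                       build_participant)

__all__ = [
    "AgentParams",
    "TrialLog",
    "StepBudgetExceededError",
    "simulate_navigation_trial",
    "simulate_participant",
    "simulate_cohort",
    "simulate_roi_activity",
    "OPA_BLOCKS",
    "NPA_BLOCKS",
]

#: Training schedule: 8 self-paced blocks on Day 1, 4 top-off blocks on
#: Day 2, then 3 new-goal learning blocks.
OPA_BLOCKS = tuple(range(1, 13))
NPA_BLOCKS = (1, 2, 3)
DAY1_BLOCKS = tuple(range(1, 9))
DAY2_BLOCKS = (9, 10, 11, 12)


class StepBudgetExceededError(RuntimeError):
    """A navigation trial exceeded its step cap — indicates a search
    coverage bug, since the bounded arena plus exhaustive sweep must
    always find the goal."""


@dataclass(frozen=True)
class AgentParams:
    """Tunable parameters of the synthetic navigator.

    base_precision
        Memory spread (a.u., isotropic Gaussian SD) of the goal estimate
        on the first hidden-goal training block (block 2).
    learning_rate
        Multiplicative per-block precision gain; block ``b`` of training
        uses ``base_precision * learning_rate**(b - 2)``.
    room_precision_sd
        SD of the lognormal between-room precision factor (the "schema
        quality" of each room).
    participant_precision_sd
        SD of the lognormal between-participant precision factor.
    coupling_beta
        Strength of the coupling between a room's (log) OPA precision
        and the log memory spread after one-shot NPA learning; positive
        values mean better prior knowledge produces better one-shot
        learning.  The default is the moderate effect size calibrated
        by the repository's power study.
    luck_prob
        Probability that a naive NPA block-1 search takes a near-direct
        heading ("lucky shot") instead of a spiral sweep.
    luck_penalty
        Additive log-spread penalty on NPA block-2 memory for rooms
        whose block-1 search was lucky (lucky finds are associated with
        worse one-shot learning).
    npa_base_precision, npa_noise_sd, npa_learning_rate
        Baseline NPA block-2 memory spread, its lognormal trial noise,
        and the block-2 to block-3 precision gain.
    heading_noise_sd
        Gaussian heading noise per step, radians.
    max_turn_rate
        Bound on the turn rate, radians per second (no backing up).
    timestep
        Integration step, seconds.
    planning_duration
        Fixed pre-navigation planning period on NPA trials, seconds.
    max_steps
        Safety cap per trial before a coverage bug is flagged.
    seed
        Base seed for all randomness in participant/cohort simulation.
    """

    base_precision: float = 8.0
    learning_rate: float = 0.85
    room_precision_sd: float = 0.5
    participant_precision_sd: float = 0.25
    coupling_beta: float = 0.8
    luck_prob: float = 0.12
    luck_penalty: float = 0.5
    npa_base_precision: float = 3.0
    npa_noise_sd: float = 0.35
    npa_learning_rate: float = 0.5
    heading_noise_sd: float = 0.08
    max_turn_rate: float = 2.0 * math.pi
    timestep: float = 0.1
    planning_duration: float = 8.0
    max_steps: int = 60_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_precision <= 0:
            raise ValueError("base_precision must be positive")
        if not 0.0 <= self.luck_prob <= 1.0:
            raise ValueError("luck_prob must lie in [0, 1]")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")


@dataclass
class TrialLog:
    """One navigation trial: identifiers, endpoints and the logged polyline."""

    participant_id: str
    room_id: int
    phase: str              # "OPA" or "NPA"
    block: int
    start: Location
    goal: Location
    t: np.ndarray           # timestamps (s), strictly increasing
    xy: np.ndarray          # (n, 2) trajectory vertices
    found: bool
    run: int | None = None  # NPA scanning run index
    planning_onset: float | None = None   # NPA only
    goal_arrival: float | None = None     # NPA only

    @property
    def time_to_goal(self) -> float:
        """Seconds from navigation onset to goal contact."""
        return float(self.t[-1] - self.t[0])

    def validate(self, geometry: ArenaGeometry) -> None:
        """Assert the log invariants; raises AssertionError on violation."""
        assert np.allclose(self.xy[0], [self.start.x, self.start.y])
        assert np.all(np.diff(self.t) > 0), "timestamps must strictly increase"
        steps = np.hypot(*np.diff(self.xy, axis=0).T)
        assert np.all(steps <= geometry.speed * np.max(np.diff(self.t)) + 1e-9)
        if self.found:
            d = np.hypot(self.xy[-1, 0] - self.goal.x, self.xy[-1, 1] - self.goal.y)
            assert d <= geometry.contact_radius + 1e-9


# ---------------------------------------------------------------------------
# Search waypoint plans
# ---------------------------------------------------------------------------

def _spiral_waypoints(geometry: ArenaGeometry, spacing: float = 1.0) -> np.ndarray:
    """Outward Archimedean spiral around the arena center, pitch kept
    below the visibility radius so successive loops cannot straddle a
    hidden goal."""
    pitch = 0.85 * geometry.visibility_radius
    b = pitch / (2.0 * math.pi)
    r_max = math.hypot(geometry.width, geometry.depth) / 2.0
    pts = []
    phi = 0.0
    cx, cy = geometry.center
    while b * phi <= r_max:
        r = b * phi
        pts.append((cx + r * math.cos(phi), cy + r * math.sin(phi)))
        # advance phi for ~`spacing` arc length
        phi += spacing / max(r, spacing)
    arr = np.asarray(pts)
    lo = np.array([1.5, 1.5])
    hi = np.array([geometry.width - 1.5, geometry.depth - 1.5])
    return np.clip(arr, lo, hi)


def _serpentine_waypoints(geometry: ArenaGeometry) -> np.ndarray:
    """Boustrophedon sweep with rows spaced below the visibility
    diameter; exhaustive fallback guaranteeing coverage of the floor."""
    row_gap = 0.85 * geometry.visibility_diameter
    ys = np.arange(1.5, geometry.depth - 1.5 + row_gap, row_gap)
    ys = np.clip(ys, 1.5, geometry.depth - 1.5)
    pts = []
    for i, y in enumerate(ys):
        xs = (1.5, geometry.width - 1.5)
        if i % 2:
            xs = xs[::-1]
        pts.append((xs[0], y))
        pts.append((xs[1], y))
    return np.asarray(pts)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(p - a)))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.hypot(*(p - (a + t * ab))))


# ---------------------------------------------------------------------------
# Trajectory-level simulation
# ---------------------------------------------------------------------------

def simulate_navigation_trial(start: Location, goal: Location,
                              memory_spread: float | str,
                              geometry: ArenaGeometry,
                              params: AgentParams,
                              seed: int,
                              *, initial_heading: float | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one navigation trial; returns ``(t, xy)``.

    With a finite ``memory_spread`` the agent aims at the goal plus a
    2-D Gaussian error of that spread, drawing a fresh estimate each
    time it reaches an aim point without discovering the goal (spiral
    fallback after repeated failures).  With ``memory_spread="naive"``
    it runs the spiral search plan — or, with probability
    ``params.luck_prob``, takes a near-direct heading.  The hidden goal
    becomes visible within ``visibility_radius``, after which the agent
    approaches directly; the trial ends inside the contact radius.
    """
    if not geometry.contains(start) or not geometry.contains(goal):
        raise ValueError("start and goal must lie inside the arena")
    rng = np.random.default_rng(seed)
    dt = params.timestep
    step_len = geometry.speed * dt
    max_turn = params.max_turn_rate * dt

    pos = np.array([start.x, start.y], dtype=float)
    gl = np.array([goal.x, goal.y], dtype=float)
    m = geometry.wall_margin

    naive = isinstance(memory_spread, str)
    if naive and memory_spread != "naive":
        raise ValueError("memory_spread must be a float or 'naive'")

    plan: list[np.ndarray] = []

    def draw_estimate() -> np.ndarray:
        est = gl + rng.normal(0.0, float(memory_spread), size=2)
        return np.clip(est, [m, m], [geometry.width - m, geometry.depth - m])

    reaims = 0
    max_reaims = 8

    if naive:
        if rng.random() < params.luck_prob:
            # near-direct heading: aim far along the goal direction with a
            # small angular error — luck, not proximity
            ang = math.atan2(gl[1] - pos[1], gl[0] - pos[0])
            ang += rng.normal(0.0, 0.06)
            far = pos + 80.0 * np.array([math.cos(ang), math.sin(ang)])
            plan = [np.clip(far, [1.5, 1.5],
                            [geometry.width - 1.5, geometry.depth - 1.5])]
        else:
            plan = list(_spiral_waypoints(geometry))
    else:
        plan = [draw_estimate()]

    if initial_heading is None:
        c = geometry.center
        initial_heading = math.atan2(c.y - pos[1], c.x - pos[0])
    heading = float(initial_heading)

    traj = [pos.copy()]
    visible = False
    for step in range(params.max_steps):
        d_goal = float(np.hypot(*(pos - gl)))
        if d_goal <= geometry.visibility_radius:
            visible = True
        if visible and d_goal <= geometry.contact_radius:
            break
        if visible:
            aim = gl
        else:
            while plan and float(np.hypot(*(pos - plan[0]))) <= step_len:
                plan.pop(0)
            if not plan:
                if naive or reaims >= max_reaims:
                    # exhaustive sweep: spiral plus serpentine fallback
                    plan = (list(_spiral_waypoints(geometry))
                            + list(_serpentine_waypoints(geometry)))
                else:
                    reaims += 1
                    plan = [draw_estimate()]
                continue
            aim = plan[0]
        desired = math.atan2(aim[1] - pos[1], aim[0] - pos[0])
        turn = (desired - heading + math.pi) % (2.0 * math.pi) - math.pi
        turn = float(np.clip(turn, -max_turn, max_turn))
        heading = heading + turn + rng.normal(0.0, params.heading_noise_sd)
        nxt = pos + step_len * np.array([math.cos(heading), math.sin(heading)])
        nxt = np.clip(nxt, [0.0, 0.0], [geometry.width, geometry.depth])
        pos = nxt
        traj.append(pos.copy())
    else:
        raise StepBudgetExceededError(
            "goal not found within the step budget — search coverage bug")

    xy = np.asarray(traj)
    t = np.arange(len(xy)) * dt
    return t, xy


def _room_spreads(config: ParticipantConfig, params: AgentParams,
                  rng: np.random.Generator) -> dict:
    """Draw the latent per-room and participant precision factors."""
    n = config.n_rooms
    z_room = rng.normal(0.0, 1.0, size=n)
    room_factor = np.exp(params.room_precision_sd * z_room)
    participant_factor = float(np.exp(
        rng.normal(0.0, params.participant_precision_sd)))
    return {"z_room": z_room, "room_factor": room_factor,
            "participant_factor": participant_factor}


def _npa_spreads(latent: dict, lucky1: np.ndarray, params: AgentParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """NPA block-2/3 memory spreads from the OPA latent room precision
    and block-1 search experience (multiplicative, lognormal noise).

    The participant-level factor is an independent draw, so the only
    systematic OPA->NPA link is the room-level coupling being tested;
    with coupling_beta = 0 the two phases are exactly unrelated.
    """
    npa_participant = rng.normal(0.0, params.participant_precision_sd)
    log_spread2 = (math.log(params.npa_base_precision)
                   + params.coupling_beta * latent["z_room"]
                   + npa_participant
                   + params.luck_penalty * lucky1
                   + rng.normal(0.0, params.npa_noise_sd, size=len(lucky1)))
    spread2 = np.exp(log_spread2)
    spread3 = spread2 * params.npa_learning_rate
    return spread2, spread3


def opa_spread(block: int, room_factor: float, participant_factor: float,
               params: AgentParams) -> float:
    """Memory spread used on hidden-goal OPA training block ``block``."""
    if block < 2:
        raise ValueError("block 1 shows the goal; no memory spread applies")
    return (params.base_precision * params.learning_rate ** (block - 2)
            * room_factor * participant_factor)


def simulate_participant(config: ParticipantConfig,
                         params: AgentParams = AgentParams()) -> list[TrialLog]:
    """Simulate the full schedule for one participant, trajectory mode.

    OPA blocks 1–12 (block 1 visible goal → direct navigation; blocks
    2–12 hidden with improving precision) followed by NPA blocks 1–3
    (block 1 naive search, blocks 2–3 one-shot memory coupled to OPA
    precision).  Room order is randomized within block; each NPA block
    is split into two scanning runs of equal size.
    """
    geometry = config.geometry
    rng = np.random.default_rng([params.seed, config.seed])
    latent = _room_spreads(config, params, rng)
    trials: list[TrialLog] = []

    # corner starts: all four used once per 4-block chunk, per room
    corner_orders = {
        room.room_id: np.concatenate([rng.permutation(4) for _ in range(3)])
        for room in config.rooms
    }

    for block in OPA_BLOCKS:
        order = rng.permutation(config.n_rooms)
        for idx in order:
            room = config.rooms[int(idx)]
            corner = geometry.corners[
                corner_orders[room.room_id][block - 1]]
            if block == 1:
                spread: float | str = 0.0  # visible goal: direct walk
            else:
                spread = opa_spread(block, latent["room_factor"][int(idx)],
                                    latent["participant_factor"], params)
            t, xy = simulate_navigation_trial(
                corner, room.opa, spread, geometry, params,
                seed=int(rng.integers(2**31 - 1)))
            trials.append(TrialLog(
                participant_id=config.participant_id, room_id=room.room_id,
                phase="OPA", block=block, start=corner, goal=room.opa,
                t=t, xy=xy, found=True))

    lucky1 = np.zeros(config.n_rooms)
    spreads2 = spreads3 = None
    for block in NPA_BLOCKS:
        order = rng.permutation(config.n_rooms)
        run_of_pos = np.repeat([1, 2], [config.n_rooms - config.n_rooms // 2,
                                        config.n_rooms // 2])
        if block == 2 and spreads2 is None:
            spreads2, spreads3 = _npa_spreads(latent, lucky1, params, rng)
        for pos_in_block, idx in enumerate(order):
            room = config.rooms[int(idx)]
            start = config.npa_start(room)
            if block == 1:
                spread = "naive"
            elif block == 2:
                spread = float(spreads2[int(idx)])
            else:
                spread = float(spreads3[int(idx)])
            trial_seed = int(rng.integers(2**31 - 1))
            t, xy = simulate_navigation_trial(
                start, room.npa, spread, geometry, params, seed=trial_seed,
                initial_heading=_facing_opposite_wall(room, geometry))
            t = t + params.planning_duration
            trial = TrialLog(
                participant_id=config.participant_id, room_id=room.room_id,
                phase="NPA", block=block, start=start, goal=room.npa,
                t=t, xy=xy, found=True,
                run=(block - 1) * 2 + int(run_of_pos[pos_in_block]),
                planning_onset=0.0, goal_arrival=float(t[-1]))
            trials.append(trial)
            if block == 1:
                # luck bookkeeping for the block-2 spread model: a search
                # counts as lucky if it hugged the optimal segment
                lucky1[int(idx)] = float(_was_direct(trial, geometry))
    return trials


def _facing_opposite_wall(room, geometry: ArenaGeometry) -> float:
    start = room.npa_start(geometry)
    c = geometry.center
    return math.atan2(c.y - start.y, c.x - start.x)


def _was_direct(trial: TrialLog, geometry: ArenaGeometry) -> bool:
    """Cheap internal luck check (max deviation from the optimal segment)."""
    a = np.array([trial.start.x, trial.start.y])
    b = np.array([trial.goal.x, trial.goal.y])
    dev = max(_point_segment_distance(p, a, b) for p in trial.xy[::5])
    return dev <= geometry.visibility_radius


# ---------------------------------------------------------------------------
# Fast cohort-level generation (aiming geometry without timestep integration)
# ---------------------------------------------------------------------------

def _fast_guided_paths(starts: np.ndarray, goals: np.ndarray,
                       spreads: np.ndarray, geometry: ArenaGeometry,
                       rng: np.random.Generator) -> np.ndarray:
    """Vectorized path lengths of guided trials under the aiming model.

    Each agent walks to successive memory estimates of its goal until
    the current leg passes within the visibility radius, then
    approaches to the contact radius.
    """
    n = len(starts)
    pos = starts.astype(float).copy()
    goals = goals.astype(float)
    length = np.zeros(n)
    active = np.ones(n, dtype=bool)
    m = geometry.wall_margin
    lo = np.array([m, m])
    hi = np.array([geometry.width - m, geometry.depth - m])
    for _ in range(12):
        if not active.any():
            break
        est = goals + rng.normal(0.0, 1.0, size=(n, 2)) * spreads[:, None]
        est = np.clip(est, lo, hi)
        ab = est - pos
        denom = np.einsum("ij,ij->i", ab, ab)
        tstar = np.einsum("ij,ij->i", goals - pos, ab) / np.where(denom > 0,
                                                                  denom, 1.0)
        tstar = np.clip(tstar, 0.0, 1.0)
        p_near = pos + tstar[:, None] * ab
        d_near = np.hypot(*(p_near - goals).T)
        hit = active & (d_near <= geometry.visibility_radius)
        if hit.any():
            leg = np.hypot(*(p_near[hit] - pos[hit]).T)
            approach = np.maximum(
                np.hypot(*(p_near[hit] - goals[hit]).T)
                - geometry.contact_radius, 0.0)
            length[hit] += leg + approach
            active[hit] = False
        miss = active & ~hit
        length[miss] += np.hypot(*(est[miss] - pos[miss]).T)
        pos[miss] = est[miss]
    # exhausted re-aims: sweep-cost fallback
    if active.any():
        length[active] += 2.0 * np.hypot(*(goals[active] - pos[active]).T)
    return length


def _fast_naive_path(start: np.ndarray, goal: np.ndarray, lucky: bool,
                     geometry: ArenaGeometry, rng: np.random.Generator
                     ) -> float:
    ed = float(np.hypot(*(goal - start)))
    if lucky:
        return (ed - geometry.contact_radius) * float(
            1.0 + abs(rng.normal(0.0, 0.04)))
    # spiral cost: walk to center, sweep the disk out to the goal radius
    c = np.array([geometry.center.x, geometry.center.y])
    r_goal = float(np.hypot(*(goal - c)))
    pitch = 0.85 * geometry.visibility_radius
    arc = math.pi * r_goal ** 2 / pitch
    length = float(np.hypot(*(c - start))) + arc * float(
        np.exp(rng.normal(0.0, 0.25)))
    return max(length, ed)


def simulate_cohort(n_participants: int = 16, n_rooms: int = 36,
                    params: AgentParams = AgentParams(),
                    geometry: ArenaGeometry = ArenaGeometry(),
                    seed: int | None = None) -> pd.DataFrame:
    """Generate per-trial summary scores for a cohort, fast mode.

    Draws path lengths from the same aiming geometry as the trajectory
    simulator but without stepwise integration, making replicate-cohort
    Monte-Carlo (type-I error, power) affordable.  Returns a tidy frame
    with one row per trial: participant, room, phase, block, ed, pe,
    time_to_goal, lucky (NPA block 1 only).
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    frames = []
    corners = np.asarray([(c.x, c.y) for c in geometry.corners])
    for p in range(n_participants):
        config = build_participant(
            n_rooms, geometry, seed=int(rng.integers(2**31 - 1)),
            participant_id=f"p{p:03d}")
        latent = _room_spreads(config, params, rng)
        room_ids = np.array([r.room_id for r in config.rooms])
        opa_xy = np.asarray([(r.opa.x, r.opa.y) for r in config.rooms])
        npa_xy = np.asarray([(r.npa.x, r.npa.y) for r in config.rooms])
        npa_starts = np.asarray([(s.x, s.y) for s in
                                 (config.npa_start(r) for r in config.rooms)])
        corner_orders = np.stack([
            np.concatenate([rng.permutation(4) for _ in range(3)])
            for _ in range(n_rooms)])

        for block in OPA_BLOCKS:
            starts = corners[corner_orders[:, block - 1]]
            ed = np.hypot(*(opa_xy - starts).T)
            if block == 1:
                plen = ed - geometry.contact_radius
            else:
                spreads = (params.base_precision
                           * params.learning_rate ** (block - 2)
                           * latent["room_factor"]
                           * latent["participant_factor"])
                plen = _fast_guided_paths(starts, opa_xy, spreads,
                                          geometry, rng)
            frames.append(pd.DataFrame({
                "participant": config.participant_id, "room": room_ids,
                "phase": "OPA", "block": block, "ed": ed, "pe": plen / ed,
                "time_to_goal": plen / geometry.speed, "lucky": np.nan}))

        lucky1 = rng.random(n_rooms) < params.luck_prob
        spread2, spread3 = _npa_spreads(latent, lucky1.astype(float),
                                        params, rng)
        ed = np.hypot(*(npa_xy - npa_starts).T)
        for block in NPA_BLOCKS:
            if block == 1:
                plen = np.array([
                    _fast_naive_path(npa_starts[i], npa_xy[i],
                                     bool(lucky1[i]), geometry, rng)
                    for i in range(n_rooms)])
                lucky = lucky1.astype(float)
            else:
                spreads = spread2 if block == 2 else spread3
                plen = _fast_guided_paths(npa_starts, npa_xy, spreads,
                                          geometry, rng)
                lucky = np.full(n_rooms, np.nan)
            frames.append(pd.DataFrame({
                "participant": config.participant_id, "room": room_ids,
                "phase": "NPA", "block": block, "ed": ed, "pe": plen / ed,
                "time_to_goal": plen / geometry.speed, "lucky": lucky}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Synthetic per-trial activity covariate
# ---------------------------------------------------------------------------

def simulate_roi_activity(trial_summaries: pd.DataFrame, activity_beta: float,
                          noise_sd: float = 1.0, seed: int = 0,
                          roi_label: str = "roi") -> pd.DataFrame:
    """Per-trial activity coupled to subsequent one-shot performance.

    ``trial_summaries`` must contain NPA block-2 rows with columns
    ``participant``, ``room`` and ``pe``.  The activity value is
    ``activity_beta * z + noise`` where ``z`` is the standardized
    negated block-2 PE (higher activity predicts better subsequent
    navigation); with ``activity_beta = 0`` and the default
    ``noise_sd = 1`` the covariate has unit variance and no signal.
    """
    if len(trial_summaries) == 0:
        raise ValueError("empty trial table")
    npa2 = trial_summaries[(trial_summaries["phase"] == "NPA")
                           & (trial_summaries["block"] == 2)]
    if len(npa2) == 0:
        raise ValueError("trial table has no NPA block-2 rows")
    rng = np.random.default_rng(seed)
    perf = -npa2["pe"].to_numpy(dtype=float)
    sd = perf.std()
    z = (perf - perf.mean()) / sd if sd > 0 else np.zeros_like(perf)
    value = activity_beta * z + rng.normal(0.0, noise_sd, size=len(z))
    return pd.DataFrame({
        "participant": npa2["participant"].to_numpy(),
        "room": npa2["room"].to_numpy(),
        "block": 2,
        "roi_label": roi_label,
        "value": value,
    })
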