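"""Participant- and room-level prior-knowledge measures.

Two room-level indices of prior (OPA) spatial knowledge feed the
inference stage:

* ``opa_recent`` — path efficiency on the final training trial of a
  room (block 12), indexing the most recent retrieval experience;
* ``opa_average`` — a weighted mean of the four Day-2 training trials
  (blocks 9–12, weights increasing linearly toward the end of
  practice), indexing trial-invariant knowledge.  Single performance
  spikes are screened out per room with Dixon's Q at the 95% level
  before averaging (with four trials, at most one value can be an
  outlier).

Also here: the Day-1 learning criterion (weighted mean PE over blocks
6–8 must fall strictly below 2 for a participant to continue to Day 2)
and Euclidean-distance scoring of post-test location placements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .geometry import ArenaGeometry, Location

__all__ = [
    "CriterionSpec",
    "day1_criterion",
    "dixon_q",
    "dixon_q_critical",
    "opa_average",
    "opa_recent",
    "posttest_error",
    "build_knowledge",
    "DAY2_WEIGHTS",
]

#: Linear weighting toward the end of practice over blocks 9-12.
DAY2_WEIGHTS = (0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class CriterionSpec:
    """Day-1 continuation criterion: weighted mean PE over the final
    three Day-1 blocks, strictly below ``threshold`` to pass."""

    block_weights: dict = field(
        default_factory=lambda: {6: 0.15, 7: 0.25, 8: 0.6})
    threshold: float = 2.0

    def __post_init__(self) -> None:
        w = np.array(list(self.block_weights.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("block weights must be non-negative and sum to 1")


def day1_criterion(pe_by_block: dict, spec: CriterionSpec = CriterionSpec()
                   ) -> tuple[float, bool]:
    """Weighted Day-1 criterion value and pass decision (strict <)."""
    missing = sorted(set(spec.block_weights) - set(pe_by_block))
    if missing:
        raise ValueError(f"missing PE for weighted blocks: {missing}")
    value = float(sum(w * pe_by_block[b] for b, w in spec.block_weights.items()))
    return value, value < spec.threshold


# ---------------------------------------------------------------------------
# Dixon's Q
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def dixon_q_critical(n: int, alpha: float = 0.05, n_draws: int = 1_000_000,
                     seed: int = 20_260_925) -> float:
    """Monte-Carlo critical value of the two-sided r10 Dixon statistic.

    The null distribution of Q = (suspect gap)/(range), taken at the
    more extreme end of a standard-Gaussian sample of size ``n``, is
    simulated once and its upper ``alpha`` quantile cached.  Derived by
    simulation rather than read from a printed table so the calibration
    is self-contained and auditable; for n=4, alpha=0.05 it reproduces
    the classic two-tailed table value (~0.83) to Monte-Carlo accuracy.
    """
    if n < 3:
        raise ValueError("Dixon's Q needs n >= 3")
    rng = np.random.default_rng(seed)
    q = np.empty(n_draws)
    chunk = 200_000
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        x = np.sort(rng.standard_normal((k, n)), axis=1)
        rng_span = x[:, -1] - x[:, 0]
        low_gap = x[:, 1] - x[:, 0]
        high_gap = x[:, -1] - x[:, -2]
        q[done:done + k] = np.maximum(low_gap, high_gap) / rng_span
        done += k
    return float(np.quantile(q, 1.0 - alpha))


def dixon_q(values, alpha: float = 0.05) -> int | None:
    """Index of the single Dixon's-Q outlier, or ``None``.

    Two-sided r10 statistic: the gap between the most extreme value and
    its neighbor, divided by the range, tested at the more suspect end.
    At most one value is ever removed — with small samples two or more
    spikes cannot be distinguished from genuine spread.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Dixon's Q needs at least 3 values")
    span = float(x.max() - x.min())
    if span == 0:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    low_gap = xs[1] - xs[0]
    high_gap = xs[-1] - xs[-2]
    if high_gap >= low_gap:
        q, suspect = high_gap / span, order[-1]
    else:
        q, suspect = low_gap / span, order[0]
    if q > dixon_q_critical(len(x), alpha):
        return int(suspect)
    return None


# ---------------------------------------------------------------------------
# Room-level knowledge indices
# ---------------------------------------------------------------------------

def opa_average(pes, weights=DAY2_WEIGHTS, *, outlier_alpha: float | None = 0.05
                ) -> tuple[float, int]:
    """Weighted mean PE of the four Day-2 training trials of one room.

    ``pes`` must hold exactly four values ordered by block (9–12).
    With ``outlier_alpha`` set, a single Dixon's-Q spike is removed and
    the weights renormalized over the surviving trials; pass ``None``
    to average all four unconditionally.  Returns ``(value, n_used)``.
    """
    x = np.asarray(pes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(x) != 4 or len(w) != 4:
        raise ValueError("opa_average needs exactly 4 trials and 4 weights")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = np.ones(4, dtype=bool)
    if outlier_alpha is not None:
        drop = dixon_q(x, outlier_alpha)
        if drop is not None:
            keep[drop] = False
    wk = w[keep] / w[keep].sum()
    return float(wk @ x[keep]), int(keep.sum())


def opa_recent(pe_by_block: dict) -> float:
    """PE on the final training trial (block 12), untransformed."""
    if 12 not in pe_by_block:
        raise ValueError("block-12 trial missing")
    return float(pe_by_block[12])


def posttest_error(click: Location, truth: Location,
                   geometry: ArenaGeometry = ArenaGeometry()) -> float:
    """Euclidean distance from a clicked to the true location (a.u.)."""
    if not geometry.contains(click):
        warnings.warn("click outside arena bounds; distance still returned",
                      stacklevel=2)
    return click.distance_to(truth)


def build_knowledge(metrics: pd.DataFrame, weights=DAY2_WEIGHTS,
                    outlier_alpha: float | None = 0.05) -> pd.DataFrame:
    """Room-level knowledge table from a per-trial metrics frame.

    ``metrics`` needs columns ``participant``, ``room``, ``phase``,
    ``block``, ``pe`` (one OPA row per room and block).  Returns one row
    per (participant, room) with ``opa_recent``, ``opa_average`` and
    ``n_trials_used``.
    """
    opa = metrics[metrics["phase"] == "OPA"]
    rows = []
    for (pid, room), grp in opa.groupby(["participant", "room"], sort=True):
        by_block = dict(zip(grp["block"], grp["pe"]))
        missing = [b for b in (9, 10, 11, 12) if b not in by_block]
        if missing:
            raise ValueError(
                f"participant {pid} room {room} missing Day-2 blocks {missing}")
        avg, n_used = opa_average([by_block[b] for b in (9, 10, 11, 12)],
                                  weights, outlier_alpha=outlier_alpha)
        rows.append({"participant": pid, "room": room,
                     "opa_recent": opa_recent(by_block),
                     "opa_average": avg, "n_trials_used": n_used})
    return pd.DataFrame(rows)
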