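"""Spin-lock-time grids, schedules, optimizers, and the acquisition-time model.

A schedule is an ordered multiset of K spin-lock times drawn from a discrete
grid (repeats are allowed and do occur in optimized schedules: acquiring the
same TSL twice is signal averaging at that point). The default grid is
non-uniform — 0.5 ms steps from 0.5 to 5 ms, then 1 ms steps from 6 to
55 ms — reflecting where the short-relaxation information lives; 55 ms is
the ceiling because longer spin-locks approach the noise floor.

Two optimizers are provided: an exhaustive enumeration of all K-multisets
(the oracle, feasible for small K) and Pareto Optimization for Subset
Selection (POSS), an evolutionary bi-objective search over (cost, size)
that scales to larger K.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "TSLGrid",
    "Schedule",
    "TimingModel",
    "build_grid",
    "paper_grid",
    "fine_grid",
    "linspaced_schedule",
    "exhaustive_search",
    "poss_optimize",
    "acquisition_time",
    "write_schedule_json",
    "read_schedule_json",
    "read_schedule_text",
]


@dataclass(frozen=True)
class TSLGrid:
    """Sorted set of allowed spin-lock times (ms)."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", vals)
        if vals.size < 2 or np.any(np.diff(vals) <= 0):
            raise ConfigError("grid values must be strictly increasing (>= 2 nodes)")

    @property
    def n_nodes(self) -> int:
        return self.values.size

    def nearest(self, tsl_ms) -> np.ndarray:
        """Snap values to the nearest grid node; ties round up."""
        tsl = np.atleast_1d(np.asarray(tsl_ms, dtype=float))
        hi = np.clip(np.searchsorted(self.values, tsl, side="left"), 0, self.n_nodes - 1)
        lo = np.clip(hi - 1, 0, self.n_nodes - 1)
        # tie (equidistant) -> keep the larger node (round-half-up)
        pick_lo = np.abs(self.values[lo] - tsl) < np.abs(self.values[hi] - tsl)
        return self.values[np.where(pick_lo, lo, hi)]

    def __contains__(self, tsl: float) -> bool:
        return bool(np.any(np.isclose(self.values, tsl, atol=1e-9)))


@dataclass(frozen=True)
class Schedule:
    """Multiset of K spin-lock times (ms), stored sorted ascending."""

    tsl_ms: tuple
    provenance: str = "user"

    def __post_init__(self):
        tsl = tuple(sorted(float(t) for t in np.atleast_1d(np.asarray(self.tsl_ms, dtype=float))))
        if len(tsl) < 1:
            raise ConfigError("a schedule needs at least one spin-lock time")
        if any(t < 0 for t in tsl):
            raise ConfigError("spin-lock times must be non-negative")
        object.__setattr__(self, "tsl_ms", tsl)
        if self.provenance not in ("crlb", "mcrlb", "linspaced", "user"):
            raise ConfigError(f"unknown provenance {self.provenance!r}")

    @property
    def k(self) -> int:
        return len(self.tsl_ms)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.tsl_ms, dtype=float)

    def append(self, tsl: float) -> "Schedule":
        return Schedule(self.tsl_ms + (float(tsl),), provenance=self.provenance)

    def __str__(self) -> str:
        inner = " ".join(f"{t:g}" for t in self.tsl_ms)
        return f"[{inner}]"


@dataclass(frozen=True)
class TimingModel:
    """Per-shot timing of the acquisition.

    One shot is spin-lock preparation (duration = the TSL itself), a 64-line
    imaging readout, and a longitudinal-recovery delay; ``shots`` shots fill
    one data matrix per TSL.
    """

    imaging_ms: float = 486.4
    recovery_ms: float = 1000.0
    shots: int = 128

    def __post_init__(self):
        if self.imaging_ms < 0 or self.recovery_ms < 0 or self.shots < 1:
            raise ConfigError("timing model values must be non-negative (shots >= 1)")


def build_grid(
    fine_step_ms: float = 0.5,
    coarse_step_ms: float = 1.0,
    boundaries: Sequence[float] = (0.5, 5.0, 6.0, 55.0),
) -> TSLGrid:
    """Two-segment TSL grid: fine steps at short times, coarse steps beyond.

    Defaults give {0.5, 1.0, …, 5.0} ∪ {6, 7, …, 55} (60 nodes).
    """
    if fine_step_ms <= 0 or coarse_step_ms <= 0:
        raise ConfigError("grid steps must be positive")
    f0, f1, c0, c1 = (float(b) for b in boundaries)
    if not (f0 <= f1 < c0 <= c1):
        raise ConfigError(f"inconsistent grid boundaries {boundaries}")
    n_fine = int(round((f1 - f0) / fine_step_ms))
    n_coarse = int(round((c1 - c0) / coarse_step_ms))
    fine = f0 + fine_step_ms * np.arange(n_fine + 1)
    coarse = c0 + coarse_step_ms * np.arange(n_coarse + 1)
    return TSLGrid(np.round(np.concatenate([fine, coarse]), 9))


def paper_grid() -> TSLGrid:
    """The default non-uniform grid (0.5:0.5:5 ∪ 6:1:55)."""
    return build_grid()


def fine_grid() -> TSLGrid:
    """A 0.1 ms-resolution variant of the short-TSL segment."""
    return build_grid(fine_step_ms=0.1)


def linspaced_schedule(k: int, grid: TSLGrid | None = None, lo: float = 0.5, hi: float = 55.0) -> Schedule:
    """Non-optimized baseline: K equally spaced TSLs snapped to the grid."""
    if k < 2:
        raise ConfigError("a linearly spaced schedule needs k >= 2")
    grid = grid or paper_grid()
    vals = grid.nearest(np.linspace(lo, hi, k))
    return Schedule(tuple(vals), provenance="linspaced")


def acquisition_time(schedule: Schedule, timing: TimingModel | None = None) -> float:
    """Total acquisition time in seconds for a schedule.

    Each TSL costs ``shots × (TSL + imaging + recovery)``: the preparation
    module lasts as long as the spin-lock itself.
    """
    timing = timing or TimingModel()
    tsl = np.asarray(getattr(schedule, "tsl_ms", schedule), dtype=float)
    per_tsl_ms = timing.shots * (tsl + timing.imaging_ms + timing.recovery_ms)
    return float(per_tsl_ms.sum() / 1000.0)


def _provenance_of(cost_fn) -> str:
    tag = getattr(cost_fn, "criterion", None)
    return tag if tag in ("crlb", "mcrlb") else "user"


def exhaustive_search(
    cost_fn: Callable,
    grid: TSLGrid,
    k: int,
    enumeration_cap: int = 10**7,
    chunk: int = 200_000,
) -> tuple[Schedule, float]:
    """Global minimum of ``cost_fn`` over all K-multisets of grid nodes.

    The oracle optimizer: exact but exponential, refused above
    ``enumeration_cap`` multisets. ``cost_fn`` may be any callable on a
    Schedule; a :class:`~tslopt.crlb.ScheduleCost` is evaluated through its
    batched path. Ties resolve to the lexicographically smallest multiset.
    """
    n = grid.n_nodes
    n_multisets = math.comb(n + k - 1, k)
    if n_multisets > enumeration_cap:
        raise ConfigError(
            f"enumeration of {n_multisets} multisets exceeds the cap of {enumeration_cap}"
        )
    combos = itertools.combinations_with_replacement(range(n), k)
    best_cost, best_idx = np.inf, None
    batched = hasattr(cost_fn, "evaluate_index_sets")
    while True:
        block = list(itertools.islice(combos, chunk))
        if not block:
            break
        idx = np.asarray(block, dtype=np.intp)
        if batched:
            costs = cost_fn.evaluate_index_sets(idx)
        else:
            costs = np.array(
                [cost_fn(Schedule(tuple(grid.values[row]))) for row in idx], dtype=float
            )
        j = int(np.argmin(costs))
        if costs[j] < best_cost:
            best_cost, best_idx = float(costs[j]), idx[j]
    if best_idx is None or not np.isfinite(best_cost):
        raise ConfigError("no feasible schedule found (all costs non-finite)")
    sched = Schedule(tuple(grid.values[best_idx]), provenance=_provenance_of(cost_fn))
    return sched, best_cost


def _counts_cost(cost_fn, grid: TSLGrid, counts: np.ndarray) -> float:
    if hasattr(cost_fn, "cost_of_counts"):
        return cost_fn.cost_of_counts(counts)
    if counts.sum() == 0:
        return np.inf
    tsl = np.repeat(grid.values, counts)
    return float(cost_fn(Schedule(tuple(tsl))))


def poss_optimize(
    cost_fn: Callable,
    grid: TSLGrid,
    k: int,
    iterations: int = 200_000,
    seed: int = 0,
) -> tuple[Schedule, float]:
    """Pareto Optimization for Subset Selection over grid-node multisets.

    Maintains an archive of mutually non-dominated solutions under the
    bi-objective (cost, multiset size) — because appending a TSL never
    increases the cost, the front holds one best solution per size. Each
    iteration mutates a random archive member by ±1 on each node's count
    with probability 1/n, evaluates it, and inserts it if non-dominated.
    Returns the best size-K member (greedily padded if the archive's best
    sits below size K). Deterministic given ``seed``.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    rng = np.random.default_rng(seed)
    n = grid.n_nodes
    # archive: size -> (counts, cost); seeded with the empty schedule plus the
    # linspaced size-k baseline (a feasible anchor: schedules smaller than the
    # parameter count have singular information and infinite cost, so an
    # empty-only seed would wait on a multi-node mutation to become feasible)
    archive: dict[int, tuple[np.ndarray, float]] = {0: (np.zeros(n, dtype=np.intp), np.inf)}
    if k >= 2:
        anchor = np.zeros(n, dtype=np.intp)
        for t in linspaced_schedule(k, grid, grid.values[0], grid.values[-1]).tsl_ms:
            anchor[int(np.argmin(np.abs(grid.values - t)))] += 1
        anchor_cost = _counts_cost(cost_fn, grid, anchor)
        if np.isfinite(anchor_cost):
            archive[k] = (anchor, anchor_cost)

    def dominated(size: int, cost: float) -> bool:
        return any(
            s <= size and c <= cost and (s < size or c < cost) for s, (_, c) in archive.items()
        )

    for _ in range(iterations):
        sizes = list(archive)
        parent = archive[sizes[rng.integers(len(sizes))]][0].copy()
        flip = rng.random(n) < 1.0 / n
        signs = rng.integers(0, 2, size=n) * 2 - 1
        parent[flip] += signs[flip]
        np.maximum(parent, 0, out=parent)
        size = int(parent.sum())
        if size > k + 1:  # no benefit in carrying oversized solutions
            continue
        cost = _counts_cost(cost_fn, grid, parent)
        if dominated(size, cost):
            continue
        archive[size] = (parent, cost)
        for s in [s for s, (_, c) in archive.items() if s != size and s >= size and c >= cost]:
            del archive[s]

    # candidates: exact size k, or smaller solutions padded greedily
    best_counts, best_cost = None, np.inf
    if k in archive:
        best_counts, best_cost = archive[k][0].copy(), archive[k][1]
    for size in sorted(s for s in archive if s < k):
        counts = archive[size][0].copy()
        cost = archive[size][1]
        while counts.sum() < k:
            trial_costs = np.full(n, np.inf)
            for j in range(n):
                counts[j] += 1
                trial_costs[j] = _counts_cost(cost_fn, grid, counts)
                counts[j] -= 1
            j = int(np.argmin(trial_costs))
            counts[j] += 1
            cost = float(trial_costs[j])
        if cost < best_cost:
            best_counts, best_cost = counts, cost
    if best_counts is None or not np.isfinite(best_cost):
        raise ConfigError("POSS found no feasible size-K schedule; increase iterations")
    tsl = np.repeat(grid.values, best_counts)
    return Schedule(tuple(tsl), provenance=_provenance_of(cost_fn)), float(best_cost)


# ---------------------------------------------------------------------------
# schedule file formats
# ---------------------------------------------------------------------------

def write_schedule_json(
    schedule: Schedule,
    path,
    model: str | None = None,
    criterion: str | None = None,
    grid: TSLGrid | None = None,
    seed: int | None = None,
    cost: float | None = None,
) -> None:
    """One JSON document per schedule, with enough metadata to regenerate it."""
    doc = {
        "model": model,
        "criterion": criterion,
        "K": schedule.k,
        "tsl_ms": list(schedule.tsl_ms),
        "grid": None if grid is None else {"values": grid.values.tolist()},
        "seed": seed,
        "cost": cost,
        "provenance": schedule.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_schedule_json(path) -> tuple[Schedule, dict]:
    doc = json.loads(Path(path).read_text())
    provenance = doc.get("provenance", "user")
    return Schedule(tuple(doc["tsl_ms"]), provenance=provenance), doc


def read_schedule_text(path) -> Schedule:
    """Plain-text interoperability format: one spin-lock time (ms) per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    tsl = [float(ln) for ln in lines if ln and not ln.startswith("#")]
    return Schedule(tuple(tsl))
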