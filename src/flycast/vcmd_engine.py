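"""Virtual-system coupled sampling over the zone grid.

Between transition attempts the system evolves freely under its own
dynamics plus a flat-bottom restraint that confines the reaction
coordinates to the current zone's box.  Every ``transition_interval_steps``
an inter-zone transition is attempted: the candidate set is the zones whose
box contains the instantaneous RC value (the current zone plus overlapping
neighbors), and the new zone is drawn with probability proportional to each
candidate's zone-conditional canonical density at that point.  Dividing by
the zone mass is what makes the stationary zone-visit distribution uniform
when the supplied density estimate is exact — the flattening property the
scheme targets — while the within-zone dynamics remain canonical.

The dynamics backend is a small contract (see :class:`DynamicsBackend`);
the bundled backend is overdamped Langevin on analytic toy potentials
(:class:`flycast.synthetic_models.LangevinBackend`).  Coupling a real MD
engine is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from flycast.qcano_estimator import QSurface
from flycast.rc_zones import ZoneGrid

__all__ = [
    "EngineConfig",
    "Snapshot",
    "ScheduleSummary",
    "DynamicsBackend",
    "restraint",
    "attempt_transition",
    "run_iteration",
    "plan_schedule",
    "select_seeds",
    "write_snapshots_tsv",
    "read_snapshots_tsv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EngineConfig:
    """Sampler schedule and physical parameters.

    Defaults mirror a production setup: a 2 fs time step with transition
    attempts every 10,000 steps (20 ps), 2,000 parallel runs of 10^6 steps
    per iteration and a snapshot every 10^5 steps.  Desk-scale studies
    override these with much smaller numbers.
    """

    time_step: float = 2.0  # fs
    transition_interval_steps: int = 10_000
    temperature: float = 300.0  # K
    restraint_spring: float = 50.0  # energy units / Å²
    runs_per_iteration: int = 2000
    steps_per_run: int = 1_000_000
    snapshot_interval_steps: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.time_step, self.temperature, self.restraint_spring) <= 0:
            raise ValueError("time step, temperature and spring must be positive")
        if min(
            self.transition_interval_steps,
            self.runs_per_iteration,
            self.steps_per_run,
            self.snapshot_interval_steps,
        ) <= 0:
            raise ValueError("all schedule counts must be positive")
        if self.transition_interval_steps > self.steps_per_run:
            raise ValueError("transition interval cannot exceed the run length")


@dataclass
class Snapshot:
    """One stored state of one run: RC value, zone label, and backend state.

    ``state`` is the toy-model state vector for the bundled backend, or a
    (structure file, model id) reference for coordinate snapshots.  The
    canonical weight is assigned after convergence and defaults to unset.
    """

    iteration: int
    run: int
    step: int
    lam: np.ndarray
    zone: tuple[int, ...]
    state: np.ndarray | tuple[str, int]
    weight: float | None = None

    def __post_init__(self) -> None:
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if not np.all(np.isfinite(self.lam)):
            raise ValueError("snapshot RC values must be finite")
        self.zone = tuple(int(z) for z in self.zone)


@dataclass(frozen=True)
class ScheduleSummary:
    total_iterations: int
    total_runs: int
    total_steps: int
    total_simulated_time_us: float
    total_snapshots: int


class DynamicsBackend(Protocol):
    """Contract for a dynamics backend usable by :func:`run_iteration`.

    States are stacked as an ``(n_runs, dim)`` array and all methods are
    vectorized over the first axis.
    """

    dim: int

    def rc(self, states: np.ndarray) -> np.ndarray:
        """Map states to RC values, shape (n_runs, rc_dim)."""

    def rc_gradient_pullback(self, states: np.ndarray, rc_grad: np.ndarray) -> np.ndarray:
        """Chain-rule an RC-space gradient back onto state coordinates."""

    def step(self, states: np.ndarray, extra_gradient: np.ndarray, noise: np.ndarray) -> np.ndarray:
        """Advance one time step under the potential plus an extra gradient."""


# ---------------------------------------------------------------------------
# Restraint


def restraint(
    lam: np.ndarray, zone: tuple[int, ...], grid: ZoneGrid, spring: float
) -> tuple[float, np.ndarray]:
    """Flat-bottom restraint confining the RC vector to a zone's box.

    Zero energy and gradient inside the box; outside, a half-harmonic
    ``½ k δ²`` per axis on the overshoot beyond the nearer edge.  Continuous
    and once-differentiable across the boundary.
    """
    lo, hi = grid.zone_box(zone)
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    over = np.clip(lam - hi, 0.0, None)
    under = np.clip(lam - lo, None, 0.0)
    delta = over + under
    energy = 0.5 * spring * float(np.sum(delta**2))
    gradient = spring * delta
    return energy, gradient


def _restraint_gradient_batch(
    lam: np.ndarray, lo: np.ndarray, hi: np.ndarray, spring: float
) -> np.ndarray:
    """Vectorized restraint gradient for per-run zone boxes."""
    delta = np.clip(lam - hi, 0.0, None) + np.clip(lam - lo, None, 0.0)
    return spring * delta


# ---------------------------------------------------------------------------
# Transitions


def attempt_transition(
    current: tuple[int, ...],
    lam: np.ndarray,
    q: QSurface,
    grid: ZoneGrid,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Attempt one inter-zone transition at the instantaneous RC value.

    Candidates are the zones containing ``lam``; the returned zone is drawn
    with probability proportional to each candidate's zone-conditional
    density there.  With a single candidate (``lam`` outside any overlap)
    the current zone is returned.  If every candidate has zero density the
    move is rejected and logged.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    # restraint overshoot may carry λ marginally outside coverage: clamp for
    # the membership query only (the recorded λ stays as-is)
    lo, hi = grid.coverage
    candidates = sorted(grid.membership(np.clip(lam, lo, hi)))
    if tuple(current) not in candidates:
        # restraint overshoot: keep the current zone in play
        candidates.append(tuple(current))
        candidates.sort()
    if len(candidates) == 1:
        return candidates[0]
    probs = np.array([q.conditional_density_at(z, lam) for z in candidates])
    total = probs.sum()
    if total <= 0:
        log.info("all candidate densities zero at %s; staying in %s", lam, current)
        return tuple(current)
    return candidates[rng.choice(len(candidates), p=probs / total)]


# ---------------------------------------------------------------------------
# Iteration driver


def run_iteration(
    config: EngineConfig,
    backend: DynamicsBackend,
    q: QSurface,
    grid: ZoneGrid,
    seeds: Sequence[Snapshot],
    iteration: int = 1,
) -> tuple[list[Snapshot], dict[tuple[int, ...], int]]:
    """Evolve every seed for one iteration and record snapshots.

    Each run gets its own RNG stream derived from ``(rng_seed, iteration,
    run)``, so results do not depend on execution order and the whole
    iteration is reproducible bitwise.  A run whose state turns non-finite
    is aborted and reported; the others continue.  Returns the recorded
    snapshots and a per-zone histogram of recorded visits.
    """
    if len(seeds) != config.runs_per_iteration:
        raise ValueError(
            f"need {config.runs_per_iteration} seeds, got {len(seeds)}"
        )
    n = len(seeds)
    states = np.stack([np.atleast_1d(np.asarray(s.state, dtype=float)) for s in seeds])
    zones: list[tuple[int, ...]] = [tuple(s.zone) for s in seeds]
    rngs = [
        np.random.default_rng([int(config.rng_seed), int(iteration), run])
        for run in range(n)
    ]
    steps = config.steps_per_run
    dim = states.shape[1]
    noise = np.empty((n, steps, dim))
    for r in range(n):
        noise[r] = rngs[r].standard_normal((steps, dim))

    lo = np.empty((n, grid.ndim))
    hi = np.empty((n, grid.ndim))
    for r in range(n):
        lo[r], hi[r] = grid.zone_box(zones[r])

    cov_lo, cov_hi = grid.coverage
    alive = np.ones(n, dtype=bool)
    snapshots: list[Snapshot] = []
    histogram: dict[tuple[int, ...], int] = {z: 0 for z in grid.zones()}

    for t in range(steps):
        lam = backend.rc(states)
        rc_grad = _restraint_gradient_batch(lam, lo, hi, config.restraint_spring)
        extra = backend.rc_gradient_pullback(states, rc_grad)
        new_states = backend.step(states, extra, noise[:, t, :])
        bad = alive & ~np.all(np.isfinite(new_states), axis=1)
        if bad.any():
            for r in np.nonzero(bad)[0]:
                log.warning("run %d diverged at step %d; aborting that run", r, t + 1)
            alive &= ~bad
        states = np.where(alive[:, None], new_states, states)
        if hasattr(backend, "reflect"):
            states = backend.reflect(states, cov_lo, cov_hi)

        # snapshots are recorded before any transition attempt at the same
        # step, so every recorded (zone, λ) pair reflects a maximally relaxed
        # segment of restrained dynamics rather than a freshly switched label
        if (t + 1) % config.snapshot_interval_steps == 0:
            lam = backend.rc(states)
            for r in range(n):
                if not alive[r]:
                    continue
                snapshots.append(
                    Snapshot(
                        iteration=iteration,
                        run=r,
                        step=t + 1,
                        lam=lam[r].copy(),
                        zone=zones[r],
                        state=states[r].copy(),
                    )
                )
                histogram[zones[r]] += 1

        if (t + 1) % config.transition_interval_steps == 0:
            lam = backend.rc(states)
            for r in range(n):
                if not alive[r]:
                    continue
                new_zone = attempt_transition(zones[r], lam[r], q, grid, rngs[r])
                if new_zone != zones[r]:
                    zones[r] = new_zone
                    lo[r], hi[r] = grid.zone_box(new_zone)
    return snapshots, histogram


def plan_schedule(config: EngineConfig, iterations: int) -> ScheduleSummary:
    """Exact bookkeeping of a sampling campaign (integer/rational arithmetic)."""
    if iterations < 1:
        raise ValueError("iterations must be positive")
    if config.snapshot_interval_steps > config.steps_per_run:
        raise ValueError("snapshot interval exceeds the run length")
    total_runs = iterations * config.runs_per_iteration
    total_steps = total_runs * config.steps_per_run
    # fs -> µs exactly, via rational arithmetic
    time_us = Fraction(total_steps) * Fraction(str(config.time_step)) / Fraction(10**9)
    total_snapshots = total_runs * (config.steps_per_run // config.snapshot_interval_steps)
    return ScheduleSummary(
        total_iterations=iterations,
        total_runs=total_runs,
        total_steps=total_steps,
        total_simulated_time_us=float(time_us),
        total_snapshots=total_snapshots,
    )


def select_seeds(
    snapshots: Sequence[Snapshot],
    histogram: dict[tuple[int, ...], int],
    n: int,
    rng: np.random.Generator,
) -> list[Snapshot]:
    """Pick the next iteration's seeds, favoring poorly sampled zones.

    Zones are ranked by ascending visit count (zones with no snapshots are
    skipped) and seeds are drawn round-robin starting from the least visited
    zone, sampling uniformly within each zone.  If more seeds than snapshots
    are requested, sampling is with replacement (logged).
    """
    if not snapshots:
        raise ValueError("no snapshots to select seeds from")
    if n < 1:
        raise ValueError("need n >= 1")
    by_zone: dict[tuple[int, ...], list[Snapshot]] = {}
    for snap in snapshots:
        by_zone.setdefault(tuple(snap.zone), []).append(snap)
    ranked = sorted(by_zone, key=lambda z: (histogram.get(z, len(by_zone[z])), z))
    if n > len(snapshots):
        log.info("requested %d seeds from %d snapshots; sampling with replacement", n, len(snapshots))
    remaining = {z: list(range(len(by_zone[z]))) for z in ranked}
    seeds: list[Snapshot] = []
    zi = 0
    while len(seeds) < n:
        zone = ranked[zi % len(ranked)]
        pool = remaining[zone]
        if pool:
            pick = pool.pop(int(rng.integers(len(pool))))
        else:  # zone exhausted: draw with replacement
            pick = int(rng.integers(len(by_zone[zone])))
        seeds.append(by_zone[zone][pick])
        zi += 1
    return seeds


# ---------------------------------------------------------------------------
# Snapshot table I/O (weighted-ensemble TSV, toy states inlined)


def write_snapshots_tsv(snapshots: Sequence[Snapshot], target: str | Path) -> None:
    rows = []
    for i, s in enumerate(snapshots):
        row = {
            "snapshot": i,
            "iteration": s.iteration,
            "run": s.run,
            "step": s.step,
            "zone": ",".join(map(str, s.zone)),
            "weight": "" if s.weight is None else f"{s.weight:.12g}",
        }
        for d, x in enumerate(np.atleast_1d(s.lam)):
            row[f"lambda_{d}"] = f"{x:.12g}"
        if isinstance(s.state, tuple):
            row["structure"], row["model"] = s.state
        else:
            for d, x in enumerate(np.atleast_1d(s.state)):
                row[f"state_{d}"] = f"{x:.12g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(target, sep="\t", index=False)


def read_snapshots_tsv(source: str | Path) -> list[Snapshot]:
    df = pd.read_csv(source, sep="\t", dtype={"zone": str})
    lam_cols = sorted(c for c in df.columns if c.startswith("lambda_"))
    state_cols = sorted(c for c in df.columns if c.startswith("state_"))
    out = []
    for _, row in df.iterrows():
        if state_cols:
            state = np.array([float(row[c]) for c in state_cols])
        else:
            state = (str(row["structure"]), int(row["model"]))
        weight = row.get("weight")
        out.append(
            Snapshot(
                iteration=int(row["iteration"]),
                run=int(row["run"]),
                step=int(row["step"]),
                lam=np.array([float(row[c]) for c in lam_cols]),
                zone=tuple(int(t) for t in str(row["zone"]).split(",")),
                state=state,
                weight=None if pd.isna(weight) else float(weight),
            )
        )
    return out
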