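"""Iterative estimation of the canonical density over the zone grid.

The sampler confines each short dynamics segment to one zone, so the raw
output of an iteration is a set of per-zone histograms of the reaction
coordinates.  Within a zone those histograms are proportional to the
canonical density restricted to the zone, but each zone carries an unknown
normalization.  The estimator therefore proceeds in three stages:

1. :func:`update_q` — within each zone, correct the previous estimate by
   the observed/expected count ratio, then stitch neighboring zones
   together by matching their mean density over the shared overlap bins;
2. :func:`ga_refine` — a genetic algorithm polishes the stitched surface in
   log space, trading fidelity to the data against cross-overlap continuity
   and smoothness;
3. :func:`e_local` — a per-zone convergence diagnostic (mean absolute
   log-ratio between consecutive iterations); a zone with ``e_local < 0.25``
   is deemed accurately determined.

Once converged, :func:`snapshot_weights` assigns a canonical weight to every
stored snapshot as the ratio of the estimated density to the actually
sampled marginal at the snapshot's (zone, bin).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from flycast.rc_zones import ZoneGrid

__all__ = [
    "QSurface",
    "ConvergenceReport",
    "update_q",
    "ga_refine",
    "e_local",
    "snapshot_weights",
    "zone_bin_histograms",
]

log = logging.getLogger(__name__)

#: Convergence gate on the per-zone diagnostic.
E_LOCAL_THRESHOLD = 0.25


@dataclass
class QSurface:
    """Estimated canonical probability over (zone, intra-zone bin) states.

    Each zone's box is subdivided into ``nbins`` uniform bins per axis; the
    stored values are probability masses per bin, normalized so the sum over
    every zone and bin is 1.  Because zones overlap, a physical RC value can
    appear under more than one zone; the (zone, bin) pair is the elementary
    state of the estimator.
    """

    grid: ZoneGrid
    nbins: int
    values: dict[tuple[int, ...], np.ndarray]

    def __post_init__(self) -> None:
        if self.nbins < 1:
            raise ValueError("need at least one bin per axis per zone")
        shape = (self.nbins,) * self.grid.ndim
        for zone in self.grid.zones():
            if zone not in self.values:
                raise ValueError(f"zone {zone} missing from surface")
            v = np.asarray(self.values[zone], dtype=float)
            if v.shape != shape:
                raise ValueError(f"zone {zone} values must have shape {shape}")
            if np.any(v < 0):
                raise ValueError("density values must be non-negative")
            self.values[zone] = v

    @classmethod
    def uniform(cls, grid: ZoneGrid, nbins: int = 10) -> "QSurface":
        shape = (nbins,) * grid.ndim
        n_states = grid.n_zones * nbins**grid.ndim
        values = {zone: np.full(shape, 1.0 / n_states) for zone in grid.zones()}
        return cls(grid, nbins, values)

    def copy(self) -> "QSurface":
        return QSurface(self.grid, self.nbins, {z: v.copy() for z, v in self.values.items()})

    # -- geometry of bins ---------------------------------------------------

    def bin_edges(self, zone: tuple[int, ...]) -> list[np.ndarray]:
        lo, hi = self.grid.zone_box(zone)
        return [np.linspace(lo[d], hi[d], self.nbins + 1) for d in range(self.grid.ndim)]

    def bin_centers(self, zone: tuple[int, ...]) -> list[np.ndarray]:
        return [(e[:-1] + e[1:]) / 2 for e in self.bin_edges(zone)]

    def bin_volume(self, zone: tuple[int, ...]) -> float:
        lo, hi = self.grid.zone_box(zone)
        return float(np.prod((hi - lo) / self.nbins))

    def bin_index(self, zone: tuple[int, ...], lam: Iterable[float]) -> tuple[int, ...]:
        lo, hi = self.grid.zone_box(zone)
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        frac = (lam - lo) / (hi - lo)
        idx = np.clip(np.floor(frac * self.nbins).astype(int), 0, self.nbins - 1)
        return tuple(int(i) for i in idx)

    def value_at(self, zone: tuple[int, ...], lam: Iterable[float]) -> float:
        return float(self.values[zone][self.bin_index(zone, lam)])

    def zone_total(self, zone: tuple[int, ...]) -> float:
        return float(self.values[zone].sum())

    def conditional_density_at(self, zone: tuple[int, ...], lam: Iterable[float]) -> float:
        """Zone-conditional density at ``lam``: bin mass / (zone mass × bin
        volume).  This is the quantity compared between candidate zones when
        an inter-zone transition is attempted."""
        total = self.zone_total(zone)
        if total <= 0:
            return 0.0
        return self.value_at(zone, lam) / (total * self.bin_volume(zone))

    def density_at(self, lam: Iterable[float]) -> float:
        """Estimated canonical density at a physical RC point: the mean of
        ``value / bin volume`` over all zones covering the point (after
        stitching, covering zones agree up to sampling noise, so the mean
        only reduces noise).  Points marginally outside coverage clamp."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        lo = np.array([ax.coverage[0] for ax in self.grid.axes])
        hi = np.array([ax.coverage[1] for ax in self.grid.axes])
        lam = np.clip(lam, lo, hi)
        zones = self.grid.membership(lam)
        vals = [self.values[z][self.bin_index(z, lam)] / self.bin_volume(z) for z in zones]
        return float(np.mean(vals))

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def normalized(self) -> "QSurface":
        total = self.total
        if total <= 0:
            raise ValueError("cannot normalize an all-zero surface")
        return QSurface(self.grid, self.nbins, {z: v / total for z, v in self.values.items()})

    # -- overlap bookkeeping ------------------------------------------------

    def overlap_bin_masks(
        self, zone_a: tuple[int, ...], zone_b: tuple[int, ...]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (one per zone) of the bins whose centers fall inside
        the overlap box shared by two neighboring zones."""
        lo_a, hi_a = self.grid.zone_box(zone_a)
        lo_b, hi_b = self.grid.zone_box(zone_b)
        lo = np.maximum(lo_a, lo_b)
        hi = np.minimum(hi_a, hi_b)
        if np.any(lo >= hi):
            raise ValueError(f"zones {zone_a} and {zone_b} do not overlap")
        masks = []
        for zone in (zone_a, zone_b):
            centers = self.bin_centers(zone)
            axis_masks = [(c >= l) & (c <= h) for c, l, h in zip(centers, lo, hi)]
            mask = axis_masks[0]
            for m in axis_masks[1:]:
                mask = np.multiply.outer(mask, m)
            masks.append(mask)
        return masks[0], masks[1]

    def overlap_weights(
        self, zone: tuple[int, ...], other: tuple[int, ...]
    ) -> np.ndarray:
        """Fraction of each of ``zone``'s bins lying inside the overlap box
        shared with ``other`` (exact, so misaligned bin grids on the two
        sides of an overlap do not bias comparisons)."""
        lo_a, hi_a = self.grid.zone_box(zone)
        lo_b, hi_b = self.grid.zone_box(other)
        lo = np.maximum(lo_a, lo_b)
        hi = np.minimum(hi_a, hi_b)
        if np.any(lo >= hi):
            raise ValueError(f"zones {zone} and {other} do not overlap")
        axis_fracs = []
        for d, edges in enumerate(self.bin_edges(zone)):
            left = np.maximum(edges[:-1], lo[d])
            right = np.minimum(edges[1:], hi[d])
            axis_fracs.append(np.clip(right - left, 0.0, None) / np.diff(edges))
        w = axis_fracs[0]
        for f in axis_fracs[1:]:
            w = np.multiply.outer(w, f)
        return w

    def overlap_mean_density(self, zone: tuple[int, ...], mask: np.ndarray) -> float:
        if not mask.any():
            return np.nan
        return float(self.values[zone][mask].mean() / self.bin_volume(zone))

    # -- serialization ------------------------------------------------------

    def to_tsv(self, target: str | Path) -> None:
        rows = []
        for zone in self.grid.zones():
            centers = self.bin_centers(zone)
            for b in itertools.product(*(range(self.nbins) for _ in range(self.grid.ndim))):
                rows.append(
                    {
                        "zone": ",".join(map(str, zone)),
                        "bin": ",".join(map(str, b)),
                        **{
                            f"lambda_{ax.label}": centers[d][b[d]]
                            for d, ax in enumerate(self.grid.axes)
                        },
                        "value": self.values[zone][b],
                    }
                )
        pd.DataFrame(rows).to_csv(target, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, source: str | Path, grid: ZoneGrid) -> "QSurface":
        df = pd.read_csv(source, sep="\t", dtype={"zone": str, "bin": str})
        nbins = df["bin"].map(lambda s: int(str(s).split(",")[0])).max() + 1
        shape = (nbins,) * grid.ndim
        values = {zone: np.zeros(shape) for zone in grid.zones()}
        for _, row in df.iterrows():
            zone = tuple(int(t) for t in str(row["zone"]).split(","))
            b = tuple(int(t) for t in str(row["bin"]).split(","))
            values[zone][b] = float(row["value"])
        return cls(grid, int(nbins), values)


@dataclass
class ConvergenceReport:
    """Per-zone convergence diagnostic for one iteration."""

    iteration: int
    e_local: dict[tuple[int, ...], float]
    threshold: float = E_LOCAL_THRESHOLD

    @property
    def converged_zones(self) -> int:
        return sum(1 for v in self.e_local.values() if v < self.threshold)

    @property
    def all_converged(self) -> bool:
        return self.converged_zones == len(self.e_local)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": self.iteration,
                "zone": ",".join(map(str, z)),
                "e_local": v,
                "converged": v < self.threshold,
            }
            for z, v in sorted(self.e_local.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Histogram collection


def zone_bin_histograms(
    snapshots: Sequence, q: QSurface
) -> dict[tuple[int, ...], np.ndarray]:
    """Count snapshots into each zone's intra-zone bins (binning taken from
    ``q``).

    Snapshots whose RC value lies outside their zone's box — soft-restraint
    tail excursions — are discarded rather than clipped into the boundary
    bins: clipping would systematically inflate every zone's edge bins by
    the wall-tail mass and distort both the within-zone shape and the
    overlap stitching."""
    hists = {zone: np.zeros((q.nbins,) * q.grid.ndim) for zone in q.grid.zones()}
    for snap in snapshots:
        zone = tuple(snap.zone)
        if q.grid.contains(zone, snap.lam):
            hists[zone][q.bin_index(zone, snap.lam)] += 1
    return hists


# ---------------------------------------------------------------------------
# Density update


def update_q(
    q_prev: QSurface, histograms: Mapping[tuple[int, ...], np.ndarray]
) -> QSurface:
    """One density-update step from per-zone RC histograms.

    Within each zone, the new unnormalized density is the previous one
    multiplied by the observed/expected count ratio per bin, where the
    expected counts distribute the zone's total according to the previous
    density.  Empty observed bins receive an add-one pseudo-count so the
    correction stays finite.  Because each zone's scale is arbitrary, zones
    are then stitched over the grid by matching mean densities on shared
    overlap bins — a count-weighted least-squares solve over every
    overlapping zone pair, so that redundant overlaps suppress the scale
    drift a sequential chain would accumulate — and the result is
    renormalized.  A zone with zero total counts keeps its previous values.
    """
    grid = q_prev.grid
    new_values: dict[tuple[int, ...], np.ndarray] = {}
    counts: dict[tuple[int, ...], np.ndarray] = {}
    for zone in grid.zones():
        obs = np.asarray(histograms.get(zone, np.zeros_like(q_prev.values[zone])), dtype=float)
        total = obs.sum()
        prev = q_prev.values[zone]
        counts[zone] = obs
        if total <= 0 or prev.sum() <= 0:
            log.info("zone %s has no counts; carrying previous density through", zone)
            new_values[zone] = prev.copy()
            continue
        obs = np.where(obs == 0, 1.0, obs)  # add-one smoothing on empty bins
        expected = total * prev / prev.sum()
        new_values[zone] = prev * (obs / expected)
    _stitch_zones(q_prev, new_values, counts)
    return QSurface(grid, q_prev.nbins, new_values).normalized()


def overlapping_zone_pairs(grid: ZoneGrid) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered zone pairs whose boxes share a finite-volume overlap."""
    zones = list(grid.zones())
    pairs = []
    for i, za in enumerate(zones):
        lo_a, hi_a = grid.zone_box(za)
        for zb in zones[i + 1 :]:
            lo_b, hi_b = grid.zone_box(zb)
            if np.all(np.maximum(lo_a, lo_b) < np.minimum(hi_a, hi_b)):
                pairs.append((za, zb))
    return pairs


def _stitch_zones(
    q: QSurface,
    values: dict[tuple[int, ...], np.ndarray],
    counts: Mapping[tuple[int, ...], np.ndarray] | None = None,
) -> None:
    """Reconcile per-zone scales in place via weighted least squares.

    Each overlapping pair contributes one observation of the difference of
    the zones' log scales (the log-ratio of their mean densities over the
    shared overlap bins), weighted by the effective number of counts both
    zones collected there.  The normal equations form a graph Laplacian;
    the gauge is fixed by the first zone.
    """
    grid = q.grid
    zones = list(grid.zones())
    pos = {z: i for i, z in enumerate(zones)}
    n = len(zones)
    lap = np.zeros((n, n))
    rhs = np.zeros(n)
    for za, zb in overlapping_zone_pairs(grid):
        wa = q.overlap_weights(za, zb)
        wb = q.overlap_weights(zb, za)
        # mean density over the exact overlap box on each side
        vol = float((wa.sum() * q.bin_volume(za)))
        if vol <= 0:
            continue
        da = float((values[za] * wa).sum()) / vol
        db = float((values[zb] * wb).sum()) / (wb.sum() * q.bin_volume(zb))
        if not (da > 0 and db > 0):
            continue
        if counts is not None:
            na = float((counts[za] * wa).sum())
            nb = float((counts[zb] * wb).sum())
            if na <= 0 or nb <= 0:
                continue
            weight = 1.0 / (1.0 / na + 1.0 / nb)
        else:
            weight = 1.0
        # want s_a - s_b = log(db) - log(da)
        d = np.log(db) - np.log(da)
        i, j = pos[za], pos[zb]
        lap[i, i] += weight
        lap[j, j] += weight
        lap[i, j] -= weight
        lap[j, i] -= weight
        rhs[i] += weight * d
        rhs[j] -= weight * d
    # zones without any usable link keep their scale
    for i in range(n):
        if lap[i, i] == 0.0:
            lap[i, i] = 1.0
            rhs[i] = 0.0
    # gauge: pin the first zone's scale
    lap[0, :] = 0.0
    lap[0, 0] = 1.0
    rhs[0] = 0.0
    try:
        scales = np.linalg.solve(lap, rhs)
    except np.linalg.LinAlgError:
        log.warning("stitching system singular (disconnected zones); scales left as-is")
        return
    for z in zones:
        values[z] = values[z] * np.exp(scales[pos[z]])


# ---------------------------------------------------------------------------
# Genetic-algorithm refinement


def _log_floor(q: QSurface) -> float:
    positive = np.concatenate([v[v > 0].ravel() for v in q.values.values()])
    if positive.size == 0:
        raise ValueError("surface has no positive values")
    return float(positive.min()) / 2.0


def _flatten(q: QSurface, floor: float) -> tuple[list[tuple[int, ...]], np.ndarray, list[slice]]:
    zones = list(q.grid.zones())
    chunks, slices, start = [], [], 0
    for zone in zones:
        v = np.log(np.maximum(q.values[zone], floor)).ravel()
        chunks.append(v)
        slices.append(slice(start, start + v.size))
        start += v.size
    return zones, np.concatenate(chunks), slices


def _ga_fitness(
    vec: np.ndarray,
    ref: np.ndarray,
    pairs: list[tuple[slice, slice, np.ndarray, np.ndarray, float, float]],
    shape: tuple[int, ...],
    slices: list[slice],
    fidelity_weight: float,
    mismatch_weight: float,
    roughness_weight: float,
) -> float:
    mismatch = 0.0
    for sl_a, sl_b, mask_a, mask_b, lva, lvb in pairs:
        mean_a = vec[sl_a].reshape(shape)[mask_a].mean() - lva
        mean_b = vec[sl_b].reshape(shape)[mask_b].mean() - lvb
        mismatch += (mean_a - mean_b) ** 2
    roughness = 0.0
    for sl in slices:
        zone_vals = vec[sl].reshape(shape)
        for axis in range(zone_vals.ndim):
            d2 = np.diff(zone_vals, n=2, axis=axis)
            roughness += float(np.sum(d2**2))
    fidelity = float(np.sum((vec - ref) ** 2))
    value = -(
        mismatch_weight * mismatch
        + roughness_weight * roughness
        + fidelity_weight * fidelity
    )
    return value if np.isfinite(value) else -np.inf


def ga_refine(
    q: QSurface,
    population: int = 32,
    generations: int = 100,
    tournament: int = 3,
    crossover_rate: float = 0.7,
    mutation_sigma: float = 0.02,
    zone_shift_sigma: float = 0.5,
    fidelity_weight: float = 1.0,
    mismatch_weight: float = 50.0,
    roughness_weight: float = 0.001,
    rng: np.random.Generator | int | None = 0,
) -> QSurface:
    """Smooth a stitched surface with a genetic algorithm in log space.

    Candidates are log-density vectors.  Fitness penalizes (i) squared
    mismatch of mean log-density over each neighboring pair's shared overlap
    bins, (ii) squared second differences along each axis within zones
    (roughness), and (iii) squared deviation from the input log values
    (fidelity) — the anchor that keeps the optimum near the data instead of
    drifting to a featureless surface.  Selection is tournament; crossover
    exchanges whole zones between parents; mutation is additive Gaussian on
    log values at two scales (per-bin jitter and a common per-zone shift,
    which is what lets the GA repair a mis-stitched zone quickly).  The best
    candidate is carried over unchanged each generation, so fitness never
    decreases; if no candidate beats the input, the input is returned.
    """
    rng = np.random.default_rng(rng)
    floor = _log_floor(q)
    zones, base, slices = _flatten(q, floor)
    shape = (q.nbins,) * q.grid.ndim
    zone_pos = {z: i for i, z in enumerate(zones)}
    pairs = []
    seen = set()
    for zone in zones:
        for nb in q.grid.neighbors(zone):
            key = tuple(sorted((zone, nb)))
            if key in seen:
                continue
            seen.add(key)
            mask_a, mask_b = q.overlap_bin_masks(zone, nb)
            lva = np.log(q.bin_volume(zone))
            lvb = np.log(q.bin_volume(nb))
            pairs.append((slices[zone_pos[zone]], slices[zone_pos[nb]], mask_a, mask_b, lva, lvb))

    def fitness(vec: np.ndarray) -> float:
        return _ga_fitness(
            vec, base, pairs, shape, slices, fidelity_weight, mismatch_weight, roughness_weight
        )

    pop = [base.copy()]
    for _ in range(population - 1):
        pop.append(base + rng.normal(0.0, mutation_sigma, size=base.size))
    scores = np.array([fitness(c) for c in pop])

    for _ in range(generations):
        best_idx = int(np.argmax(scores))
        new_pop = [pop[best_idx].copy()]  # elitism
        while len(new_pop) < population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, population, size=tournament)
                parents.append(pop[contenders[np.argmax(scores[contenders])]])
            if rng.random() < crossover_rate:
                child = parents[0].copy()
                for sl in slices:
                    if rng.random() < 0.5:
                        child[sl] = parents[1][sl]
            else:
                child = parents[rng.integers(2)].copy()
            child = child + rng.normal(0.0, mutation_sigma, size=child.size)
            if rng.random() < 0.5:
                sl = slices[rng.integers(len(slices))]
                child[sl] += rng.normal(0.0, zone_shift_sigma)
            new_pop.append(child)
        pop = new_pop
        scores = np.array([fitness(c) for c in pop])

    best = pop[int(np.argmax(scores))]
    if fitness(best) <= fitness(base):
        best = base
    values = {
        zone: np.exp(best[slices[i]]).reshape(shape) for i, zone in enumerate(zones)
    }
    return QSurface(q.grid, q.nbins, values).normalized()


# ---------------------------------------------------------------------------
# Convergence diagnostic


def e_local(
    q_curr: QSurface,
    q_prev: QSurface,
    iteration: int = 0,
    threshold: float = E_LOCAL_THRESHOLD,
    mode: str = "iteration",
) -> ConvergenceReport:
    """Per-zone convergence diagnostic.

    ``mode="iteration"`` (default): mean absolute log-ratio of the current to
    the previous surface over the zone's bins, comparing raw values (no
    renormalization).  Bins where both surfaces are zero are skipped;
    one-sided zeros are floored at half the smallest positive value so the
    log stays finite.  ``mode="overlap"``: the alternative reading of the
    diagnostic — mean absolute mismatch of log density across each zone's
    overlaps with its neighbors on the *current* surface only.
    """
    if q_curr.grid is not q_prev.grid and q_curr.grid != q_prev.grid:
        raise ValueError("surfaces must share the same zone grid")
    if q_curr.nbins != q_prev.nbins:
        raise ValueError("surfaces must share the same intra-zone binning")
    values: dict[tuple[int, ...], float] = {}
    if mode == "iteration":
        floor = min(_log_floor(q_curr), _log_floor(q_prev))
        for zone in q_curr.grid.zones():
            a = q_curr.values[zone].ravel()
            b = q_prev.values[zone].ravel()
            keep = ~((a == 0) & (b == 0))
            if not keep.any():
                values[zone] = 0.0
                continue
            la = np.log(np.maximum(a[keep], floor))
            lb = np.log(np.maximum(b[keep], floor))
            values[zone] = float(np.mean(np.abs(la - lb)))
    elif mode == "overlap":
        for zone in q_curr.grid.zones():
            diffs = []
            for nb in q_curr.grid.neighbors(zone):
                mask_a, mask_b = q_curr.overlap_bin_masks(zone, nb)
                da = q_curr.overlap_mean_density(zone, mask_a)
                db = q_curr.overlap_mean_density(nb, mask_b)
                if da > 0 and db > 0:
                    diffs.append(abs(np.log(da) - np.log(db)))
            values[zone] = float(np.mean(diffs)) if diffs else 0.0
    else:
        raise ValueError(f"unknown e_local mode {mode!r}")
    return ConvergenceReport(iteration=iteration, e_local=values, threshold=threshold)


# ---------------------------------------------------------------------------
# Snapshot reweighting


def physical_bin_edges(q: QSurface) -> list[np.ndarray]:
    """A zone-independent binning of RC space for marginals: per axis, bins
    of the smallest intra-zone bin width spanning the axis coverage."""
    edges = []
    for ax in q.grid.axes:
        widths = [(hi - lo) / q.nbins for lo, hi in ax.intervals]
        width = min(widths)
        lo, hi = ax.coverage
        n = max(1, int(round((hi - lo) / width)))
        edges.append(np.linspace(lo, hi, n + 1))
    return edges


def sampled_lambda_histogram(
    snapshots: Sequence, edges: Sequence[np.ndarray]
) -> np.ndarray:
    """Snapshot counts on a physical RC binning (all axes)."""
    lams = np.stack([np.atleast_1d(np.asarray(s.lam, dtype=float)) for s in snapshots])
    hist, _ = np.histogramdd(lams, bins=[np.asarray(e) for e in edges])
    return hist


def snapshot_weights(
    snapshots: Sequence,
    q: QSurface,
    sampled_marginal: np.ndarray | None = None,
    edges: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Canonical weights for stored snapshots.

    Each snapshot's weight is proportional to the estimated canonical
    density at its RC value divided by the density actually sampled there
    (the λ histogram over all snapshots, on a zone-independent physical
    binning), which removes the flattening bias of the zone scheme.
    Weights are normalized to sum to 1; a warning is logged where the
    canonical estimate is zero although samples exist.
    """
    if len(snapshots) == 0:
        raise ValueError("no snapshots to weight")
    if edges is None:
        edges = physical_bin_edges(q)
    if sampled_marginal is None:
        sampled_marginal = sampled_lambda_histogram(snapshots, edges)
    n_total = float(sampled_marginal.sum())
    bin_vol = float(np.prod([e[1] - e[0] for e in edges]))
    lams = np.stack([np.atleast_1d(np.asarray(s.lam, dtype=float)) for s in snapshots])
    idx = []
    for d, e in enumerate(edges):
        i = np.clip(np.searchsorted(e, lams[:, d], side="right") - 1, 0, len(e) - 2)
        idx.append(i)
    counts = sampled_marginal[tuple(idx)]
    if np.any(counts <= 0):
        raise ValueError("snapshot falls in a bin with zero sampled marginal")
    dens = np.array([q.density_at(lam) for lam in lams])
    if np.any(dens <= 0):
        log.warning("canonical estimate is zero where samples exist; weights set to 0")
    weights = dens / (counts / (n_total * bin_vol))
    total = weights.sum()
    if total <= 0:
        raise ValueError("all snapshot weights vanished")
    return weights / total
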