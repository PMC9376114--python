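"""Reaction coordinates and the overlapping zone decomposition of RC space.

A reaction coordinate (RC) is the distance between the centroids of two
named atom groups.  Each RC axis is divided into ordered 1-D intervals
("zones") that overlap pairwise; the Cartesian product over the axes forms
the multi-dimensional zone grid.  The overlap regions are what makes
inter-zone transitions possible in the sampler, so consecutive intervals
are required to overlap.

Conventions
-----------
* Overlap-aware *membership* uses closed containment on every axis and can
  therefore return several zones for a point in an overlap region.
* Deterministic *assignment* (for histograms) uses the half-open rule
  [lower, upper) — the last interval closed at both ends — and, where the
  half-open rule still leaves a choice inside an overlap, picks the
  highest-index interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from flycast.structure_io import AtomGroup, Structure, centroid

__all__ = ["RCDef", "ZoneAxis", "ZoneGrid", "compute_rc", "OutOfRangeError"]


class OutOfRangeError(ValueError):
    """A point lies outside the coverage of the zone grid."""


@dataclass(frozen=True)
class RCDef:
    """A reaction coordinate: centroid–centroid distance of two atom groups."""

    label: str
    group_a: AtomGroup
    group_b: AtomGroup

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("RC groups must differ")


def compute_rc(structure: Structure, rc: RCDef) -> float:
    """Euclidean distance between the centroids of the RC's two groups (Å)."""
    return float(np.linalg.norm(centroid(structure, rc.group_a) - centroid(structure, rc.group_b)))


@dataclass(frozen=True)
class ZoneAxis:
    """One RC axis divided into ordered, pairwise overlapping intervals."""

    label: str
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) == 0:
            raise ValueError("axis needs at least one interval")
        for lo, hi in iv:
            if not lo < hi:
                raise ValueError(f"interval ({lo}, {hi}) must have lower < upper")
        for (lo0, hi0), (lo1, hi1) in zip(iv, iv[1:]):
            if not lo0 < lo1:
                raise ValueError("intervals must be ordered by lower edge")
            if not lo1 < hi0:
                raise ValueError("consecutive intervals must overlap")
            if not hi0 < hi1:
                raise ValueError("intervals must be ordered by upper edge")

    @classmethod
    def uniform(
        cls, label: str, lower: float, upper: float, count: int, overlap_fraction: float = 0.5
    ) -> "ZoneAxis":
        """Equal-width intervals covering [lower, upper] with the given pairwise
        overlap fraction (overlap width / interval width).

        Coverage bounds are mandatory arguments; no silent defaults.
        """
        if not 0 < overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in (0, 1)")
        if count < 1:
            raise ValueError("count must be >= 1")
        if not lower < upper:
            raise ValueError("need lower < upper")
        if count == 1:
            return cls(label, ((float(lower), float(upper)),))
        width = (upper - lower) / (1.0 + (count - 1) * (1.0 - overlap_fraction))
        stride = width * (1.0 - overlap_fraction)
        intervals = []
        for i in range(count):
            lo = lower + i * stride
            hi = lo + width
            intervals.append((float(lo), float(hi)))
        # pin the last edge exactly to the requested bound
        intervals[-1] = (intervals[-1][0], float(upper))
        return cls(label, tuple(intervals))

    @property
    def n_zones(self) -> int:
        return len(self.intervals)

    @property
    def coverage(self) -> tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]

    def membership(self, x: float) -> tuple[int, ...]:
        """Indices of all intervals containing x (closed containment)."""
        hits = tuple(i for i, (lo, hi) in enumerate(self.intervals) if lo <= x <= hi)
        if not hits:
            raise OutOfRangeError(f"{x} is outside axis {self.label!r} coverage {self.coverage}")
        return hits

    def assign(self, x: float) -> int:
        """Deterministic single-interval assignment (half-open convention)."""
        hits = [
            i
            for i, (lo, hi) in enumerate(self.intervals)
            if (lo <= x < hi) or (i == self.n_zones - 1 and lo <= x <= hi)
        ]
        if not hits:
            raise OutOfRangeError(f"{x} is outside axis {self.label!r} coverage {self.coverage}")
        return hits[-1]


@dataclass(frozen=True)
class ZoneGrid:
    """Cartesian product of per-axis zone decompositions."""

    axes: tuple[ZoneAxis, ...]

    def __post_init__(self) -> None:
        if len(self.axes) < 1:
            raise ValueError("grid needs at least one axis")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(ax.n_zones for ax in self.axes)

    @property
    def n_zones(self) -> int:
        return int(np.prod(self.shape))

    def zones(self) -> Iterator[tuple[int, ...]]:
        return itertools.product(*(range(n) for n in self.shape))

    def _check(self, zone: tuple[int, ...]) -> None:
        if len(zone) != self.ndim or any(
            not 0 <= z < n for z, n in zip(zone, self.shape)
        ):
            raise IndexError(f"invalid zone index {zone} for grid of shape {self.shape}")

    def zone_box(self, zone: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the zone's box in RC space."""
        self._check(zone)
        lo = np.array([ax.intervals[z][0] for ax, z in zip(self.axes, zone)])
        hi = np.array([ax.intervals[z][1] for ax, z in zip(self.axes, zone)])
        return lo, hi

    @property
    def coverage(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([ax.coverage[0] for ax in self.axes])
        hi = np.array([ax.coverage[1] for ax in self.axes])
        return lo, hi

    def membership(self, lam: Iterable[float]) -> set[tuple[int, ...]]:
        """All zones whose box contains ``lam`` (closed containment per axis)."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        if lam.shape != (self.ndim,):
            raise ValueError(f"lambda must have {self.ndim} components")
        per_axis = [ax.membership(x) for ax, x in zip(self.axes, lam)]
        return set(itertools.product(*per_axis))

    def assign(self, lam: Iterable[float]) -> tuple[int, ...]:
        """Deterministic single-zone assignment (half-open convention per axis)."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        return tuple(ax.assign(x) for ax, x in zip(self.axes, lam))

    def contains(self, zone: tuple[int, ...], lam: Iterable[float], tol: float = 0.0) -> bool:
        lo, hi = self.zone_box(zone)
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        return bool(np.all(lam >= lo - tol) and np.all(lam <= hi + tol))

    def neighbors(self, zone: tuple[int, ...]) -> list[tuple[int, ...]]:
        """Zones differing by ±1 on exactly one axis."""
        self._check(zone)
        out = []
        for axis in range(self.ndim):
            for step in (-1, 1):
                cand = list(zone)
                cand[axis] += step
                if 0 <= cand[axis] < self.shape[axis]:
                    out.append(tuple(cand))
        return out

    # -- serialization ------------------------------------------------------

    def to_tsv(self, target: str | Path) -> None:
        rows = []
        for ax in self.axes:
            for i, (lo, hi) in enumerate(ax.intervals):
                rows.append({"axis": ax.label, "zone": i, "lower": lo, "upper": hi})
        pd.DataFrame(rows).to_csv(target, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, source: str | Path) -> "ZoneGrid":
        df = pd.read_csv(source, sep="\t")
        axes = []
        for label, sub in df.groupby("axis", sort=False):
            sub = sub.sort_values("zone")
            axes.append(
                ZoneAxis(str(label), tuple(zip(sub["lower"].astype(float), sub["upper"].astype(float))))
            )
        return cls(tuple(axes))
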