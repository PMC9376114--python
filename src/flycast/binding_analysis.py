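"""Weighted-ensemble statistics for ligand–receptor binding pathways.

All statistics are weighted averages over a snapshot ensemble carrying
canonical weights.  Before any spatial statistic is formed, every snapshot
is superposed onto the reference complex using the receptor-frame alignment
group (typically the transmembrane selection) — the ligand itself is never
fitted, so ligand RMSDs and displacements are measured in the receptor
frame.

The real-space statistics live on a grid of cubes (3 Å edge by default)
centered in the receptor frame: occupancy densities ρ (max-normalized so
contour levels like 0.5/0.1/0.01 are directly meaningful), contact-ratio
fields c̄ ∈ [0, 1], averaged orientation-vector fields v̄ with |v̄| ∈ [0, 1],
and scalar products SP ∈ [−1, 1] against the native-pose orientation.

The pathway statistics slice the ligand-centroid displacement axis
r_bb = |r_CM − r_CM^ref| into 5 Å shells Δ_k and report, per slice,
residue-contact free energies F(j) = −RT ln ρ_cnt(j), atom–residue contact
maps, and minimum-distance potentials of mean force.  Native-contact
formation is profiled in narrow r_bb windows (half-width 0.25 Å).

Empty cubes, slices and windows are flagged undefined, never imputed as
zero: the PMF of an unsampled bin is +∞, not a large finite number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from flycast.structure_io import (
    AtomGroup,
    NativeContactDef,
    OrientationAnchors,
    Structure,
    _is_hydrogen,
    read_pdb,
    write_pdb,
)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "WeightedEnsemble",
    "CubeGrid",
    "ScalarField",
    "VectorField",
    "SliceSet",
    "PMFProfile",
    "NativeContactProfile",
    "RMSDDistributions",
    "slice_assign",
    "density_field",
    "contact_ratio_field",
    "membrane_contact_field",
    "residue_contact_pmf",
    "atom_residue_contact",
    "min_distance_pmf",
    "orientation_field",
    "sp_field",
    "native_contact_profile",
    "rmsd_distributions",
    "neutral_fraction",
    "write_dx",
]

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal/(mol K)


def _rt(temperature: float) -> float:
    return GAS_CONSTANT_KCAL * temperature


# ---------------------------------------------------------------------------
# Ensemble container


@dataclass
class WeightedEnsemble:
    """Snapshots with canonical weights, sharing atom ordering with a
    reference structure.

    ``positions`` stacks all snapshot coordinates as ``(n_snapshots,
    n_atoms, 3)`` in Å.  Weights are normalized to sum to 1 on
    construction.  ``aligned`` records whether snapshots are already in the
    receptor frame of the reference.
    """

    reference: Structure
    positions: np.ndarray
    weights: np.ndarray
    align_group: AtomGroup
    aligned: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_snapshots, n_atoms, 3)")
        if self.positions.shape[1] != self.reference.n_atoms:
            raise ValueError("snapshots must share atom ordering with the reference")
        if self.weights.shape != (self.positions.shape[0],):
            raise ValueError("need one weight per snapshot")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must not all vanish")
        self.weights = self.weights / total

    @property
    def n_snapshots(self) -> int:
        return self.positions.shape[0]

    def indices(self, group: AtomGroup, heavy_only: bool = False) -> np.ndarray:
        g = replace(group, heavy_only=group.heavy_only or heavy_only)
        return self.reference.group_indices(g)

    def snapshot(self, i: int) -> Structure:
        return self.reference.with_positions(self.positions[i])

    def ensure_aligned(self) -> "WeightedEnsemble":
        """Superpose every snapshot onto the reference by the alignment
        group (batched Kabsch, proper rotations only)."""
        if self.aligned:
            return self
        idx = self.indices(self.align_group)
        ref = self.reference.positions[idx]
        ref_c = ref.mean(axis=0)
        ref0 = ref - ref_c
        mob = self.positions[:, idx, :]
        mob_c = mob.mean(axis=1, keepdims=True)
        mob0 = mob - mob_c
        h = np.einsum("sni,nj->sij", mob0, ref0)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(np.einsum("sij,sjk->sik", u, vt)))
        u[:, :, -1] *= d[:, None]
        rot = np.einsum("sij,sjk->ski", u, vt)  # transpose of u@vt per snapshot
        new_pos = (
            np.einsum("sij,snj->sni", rot, self.positions - mob_c) + ref_c
        )
        return replace(self, positions=new_pos, aligned=True)

    def centroids(self, group: AtomGroup) -> np.ndarray:
        """Per-snapshot centroid of a group, shape (n_snapshots, 3)."""
        idx = self.indices(group)
        return self.positions[:, idx, :].mean(axis=1)

    def r_bb(self, ligand: AtomGroup) -> np.ndarray:
        """Ligand-centroid displacement from the reference pose (aligned frame)."""
        ens = self.ensure_aligned()
        ref_c = self.reference.coords(ligand).mean(axis=0)
        return np.linalg.norm(ens.centroids(ligand) - ref_c, axis=1)

    def min_group_distance(
        self, group_a: AtomGroup, group_b: AtomGroup, chunk: int = 4096
    ) -> np.ndarray:
        """Per-snapshot minimum heavy-atom distance between two groups."""
        ia = self.indices(group_a, heavy_only=True)
        ib = self.indices(group_b, heavy_only=True)
        out = np.empty(self.n_snapshots)
        for s0 in range(0, self.n_snapshots, chunk):
            block = self.positions[s0 : s0 + chunk]
            d = block[:, ia, None, :] - block[:, None, ib, :]
            out[s0 : s0 + chunk] = np.sqrt((d**2).sum(-1)).min(axis=(1, 2))
        return out

    def per_atom_min_distance(
        self, atoms: AtomGroup, group: AtomGroup, chunk: int = 2048
    ) -> np.ndarray:
        """Minimum distance from each heavy atom of ``atoms`` to ``group``,
        per snapshot, shape (n_snapshots, n_atoms)."""
        ia = self.indices(atoms, heavy_only=True)
        ib = self.indices(group, heavy_only=True)
        out = np.empty((self.n_snapshots, len(ia)))
        for s0 in range(0, self.n_snapshots, chunk):
            block = self.positions[s0 : s0 + chunk]
            d = block[:, ia, None, :] - block[:, None, ib, :]
            out[s0 : s0 + chunk] = np.sqrt((d**2).sum(-1)).min(axis=2)
        return out

    # -- file I/O -----------------------------------------------------------

    def to_files(self, table: str | Path, structures: str | Path) -> None:
        """Write the weighted-ensemble table (TSV) and the snapshot
        coordinates as a multi-model PDB."""
        rows = [
            {
                "snapshot": i,
                "weight": f"{self.weights[i]:.12g}",
                "structure": str(structures),
                "model": i + 1,
            }
            for i in range(self.n_snapshots)
        ]
        pd.DataFrame(rows).to_csv(table, sep="\t", index=False)
        models = [
            replace(self.reference, positions=self.positions[i], model_id=i + 1, _lookup=None)
            for i in range(self.n_snapshots)
        ]
        write_pdb(models, structures)

    @classmethod
    def from_files(
        cls,
        table: str | Path,
        reference: Structure,
        align_group: AtomGroup,
        structures: str | Path | None = None,
    ) -> "WeightedEnsemble":
        df = pd.read_csv(table, sep="\t")
        path = structures if structures is not None else df["structure"].iloc[0]
        models = read_pdb(path)
        by_id = {m.model_id: m for m in models}
        positions = np.stack([by_id[int(m)].positions for m in df["model"]])
        return cls(
            reference=reference,
            positions=positions,
            weights=df["weight"].to_numpy(dtype=float),
            align_group=align_group,
        )


# ---------------------------------------------------------------------------
# Cube grid and fields


@dataclass(frozen=True)
class CubeGrid:
    """Regular grid of cubes in the receptor frame (edge in Å)."""

    origin: tuple[float, float, float]
    edge: float = 3.0
    shape: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("cube edge must be positive")
        if min(self.shape) < 1:
            raise ValueError("grid shape must be positive")

    @classmethod
    def from_points(cls, points: np.ndarray, edge: float = 3.0, pad: float = 1.0) -> "CubeGrid":
        points = np.asarray(points, dtype=float)
        lo = points.min(axis=0) - pad
        hi = points.max(axis=0) + pad
        shape = tuple(int(np.ceil((h - l) / edge)) for l, h in zip(lo, hi))
        return cls(origin=tuple(float(x) for x in lo), edge=float(edge), shape=shape)

    def index_of(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((points - np.asarray(self.origin)) / self.edge).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise ValueError("point outside the cube grid")
        return idx

    def centers(self) -> np.ndarray:
        axes = [
            self.origin[d] + (np.arange(self.shape[d]) + 0.5) * self.edge for d in range(3)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)


@dataclass
class ScalarField:
    """One scalar per cube plus an occupancy count; unoccupied cubes are
    masked undefined."""

    grid: CubeGrid
    values: np.ndarray
    occupancy: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.values, self.occupancy, self.defined):
            if arr.shape != self.grid.shape:
                raise ValueError("field arrays must match the grid shape")


@dataclass
class VectorField:
    grid: CubeGrid
    vectors: np.ndarray  # (nx, ny, nz, 3)
    occupancy: np.ndarray
    defined: np.ndarray

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


def _bin_points(
    points: np.ndarray, weights: np.ndarray, grid: CubeGrid | None, edge: float, pad: float
) -> tuple[CubeGrid, np.ndarray, np.ndarray, np.ndarray]:
    if grid is None:
        grid = CubeGrid.from_points(points, edge=edge, pad=pad)
    idx = grid.index_of(points)
    mass = np.zeros(grid.shape)
    count = np.zeros(grid.shape)
    np.add.at(mass, tuple(idx.T), weights)
    np.add.at(count, tuple(idx.T), 1)
    return grid, idx, mass, count


def density_field(
    ensemble: WeightedEnsemble,
    target: AtomGroup,
    grid: CubeGrid | None = None,
    edge: float = 3.0,
    normalize: str = "max",
) -> ScalarField:
    """Spatial occupancy density of a target group's centroid on the cube
    grid: the weighted probability of finding the centroid in each cube.

    ``normalize="max"`` (default) scales the peak cube to 1 so contour
    levels like 0.5 / 0.1 / 0.01 are directly meaningful;
    ``normalize="mass"`` returns raw probability mass per cube.
    """
    ens = ensemble.ensure_aligned()
    pts = ens.centroids(target)
    grid, _, mass, count = _bin_points(pts, ens.weights, grid, edge, pad=1.0)
    if normalize == "max":
        values = mass / mass.max() if mass.max() > 0 else mass
    elif normalize == "mass":
        values = mass
    else:
        raise ValueError("normalize must be 'max' or 'mass'")
    return ScalarField(grid=grid, values=values, occupancy=count, defined=count > 0)


def contact_ratio_field(
    ensemble: WeightedEnsemble,
    ligand: AtomGroup,
    partner: AtomGroup,
    cutoff: float = 5.0,
    grid: CubeGrid | None = None,
    edge: float = 3.0,
) -> ScalarField:
    """Per-cube ratio of snapshots (weighted) in which the ligand contacts
    the partner group, indexed by the cube holding the ligand centroid.

    A contact is a minimum heavy-atom distance below ``cutoff``.  Values lie
    in [0, 1]; cubes without occupancy are flagged undefined.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ens = ensemble.ensure_aligned()
    pts = ens.centroids(ligand)
    indicator = (ens.min_group_distance(ligand, partner) < cutoff).astype(float)
    grid, idx, mass, count = _bin_points(pts, ens.weights, grid, edge, pad=1.0)
    hit = np.zeros(grid.shape)
    np.add.at(hit, tuple(idx.T), ens.weights * indicator)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(mass > 0, hit / np.where(mass > 0, mass, 1.0), 0.0)
    return ScalarField(grid=grid, values=values, occupancy=count, defined=mass > 0)


def membrane_contact_field(
    ensemble: WeightedEnsemble,
    ligand: AtomGroup,
    z_level: float,
    cutoff: float = 5.0,
    grid: CubeGrid | None = None,
    edge: float = 3.0,
) -> ScalarField:
    """Ligand–membrane contact ratio per cube, with the membrane modeled as
    a planar exclusion slab below ``z_level`` (receptor frame, Å).

    A snapshot is in contact when any ligand heavy atom comes within
    ``cutoff`` of the slab surface, i.e. its z coordinate drops below
    ``z_level + cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ens = ensemble.ensure_aligned()
    idx = ens.indices(ligand, heavy_only=True)
    min_z = ens.positions[:, idx, 2].min(axis=1)
    indicator = (min_z < z_level + cutoff).astype(float)
    pts = ens.centroids(ligand)
    grid, gidx, mass, count = _bin_points(pts, ens.weights, grid, edge, pad=1.0)
    hit = np.zeros(grid.shape)
    np.add.at(hit, tuple(gidx.T), ens.weights * indicator)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(mass > 0, hit / np.where(mass > 0, mass, 1.0), 0.0)
    return ScalarField(grid=grid, values=values, occupancy=count, defined=mass > 0)


# ---------------------------------------------------------------------------
# r_bb slices


@dataclass(frozen=True)
class SliceSet:
    """Contiguous half-open shells of the r_bb axis: slice k covers
    [thickness·(k−1), thickness·k), k = 1..count."""

    thickness: float = 5.0
    count: int = 13

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.count < 1:
            raise ValueError("slice thickness and count must be positive")

    @property
    def upper_bound(self) -> float:
        return self.thickness * self.count

    def bounds(self, k: int) -> tuple[float, float]:
        if not 1 <= k <= self.count:
            raise ValueError(f"slice index {k} out of range 1..{self.count}")
        return self.thickness * (k - 1), self.thickness * k


def slice_assign(r_bb: float, slices: SliceSet | None = None) -> int:
    """1-based slice index of an r_bb value (half-open convention: an exact
    boundary multiple belongs to the upper slice)."""
    slices = slices or SliceSet()
    if r_bb < 0 or r_bb >= slices.upper_bound:
        raise ValueError(
            f"r_bb = {r_bb} outside slice coverage [0, {slices.upper_bound})"
        )
    return int(r_bb // slices.thickness) + 1


def _slice_indices(r_bb: np.ndarray, slices: SliceSet) -> np.ndarray:
    if np.any(r_bb < 0) or np.any(r_bb >= slices.upper_bound):
        raise ValueError("r_bb values outside the slice coverage")
    return (r_bb // slices.thickness).astype(int)  # 0-based


# ---------------------------------------------------------------------------
# PMF profiles


@dataclass
class PMFProfile:
    """A potential of mean force −RT ln p over some discrete support.

    ``values`` holds F in kcal/mol where ``defined`` is True; undefined
    cells (zero probability or empty slice) are flagged, not zero-filled.
    """

    values: np.ndarray
    probabilities: np.ndarray
    defined: np.ndarray
    rt: float
    axis_labels: tuple = ()
    meta: dict = field(default_factory=dict)


def residue_contact_pmf(
    ensemble: WeightedEnsemble,
    ligand: AtomGroup,
    tail_residues: Sequence[AtomGroup],
    slices: SliceSet | None = None,
    cutoff: float = 5.0,
    temperature: float = 300.0,
) -> PMFProfile:
    """Residue-based contact free energy F(j) = −RT ln ρ_cnt(j) per slice.

    ρ_cnt is the weighted fraction of the slice's snapshots in which residue
    j's heavy atoms contact the ligand within ``cutoff``.  Cells with ρ = 0
    and entirely empty slices are flagged undefined (rendered as the
    unsampled / > 5 kcal/mol class downstream).
    """
    slices = slices or SliceSet()
    ens = ensemble.ensure_aligned()
    r = ens.r_bb(ligand)
    sk = _slice_indices(r, slices)
    n_res = len(tail_residues)
    rho = np.zeros((slices.count, n_res))
    slice_mass = np.zeros(slices.count)
    np.add.at(slice_mass, sk, ens.weights)
    for j, res in enumerate(tail_residues):
        contact = (ens.min_group_distance(ligand, res) < cutoff).astype(float)
        hit = np.zeros(slices.count)
        np.add.at(hit, sk, ens.weights * contact)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho[:, j] = np.where(slice_mass > 0, hit / np.where(slice_mass > 0, slice_mass, 1), 0.0)
    defined = (rho > 0) & (slice_mass[:, None] > 0)
    rt = _rt(temperature)
    values = np.where(defined, -rt * np.log(np.where(defined, rho, 1.0)), np.nan)
    return PMFProfile(
        values=values,
        probabilities=rho,
        defined=defined,
        rt=rt,
        axis_labels=("slice", "residue"),
        meta={"residues": [g.label for g in tail_residues], "slices": slices},
    )


def atom_residue_contact(
    ensemble: WeightedEnsemble,
    ligand: AtomGroup,
    tail_residues: Sequence[AtomGroup],
    slices: SliceSet | None = None,
    cutoff: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Atom–residue contact ratio θ(i, j) per slice, max-normalized per panel.

    Returns ``(theta, defined)`` with shape (n_slices, n_ligand_heavy_atoms,
    n_residues); each slice's matrix is divided by its own maximum so the
    atom specificity within the slice stands out.  Empty slices are flagged.
    """
    slices = slices or SliceSet()
    ens = ensemble.ensure_aligned()
    r = ens.r_bb(ligand)
    sk = _slice_indices(r, slices)
    lig_heavy = ens.indices(ligand, heavy_only=True)
    n_atoms = len(lig_heavy)
    n_res = len(tail_residues)
    theta = np.zeros((slices.count, n_atoms, n_res))
    slice_mass = np.zeros(slices.count)
    np.add.at(slice_mass, sk, ens.weights)
    for j, res in enumerate(tail_residues):
        dmin = ens.per_atom_min_distance(ligand, res)  # (S, n_atoms)
        contact = (dmin < cutoff).astype(float)
        hit = np.zeros((slices.count, n_atoms))
        np.add.at(hit, sk, ens.weights[:, None] * contact)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta[:, :, j] = np.where(
                slice_mass[:, None] > 0, hit / np.where(slice_mass[:, None] > 0, slice_mass[:, None], 1), 0.0
            )
    defined = np.zeros(slices.count, dtype=bool)
    for k in range(slices.count):
        peak = theta[k].max()
        defined[k] = slice_mass[k] > 0 and peak > 0
        if peak > 0:
            theta[k] /= peak
    return theta, defined


def min_distance_pmf(
    ensemble: WeightedEnsemble,
    ligand: AtomGroup,
    tail: AtomGroup,
    slices: SliceSet | None = None,
    bin_width: float = 0.5,
    r_max: float = 30.0,
    temperature: float = 300.0,
    min_shift: bool = True,
) -> PMFProfile:
    """Per-slice PMF of the ligand–tail minimum heavy-atom distance.

    P is the weighted, per-slice-normalized histogram of r_(b−N);
    PMF = −RT ln P, shifted so each defined slice's minimum is 0 (display
    convention, disable with ``min_shift=False``).  Distances beyond
    ``r_max`` are pooled into the last bin.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    slices = slices or SliceSet()
    ens = ensemble.ensure_aligned()
    r = ens.r_bb(ligand)
    sk = _slice_indices(r, slices)
    d = np.clip(ens.min_group_distance(ligand, tail), 0.0, r_max - 1e-9)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    bins = np.clip((d // bin_width).astype(int), 0, n_bins - 1)
    p = np.zeros((slices.count, n_bins))
    np.add.at(p, (sk, bins), ens.weights)
    slice_mass = p.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(slice_mass[:, None] > 0, p / np.where(slice_mass[:, None] > 0, slice_mass[:, None], 1), 0.0)
    rt = _rt(temperature)
    defined = p > 0
    values = np.where(defined, -rt * np.log(np.where(defined, p, 1.0)), np.nan)
    if min_shift:
        for k in range(slices.count):
            if defined[k].any():
                values[k] -= np.nanmin(values[k])
    return PMFProfile(
        values=values,
        probabilities=p,
        defined=defined,
        rt=rt,
        axis_labels=("slice", "distance_bin"),
        meta={"edges": edges, "slices": slices},
    )


# ---------------------------------------------------------------------------
# Orientation fields


def orientation_field(
    ensemble: WeightedEnsemble,
    core: AtomGroup,
    anchors: OrientationAnchors,
    grid: CubeGrid | None = None,
    edge: float = 3.0,
    ligand: AtomGroup | None = None,
) -> tuple[VectorField, VectorField]:
    """Averaged orientation-vector fields (v̄_left, v̄_down) on the cube grid.

    Per snapshot the two unit orientation vectors fixed in the ligand core
    are computed in the aligned frame and assigned to the cube holding the
    ligand centroid (the core centroid if no ligand group is given); each
    cube stores the weighted vector mean, whose norm is 1 for perfectly
    ordered orientations and 0 for fully randomized ones.
    """
    ens = ensemble.ensure_aligned()
    members = set(core.member_serials)
    for pair in (anchors.left, anchors.down):
        if not set(pair) <= members:
            raise ValueError("anchor atoms must be members of the core group")
    pts = ens.centroids(ligand if ligand is not None else core)
    grid, idx, mass, count = _bin_points(pts, ens.weights, grid, edge, pad=1.0)
    fields = []
    for pair in (anchors.left, anchors.down):
        i, j = ens.reference.index_of(pair)
        v = ens.positions[:, j, :] - ens.positions[:, i, :]
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        if np.any(norms < 1e-9):
            raise ValueError("anchor atoms coincide in some snapshot")
        v = v / norms
        acc = np.zeros(grid.shape + (3,))
        np.add.at(acc, tuple(idx.T), ens.weights[:, None] * v)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(mass[..., None] > 0, acc / np.where(mass[..., None] > 0, mass[..., None], 1), 0.0)
        fields.append(VectorField(grid=grid, vectors=mean, occupancy=count, defined=mass > 0))
    return fields[0], fields[1]


def sp_field(
    vfield: VectorField, reference_vector: np.ndarray, norm_floor: float = 0.3
) -> ScalarField:
    """Scalar product of the cube-averaged orientation direction with the
    native-pose reference vector: SP = ê(v̄) · v_ref ∈ [−1, 1].

    Cubes whose averaged-vector norm falls below ``norm_floor`` (default
    0.3) are flagged undefined — a nearly randomized cube has no meaningful
    direction.
    """
    ref = np.asarray(reference_vector, dtype=float)
    if abs(np.linalg.norm(ref) - 1.0) > 1e-6:
        raise ValueError("reference vector must be normalized")
    norms = vfield.norms
    defined = vfield.defined & (norms >= norm_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms[..., None] > 0, vfield.vectors / np.where(norms[..., None] > 0, norms[..., None], 1), 0.0)
    values = np.where(defined, np.tensordot(unit, ref, axes=([-1], [0])), np.nan)
    return ScalarField(grid=vfield.grid, values=values, occupancy=vfield.occupancy, defined=defined)


# ---------------------------------------------------------------------------
# Native contacts


@dataclass
class NativeContactProfile:
    """Windowed native-contact count profile along r_bb.

    ``centers`` start at 0.25 Å with 0.5 Å spacing; each window covers
    [center − 0.25 Å, center + 0.25 Å).  ``mean`` and ``sd`` are the
    weighted mean and standard deviation of the per-snapshot contact count;
    empty windows are flagged undefined.
    """

    centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    occupancy: np.ndarray
    defined: np.ndarray
    n_contacts: int = 4


def native_contact_profile(
    ensemble: WeightedEnsemble,
    contacts: Sequence[NativeContactDef],
    ligand: AtomGroup,
    r_max: float = 15.5,
    half_width: float = 0.25,
) -> NativeContactProfile:
    """Weighted mean and SD of the native-contact count in narrow r_bb
    windows (centers 0.25, 0.75, … Å; half-width 0.25 Å).

    The per-snapshot count is the number of contact definitions whose
    minimum heavy-atom distance is below that contact's cutoff.  Windows
    are half-open so a boundary value is counted once.
    """
    if not contacts:
        raise ValueError("need at least one contact definition")
    ens = ensemble.ensure_aligned()
    r = ens.r_bb(ligand)
    counts = np.zeros(ens.n_snapshots)
    for c in contacts:
        counts += (ens.min_group_distance(c.ligand_atoms, c.receptor_atoms) < c.cutoff).astype(float)
    centers = np.arange(half_width, r_max, 2 * half_width)
    widx = ((r - 0.0) // (2 * half_width)).astype(int)
    in_range = (r >= 0) & (r < centers[-1] + half_width)
    if not in_range.any():
        raise ValueError("no snapshots fall inside the window range")
    mass = np.zeros(len(centers))
    m1 = np.zeros(len(centers))
    m2 = np.zeros(len(centers))
    occ = np.zeros(len(centers))
    w = ens.weights[in_range]
    wi = widx[in_range]
    cc = counts[in_range]
    np.add.at(mass, wi, w)
    np.add.at(m1, wi, w * cc)
    np.add.at(m2, wi, w * cc**2)
    np.add.at(occ, wi, 1)
    defined = mass > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(defined, m1 / np.where(defined, mass, 1), np.nan)
        var = np.where(defined, m2 / np.where(defined, mass, 1) - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return NativeContactProfile(
        centers=centers, mean=mean, sd=sd, occupancy=occ, defined=defined, n_contacts=len(contacts)
    )


# ---------------------------------------------------------------------------
# RMSD distributions


@dataclass
class RMSDDistributions:
    """Distance distribution function (raw weighted histogram) and radial
    distribution function (shell-volume corrected, ∝ DDF / 4πR²) of an RMSD."""

    edges: np.ndarray
    p_ddf: np.ndarray
    p_rdf: np.ndarray
    selection: str

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2


def rmsd_distributions(
    ensemble: WeightedEnsemble,
    selection: AtomGroup,
    bin_width: float = 0.25,
    r_max: float | None = None,
) -> RMSDDistributions:
    """Weighted DDF and RDF of the selection's RMSD from the reference pose.

    Snapshots are superposed on the receptor alignment group only — the
    selection (e.g. the ligand, whole or core, heavy atoms) is *not* fitted
    — and the RMSD is the plain coordinate deviation in that frame.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    ens = ensemble.ensure_aligned()
    idx = ens.indices(selection, heavy_only=True)
    d = ens.positions[:, idx, :] - ens.reference.positions[idx]
    rmsd = np.sqrt((d**2).sum(-1).mean(axis=1))
    if r_max is None:
        r_max = float(np.ceil(rmsd.max() / bin_width) * bin_width) + bin_width
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    bins = np.clip((rmsd // bin_width).astype(int), 0, n_bins - 1)
    p = np.zeros(n_bins)
    np.add.at(p, bins, ens.weights)
    p_ddf = p / p.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    shell = 4.0 * np.pi * centers**2
    p_rdf = p_ddf / shell
    p_rdf = p_rdf / p_rdf.sum()
    return RMSDDistributions(edges=edges, p_ddf=p_ddf, p_rdf=p_rdf, selection=selection.label)


# ---------------------------------------------------------------------------
# Protonation helper


def neutral_fraction(pka: float, ph: float) -> float:
    """Henderson–Hasselbalch neutral (protonated acid) fraction:
    1 / (1 + 10^(pH − pKa))."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


# ---------------------------------------------------------------------------
# OpenDX output


def write_dx(field: ScalarField, target: str | Path, undefined_value: float = 0.0) -> None:
    """Write a scalar cube field as an OpenDX volumetric file (text format
    readable by common molecular-graphics tools)."""
    g = field.grid
    nx, ny, nz = g.shape
    values = np.where(field.defined, field.values, undefined_value).ravel(order="C")
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(
            g.origin[0] + g.edge / 2, g.origin[1] + g.edge / 2, g.origin[2] + g.edge / 2
        ),
        f"delta {g.edge:.6f} 0.000000 0.000000",
        f"delta 0.000000 {g.edge:.6f} 0.000000",
        f"delta 0.000000 0.000000 {g.edge:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    for i in range(0, values.size, 3):
        lines.append(" ".join(f"{v:.8g}" for v in values[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(target).write_text("\n".join(lines) + "\n")
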