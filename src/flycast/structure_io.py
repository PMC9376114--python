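"""Structures, atom selections, and the geometric primitives built on them.

Coordinates are handled in ångströms throughout; there is no internal unit
conversion.  PDB is the only structure format: fixed-column ATOM/HETATM
records, with multi-model files (MODEL/ENDMDL) serving as the snapshot
container for ensembles.  Parsing and writing are delegated to gemmi; the
in-memory representation is a flat, array-backed :class:`Structure` so that
per-snapshot geometry (centroids, minimum distances, superposition) stays
cheap on large ensembles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "AtomGroup",
    "NativeContactDef",
    "OrientationAnchors",
    "Transform",
    "read_pdb",
    "write_pdb",
    "centroid",
    "min_heavy_distance",
    "superpose_rmsd",
    "orientation_vectors",
    "native_contact_distances",
]

#: Elements removed by the heavy-atom filter.
_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


def _is_hydrogen(element: str, name: str) -> bool:
    """Heavy-atom filter: decide by the element symbol, falling back to a
    name-prefix heuristic (leading digits stripped) when the element is blank."""
    el = element.strip().upper()
    if el:
        return el in _HYDROGEN_ELEMENTS
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() in _HYDROGEN_ELEMENTS


@dataclass
class Structure:
    """One model of a molecular structure.

    Parallel arrays/lists hold per-atom records; ``positions`` is an
    ``(n_atoms, 3)`` float array in Å.  Serial numbers must be unique within
    the model.  Residue identity is (chain, residue number, insertion code).
    """

    serials: np.ndarray
    names: list[str]
    elements: list[str]
    res_numbers: np.ndarray
    res_names: list[str]
    chains: list[str]
    positions: np.ndarray
    icodes: list[str] | None = None
    model_id: int = 1
    _lookup: dict[int, int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.serials = np.asarray(self.serials, dtype=np.int64)
        self.res_numbers = np.asarray(self.res_numbers, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.serials)
        if n == 0:
            raise ValueError("a Structure must contain at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must have shape ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("all atom positions must be finite")
        if len(np.unique(self.serials)) != n:
            raise ValueError("atom serial numbers must be unique within a model")
        if self.icodes is None:
            self.icodes = [""] * n

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def index_of(self, serials: Iterable[int]) -> np.ndarray:
        """Map serial numbers to row indices; unknown serials raise KeyError."""
        if self._lookup is None:
            self._lookup = {int(s): i for i, s in enumerate(self.serials)}
        try:
            return np.array([self._lookup[int(s)] for s in serials], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(
                f"serial {exc.args[0]} does not resolve in model {self.model_id}"
            ) from None

    def group_indices(self, group: "AtomGroup") -> np.ndarray:
        """Row indices of a group's members, applying its heavy-atom filter."""
        idx = self.index_of(group.member_serials)
        if group.heavy_only:
            keep = [
                i
                for i in idx
                if not _is_hydrogen(self.elements[i], self.names[i])
            ]
            idx = np.array(keep, dtype=np.intp)
            if idx.size == 0:
                raise ValueError(
                    f"atom group {group.label!r} is empty after the hydrogen filter"
                )
        return idx

    def coords(self, group: "AtomGroup") -> np.ndarray:
        return self.positions[self.group_indices(group)]

    def select(
        self,
        label: str,
        chain: str | None = None,
        res_numbers: Iterable[int] | None = None,
        res_names: Iterable[str] | None = None,
        names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> "AtomGroup":
        """Build an :class:`AtomGroup` from chain / residue-range / atom-name
        criteria, the declaration style used in structured configs."""
        res_numbers = None if res_numbers is None else set(int(r) for r in res_numbers)
        res_names = None if res_names is None else set(res_names)
        names = None if names is None else set(names)
        members = []
        for i in range(self.n_atoms):
            if chain is not None and self.chains[i] != chain:
                continue
            if res_numbers is not None and int(self.res_numbers[i]) not in res_numbers:
                continue
            if res_names is not None and self.res_names[i] not in res_names:
                continue
            if names is not None and self.names[i] not in names:
                continue
            if heavy_only and _is_hydrogen(self.elements[i], self.names[i]):
                continue
            members.append(int(self.serials[i]))
        if not members:
            raise ValueError(f"selection {label!r} matched no atoms")
        return AtomGroup(label=label, member_serials=tuple(members), heavy_only=heavy_only)

    def transformed(self, transform: "Transform") -> "Structure":
        return replace(self, positions=transform.apply(self.positions), _lookup=None)

    def with_positions(self, positions: np.ndarray) -> "Structure":
        return replace(self, positions=np.asarray(positions, dtype=float), _lookup=None)


@dataclass(frozen=True)
class AtomGroup:
    """A named set of atoms, referenced by serial number."""

    label: str
    member_serials: tuple[int, ...]
    heavy_only: bool = False

    def __post_init__(self) -> None:
        if len(self.member_serials) == 0:
            raise ValueError(f"atom group {self.label!r} must not be empty")


@dataclass(frozen=True)
class NativeContactDef:
    """A ligand/receptor atom-pair contact with a distance criterion.

    The contact is considered formed when the minimum heavy-atom distance
    between the two groups is below ``cutoff`` (default 5.0 Å).  When several
    atom pairs are possible the minimum distance is taken.
    """

    ligand_atoms: AtomGroup
    receptor_atoms: AtomGroup
    cutoff: float = 5.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass(frozen=True)
class OrientationAnchors:
    """Anchor atom pairs (serials, tail -> head) defining the two ligand
    orientation vectors fixed in the rigid core region."""

    left: tuple[int, int]
    down: tuple[int, int]


@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ np.asarray(self.rotation).T + np.asarray(
            self.translation
        )

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# PDB input / output


def read_pdb(source: str | Path | io.TextIOBase) -> list[Structure]:
    """Read a (possibly multi-model) PDB file into one Structure per model.

    HETATM ligand records are retained.  Alternate locations keep the first
    conformer; insertion codes are preserved as part of residue identity.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        path = Path(source)
        if path.exists():
            text = path.read_text()
        elif isinstance(source, str) and ("\n" in source or source.startswith(("ATOM", "HETATM", "MODEL"))):
            text = source
        else:
            raise FileNotFoundError(f"no such PDB file: {source}")
    if not text.strip():
        raise ValueError("empty PDB input")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"PDB parse error: {exc}") from exc
    st.remove_alternative_conformations()
    models: list[Structure] = []
    for model in st:
        serials, names, elements, resnums, resnames, chains, icodes, pos = (
            [], [], [], [], [], [], [], [],
        )
        for chain in model:
            for res in chain:
                for atom in res:
                    serials.append(atom.serial)
                    names.append(atom.name)
                    elements.append(atom.element.name)
                    resnums.append(res.seqid.num)
                    resnames.append(res.name)
                    chains.append(chain.name)
                    icodes.append(res.seqid.icode.strip())
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if not serials:
            continue
        models.append(
            Structure(
                serials=np.array(serials),
                names=names,
                elements=elements,
                res_numbers=np.array(resnums),
                res_names=resnames,
                chains=chains,
                icodes=icodes,
                positions=np.array(pos),
                model_id=model.num,
            )
        )
    if not models:
        raise ValueError("PDB input contained no atoms")
    return models


def write_pdb(structures: Structure | Sequence[Structure], target: str | Path | io.TextIOBase) -> None:
    """Write one or more models as a (multi-model) PDB file."""
    if isinstance(structures, Structure):
        structures = [structures]
    st = gemmi.Structure()
    for s in structures:
        # gemmi's add_residue/add_chain copy their argument, so each object
        # must be complete before it is added to its parent
        grouped: dict[str, list[tuple[tuple, list[int]]]] = {}
        for i in range(s.n_atoms):
            cname = s.chains[i]
            key = (int(s.res_numbers[i]), s.res_names[i], s.icodes[i])
            residues = grouped.setdefault(cname, [])
            if not residues or residues[-1][0] != key:
                residues.append((key, []))
            residues[-1][1].append(i)
        model = gemmi.Model(int(s.model_id))
        for cname, residues in grouped.items():
            chain = gemmi.Chain(cname)
            for (resnum, resname, icode), atom_idx in residues:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, icode or " ")
                for i in atom_idx:
                    atom = gemmi.Atom()
                    atom.name = s.names[i]
                    atom.element = gemmi.Element(s.elements[i])
                    atom.serial = int(s.serials[i])
                    atom.pos = gemmi.Position(*s.positions[i])
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if isinstance(target, io.TextIOBase):
        target.write(text)
    else:
        Path(target).write_text(text)


# ---------------------------------------------------------------------------
# Geometry


def centroid(structure: Structure, group: AtomGroup, mass_weighted: bool = False) -> np.ndarray:
    """Centroid of an atom group (unweighted geometric mean by default)."""
    idx = structure.group_indices(group)
    pts = structure.positions[idx]
    if not mass_weighted:
        return pts.mean(axis=0)
    masses = np.array([gemmi.Element(structure.elements[i]).weight for i in idx])
    if masses.sum() <= 0:
        raise ValueError("mass-weighted centroid requires known elements")
    return (pts * masses[:, None]).sum(axis=0) / masses.sum()


def min_heavy_distance(
    structure: Structure,
    group_a: AtomGroup,
    group_b: AtomGroup,
    structure_b: Structure | None = None,
) -> float:
    """Minimum pairwise heavy-atom distance between two groups (Å).

    Hydrogens are always excluded regardless of the groups' ``heavy_only``
    flags.  ``structure_b`` lets the second group live on another model.
    """
    sb = structure_b if structure_b is not None else structure
    a = replace(group_a, heavy_only=True)
    b = replace(group_b, heavy_only=True)
    pa = structure.coords(a)
    pb = sb.coords(b)
    return float(cdist(pa, pb).min())


def native_contact_distances(
    structure: Structure, contacts: Sequence[NativeContactDef]
) -> np.ndarray:
    """Minimum heavy-atom distance for each native-contact definition."""
    return np.array(
        [min_heavy_distance(structure, c.ligand_atoms, c.receptor_atoms) for c in contacts]
    )


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> Transform:
    """Least-squares proper rotation + translation mapping mobile onto reference."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    sv = np.linalg.svd(a, compute_uv=False)
    # A degenerate (collinear or coincident) fit set leaves the rotation
    # underdetermined about the common axis.
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("fit group is collinear or degenerate; superposition undefined")
    rot, _ = Rotation.align_vectors(b, a)
    mat = rot.as_matrix()
    return Transform(rotation=mat, translation=rc - mat @ mc)


def superpose_rmsd(
    mobile: Structure,
    reference: Structure,
    fit_group: AtomGroup,
    rmsd_group: AtomGroup | None = None,
) -> tuple[Transform, float]:
    """Kabsch superposition on ``fit_group``; RMSD evaluated on ``rmsd_group``.

    The fitting selection and the RMSD selection are independent, so the RMSD
    of e.g. a ligand can be measured in the frame defined by the receptor's
    transmembrane helices.  Atoms are paired 1:1 by group order; counts must
    match between the two structures.
    """
    if rmsd_group is None:
        rmsd_group = fit_group
    mob_fit = mobile.coords(fit_group)
    ref_fit = reference.coords(fit_group)
    if mob_fit.shape != ref_fit.shape:
        raise ValueError("fit group atom counts differ between structures")
    if len(mob_fit) < 3:
        raise ValueError("fit group needs at least 3 atoms")
    transform = _kabsch(mob_fit, ref_fit)
    mob_rmsd = transform.apply(mobile.coords(rmsd_group))
    ref_rmsd = reference.coords(rmsd_group)
    if mob_rmsd.shape != ref_rmsd.shape:
        raise ValueError("rmsd group atom counts differ between structures")
    rmsd = float(np.sqrt(np.mean(np.sum((mob_rmsd - ref_rmsd) ** 2, axis=1))))
    return transform, rmsd


def orientation_vectors(
    structure: Structure, core: AtomGroup, anchors: OrientationAnchors
) -> tuple[np.ndarray, np.ndarray]:
    """The two unit orientation vectors fixed in the ligand core region.

    Each vector points from the first to the second anchor atom and is
    normalized to unit length.  Anchors must be members of the core group.
    """
    members = set(core.member_serials)
    out = []
    for pair in (anchors.left, anchors.down):
        if not set(pair) <= members:
            raise ValueError(f"anchor atoms {pair} are not members of core group {core.label!r}")
        i, j = structure.index_of(pair)
        v = structure.positions[j] - structure.positions[i]
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError(f"anchor atoms {pair} are coincident")
        out.append(v / norm)
    return out[0], out[1]
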