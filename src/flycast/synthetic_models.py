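"""Analytic toy systems and synthetic ensembles with known ground truth.

Two families of test systems live here:

* **Toy potentials** (1–3 dimensional) with quadrature ground truth for
  validating the sampler and the canonical-density estimator: a harmonic
  well, a symmetric/asymmetric double well, and a 3-RC binding funnel.
  The bundled dynamics backend is overdamped Langevin (Euler–Maruyama) on
  these potentials.

* **Synthetic weighted binding ensembles** emulating the statistical
  structure of a ligand–receptor study: a ligand centroid density mixing a
  pocket Gaussian with a diffuse shell, per-distance-slice tail-contact
  probabilities, distance-dependent orientation concentration, and native
  contact formation curves.  Snapshots are emitted as genuine structures so
  the analysis operations exercise the same code path as real data, and the
  generating parameters are returned alongside for recovery tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from flycast.binding_analysis import SliceSet, WeightedEnsemble, slice_assign
from flycast.structure_io import (
    AtomGroup,
    NativeContactDef,
    OrientationAnchors,
    Structure,
)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "Harmonic",
    "DoubleWell1D",
    "BindingFunnel3D",
    "boltzmann_marginal",
    "simulate_langevin",
    "LangevinBackend",
    "SyntheticEnsembleSpec",
    "SyntheticGroundTruth",
    "generate_binding_ensemble",
]

#: Molar gas constant in kcal/(mol K) (CODATA).
GAS_CONSTANT_KCAL = 1.987204259e-3


# ---------------------------------------------------------------------------
# Toy potentials


@dataclass(frozen=True)
class Harmonic:
    """Isotropic harmonic well ``U = ½ k |x - center|²`` (kcal/mol, Å)."""

    k: float = 1.0
    center: tuple[float, ...] = (0.0,)
    domain_halfwidth: float = 10.0

    @property
    def dim(self) -> int:
        return len(self.center)

    @property
    def domain(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        return c - self.domain_halfwidth, c + self.domain_halfwidth

    def energy(self, x: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(x) - np.asarray(self.center)
        return 0.5 * self.k * np.sum(d**2, axis=-1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.k * (np.atleast_2d(x) - np.asarray(self.center))


@dataclass(frozen=True)
class DoubleWell1D:
    """Symmetric quartic double well with minima at ±a and barrier height h:
    ``U(x) = h ((x² - a²) / a²)²`` (kcal/mol, Å)."""

    barrier_height: float = 1.8
    half_separation: float = 1.0
    domain_halfwidth: float = 2.5

    dim = 1

    @property
    def domain(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array([-self.domain_halfwidth]), np.array([self.domain_halfwidth])

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)[..., 0]
        a2 = self.half_separation**2
        return self.barrier_height * ((x**2 - a2) / a2) ** 2

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        a2 = self.half_separation**2
        return 4.0 * self.barrier_height * x * (x[..., :1] ** 2 - a2) / a2**2


@dataclass(frozen=True)
class BindingFunnel3D:
    """A 3-RC caricature of a binding landscape: a Gaussian funnel of the
    given depth at the pocket position on an otherwise flat plateau."""

    pocket: tuple[float, float, float] = (0.0, 0.0, 0.0)
    depth: float = 3.0
    funnel_width: float = 1.5
    plateau: float = 0.0
    domain_halfwidth: float = 6.0

    dim = 3

    @property
    def domain(self) -> tuple[np.ndarray, np.ndarray]:
        p = np.asarray(self.pocket)
        return p - self.domain_halfwidth, p + self.domain_halfwidth

    def energy(self, x: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(x) - np.asarray(self.pocket)
        r2 = np.sum(d**2, axis=-1)
        return self.plateau - self.depth * np.exp(-r2 / (2 * self.funnel_width**2))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(x) - np.asarray(self.pocket)
        r2 = np.sum(d**2, axis=-1, keepdims=True)
        g = self.depth * np.exp(-r2 / (2 * self.funnel_width**2)) / self.funnel_width**2
        return g * d


def boltzmann_marginal(
    potential, edges: np.ndarray | Sequence[np.ndarray], temperature: float = 300.0, refine: int = 64
) -> np.ndarray:
    """Quadrature Boltzmann probability mass per bin, normalized to sum 1.

    For 1-D potentials ``edges`` is a bin-edge array; each bin is integrated
    with a ``refine``-point midpoint rule.  For multi-dimensional potentials
    pass per-axis edge arrays; the midpoint rule is applied per cell.
    """
    rt = GAS_CONSTANT_KCAL * temperature
    if isinstance(edges, np.ndarray) and edges.ndim == 1:
        edges_list = [np.asarray(edges, dtype=float)]
    else:
        edges_list = [np.asarray(e, dtype=float) for e in edges]
    dim = getattr(potential, "dim", len(edges_list))
    if len(edges_list) != dim:
        raise ValueError(f"need {dim} edge arrays for a {dim}-D potential")
    fine_axes = []
    for e in edges_list:
        widths = np.diff(e)
        pts = (
            e[:-1, None] + (np.arange(refine)[None, :] + 0.5) * widths[:, None] / refine
        ).ravel()
        fine_axes.append(pts)
    mesh = np.meshgrid(*fine_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    u = potential.energy(pts)
    if not np.all(np.isfinite(u)):
        raise ValueError("potential is not finite over the requested bins")
    w = np.exp(-(u - u.min()) / rt).reshape([len(a) for a in fine_axes])
    # collapse the refine sub-grid within each bin
    for axis, e in enumerate(edges_list):
        nb = len(e) - 1
        shape = list(w.shape)
        shape[axis : axis + 1] = [nb, refine]
        w = w.reshape(shape).sum(axis=axis + 1)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("Boltzmann integral diverged or vanished on the domain")
    out = w / total
    return out[0] if False else (out.ravel() if dim == 1 else out)


def simulate_langevin(
    potential,
    steps: int,
    dt: float = 0.01,
    friction: float = 1.0,
    temperature: float = 300.0,
    seed: int | np.random.Generator = 0,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Overdamped Langevin (Euler–Maruyama) trajectory on a toy potential.

    ``x_{t+1} = x_t - (dt/γ) ∇U + √(2 RT dt/γ) ξ``; deterministic given the
    seed.  Aborts with the step index if the state turns non-finite.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dim = potential.dim
    x = np.zeros(dim) if x0 is None else np.atleast_1d(np.asarray(x0, dtype=float))
    sigma = np.sqrt(2.0 * GAS_CONSTANT_KCAL * temperature * dt / friction)
    out = np.empty((steps + 1, dim))
    out[0] = x
    noise = rng.standard_normal((steps, dim))
    for t in range(steps):
        x = x - (dt / friction) * potential.gradient(x)[0] + sigma * noise[t]
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"trajectory diverged at step {t + 1}")
        out[t + 1] = x
    return out


class LangevinBackend:
    """Overdamped Langevin dynamics backend for the sampling engine.

    The reaction coordinates are the state coordinates themselves, so the
    restraint gradient pulls back through an identity Jacobian.
    """

    def __init__(
        self,
        potential,
        dt: float = 0.01,
        friction: float = 1.0,
        temperature: float = 300.0,
    ) -> None:
        self.potential = potential
        self.dt = dt
        self.friction = friction
        self.temperature = temperature
        self.dim = potential.dim
        self._sigma = np.sqrt(2.0 * GAS_CONSTANT_KCAL * temperature * dt / friction)

    def rc(self, states: np.ndarray) -> np.ndarray:
        return states

    def rc_gradient_pullback(self, states: np.ndarray, rc_grad: np.ndarray) -> np.ndarray:
        return rc_grad

    def step(self, states: np.ndarray, extra_gradient: np.ndarray, noise: np.ndarray) -> np.ndarray:
        grad = self.potential.gradient(states) + extra_gradient
        return states - (self.dt / self.friction) * grad + self._sigma * noise

    def reflect(self, states: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Reflective hard walls at the RC coverage bounds (identity RC).

        Without them the softly restrained edge zones would gain extra
        stationary mass in the wall tail beyond the grid coverage, where no
        competing zone exists, biasing the zone-visit distribution."""
        span = hi - lo
        y = np.mod(states - lo, 2.0 * span)
        return lo + np.minimum(y, 2.0 * span - y)


# ---------------------------------------------------------------------------
# Synthetic binding ensembles


#: N-terminal tail beads: capping group plus ten residues, tip to root.
TAIL_RESIDUES: tuple[tuple[int, str], ...] = (
    (79, "ACE"),
    (80, "SER"),
    (81, "PRO"),
    (82, "PRO"),
    (83, "ARG"),
    (84, "THR"),
    (85, "ILE"),
    (86, "SER"),
    (87, "PRO"),
    (88, "PRO"),
    (89, "PRO"),
)


def _default_tail_contact_table(n_slices: int = 13) -> np.ndarray:
    """Per-(slice, residue) contact probabilities shaped like the two-basin
    tip-capture / root-capture pattern: the ligand first touches the tail
    tip far from the pocket (basin near the tip residues, outer slices),
    then the stable contact shifts to the root residues just inside the
    pocket, and is lost at the pocket bottom except a weak Arg contact."""
    p = np.zeros((n_slices, len(TAIL_RESIDUES)))
    p[11, 0] = 0.10  # slice 12: first touch at the capping group
    for k in (8, 9, 10):  # slices 9-11: non-specific tip contact
        p[k, 0:4] = 0.45
    for k in (4, 5, 6):  # slices 5-7: tip-side basin (Ser80..Arg83)
        p[k, 1:5] = 0.80
        p[k, 5:8] = 0.30
    for k in (2, 3):  # slices 3-4: root-side basin (Ile85..Pro89)
        p[k, 6:11] = 0.90
        p[k, 1:5] = 0.20
    for k in (0, 1):  # pocket bottom: contact lost, weak Arg-residue touch
        p[k, :] = 0.05
        p[k, 4] = 0.30
    return p


def _default_native_curves() -> tuple[tuple[float, float], ...]:
    """Logistic formation-midpoint/width pairs (Å) for the four contacts."""
    return ((1.0, 0.8), (2.0, 0.8), (3.0, 0.8), (1.5, 0.8))


@dataclass
class SyntheticEnsembleSpec:
    """Parameters of the synthetic weighted binding ensemble.

    The ligand centroid is drawn from a mixture of a Gaussian at the pocket
    site (weight ``pocket_weight``, width ``pocket_sigma``) and a diffuse
    uniform-radius shell; tail residues contact the ligand with per-slice
    probabilities ``tail_contact_prob``; the ligand orientation concentrates
    around the native pose with ``kappa_inside`` in pocket slices (1–4) and
    ``kappa_outside`` beyond the gate; the four native contacts form with
    logistic probability curves in the centroid displacement r_bb.
    """

    n_snapshots: int = 20_000
    seed: int = 0
    pocket_weight: float = 0.35
    pocket_sigma: float = 4.0
    shell_radius: tuple[float, float] = (5.0, 62.0)
    slices: SliceSet | None = None
    tail_contact_prob: np.ndarray | None = None
    kappa_inside: float = 50.0
    kappa_outside: float = 0.5
    native_curves: tuple[tuple[float, float], ...] | None = None
    contact_cutoff: float = 5.0
    weights: np.ndarray | str = "uniform"
    rigid_jitter: bool = True

    def __post_init__(self) -> None:
        if self.slices is None:
            self.slices = SliceSet()
        if self.tail_contact_prob is None:
            self.tail_contact_prob = _default_tail_contact_table(self.slices.count)
        self.tail_contact_prob = np.asarray(self.tail_contact_prob, dtype=float)
        if self.tail_contact_prob.shape != (self.slices.count, len(TAIL_RESIDUES)):
            raise ValueError(
                "tail_contact_prob must have shape (n_slices, n_tail_residues) = "
                f"({self.slices.count}, {len(TAIL_RESIDUES)})"
            )
        if np.any((self.tail_contact_prob < 0) | (self.tail_contact_prob > 1)):
            raise ValueError("contact probabilities must lie in [0, 1]")
        if self.native_curves is None:
            self.native_curves = _default_native_curves()
        if min(self.kappa_inside, self.kappa_outside) < 0:
            raise ValueError("orientation concentrations must be >= 0")
        if not 0 <= self.pocket_weight <= 1:
            raise ValueError("pocket_weight must be in [0, 1]")
        if self.shell_radius[1] >= self.slices.count * self.slices.thickness:
            raise ValueError("shell must stay inside the slice coverage")

    def kappa(self, r_bb: float) -> float:
        k = slice_assign(r_bb, self.slices)
        return self.kappa_inside if k <= 4 else self.kappa_outside

    def native_contact_prob(self, r_bb: float) -> np.ndarray:
        return np.array(
            [1.0 / (1.0 + np.exp((r_bb - r0) / w)) for r0, w in self.native_curves]
        )


@dataclass
class SyntheticGroundTruth:
    """Generating parameters plus the per-snapshot latent variables."""

    spec: SyntheticEnsembleSpec
    groups: dict[str, AtomGroup]
    anchors: OrientationAnchors
    native_contacts: tuple[NativeContactDef, ...]
    r_bb: np.ndarray
    slice_index: np.ndarray
    tail_contacts: np.ndarray
    native_formed: np.ndarray
    reference_orientation: tuple[np.ndarray, np.ndarray]


def _build_template() -> tuple[Structure, dict[str, AtomGroup], OrientationAnchors]:
    """Reference structure: rigid receptor frame, pocket-site ligand, tail
    beads and four dedicated native-contact receptor atoms.

    Entirely synthetic pseudo-atoms; the receptor-side partner of the
    sulfonamide-nitrogen contact gets its own atom so each formation curve
    is independently controllable.
    """
    pocket = np.array([0.0, 0.0, -6.0])
    records: list[tuple[str, str, int, str, str, np.ndarray]] = []
    # (name, element, resnum, resname, chain, position)
    tm_sites = [
        (4.0, 0.0, -10.0), (-4.0, 1.0, -10.0), (0.0, 4.0, -11.0), (0.0, -4.0, -9.0),
        (3.0, 3.0, -14.0), (-3.0, -3.0, -13.0), (2.0, -3.0, -12.0), (-2.0, 3.0, -15.0),
    ]
    for i, pos in enumerate(tm_sites):
        records.append(("CA", "C", 201 + i, "TMH", "R", np.array(pos)))
    contact_sites = [
        ("NZ", "N", 182, "LYS", "R"),
        ("NZ", "N", 273, "LYS", "R"),
        ("NH1", "N", 343, "ARG", "R"),
        ("NZ", "N", 185, "LYS", "R"),  # synthetic stand-in partner for the N14 contact
    ]
    for name, el, num, resname, chain in contact_sites:
        records.append((name, el, num, resname, chain, pocket + np.array([3.0, 0.0, 0.0])))
    for resnum, resname in TAIL_RESIDUES:
        # tail extends from the gate region outward; exact placement is
        # overwritten per snapshot
        records.append(("CA", "C", resnum, resname, "A", np.array([6.0, 0.0, float(resnum - 79)])))
    # ligand: planar six-ring core + sulfonamide-like appendage + two side atoms
    ring = [
        np.array([np.cos(a), np.sin(a), 0.0]) * 1.4
        for a in np.deg2rad([0, 60, 120, 180, 240, 300])
    ]
    lig_offsets = ring + [
        np.array([2.6, 0.0, 0.4]),   # S1
        np.array([3.6, 0.9, 0.4]),   # N1 (sulfonamide nitrogen)
        np.array([3.1, -1.2, 0.9]),  # O1
        np.array([2.9, -0.4, 1.8]),  # O2
        np.array([-2.4, 1.0, 0.3]),  # C7
        np.array([-2.6, -1.0, -0.4]),  # C8
    ]
    lig_offsets = np.array(lig_offsets)
    lig_offsets -= lig_offsets.mean(axis=0)
    lig_names = ["C1", "C2", "C3", "C4", "C5", "C6", "S1", "N1", "O1", "O2", "C7", "C8"]
    lig_elements = ["C", "C", "C", "C", "C", "C", "S", "N", "O", "O", "C", "C"]
    for name, el, off in zip(lig_names, lig_elements, lig_offsets):
        records.append((name, el, 1, "LIG", "L", pocket + off))

    serials = np.arange(1, len(records) + 1)
    template = Structure(
        serials=serials,
        names=[r[0] for r in records],
        elements=[r[1] for r in records],
        res_numbers=np.array([r[2] for r in records]),
        res_names=[r[3] for r in records],
        chains=[r[4] for r in records],
        positions=np.array([r[5] for r in records]),
        model_id=1,
    )
    groups = synthetic_groups(template)
    return template, groups, synthetic_anchors(groups)


def synthetic_groups(structure: Structure) -> dict[str, AtomGroup]:
    """The synthetic template's named selections, derived from any structure
    following its layout (e.g. one re-read from a PDB file, whose serial
    numbering may differ from the in-memory builder's)."""
    return {
        "tm": structure.select("tm", chain="R", res_names=["TMH"]),
        "tail": structure.select("tail", chain="A"),
        "ligand": structure.select("ligand", chain="L", heavy_only=True),
        "core": structure.select("core", chain="L", names=["C1", "C2", "C3", "C4", "C5", "C6"]),
        "soo": structure.select("soo", chain="L", names=["O1", "O2"]),
        "n14": structure.select("n14", chain="L", names=["N1"]),
        "lys182": structure.select("lys182", chain="R", res_numbers=[182]),
        "lys273": structure.select("lys273", chain="R", res_numbers=[273]),
        "arg343": structure.select("arg343", chain="R", res_numbers=[343]),
        "lys185": structure.select("lys185", chain="R", res_numbers=[185]),
    }


def synthetic_anchors(groups: dict[str, AtomGroup]) -> OrientationAnchors:
    """Orientation anchors on the template core ring: C1→C4 in-plane, C6→C2
    perpendicular in-plane."""
    core_serials = groups["core"].member_serials
    return OrientationAnchors(
        left=(core_serials[0], core_serials[3]),
        down=(core_serials[5], core_serials[1]),
    )


def template_native_contacts(
    groups: dict[str, AtomGroup], cutoff: float = 5.0
) -> tuple[NativeContactDef, ...]:
    """The four native-contact definitions of the synthetic template: the
    sulfonyl oxygens against three basic receptor sites, and the sulfonamide
    nitrogen against its own (synthetic) receptor partner."""
    return tuple(
        NativeContactDef(
            ligand_atoms=groups[lg],
            receptor_atoms=groups[sg],
            cutoff=cutoff,
            label=label,
        )
        for lg, sg, label in (
            ("soo", "lys182", "SOO-Lys182"),
            ("soo", "lys273", "SOO-Lys273"),
            ("soo", "arg343", "SOO-Arg343"),
            ("n14", "lys185", "N14-site"),
        )
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.standard_normal(4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


def generate_binding_ensemble(
    spec: SyntheticEnsembleSpec,
) -> tuple[WeightedEnsemble, SyntheticGroundTruth]:
    """Generate a synthetic weighted binding ensemble with known truth.

    Every snapshot realizes: a ligand centroid from the declared mixture
    density; a rigid-body ligand orientation dispersed around the native
    pose with the slice's concentration; tail-bead positions whose contact
    indicators are exact Bernoulli draws from the per-slice table; and
    receptor contact-site positions realizing the native-contact formation
    curves.  Each snapshot is finally subjected to a random rigid motion so
    analyses must perform the receptor-frame superposition, exactly as with
    real data.
    """
    rng = np.random.default_rng(spec.seed)
    template, groups, anchors = _build_template()
    n = spec.n_snapshots
    if n < 1:
        raise ValueError("need at least one snapshot")

    lig_idx = template.group_indices(groups["ligand"])
    tail_idx = template.group_indices(groups["tail"])
    tm_idx = template.group_indices(groups["tm"])
    site_idx = {
        name: template.group_indices(groups[name])
        for name in ("lys182", "lys273", "arg343", "lys185")
    }
    soo_idx = template.group_indices(groups["soo"])
    n14_idx = template.group_indices(groups["n14"])
    ref_pos = template.positions
    lig_offsets = ref_pos[lig_idx] - ref_pos[lig_idx].mean(axis=0)
    pocket = ref_pos[lig_idx].mean(axis=0)
    lig_radius = float(np.linalg.norm(lig_offsets, axis=1).max())

    # ligand-side partner index (into the ligand block) per native contact
    partner_groups = [soo_idx, soo_idx, soo_idx, n14_idx]
    site_order = ["lys182", "lys273", "arg343", "lys185"]

    positions = np.empty((n, template.n_atoms, 3))
    r_bb = np.empty(n)
    slice_k = np.empty(n, dtype=int)
    tail_contacts = np.zeros((n, len(TAIL_RESIDUES)), dtype=bool)
    native_formed = np.zeros((n, 4), dtype=bool)

    in_pocket = rng.random(n) < spec.pocket_weight
    for i in range(n):
        if in_pocket[i]:
            c = pocket + spec.pocket_sigma * rng.standard_normal(3)
        else:
            r = rng.uniform(*spec.shell_radius)
            c = pocket + r * _random_unit(rng)
        r_bb[i] = np.linalg.norm(c - pocket)
        if r_bb[i] >= spec.slices.count * spec.slices.thickness:
            c = pocket + (spec.slices.upper_bound - 1e-6) * (c - pocket) / r_bb[i]
            r_bb[i] = np.linalg.norm(c - pocket)
        k = slice_assign(r_bb[i], spec.slices)
        slice_k[i] = k

        kappa = spec.kappa(r_bb[i])
        if kappa < 1e-6:
            rot = _random_rotation(rng)
        else:
            angle = rng.normal(0.0, 1.0 / np.sqrt(kappa))
            rot = Rotation.from_rotvec(_random_unit(rng) * angle).as_matrix()
        snap = ref_pos.copy()
        lig_pos = lig_offsets @ rot.T + c
        snap[lig_idx] = lig_pos

        for j in range(len(TAIL_RESIDUES)):
            p = spec.tail_contact_prob[k - 1, j]
            if rng.random() < p:
                tail_contacts[i, j] = True
                base = lig_pos[rng.integers(len(lig_idx))]
                snap[tail_idx[j]] = base + rng.uniform(3.0, 4.5) * _random_unit(rng)
            else:
                dist = lig_radius + spec.contact_cutoff + 1.0 + rng.exponential(2.0)
                snap[tail_idx[j]] = c + dist * _random_unit(rng)

        p_native = spec.native_contact_prob(r_bb[i])
        for ci in range(4):
            partner = lig_pos[
                np.searchsorted(lig_idx, partner_groups[ci])
            ]  # ligand-side heavy atoms of this contact
            g_center = partner.mean(axis=0)
            g_radius = float(np.linalg.norm(partner - g_center, axis=1).max())
            if rng.random() < p_native[ci]:
                native_formed[i, ci] = True
                base = partner[rng.integers(len(partner))]
                pos = base + rng.uniform(2.8, min(4.7, spec.contact_cutoff - 0.3)) * _random_unit(rng)
            else:
                pos = g_center + (
                    spec.contact_cutoff + 0.5 + g_radius + rng.exponential(2.0)
                ) * _random_unit(rng)
            snap[site_idx[site_order[ci]]] = pos

        if spec.rigid_jitter:
            rg = _random_rotation(rng)
            tg = rng.normal(0.0, 10.0, 3)
            snap = snap @ rg.T + tg
        positions[i] = snap

    if isinstance(spec.weights, str):
        if spec.weights != "uniform":
            raise ValueError("weights must be 'uniform' or an array")
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(spec.weights, dtype=float)
        if weights.shape != (n,) or np.any(weights < 0):
            raise ValueError("weights must be n non-negative values")
        weights = weights / weights.sum()

    from flycast.structure_io import orientation_vectors

    ref_orient = orientation_vectors(template, groups["core"], anchors)
    contacts = template_native_contacts(groups, cutoff=spec.contact_cutoff)
    ensemble = WeightedEnsemble(
        reference=template,
        positions=positions,
        weights=weights,
        align_group=groups["tm"],
    )
    truth = SyntheticGroundTruth(
        spec=spec,
        groups=groups,
        anchors=anchors,
        native_contacts=contacts,
        r_bb=r_bb,
        slice_index=slice_k,
        tail_contacts=tail_contacts,
        native_formed=native_formed,
        reference_orientation=ref_orient,
    )
    return ensemble, truth
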