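"""Weighted-ensemble binding statistics: fields, slices, PMFs, contacts."""

import numpy as np
import pytest

from flycast.binding_analysis import (
    GAS_CONSTANT_KCAL,
    CubeGrid,
    SliceSet,
    VectorField,
    WeightedEnsemble,
    atom_residue_contact,
    contact_ratio_field,
    density_field,
    min_distance_pmf,
    native_contact_profile,
    neutral_fraction,
    orientation_field,
    residue_contact_pmf,
    rmsd_distributions,
    slice_assign,
    sp_field,
    write_dx,
)
from flycast.structure_io import (
    AtomGroup,
    NativeContactDef,
    OrientationAnchors,
    Structure,
)
from flycast.synthetic_models import (
    SyntheticEnsembleSpec,
    TAIL_RESIDUES,
    generate_binding_ensemble,
)

RT300 = GAS_CONSTANT_KCAL * 300.0


def build_reference(records):
    """records: list of (name, element, resnum, resname, chain, position)."""
    return Structure(
        serials=np.arange(1, len(records) + 1),
        names=[r[0] for r in records],
        elements=[r[1] for r in records],
        res_numbers=np.array([r[2] for r in records]),
        res_names=[r[3] for r in records],
        chains=[r[4] for r in records],
        positions=np.array([r[5] for r in records], dtype=float),
    )


ALIGN_RECORDS = [
    ("CA", "C", 201, "TMH", "R", [10.0, 0.0, 0.0]),
    ("CA", "C", 202, "TMH", "R", [0.0, 10.0, 0.0]),
    ("CA", "C", 203, "TMH", "R", [0.0, 0.0, 10.0]),
    ("CA", "C", 204, "TMH", "R", [7.0, 7.0, 0.0]),
]


def mini_ensemble(extra_records, edits, weights=None):
    """Small ensemble: fixed alignment frame + per-snapshot position edits.

    ``edits`` is a list of dicts serial -> position; snapshots start from
    the reference coordinates.
    """
    ref = build_reference(ALIGN_RECORDS + extra_records)
    n = len(edits)
    positions = np.repeat(ref.positions[None], n, axis=0)
    for i, edit in enumerate(edits):
        for serial, pos in edit.items():
            positions[i, serial - 1] = pos
    weights = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    align = ref.select("tm", chain="R")
    return WeightedEnsemble(
        reference=ref, positions=positions, weights=weights, align_group=align, aligned=True
    )


@pytest.fixture(scope="module")
def slice3_ensemble():
    """Ligand confined to slice 3 with a planted Arg-bead contact p = 0.8."""
    table = np.zeros((13, len(TAIL_RESIDUES)))
    table[2, 4] = 0.8
    spec = SyntheticEnsembleSpec(
        n_snapshots=20_000,
        seed=6,
        pocket_weight=0.0,
        shell_radius=(10.0, 15.0),
        tail_contact_prob=table,
    )
    ens, truth = generate_binding_ensemble(spec)
    return ens.ensure_aligned(), truth


class TestDensityField:
    def test_single_snapshot_single_cube(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        ens = mini_ensemble(lig, [{5: [1.0, 1.0, 1.0]}])
        field = density_field(ens, ens.reference.select("lig", chain="L"))
        assert field.values.max() == 1.0
        assert (field.values > 0).sum() == 1

    def test_two_snapshots_max_normalized(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        ens = mini_ensemble(
            lig,
            [{5: [0.0, 0.0, 0.0]}, {5: [20.0, 0.0, 0.0]}],
            weights=[0.75, 0.25],
        )
        field = density_field(ens, ens.reference.select("lig", chain="L"))
        vals = sorted(field.values[field.values > 0].ravel())
        assert vals == pytest.approx([1.0 / 3.0, 1.0])

    def test_mass_mode_sums_to_one(self, slice3_ensemble):
        ens, truth = slice3_ensemble
        field = density_field(ens, truth.groups["ligand"], normalize="mass")
        assert field.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestContactRatioField:
    def test_all_in_contact_gives_one(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        tail = [("CA", "C", 80, "SER", "A", [2.0, 0.0, 0.0])]
        ens = mini_ensemble(lig + tail, [{}, {}])
        field = contact_ratio_field(
            ens,
            ens.reference.select("lig", chain="L"),
            ens.reference.select("tail", chain="A"),
        )
        assert np.all(field.values[field.defined] == 1.0)

    def test_half_contact_in_shared_cube(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        tail = [("CA", "C", 80, "SER", "A", [2.0, 0.0, 0.0])]
        # same ligand cube; tail near in one snapshot, far in the other
        ens = mini_ensemble(lig + tail, [{}, {6: [50.0, 0.0, 0.0]}])
        field = contact_ratio_field(
            ens,
            ens.reference.select("lig", chain="L"),
            ens.reference.select("tail", chain="A"),
        )
        assert field.values[field.defined] == pytest.approx([0.5])

    def test_planted_contact_probability_recovered(self, slice3_ensemble):
        ens, truth = slice3_ensemble
        field = contact_ratio_field(
            ens, truth.groups["ligand"], truth.groups["tail"], cutoff=5.0
        )
        # weighted mean of the field over occupancy = overall contact fraction
        mass_weighted = float(
            np.nansum(field.values[field.defined] * field.occupancy[field.defined])
            / field.occupancy[field.defined].sum()
        )
        sigma = np.sqrt(0.8 * 0.2 / ens.n_snapshots)
        assert abs(mass_weighted - 0.8) <= 3 * sigma + 1e-3

    def test_invalid_cutoff(self, slice3_ensemble):
        ens, truth = slice3_ensemble
        with pytest.raises(ValueError):
            contact_ratio_field(ens, truth.groups["ligand"], truth.groups["tail"], cutoff=0.0)


class TestMembraneContactField:
    def test_slab_contact_indicator(self):
        from flycast.binding_analysis import membrane_contact_field

        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        # one snapshot hovering at the slab surface, one far above it
        ens = mini_ensemble(lig, [{5: [0.0, 0.0, -18.0]}, {5: [0.0, 0.0, 30.0]}])
        field = membrane_contact_field(
            ens, ens.reference.select("lig", chain="L"), z_level=-20.0, cutoff=5.0
        )
        vals = sorted(field.values[field.defined].ravel())
        assert vals == pytest.approx([0.0, 1.0])


class TestSliceAssign:
    @pytest.mark.parametrize(
        "r_bb,expected", [(0.0, 1), (12.0, 3), (20.0, 5), (64.999, 13)]
    )
    def test_examples(self, r_bb, expected):
        assert slice_assign(r_bb) == expected

    @pytest.mark.parametrize("bad", [-0.1, 65.0, 100.0])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            slice_assign(bad)

    def test_custom_slices(self):
        s = SliceSet(thickness=2.0, count=5)
        assert slice_assign(3.9, s) == 2
        assert s.bounds(2) == (2.0, 4.0)


class TestResidueContactPmf:
    def test_f_zero_at_probability_one(self):
        table = np.zeros((13, len(TAIL_RESIDUES)))
        table[2, 4] = 1.0
        spec = SyntheticEnsembleSpec(
            n_snapshots=200, seed=3, pocket_weight=0.0,
            shell_radius=(10.0, 15.0), tail_contact_prob=table,
        )
        ens, truth = generate_binding_ensemble(spec)
        groups = [
            ens.reference.select(f"{name}{num}", chain="A", res_numbers=[num])
            for num, name in TAIL_RESIDUES
        ]
        pmf = residue_contact_pmf(ens, truth.groups["ligand"], groups)
        assert pmf.values[2, 4] == 0.0
        assert pmf.defined[2, 4]
        # unsampled slices are flagged, not zero-filled
        assert not pmf.defined[12].any()

    def test_rt_at_probability_exp_minus_one(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        tail = [("CA", "C", 80, "SER", "A", [2.0, 0.0, 0.0])]
        w = np.exp(-1.0)
        ens = mini_ensemble(lig + tail, [{}, {6: [50.0, 0.0, 0.0]}], weights=[w, 1 - w])
        pmf = residue_contact_pmf(
            ens,
            ens.reference.select("lig", chain="L"),
            [ens.reference.select("ser80", chain="A", res_numbers=[80])],
        )
        assert pmf.probabilities[0, 0] == pytest.approx(np.exp(-1.0))
        assert pmf.values[0, 0] == pytest.approx(RT300, abs=1e-6)
        assert RT300 == pytest.approx(0.5961, abs=2e-4)

    def test_planted_f_recovered(self, slice3_ensemble):
        ens, truth = slice3_ensemble
        groups = [
            ens.reference.select(f"{name}{num}", chain="A", res_numbers=[num])
            for num, name in TAIL_RESIDUES
        ]
        pmf = residue_contact_pmf(ens, truth.groups["ligand"], groups)
        assert pmf.values[2, 4] == pytest.approx(-RT300 * np.log(0.8), abs=0.02)


class TestAtomResidueContact:
    def test_single_pair_peaks(self):
        lig = [
            ("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0]),
            ("C2", "C", 1, "LIG", "L", [0.0, 30.0, 0.0]),
        ]
        tail = [("CA", "C", 80, "SER", "A", [2.0, 0.0, 0.0])]
        ens = mini_ensemble(lig + tail, [{}, {}])
        theta, defined = atom_residue_contact(
            ens,
            ens.reference.select("lig", chain="L"),
            [ens.reference.select("ser80", chain="A", res_numbers=[80])],
            slices=SliceSet(thickness=50.0, count=1),
        )
        assert defined[0]
        assert theta[0, 0, 0] == 1.0
        assert theta[0, 1, 0] == 0.0

    def test_uniform_contacts_all_one(self):
        lig = [
            ("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0]),
            ("C2", "C", 1, "LIG", "L", [1.0, 0.0, 0.0]),
        ]
        tail = [
            ("CA", "C", 80, "SER", "A", [0.5, 1.0, 0.0]),
            ("CA", "C", 81, "PRO", "A", [0.5, -1.0, 0.0]),
        ]
        ens = mini_ensemble(lig + tail, [{}, {}])
        theta, _ = atom_residue_contact(
            ens,
            ens.reference.select("lig", chain="L"),
            [
                ens.reference.select("r80", chain="A", res_numbers=[80]),
                ens.reference.select("r81", chain="A", res_numbers=[81]),
            ],
            slices=SliceSet(thickness=50.0, count=1),
        )
        np.testing.assert_allclose(theta[0], 1.0)

    def test_planted_specificity_raises_entropy_contrast(self):
        # inner slice: only ligand atom 1 contacts the Arg-like bead;
        # outer slice: contacts spread over random (atom, residue) pairs
        rng = np.random.default_rng(0)
        lig_names = [f"C{i+1}" for i in range(6)]
        lig = [
            (n, "C", 1, "LIG", "L", [1.4 * np.cos(a), 1.4 * np.sin(a), 0.0])
            for n, a in zip(lig_names, np.deg2rad(np.arange(0, 360, 60)))
        ]
        tail = [("CA", "C", 83, "ARG", "A", [50.0, 0.0, 0.0])]
        edits = []
        cutoff = 2.5
        for i in range(300):
            ed = {}
            if i < 150:  # inner: bead 2.0 A radially out from atom C1
                ed[11] = [1.4 + 2.0, 0.0, 0.0]
                centroid = np.zeros(3)
            else:  # outer: displace ligand far; bead near a random atom
                shift = np.array([0.0, 0.0, 60.0])
                for s in range(5, 11):
                    base = np.array(lig[s - 5][5]) + shift
                    ed[s] = base
                k = rng.integers(6)
                direction = np.array(lig[k][5]) / 1.4
                ed[11] = np.array(lig[k][5]) + shift + 2.0 * direction
            edits.append(ed)
        ens = mini_ensemble(lig + tail, edits)
        lig_group = ens.reference.select("lig", chain="L")
        arg = ens.reference.select("arg", chain="A", res_numbers=[83])
        theta, defined = atom_residue_contact(
            ens, lig_group, [arg], slices=SliceSet(thickness=30.0, count=3), cutoff=cutoff
        )
        def entropy(mat):
            p = mat[mat > 0]
            p = p / p.sum()
            return float(-(p * np.log(p)).sum())
        assert defined[0] and defined[2]
        assert entropy(theta[2]) >= 2 * max(entropy(theta[0]), 1e-12) or entropy(theta[0]) == 0.0


class TestMinDistancePmf:
    def test_single_distance_single_bin(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        tail = [("CA", "C", 80, "SER", "A", [3.2, 0.0, 0.0])]
        ens = mini_ensemble(lig + tail, [{}, {}])
        pmf = min_distance_pmf(
            ens,
            ens.reference.select("lig", chain="L"),
            ens.reference.select("tail", chain="A"),
            slices=SliceSet(thickness=50.0, count=1),
        )
        assert pmf.defined[0].sum() == 1
        assert np.nanmin(pmf.values[0]) == 0.0

    def test_two_equal_bins_zero_after_shift(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        tail = [("CA", "C", 80, "SER", "A", [3.2, 0.0, 0.0])]
        ens = mini_ensemble(lig + tail, [{}, {6: [7.2, 0.0, 0.0]}])
        pmf = min_distance_pmf(
            ens,
            ens.reference.select("lig", chain="L"),
            ens.reference.select("tail", chain="A"),
            slices=SliceSet(thickness=50.0, count=1),
        )
        vals = pmf.values[0][pmf.defined[0]]
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_basin_depth_follows_weight_ratio(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        tail = [("CA", "C", 80, "SER", "A", [3.2, 0.0, 0.0])]
        ens = mini_ensemble(
            lig + tail, [{}, {6: [12.2, 0.0, 0.0]}], weights=[0.9, 0.1]
        )
        pmf = min_distance_pmf(
            ens,
            ens.reference.select("lig", chain="L"),
            ens.reference.select("tail", chain="A"),
            slices=SliceSet(thickness=50.0, count=1),
        )
        vals = pmf.values[0][pmf.defined[0]]
        assert max(vals) - min(vals) == pytest.approx(RT300 * np.log(9.0), abs=1e-9)


def orientation_mini(vectors, weights=None):
    """Ensemble of 2-anchor cores sharing one cube, with given directions."""
    core = [
        ("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0]),
        ("C2", "C", 1, "LIG", "L", [1.0, 0.0, 0.0]),
    ]
    edits = [{6: np.array(v, dtype=float)} for v in vectors]
    ens = mini_ensemble(core + [], edits, weights=weights)
    group = ens.reference.select("core", chain="L")
    anchors = OrientationAnchors(left=(5, 6), down=(5, 6))
    return ens, group, anchors


class TestOrientationField:
    def test_identical_orientations_norm_one(self):
        ens, core, anchors = orientation_mini([[1, 0, 0]] * 5)
        vl, _ = orientation_field(ens, core, anchors)
        assert np.nanmax(vl.norms[vl.defined]) == pytest.approx(1.0)

    def test_antiparallel_cancel(self):
        ens, core, anchors = orientation_mini([[1, 0, 0], [-1, 0, 0]])
        vl, _ = orientation_field(ens, core, anchors)
        assert np.nanmax(vl.norms[vl.defined]) == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_norm_small(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((10_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ens, core, anchors = orientation_mini(list(v))
        vl, _ = orientation_field(ens, core, anchors)
        assert np.nanmax(vl.norms[vl.defined]) < 0.03


class TestSpField:
    def field_with(self, vec):
        grid = CubeGrid(origin=(0, 0, 0), edge=3.0, shape=(1, 1, 1))
        vectors = np.array(vec, dtype=float).reshape(1, 1, 1, 3)
        return VectorField(
            grid=grid, vectors=vectors, occupancy=np.ones((1, 1, 1)),
            defined=np.ones((1, 1, 1), dtype=bool),
        )

    @pytest.mark.parametrize(
        "vec,expected", [([0.8, 0, 0], 1.0), ([-0.8, 0, 0], -1.0), ([0, 0.8, 0], 0.0)]
    )
    def test_parallel_antiparallel_perpendicular(self, vec, expected):
        field = sp_field(self.field_with(vec), np.array([1.0, 0.0, 0.0]))
        assert field.values[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_low_norm_flagged(self):
        field = sp_field(self.field_with([0.1, 0, 0]), np.array([1.0, 0.0, 0.0]))
        assert not field.defined[0, 0, 0]

    def test_unnormalized_reference_rejected(self):
        with pytest.raises(ValueError):
            sp_field(self.field_with([1, 0, 0]), np.array([2.0, 0.0, 0.0]))


def contact_records():
    lig = [
        ("O1", "O", 1, "LIG", "L", [0.0, 0.0, 0.0]),
        ("N1", "N", 1, "LIG", "L", [1.5, 0.0, 0.0]),
    ]
    rec = [
        ("NZ", "N", 182, "LYS", "R", [3.0, 0.0, 0.0]),
        ("NZ", "N", 273, "LYS", "R", [0.0, 3.0, 0.0]),
        ("NH1", "N", 343, "ARG", "R", [0.0, 0.0, 3.0]),
        ("NZ", "N", 185, "LYS", "R", [1.5, 3.0, 0.0]),
    ]
    return lig, rec


def contact_defs(ref):
    soo = ref.select("soo", chain="L", names=["O1"])
    n14 = ref.select("n14", chain="L", names=["N1"])
    return [
        NativeContactDef(soo, ref.select("a", chain="R", res_numbers=[182]), label="1"),
        NativeContactDef(soo, ref.select("b", chain="R", res_numbers=[273]), label="2"),
        NativeContactDef(soo, ref.select("c", chain="R", res_numbers=[343]), label="3"),
        NativeContactDef(n14, ref.select("d", chain="R", res_numbers=[185]), label="4"),
    ]


class TestNativeContactProfile:
    def test_all_contacts_everywhere(self):
        lig, rec = contact_records()
        ens = mini_ensemble(lig + rec, [{}, {}])
        profile = native_contact_profile(
            ens, contact_defs(ens.reference), ens.reference.select("lig", chain="L")
        )
        occupied = profile.defined
        np.testing.assert_allclose(profile.mean[occupied], 4.0)
        np.testing.assert_allclose(profile.sd[occupied], 0.0, atol=1e-12)

    def test_mixed_counts_mean_and_sd(self):
        lig, rec = contact_records()
        far = {s: [100.0 + s, 100.0, 100.0] for s in (7, 8, 9, 10)}
        # both snapshots share the ligand pose (same window); one loses all
        # four contacts
        ens = mini_ensemble(lig + rec, [{}, far])
        profile = native_contact_profile(
            ens, contact_defs(ens.reference), ens.reference.select("lig", chain="L")
        )
        k = int(np.nonzero(profile.defined)[0][0])
        assert profile.mean[k] == pytest.approx(2.0)
        assert profile.sd[k] == pytest.approx(2.0)

    def test_windows_are_quarter_angstrom(self):
        lig, rec = contact_records()
        ens = mini_ensemble(lig + rec, [{}])
        profile = native_contact_profile(
            ens, contact_defs(ens.reference), ens.reference.select("lig", chain="L")
        )
        assert profile.centers[0] == pytest.approx(0.25)
        assert np.diff(profile.centers)[0] == pytest.approx(0.5)


class TestRmsdDistributions:
    def test_reference_copies_all_mass_at_zero(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        ens = mini_ensemble(lig, [{}, {}, {}])
        dist = rmsd_distributions(ens, ens.reference.select("lig", chain="L"))
        assert dist.p_ddf[0] == pytest.approx(1.0)
        assert dist.p_rdf[0] == pytest.approx(1.0)

    def test_flat_ddf_gives_decreasing_rdf(self):
        lig = [("C1", "C", 1, "LIG", "L", [0.0, 0.0, 0.0])]
        bw = 0.25
        centers = np.arange(2.0 + bw / 2, 6.0, bw)
        edits = [{5: [c, 0.0, 0.0]} for c in centers]  # rmsd = displacement
        ens = mini_ensemble(lig, edits)
        dist = rmsd_distributions(ens, ens.reference.select("lig", chain="L"), bin_width=bw)
        occupied = dist.p_ddf > 0
        np.testing.assert_allclose(dist.p_ddf[occupied], dist.p_ddf[occupied][0], rtol=1e-9)
        rdf = dist.p_rdf[occupied]
        assert np.all(np.diff(rdf) < 0)  # monotone decreasing, peak at low edge
        ratio = rdf / rdf[0]
        expected = (dist.centers[occupied][0] / dist.centers[occupied]) ** 2
        np.testing.assert_allclose(ratio, expected, rtol=1e-9)


class TestNeutralFraction:
    def test_printed_value(self):
        assert round(100 * neutral_fraction(5.1, 7.4), 1) == 0.5

    def test_ph_equals_pka(self):
        assert neutral_fraction(6.0, 6.0) == pytest.approx(0.5)

    def test_alternate_pka(self):
        assert 100 * neutral_fraction(5.79, 7.4) == pytest.approx(2.40, abs=0.005)


class TestEnsembleInvariances:
    def test_weight_invariance_under_duplication(self, slice3_ensemble):
        ens, truth = slice3_ensemble
        sub = WeightedEnsemble(
            reference=ens.reference,
            positions=ens.positions[:500],
            weights=ens.weights[:500],
            align_group=ens.align_group,
            aligned=True,
        )
        dup = WeightedEnsemble(
            reference=ens.reference,
            positions=np.concatenate([sub.positions, sub.positions]),
            weights=np.concatenate([sub.weights, sub.weights]) / 2,
            align_group=ens.align_group,
            aligned=True,
        )
        lig = truth.groups["ligand"]
        grid = CubeGrid.from_points(sub.centroids(lig), edge=3.0, pad=2.0)
        f1 = density_field(sub, lig, grid=grid)
        f2 = density_field(dup, lig, grid=grid)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_rigid_motion_invariance(self, slice3_ensemble):
        from .conftest import random_rigid_transform

        ens, truth = slice3_ensemble
        sub_pos = ens.positions[:300]
        rng = np.random.default_rng(3)
        t = random_rigid_transform(rng)
        moved = WeightedEnsemble(
            reference=ens.reference.transformed(t),
            positions=sub_pos @ t.rotation.T + t.translation,
            weights=ens.weights[:300],
            align_group=ens.align_group,
        )
        base = WeightedEnsemble(
            reference=ens.reference,
            positions=sub_pos,
            weights=ens.weights[:300],
            align_group=ens.align_group,
        )
        lig = truth.groups["ligand"]
        np.testing.assert_allclose(moved.r_bb(lig), base.r_bb(lig), atol=1e-8)
        groups = [
            ens.reference.select("arg83", chain="A", res_numbers=[83]),
        ]
        p1 = residue_contact_pmf(base, lig, groups)
        p2 = residue_contact_pmf(moved, lig, groups)
        np.testing.assert_allclose(
            p1.probabilities, p2.probabilities, atol=1e-9
        )


class TestWriteDx:
    def test_round_trip_values(self, tmp_path):
        grid = CubeGrid(origin=(-3.0, 0.0, 3.0), edge=3.0, shape=(2, 2, 2))
        rng = np.random.default_rng(0)
        vals = rng.random((2, 2, 2))
        field = __import__("flycast.binding_analysis", fromlist=["ScalarField"]).ScalarField(
            grid=grid, values=vals, occupancy=np.ones((2, 2, 2)),
            defined=np.ones((2, 2, 2), dtype=bool),
        )
        path = tmp_path / "field.dx"
        write_dx(field, path)
        text = path.read_text()
        assert "object 1 class gridpositions counts 2 2 2" in text
        data = []
        for line in text.splitlines():
            parts = line.split()
            if parts and all(p.replace(".", "").replace("-", "").replace("e", "").replace("+", "").isdigit() for p in parts):
                try:
                    data.extend(float(p) for p in parts)
                except ValueError:
                    pass
        np.testing.assert_allclose(
            np.array(data[-8:]), vals.ravel(), rtol=1e-6
        )
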