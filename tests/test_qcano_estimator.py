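"""Canonical-density estimation: update, GA smoothing, convergence, weights."""

import numpy as np
import pytest

from flycast.qcano_estimator import (
    QSurface,
    e_local,
    ga_refine,
    physical_bin_edges,
    snapshot_weights,
    update_q,
    zone_bin_histograms,
)
from flycast.rc_zones import ZoneAxis, ZoneGrid
from flycast.synthetic_models import DoubleWell1D, boltzmann_marginal
from flycast.vcmd_engine import Snapshot


def grid1d(count=2, overlap=0.5, lo=0.0, hi=4.0):
    return ZoneGrid((ZoneAxis.uniform("x", lo, hi, count, overlap),))


def project_marginal(q, edges):
    centers = (edges[:-1] + edges[1:]) / 2
    dens = np.array([q.density_at([c]) for c in centers])
    return dens / dens.sum()


class TestQSurface:
    def test_uniform_is_normalized(self):
        q = QSurface.uniform(grid1d(3), 5)
        assert q.total == pytest.approx(1.0, abs=1e-12)

    def test_bin_index_and_volume(self):
        q = QSurface.uniform(grid1d(2), 4)
        lo, hi = q.grid.zone_box((0,))
        assert q.bin_index((0,), [lo[0] + 1e-9]) == (0,)
        assert q.bin_index((0,), [hi[0] - 1e-9]) == (3,)
        assert q.bin_volume((0,)) == pytest.approx((hi[0] - lo[0]) / 4)

    def test_negative_values_rejected(self):
        q = QSurface.uniform(grid1d(2), 4)
        vals = {z: v.copy() for z, v in q.values.items()}
        vals[(0,)][0] = -1.0
        with pytest.raises(ValueError):
            QSurface(q.grid, 4, vals)


class TestUpdateQ:
    def test_uniform_fixed_point(self):
        q = QSurface.uniform(grid1d(2), 4)
        hists = {z: np.full(4, 25.0) for z in q.grid.zones()}
        q1 = update_q(q, hists)
        for z in q.grid.zones():
            np.testing.assert_allclose(q1.values[z], q.values[z], atol=1e-12)

    def test_two_level_density_ratio_recovered(self):
        # zones sampled from an analytic two-level density: zone 0 twice as
        # dense as zone 1; counts proportional to the true density
        g = grid1d(2, 0.5, 0.0, 3.0)  # zones [0, 2] and [1, 3]
        q = QSurface.uniform(g, 4)
        # true density: 2 on [0, 1.5), 1 on [1.5, 3); zone bins are 0.5 wide
        true = lambda a, b: 2.0 * max(0, min(b, 1.5) - a) + 1.0 * max(0, b - max(a, 1.5))
        hists = {}
        for z in g.zones():
            e = q.bin_edges(z)[0]
            hists[z] = np.array([true(a, b) for a, b in zip(e[:-1], e[1:])]) * 1000
        q1 = update_q(q, hists)
        dens_left = q1.density_at([0.5])
        dens_right = q1.density_at([2.5])
        assert dens_left / dens_right == pytest.approx(2.0, rel=1e-6)

    def test_empty_zone_carries_previous(self):
        g = grid1d(3)
        q = QSurface.uniform(g, 4)
        hists = {z: np.full(4, 10.0) for z in g.zones()}
        hists[(2,)] = np.zeros(4)
        q1 = update_q(q, hists)
        ratio = q1.values[(2,)] / q.values[(2,)]
        np.testing.assert_allclose(ratio, ratio[0])  # shape preserved

    def test_repeated_update_converges_to_boltzmann(self):
        # multinomial counts drawn from the true zone-restricted canonical
        # shape; after 10 iterations the recovered marginal is within L1
        # 0.05 of quadrature
        pot = DoubleWell1D()
        g = ZoneGrid((ZoneAxis.uniform("x", -2.5, 2.5, 8, 0.75),))
        q = QSurface.uniform(g, 8)
        rng = np.random.default_rng(12)
        truth = {z: boltzmann_marginal(pot, q.bin_edges(z)[0]) for z in g.zones()}
        for _ in range(10):
            hists = {
                z: rng.multinomial(100_000 // g.n_zones, truth[z]).astype(float)
                for z in g.zones()
            }
            q = update_q(q, hists)
        edges = physical_bin_edges(q)[0]
        quad = boltzmann_marginal(pot, edges)
        l1 = float(np.abs(project_marginal(q, edges) - quad).sum())
        assert l1 < 0.05


class TestGaRefine:
    def smooth_surface(self):
        g = grid1d(3, 0.5, 0.0, 6.0)
        q = QSurface.uniform(g, 8)
        for z in g.zones():
            c = q.bin_centers(z)[0]
            q.values[z] = np.exp(-0.5 * (c - 3.0) ** 2)
        return q.normalized()

    def test_continuous_surface_unchanged(self):
        q = self.smooth_surface()
        out = ga_refine(q, generations=30, rng=0)
        for z in q.grid.zones():
            np.testing.assert_allclose(out.values[z], q.values[z], rtol=1e-9)

    def test_step_discontinuity_repaired(self):
        q = self.smooth_surface()
        broken = q.copy()
        broken.values[(2,)] = broken.values[(2,)] * 10.0  # factor-10 step
        broken = broken.normalized()

        def mismatch(s):
            total = 0.0
            for za, zb in [((0,), (1,)), ((1,), (2,))]:
                ma, mb = s.overlap_bin_masks(za, zb)
                da = np.log(s.values[za][ma].mean() / s.bin_volume(za))
                db = np.log(s.values[zb][mb].mean() / s.bin_volume(zb))
                total += (da - db) ** 2
            return total

        before = mismatch(broken)
        out = ga_refine(broken, rng=0)
        after = mismatch(out)
        assert after <= before / 10.0

    def test_deterministic_given_seed(self):
        q = self.smooth_surface()
        broken = q.copy()
        broken.values[(0,)] *= 3.0
        a = ga_refine(broken.normalized(), rng=42)
        b = ga_refine(broken.normalized(), rng=42)
        for z in q.grid.zones():
            np.testing.assert_array_equal(a.values[z], b.values[z])


class TestELocal:
    def test_identical_surfaces_all_converged(self):
        q = QSurface.uniform(grid1d(3), 4)
        report = e_local(q, q)
        assert all(v == 0.0 for v in report.e_local.values())
        assert report.all_converged

    def test_uniform_log_shift(self):
        q = QSurface.uniform(grid1d(3), 4)
        shifted = q.copy()
        for z in q.grid.zones():
            shifted.values[z] = q.values[z] * np.exp(0.5)
        report = e_local(shifted, q)
        for v in report.e_local.values():
            assert v == pytest.approx(0.5, abs=1e-12)
        assert report.converged_zones == 0

    def test_random_perturbation_matches_direct_recomputation(self):
        rng = np.random.default_rng(8)
        q = QSurface.uniform(grid1d(2), 6)
        pert = q.copy()
        deltas = {}
        for z in q.grid.zones():
            d = rng.normal(0, 0.3, q.values[z].shape)
            pert.values[z] = q.values[z] * np.exp(d)
            deltas[z] = d
        report = e_local(pert, q)
        for z in q.grid.zones():
            assert report.e_local[z] == pytest.approx(np.mean(np.abs(deltas[z])), abs=1e-9)

    def test_binning_mismatch_errors(self):
        with pytest.raises(ValueError):
            e_local(QSurface.uniform(grid1d(2), 4), QSurface.uniform(grid1d(2), 5))

    def test_overlap_mode_flags_inconsistent_scales(self):
        q = QSurface.uniform(grid1d(2), 4)
        assert e_local(q, q, mode="overlap").all_converged
        stepped = q.copy()
        stepped.values[(1,)] = stepped.values[(1,)] * 10.0
        report = e_local(stepped.normalized(), q, mode="overlap")
        assert all(v == pytest.approx(np.log(10.0)) for v in report.e_local.values())


def make_snaps(xs, zones):
    return [
        Snapshot(iteration=1, run=i, step=1, lam=[x], zone=z, state=np.array([x]))
        for i, (x, z) in enumerate(zip(xs, zones))
    ]


class TestSnapshotWeights:
    def test_uniform_everything_gives_equal_weights(self):
        g = grid1d(2, 0.5, 0.0, 4.0)
        q = QSurface.uniform(g, 4)
        edges = physical_bin_edges(q)[0]
        centers = (edges[:-1] + edges[1:]) / 2
        # exactly uniform sampled marginal: equal counts in every bin
        xs = np.repeat(centers, 10)
        zones = [sorted(g.membership([x]))[0] for x in xs]
        w = snapshot_weights(make_snaps(xs, zones), q, edges=[edges])
        assert w.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(w, 1.0 / len(xs), rtol=1e-9)

    def test_two_bin_ratio(self):
        # q masses (2/3, 1/3) over two physical bins with equal sample
        # counts: per-snapshot weights in ratio 2:1
        g = ZoneGrid((ZoneAxis("x", ((0.0, 1.0), (0.5, 1.5))),))
        q = QSurface(g, 1, {(0,): np.array([2 / 3]), (1,): np.array([1 / 3])})
        xs = [0.25] * 100 + [1.25] * 100
        zones = [(0,)] * 100 + [(1,)] * 100
        edges = [np.array([0.0, 0.75, 1.5])]
        w = snapshot_weights(make_snaps(xs, zones), q, edges=edges)
        assert w[0] / w[-1] == pytest.approx(2.0, rel=1e-9)

    def test_reweighting_identity_on_unbiased_sample(self):
        # sampling marginal equal to q itself -> uniform weights up to noise
        pot = DoubleWell1D()
        g = ZoneGrid((ZoneAxis.uniform("x", -2.5, 2.5, 8, 0.75),))
        q = QSurface.uniform(g, 8)
        truth = {z: boltzmann_marginal(pot, q.bin_edges(z)[0]) for z in g.zones()}
        rng = np.random.default_rng(5)
        hists = {z: rng.multinomial(200_000 // g.n_zones, truth[z]).astype(float) for z in g.zones()}
        q = update_q(q, hists)
        # draw snapshots from q's own physical marginal
        edges = physical_bin_edges(q)[0]
        centers = (edges[:-1] + edges[1:]) / 2
        p = project_marginal(q, edges)
        counts = rng.multinomial(50_000, p)
        xs, zones = [], []
        for c, n in zip(centers, counts):
            for _ in range(n):
                xs.append(c)
                zones.append(sorted(g.membership([c]))[0])
        w = snapshot_weights(make_snaps(xs, zones), q, edges=[edges])
        assert w.std() / w.mean() < 0.05


class TestZoneBinHistograms:
    def test_out_of_box_snapshots_discarded(self):
        g = grid1d(2, 0.5, 0.0, 4.0)
        q = QSurface.uniform(g, 4)
        snaps = make_snaps([0.5, 3.5], [(0,), (0,)])  # 3.5 outside zone 0 box
        hists = zone_bin_histograms(snaps, q)
        assert hists[(0,)].sum() == 1
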