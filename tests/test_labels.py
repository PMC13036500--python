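"""Spin-label cloud models and forward prediction of restraints."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from flexens import labels, nmr
from flexens.io_formats import ConformerEnsemble

OMEGA = 2 * np.pi * 700e6
TAU = 11e-9


def point_ensemble(positions):
    """One CA atom per residue at the given (C, R, 3) positions."""
    positions = np.asarray(positions, dtype=float)
    c, r, _ = positions.shape
    return ConformerEnsemble(
        names=np.full(r, "CA", dtype=object),
        residue_ids=np.arange(1, r + 1),
        chain_ids=np.full(r, "A", dtype=object),
        elements=np.full(r, "C", dtype=object),
        coords=positions,
    )


def point_site(site_id, residue, positions):
    """Single-point label clouds at explicit positions (C, 3)."""
    positions = np.asarray(positions, dtype=float)[:, None, :]
    return labels.LabelSite(
        site_id, residue, "point", positions, np.ones(positions.shape[:2])
    )


class TestAttachLabel:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.ens = point_ensemble(rng.uniform(-10, 10, size=(2, 6, 3)))

    def test_unknown_model_lists_registered(self):
        with pytest.raises(ValueError, match="gauss_cloud"):
            labels.attach_label(self.ens.conformer(0), 1, model="nope")

    def test_seeding_is_deterministic(self):
        a, _ = labels.attach_label(self.ens.conformer(0), 2, seed=9)
        b, _ = labels.attach_label(self.ens.conformer(0), 2, seed=9)
        assert np.array_equal(a, b)

    def test_cloud_centred_near_offset_position(self):
        pts, w = labels.attach_label(self.ens.conformer(0), 2, seed=3)
        conf = self.ens.conformer(0)
        ca = conf.coords[conf.atom_index(2, "CA")]
        d = np.linalg.norm(pts.mean(axis=0) - ca)
        # mean of 64 points, sigma 2.5: within 3 sigma/sqrt(64) of 7 Å
        assert abs(d - 7.0) < 3 * 2.5 / 8
        assert w.sum() == pytest.approx(1.0)

    def test_point_model_at_exact_offset(self):
        pts, w = labels.attach_label(self.ens.conformer(0), 2, model="point", seed=0)
        conf = self.ens.conformer(0)
        ca = conf.coords[conf.atom_index(2, "CA")]
        assert pts.shape == (1, 3)
        assert np.linalg.norm(pts[0] - ca) == pytest.approx(7.0, abs=1e-9)

    def test_subset_keeps_parent_clouds(self):
        site_full = labels.build_site(self.ens, "s", 2, seed=5)
        sub = self.ens.subset([1])
        site_sub = labels.build_site(sub, "s", 2, seed=5)
        assert np.allclose(site_full.points[1], site_sub.points[0])


class TestCloudCentroid:
    def test_symmetric_two_point_cloud(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        cen = labels.cloud_centroid(pts, np.array([0.5, 0.5]), np.array([[5.0, 0, 0]]))
        assert np.allclose(cen.centroid, [1.0, 0, 0])
        assert cen.anchor_distances[0] == pytest.approx(4.0)

    def test_single_point_identity(self):
        pts = np.array([[1.0, 2.0, 3.0]])
        cen = labels.cloud_centroid(pts, np.array([1.0]), np.array([[1.0, 2.0, 7.0]]))
        assert np.allclose(cen.centroid, pts[0])
        assert cen.anchor_distances[0] == pytest.approx(4.0)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(64, 3))
        w = rng.uniform(0.5, 1.5, 64)
        w /= w.sum()
        anchors = rng.normal(size=(7, 3)) * 5
        cen = labels.cloud_centroid(pts, w, anchors)
        brute = np.sum(w[:, None] * pts, axis=0)
        assert np.allclose(cen.centroid, brute, atol=1e-12)
        assert np.allclose(
            cen.anchor_distances, np.linalg.norm(anchors - brute, axis=1), atol=1e-9
        )

    def test_placement_verification_tolerance(self):
        anchors = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        target = np.array([2.0, 2.0])
        centre = np.array([2.0, np.sqrt(4 - 4), 0.0])  # exactly consistent
        labels.verify_placement(centre, anchors, target, tol=0.2)
        with pytest.raises(ValueError, match="deviates"):
            labels.verify_placement(centre + [0.5, 0, 0], anchors, target, tol=0.2)

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            labels.cloud_centroid(
                np.zeros((1, 3)), np.ones(1), np.empty((0, 3))
            )


class TestPredictDistanceDistribution:
    grid = np.arange(10.0, 60.0, 0.5)

    def test_single_pair_gives_kernel_gaussian(self):
        ens = point_ensemble(np.zeros((1, 2, 3)))
        sa = point_site("a", 1, [[0.0, 0, 0]])
        sb = point_site("b", 2, [[30.0, 0, 0]])
        dist = labels.predict_distance_distribution(ens, sa, sb, self.grid, 1.0)
        assert dist.mean() == pytest.approx(30.0, abs=1e-6)
        assert dist.std() == pytest.approx(1.0, abs=1e-3)

    def test_two_conformer_mixture_mass_split(self):
        ens = point_ensemble(np.zeros((2, 2, 3)))
        sa = point_site("a", 1, [[0, 0, 0], [0, 0, 0]])
        sb = point_site("b", 2, [[25.0, 0, 0], [45.0, 0, 0]])
        dist = labels.predict_distance_distribution(ens, sa, sb, self.grid, 1.0)
        masses = dist.masses()
        below = masses[dist.grid < 35].sum()
        assert below == pytest.approx(0.5, abs=1e-6)

    def test_mean_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(3)
        ens = point_ensemble(rng.uniform(-5, 5, size=(2, 4, 3)))
        site_a = labels.build_site(ens, "a", 1, seed=1)
        site_b = labels.build_site(ens, "b", 3, seed=2)
        grid = np.arange(0.0, 80.0, 0.25)
        dist = labels.predict_distance_distribution(ens, site_a, site_b, grid, 1.0)
        brute = 0.0
        for c in range(2):
            d = cdist(site_a.points[c], site_b.points[c]).ravel()
            w = np.outer(site_a.point_weights[c], site_b.point_weights[c]).ravel()
            brute += ens.weights[c] * np.sum(w * d)
        assert dist.mean() == pytest.approx(brute, abs=1e-3)

    def test_mass_is_conserved(self):
        rng = np.random.default_rng(4)
        ens = point_ensemble(rng.uniform(-5, 5, size=(3, 4, 3)))
        site_a = labels.build_site(ens, "a", 1, seed=1)
        site_b = labels.build_site(ens, "b", 4, seed=2)
        grid = np.arange(0.0, 80.0, 0.5)
        dens = labels.per_conformer_distributions(site_a, site_b, grid, 1.0)
        for row in dens:
            assert np.trapezoid(row, grid) == pytest.approx(1.0, abs=1e-6)

    def test_narrow_grid_rejected(self):
        ens = point_ensemble(np.zeros((1, 2, 3)))
        sa = point_site("a", 1, [[0.0, 0, 0]])
        sb = point_site("b", 2, [[70.0, 0, 0]])
        with pytest.raises(ValueError, match="widen"):
            labels.predict_distance_distribution(ens, sa, sb, self.grid, 1.0)

    def test_rigid_body_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        base = rng.uniform(-5, 5, size=(1, 4, 3))
        rot = Rotation.from_rotvec([0.3, -1.0, 0.7])
        moved = rot.apply(base[0]) + np.array([5.0, -3.0, 2.0])
        grid = np.arange(0.0, 80.0, 0.5)
        results = []
        for coords in (base, moved[None]):
            ens = point_ensemble(coords)
            # transform the clouds with the conformer (same relative geometry)
            sa = labels.build_site(ens, "a", 1, seed=1)
            sb = labels.build_site(ens, "b", 4, seed=2)
            if coords is not base:
                sa = labels.LabelSite(
                    "a", 1, "gauss_cloud",
                    (rot.apply(base_sa.points[0]) + np.array([5.0, -3.0, 2.0]))[None],
                    base_sa.point_weights,
                )
                sb = labels.LabelSite(
                    "b", 4, "gauss_cloud",
                    (rot.apply(base_sb.points[0]) + np.array([5.0, -3.0, 2.0]))[None],
                    base_sb.point_weights,
                )
            else:
                base_sa, base_sb = sa, sb
            results.append(
                labels.predict_distance_distribution(ens, sa, sb, grid, 1.0)
            )
        assert np.allclose(results[0].density, results[1].density, atol=1e-9)


class TestPredictPre:
    def test_single_point_cloud_inverts_distance_conversion(self):
        r = nmr.gamma2_to_distance(100.0, TAU, OMEGA)
        ens = point_ensemble([[[0, 0, 0], [r, 0, 0]]])
        site = point_site("s", 1, [[0.0, 0, 0]])
        out = labels.predict_pre(ens, site, [2], TAU, OMEGA)
        assert out[0] == pytest.approx(100.0, rel=1e-6)

    def test_weighted_mean_over_conformers(self):
        r40 = nmr.gamma2_to_distance(40.0, TAU, OMEGA)
        r80 = nmr.gamma2_to_distance(80.0, TAU, OMEGA)
        ens = point_ensemble([[[0, 0, 0], [r40, 0, 0]], [[0, 0, 0], [r80, 0, 0]]])
        ens = ens.with_weights(np.array([0.25, 0.75]))
        site = point_site("s", 1, [[0.0, 0, 0], [0.0, 0, 0]])
        out = labels.predict_pre(ens, site, [2], TAU, OMEGA)
        assert out[0] == pytest.approx(70.0, rel=1e-6)

    def test_single_conformer_rate_clipped_at_cap(self):
        r500 = nmr.gamma2_to_distance(500.0, TAU, OMEGA)
        ens = point_ensemble([[[0, 0, 0], [r500, 0, 0]]])
        site = point_site("s", 1, [[0.0, 0, 0]])
        out = labels.predict_pre(ens, site, [2], TAU, OMEGA, cap=170.0)
        assert out[0] == pytest.approx(170.0)

    def test_effective_distance_uses_r6_weighting(self):
        ens = point_ensemble([[[0, 0, 0], [0, 0, 0]]])
        pts = np.array([[[10.0, 0, 10.0], [30.0, 0, 10.0]]])
        site = labels.LabelSite("s", 1, "point", pts, np.full((1, 2), 0.5))
        out = labels.per_conformer_pre(ens, site, [2], TAU, OMEGA, cap=None)
        d = np.linalg.norm(pts[0], axis=1)
        r_eff = (0.5 * d[0] ** -6 + 0.5 * d[1] ** -6) ** (-1 / 6)
        assert out[0, 0] == pytest.approx(
            nmr.distance_to_gamma2(r_eff, TAU, OMEGA), rel=1e-9
        )

    def test_label_on_target_rejected(self):
        ens = point_ensemble(np.zeros((1, 1, 3)))
        site = point_site("s", 1, [[0.0, 0, 0]])
        with pytest.raises(ValueError, match="coincides"):
            labels.predict_pre(ens, site, [1], TAU, OMEGA)
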