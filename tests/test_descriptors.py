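"""Ensemble descriptors: R_g, dRMSD, disorder parameter, contacts, poses,
merged-pool clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flexens import descriptors as dsc
from flexens import synthetic as syn
from flexens.io_formats import ConformerEnsemble


def ca_ensemble(coords, weights=None):
    coords = np.asarray(coords, dtype=float)
    c, r, _ = coords.shape
    return ConformerEnsemble(
        names=np.full(r, "CA", dtype=object),
        residue_ids=np.arange(1, r + 1),
        chain_ids=np.full(r, "A", dtype=object),
        elements=np.full(r, "C", dtype=object),
        coords=coords,
        weights=weights,
    )


class TestRadiusOfGyration:
    def test_single_point_conformers(self):
        ens = ca_ensemble(np.zeros((3, 1, 3)))
        assert dsc.radius_of_gyration(ens) == 0.0

    def test_weighted_rms_combination(self):
        # conformers with per-conformer Rg 3 and 4 combine to sqrt(12.5)
        line3 = np.array([[-3.0, 0, 0], [3.0, 0, 0]])  # Rg 3
        line4 = np.array([[-4.0, 0, 0], [4.0, 0, 0]])  # Rg 4
        ens = ca_ensemble([line3, line4])
        assert dsc.per_conformer_rg(ens) == pytest.approx([3.0, 4.0])
        assert dsc.radius_of_gyration(ens) == pytest.approx(np.sqrt(12.5))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(1, 8, 3))
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).apply(base[0]) + 4.0
        assert dsc.radius_of_gyration(ca_ensemble(base)) == pytest.approx(
            dsc.radius_of_gyration(ca_ensemble(rot[None])), rel=1e-12
        )

    def test_no_ca_atoms_rejected(self):
        ens = ca_ensemble(np.zeros((1, 2, 3)))
        ens.names[:] = "P"
        with pytest.raises(ValueError, match="CA"):
            dsc.radius_of_gyration(ens)


class TestDrmsd:
    def test_identical_conformers_give_zeros(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 5, 3)), (3, 1, 1))
        d = dsc.drmsd_matrix(ca_ensemble(coords))
        assert np.allclose(d, 0.0)

    def test_rigid_body_move_gives_zero(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 3))
        moved = Rotation.from_rotvec([0.4, 0.4, 0.4]).apply(base) + 7.0
        d = dsc.drmsd_matrix(ca_ensemble([base, moved]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_three_atom_hand_enumeration(self):
        a = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4.0, 0]])
        b = np.array([[0.0, 0, 0], [5.0, 0, 0], [0.0, 4.0, 0]])
        # pair distances a: (3, 4, 5); b: (5, 4, sqrt(41))
        expected = np.sqrt(((3 - 5) ** 2 + 0.0 + (5 - np.sqrt(41)) ** 2) / 3)
        d = dsc.drmsd_matrix(ca_ensemble([a, b]))
        assert d[0, 1] == pytest.approx(expected, rel=1e-12)
        assert d[1, 0] == d[0, 1] and d[0, 0] == 0.0


class TestDisorderParameter:
    def test_identical_conformers_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 5, 3)), (4, 1, 1))
        _, delta = dsc.disorder_parameter(ca_ensemble(coords))
        assert delta == 0.0

    def test_equilateral_triple_circumradius(self):
        # three conformers with all pairwise D_kl equal to a embed as an
        # equilateral triangle: weighted Rg of the point set is a/sqrt(3)
        a = 2.4
        d = np.array([[0, a, a], [a, 0, a], [a, a, 0]], dtype=float)
        ens = ca_ensemble(np.random.default_rng(1).normal(size=(3, 4, 3)))
        rg_acs, _ = dsc.disorder_parameter(ens, drmsd=d)
        assert rg_acs == pytest.approx(a / np.sqrt(3), rel=1e-9)

    def test_embedding_reproduces_distances_when_psd(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 3))  # genuine Euclidean configuration
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        c = d.shape[0]
        j = np.eye(c) - np.full((c, c), 1 / c)
        b = -0.5 * j @ (d**2) @ j
        evals, evecs = np.linalg.eigh(b)
        coords = evecs * np.sqrt(np.clip(evals, 0, None))
        d_back = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(d_back, d, atol=1e-6)

    def test_rigid_versus_broad_pool_ordering(self, disorder_pools):
        rigid, broad = disorder_pools
        _, delta_rigid = dsc.disorder_parameter(rigid)
        _, delta_broad = dsc.disorder_parameter(broad)
        assert delta_rigid < 0.15
        assert delta_broad > 0.35

    def test_rotation_translation_invariance(self, disorder_pools):
        rigid, _ = disorder_pools
        moved = rigid.coords.copy()
        rot = Rotation.from_rotvec([0.2, 1.0, -0.3])
        for c in range(moved.shape[0]):
            moved[c] = rot.apply(moved[c]) + np.array([10.0, -5.0, 3.0])
        ens2 = ca_ensemble(moved, weights=rigid.weights)
        _, d1 = dsc.disorder_parameter(rigid)
        _, d2 = dsc.disorder_parameter(ens2)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestContactMap:
    def two_residue_ensemble(self, separations, weights=None):
        coords = np.array(
            [[[0.0, 0, 0], [s, 0.0, 0.0]] for s in separations]
        )
        return ca_ensemble(coords, weights)

    def test_count_fraction_with_uniform_weights(self):
        seps = [2.5] * 4 + [50.0] * 136  # 4 of 140 conformers in contact
        ens = self.two_residue_ensemble(seps)
        fractions, _ = dsc.contact_map(ens, [1], [2], cutoff=3.0)
        assert fractions[(1, 2)] == pytest.approx(4 / 140)
        assert dsc.format_contact_percent(fractions[(1, 2)]) == "2.9 %"

    def test_weighted_fraction(self):
        ens = self.two_residue_ensemble([2.0, 50.0], weights=np.array([0.3, 0.7]))
        fractions, per_res = dsc.contact_map(ens, [1], [2])
        assert fractions[(1, 2)] == pytest.approx(0.3)
        assert per_res[1] == pytest.approx(0.3)

    def test_scaling_removes_contacts(self):
        ens = self.two_residue_ensemble([2.5, 2.9])
        doubled = ca_ensemble(ens.coords * 2.0)
        assert dsc.contact_map(ens, [1], [2])[0] != {}
        assert dsc.contact_map(doubled, [1], [2])[0] == {}

    def test_empty_group_rejected(self):
        ens = self.two_residue_ensemble([2.0])
        with pytest.raises(ValueError):
            dsc.contact_map(ens, [], [2])


class TestBindingPose:
    def test_threshold_boundaries(self):
        conf = ca_ensemble(np.array([[[0.0, 0, 0], [7.4, 0, 0]]])).conformer(0)
        dmin, ok = dsc.binding_pose_check(conf, [0], [1])
        assert dmin == pytest.approx(7.4) and ok
        conf = ca_ensemble(np.array([[[0.0, 0, 0], [7.6, 0, 0]]])).conformer(0)
        _, ok = dsc.binding_pose_check(conf, [0], [1])
        assert not ok

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-20, 20, size=(1, 12, 3))
        conf = ca_ensemble(coords).conformer(0)
        motif, domain = [0, 1, 2], [5, 8, 11]
        dmin, _ = dsc.binding_pose_check(conf, motif, domain)
        brute = min(
            np.linalg.norm(conf.coords[i] - conf.coords[j])
            for i in motif for j in domain
        )
        assert dmin == pytest.approx(brute, rel=1e-12)

    def test_ensemble_summary_counts_joint_passes(self):
        coords = np.array(
            [
                [[0.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0], [0, 0, 5.0]],
                [[0.0, 0, 0], [50.0, 0, 0], [0, 5.0, 0], [0, 0, 5.0]],
            ]
        )
        ens = ca_ensemble(coords)
        count, weight = dsc.ensemble_pose_summary(ens, [0], [1], [2], [3])
        assert count == 1 and weight == pytest.approx(0.5)


class TestMergedClusters:
    def test_identical_sources_fully_mixed(self, toy_spec):
        pool = syn.build_pool(toy_spec, 24, seed=3)
        report = dsc.merged_cluster_analysis(pool, pool, mean_cluster_size=12)
        assert report.class_fractions["A"]["mixed"] == pytest.approx(1.0)
        assert report.class_fractions["B"]["mixed"] == pytest.approx(1.0)

    def test_disjoint_islands_have_no_mixed_clusters(self, toy_spec):
        a = syn.build_rigid_jitter_pool(toy_spec, 12, seed=1, jitter_sigma=0.2)
        b = syn.build_rigid_jitter_pool(toy_spec, 12, seed=99, jitter_sigma=0.2)
        report = dsc.merged_cluster_analysis(a, b, mean_cluster_size=12)
        assert report.class_fractions["A"]["mixed"] == pytest.approx(0.0)
        assert report.class_fractions["B"]["mixed"] == pytest.approx(0.0)

    def test_default_mean_cluster_size_is_12(self):
        import inspect

        sig = inspect.signature(dsc.merged_cluster_analysis)
        assert sig.parameters["mean_cluster_size"].default == 12

    def test_fractions_normalized_per_source(self, toy_spec):
        a = syn.build_pool(toy_spec, 18, seed=3)
        b = syn.build_pool(toy_spec, 18, seed=4)
        report = dsc.merged_cluster_analysis(a, b, mean_cluster_size=6)
        for src in ("A", "B"):
            total = sum(report.class_fractions[src].values())
            assert total == pytest.approx(1.0, abs=1e-9)
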