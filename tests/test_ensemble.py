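"""Radius of gyration, Kabsch RMSD, free-energy surfaces and helix
propensities on synthetic ensembles."""

import numpy as np
import numpy.ma as ma
import pytest

from p53mdm2.ensemble import (Ensemble, build_fes, helix_propensity,
                              radius_of_gyration, rmsd_to_reference)
from p53mdm2.geometry import backbone_dihedrals, build_backbone, ideal_helix
from p53mdm2.synthetic import GroundTruth, Kind, generate_ensemble


def rigid_motion(coords, seed=0):
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0, 5.0, 3)
    return coords @ R.T + t


class TestRadiusOfGyration:
    def test_two_point_formula(self):
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(frame) == pytest.approx(1.5)

    def test_coincident_atoms(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_ring_equals_radius(self):
        # brute-force centroid oracle: N points on a circle of radius r
        r, n = 2.5, 17
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ring = np.stack([r * np.cos(ang), r * np.sin(ang),
                         np.zeros(n)], axis=1)
        centered = ring - ring.mean(axis=0)
        brute = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
        assert radius_of_gyration(ring) == pytest.approx(r, rel=1e-12)
        assert radius_of_gyration(ring) == pytest.approx(brute)

    def test_single_atom_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((1, 3)))


class TestRmsd:
    def test_identity(self):
        helix = ideal_helix(10)
        assert rmsd_to_reference(helix, helix) == pytest.approx(0.0,
                                                                abs=1e-12)

    def test_rigid_motion_invariance(self):
        helix = ideal_helix(10)
        moved = rigid_motion(helix, seed=3)
        assert rmsd_to_reference(moved, helix) == pytest.approx(0.0,
                                                                abs=1e-9)

    def test_two_point_closed_form(self):
        # two-atom frames with internal distances d1, d2: optimal
        # superposition leaves |d1 - d2| / 2
        d1, d2 = 3.0, 1.4
        a = np.array([[0.0, 0, 0], [d1, 0, 0]])
        b = np.array([[0.0, 0, 0], [0, d2, 0]])
        assert rmsd_to_reference(a, b) == pytest.approx(abs(d1 - d2) / 2,
                                                        rel=1e-9)

    def test_mismatched_atoms_rejected(self):
        with pytest.raises(ValueError):
            rmsd_to_reference(np.zeros((4, 3)), np.zeros((5, 3)))


def make_ensemble(helix_prob, n_frames, seed=0, n_res=13):
    truth = GroundTruth(Kind.ENSEMBLE, {"helix_prob": helix_prob}, 0.0,
                        seed)
    return generate_ensemble(truth, n_frames, n_res)


class TestBuildFes:
    def test_populations_sum_to_one(self):
        ens = make_ensemble(0.5, 300)
        grid = build_fes(ens, 20, 20)
        assert grid.populations.sum() == pytest.approx(1.0)

    def test_uniform_population_is_flat(self):
        # equally populated bins -> FES exactly 0 on every occupied bin
        coords = np.zeros((40, 2, 3))
        coords[:, 1, 0] = np.repeat(np.linspace(1.0, 2.0, 4), 10)
        ref = coords[0]
        ens = Ensemble(coords, ["CA", "CA"], reference=ref)
        with pytest.warns(UserWarning):
            grid = build_fes(ens, 4, 1)
        occupied = ~grid.free_energy.mask
        assert np.allclose(grid.free_energy[occupied], 0.0)

    def test_two_cluster_log_ratio(self):
        # 90%/10% clusters: FES gap = ln 9
        coords = np.zeros((200, 2, 3))
        coords[:20, 1, 0] = 2.0
        coords[20:, 1, 0] = 1.0
        ens = Ensemble(coords, ["CA", "CA"], reference=coords[-1])
        grid = build_fes(ens, 2, 1)
        vals = np.sort(grid.free_energy.compressed())
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(np.log(9.0), rel=1e-12)

    def test_empty_bins_masked_not_numeric(self):
        ens = make_ensemble(0.5, 200)
        grid = build_fes(ens, 30, 30)
        assert ma.isMaskedArray(grid.free_energy)
        assert grid.free_energy.mask.any()

    def test_rigid_motion_invariance(self):
        ens = make_ensemble(0.5, 150, seed=2)
        moved = Ensemble(
            np.stack([rigid_motion(f, seed=i)
                      for i, f in enumerate(ens.coords)]),
            ens.atom_names, reference=ens.reference)
        g0 = build_fes(ens, 15, 15)
        g1 = build_fes(moved, 15, 15)
        assert np.allclose(g0.populations, g1.populations)
        assert np.allclose(g0.rmsd_edges, g1.rmsd_edges)

    def test_frame_duplication_leaves_fes_unchanged(self):
        ens = make_ensemble(0.5, 120, seed=4)
        doubled = Ensemble(np.concatenate([ens.coords, ens.coords]),
                           ens.atom_names, reference=ens.reference)
        g0 = build_fes(ens, 12, 12)
        g1 = build_fes(doubled, 12, 12)
        assert np.allclose(g0.populations, g1.populations)
        assert np.allclose(g0.free_energy.filled(-1.0),
                           g1.free_energy.filled(-1.0))

    def test_brute_force_histogram_equivalence(self):
        from p53mdm2.ensemble import order_parameters
        ens = make_ensemble(0.4, 250, seed=9)
        grid = build_fes(ens, 10, 10)
        rmsd, rg = order_parameters(ens)
        counts = np.zeros((10, 10))
        for x, y in zip(rmsd, rg):
            i = min(np.searchsorted(grid.rmsd_edges, x, side="right") - 1, 9)
            j = min(np.searchsorted(grid.rg_edges, y, side="right") - 1, 9)
            counts[i, j] += 1
        assert np.allclose(grid.populations, counts / counts.sum())


class TestHelixPropensity:
    def test_ideal_helix_is_fully_helical(self):
        ens = make_ensemble(1.0, 5)
        prop = helix_propensity(ens)
        assert np.isnan(prop[0]) and np.isnan(prop[-1])
        assert np.allclose(prop[1:-1], 1.0)

    def test_extended_conformation_scores_zero(self):
        coords = build_backbone(np.full(8, -135.0), np.full(8, 135.0))
        ens = Ensemble(coords[None, :, :], ["N", "CA", "C"] * 8)
        prop = helix_propensity(ens)
        assert np.allclose(prop[1:-1], 0.0)

    def test_prescribed_probability_recovered(self):
        # binomial oracle: 2000 frames at p=0.5 -> 0.5 +/- ~3 SE
        hp = np.zeros(13)
        hp[6] = 0.5
        ens = make_ensemble(hp, 2000, seed=11)
        prop = helix_propensity(ens)
        assert prop[6] == pytest.approx(0.5, abs=0.03)
        assert np.allclose(np.delete(prop[1:-1], 5), 0.0)

    def test_ensemble_matches_generator_mask(self):
        # the dihedral-window assignment agrees with the generator's own
        # record of which residue-frames were drawn helical
        ens = make_ensemble(0.5, 100, seed=3)
        mask = ens.meta["helical_mask"]
        for k, frame in enumerate(ens.coords[:10]):
            phi, psi = backbone_dihedrals(frame)
            for i in range(1, 12):
                helical = (-100 <= phi[i] <= -30) and (-67 <= psi[i] <= -7)
                assert helical == mask[k, i]


class TestGeometryRoundTrip:
    def test_dihedrals_round_trip_through_coordinates(self):
        rng = np.random.default_rng(8)
        phi = rng.uniform(-170, -40, 9)
        psi = rng.uniform(-60, 170, 9)
        coords = build_backbone(phi, psi)
        phi2, psi2 = backbone_dihedrals(coords)
        assert np.allclose(phi[1:], phi2[1:], atol=1e-8)
        assert np.allclose(psi[:-1], psi2[:-1], atol=1e-8)

    def test_determinism(self):
        a = make_ensemble(0.5, 10, seed=42)
        b = make_ensemble(0.5, 10, seed=42)
        assert np.array_equal(a.coords, b.coords)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            make_ensemble(0.5, 5, n_res=2)
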