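"""Ensemble analytics: assignment, DCC, contacts, helicity, RMSD/ΔRMSF."""

import math

import numpy as np
import pytest

from funnelmd.ensembles import (LabeledEnsemble, assign_frames,
                                backbone_dihedrals, ca_distance_stats,
                                contact_occupancy, dcc_map, delta_rmsf,
                                helicity, rmsf, superpose,
                                superpose_ensemble_to_mean)
from funnelmd.fes import Basin
from funnelmd.synth import PlantedEnsembleSpec, make_ensemble


def _basin(label, loc, depth, extent, value=0.0):
    return Basin(label=label, location=loc, depth=depth,
                 extent=np.asarray(extent, float), value=value,
                 grid_index=(0,))


def _apply_rigid(ens, rng, random_rigid_transform):
    coords = ens.coords.copy()
    for k in range(ens.n_frames):
        rot, trans = random_rigid_transform(rng)
        coords[k] = coords[k] @ rot.T + trans
    return LabeledEnsemble(atoms=ens.atoms, coords=coords,
                           weights=ens.weights)


class TestAssignFrames:
    B1 = _basin("Minimum 1", (0.5, 100.0), 10.0,
                [[0.3, 0.8], [50.0, 150.0]], value=0.0)
    B2 = _basin("Minimum 2", (1.5, 20.0), 5.0,
                [[1.2, 1.9], [0.0, 60.0]], value=4.0)

    def test_point_at_minimum_assigned(self):
        assert assign_frames([(0.5, 100.0)], [self.B1, self.B2]) \
            == ["Minimum 1"]

    def test_point_outside_all_extents(self):
        assert assign_frames([(3.0, 300.0)], [self.B1, self.B2]) \
            == ["unassigned"]

    def test_overlap_resolved_to_deeper_basin(self):
        overlap = _basin("Minimum 2", (0.6, 110.0), 3.0,
                         [[0.4, 0.9], [90.0, 140.0]], value=2.0)
        # B1 has the lower minimum -> wins on overlap
        assert assign_frames([(0.55, 105.0)], [overlap, self.B1]) \
            == ["Minimum 1"]

    def test_synthetic_series_in_known_boxes(self):
        rng = np.random.default_rng(0)
        pts, want = [], []
        for _ in range(200):
            which = rng.integers(0, 3)
            if which == 0:
                pts.append((rng.uniform(0.3, 0.8), rng.uniform(50, 150)))
                want.append("Minimum 1")
            elif which == 1:
                pts.append((rng.uniform(1.2, 1.9), rng.uniform(0, 60)))
                want.append("Minimum 2")
            else:
                pts.append((rng.uniform(2.5, 3.0), rng.uniform(200, 250)))
                want.append("unassigned")
        assert assign_frames(pts, [self.B1, self.B2]) == want


class TestSuperpose:
    def test_identical_structures(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (10, 3))
        _, rmsd = superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovers_zero(self, random_rigid_transform):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (12, 3))
        rot, trans = random_rigid_transform(rng)
        moved, rmsd = superpose(x @ rot.T + trans, x)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved, x, atol=1e-9)

    def test_collinear_pair_closed_form(self):
        # ref at +-1 A, model at +-2 A -> RMSD 1.0 A after centering
        ref = np.array([[0.1, 0, 0], [-0.1, 0, 0]])
        mob = np.array([[0.2, 0, 0], [-0.2, 0, 0]])
        _, rmsd = superpose(mob, ref)
        assert rmsd == pytest.approx(1.0, abs=1e-9)

    def test_fully_degenerate_fit_raises(self):
        x = np.zeros((4, 3))
        with pytest.raises(ValueError, match="degenerate"):
            superpose(x, np.random.default_rng(0).uniform(0, 1, (4, 3)))

    def test_report_selection_differs_from_fit(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(0, 1, (8, 3))
        mob = ref.copy()
        mob[6:] += 0.1   # displace only the reported atoms
        _, rmsd = superpose(mob, ref, fit_selection=np.arange(6),
                            report_selection=np.array([6, 7]))
        assert rmsd == pytest.approx(np.sqrt(3) * 0.1 * 10, rel=1e-6)


class TestDCC:
    def _two_residue_ens(self, anti=True, n=64):
        # residues displacing along x, exactly opposite (or equal)
        rng = np.random.default_rng(4)
        amp = rng.normal(0, 0.05, n)
        coords = np.zeros((n, 2, 3))
        coords[:, 0, 0] = amp
        coords[:, 1, 0] = (-amp if anti else amp) + 1.0
        from funnelmd.colvars import StructureModel
        atoms = StructureModel(serial=np.arange(1, 3),
                               name=np.array(["CA", "CA"], object),
                               resname=np.array(["ALA"] * 2, object),
                               resid=np.array([1, 2]),
                               chain=np.array(["A"] * 2, object),
                               element=np.array(["C", "C"], object),
                               coords=coords[0])
        return LabeledEnsemble(atoms=atoms, coords=coords)

    def test_diagonal_is_one(self):
        mat = dcc_map(self._two_residue_ens(), [1, 2])
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_planted_opposite_displacement_gives_minus_one(self):
        mat = dcc_map(self._two_residue_ens(anti=True), [1, 2])
        assert mat.values[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_planted_block_correlation_recovered(self):
        block_a = tuple(range(690, 698))
        block_b = tuple(range(702, 710))
        spec = PlantedEnsembleSpec(
            n_frames=5000, n_residues=24, helix_prob=1.0,
            dihedral_jitter=0.0, corr_blocks=((block_a, block_b, -0.6),),
            corr_sigma=0.03, seed=5)
        ens, truth = make_ensemble(spec)
        sel = list(range(690, 714))
        mat = dcc_map(ens, sel)
        ai = [sel.index(r) for r in block_a]
        bi = [sel.index(r) for r in block_b]
        recovered = mat.values[np.ix_(ai, bi)].mean()
        assert recovered == pytest.approx(-0.6, abs=0.05)

    def test_independent_residues_have_small_off_diagonal(self):
        spec = PlantedEnsembleSpec(n_frames=2000, n_residues=12,
                                   helix_prob=1.0, dihedral_jitter=0.0,
                                   fluct_sigma=0.03, seed=6)
        ens, _ = make_ensemble(spec)
        sel = list(range(690, 702))
        mat = dcc_map(ens, sel)
        off = mat.values[~np.eye(len(sel), dtype=bool)]
        assert np.abs(off).mean() < 3.0 / math.sqrt(2000)

    def test_zero_variance_reported_missing_not_zero(self):
        ens = self._two_residue_ens()
        ens.coords[:, 1, :] = 1.0  # residue 2 frozen
        mat = dcc_map(ens, [1, 2])
        assert np.isnan(mat.values[0, 1]) and np.isnan(mat.values[1, 1])
        assert mat.missing[0, 1]

    def test_requires_ten_frames(self):
        ens = self._two_residue_ens(n=5)
        with pytest.raises(ValueError, match="10 frames"):
            dcc_map(ens, [1, 2])


class TestContactOccupancy:
    def test_always_and_never(self, make_structure):
        atoms = make_structure([[0, 0, 0], [0.2, 0, 0]], resids=[1, 2])
        near = LabeledEnsemble(atoms=atoms,
                               coords=np.tile(atoms.coords, (5, 1, 1)))
        assert contact_occupancy(near, (1, 2), cutoff=0.45) == 1.0
        far_coords = atoms.coords.copy()
        far_coords[1, 0] = 5.0
        far = LabeledEnsemble(atoms=atoms,
                              coords=np.tile(far_coords, (5, 1, 1)))
        assert contact_occupancy(far, (1, 2), cutoff=0.45) == 0.0

    def test_planted_occupancy_recovered_exactly(self):
        spec = PlantedEnsembleSpec(n_frames=600, n_residues=16,
                                   helix_prob=0.0, contacts=((692, 702, 0.6),),
                                   seed=8)
        ens, truth = make_ensemble(spec)
        occ = contact_occupancy(ens, (692, 702), cutoff=0.45)
        realized = truth["contact_occupancy_realized"][(692, 702)]
        assert occ == pytest.approx(realized, abs=1e-12)
        assert occ == pytest.approx(0.6, abs=3.0 / math.sqrt(600))

    def test_monotone_in_cutoff(self):
        spec = PlantedEnsembleSpec(n_frames=200, n_residues=16,
                                   helix_prob=0.0, contacts=((692, 702, 0.5),),
                                   seed=9)
        ens, _ = make_ensemble(spec)
        occs = [contact_occupancy(ens, (692, 702), cutoff=c)
                for c in (0.2, 0.35, 0.45, 0.7, 1.2)]
        assert np.all(np.diff(occs) >= 0)

    def test_rigid_transform_invariance(self, random_rigid_transform):
        spec = PlantedEnsembleSpec(n_frames=60, n_residues=16,
                                   helix_prob=0.0, contacts=((692, 702, 0.5),),
                                   seed=10)
        ens, _ = make_ensemble(spec)
        rng = np.random.default_rng(11)
        moved = _apply_rigid(ens, rng, random_rigid_transform)
        assert contact_occupancy(moved, (692, 702), 0.45) == pytest.approx(
            contact_occupancy(ens, (692, 702), 0.45), abs=1e-12)

    def test_missing_residue_raises(self, make_structure):
        atoms = make_structure([[0, 0, 0]], resids=[1])
        ens = LabeledEnsemble(atoms=atoms, coords=atoms.coords[None])
        with pytest.raises(KeyError):
            contact_occupancy(ens, (1, 99), 0.45)


class TestHelicity:
    def test_ideal_helix_and_extended_chain(self):
        helix, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=20, n_residues=10, helix_prob=1.0, dihedral_jitter=0.0,
            seed=12))
        coil, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=20, n_residues=10, helix_prob=0.0, dihedral_jitter=0.0,
            seed=13))
        mid = list(range(691, 699))
        assert all(v == pytest.approx(1.0, abs=1e-12)
                   for v in helicity(helix, mid).values())
        assert all(v == 0.0 for v in helicity(coil, mid).values())

    def test_half_helical_matches_realized_fraction(self):
        ens, truth = make_ensemble(PlantedEnsembleSpec(
            n_frames=400, n_residues=16, helix_prob=0.5, seed=14))
        est = helicity(ens, list(range(691, 705)))
        realized = truth["helix_fraction_realized"]
        for r, v in est.items():
            assert v == pytest.approx(realized[r], abs=1e-12)

    def test_terminus_reported_missing(self):
        ens, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=5, n_residues=6, seed=15))
        out = helicity(ens, [690, 692, 695])
        assert math.isnan(out[690]) and math.isnan(out[695])
        assert not math.isnan(out[692])

    def test_rigid_transform_invariance(self, random_rigid_transform):
        ens, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=30, n_residues=10, helix_prob=0.5, seed=16))
        rng = np.random.default_rng(17)
        moved = _apply_rigid(ens, rng, random_rigid_transform)
        res = list(range(691, 699))
        a, b = helicity(ens, res), helicity(moved, res)
        for r in res:
            assert a[r] == pytest.approx(b[r], abs=1e-9)

    def test_folded_vs_unfolded_helix11_surrogate(self):
        """The folded/unfolded contrast of the helix-11 C-terminus
        (872-879): a folded ensemble is helical essentially always, an
        unfolding-prone one in fewer than 35% of frames."""
        folded, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=300, n_residues=12, resid_start=870,
            helix_prob={r: 1.0 for r in range(870, 882)}, seed=18))
        disturbed, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=300, n_residues=12, resid_start=870,
            helix_prob={r: 0.25 for r in range(872, 880)}, seed=19))
        region = list(range(872, 880))
        assert min(helicity(folded, region).values()) > 0.95
        assert max(helicity(disturbed, region).values()) < 0.35


class TestRmsf:
    def test_identical_ensembles_give_zero(self):
        ens, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=50, n_residues=8, fluct_sigma=0.05, seed=20))
        sel = np.flatnonzero(np.isin(ens.atoms.name, ("N", "CA", "C")))
        assert delta_rmsf(ens, ens, sel) == 0.0

    def test_uniform_inflation_is_linear(self):
        ens, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=200, n_residues=8, fluct_sigma=0.05,
            dihedral_jitter=0.0, seed=21))
        sel = np.flatnonzero(np.isin(ens.atoms.name, ("N", "CA", "C")))
        base = rmsf(ens, sel)
        mean = np.einsum("f,fad->ad", ens.frame_weights(), ens.coords)
        # scale deviations so every selected atom's RMSF grows by exactly 0.1 A
        full_scale = np.ones(ens.atoms.n_atoms)
        full_scale[sel] = (base + 0.1) / base
        coords2 = mean[None] + (ens.coords - mean[None]) \
            * full_scale[None, :, None]
        ens2 = LabeledEnsemble(atoms=ens.atoms, coords=coords2)
        assert delta_rmsf(ens2, ens, sel) == pytest.approx(0.1, abs=1e-9)

    def test_planted_increment_recovered(self):
        wt, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=2000, n_residues=12, helix_prob=1.0,
            dihedral_jitter=0.0, fluct_sigma=0.05, seed=22))
        mut, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=2000, n_residues=12, helix_prob=1.0,
            dihedral_jitter=0.0, fluct_sigma=0.08, seed=23))
        sel = np.flatnonzero(np.isin(wt.atoms.name, ("N", "CA", "C")))
        expected = (0.8 - 0.5) * math.sqrt(3)   # chi-distribution mean scale
        assert delta_rmsf(mut, wt, sel) == pytest.approx(expected, rel=0.05)

    def test_antisymmetry_exact(self):
        a, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=100, n_residues=8, fluct_sigma=0.04, seed=24))
        b, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=100, n_residues=8, fluct_sigma=0.07, seed=25))
        sel = np.flatnonzero(np.isin(a.atoms.name, ("N", "CA", "C")))
        assert delta_rmsf(a, b, sel) == -delta_rmsf(b, a, sel)

    def test_atom_count_mismatch_raises(self):
        ens, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=20, n_residues=8, seed=26))
        with pytest.raises(ValueError, match="atom count"):
            delta_rmsf(ens, ens, np.arange(6), np.arange(4))


class TestCaDistances:
    def _ens_with_distances(self, dists_nm, make_structure):
        atoms = make_structure(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]], resids=[720, 734, 897],
            names=["CA", "CA", "CA"])
        coords = np.zeros((len(dists_nm), 3, 3))
        for k, d in enumerate(dists_nm):
            coords[k, 1, 0] = d          # vary 720-734 only
            coords[k, 2, 1] = 1.0
        return LabeledEnsemble(atoms=atoms, coords=coords)

    def test_single_frame_sd_zero(self, make_structure):
        ens = self._ens_with_distances([1.0], make_structure)
        stats = ca_distance_stats(ens, (720, 734, 897))
        mean, sd = stats[(720, 734)]
        assert (mean, sd) == pytest.approx((10.0, 0.0))

    def test_two_frames_population_sd(self, make_structure):
        ens = self._ens_with_distances([1.0, 1.2], make_structure)
        mean, sd = ca_distance_stats(ens, (720, 734, 897))[(720, 734)]
        assert mean == pytest.approx(11.0)
        assert sd == pytest.approx(1.0)   # population, not sample, SD

    def test_planted_gaussian_distance_recovered(self, make_structure):
        rng = np.random.default_rng(27)
        d = rng.normal(1.5, 0.05, 800)   # ~N(15 A, 0.5 A)
        ens = self._ens_with_distances(d, make_structure)
        mean, sd = ca_distance_stats(ens, (720, 734, 897))[(720, 734)]
        assert mean == pytest.approx(15.0, abs=3 * 0.5 / math.sqrt(800))
        assert sd == pytest.approx(0.5, rel=0.15)

    def test_missing_ca_raises(self, make_structure):
        atoms = make_structure([[0, 0, 0]], resids=[720], names=["CB"])
        ens = LabeledEnsemble(atoms=atoms, coords=atoms.coords[None])
        with pytest.raises(KeyError, match="CA"):
            ca_distance_stats(ens, (720, 720, 720))


class TestSuperposeEnsemble:
    def test_undoes_per_frame_rigid_motion(self, random_rigid_transform):
        ens, _ = make_ensemble(PlantedEnsembleSpec(
            n_frames=40, n_residues=10, helix_prob=1.0, dihedral_jitter=0.0,
            fluct_sigma=0.01, seed=28))
        rng = np.random.default_rng(29)
        moved = _apply_rigid(ens, rng, random_rigid_transform)
        fixed = superpose_ensemble_to_mean(moved)
        # after refitting, frame scatter is back at the planted noise scale
        spread = fixed.coords.std(axis=0).mean()
        assert spread < 0.02
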