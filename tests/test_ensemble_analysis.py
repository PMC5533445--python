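"""Superposition, RMSD, RMSF, secondary structure, SASA and patches."""

import numpy as np
import pytest

from bboxnmr import ensemble_analysis as ea
from bboxnmr.io_formats import StructureEnsemble
from bboxnmr.synthetic_data import EnsembleRecipe, gen_ensemble
from conftest import random_rotation


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3))
        result = ea.superpose(coords, coords)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(15, 3)) * 5
        rot = random_rotation(rng)
        moved = coords @ rot.T + np.array([3.0, -2.0, 7.0])
        assert ea.superpose(coords, moved).rmsd < 1e-6

    def test_symmetry_and_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3)) * 3
        b = a + rng.normal(size=(8, 3)) * 0.5
        assert ea.superpose(a, b).rmsd == pytest.approx(ea.superpose(b, a).rmsd, abs=1e-9)
        rot = random_rotation(rng)
        assert ea.superpose(a, b @ rot.T + 5.0).rmsd \
            == pytest.approx(ea.superpose(a, b).rmsd, abs=1e-9)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 6, 3))
        result = ea.superpose(a, b)
        assert np.allclose(result.rotation @ result.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_brute_force_oracle_four_atoms(self):
        """Quaternion grid + local refinement oracle on a 4-atom toy."""
        a = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
        b = a.copy()
        b[3] += np.array([0.4, -0.2, 0.3])  # displace one atom
        fitted = ea.superpose(a, b).rmsd

        from scipy.optimize import minimize

        def rmsd_of(quat_trans):
            q = quat_trans[:4]
            q = q / np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
            moved = b @ rot.T + quat_trans[4:]
            return np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1)))

        rng = np.random.default_rng(4)
        best = np.inf
        for _ in range(60):  # random quaternion starts + refinement
            x0 = np.concatenate([rng.normal(size=4), np.zeros(3)])
            res = minimize(rmsd_of, x0, method="Nelder-Mead",
                           options=dict(maxiter=2000, xatol=1e-10, fatol=1e-12))
            best = min(best, res.fun)
        assert fitted == pytest.approx(best, abs=1e-6)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            ea.superpose(line, line)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            ea.superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPairwiseRMSD:
    def test_duplicate_models_zero(self):
        ens = gen_ensemble(EnsembleRecipe(topology="helix", length=8, n_models=4))
        mean, sd = ea.average_pairwise_rmsd(ens)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_jitter_expectation_and_oracle(self):
        """Mean pairwise RMSD of iid jitter ~ sqrt(2)*sigma for many atoms;
        cross-checked against an independent superposition implementation."""
        sigma = 0.5
        ens = gen_ensemble(EnsembleRecipe(topology="helix", length=60, n_models=3,
                                          core_sigma=sigma, seed=11))
        mean, _ = ea.average_pairwise_rmsd(ens, atom_set="heavy")
        assert mean == pytest.approx(np.sqrt(2) * sigma, rel=0.10)

        from scipy.spatial.transform import Rotation
        mask = ens.select(heavy_only=True)
        coords = ens.coords[:, mask, :]
        oracle = []
        for i in range(3):
            for j in range(i + 1, 3):
                a = coords[i] - coords[i].mean(axis=0)
                b = coords[j] - coords[j].mean(axis=0)
                rot, rssd = Rotation.align_vectors(a, b)
                oracle.append(rssd / np.sqrt(a.shape[0]))
        assert mean == pytest.approx(np.mean(oracle), rel=1e-6)

    def test_heavy_at_least_backbone(self, jittered_helix_tail):
        residues = range(1, 17)
        backbone, _ = ea.average_pairwise_rmsd(jittered_helix_tail, residues, "backbone")
        heavy, _ = ea.average_pairwise_rmsd(jittered_helix_tail, residues, "heavy")
        assert heavy >= backbone * 0.95  # uniform per-atom jitter: comparable or larger

    def test_empty_selection_rejected(self, helix_ensemble):
        with pytest.raises(ValueError):
            ea.average_pairwise_rmsd(helix_ensemble, residues=[999])


class TestOrderedResidues:
    def test_rigid_ensemble_all_ordered(self):
        ens = gen_ensemble(EnsembleRecipe(topology="helix", length=8, n_models=3))
        region = ea.ordered_residues(ens)
        assert region.residues == set(range(1, 9))

    def test_floppy_tail_excluded(self, jittered_helix_tail):
        region = ea.ordered_residues(jittered_helix_tail, rmsf_threshold=1.0)
        tail = {13, 14, 15, 16}
        assert not region.residues & tail
        core_rmsf = np.mean([region.rmsf[r] for r in range(1, 13)])
        tail_rmsf = np.mean([region.rmsf[r] for r in tail])
        assert tail_rmsf > core_rmsf


class TestSecondaryStructure:
    def test_ideal_helix_interior(self, helix_ensemble):
        states = ea.secondary_structure(helix_ensemble)
        assert all(states[r] == "H" for r in range(2, 11))

    def test_antiparallel_hairpin_strands(self, hairpin_ensemble):
        states = ea.secondary_structure(hairpin_ensemble)
        strand_a = [r for r in states if r <= 7]
        strand_b = [r for r in states if r > 7]
        assert sum(states[r] == "E" for r in strand_a) >= 3
        assert sum(states[r] == "E" for r in strand_b) >= 3
        assert "H" not in states.values()

    def test_isolated_extended_strand_is_coil(self):
        from bboxnmr.peptide import STRAND_DIHEDRALS, build_peptide
        strand = build_peptide("A" * 10, [STRAND_DIHEDRALS] * 10)
        assert set(ea.secondary_structure(strand).values()) == {"C"}

    def test_rigid_motion_invariance(self, helix_ensemble):
        rng = np.random.default_rng(9)
        rot = random_rotation(rng)
        moved = StructureEnsemble(
            atoms=list(helix_ensemble.atoms),
            coords=helix_ensemble.coords @ rot.T + np.array([10.0, -5.0, 2.0]))
        assert ea.secondary_structure(moved) == ea.secondary_structure(helix_ensemble)

    def test_profile_frequencies(self, helix_ensemble):
        profile = ea.secondary_structure_profile(helix_ensemble)
        assert len(profile.per_model) == helix_ensemble.n_models
        assert profile.frequency[6]["H"] == 1.0


class TestAccessibility:
    def test_isolated_atom_closed_form(self):
        area = ea.shrake_rupley(np.zeros((1, 3)), np.array([1.7]))
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area[0] == pytest.approx(expected, rel=0.005)

    def test_fully_enclosed_atom(self):
        # icosahedral-ish shell of large neighbors around a small atom
        shell = ea._sphere_points(40) * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.array([1.2] + [1.8] * len(shell))
        assert ea.shrake_rupley(coords, radii)[0] == 0.0

    def test_pair_sasa_monotone_in_separation(self):
        radii = np.array([1.7, 1.7])
        totals = []
        for d in np.linspace(0.0, 6.5, 21):
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            totals.append(ea.shrake_rupley(coords, radii).sum())
        assert np.all(np.diff(totals) >= -1e-9)

    def test_gly_x_gly_self_normalization(self):
        from bboxnmr.peptide import build_peptide
        for letter, res in (("A", 2), ("L", 2), ("W", 2)):
            peptide = build_peptide(f"G{letter}G", amide_h=False)
            records = {r.residue_index: r for r in ea.accessibility(peptide)}
            assert 0.9 <= records[res].relative_exposure <= 1.1

    def test_buried_flag_threshold(self, helix_ensemble):
        records = ea.accessibility(helix_ensemble)
        for rec in records:
            if np.isfinite(rec.relative_exposure):
                assert rec.buried == (rec.relative_exposure < 0.15)


class TestPatches:
    def test_empty_sites(self, helix_ensemble):
        patches, _ = ea.cluster_patches(helix_ensemble, [])
        assert patches == []

    def test_two_separated_groups_with_oracle(self):
        """Two helices far apart: single-linkage brute-force oracle."""
        a = gen_ensemble(EnsembleRecipe(topology="helix", length=8))
        offset_atoms = [(r + 20, n, at, e) for r, n, at, e in a.atoms]
        far = StructureEnsemble(atoms=list(a.atoms) + offset_atoms,
                                coords=np.concatenate(
                                    [a.coords, a.coords + np.array([50.0, 0, 0])], axis=1))
        sites = [1, 3, 5, 21, 23, 25]
        patches, warnings = ea.cluster_patches(far, sites, linkage_cutoff=8.0)
        assert not warnings
        assert len(patches) == 2
        memberships = {frozenset(p.members) for p in patches}
        assert memberships == {frozenset({1, 3, 5}), frozenset({21, 23, 25})}

        # brute-force single linkage: repeatedly merge closest clusters <= cutoff
        def min_dist(res_a, res_b):
            mask_a = far.select(residue_indices=[res_a], heavy_only=True)
            mask_b = far.select(residue_indices=[res_b], heavy_only=True)
            ca, cb = far.coords[0, mask_a], far.coords[0, mask_b]
            return np.sqrt(((ca[:, None] - cb[None]) ** 2).sum(-1)).min()

        clusters = [{s} for s in sites]
        merged = True
        while merged:
            merged = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(min_dist(x, y) <= 8.0 for x in clusters[i] for y in clusters[j]):
                        clusters[i] |= clusters[j]
                        del clusters[j]
                        merged = True
                        break
                if merged:
                    break
        assert {frozenset(c) for c in clusters} == memberships

    def test_count_non_increasing_in_cutoff(self, helix_ensemble):
        sites = [1, 4, 7, 10]
        counts = [len(ea.cluster_patches(helix_ensemble, sites, cutoff)[0])
                  for cutoff in (2.0, 4.0, 8.0, 16.0)]
        assert counts == sorted(counts, reverse=True)

    def test_partition_property(self, helix_ensemble):
        sites = [1, 2, 5, 9, "12sc"][:4]
        patches, _ = ea.cluster_patches(helix_ensemble, sites, 6.0)
        members = [m for p in patches for m in p.members]
        assert sorted(members, key=str) == sorted(sites, key=str)

    def test_unresolvable_site_warned(self, helix_ensemble):
        patches, warnings = ea.cluster_patches(helix_ensemble, [1, 99])
        assert warnings and all(99 not in p.members for p in patches)
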