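"""RFA, RMSD matrices, range statistic and average-linkage clustering."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import ensemble_mimic as em
from ensemble_mimic.superposition import superposed_rmsd
from ensemble_mimic.trajectory import RmsdMatrix
from oracles import naive_average_linkage


def distance_matrix_from_points(seed, n):
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=2.0, size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    labels = [f"f{i}" for i in range(n)]
    return RmsdMatrix(d, labels, labels)


def partition_of(clustering):
    groups = {}
    for f, c in clustering.assignment.items():
        groups.setdefault(c, set()).add(f)
    return {frozenset(g) for g in groups.values()}


class TestResidueFluctuation:
    def test_identical_frames_zero(self, toy_conformer):
        ens = em.Ensemble([toy_conformer] * 3)
        prof = em.residue_fluctuation(ens)
        assert np.all(prof.rmsf < 1e-12)

    def test_single_frame_rejected(self, toy_conformer):
        with pytest.raises(em.StructureError):
            em.residue_fluctuation(em.Ensemble([toy_conformer]))

    def test_gaussian_amplitude_recovery_after_alignment(self):
        """Aligned CA RMSF stays within 5% of the analytic a*sqrt(3) for a
        long chain (the 6 rigid-body DOF absorb ~1% of 3N motion DOF)."""
        amp = 0.5
        seq = em.DEFAULT_PROTEIN_SEQUENCE
        spec = em.EnsembleSpec(sequence=seq, seed=13, n_frames=1000,
                               amplitude_profile=np.full(len(seq), amp))
        prof = em.residue_fluctuation(em.sample_gaussian_ensemble(spec))
        expected = amp * np.sqrt(3.0)
        assert np.all(np.abs(prof.rmsf / expected - 1.0) < 0.05)

    def test_residue_heavy_basis(self, small_ensemble):
        prof = em.residue_fluctuation(small_ensemble,
                                      atom_basis="residue-heavy")
        assert prof.atom_basis == "residue-heavy"
        assert np.all(prof.rmsf >= 0)


class TestPairwiseMatrix:
    def test_identical_frames_zero_matrix(self, toy_conformer):
        ens = em.Ensemble([toy_conformer, toy_conformer])
        m = em.pairwise_rmsd_matrix(ens, fit="all")
        np.testing.assert_allclose(m.values, 0.0, atol=1e-9)

    def test_symmetric_zero_diagonal(self, small_ensemble):
        m = em.pairwise_rmsd_matrix(small_ensemble)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(m.values), 0.0, atol=1e-9)

    def test_matches_direct_recomputation(self, small_ensemble):
        """Batched matrix equals entrywise independent Kabsch RMSD."""
        m = em.pairwise_rmsd_matrix(small_ensemble, fit="backbone")
        template = small_ensemble.frames[0]
        fit = em.select_atoms(template, "backbone")
        coords = small_ensemble.coords
        for i in range(5):
            for j in range(5):
                direct = superposed_rmsd(coords[i], coords[j], fit, fit)
                assert abs(m.values[i, j] - direct) < 1e-6


class TestCrossMatrix:
    def _pair(self, n_frag=3, n_prot=4):
        pspec = em.EnsembleSpec(sequence=em.DEFAULT_PROTEIN_SEQUENCE,
                                seed=21, n_frames=n_prot)
        mim = em.MimicrySpec(planted_window=em.ResidueRange(8, 12),
                             seed=22)
        protein, fragment = em.sample_fragment_pair(pspec, mim)
        fragment.frames = fragment.frames[:n_frag]
        return fragment, protein

    def test_shape_contract(self):
        fragment, protein = self._pair(3, 4)
        mapping = em.ResidueMapping.identity(em.ResidueRange(1, 38))
        m = em.cross_rmsd_matrix(fragment, protein, mapping)
        assert m.values.shape == (3, 4)
        assert m.n_entries == 12

    def test_self_comparison_zero_diagonal(self):
        """Fragment == protein restricted to 1-38 gives a zero diagonal."""
        spec = em.EnsembleSpec(sequence=em.FHIT_NTERM_SEQ, seed=5,
                               n_frames=4)
        ens = em.sample_gaussian_ensemble(spec)
        mapping = em.ResidueMapping.identity(em.ResidueRange(1, 38))
        m = em.cross_rmsd_matrix(ens, ens, mapping)
        # closed-form evaluation cancels at the squared scale: ~1e-7 floor
        np.testing.assert_allclose(np.diag(m.values), 0.0, atol=1e-5)

    def test_matches_direct_recomputation(self):
        fragment, protein = self._pair(3, 3)
        mapping = em.ResidueMapping.identity(em.ResidueRange(1, 38))
        m = em.cross_rmsd_matrix(fragment, protein, mapping)
        from ensemble_mimic.trajectory import _mapped_atom_indices
        ff, pf, fa, pa = _mapped_atom_indices(
            fragment.frames[0], protein.frames[0], mapping)
        for i in range(3):
            for j in range(3):
                fc = fragment.coords[i][np.concatenate([ff, fa])]
                pc = protein.coords[j][np.concatenate([pf, pa])]
                direct = superposed_rmsd(
                    fc, pc, np.arange(ff.size),
                    np.arange(ff.size, ff.size + fa.size))
                assert abs(m.values[i, j] - direct) < 1e-6

    def test_mapping_mismatch_rejected(self):
        fragment, protein = self._pair(2, 2)
        # map a fragment residue onto a protein residue of different type
        bad = em.ResidueMapping(tuple((r, r + 40) for r in range(1, 11)))
        with pytest.raises(em.StructureError):
            em.cross_rmsd_matrix(fragment, protein, bad)


class TestFractionInRange:
    def test_all_inside(self):
        m = RmsdMatrix(np.full((3, 3), 3.0), list("abc"), list("abc"))
        assert em.fraction_in_range(m, 2.0, 4.0) == 1.0

    def test_all_outside(self):
        m = RmsdMatrix(np.full((3, 3), 5.0), list("abc"), list("abc"))
        assert em.fraction_in_range(m, 2.0, 4.0) == 0.0

    def test_hand_built_matrix(self):
        m = RmsdMatrix(np.array([[1.0, 2.5], [3.9, 4.1]]),
                       list("ab"), list("cd"))
        assert em.fraction_in_range(m, 2.0, 4.0) == 0.5

    def test_boundaries_closed(self):
        m = RmsdMatrix(np.array([[2.0, 4.0]]), ["a"], list("cd"))
        assert em.fraction_in_range(m, 2.0, 4.0) == 1.0

    def test_infinite_band_is_one(self):
        m = RmsdMatrix(np.array([[0.1, 99.0]]), ["a"], list("cd"))
        assert em.fraction_in_range(m, -np.inf, np.inf) == 1.0

    def test_per_frame_variant(self):
        m = RmsdMatrix(np.array([[3.0, 3.0], [9.0, 9.0]]),
                       list("ab"), list("cd"))
        assert em.fraction_in_range(m, 2.0, 4.0, per_frame=True) == 0.5

    def test_bad_bounds_rejected(self):
        m = RmsdMatrix(np.zeros((2, 2)), list("ab"), list("ab"))
        with pytest.raises(em.StructureError):
            em.fraction_in_range(m, 4.0, 2.0)


class TestAverageLinkage:
    def test_all_far_apart_singletons(self):
        d = np.array([[0.0, 5, 6], [5, 0, 7], [6, 7, 0.0]])
        m = RmsdMatrix(d, list("abc"), list("abc"))
        c = em.average_linkage_cluster(m, 2.0)
        assert c.n_clusters == 3

    def test_all_close_one_cluster(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        m = RmsdMatrix(d, list("abcd"), list("abcd"))
        c = em.average_linkage_cluster(m, 2.0)
        assert c.n_clusters == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        """Lance-Williams agglomeration equals exhaustive re-averaging."""
        n = int(np.random.default_rng(seed).integers(4, 9))
        m = distance_matrix_from_points(seed, n)
        mine = partition_of(em.average_linkage_cluster(m, 2.0))
        oracle = naive_average_linkage(m.values, 2.0)
        assert mine == oracle

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy(self, seed):
        n = 8
        m = distance_matrix_from_points(seed + 100, n)
        mine = partition_of(em.average_linkage_cluster(m, 2.0))
        z = linkage(squareform(m.values, checks=False), method="average")
        flat = fcluster(z, t=2.0, criterion="distance")
        scipy_partition = {}
        for f, c in enumerate(flat):
            scipy_partition.setdefault(c, set()).add(f)
        assert mine == {frozenset(g) for g in scipy_partition.values()}

    def test_frame_order_invariance(self):
        m = distance_matrix_from_points(3, 7)
        base = partition_of(em.average_linkage_cluster(m, 2.0))
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        permuted = RmsdMatrix(m.values[np.ix_(perm, perm)],
                              [f"f{i}" for i in perm],
                              [f"f{i}" for i in perm])
        relabeled = partition_of(em.average_linkage_cluster(permuted, 2.0))
        mapped = {frozenset(int(perm[i]) for i in g) for g in relabeled}
        assert mapped == base

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        m = RmsdMatrix(d, list("ab"), list("ab"))
        with pytest.raises(em.StructureError):
            em.average_linkage_cluster(m, 2.0)


class TestRepresentatives:
    def test_singleton_is_its_own_representative(self):
        d = np.array([[0.0, 9.0], [9.0, 0.0]])
        m = RmsdMatrix(d, list("ab"), list("ab"))
        c = em.average_linkage_cluster(m, 2.0)
        assert c.representatives == {0: 0, 1: 1}

    def test_medoid_by_mean_distance(self):
        d = np.array([[0.0, 1.0, 1.0],
                      [1.0, 0.0, 2.0],
                      [1.0, 2.0, 0.0]])
        m = RmsdMatrix(d, list("abc"), list("abc"))
        c = em.Clustering({0: 0, 1: 0, 2: 0}, cutoff=5.0)
        reps = em.cluster_representatives(c, m)
        assert reps == {0: 0}

    def test_tie_goes_to_lowest_index(self):
        d = np.ones((3, 3))
        np.fill_diagonal(d, 0.0)
        m = RmsdMatrix(d, list("abc"), list("abc"))
        c = em.Clustering({0: 0, 1: 0, 2: 0}, cutoff=5.0)
        assert em.cluster_representatives(c, m) == {0: 0}
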