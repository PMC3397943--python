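import numpy as np
import pytest

from pocketscan.conformers import (
    EnsemblePCA,
    cluster_rmsd,
    covariance_matrix,
    dccm,
    pca,
    rmsf,
    select_representatives,
)
from pocketscan.structure import CoordinateSet, pairwise_rmsd, superpose
from scipy.spatial.transform import Rotation

from _oracles import naive_average_linkage


def make_cs(coords, states=None):
    coords = np.asarray(coords, float)
    n_struct, n_res = coords.shape[:2]
    return CoordinateSet(
        labels=[str(i + 1) for i in range(n_res)],
        coords=coords,
        states=states or ["UNKNOWN"] * n_struct,
        bfactors=np.zeros((n_struct, n_res)),
    )


class TestCovariance:
    def test_identical_structures_zero(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        c = covariance_matrix(make_cs([pts] * 4))
        np.testing.assert_allclose(c, 0.0, atol=1e-12)

    def test_two_structures_closed_form(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 5, 3))
        c = covariance_matrix(make_cs([a, b]))
        delta = (a - b).reshape(-1)
        np.testing.assert_allclose(c, np.outer(delta, delta) / 4.0, atol=1e-12)

    def test_trace_equals_sum_of_coordinate_variances(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(9, 4, 3))
        c = covariance_matrix(make_cs(coords))
        x = coords.reshape(9, -1)
        manual = np.mean(x**2, axis=0) - np.mean(x, axis=0) ** 2
        assert np.trace(c) == pytest.approx(manual.sum(), rel=1e-10)

    def test_positive_semidefinite_and_symmetric(self):
        rng = np.random.default_rng(3)
        c = covariance_matrix(make_cs(rng.normal(size=(7, 5, 3))))
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.linalg.eigvalsh(c).min() > -1e-10


class TestPCA:
    def test_rank_one_ensemble_captures_everything(self):
        base = np.random.default_rng(4).normal(size=(6, 3))
        direction = np.random.default_rng(5).normal(size=(6, 3))
        direction /= np.linalg.norm(direction)
        coords = [base + t * direction for t in np.linspace(-2, 2, 9)]
        res = pca(make_cs(coords))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)
        assert res.cumulative_variance(1) == pytest.approx(1.0, abs=1e-10)

    def test_two_mode_variance_ratio(self):
        # planted orthogonal modes with generative variances 9:1
        rng = np.random.default_rng(6)
        base = rng.normal(size=(8, 3))
        q, _ = np.linalg.qr(rng.normal(size=(24, 2)))
        scores = rng.normal(size=(100, 2))
        scores -= scores.mean(0)
        u, _, _ = np.linalg.svd(scores, full_matrices=False)
        scores = u * np.sqrt(100) * [3.0, 1.0]  # exact sample variances 9 and 1
        coords = (base.reshape(-1) + scores @ q.T).reshape(100, 8, 3)
        res = pca(make_cs(coords))
        assert res.variance_fraction[0] == pytest.approx(0.9, abs=0.02)
        # rank-2 ensemble: the two PCs recover the planted variances exactly
        np.testing.assert_allclose(res.eigenvalues[:2], [9.0, 1.0], rtol=1e-8)

    def test_modes_orthonormal_and_eigenvalues_sorted(self):
        rng = np.random.default_rng(7)
        res = pca(make_cs(rng.normal(size=(12, 5, 3))))
        np.testing.assert_allclose(res.modes.T @ res.modes, np.eye(15), atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(8)
        cs = make_cs(rng.normal(size=(10, 6, 3)))
        res = pca(cs)
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(covariance_matrix(cs)), rel=1e-6
        )

    def test_full_reconstruction(self):
        rng = np.random.default_rng(9)
        cs = make_cs(rng.normal(size=(8, 4, 3)))
        res = pca(cs)
        centered = cs.flat() - res.mean
        recon = (centered @ res.modes) @ res.modes.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_single_structure_errors(self):
        with pytest.raises(ValueError):
            EnsemblePCA(make_cs(np.zeros((1, 4, 3))))


class TestProject:
    def test_mean_structure_scores_zero(self):
        rng = np.random.default_rng(10)
        cs = make_cs(rng.normal(size=(9, 5, 3)))
        res = pca(cs)
        mean_cs = make_cs(res.mean.reshape(1, 5, 3))
        np.testing.assert_allclose(res.project(mean_cs, 3), 0.0, atol=1e-10)

    def test_training_score_variance_equals_eigenvalues(self):
        rng = np.random.default_rng(11)
        cs = make_cs(rng.normal(size=(20, 4, 3)))
        res = pca(cs)
        scores = res.project(cs, n_modes=5)
        np.testing.assert_allclose(
            scores.var(axis=0), res.eigenvalues[:5], rtol=1e-6, atol=1e-12
        )

    def test_held_out_state_displaced_along_planted_mode(self):
        from pocketscan.synthetic import SyntheticSpec, make_two_state_ensemble

        spec = SyntheticSpec(n_residues=40, n_per_state=40, mode_block=(10, 20),
                             pocket_residues=(30, 31), sigma=0.1, seed=12)
        cs, truth = make_two_state_ensemble(spec)
        train = make_cs(cs.coords[:-10], states=cs.states[:-10])
        held_b = make_cs(cs.coords[-10:])  # all second-state members
        res = pca(train)
        scores = res.project(held_b, n_modes=1)[:, 0]
        sign = np.sign(res.modes[:, 0] @ truth["mode"])
        # second state sits at -amplitude/2 along the planted mode
        assert np.mean(scores) * sign == pytest.approx(-spec.amplitude / 2, abs=0.3)

    def test_label_mismatch_errors(self):
        rng = np.random.default_rng(13)
        res = pca(make_cs(rng.normal(size=(5, 4, 3))))
        other = CoordinateSet(
            labels=["9", "10", "11", "12"],
            coords=rng.normal(size=(2, 4, 3)),
            states=["UNKNOWN"] * 2,
            bfactors=np.zeros((2, 4)),
        )
        with pytest.raises(ValueError, match="label mismatch"):
            res.project(other)


class TestCumulativeVariance:
    def test_monotone_and_one_at_rank(self):
        rng = np.random.default_rng(14)
        res = pca(make_cs(rng.normal(size=(6, 4, 3))))
        values = [res.cumulative_variance(k) for k in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_errors(self):
        res = pca(make_cs(np.random.default_rng(15).normal(size=(4, 3, 3))))
        for k in (0, 10):
            with pytest.raises(ValueError):
                res.cumulative_variance(k)


class TestClusterRmsd:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(16)
        base = rng.normal(size=(6, 3)) * 4
        far = base.copy()
        far[:3] += 15.0  # a genuinely different conformation, not a rigid shift
        members = [base + rng.normal(scale=0.05, size=base.shape) for _ in range(5)]
        members += [far + rng.normal(scale=0.05, size=base.shape) for _ in range(3)]
        cs = make_cs(members)
        part = cluster_rmsd(pairwise_rmsd(cs), 2)
        assert part.k == 2
        # largest cluster ranked first; generative labels recovered exactly
        assert list(part.labels[:5]) == [1] * 5
        assert list(part.labels[5:]) == [2] * 3

    def test_k_equals_n_singletons(self):
        m = pairwise_rmsd(make_cs(np.random.default_rng(17).normal(size=(5, 4, 3))))
        part = cluster_rmsd(m, 5)
        assert sorted(part.labels) == [1, 2, 3, 4, 5]

    def test_k_one_single_cluster(self):
        m = pairwise_rmsd(make_cs(np.random.default_rng(18).normal(size=(5, 4, 3))))
        assert set(cluster_rmsd(m, 1).labels) == {1}

    def test_k_out_of_range_errors(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValueError):
            cluster_rmsd(m, 4)

    def test_matches_naive_agglomeration(self):
        rng = np.random.default_rng(19)
        for k in (2, 3, 4):
            cs = make_cs(rng.normal(size=(10, 5, 3)))
            m = pairwise_rmsd(cs)
            part = cluster_rmsd(m, k)
            ours = {frozenset(np.flatnonzero(part.labels == c)) for c in range(1, k + 1)}
            assert ours == naive_average_linkage(m, k)

    def test_invariant_under_member_permutation(self):
        rng = np.random.default_rng(20)
        coords = rng.normal(size=(8, 5, 3))
        m = pairwise_rmsd(make_cs(coords))
        part = cluster_rmsd(m, 3)
        perm = rng.permutation(8)
        part_p = cluster_rmsd(m[np.ix_(perm, perm)], 3)
        sets_a = {frozenset(np.flatnonzero(part.labels == c)) for c in range(1, 4)}
        sets_b = {
            frozenset(perm[i] for i in np.flatnonzero(part_p.labels == c))
            for c in range(1, 4)
        }
        assert sets_a == sets_b


class TestSelectRepresentatives:
    def test_singleton_cluster_is_its_member(self):
        cs = make_cs(np.random.default_rng(21).normal(size=(4, 5, 3)))
        part = cluster_rmsd(pairwise_rmsd(cs), 4)
        reps = select_representatives(cs, part)
        for c, idx in reps.items():
            assert part.labels[idx] == c

    def test_central_member_wins(self):
        rng = np.random.default_rng(22)
        base = rng.normal(size=(6, 3)) * 3
        offset = rng.normal(size=(6, 3))
        offset -= offset.mean(axis=0)
        members = [base + offset, base, base - offset]  # member 1 is the centroid
        cs = make_cs(members)
        part = cluster_rmsd(pairwise_rmsd(cs), 1)
        assert select_representatives(cs, part)[1] == 1

    def test_matches_exhaustive_argmin(self):
        rng = np.random.default_rng(23)
        cs = make_cs(rng.normal(size=(9, 6, 3)) + rng.normal(size=(1, 6, 3)) * 2)
        part = cluster_rmsd(pairwise_rmsd(cs), 2)
        reps = select_representatives(cs, part)
        from pocketscan.conformers import _cluster_mean

        for c in (1, 2):
            members = part.members(c)
            mean = _cluster_mean(cs, members)
            rmsds = [superpose(cs.coords[m], mean)[1] for m in members]
            assert reps[c] == members[int(np.argmin(rmsds))]


class TestRmsf:
    def test_identical_copies_zero(self):
        pts = np.random.default_rng(24).normal(size=(5, 3))
        table = rmsf(make_cs([pts] * 6))
        np.testing.assert_allclose(table["rmsf"], 0.0, atol=1e-12)

    def test_isotropic_jitter_gives_sqrt3_sigma(self):
        rng = np.random.default_rng(25)
        base = np.zeros((3, 3))
        coords = np.tile(base, (1000, 1, 1))
        coords[:, 1, :] += rng.normal(scale=1.0, size=(1000, 3))
        table = rmsf(make_cs(coords))
        assert table["rmsf"].iloc[1] == pytest.approx(np.sqrt(3.0), rel=0.05)
        np.testing.assert_allclose(table["rmsf"].iloc[[0, 2]], 0.0, atol=1e-12)

    def test_sum_of_squares_equals_covariance_trace(self):
        rng = np.random.default_rng(26)
        cs = make_cs(rng.normal(size=(11, 4, 3)))
        total = (rmsf(cs)["rmsf"] ** 2).sum()
        assert total == pytest.approx(np.trace(covariance_matrix(cs)), rel=1e-10)

    def test_mean_bfactor_column(self):
        cs = make_cs(np.random.default_rng(27).normal(size=(3, 2, 3)))
        cs.bfactors = np.array([[10.0, 20.0], [30.0, 40.0], [50.0, 60.0]])
        table = rmsf(cs)
        np.testing.assert_allclose(table["mean_bfactor"], [30.0, 40.0])


class TestDccm:
    def test_identical_displacement_is_one(self):
        rng = np.random.default_rng(28)
        t = rng.normal(size=(20, 1, 3))
        coords = np.concatenate([t, t], axis=1)  # two residues move identically
        c = dccm(make_cs(coords))
        assert c[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_opposite_displacement_is_minus_one(self):
        rng = np.random.default_rng(29)
        t = rng.normal(size=(20, 1, 3))
        coords = np.concatenate([t, -t], axis=1)
        c = dccm(make_cs(coords))
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(30)
        c = dccm(make_cs(rng.normal(size=(2000, 6, 3))))
        off = c[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)

    def test_zero_fluctuation_residue_is_nan(self):
        rng = np.random.default_rng(31)
        coords = rng.normal(size=(10, 3, 3))
        coords[:, 2, :] = 7.0  # frozen residue
        c = dccm(make_cs(coords))
        assert np.isnan(c[2, 0]) and np.isnan(c[0, 2])

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(32)
        coords = rng.normal(size=(15, 5, 3))
        c0 = dccm(make_cs(coords))
        rot = Rotation.random(random_state=rng)
        moved = np.stack([rot.apply(frame) + [1.0, 2.0, 3.0] for frame in coords])
        np.testing.assert_allclose(dccm(make_cs(moved)), c0, atol=1e-9)
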