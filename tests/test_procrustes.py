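"""Centroid size, Procrustes superimposition, shape PCA, allometry, CVA."""

import numpy as np
import pytest

from wingfa import procrustes as pro
from wingfa import simulate as sim
from wingfa.io import LandmarkConfiguration


def _rigid(coords, theta, shift, scale=1.0, rng=None):
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return scale * coords @ rot.T + shift


class TestCentroidSize:
    def test_unit_square_corners(self):
        square = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        assert pro.centroid_size(square) == pytest.approx(np.sqrt(8))

    def test_scales_linearly(self, rng):
        coords = rng.standard_normal((15, 2))
        assert pro.centroid_size(3 * coords) == pytest.approx(
            3 * pro.centroid_size(coords), rel=1e-12
        )

    def test_matches_brute_force_sum(self, rng):
        coords = rng.standard_normal((15, 2))
        centroid = coords.mean(axis=0)
        brute = np.sqrt(sum(np.sum((p - centroid) ** 2) for p in coords))
        assert pro.centroid_size(coords) == pytest.approx(brute, rel=1e-14)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(pro.DegenerateConfigurationError):
            pro.centroid_size(np.ones((4, 2)))


class TestAlignPair:
    def test_rigid_copy_aligns_exactly(self, rng):
        ref = rng.standard_normal((10, 2))
        target = _rigid(ref, np.pi / 2, [5.0, -3.0])
        _, dist = pro.align_pair(target, ref)
        assert dist < 1e-10

    def test_reflection_flag(self, rng):
        ref = rng.standard_normal((10, 2))
        mirrored = pro.reflect(ref)
        _, d_with = pro.align_pair(mirrored, ref, allow_reflection=True)
        _, d_without = pro.align_pair(mirrored, ref, allow_reflection=False)
        assert d_with < 1e-10
        assert d_without > 1e-3

    def test_k_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            pro.align_pair(rng.standard_normal((4, 2)), rng.standard_normal((5, 2)))

    def test_rotation_matches_grid_search(self, rng):
        """SVD rotation beats every rotation on a fine grid (3-landmark toy)."""
        ref = rng.standard_normal((3, 2))
        target = rng.standard_normal((3, 2))
        fitted, dist = pro.align_pair(target, ref)
        refc = ref - ref.mean(axis=0)
        tc = target - target.mean(axis=0)
        best = np.inf
        for theta in np.arange(0, 2 * np.pi, 1e-4):
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            tr = tc @ rot
            beta = (tr * refc).sum() / (tr * tr).sum()
            best = min(best, np.linalg.norm(beta * tr - refc))
        assert dist <= best + 1e-6


class TestGpa:
    def test_rigid_copies_collapse_to_consensus(self, rng):
        base = rng.standard_normal((15, 2))
        configs = [
            _rigid(base, rng.uniform(0, 2 * np.pi), rng.uniform(-9, 9, 2), rng.uniform(0.5, 2))
            for _ in range(20)
        ]
        fit = pro.gpa(configs, reflect_side=None)
        dev = fit.flat() - fit.consensus_flat()
        assert np.abs(dev).max() < 1e-9
        assert dev.var() < 1e-18

    def test_two_shapes_consensus_equidistant(self, rng):
        a = rng.standard_normal((10, 2))
        b = rng.standard_normal((10, 2))
        fit = pro.gpa([a, b], reflect_side=None)
        da = np.linalg.norm(fit.flat()[0] - fit.consensus_flat())
        db = np.linalg.norm(fit.flat()[1] - fit.consensus_flat())
        assert da == pytest.approx(db, abs=1e-9)

    def test_consensus_recovers_generator_mean_shape(self):
        grp = sim.GroupParams(
            genotype="g", sex="F", n_individuals=250, ind_sigma2=1e-4,
            fa_sigma2=1e-6,
        )
        params = sim.SimulationParams(
            groups=(grp,), m_replicates=1, me_sigma2=1e-8, seed=9
        )
        dataset, _ = sim.simulate_landmark_dataset(params)
        fit = pro.gpa(dataset)
        mu = sim.WING_TEMPLATE - sim.WING_TEMPLATE.mean(axis=0)
        mu = mu / np.linalg.norm(mu)
        rot = pro.frame_rotation(fit.consensus, mu)
        aligned_consensus = (fit.consensus @ rot).ravel()
        cos = abs(aligned_consensus @ mu.ravel())
        assert np.degrees(np.arccos(min(1, cos))) < 1.0

    def test_invariant_to_nuisance_transforms_and_order(self, rng):
        base = [rng.standard_normal((8, 2)) for _ in range(12)]
        fit1 = pro.gpa(base, reflect_side=None)
        moved = [
            _rigid(c, rng.uniform(0, 2 * np.pi), rng.uniform(-5, 5, 2), rng.uniform(0.5, 2))
            for c in base
        ]
        fit2 = pro.gpa(moved, reflect_side=None)
        rot = pro.frame_rotation(fit2.consensus, fit1.consensus)
        np.testing.assert_allclose(fit2.consensus @ rot, fit1.consensus, atol=1e-9)
        np.testing.assert_allclose(fit2.aligned @ rot, fit1.aligned, atol=1e-9)
        perm = rng.permutation(len(base))
        fit3 = pro.gpa([moved[i] for i in perm], reflect_side=None)
        rot3 = pro.frame_rotation(fit3.consensus, fit1.consensus)
        np.testing.assert_allclose(fit3.aligned @ rot3, fit1.aligned[perm], atol=1e-9)

    def test_symmetric_individual_has_zero_asymmetry(self):
        """Right = mirrored left -> both sides identical after reflection."""
        rng = np.random.default_rng(4)
        from wingfa.io import LandmarkDataset, SpecimenRecord

        records = []
        for i in range(5):
            left = rng.standard_normal((6, 2))
            right = pro.reflect(left)
            for side, coords in (("L", left), ("R", right)):
                records.append(
                    SpecimenRecord(
                        f"i{i}", side, 1, "g", "F", LandmarkConfiguration(coords)
                    )
                )
        fit = pro.gpa(LandmarkDataset(records), reflect_side="L")
        flat = fit.flat()
        for i in range(5):
            np.testing.assert_allclose(flat[2 * i], flat[2 * i + 1], atol=1e-9)


class TestShapePca:
    def test_dimension_is_2k_minus_4(self, rng):
        configs = [rng.standard_normal((15, 2)) for _ in range(200)]
        fit = pro.gpa(configs, reflect_side=None)
        space = pro.shape_pca(fit)
        assert space.d == 26

    def test_single_direction_dominates(self, rng):
        u = sim.random_shape_direction(sim.WING_TEMPLATE, rng)
        mu = sim.WING_TEMPLATE - sim.WING_TEMPLATE.mean(axis=0)
        mu_flat = mu.ravel(order="F")  # x1..xk then y1..yk
        configs = []
        for _ in range(100):
            flat = np.concatenate([mu[:, 0], mu[:, 1]]) + rng.normal(0, 0.02) * u
            configs.append(np.column_stack([flat[:15], flat[15:]]))
        fit = pro.gpa(configs, reflect_side=None)
        space = pro.shape_pca(fit)
        assert space.eigenvalues[0] / space.eigenvalues.sum() > 0.99

    def test_total_variance_preserved(self, small_fit):
        fit, space = small_fit
        flat = fit.flat()
        total = ((flat - flat.mean(axis=0)) ** 2).sum() / (fit.n - 1)
        assert space.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_scores_reconstruct_aligned_coordinates(self, small_fit):
        fit, space = small_fit
        recon = space.to_coordinates(space.scores)
        np.testing.assert_allclose(recon, fit.flat(), atol=1e-9)


class TestAllometry:
    def test_orthogonal_scores_unchanged(self, rng):
        x = rng.standard_normal(50)
        scores = rng.standard_normal((50, 3))
        scores -= np.outer(x - x.mean(), np.linalg.lstsq(
            (x - x.mean())[:, None], scores, rcond=None
        )[0][0])
        res = pro.allometry_regression(scores, x)
        np.testing.assert_allclose(res.residuals, scores - scores.mean(axis=0) + scores.mean(axis=0) - res.intercepts, atol=1e-9)

    def test_pure_allometry_gives_zero_residuals(self, rng):
        x = rng.standard_normal(40)
        beta = np.array([1.0, -2.0, 0.5])
        scores = np.outer(x, beta)
        res = pro.allometry_regression(scores, x)
        assert np.abs(res.residuals).max() < 1e-9
        np.testing.assert_allclose(res.slopes, beta, atol=1e-9)

    def test_residuals_uncorrelated_with_size(self, rng):
        x = rng.standard_normal(80)
        scores = rng.standard_normal((80, 4)) + np.outer(x, [0.5, 0, -1, 2])
        res = pro.allometry_regression(scores, x)
        for j in range(4):
            assert abs(np.corrcoef(res.residuals[:, j], x)[0, 1]) < 1e-9

    def test_slope_recovery_within_5pct(self, rng):
        n = 500
        x = rng.standard_normal(n)
        beta = np.array([2.0, -1.0])
        scores = np.outer(x, beta) + 0.1 * rng.standard_normal((n, 2))
        res = pro.allometry_regression(scores, x)
        np.testing.assert_allclose(res.slopes, beta, rtol=0.05)

    def test_constant_size_rejected(self, rng):
        with pytest.raises(np.linalg.LinAlgError):
            pro.allometry_regression(rng.standard_normal((30, 2)), np.ones(30))


class TestCva:
    def test_identical_groups_no_discrimination(self, rng):
        half = rng.standard_normal((30, 4))
        scores = np.vstack([half, half])  # group b duplicates group a exactly
        groups = np.repeat(["a", "b"], 30)
        res = pro.cva(scores, groups)
        assert res.eigenvalues.max() < 1e-9

    def test_known_separation_vector_recovered(self):
        """CV1 shape change points along the true group-separation vector."""
        errors = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            n = 200
            a = rng.standard_normal((n, 3))
            b = rng.standard_normal((n, 3)) + 5 * v
            scores = np.vstack([a, b])
            groups = np.array(["a"] * n + ["b"] * n)
            res = pro.cva(scores, groups)
            change = res.shape_change[0]
            cos = abs(change @ v) / np.linalg.norm(change)
            errors.append(np.degrees(np.arccos(min(1, cos))))
        assert np.mean(errors) < 2.0

    def test_canonical_scores_unit_within_group_variance(self, rng):
        scores = np.vstack(
            [rng.standard_normal((40, 5)), rng.standard_normal((40, 5)) + 1.0,
             rng.standard_normal((40, 5)) - 1.0]
        )
        groups = np.repeat(["a", "b", "c"], 40)
        res = pro.cva(scores, groups)
        grand = 0.0
        for g in "abc":
            sub = res.canonical_scores[groups == g]
            dev = sub - sub.mean(axis=0)
            grand += (dev**2).sum(axis=0)
        pooled = grand / (120 - 3)
        np.testing.assert_allclose(pooled, 1.0, rtol=1e-9)

    def test_variance_shares_sum_to_one(self, rng):
        scores = np.vstack(
            [rng.standard_normal((30, 4)) + off for off in (0, 1, 2)]
        )
        groups = np.repeat(["a", "b", "c"], 30)
        res = pro.cva(scores, groups)
        assert res.variance_shares.sum() == pytest.approx(1.0)
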