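"""DCT shape descriptors: transform correctness, PCA, PC reconstructions."""

import numpy as np
import pytest

from samshape import (
    AlignedContourSet,
    DctCoefficients,
    dct_transform,
    inverse_dct,
    procrustes_align,
    reconstruct_at_pc,
    resample_contour,
    shape_pca,
)

from conftest import parabola_contour


def aligned_from_arrays(arrays) -> AlignedContourSet:
    """Wrap raw (n_points, 2) arrays as an aligned set without re-aligning."""
    lm = np.stack(arrays)
    lm = lm - lm.mean(axis=1, keepdims=True)
    return AlignedContourSet(
        landmarks=lm,
        ids=[str(i) for i in range(lm.shape[0])],
        centroid_sizes=np.sqrt(np.sum(lm**2, axis=(1, 2))),
        mean_shape=lm.mean(axis=0),
        converged=True,
        iterations=0,
        with_scaling=False,
    )


class TestTransform:
    def test_constant_signal_has_zero_retained_coeffs(self):
        n = 64
        pts = np.column_stack([np.full(n, 3.0), np.linspace(0, 1, n)])
        aligned = aligned_from_arrays([pts, pts])
        coeffs = dct_transform(aligned, 12)[0]
        assert np.allclose(coeffs.coeff_x, 0, atol=1e-12)

    def test_basis_function_selectivity(self):
        n, k = 64, 3
        i = np.arange(n)
        basis = np.cos(np.pi * (2 * i + 1) * k / (2 * n))
        pts = np.column_stack([basis, np.zeros(n)])
        lm = np.stack([pts, pts])  # deliberately NOT centred in x (mean is ~0 anyway)
        aligned = AlignedContourSet(
            landmarks=lm, ids=["a", "b"], centroid_sizes=np.ones(2),
            mean_shape=pts, converged=True, iterations=0, with_scaling=False,
        )
        cx = dct_transform(aligned, 12)[0].coeff_x
        assert abs(cx[k - 1]) > 1e-6
        mask = np.ones(12, bool)
        mask[k - 1] = False
        assert np.allclose(cx[mask], 0, atol=1e-10)

    def test_full_harmonic_round_trip(self, rng):
        n = 32
        pts = rng.normal(size=(n, 2))
        aligned = aligned_from_arrays([pts, pts])
        coeffs = dct_transform(aligned, n - 1)[0]
        rec = inverse_dct(coeffs)
        assert np.allclose(rec.points, aligned.landmarks[0], atol=1e-9)

    def test_parseval_inequality_and_equality(self, rng):
        n = 40
        pts = rng.normal(size=(n, 2))
        aligned = aligned_from_arrays([pts, pts])
        energy = float(np.sum(aligned.landmarks[0] ** 2))
        partial = dct_transform(aligned, 12)[0]
        assert np.sum(partial.vector**2) <= energy + 1e-9
        full = dct_transform(aligned, n - 1)[0]
        assert np.sum(full.vector**2) == pytest.approx(energy, abs=1e-9)

    def test_truncation_error_small_on_smooth_parabola(self):
        c = resample_contour(parabola_contour(120.0, 80.0, 1601), 800)
        aligned = procrustes_align([c, c], with_scaling=False)
        coeffs = dct_transform(aligned, 12)[0]
        rec = inverse_dct(coeffs)
        height = np.ptp(aligned.landmarks[0][:, 1])
        rmse = np.sqrt(np.mean(np.sum((rec.points - aligned.landmarks[0]) ** 2, axis=1)))
        assert rmse / height < 0.01

    def test_too_many_harmonics_rejected(self):
        aligned = aligned_from_arrays([np.random.default_rng(0).normal(size=(10, 2))] * 2)
        with pytest.raises(ValueError, match="n_harmonics"):
            dct_transform(aligned, 10)

    def test_zero_coefficients_reconstruct_origin(self):
        coeffs = DctCoefficients("z", np.zeros(12), np.zeros(12), 12, 50)
        rec = inverse_dct(coeffs)
        assert np.allclose(rec.points, 0)


def coeffs_along_directions(rng, n_shapes, sds, n_harmonics=12):
    """Coefficient sets varying along orthonormal directions with given SDs."""
    p = 2 * n_harmonics
    dirs = np.linalg.qr(rng.normal(size=(p, len(sds))))[0].T
    amounts = rng.normal(0.0, sds, size=(n_shapes, len(sds)))
    base = rng.normal(size=p)
    out = []
    for i in range(n_shapes):
        vec = base + amounts[i] @ dirs
        out.append(DctCoefficients(str(i), vec[:n_harmonics], vec[n_harmonics:],
                                   n_harmonics, 100))
    return out, amounts, dirs


class TestShapePca:
    def test_rank_one_data_explained_fully(self, rng):
        coeffs, _, _ = coeffs_along_directions(rng, 20, [2.0])
        space = shape_pca(coeffs)
        assert space.explained_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_ordered_and_sum_to_one(self, rng):
        coeffs, _, _ = coeffs_along_directions(rng, 30, [3.0, 1.0, 0.5])
        space = shape_pca(coeffs)
        f = space.explained_fraction
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_variance_ratio_recovery_9_to_1(self, rng):
        coeffs, amounts, dirs = coeffs_along_directions(rng, 200, [3.0, 1.0])
        space = shape_pca(coeffs)
        # eigenvalues must match the realised sample variances along the two
        # generator directions (the data are exactly 2-D in coefficient space)
        realised = np.sort(np.var(amounts, axis=0, ddof=1))[::-1]
        lam = space.explained_fraction[:2] * realised.sum() / space.explained_fraction[:2].sum()
        var = space.explained_fraction * (space.score_sd(0) ** 2 / space.explained_fraction[0])
        assert space.explained_fraction[2] == pytest.approx(0.0, abs=1e-9)
        ratio = space.explained_fraction[0] / space.explained_fraction[1]
        realised_ratio = realised[0] / realised[1]
        assert ratio == pytest.approx(realised_ratio, rel=0.05)
        assert 5.0 < ratio < 16.0  # ~9:1 up to sampling error at n=200

        # PC1 aligns with the dominant generator direction
        align = abs(space.loadings[0] @ dirs[0])
        assert align > 0.99

    def test_scores_centred_uncorrelated_loadings_orthonormal(self, rng):
        coeffs, _, _ = coeffs_along_directions(rng, 40, [3.0, 1.0, 0.3])
        space = shape_pca(coeffs)
        assert np.allclose(space.scores.mean(axis=0), 0, atol=1e-9)
        G = space.loadings @ space.loadings.T
        assert np.allclose(G, np.eye(space.n_pcs), atol=1e-9)
        c = np.cov(space.scores[:, :3], rowvar=False)
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) < 1e-9

    def test_sign_convention_deterministic(self, rng):
        coeffs, _, _ = coeffs_along_directions(rng, 25, [2.0, 1.0])
        space = shape_pca(coeffs)
        for k, j in space.pc_sign_convention.items():
            assert space.loadings[k, j] > 0
            assert j == int(np.argmax(np.abs(space.loadings[k])))

    def test_fewer_than_three_shapes_rejected(self, rng):
        coeffs, _, _ = coeffs_along_directions(rng, 2, [1.0])
        with pytest.raises(ValueError):
            shape_pca(coeffs)


def signed_area_asymmetry(points: np.ndarray) -> float:
    """Left-half minus right-half area under the outline, by trapezoid integration."""
    x, y = points[:, 0], points[:, 1]
    left = x <= 0
    area = lambda m: np.trapezoid(y[m], x[m]) if m.sum() > 1 else 0.0
    return area(left) - area(~left)


class TestReconstruct:
    @pytest.fixture()
    def lean_space(self):
        from samshape import SimulationConfig, dct_transform, simulate_contour

        rng = np.random.default_rng(7)
        contours = []
        shears = rng.normal(0.0, 0.08, 60)
        for i, s in enumerate(shears):
            cfg = SimulationConfig(seed=1, contour_points=200, contour_noise_sd_um=0.2,
                                   asymmetry_shear=float(s))
            contours.append(simulate_contour(100.0, 55.0, cfg, rng=rng, contour_id=str(i)))
        aligned = procrustes_align([resample_contour(c, 200) for c in contours])
        return shape_pca(dct_transform(aligned, 12)), shears

    def test_zero_multiple_returns_mean_shape(self, lean_space):
        space, _ = lean_space
        rec = reconstruct_at_pc(space, 0, [0.0])[0]
        from samshape.dct import _inverse_vector

        expected = _inverse_vector(space.mean_coeffs, space.n_harmonics, space.n_points)
        assert np.allclose(rec.points, expected)

    def test_plus_minus_symmetry_in_coefficient_space(self, lean_space):
        space, _ = lean_space
        lo, mid, hi = reconstruct_at_pc(space, 1, [-2.0, 0.0, 2.0])
        assert np.allclose(lo.points + hi.points, 2 * mid.points, atol=1e-9)

    def test_lean_pc_reconstructions_have_opposite_asymmetry(self, lean_space):
        space, shears = lean_space
        # the lean PC is the one most correlated with the generating shear
        cors = [abs(np.corrcoef(space.scores[:, k], shears)[0, 1]) for k in range(3)]
        k = int(np.argmax(cors))
        assert cors[k] > 0.8
        lo, hi = reconstruct_at_pc(space, k, [-2.0, 2.0])
        a_lo = signed_area_asymmetry(lo.points)
        a_hi = signed_area_asymmetry(hi.points)
        assert a_lo * a_hi < 0

    def test_pc_out_of_range_rejected(self, lean_space):
        space, _ = lean_space
        with pytest.raises(ValueError):
            reconstruct_at_pc(space, space.n_pcs, [0.0])
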