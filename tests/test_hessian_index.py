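import itertools

import numpy as np
import pytest
from scipy import ndimage

from hessrad import (
    DEFAULT_SCALES,
    GaussianScale,
    Volume3D,
    eigenvalues_symmetric3,
    generate_index_images,
    index_image,
    second_derivative_filter_bank,
    smooth_and_requantize,
)
from hessrad.hessian_index import HessianField

from conftest import quadratic_volume

S10 = GaussianScale(1.0, 5)


def _interior(arr, margin=5):
    return arr[margin:-margin, margin:-margin, margin:-margin]


class TestFilterBank:
    def test_constant_volume_zero_hessian(self):
        field = second_derivative_filter_bank(Volume3D(np.full((12, 12, 12), 37.0)), S10)
        for e in field.entries.values():
            np.testing.assert_allclose(e, 0.0, atol=1e-10)

    def test_quadratic_ramp_second_derivative(self):
        a = 1.7
        vol = quadratic_volume(lambda x, y, z: a * x**2, n=20)
        field = second_derivative_filter_bank(vol, S10)
        np.testing.assert_allclose(_interior(field.entries["xx"]), 2 * a, rtol=1e-9)
        for name in ("yy", "zz", "xy", "xz", "yz"):
            np.testing.assert_allclose(_interior(field.entries[name]), 0.0, atol=1e-9)

    def test_mixed_derivative_of_bilinear(self):
        vol = quadratic_volume(lambda x, y, z: x * y, n=20)
        field = second_derivative_filter_bank(vol, S10)
        np.testing.assert_allclose(_interior(field.entries["xy"]), 1.0, rtol=1e-9)

    def test_mixed_derivative_matches_finite_difference(self):
        # compare the smoothed-field mixed derivative against a central
        # finite difference of the smoothed field itself
        rng = np.random.default_rng(5)
        data = ndimage.gaussian_filter(rng.normal(0, 50, (24, 24, 24)), 3.0)
        vol = Volume3D(data)
        field = second_derivative_filter_bank(vol, S10)
        from hessrad.hessian_index import gaussian_derivative_kernel

        w0 = gaussian_derivative_kernel(1.0, 5, 0)
        sm = data
        for ax in range(3):
            sm = ndimage.correlate1d(sm, w0, axis=ax, mode="nearest")
        fd = (
            sm[2:, 2:, :] - sm[2:, :-2, :] - sm[:-2, 2:, :] + sm[:-2, :-2, :]
        ) / 4.0
        # fd[i, j, k] approximates d2/dxdy of the smoothed field at (i+1, j+1, k)
        np.testing.assert_allclose(
            field.entries["xy"][6:-6, 6:-6, 6:-6],
            fd[5:-5, 5:-5, 6:-6],
            rtol=0.15, atol=0.05,
        )

    def test_anisotropic_volume_rejected(self):
        with pytest.raises(ValueError, match="isotropic"):
            second_derivative_filter_bank(
                Volume3D(np.zeros((6, 6, 6)), (1.0, 1.0, 3.0)), S10
            )

    def test_spacing_aware_mm_units(self):
        # same world-mm quadratic sampled at two grid spacings gives the
        # same second derivative in per-mm^2 units
        a = 0.9
        v1 = quadratic_volume(lambda x, y, z: a * x**2, n=30, spacing=0.5)
        v2 = quadratic_volume(lambda x, y, z: a * x**2, n=15, spacing=1.0)
        f1 = second_derivative_filter_bank(v1, S10)
        f2 = second_derivative_filter_bank(v2, S10)
        np.testing.assert_allclose(_interior(f1.entries["xx"], 6), 2 * a, rtol=1e-9)
        np.testing.assert_allclose(_interior(f2.entries["xx"], 4), 2 * a, rtol=1e-9)


def _field_from_matrix(m):
    shape = (1, 1, 1)
    entries = {
        "xx": np.full(shape, m[0][0]), "yy": np.full(shape, m[1][1]),
        "zz": np.full(shape, m[2][2]), "xy": np.full(shape, m[0][1]),
        "xz": np.full(shape, m[0][2]), "yz": np.full(shape, m[1][2]),
    }
    return HessianField(entries, S10, (1.0, 1.0, 1.0))


class TestEigenvalues:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[2, 0, 0], [0, -1, 0], [0, 0, 5]], (5.0, 2.0, -1.0)),
            ([[0, 0, 0], [0, 0, 0], [0, 0, 0]], (0.0, 0.0, 0.0)),
            ([[0, 1, 1], [1, 0, 1], [1, 1, 0]], (2.0, -1.0, -1.0)),
        ],
    )
    def test_known_spectra_sorted_descending(self, matrix, expected):
        lam = eigenvalues_symmetric3(_field_from_matrix(matrix), (0, 0, 0))
        np.testing.assert_allclose(lam, expected, atol=1e-9)

    def test_random_symmetric_matches_characteristic_polynomial(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = rng.normal(size=(3, 3))
            m = (a + a.T) / 2
            lam = eigenvalues_symmetric3(_field_from_matrix(m), (0, 0, 0))
            # oracle: roots of det(M - x I) expanded by hand
            c2 = -np.trace(m)
            c1 = (
                m[0, 0] * m[1, 1] + m[0, 0] * m[2, 2] + m[1, 1] * m[2, 2]
                - m[0, 1] ** 2 - m[0, 2] ** 2 - m[1, 2] ** 2
            )
            c0 = -np.linalg.det(m)
            roots = np.sort(np.roots([1.0, c2, c1, c0]).real)[::-1]
            np.testing.assert_allclose(lam, roots, rtol=1e-6, atol=1e-8)
            assert lam[0] >= lam[1] >= lam[2]


class TestIndexImage:
    @pytest.mark.parametrize(
        "form,expected",
        [
            (lambda x, y, z: -(x**2 + y**2 + z**2), 3),
            (lambda x, y, z: x**2 + y**2 + z**2, 0),
            (lambda x, y, z: x**2 + y**2 - z**2, 1),
            (lambda x, y, z: x**2 - y**2 - z**2, 2),
        ],
    )
    @pytest.mark.parametrize("scale", DEFAULT_SCALES, ids=lambda s: f"sigma{s.sigma}")
    def test_quadratic_archetypes_exact(self, form, expected, scale):
        idx = index_image(quadratic_volume(form), scale)
        assert np.all(_interior(idx.data) == expected)

    def test_raw_values_bounded(self, interior_roi_volume):
        vol, _ = interior_roi_volume
        idx = index_image(vol, S10)
        assert set(np.unique(idx.data)) <= {0, 1, 2, 3}

    def test_sign_flip_complements_index(self):
        rng = np.random.default_rng(13)
        data = ndimage.gaussian_filter(rng.normal(0, 100, (20, 20, 20)), 2.0)
        pos = index_image(Volume3D(data), S10)
        neg = index_image(Volume3D(-data), S10)
        # exclude voxels with near-zero eigenvalues
        field = second_derivative_filter_bank(Volume3D(data), S10)
        lam = np.linalg.eigvalsh(field.matrices().reshape(-1, 3, 3))
        tol = 1e-6 * np.abs(lam).max()
        safe = (np.abs(lam) > tol).all(axis=1).reshape(data.shape)
        np.testing.assert_array_equal(pos.data[safe], 3 - neg.data[safe])

    def test_rotation_invariance_under_axis_permutation(self):
        rng = np.random.default_rng(21)
        data = ndimage.gaussian_filter(rng.normal(0, 100, (18, 18, 18)), 1.5)
        base = index_image(Volume3D(data), S10).data
        for perm in itertools.permutations((0, 1, 2)):
            rotated = index_image(Volume3D(np.transpose(data, perm)), S10).data
            np.testing.assert_array_equal(rotated, np.transpose(base, perm))

    def test_flat_background_is_index_zero(self):
        idx = index_image(Volume3D(np.zeros((10, 10, 10))), S10)
        assert np.all(idx.data == 0)


class TestSmoothAndRequantize:
    def test_constant_extremes(self):
        for raw, out in [(3, 255), (0, 0)]:
            idx = index_image(Volume3D(np.zeros((9, 9, 9))), S10)
            idx.data = np.full((9, 9, 9), raw, dtype=np.uint8)
            sm = smooth_and_requantize(idx, 3)
            assert np.all(sm.data == out)

    def test_single_voxel_box_mean(self):
        idx = index_image(Volume3D(np.zeros((9, 9, 9))), S10)
        data = np.zeros((9, 9, 9), dtype=np.uint8)
        data[4, 4, 4] = 3
        idx.data = data
        sm = smooth_and_requantize(idx, 3)
        # box mean 3/27 = 1/9; round(1/9 / 3 * 255) = round(9.44) = 9
        assert sm.data[4, 4, 4] == 9

    def test_smoothed_stage_rejected_as_input(self):
        idx = index_image(Volume3D(np.zeros((9, 9, 9))), S10)
        sm = smooth_and_requantize(idx, 3)
        with pytest.raises(ValueError, match="raw"):
            smooth_and_requantize(sm, 3)
        with pytest.raises(ValueError, match="avg_kernel"):
            smooth_and_requantize(idx, 4)


class TestGenerateIndexImages:
    def test_six_images_deterministically_ordered(self, interior_roi_volume):
        vol, _ = interior_roi_volume
        imgs = generate_index_images(vol)
        assert len(imgs) == 6
        assert [(im.scale.sigma, im.avg_kernel) for im in imgs] == [
            (0.5, 3), (0.5, 5), (1.0, 3), (1.0, 5), (1.5, 3), (1.5, 5)
        ]
        for im in imgs:
            assert im.stage == "smoothed"
            assert im.data.min() >= 0 and im.data.max() <= 255

    def test_constant_volume_all_zero(self):
        for im in generate_index_images(Volume3D(np.full((12, 12, 12), 100.0))):
            assert np.all(im.data == 0)

    def test_bright_blob_core_matches_analytic_oracle(self):
        # Smoothing a Gaussian blob of width s with G_sigma gives a Gaussian
        # of width s_eff = sqrt(s^2 + sigma^2); its Hessian is negative
        # definite (index 3) for r < s_eff and has one positive radial
        # eigenvalue (index 2) beyond, which predicts the box-averaged
        # 8-bit value at the mode exactly.
        from hessrad import GaussianBlob, PhantomSpec, make_phantom

        fwhm = 4.0
        s_blob = fwhm / (2 * np.sqrt(2 * np.log(2)))
        spec = PhantomSpec(
            shape=(24, 24, 24), isovoxel=1.0,
            primitives=[GaussianBlob((12.0, 12.0, 12.0), 100.0, fwhm)],
        )
        vol, _, _ = make_phantom(spec)
        s10 = [im for im in generate_index_images(vol) if im.scale.sigma == 1.0]
        assert [im.avg_kernel for im in s10] == [3, 5]
        s_eff2 = s_blob**2 + 1.0**2
        for im in s10:
            r = im.avg_kernel // 2
            off = np.indices((2 * r + 1,) * 3) - r
            r2 = (off**2).sum(axis=0)
            oracle_mean = np.where(r2 < s_eff2, 3, 2).mean()
            expected = int(np.floor(oracle_mean / 3 * 255 + 0.5))
            assert im.data[12, 12, 12] == expected
        assert s10[0].data[12, 12, 12] == 255  # 3^3 box sits inside the core
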