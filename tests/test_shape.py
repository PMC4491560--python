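import math

import numpy as np
import pytest

from taxvision import (
    DegenerateInputError,
    InputError,
    ZERNIKE_INDICES,
    hog_baseline,
    shape_descriptor,
    standardized_moments,
    zernike_magnitudes,
)
from taxvision.shape import descriptor_table


# ---------------------------------------------------------------------------
# standardized moments
# ---------------------------------------------------------------------------

def _moment_oracle(values):
    """Direct-summation mean/variance/standardized central moments 3..8."""
    m1 = sum(values) / len(values)
    c = [v - m1 for v in values]
    var = sum(x**2 for x in c) / len(c)
    sd = math.sqrt(var)
    out = [m1, var]
    for k in range(3, 9):
        mk = sum(x**k for x in c) / len(c) / sd**k
        out.append(abs(mk) if k % 2 else mk)
    return out


class TestStandardizedMoments:
    def test_centered_square_symmetry(self):
        mask = np.zeros((41, 41), dtype=np.uint8)
        mask[10:31, 10:31] = 1
        mu = standardized_moments(mask)
        # mu1 = (0.5, 0.5); odd moments vanish by symmetry
        np.testing.assert_allclose(mu[0:2], 0.5)
        np.testing.assert_allclose(mu[[4, 5, 8, 9, 12, 13]], 0.0, atol=1e-12)

    def test_full_frame_matches_discrete_uniform_oracle(self):
        n = 101
        mask = np.ones((n, n), dtype=np.uint8)
        mu = standardized_moments(mask)
        oracle = _moment_oracle([i / (n - 1) for i in range(n)])
        for k in range(8):
            assert mu[2 * k] == pytest.approx(oracle[k], rel=1e-10)
            assert mu[2 * k + 1] == pytest.approx(oracle[k], rel=1e-10)
        # continuous-uniform limits: variance -> 1/12, kurtosis -> 1.8
        # (discrete N=101 values sit within ~2% of the limits)
        assert mu[2] == pytest.approx(1 / 12, rel=0.025)
        assert mu[6] == pytest.approx(1.8, rel=0.025)

    def test_translation_invariance_of_central_moments(self, blob_mask):
        moved = np.roll(blob_mask, (5, -4), axis=(0, 1))
        assert not np.array_equal(moved, blob_mask)
        mu0 = standardized_moments(blob_mask)
        mu1 = standardized_moments(moved)
        np.testing.assert_allclose(mu1[2:], mu0[2:], rtol=1e-9)
        assert not np.allclose(mu1[:2], mu0[:2])

    def test_empty_and_degenerate_rejected(self):
        with pytest.raises(InputError):
            standardized_moments(np.zeros((5, 5), dtype=np.uint8))
        line = np.zeros((9, 9), dtype=np.uint8)
        line[:, 4] = 1  # all foreground in one column
        with pytest.raises(DegenerateInputError):
            standardized_moments(line)


# ---------------------------------------------------------------------------
# Zernike magnitudes
# ---------------------------------------------------------------------------

def _radial_oracle(n, m, rho):
    """R_nm from the explicit factorial sum (independent of the comb-based path)."""
    total = 0.0
    for s in range((n - m) // 2 + 1):
        num = (-1) ** s * math.factorial(n - s)
        den = (
            math.factorial(s)
            * math.factorial((n + m) // 2 - s)
            * math.factorial((n - m) // 2 - s)
        )
        total += num / den * rho ** (n - 2 * s)
    return total


def _zernike_oracle(mask):
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    r = np.hypot(xs - cx, ys - cy)
    radius = r.max()
    out = []
    for n, m in ZERNIKE_INDICES:
        acc = 0.0j
        for y, x in zip(ys, xs):
            rho = math.hypot(x - cx, y - cy) / radius
            theta = math.atan2(y - cy, x - cx)
            acc += _radial_oracle(n, m, rho) * complex(
                math.cos(m * theta), -math.sin(m * theta)
            )
        out.append(abs((n + 1) / len(ys) * acc))
    return np.array(out)


class TestZernike:
    def test_index_set(self):
        assert len(ZERNIKE_INDICES) == 16
        assert all((n - m) % 2 == 0 and 0 <= m <= n <= 6 for n, m in ZERNIKE_INDICES)

    def test_full_disk_dc_magnitude(self):
        yy, xx = np.mgrid[:128, :128]
        mask = (yy - 63.5) ** 2 + (xx - 63.5) ** 2 <= 60**2
        z = zernike_magnitudes(mask)
        assert z[0] == pytest.approx(1.0, abs=1e-2)

    def test_matches_factorial_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((24, 24)) < 0.3
            if mask.sum() < 3:
                continue
            z = zernike_magnitudes(mask)
            np.testing.assert_allclose(z, _zernike_oracle(mask), atol=1e-10)

    def test_rotation_invariance_90deg(self, rng):
        from skimage.draw import ellipse

        mask = np.zeros((128, 128), dtype=bool)
        rr, cc = ellipse(64, 64, 25, 45, rotation=0.4)
        mask[rr, cc] = True
        z0 = zernike_magnitudes(mask)
        z90 = zernike_magnitudes(np.rot90(mask))
        np.testing.assert_allclose(z90, z0, rtol=0.02, atol=1e-3)

    def test_single_pixel_rejected(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 1
        with pytest.raises(DegenerateInputError):
            zernike_magnitudes(mask)


# ---------------------------------------------------------------------------
# combined descriptor and HOG baseline
# ---------------------------------------------------------------------------

class TestShapeDescriptor:
    def test_dimensionality_and_concatenation(self, blob_mask):
        d = shape_descriptor(blob_mask)
        assert d.full.shape == (32,)
        np.testing.assert_array_equal(d.full[:16], standardized_moments(blob_mask))
        np.testing.assert_array_equal(d.full[16:], zernike_magnitudes(blob_mask))

    def test_determinism(self, blob_mask):
        a = shape_descriptor(blob_mask).full
        b = shape_descriptor(blob_mask.copy()).full
        np.testing.assert_array_equal(a, b)

    def test_table_layout(self, blob_mask):
        df = descriptor_table([blob_mask] * 2, ids=["a", "b"], labels=["animal"] * 2)
        assert df.shape == (2, 34)  # id + 32 features + label
        assert df.columns[0] == "id" and df.columns[-1] == "basic_label"


class TestHogBaseline:
    def test_dimensionality(self, rng):
        assert hog_baseline(rng.random((32, 32))).full.shape == (128,)
        assert hog_baseline(rng.random((7, 50))).full.shape == (128,)

    def test_constant_image_all_zero(self):
        np.testing.assert_array_equal(hog_baseline(np.full((16, 16), 0.3)).full, 0.0)

    def test_vertical_edge_votes_horizontal_gradient_bin(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0  # vertical step edge -> gradient along x, orientation 0
        h = hog_baseline(img).full.reshape(16, 8)
        active = h.sum(axis=1) > 0
        assert active.any()
        np.testing.assert_allclose(h[active, 0], 1.0)
        np.testing.assert_allclose(h[:, 1:], 0.0, atol=1e-12)

    def test_small_image_rejected(self):
        with pytest.raises(InputError):
            hog_baseline(np.zeros((3, 10)))
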