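"""Basic-level global shape features: standardized moments and Zernike magnitudes.

The animal/plant distinction is carried by the overall silhouette of an
object rather than by local texture, so the descriptor works on a binary
mask.  It concatenates

* eight per-axis moment statistics of the foreground coordinate distribution
  (center of mass, variance, and standardized central moments of orders 3-8,
  odd orders in absolute value so left and right asymmetry count equally),
  computed independently for x and y (16 values), and
* the magnitudes of the 16 Zernike moments of order at most 6 (rotation
  invariant shape-frequency content on the unit disk),

for a 32-dimensional vector.  A block-histogram-of-gradients descriptor with
the classic 4x4-block / 8-bin layout (128 values) is provided as a local
baseline to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .exceptions import DegenerateInputError, InputError

#: (n, m) index pairs for Zernike moments of order <= 6 with n - m even,
#: m >= 0, in ascending (n, m) order; exactly 16 pairs.
ZERNIKE_INDICES: tuple[tuple[int, int], ...] = tuple(
    (n, m) for n in range(7) for m in range(n % 2, n + 1, 2)
)


@dataclass(frozen=True)
class ShapeDescriptor:
    """32-dim silhouette descriptor: 16 moment values then 16 Zernike magnitudes."""

    mu: np.ndarray
    zernike: np.ndarray

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.mu, self.zernike])


@dataclass(frozen=True)
class HogDescriptor:
    """Concatenated per-block orientation histograms (16 blocks x 8 bins)."""

    histograms: np.ndarray

    @property
    def full(self) -> np.ndarray:
        return self.histograms


def _foreground_coords(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InputError("mask must be 2-D")
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise InputError("mask has empty foreground")
    return ys, xs


def _axis_moments(v: np.ndarray) -> np.ndarray:
    """[mean, variance, |std-moment 3|, m4, |m5|, m6, |m7|, m8] of one axis."""
    m1 = v.mean()
    c = v - m1
    var = np.mean(c**2)
    if var == 0.0:
        raise DegenerateInputError(
            "foreground collapsed onto a single row/column; moments of order"
            " >= 2 are undefined"
        )
    sd = np.sqrt(var)
    out = [m1, var]
    for k in range(3, 9):
        mk = np.mean(c**k) / sd**k
        out.append(abs(mk) if k % 2 else mk)
    return np.asarray(out)


def standardized_moments(mask: np.ndarray) -> np.ndarray:
    """Per-axis moment statistics of the foreground pixel distribution.

    Foreground pixel coordinates are normalized to [0, 1] by (width - 1) and
    (height - 1) so that the values are comparable across image sizes.  The
    result interleaves axes: ``mu1_x, mu1_y, mu2_x, mu2_y, ..., mu8_x, mu8_y``.
    ``mu1`` is the center of mass, ``mu2`` the variance; orders 3-8 are
    standardized central moments with odd orders in absolute value.
    """
    ys, xs = _foreground_coords(mask)
    h, w = np.asarray(mask).shape
    x = xs / (w - 1) if w > 1 else xs.astype(np.float64)
    y = ys / (h - 1) if h > 1 else ys.astype(np.float64)
    mx = _axis_moments(x)
    my = _axis_moments(y)
    return np.stack([mx, my], axis=1).ravel()


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_nm evaluated via its binomial coefficients."""
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        coef = (-1) ** s * comb(n - s, s, exact=True) * comb(
            n - 2 * s, (n - m) // 2 - s, exact=True
        )
        out += coef * rho ** (n - 2 * s)
    return out


def zernike_magnitudes(mask: np.ndarray, max_order: int = 6) -> np.ndarray:
    """Magnitudes |A_nm| of the Zernike moments of the mask foreground.

    The foreground is mapped to the unit disk centered at its centroid with
    radius equal to the largest centroid-to-pixel distance.  Each foreground
    pixel carries area weight pi / N_fg, so

        A_nm = (n + 1) / N_fg * sum_fg R_nm(rho) * exp(-i m theta),

    which makes |A_00| equal 1 for a filled disk, matching the continuous
    normalization (n+1)/pi per unit disk area.  Returns magnitudes for all
    (n, m) with 0 <= n <= max_order, 0 <= m <= n, n - m even, in ascending
    (n, m) order (16 values at the default order 6).
    """
    ys, xs = _foreground_coords(mask)
    cy, cx = ys.mean(), xs.mean()
    dy = ys - cy
    dx = xs - cx
    r = np.hypot(dx, dy)
    radius = r.max()
    if radius == 0.0:
        raise DegenerateInputError("single-pixel foreground has zero radius")
    rho = r / radius
    theta = np.arctan2(dy, dx)
    n_fg = ys.size
    mags = []
    for n in range(max_order + 1):
        for m in range(n % 2, n + 1, 2):
            vals = _radial_poly(n, m, rho) * np.exp(-1j * m * theta)
            mags.append(abs((n + 1) / n_fg * vals.sum()))
    return np.asarray(mags)


def shape_descriptor(mask: np.ndarray) -> ShapeDescriptor:
    """The full 32-dim descriptor: standardized moments then Zernike magnitudes."""
    return ShapeDescriptor(
        mu=standardized_moments(mask), zernike=zernike_magnitudes(mask)
    )


def hog_baseline(image: np.ndarray) -> HogDescriptor:
    """Block histogram-of-gradients baseline (4x4 nonoverlapping blocks, 8 bins).

    Central-difference gradients; unsigned orientation in [0, 180) quantized
    into 8 equal bins with votes weighted by gradient magnitude; each block's
    histogram is L2-normalized independently (zero blocks stay zero) and the
    16 histograms are concatenated into a 128-vector.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 4 or image.shape[1] < 4:
        raise InputError("hog_baseline needs a 2-D image at least 4x4")
    gy, gx = np.gradient(image)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned orientation
    bins = np.minimum((ang / (np.pi / 8)).astype(int), 7)
    row_edges = np.linspace(0, image.shape[0], 5).astype(int)
    col_edges = np.linspace(0, image.shape[1], 5).astype(int)
    hists = []
    for i in range(4):
        for j in range(4):
            sl = (
                slice(row_edges[i], row_edges[i + 1]),
                slice(col_edges[j], col_edges[j + 1]),
            )
            h = np.bincount(
                bins[sl].ravel(), weights=mag[sl].ravel(), minlength=8
            )
            norm = np.linalg.norm(h)
            hists.append(h / norm if norm > 0 else h)
    return HogDescriptor(histograms=np.concatenate(hists))


def descriptor_table(masks, ids=None, labels=None) -> pd.DataFrame:
    """Tabulate 32-dim shape descriptors, one row per mask.

    Columns: ``id``, ``mu_1x .. mu_8y``, ``z_00 .. z_66``, ``basic_label``.
    """
    mu_cols = [f"mu_{k}{ax}" for k in range(1, 9) for ax in ("x", "y")]
    z_cols = [f"z_{n}{m}" for n, m in ZERNIKE_INDICES]
    rows = []
    for i, mask in enumerate(masks):
        d = shape_descriptor(mask)
        row = {"id": ids[i] if ids is not None else str(i)}
        row.update(dict(zip(mu_cols + z_cols, d.full)))
        row["basic_label"] = labels[i] if labels is not None else "-"
        rows.append(row)
    return pd.DataFrame(rows)
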