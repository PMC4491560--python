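"""Shared image preparation: grayscale conversion, cropping, binarization, resizing.

All operations work on plain :class:`numpy.ndarray` images.  Grayscale images
are 2-D float arrays with values in ``[0, 1]``; binary masks are 2-D arrays
whose values are exactly 0 or 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import DegenerateInputError, InputError

# ITU-R BT.601 luma weights for RGB -> gray.
_BT601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a raster image to a single-channel gray array in [0, 1].

    Integer inputs are rescaled by their dtype maximum (255 -> 1.0 for 8-bit);
    float inputs are assumed to already be on the [0, 1] scale and are clipped.
    RGB(A) input is reduced with BT.601 luma weights (alpha is ignored).
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise InputError("empty image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        return np.clip(arr, 0.0, 1.0)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        gray = arr[:, :, :3] @ _BT601
        return np.clip(gray, 0.0, 1.0)
    raise InputError(f"unsupported image shape {arr.shape}")


def crop_to_foreground(
    image: np.ndarray, mask: np.ndarray, margin: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Crop ``image`` and ``mask`` to the bounding box of the mask foreground.

    The tight box is expanded by ``margin`` pixels on every side, clipped to
    the image bounds.
    """
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise InputError("image and mask shapes differ")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise InputError("mask has empty foreground")
    r0 = max(rows[0] - margin, 0)
    r1 = min(rows[-1] + margin + 1, mask.shape[0])
    c0 = max(cols[0] - margin, 0)
    c1 = min(cols[-1] + margin + 1, mask.shape[1])
    return image[r0:r1, c0:c1], mask[r0:r1, c0:c1]


def binarize(image: np.ndarray) -> np.ndarray:
    """Otsu-threshold a gray image into a {0, 1} object mask.

    The global Otsu threshold splits pixels in two; the side whose mean
    intensity differs more from the image's one-pixel border ring is taken as
    the object (the border samples the background for centered objects on
    plain fields, so this resolves bright-on-dark vs dark-on-bright).  The
    returned foreground is guaranteed nonempty.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InputError("binarize expects a 2-D gray image")
    if np.unique(image).size < 2:
        raise DegenerateInputError("constant image cannot be binarized")
    # canonical polarity (dark border) so that inverting the input gives the
    # exact same mask: Otsu's histogram split is not bit-symmetric under x -> 1-x
    border_mean = np.concatenate(
        [image[0, :], image[-1, :], image[1:-1, 0], image[1:-1, -1]]
    ).mean()
    work = (image.max() + image.min()) - image if border_mean > image.mean() else image
    t = threshold_otsu(work, nbins=256)
    high = work > t
    low = ~high
    wborder = np.concatenate(
        [work[0, :], work[-1, :], work[1:-1, 0], work[1:-1, -1]]
    ).mean()
    hi_d = abs(work[high].mean() - wborder) if high.any() else -np.inf
    lo_d = abs(work[low].mean() - wborder) if low.any() else -np.inf
    fg = high if hi_d >= lo_d else low
    if not fg.any():  # pragma: no cover - guarded by the distance logic
        fg = high if high.any() else low
    return fg.astype(np.uint8)


def resize(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinearly resample a gray image to ``side`` x ``side``, clipped to [0, 1].

    Output pixel ``(i, j)`` samples input coordinate
    ``(i * (H-1) / (side-1), j * (W-1) / (side-1))`` (corner-aligned mapping),
    so constant images and identity resizes are preserved exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    if side < 1:
        raise InputError("side must be >= 1")
    h, w = image.shape
    if (h, w) == (side, side):
        return image.copy()
    ri = np.linspace(0.0, h - 1.0, side) if side > 1 else np.array([(h - 1) / 2.0])
    ci = np.linspace(0.0, w - 1.0, side) if side > 1 else np.array([(w - 1) / 2.0])
    coords = np.meshgrid(ri, ci, indexing="ij")
    out = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)
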