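"""Seeded synthetic image families with the separability structure each
pipeline stage assumes.

Real benchmarks for the three taxonomy levels are photographic collections
that cannot be bundled; these generators substitute parametric families whose
*discriminative structure* matches what each stage relies on:

* superordinate — "artificial" images are compositions of axis-aligned
  constant rectangles and square-wave gratings (sharp edges, sparse spectra);
  "natural" images are 1/f^beta random-phase noise textures (broadband
  spectra), so the two families separate in the 3-dim frequency-feature space;
* basic — binary silhouettes: "animal" is an ellipse body with four legs and
  a round head, "plant" is a radial flower or a two-level branching tree, so
  the families separate on global shape moments;
* subordinate — each fine class is a frozen prototype silhouette filled with
  a class-specific oriented sinusoidal carrier, plus noise and small
  translation jitter, so fine classes under one basic class share a coarse
  shape and genuinely need finer (eigenspace) features to tell apart.

Everything is driven by one integer seed: identical configs give
bit-identical image sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .exceptions import ConfigurationError, DataError, InputError

#: valid (superordinate, basic) edges of the taxonomy tree; "-" = level unused
TAXONOMY = {
    "artificial": {"-"},
    "natural": {"-", "animal", "plant"},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters shared by all three generators.

    ``noise_sigma`` is the std of additive gray-level noise on the [0, 1]
    scale; ``jitter`` the max translation (pixels) applied to subordinate
    samples; ``class_params`` optionally pins the per-class texture of the
    subordinate generator (mapping class name -> dict with keys ``freq``,
    ``orientation``, ``phase``).
    """

    image_side: int = 100
    n_per_class: int = 50
    seed: int = 0
    noise_sigma: float = 0.02
    jitter: int = 5
    class_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image_side < 16:
            raise ConfigurationError("image_side must be >= 16")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.jitter < 0:
            raise ConfigurationError("jitter must be >= 0")


@dataclass(frozen=True)
class LabeledImage:
    """A gray image (values in [0, 1]) with its three-level taxonomy label."""

    pixels: np.ndarray
    label: tuple[str, str, str]  # (superordinate, basic, subordinate)
    id: str

    def __post_init__(self):
        sup, basic, _ = self.label
        if sup not in TAXONOMY or basic not in TAXONOMY[sup]:
            raise InputError(f"label {self.label} is not a valid taxonomy path")


# ---------------------------------------------------------------------------
# superordinate: artificial compositions vs 1/f^beta textures
# ---------------------------------------------------------------------------

def _artificial_texture(side: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((side, side), rng.uniform(0.2, 0.8))
    for _ in range(rng.integers(2, 7)):
        r0, r1 = np.sort(rng.integers(0, side, 2))
        c0, c1 = np.sort(rng.integers(0, side, 2))
        r1, c1 = max(r1, r0 + 4), max(c1, c0 + 4)
        block = img[r0:r1, c0:c1]
        if rng.random() < 0.5:
            block[:] = rng.uniform(0.0, 1.0)
        else:  # axis-aligned square-wave grating
            period = int(rng.integers(4, 17))
            lo, hi = np.sort(rng.uniform(0.0, 1.0, 2))
            axis = int(rng.integers(0, 2))
            idx = np.arange(block.shape[axis])
            wave = np.where((idx // (period // 2)) % 2 == 0, lo, hi)
            block[:] = wave[:, None] if axis == 0 else wave[None, :]
    # stretch to the full gray range: man-made graphics are high-contrast
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img


def _natural_texture(side: int, rng: np.random.Generator) -> np.ndarray:
    beta = rng.uniform(1.5, 2.5)
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-beta)
    spectrum = amp * (rng.standard_normal(f.shape) + 1j * rng.standard_normal(f.shape))
    img = np.fft.ifft2(spectrum).real
    # moderate-contrast texture around mid gray, clipped into [0, 1]
    img = (img - img.mean()) / img.std() * 0.10 + 0.5
    return np.clip(img, 0.0, 1.0)


def gen_superordinate_set(cfg: SyntheticConfig) -> list[LabeledImage]:
    """2 * n_per_class gray textures labeled artificial / natural."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for i in range(cfg.n_per_class):
        img = _artificial_texture(cfg.image_side, rng)
        img = np.clip(img + rng.normal(0, cfg.noise_sigma, img.shape), 0, 1)
        out.append(LabeledImage(img, ("artificial", "-", "-"), f"art_{i:04d}"))
    for i in range(cfg.n_per_class):
        img = _natural_texture(cfg.image_side, rng)
        img = np.clip(img + rng.normal(0, cfg.noise_sigma, img.shape), 0, 1)
        out.append(LabeledImage(img, ("natural", "-", "-"), f"nat_{i:04d}"))
    return out


# ---------------------------------------------------------------------------
# basic: animal vs plant silhouettes
# ---------------------------------------------------------------------------

def _draw_animal(side: int, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((side, side), dtype=bool)
    cy, cx = side * 0.48, side * 0.5
    a = side * rng.uniform(0.18, 0.26)          # body semi-axis, horizontal
    b = a * rng.uniform(0.45, 0.70)             # vertical semi-axis
    rr, cc = draw.ellipse(cy, cx, b, a, shape=mask.shape)
    mask[rr, cc] = True
    leg_len = side * rng.uniform(0.12, 0.20)
    leg_w = max(2, int(side * rng.uniform(0.02, 0.04)))
    for off in (-0.75, -0.3, 0.3, 0.75):
        lc = int(cx + off * a)
        r0 = int(cy + b * 0.5)
        r1 = min(int(r0 + leg_len), side)
        mask[r0:r1, max(lc - leg_w // 2, 0): lc + leg_w // 2 + 1] = True
    head_r = b * rng.uniform(0.55, 0.80)
    hy = cy - b * rng.uniform(0.3, 0.7)
    hx = cx + a * rng.uniform(0.9, 1.1)
    rr, cc = draw.disk((hy, hx), head_r, shape=mask.shape)
    mask[rr, cc] = True
    angle = rng.uniform(-15.0, 15.0)
    rot = ndimage.rotate(mask.astype(float), angle, reshape=False, order=0)
    return rot > 0.5


def _draw_flower(side: int, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((side, side), dtype=bool)
    cy = cx = side * 0.5
    r0 = side * rng.uniform(0.05, 0.08)
    petals = int(rng.integers(5, 13))
    plen = side * rng.uniform(0.16, 0.26)
    pwid = plen * rng.uniform(0.30, 0.50)
    rr, cc = draw.disk((cy, cx), r0, shape=mask.shape)
    mask[rr, cc] = True
    for i in range(petals):
        phi = 2 * math.pi * i / petals + rng.uniform(-0.08, 0.08)
        py = cy + (r0 + plen / 2) * math.sin(phi)
        px = cx + (r0 + plen / 2) * math.cos(phi)
        rr, cc = draw.ellipse(py, px, pwid / 2, plen / 2,
                              shape=mask.shape, rotation=-phi)
        mask[rr, cc] = True
    return mask


def _thick_line(mask: np.ndarray, p0, p1, width: int) -> None:
    rr, cc = draw.line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    keep = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    line = np.zeros_like(mask)
    line[rr[keep], cc[keep]] = True
    if width > 1:
        line = ndimage.binary_dilation(line, iterations=width - 1)
    mask |= line


def _draw_tree(side: int, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((side, side), dtype=bool)
    base = (int(side * 0.92), int(side * 0.5))
    top = (int(side * rng.uniform(0.45, 0.55)), int(side * 0.5))
    _thick_line(mask, base, top, max(2, int(side * 0.02)))
    for ang in (-50, 0, 50):
        a1 = math.radians(ang + rng.uniform(-10, 10))
        L1 = side * rng.uniform(0.14, 0.20)
        tip1 = (top[0] - L1 * math.cos(a1), top[1] + L1 * math.sin(a1))
        _thick_line(mask, top, tip1, max(2, int(side * 0.012)))
        for sub in (-35, 35):
            a2 = a1 + math.radians(sub + rng.uniform(-8, 8))
            L2 = L1 * rng.uniform(0.5, 0.7)
            tip2 = (tip1[0] - L2 * math.cos(a2), tip1[1] + L2 * math.sin(a2))
            _thick_line(mask, tip1, tip2, max(1, int(side * 0.01)))
            rr, cc = draw.disk(tip2, side * rng.uniform(0.045, 0.07),
                               shape=mask.shape)
            mask[rr, cc] = True
    return mask


_FG_RANGE = (0.05, 0.6)


def _draw_silhouette(basic: str, side: int, rng: np.random.Generator) -> np.ndarray:
    """One silhouette of the requested basic class, with the foreground
    fraction guaranteed inside the generator contract range."""
    for _ in range(20):
        if basic == "animal":
            mask = _draw_animal(side, rng)
        else:
            mask = _draw_flower(side, rng) if rng.random() < 0.5 else _draw_tree(side, rng)
        frac = mask.mean()
        if _FG_RANGE[0] <= frac <= _FG_RANGE[1]:
            return mask
    raise DataError("silhouette generator failed the foreground-fraction contract")


def gen_basic_silhouette_set(cfg: SyntheticConfig) -> list[LabeledImage]:
    """2 * n_per_class binary masks labeled animal / plant (values in {0, 1})."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for basic, tag in (("animal", "ani"), ("plant", "pla")):
        for i in range(cfg.n_per_class):
            mask = _draw_silhouette(basic, cfg.image_side, rng)
            out.append(
                LabeledImage(
                    mask.astype(np.float64),
                    ("natural", basic, "-"),
                    f"{tag}_{i:04d}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# subordinate: textured prototype silhouettes nested under the basic classes
# ---------------------------------------------------------------------------

def _class_texture(mask: np.ndarray, freq: float, orientation: float,
                   phase: float) -> np.ndarray:
    side = mask.shape[0]
    v, u = np.mgrid[0:side, 0:side] / side
    carrier = np.sin(
        2 * np.pi * freq * (u * np.cos(orientation) + v * np.sin(orientation))
        + phase
    )
    return mask * (0.55 + 0.40 * carrier)


def gen_subordinate_set(
    cfg: SyntheticConfig, classes_per_basic: int = 6
) -> list[LabeledImage]:
    """Gray images for ``classes_per_basic`` fine classes under each basic class.

    Each class is a frozen prototype silhouette (drawn once from a
    class-derived seed) filled with a class-specific oriented sinusoid;
    samples differ by translation jitter (± ``cfg.jitter`` px) and additive
    Gaussian noise (``cfg.noise_sigma``).
    """
    if classes_per_basic < 2:
        raise ConfigurationError("classes_per_basic must be >= 2")
    sample_rng = np.random.default_rng(cfg.seed)
    out = []
    for b_idx, basic in enumerate(("animal", "plant")):
        for j in range(classes_per_basic):
            cls = f"{basic}_{j}"
            class_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, b_idx, j])
            )
            proto = _draw_silhouette(basic, cfg.image_side, class_rng)
            params = {
                "freq": class_rng.uniform(4.0, 12.0),
                "orientation": class_rng.uniform(0.0, np.pi),
                "phase": class_rng.uniform(0.0, 2 * np.pi),
            }
            params.update(cfg.class_params.get(cls, {}))
            base_img = _class_texture(
                proto.astype(float), params["freq"], params["orientation"],
                params["phase"],
            )
            for i in range(cfg.n_per_class):
                img = base_img
                if cfg.jitter > 0:
                    dy, dx = sample_rng.integers(-cfg.jitter, cfg.jitter + 1, 2)
                    img = ndimage.shift(img, (dy, dx), order=0, cval=0.0)
                if cfg.noise_sigma > 0:
                    img = img + sample_rng.normal(0, cfg.noise_sigma, img.shape)
                out.append(
                    LabeledImage(
                        np.clip(img, 0.0, 1.0),
                        ("natural", basic, cls),
                        f"{cls}_{i:04d}",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# on-disk layout: <root>/<superordinate>/<basic>/<subordinate>/<id>.png
# ---------------------------------------------------------------------------

def write_dataset(images: list[LabeledImage], root, overwrite: bool = False) -> Path:
    """Write PNGs into the three-level label tree plus a manifest.csv.

    Pixels are quantized to 8 bits.  Refuses to write into an existing
    non-empty directory unless ``overwrite`` is set.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise DataError(f"target {root} exists and is not empty")
    rows = []
    for im in images:
        sup, basic, sub = im.label
        d = root / sup / basic / sub
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{im.id}.png"
        iio.imwrite(path, np.round(im.pixels * 255).astype(np.uint8))
        rows.append(
            {
                "id": im.id,
                "path": str(path.relative_to(root)),
                "superordinate": sup,
                "basic": basic,
                "subordinate": sub,
            }
        )
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root / "manifest.csv"


def load_dataset(root) -> list[LabeledImage]:
    """Read a dataset written by :func:`write_dataset` back into memory."""
    root = Path(root)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise DataError(f"no manifest.csv under {root}")
    df = pd.read_csv(manifest, keep_default_na=False)
    if df.empty:
        raise DataError(f"manifest under {root} lists no images")
    out = []
    for row in df.itertuples():
        pixels = iio.imread(root / row.path).astype(np.float64) / 255.0
        out.append(
            LabeledImage(
                pixels,
                (row.superordinate, row.basic, row.subordinate),
                row.id,
            )
        )
    return out
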