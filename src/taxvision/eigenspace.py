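"""Subordinate-level eigenspace features: flat vs conceptual subspace projection.

Fine-grained classes nested under broad "basic" classes (e.g. six animal and
six plant species) are represented by projecting each 100x100 gray image onto
principal axes of the training set.  Two regimes are compared:

* **flat** — one pooled PCA basis fitted over all training images;
* **conceptual** — a separate basis per basic class, with the per-class
  projections concatenated, so each feature block measures resemblance to one
  conceptual family.

Because the number of training images n is far smaller than the pixel
dimension d = side^2, the bases are obtained through the small-covariance
(Gram) trick: eigendecompose the n x n matrix Sc'Sc of the centered data and
map eigenvectors back by u = Sc v, then unit-normalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, RankError

_RANK_RTOL = 1e-10  # eigenvalues below this fraction of the largest are noise

#: key used for the pooled basis in flat mode
FLAT_KEY = "__flat__"


@dataclass
class EigenSpaceModel:
    """Mean image(s) plus orthonormal eigenbasis/bases with eigenvalues.

    ``mode`` is ``"flat"`` (single pooled subspace, key ``FLAT_KEY``) or
    ``"conceptual"`` (one subspace per basic class, concatenated in sorted
    class order at projection time).  Basis columns are unit-norm, pairwise
    orthogonal, sorted by descending eigenvalue, with the deterministic sign
    convention that each column's largest-magnitude entry is positive.
    Images are vectorized in row-major (row-then-column) scan order.
    """

    mode: str
    image_shape: tuple[int, int]
    means: dict[str, np.ndarray] = field(default_factory=dict)
    bases: dict[str, np.ndarray] = field(default_factory=dict)
    eigenvalues: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def subspace_keys(self) -> list[str]:
        return [FLAT_KEY] if self.mode == "flat" else sorted(self.bases)

    @property
    def n_features(self) -> int:
        return sum(self.bases[k].shape[1] for k in self.subspace_keys)

    def save(self, path) -> None:
        payload = {"mode": self.mode, "image_shape": np.array(self.image_shape)}
        for k in self.bases:
            payload[f"mean::{k}"] = self.means[k]
            payload[f"basis::{k}"] = self.bases[k]
            payload[f"eigenvalues::{k}"] = self.eigenvalues[k]
        np.savez(path, vectorization="row-major", **payload)

    @classmethod
    def load(cls, path) -> "EigenSpaceModel":
        with np.load(path, allow_pickle=False) as z:
            model = cls(
                mode=str(z["mode"]), image_shape=tuple(int(v) for v in z["image_shape"])
            )
            for name in z.files:
                if "::" in name:
                    kind, key = name.split("::", 1)
                    getattr(model, {"mean": "means", "basis": "bases",
                                    "eigenvalues": "eigenvalues"}[kind])[key] = z[name]
        return model


def _as_matrix(images) -> tuple[np.ndarray, tuple[int, int]]:
    imgs = [np.asarray(im, dtype=np.float64) for im in images]
    if not imgs:
        raise InputError("no images given")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise InputError("all images must share one shape")
    S = np.stack([im.ravel(order="C") for im in imgs], axis=1)
    return S, shape


def fit_subspace(images, k: int | None = None):
    """PCA basis of a set of same-size gray images via the Gram-matrix trick.

    Returns ``(mean, basis, eigenvalues)``: the mean image vector, a d x k
    orthonormal basis, and the k leading Gram eigenvalues (descending).
    ``k=None`` keeps every direction whose eigenvalue exceeds 1e-10 of the
    largest; asking for more than that rank raises :class:`RankError`.
    """
    S, _ = _as_matrix(images)
    n = S.shape[1]
    if n < 2:
        raise InputError("need at least 2 images to fit a subspace")
    mean = S.mean(axis=1)
    Sc = S - mean[:, None]
    G = Sc.T @ Sc
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.maximum(w, 0.0)
    avail = int(np.count_nonzero(w > _RANK_RTOL * w[0])) if w[0] > 0 else 0
    if avail == 0:
        raise RankError("centered data has rank 0 (all images identical)")
    if k is None:
        k = avail
    elif k > avail:
        raise RankError(f"requested k={k} exceeds available rank {avail}")
    U = Sc @ V[:, :k]
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    # sign convention: largest-magnitude entry of each eigenvector is positive
    idx = np.argmax(np.abs(U), axis=0)
    U *= np.where(U[idx, np.arange(k)] < 0, -1.0, 1.0)
    return mean, U, w[:k]


def fit_flat(images, labels, k: int | None = None) -> EigenSpaceModel:
    """Single pooled subspace over all training images (flat mode)."""
    labels = list(labels)
    if len(set(labels)) < 2:
        raise InputError("flat training set must contain both basic classes")
    S, shape = _as_matrix(images)
    if len(labels) != S.shape[1]:
        raise InputError("labels/images length mismatch")
    mean, U, w = fit_subspace(images, k)
    return EigenSpaceModel(
        mode="flat",
        image_shape=shape,
        means={FLAT_KEY: mean},
        bases={FLAT_KEY: U},
        eigenvalues={FLAT_KEY: w},
    )


def fit_conceptual(images, labels, k: int | dict | None = None) -> EigenSpaceModel:
    """Independent subspace per basic class; projections concatenate (sorted keys).

    ``k`` may be a single count applied to every class, a dict keyed by class,
    or ``None`` for the full available rank per class.
    """
    imgs = list(images)
    labels = list(labels)
    if len(imgs) != len(labels):
        raise InputError("labels/images length mismatch")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise InputError("conceptual mode needs at least two basic classes")
    _, shape = _as_matrix(imgs)
    model = EigenSpaceModel(mode="conceptual", image_shape=shape)
    for cls in classes:
        members = [im for im, lb in zip(imgs, labels) if lb == cls]
        if len(members) < 2:
            raise InputError(f"basic class {cls!r} has fewer than 2 images")
        kc = k.get(cls) if isinstance(k, dict) else k
        mean, U, w = fit_subspace(members, kc)
        model.means[cls] = mean
        model.bases[cls] = U
        model.eigenvalues[cls] = w
    return model


def project(model: EigenSpaceModel, image: np.ndarray) -> np.ndarray:
    """Project one gray image into the model's feature space.

    Flat mode returns ``U'(x - mean)``; conceptual mode concatenates the
    centered projections onto each class subspace in sorted class order.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != model.image_shape:
        raise InputError(
            f"image shape {image.shape} does not match model {model.image_shape}"
        )
    x = image.ravel(order="C")
    parts = [
        model.bases[kk].T @ (x - model.means[kk]) for kk in model.subspace_keys
    ]
    return np.concatenate(parts)


def project_many(model: EigenSpaceModel, images) -> np.ndarray:
    """Stack :func:`project` over a batch into an (n_images, n_features) array."""
    return np.stack([project(model, im) for im in images])
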