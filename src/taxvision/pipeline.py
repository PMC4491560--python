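"""End-to-end pipelines tying the feature stages to the evaluation harnesses.

These are the workflows the package exists for, expressed once so the CLI,
the examples and the acceptance checks all run the same code paths:

* :func:`superordinate_clustering` — frequency features + fuzzy c-means +
  cluster metrics for the unsupervised artificial/natural split;
* :func:`basic_classification` — 32-dim shape descriptors + repeated-split
  linear SVM for the animal/plant split;
* :func:`eigen_recognition_harness` — flat or conceptual eigenspace features
  refitted on each training split + linear SVM for subordinate classes.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import eigenspace, evaluate
from .evaluate import ClassificationReport, ClusterMetrics, FuzzyClustering
from .exceptions import InputError
from .frequency import frequency_features
from .shape import shape_descriptor
from .synthetic import LabeledImage


def superordinate_clustering(
    dataset: list[LabeledImage], seed: int | None = 0
) -> tuple[ClusterMetrics, FuzzyClustering]:
    """Cluster frequency features of a labeled set and score the 2-way split.

    Returns the cluster metrics (positive class "natural") together with the
    fuzzy partition itself.
    """
    feats = np.stack([frequency_features(im.pixels).as_array() for im in dataset])
    truth = np.array([im.label[0] for im in dataset])
    fcm = evaluate.fuzzy_cmeans(feats, c=2, seed=seed)
    hard = fcm.memberships.argmax(axis=1)
    metrics = evaluate.cluster_metrics(hard, truth, positive_class="natural")
    return metrics, fcm


def basic_classification(
    dataset: list[LabeledImage],
    train_fraction: float = 0.5,
    n_runs: int = 10,
    seed: int | None = 0,
) -> ClassificationReport:
    """Repeated-split linear-SVM accuracy of the 32-dim shape descriptor."""
    feats = np.stack([shape_descriptor(im.pixels > 0.5).full for im in dataset])
    labels = [im.label[1] for im in dataset]
    return evaluate.classification_harness(
        feats, labels, train_fraction=train_fraction, n_runs=n_runs, seed=seed
    )


def _resolve_k(n_train: int, k) -> int | None:
    """Translate a k request into a per-subspace count.

    ``None`` keeps the full post-centering rank (n - 1); ``"half"`` keeps
    half of it; an int is passed through.
    """
    if k is None:
        return None
    if k == "half":
        return max(1, (n_train - 1) // 2)
    return int(k)


def eigen_recognition_harness(
    dataset: list[LabeledImage],
    mode: str = "conceptual",
    k=None,
    train_fraction: float = 0.5,
    n_runs: int = 10,
    seed: int | None = 0,
) -> ClassificationReport:
    """Subordinate-class accuracy of flat or conceptual eigenspace features.

    Per run: stratified split over subordinate labels, eigenspace model
    fitted on the training images only (pooled for ``mode="flat"``, per basic
    class for ``mode="conceptual"``), all images projected, and a linear SVM
    (C = 1, z-scored projections) evaluated on the held-out images.  ``k``
    may be ``None`` (all available eigenvectors), ``"half"``, or an int per
    subspace.
    """
    if mode not in ("flat", "conceptual"):
        raise InputError(f"unknown mode {mode!r}")
    pixels = [im.pixels for im in dataset]
    basic = np.array([im.label[1] for im in dataset])
    sub = np.array([im.label[2] for im in dataset])
    classes = np.unique(sub)
    splitter = StratifiedShuffleSplit(
        n_splits=n_runs, train_size=train_fraction, random_state=seed
    )
    totals, per_cls = [], {c: [] for c in classes}
    for train_idx, test_idx in splitter.split(np.zeros(len(sub)), sub):
        train_imgs = [pixels[i] for i in train_idx]
        if mode == "flat":
            model = eigenspace.fit_flat(
                train_imgs, basic[train_idx], _resolve_k(len(train_idx), k)
            )
        else:
            counts = {
                c: int(np.sum(basic[train_idx] == c))
                for c in np.unique(basic[train_idx])
            }
            kc = {c: _resolve_k(n, k) for c, n in counts.items()}
            model = eigenspace.fit_conceptual(train_imgs, basic[train_idx], kc)
        feats = eigenspace.project_many(model, pixels)
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(feats[train_idx], sub[train_idx])
        pred = clf.predict(feats[test_idx])
        yt = sub[test_idx]
        totals.append(100.0 * np.mean(pred == yt))
        for c in classes:
            sel = yt == c
            per_cls[c].append(100.0 * np.mean(pred[sel] == c))
    return ClassificationReport(
        per_class={c: evaluate._mean_std(np.array(v)) for c, v in per_cls.items()},
        total=evaluate._mean_std(np.array(totals)),
        n_runs=n_runs,
        train_fraction=train_fraction,
        seed=seed,
        per_run_total=np.asarray(totals),
        per_run_class={c: np.asarray(v) for c, v in per_cls.items()},
    )
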