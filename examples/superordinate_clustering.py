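"""Unsupervised artificial-vs-natural separation from global spectrum features.

Generates 100 synthetic textures (50 sharp-edged "artificial" compositions,
50 1/f-noise "natural" textures), summarizes each image's 2-D Fourier
spectrum into three numbers (total magnitude, total log-magnitude, total
phase), clusters them with fuzzy c-means, and scores the discovered 2-way
partition against the true superordinate labels.
"""

import numpy as np

import taxvision as tv
from taxvision.frequency import frequency_features
from taxvision.pipeline import superordinate_clustering

cfg = tv.SyntheticConfig(n_per_class=50, seed=7)
images = tv.gen_superordinate_set(cfg)

feats = np.stack([frequency_features(im.pixels).as_array() for im in images])
labels = np.array([im.label[0] for im in images])
for name in ("artificial", "natural"):
    mean = feats[labels == name].mean(axis=0)
    print(f"{name:>10s}: f1={mean[0]:9.0f}  f2={mean[1]:8.0f}  f3={mean[2]:6.2f}")

metrics, fcm = superordinate_clustering(images, seed=0)
print(f"\nfuzzy c-means converged in {fcm.n_iter} iterations")
print(
    f"f-measure={metrics.f_measure:.3f}  precision={metrics.precision:.3f}  "
    f"recall={metrics.recall:.3f}  accuracy={metrics.accuracy:.3f}"
)
print(
    "\nThe two texture families separate without supervision: high-contrast\n"
    "sharp-edged compositions put far more total spectral magnitude (f1, f2)\n"
    "on the table than moderate-contrast 1/f noise, so the fuzzy clusters\n"
    "align with the true artificial/natural labels."
)
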