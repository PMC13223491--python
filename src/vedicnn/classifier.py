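"""Lesion classification: handcrafted features + maximum-margin separator.

After segmentation, the lesion is described by shape (area fraction,
circularity, solidity, boundary-curvature variance), texture (interior
variance, local contrast) and intensity (interior mean, interior/background
contrast ratio) features, and a linear maximum-margin classifier on
standardized features emits a benign(0)/malignant(1) decision score with a
signed margin for diagnostics.  Spiculated malignant lesions separate from
smooth benign ones chiefly through circularity and curvature variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label, regionprops
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .phantom_data import boundary_roughness

__all__ = ["FEATURE_NAMES", "extract_features", "LesionClassifier",
           "fit", "predict"]

FEATURE_NAMES = (
    "area_frac", "circularity", "solidity", "curvature_var",
    "interior_var", "local_contrast", "interior_mean", "contrast_ratio",
)


def extract_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Feature vector of the largest connected mask component.

    Raises ``ValueError`` on an empty mask ("no lesion").
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask: no lesion to describe")
    lab = cc_label(mask)
    props = max(regionprops(lab), key=lambda p: p.area)
    comp = lab == props.label

    area = float(props.area)
    # Crofton perimeter: unbiased for smooth shapes, unlike the chain-code
    # estimator which overestimates circles by ~3%
    perim = max(float(props.perimeter_crofton), 1.0)
    circularity = min(4.0 * np.pi * area / perim**2, 1.0)
    solidity = float(props.solidity)
    curva = boundary_roughness(comp.astype(np.uint8))

    inside = image[comp]
    outside = image[~comp]
    smooth = gaussian_filter(image, 2.0)
    local_contrast = float(np.mean(np.abs(image - smooth)[comp]))
    interior_mean = float(inside.mean())
    bg_mean = float(outside.mean()) if outside.size else interior_mean
    contrast_ratio = interior_mean / max(bg_mean, 1e-9)

    return np.array([
        area / mask.size, circularity, solidity, curva,
        float(inside.var()), local_contrast, interior_mean, contrast_ratio,
    ])


@dataclass
class LesionClassifier:
    pipeline: Pipeline

    def predict(self, features: np.ndarray) -> tuple[int, float]:
        """Hard 0/1 label plus the signed margin (distance to the hyperplane
        in standardized feature space)."""
        f = np.asarray(features, dtype=np.float64).reshape(1, -1)
        label = int(self.pipeline.predict(f)[0])
        margin = float(self.pipeline.decision_function(f)[0])
        return label, margin

    def predict_batch(self, features: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(features, dtype=np.float64))


def fit(features, labels, C: float = 1.0) -> LesionClassifier:
    """Fit the maximum-margin linear separator on standardized features.

    ``labels`` are 0 (benign) / 1 (malignant); at least two classes must be
    present.  Deterministic for a given input.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need samples from at least two classes")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="linear", C=C, random_state=0)),
    ])
    pipe.fit(X, y)
    return LesionClassifier(pipe)


def predict(model: LesionClassifier, features) -> tuple[int, float]:
    return model.predict(features)
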