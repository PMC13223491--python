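"""Segmentation and image-quality metrics.

Pixel-level confusion counts and the ratio scores derived from them
(accuracy, precision, specificity, sensitivity, F-score, IoU, Dice), plus
PSNR and SSIM for denoising quality.  Undefined ratios (zero denominators,
e.g. an empty predicted and true mask) are reported as NaN with a flag
rather than silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ConfusionMatrix", "confusion", "scores", "psnr", "ssim",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Pixelwise confusion counts between two binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def scores(cm: ConfusionMatrix) -> dict[str, float]:
    """Derived scores; NaN marks an undefined ratio, ``defined`` lists flags."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(sensitivity) \
            or precision + sensitivity == 0:
        f_score = float("nan")
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    out = {
        "accuracy": _ratio(tp + tn, cm.total),
        "precision": precision,
        "specificity": _ratio(tn, tn + fp),
        "sensitivity": sensitivity,
        "f_score": f_score,
        "iou": _ratio(tp, tp + fp + fn),
        "dsc": _ratio(2 * tp, 2 * tp + fp + fn),
    }
    out["defined"] = {k: not math.isnan(v) for k, v in out.items()}
    return out


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError("image shapes differ")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * math.log10(peak * peak / mse)


def ssim(ref: np.ndarray, test: np.ndarray, peak: float = 1.0,
         sigma: float = 1.5, truncate: float = 3.5,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with a Gaussian window.

    Standard formulation: 11×11 Gaussian weights (sigma 1.5), stabilizers
    C1=(k1·peak)^2, C2=(k2·peak)^2, population (weighted) moments, and the
    half-window border cropped before averaging.
    """
    x = np.asarray(ref, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("image shapes differ")
    r = int(truncate * sigma + 0.5)
    win = 2 * r + 1
    if min(x.shape) < win:
        raise ValueError("window larger than image")
    f = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(x, **f)
    uy = gaussian_filter(y, **f)
    uxx = gaussian_filter(x * x, **f)
    uyy = gaussian_filter(y * y, **f)
    uxy = gaussian_filter(x * y, **f)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * peak) ** 2
    c2 = (k2 * peak) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / \
        ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    core = s[tuple(slice(pad, d - pad) for d in s.shape)]
    return float(core.mean(dtype=np.float64))
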