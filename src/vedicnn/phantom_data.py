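"""Seeded synthetic breast-ultrasound-like phantoms.

Stands in for a clinical B-mode ultrasound dataset: each phantom is a
grayscale image with a paired binary ground-truth mask and a benign /
malignant / normal label.  Benign lesions are smooth-margined ellipses,
malignant lesions are irregular spiculated polygons with heterogeneous
interior texture; both are hypoechoic (darker than the surrounding tissue).
Noise is first-order ultrasound speckle — a multiplicative Rayleigh field —
plus optional additive Gaussian sensor noise.  Everything is deterministic
under the spec's seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours

__all__ = [
    "PhantomSpec", "Phantom", "generate", "generate_dataset",
    "boundary_roughness", "write_manifest",
]

LESION_CLASSES = ("benign", "malignant", "normal")


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (128, 128)
    lesion_class: str = "benign"
    lesion_area_frac: float = 0.08
    speckle_scale: float = 0.5
    gaussian_sigma: float = 0.02
    contrast: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")
        if self.lesion_class != "normal" and not 0 < self.lesion_area_frac <= 0.3:
            raise ValueError("lesion area fraction must be in (0, 0.3]")
        if self.speckle_scale < 0 or self.gaussian_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if min(self.size) < 16:
            raise ValueError("phantom smaller than 16 pixels is infeasible")


@dataclass
class Phantom:
    image: np.ndarray          # noisy observation in [0, 1]
    clean: np.ndarray          # noise-free construction (denoising target)
    mask: np.ndarray           # binary ground truth
    label: str
    spec: PhantomSpec


def _lesion_polygon(rng: np.random.Generator, cls: str,
                    target_area: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed boundary (y, x offsets from center) scaled to ``target_area``."""
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    if cls == "benign":
        # smooth ellipse with mild eccentricity and random orientation
        q = rng.uniform(0.6, 0.95)
        rot = rng.uniform(0, np.pi)
        r = 1.0 / np.sqrt((np.cos(theta - rot) ** 2) + (np.sin(theta - rot) / q) ** 2)
    else:
        # spiculated star: low-order lobes plus sharp high-order spikes
        n_spikes = int(rng.integers(7, 13))
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.30, 0.50)
        lobes = 0.15 * np.sin(int(rng.integers(2, 5)) * theta
                              + rng.uniform(0, 2 * np.pi))
        spikes = amp * np.abs(np.sin(n_spikes * theta / 2 + phase)) ** 3
        r = 1.0 + lobes + spikes
    # shoelace area of the unit-scale outline, then exact rescale
    y = r * np.sin(theta)
    x = r * np.cos(theta)
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    s = np.sqrt(target_area / area)
    return y * s, x * s


def generate(spec: PhantomSpec) -> Phantom:
    """Generate one phantom (image, mask, label) from its spec, seeded."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)

    # textured tissue background
    base = 0.55 + 0.05 * rng.uniform(-1, 1)
    tex = gaussian_filter(rng.standard_normal((h, w)), sigma=4.0)
    tex /= max(np.abs(tex).max(), 1e-12)
    clean = base + 0.06 * tex

    mask = np.zeros((h, w), dtype=np.uint8)
    if spec.lesion_class != "normal":
        target_area = spec.lesion_area_frac * h * w
        cy = h / 2 + rng.uniform(-0.12, 0.12) * h
        cx = w / 2 + rng.uniform(-0.12, 0.12) * w
        dy, dx = _lesion_polygon(rng, spec.lesion_class, target_area)
        rr, cc = draw_polygon(cy + dy, cx + dx, shape=(h, w))
        mask[rr, cc] = 1
        if mask.sum() < 0.5 * target_area:
            raise ValueError("lesion does not fit the image at this area fraction")
        interior = mask.astype(float)
        if spec.lesion_class == "benign":
            # well-defined smooth margin: soft transition of the contrast dip
            soft = gaussian_filter(interior, sigma=1.2)
            clean = clean - spec.contrast * soft
        else:
            # irregular margin and heterogeneous interior echo texture
            soft = gaussian_filter(interior, sigma=0.5)
            inner_tex = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
            inner_tex /= max(np.abs(inner_tex).max(), 1e-12)
            clean = clean - spec.contrast * soft * (1.0 + 0.45 * inner_tex)
    clean = np.clip(clean, 0.02, 0.98)

    noisy = clean.copy()
    if spec.speckle_scale > 0:
        # Rayleigh field normalized to unit mean; blend controls noise power
        ray = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(h, w))
        noisy = noisy * (1.0 + spec.speckle_scale * (ray - 1.0))
    if spec.gaussian_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sigma, size=(h, w))
    noisy = np.clip(noisy, 0.0, 1.0)
    return Phantom(image=noisy, clean=clean, mask=mask,
                   label=spec.lesion_class, spec=spec)


def boundary_roughness(mask: np.ndarray, smooth: float = 2.0) -> float:
    """Curvature variance of the longest mask contour.

    The contour is lightly smoothed before differentiating so the statistic
    reflects lesion-margin geometry rather than pixel-grid staircase.
    """
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    c = max(contours, key=len)
    y = gaussian_filter(c[:, 0], smooth, mode="wrap")
    x = gaussian_filter(c[:, 1], smooth, mode="wrap")
    dy, dx = np.gradient(y), np.gradient(x)
    d2y, d2x = np.gradient(dy), np.gradient(dx)
    denom = (dx**2 + dy**2) ** 1.5 + 1e-12
    kappa = (dx * d2y - dy * d2x) / denom
    return float(np.var(kappa))


def generate_dataset(n: int, class_mix: dict[str, float] | None = None,
                     split_ratio: float = 0.8, seed: int = 0,
                     size: tuple[int, int] = (128, 128),
                     **spec_kwargs) -> tuple[list[Phantom], list[Phantom]]:
    """Seeded stratified train/test phantom sets.

    ``class_mix`` gives per-class proportions (default: half benign, half
    malignant).  Each phantom draws its own child seed from the master seed,
    so the dataset is reproducible element by element.
    """
    if n < 5:
        raise ValueError("need at least 5 phantoms for a stratified split")
    if not 0 < split_ratio < 1:
        raise ValueError("split ratio must be in (0, 1)")
    mix = class_mix or {"benign": 0.5, "malignant": 0.5}
    if any(c not in LESION_CLASSES for c in mix):
        raise ValueError("unknown class in mix")
    counts = {c: int(round(f * n)) for c, f in mix.items()}
    # rounding drift goes to the first class
    first = next(iter(counts))
    counts[first] += n - sum(counts.values())
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(n))
    train: list[Phantom] = []
    test: list[Phantom] = []
    for cls, cnt in counts.items():
        if cnt < 2:
            raise ValueError(f"class {cls!r} too small to stratify ({cnt})")
        n_train = int(round(split_ratio * cnt))
        n_train = min(max(n_train, 1), cnt - 1)
        for i in range(cnt):
            child_seed = int(next(child).generate_state(1)[0] % (2**31))
            spec = PhantomSpec(size=size, lesion_class=cls, seed=child_seed,
                               **spec_kwargs)
            ph = generate(spec)
            (train if i < n_train else test).append(ph)
    return train, test


def write_manifest(path, phantoms: list[Phantom],
                   filenames: list[str] | None = None) -> None:
    """CSV manifest: one row per phantom with its full generating spec."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed", "height", "width",
                         "lesion_area_frac", "speckle_scale",
                         "gaussian_sigma", "contrast"])
        for i, ph in enumerate(phantoms):
            name = filenames[i] if filenames else f"phantom_{i:04d}.png"
            s = ph.spec
            writer.writerow([name, ph.label, s.seed, s.size[0], s.size[1],
                             s.lesion_area_frac, s.speckle_scale,
                             s.gaussian_sigma, s.contrast])
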