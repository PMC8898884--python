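"""Seeded generator of labelled toy cervical-cell crops.

Real Feulgen-stained single-cell crops are private clinical data, so the
pipeline is exercised on small synthetic grey images that reproduce the
statistical structure the method relies on:

* distinct morphological families — single round epithelial nuclei, paired
  nuclei, clumped nuclei, pyknotic (small, dense) nuclei, 2-5-lobed
  neutrophil nuclei, enlarged deeply stained abnormal nuclei, and two kinds
  of non-cellular debris ("garbage": dark opaque spots and light glassy
  smudges);
* the DNA-ploidy axis: darker staining = more DNA, and the abnormal family
  is generated so that its expected integrated optical density is at least
  2.5x that of the normal single-nucleus family;
* injectable Gaussian blur (a stated fraction of images) and additive grey
  noise, so the clarity-screening stage has real work to do;
* controllable per-class counts, so the balancing stage has real work to do.

Nuclei are rendered as smooth absorbance stamps (radially decaying optical
density with an irregular boundary) composited over a light background and
converted to grey intensity through the Beer-Lambert relation
``I = (I0+1) * 10^-gamma - 1``; a sample's ``true_iod`` is the absorbance of
its clean rendering summed over the true nucleus mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassDef",
    "SyntheticConfig",
    "SyntheticSample",
    "DEFAULT_CLASS_DEFS",
    "generate_cell_image",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

_FAMILIES = {
    "single_round", "paired", "clumped", "pyknotic",
    "lobed", "abnormal", "garbage_dark", "garbage_light",
}

# Absorbance above this level counts as nucleus when building the true mask
# (below it the stamp's faint rim is visually indistinguishable from
# background and a threshold segmenter cannot be expected to find it).
_MASK_LEVEL = 0.05


@dataclass(frozen=True)
class ClassDef:
    """One morphological family and the parameter ranges it draws from."""

    name: str
    family: str
    radius_range: tuple = (3.5, 5.5)
    peak_absorbance_range: tuple = (0.25, 0.45)
    lobe_count_range: tuple = (2, 5)
    n_nuclei_range: tuple = (1, 1)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown class family {self.family!r}; "
                             f"expected one of {sorted(_FAMILIES)}")


#: The eight default families.  Radii in pixels (for a 32x32 crop), peak
#: absorbance dimensionless optical density.  The abnormal family's radius and
#: stain depth are set so its expected IOD clears 2.5x the single_round mean
#: with margin (ratio is checked, not assumed, by the test suite).
DEFAULT_CLASS_DEFS = {
    "single_round": ClassDef("single_round", "single_round",
                             radius_range=(3.0, 5.5),
                             peak_absorbance_range=(0.20, 0.50)),
    "paired": ClassDef("paired", "paired",
                       radius_range=(2.5, 5.0),
                       peak_absorbance_range=(0.20, 0.50),
                       n_nuclei_range=(2, 2)),
    "clumped": ClassDef("clumped", "clumped",
                        radius_range=(2.2, 4.2),
                        peak_absorbance_range=(0.20, 0.50),
                        n_nuclei_range=(3, 6)),
    "pyknotic": ClassDef("pyknotic", "pyknotic",
                         radius_range=(1.6, 3.2),
                         peak_absorbance_range=(0.65, 1.15)),
    "lobed": ClassDef("lobed", "lobed",
                      radius_range=(1.8, 3.2),
                      peak_absorbance_range=(0.30, 0.60),
                      lobe_count_range=(2, 5)),
    "abnormal": ClassDef("abnormal", "abnormal",
                         radius_range=(5.5, 8.5),
                         peak_absorbance_range=(0.60, 1.05)),
    "garbage_dark": ClassDef("garbage_dark", "garbage_dark",
                             radius_range=(2.0, 6.0)),
    "garbage_light": ClassDef("garbage_light", "garbage_light",
                              radius_range=(4.0, 10.0)),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic dataset.

    ``per_class_counts`` aligns with ``class_spec``; ``blur_fraction`` of all
    images (an exact count, chosen without replacement) receive Gaussian blur
    with sigma drawn uniformly from ``blur_sigma_range``; ``noise_sigma`` is
    the std of additive grey noise applied to every image.
    """

    image_size: int = 32
    class_spec: tuple = tuple(DEFAULT_CLASS_DEFS.values())
    per_class_counts: tuple = (50,) * len(DEFAULT_CLASS_DEFS)
    blur_fraction: float = 0.0
    blur_sigma_range: tuple = (1.0, 2.0)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8 pixels")
        if len(self.per_class_counts) != len(self.class_spec):
            raise ValueError("per_class_counts must align with class_spec")
        if any(c < 0 for c in self.per_class_counts):
            raise ValueError("per-class counts must be non-negative")
        if not 0.0 <= self.blur_fraction <= 1.0:
            raise ValueError("blur_fraction must lie in [0, 1]")


@dataclass
class SyntheticSample:
    """One generated crop with its ground truth."""

    image: np.ndarray            # uint8 grey, size x size
    label: int
    class_name: str
    nucleus_mask: np.ndarray     # bool, same shape
    true_iod: float
    blurred: bool = False

    def __post_init__(self) -> None:
        if self.image.shape != self.nucleus_mask.shape:
            raise ValueError("mask and image dimensions differ")


def _blob_absorbance(size, cx, cy, radius, peak, rng, elongation=1.0, angle=0.0,
                     wobble=0.15):
    """Absorbance stamp of one nucleus blob with an irregular boundary."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    rx = (ca * dx + sa * dy) * elongation
    ry = -sa * dx + ca * dy
    r = np.hypot(rx, ry)
    theta = np.arctan2(ry, rx)
    k = rng.integers(3, 7)
    phase = rng.uniform(0, 2 * np.pi)
    r_eff = radius * (1.0 + wobble * np.sin(k * theta + phase))
    return peak * np.exp(-(r / np.maximum(r_eff, 0.5)) ** 4)


def _render_nuclei(class_def: ClassDef, size: int, rng: np.random.Generator):
    """Composite absorbance map for a nucleated family."""
    gamma = np.zeros((size, size))
    c = size / 2.0
    fam = class_def.family
    radius = rng.uniform(*class_def.radius_range)
    peak = rng.uniform(*class_def.peak_absorbance_range)
    jit = size * 0.12

    if fam in ("single_round", "pyknotic", "abnormal"):
        cx, cy = c + rng.normal(0, jit), c + rng.normal(0, jit)
        gamma = np.maximum(gamma, _blob_absorbance(
            size, cx, cy, radius, peak, rng,
            elongation=rng.uniform(0.9, 1.25), angle=rng.uniform(0, np.pi)))
        if fam == "single_round" and rng.random() < 0.5:
            # nucleolus: a small darker dot inside the nucleus
            gamma = np.maximum(gamma, _blob_absorbance(
                size, cx + rng.normal(0, 1), cy + rng.normal(0, 1),
                radius * 0.22, peak * 1.6, rng, wobble=0.05))
    elif fam == "paired":
        sep = radius * rng.uniform(1.6, 2.2)
        ang = rng.uniform(0, np.pi)
        for s in (-0.5, 0.5):
            gamma = np.maximum(gamma, _blob_absorbance(
                size, c + s * sep * np.cos(ang) + rng.normal(0, 1),
                c + s * sep * np.sin(ang) + rng.normal(0, 1),
                radius, peak * rng.uniform(0.9, 1.1), rng))
    elif fam == "clumped":
        n = int(rng.integers(*class_def.n_nuclei_range))
        for _ in range(max(n, class_def.n_nuclei_range[0])):
            gamma = np.maximum(gamma, _blob_absorbance(
                size, c + rng.normal(0, radius), c + rng.normal(0, radius),
                radius * rng.uniform(0.8, 1.1), peak * rng.uniform(0.85, 1.15),
                rng))
    elif fam == "lobed":
        lo, hi = class_def.lobe_count_range
        n_lobes = int(rng.integers(lo, hi + 1))
        arc = rng.uniform(0, 2 * np.pi)
        spread = radius * 1.5
        for i in range(n_lobes):
            a = arc + i * rng.uniform(0.7, 1.2)
            gamma = np.maximum(gamma, _blob_absorbance(
                size, c + spread * np.cos(a), c + spread * np.sin(a),
                radius * rng.uniform(0.85, 1.15), peak, rng,
                elongation=rng.uniform(1.0, 1.4), angle=a))
    else:  # pragma: no cover - guarded by ClassDef validation
        raise ValueError(f"unknown nucleated family {fam!r}")
    return gamma


def _render_garbage(class_def: ClassDef, size: int, rng: np.random.Generator):
    """Intensity image of non-cellular debris (no nucleus, zero IOD)."""
    radius = rng.uniform(*class_def.radius_range)
    texture = gaussian_filter(rng.normal(0, 1, (size, size)), 1.5)
    texture = (texture - texture.min()) / max(np.ptp(texture), 1e-9)
    blob = _blob_absorbance(size, size / 2 + rng.normal(0, 2),
                            size / 2 + rng.normal(0, 2), radius, 1.0, rng,
                            wobble=0.35)
    if class_def.family == "garbage_dark":
        # black-spot debris: several jagged opaque speckles scattered across
        # the crop (unlike a nucleus, not a single centred round body)
        img = np.full((size, size), 250.0)
        n_spots = int(rng.integers(2, 6))
        for _ in range(n_spots):
            spot = _blob_absorbance(size, rng.uniform(4, size - 4),
                                    rng.uniform(4, size - 4),
                                    rng.uniform(1.0, max(1.2, radius * 0.45)),
                                    1.0, rng,
                                    elongation=rng.uniform(1.0, 2.5),
                                    angle=rng.uniform(0, np.pi), wobble=0.45)
            dark = (spot > rng.uniform(0.35, 0.6)).astype(float)
            img = np.minimum(img, 250.0 - dark * (rng.uniform(170, 230)
                                                  + 30 * texture))
    else:
        # glassy light smudge: faint, soft, large
        img = 250.0 - blob * rng.uniform(25, 55) * (0.6 + 0.4 * texture)
    return np.clip(img, 0, 255)


def generate_cell_image(class_def: ClassDef, image_size: int = 32,
                        rng: np.random.Generator | int = 0,
                        label: int = 0) -> SyntheticSample:
    """Render one clean (unblurred, noise-free) sample of a family.

    Deterministic given the generator state.  Garbage families return an
    empty nucleus mask and ``true_iod = 0``.
    """
    if image_size < 8:
        raise ValueError("image_size too small to place the requested shape")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    background = rng.uniform(232, 252)
    if class_def.family.startswith("garbage"):
        img = _render_garbage(class_def, image_size, rng)
        image = np.clip(np.round(img), 0, 255).astype(np.uint8)
        mask = np.zeros((image_size, image_size), dtype=bool)
        return SyntheticSample(image=image, label=label,
                               class_name=class_def.name,
                               nucleus_mask=mask, true_iod=0.0)

    gamma = _render_nuclei(class_def, image_size, rng)
    mask = gamma > _MASK_LEVEL
    intensity = (background + 1.0) * np.power(10.0, -gamma) - 1.0
    image = np.clip(np.round(intensity), 0, 255).astype(np.uint8)
    # ground-truth IOD: absorbance of the clean quantized rendering over the
    # true mask, on the same scale the feature extractor measures (I0 = 255)
    measured = np.log10(256.0 / (image.astype(float) + 1.0))
    true_iod = float(np.clip(measured, 0, None)[mask].sum())
    return SyntheticSample(image=image, label=label, class_name=class_def.name,
                           nucleus_mask=mask, true_iod=true_iod)


def generate_dataset(config: SyntheticConfig):
    """Generate the full labelled collection described by a config.

    Returns ``(samples, manifest)`` where the manifest is a DataFrame with
    columns ``path, label, class_name, blurred, true_iod`` (paths filled in
    by :func:`save_dataset`).  Per-class counts match the config exactly and
    exactly ``round(blur_fraction * n)`` images are blurred.  Byte-level
    deterministic for a fixed config.
    """
    if all(c == 0 for c in config.per_class_counts):
        raise ValueError("at least one class count must be positive")
    rng = np.random.default_rng(config.seed)
    samples: list[SyntheticSample] = []
    for label, (cdef, count) in enumerate(zip(config.class_spec,
                                              config.per_class_counts)):
        for _ in range(count):
            samples.append(generate_cell_image(cdef, config.image_size, rng,
                                               label=label))

    n = len(samples)
    n_blur = int(round(config.blur_fraction * n))
    blur_idx = rng.choice(n, size=n_blur, replace=False) if n_blur else []
    for i in sorted(blur_idx):
        s = samples[i]
        sigma = rng.uniform(*config.blur_sigma_range)
        blurred = gaussian_filter(s.image.astype(float), sigma, mode="nearest")
        s.image = np.clip(np.round(blurred), 0, 255).astype(np.uint8)
        s.blurred = True
    if config.noise_sigma > 0:
        for s in samples:
            noisy = s.image.astype(float) + rng.normal(0, config.noise_sigma,
                                                       s.image.shape)
            s.image = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    manifest = pd.DataFrame({
        "path": [f"img_{i:05d}.png" for i in range(n)],
        "label": [s.label for s in samples],
        "class_name": [s.class_name for s in samples],
        "blurred": [s.blurred for s in samples],
        "true_iod": [s.true_iod for s in samples],
    })
    return samples, manifest


def save_dataset(samples, manifest: pd.DataFrame, out_dir: str) -> str:
    """Write PNGs and the manifest CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    for s, path in zip(samples, manifest["path"]):
        Image.fromarray(s.image, mode="L").save(os.path.join(out_dir, path))
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(manifest_path: str):
    """Read a saved dataset back as ``(images, manifest)``."""
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(manifest_path)
    images = [np.asarray(Image.open(os.path.join(base, p)).convert("L"))
              for p in manifest["path"]]
    return images, manifest
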