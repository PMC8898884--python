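"""Absorbance maps, integrated optical density and cell feature similarity.

In Feulgen-stained cytology the darkness of a nucleus is stoichiometric for
its DNA content, so per-pixel absorbance (optical density) summed over the
nucleus region — the integrated optical density, IOD — is a DNA-ploidy
proxy: abnormal epithelial nuclei accumulate >= 2.5 N DNA relative to normal
diploid nuclei.  The class-balancing stage compares cells of one class by
the cosine of their mean-centred feature vectors [IOD, area, mean
absorbance].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "AbsorbanceMap",
    "CellFeature",
    "ClassFeatureStats",
    "absorbance",
    "iod",
    "cell_feature_vector",
    "centered_cosine",
    "cosine_angle_degrees",
]

#: Default background (unstained) transmitted intensity.
DEFAULT_BACKGROUND = 255.0

#: A nucleus mask is only extracted when some pixel is at least this much
#: darker than the background; otherwise the image is treated as empty.
DARKNESS_MARGIN = 20.0


@dataclass
class AbsorbanceMap:
    """Per-pixel absorbance values with the region-of-interest mask Omega."""

    values: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region = np.asarray(self.region, dtype=bool)
        if self.values.shape != self.region.shape:
            raise ValueError("values and region must have equal dimensions")
        if (self.values < 0).any():
            raise ValueError("absorbance values must be non-negative")


@dataclass(frozen=True)
class CellFeature:
    """IOD-centred cell descriptor: (iod, area, mean_absorbance)."""

    iod: float
    area: int
    mean_absorbance: float

    def as_array(self) -> np.ndarray:
        return np.array([self.iod, float(self.area), self.mean_absorbance])


@dataclass
class ClassFeatureStats:
    """Feature vectors of one class together with their centroid u-bar."""

    members: list

    @property
    def centroid(self) -> np.ndarray:
        arr = np.stack([m.as_array() if isinstance(m, CellFeature) else np.asarray(m, float)
                        for m in self.members])
        return arr.mean(axis=0)


def absorbance(image: np.ndarray, background_intensity: float = DEFAULT_BACKGROUND,
               region: np.ndarray | None = None) -> AbsorbanceMap:
    """Per-pixel absorbance gamma = log10((I0+1)/(I+1)), clipped at 0.

    The +1 offsets keep the logarithm finite at zero intensity; pixels
    brighter than the background clip to zero absorbance.
    """
    if background_intensity <= 0:
        raise ValueError("background intensity must be positive")
    img = np.asarray(image, dtype=float)
    gamma = np.log10((background_intensity + 1.0) / (img + 1.0))
    gamma = np.clip(gamma, 0.0, None)
    if region is None:
        region = np.ones_like(gamma, dtype=bool)
    return AbsorbanceMap(values=gamma, region=region)


def iod(amap: AbsorbanceMap) -> float:
    """Integrated optical density: sum of absorbance over the region Omega."""
    return float(amap.values[amap.region].sum())


def segment_nucleus(image: np.ndarray,
                    background_intensity: float = DEFAULT_BACKGROUND,
                    margin: float = DARKNESS_MARGIN) -> np.ndarray:
    """Threshold-based nucleus mask (dark pixels); all-false when nothing is
    meaningfully darker than the background."""
    img = np.asarray(image, dtype=float)
    if img.min() >= background_intensity - margin:
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    return img < t


def cell_feature_vector(image: np.ndarray,
                        background_intensity: float = DEFAULT_BACKGROUND) -> CellFeature:
    """IOD / area / mean-absorbance features over an Otsu nucleus mask.

    A degenerate image with no dark pixels (e.g. pure background or debris
    lighter than the margin) yields the zero feature (0, 0, 0).
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("cell images must be at least 2x2 pixels")
    mask = segment_nucleus(img, background_intensity)
    area = int(mask.sum())
    if area == 0:
        return CellFeature(iod=0.0, area=0, mean_absorbance=0.0)
    amap = absorbance(img, background_intensity, region=mask)
    total = iod(amap)
    return CellFeature(iod=total, area=area, mean_absorbance=total / area)


def _vec(u) -> np.ndarray:
    if isinstance(u, CellFeature):
        return u.as_array()
    return np.asarray(u, dtype=float)


def centered_cosine(u_i, u_j, u_bar) -> float:
    """Cosine similarity of two feature vectors after centring on the class
    centroid u-bar.

    Degenerate pairs — either centred vector having zero norm — are treated
    as maximally similar (returns 1), so that exact class-centroid duplicates
    are eligible for downsampling.
    """
    a, b, c = _vec(u_i), _vec(u_j), _vec(u_bar)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("feature vectors must have equal length")
    da, db = a - c, b - c
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        return 1.0
    return float(np.clip(np.dot(da, db) / (na * nb), -1.0, 1.0))


def cosine_angle_degrees(u_i, u_j, u_bar) -> float:
    """Angle (degrees, in [0, 180]) between centred feature vectors."""
    return float(np.degrees(np.arccos(centered_cosine(u_i, u_j, u_bar))))
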