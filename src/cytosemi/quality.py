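"""Clarity screening and enhancement of single-cell images.

Implements the SMD2 (grey-variance-product) focus measure, mean-threshold
clarity screening, a regularized gradient-descent deblurring step for images
that fail the screen, and dataset size standardization.

SMD2 rests on the observation that an in-focus image carries more
pixel-to-pixel grey variation than a defocused one: for every pixel with both
a right and a down neighbour the absolute horizontal and vertical differences
are multiplied and the products summed over the image.  Absolute values are
used so that the score is non-negative and signed products cannot cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = [
    "DeblurSettings",
    "ClarityReport",
    "smd2",
    "clarity_screen",
    "deblur",
    "rescreen_after_deblur",
    "standardize_size",
]


@dataclass(frozen=True)
class DeblurSettings:
    """Settings for the regularized deconvolution used on blurry images.

    Parameters
    ----------
    epsilon : float
        Positive constant of the gradient regularizer phi(D) = sum D/(D+eps)
        with D = u_x^2 + u_y^2 (forward differences, replicate borders).
    kernel_sigma : float
        Standard deviation (pixels) of the Gaussian blur kernel assumed by
        the data-fidelity term.
    iterations : int
        Number of gradient-descent steps; 0 returns the input unchanged.
    step_size : float
        Gradient-descent step length.
    reg_weight : float
        Weight of the regularizer relative to the data term.
    """

    epsilon: float = 1e-3
    kernel_sigma: float = 1.0
    iterations: int = 30
    step_size: float = 0.4
    reg_weight: float = 0.05

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")


@dataclass
class ClarityReport:
    """Per-image SMD2 scores with the dataset-mean pass threshold."""

    scores: np.ndarray
    mean_threshold: float
    passed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.passed is None:
            self.passed = self.scores >= self.mean_threshold
        self.passed = np.asarray(self.passed, dtype=bool)


def _as_grey(image: np.ndarray) -> np.ndarray:
    a = np.asarray(image, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {a.shape}")
    return a


def smd2(image: np.ndarray) -> float:
    """Grey-variance-product focus score of a grey image.

    ``sum_{x,y} |f(x,y)-f(x+1,y)| * |f(x,y)-f(x,y+1)|`` over every pixel that
    has both a right and a down neighbour.  Zero on constant images; larger
    for sharper images.

    Raises
    ------
    ValueError
        If the image is smaller than 2x2.
    """
    f = _as_grey(image)
    if f.shape[0] < 2 or f.shape[1] < 2:
        raise ValueError("smd2 requires an image of at least 2x2 pixels")
    dx = np.abs(f[:-1, :-1] - f[:-1, 1:])
    dy = np.abs(f[:-1, :-1] - f[1:, :-1])
    return float(np.sum(dx * dy))


def clarity_screen(images):
    """Partition images into clarity pass/fail sets by the dataset mean.

    The threshold is the arithmetic mean of all SMD2 scores; an image passes
    when its score is >= the mean (so a perfectly uniform-quality collection
    is kept in full).

    Returns
    -------
    report : ClarityReport
    passing : list of int
        Indices of images at or above the mean.
    failing : list of int
        Indices below the mean.
    """
    images = list(images)
    if not images:
        raise ValueError("clarity_screen requires a non-empty collection")
    scores = np.array([smd2(im) for im in images])
    threshold = float(scores.mean())
    passed = scores >= threshold
    report = ClarityReport(scores=scores, mean_threshold=threshold, passed=passed)
    passing = [i for i in range(len(images)) if passed[i]]
    failing = [i for i in range(len(images)) if not passed[i]]
    return report, passing, failing


def _grad_regularizer(u: np.ndarray, epsilon: float) -> np.ndarray:
    # phi(D) = sum D/(D+eps); d phi/du = -2 div(w grad u), w = eps/(D+eps)^2.
    ux = np.diff(u, axis=1, append=u[:, -1:])
    uy = np.diff(u, axis=0, append=u[-1:, :])
    d = ux**2 + uy**2
    w = epsilon / (d + epsilon) ** 2
    fx = w * ux
    fy = w * uy
    div = np.zeros_like(u)
    div += fx - np.pad(fx, ((0, 0), (1, 0)), mode="constant")[:, :-1]
    div += fy - np.pad(fy, ((1, 0), (0, 0)), mode="constant")[:-1, :]
    return -2.0 * div


def deblur(image: np.ndarray, settings: DeblurSettings = DeblurSettings()) -> np.ndarray:
    """Sharpen a grey image by regularized deconvolution.

    Gradient descent on ``||k*u - g||^2 + w * phi(D)`` where ``g`` is the
    observed image, ``k`` a Gaussian kernel of ``kernel_sigma`` and ``phi``
    the bounded gradient penalty D/(D+eps).  Output is clipped to [0, 255]
    and has the input's dimensions; with ``iterations = 0`` the input is
    returned unchanged.  Deterministic.
    """
    g = _as_grey(image)
    u = g.copy()
    for _ in range(settings.iterations):
        blurred = gaussian_filter(u, settings.kernel_sigma, mode="nearest")
        residual = blurred - g
        grad_data = 2.0 * gaussian_filter(residual, settings.kernel_sigma, mode="nearest")
        grad = grad_data + settings.reg_weight * _grad_regularizer(u, settings.epsilon)
        u = np.clip(u - settings.step_size * grad, 0.0, 255.0)
    return u


def rescreen_after_deblur(failing_images, mean_threshold: float,
                          settings: DeblurSettings = DeblurSettings()):
    """Deblur each failing image once and re-test against the prior threshold.

    Returns ``(recovered, discarded)`` index lists plus the deblurred images
    keyed by index; an image is recovered when its post-deblur SMD2 reaches
    the original dataset-mean threshold, otherwise discarded.
    """
    failing_images = list(failing_images)
    recovered, discarded, outputs = [], [], {}
    for i, im in enumerate(failing_images):
        out = deblur(im, settings)
        outputs[i] = out
        if smd2(out) >= mean_threshold:
            recovered.append(i)
        else:
            discarded.append(i)
    return recovered, discarded, outputs


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def standardize_size(images):
    """Rescale a collection to a uniform square side length.

    The target side L is the half-up-rounded mean of all edge lengths (widths
    and heights pooled).  Each image is resized, preserving aspect ratio, so
    its longer side equals L, then padded to L x L with white (255) pixels.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    if not images:
        raise ValueError("standardize_size requires a non-empty collection")
    edges = [e for im in images for e in im.shape[:2]]
    target = _round_half_up(float(np.mean(edges)))
    out = []
    for im in images:
        h, w = im.shape[:2]
        scale = target / max(h, w)
        nh = max(1, _round_half_up(h * scale))
        nw = max(1, _round_half_up(w * scale))
        if (nh, nw) != (h, w):
            im = resize(im, (nh, nw), order=1, mode="edge",
                        anti_aliasing=max(h, w) > target, preserve_range=True)
        canvas = np.full((target, target), 255.0)
        top = (target - im.shape[0]) // 2
        left = (target - im.shape[1]) // 2
        canvas[top:top + im.shape[0], left:left + im.shape[1]] = im
        out.append(np.clip(canvas, 0, 255))
    return out
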