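"""Pluggable backbone classifiers and confidence-weighted fusion.

The self-training scheme is backbone-agnostic: it only needs a set of
classifiers that emit per-class probability vectors, trained with Adam
(beta1 = 0.9, beta2 = 0.999, eps = 1e-8, lr = 0.001) under cross-entropy.
The registry provides scaled-down multilayer-perceptron analogues of the
five convolutional backbones the full-scale study combines (VGG19,
ResNet18, ResNet50, ResNeXt29_2*64d, ResNeXt29_4*64d) plus a tiny baseline,
all sized for 32x32 crops and single-CPU training; each registry entry
differs in capacity so the ensemble retains the diversity the voting step
exploits.

Fusion combines the m classifier confidence vectors M_i with weights w_i
taken from validation macro-precision::

    Result = sum_i w_i * M_i / sum_i w_i

which stays on the probability simplex and is invariant to rescaling the
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, rotate
from sklearn.decomposition import PCA
from sklearn.neural_network import MLPClassifier

__all__ = [
    "BACKBONES",
    "ClassifierSpec",
    "TrainingTrace",
    "ClassifierHandle",
    "EnsembleWeights",
    "cross_entropy",
    "train_classifier",
    "predict",
    "fuse",
    "ensemble_weights",
    "augment_image",
]

#: backbone id -> (PCA components, hidden layer widths) of its scaled-down
#: analogue.  Each backbone embeds the flattened crop into a principal
#: subspace fitted on its first training batch (the cheap stand-in for a
#: convolutional feature extractor at this scale) and differs from the
#: others in embedding dimension and head capacity, preserving the ensemble
#: diversity the voting step relies on.
BACKBONES = {
    "tiny": (16, (16,)),
    "vgg19": (32, (64, 32)),
    "resnet18": (32, (48, 24)),
    "resnet50": (48, (64, 48)),
    "resnext29_2x64d": (48, (80, 40)),
    "resnext29_4x64d": (64, (96, 48)),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Backbone choice plus optimizer hyperparameters."""

    backbone_id: str = "tiny"
    epochs: int = 20
    learning_rate: float = 0.001
    l2_penalty: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_id not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone_id!r}; "
                             f"registry has {sorted(BACKBONES)}")
        if self.epochs < 0 or self.learning_rate <= 0 or self.adam_eps <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be non-negative")
        if not (0 < self.adam_beta1 < 1 and 0 < self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")


@dataclass
class TrainingTrace:
    """Per-epoch cross-entropy loss and validation macro-precision."""

    losses: list = field(default_factory=list)
    val_macro_p: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.losses)


@dataclass
class EnsembleWeights:
    """Non-negative fusion weights, sourced from validation macro-precision."""

    weights: np.ndarray
    source: str = "validation_macro_precision"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("fusion weights must be non-negative")


def cross_entropy(true_dist, pred_dist) -> float:
    """Cross-entropy ``-sum_i y_i ln(yhat_i)`` between two distributions.

    Predicted probabilities are clipped to 1e-12 before the log so a
    confident wrong prediction yields a large finite loss, not infinity.
    """
    y = np.asarray(true_dist, dtype=float)
    p = np.asarray(pred_dist, dtype=float)
    if y.shape != p.shape:
        raise ValueError("distributions must have equal length")
    p = np.clip(p, 1e-12, None)
    return float(-(y * np.log(p)).sum())


def augment_image(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random training-time augmentation of a grey image.

    Draws uniformly among centre cropping (re-inflated to the input size),
    rotation by a uniform angle in [-180, 180] degrees, and brightness or
    contrast scaling by a factor in [0.8, 1.2].
    """
    img = np.asarray(image, dtype=float)
    op = rng.integers(4)
    if op == 0:  # centre crop, back to original size
        h, w = img.shape
        m_h, m_w = max(1, h // 8), max(1, w // 8)
        crop = img[m_h:h - m_h, m_w:w - m_w]
        img = resize(crop, (h, w), order=1, mode="edge", preserve_range=True,
                     anti_aliasing=False)
    elif op == 1:  # random rotation, background-white fill
        img = rotate(img, rng.uniform(-180, 180), preserve_range=True,
                     cval=255.0, order=1)
    elif op == 2:  # brightness
        img = img * rng.uniform(0.8, 1.2)
    else:  # contrast about the mean
        m = img.mean()
        img = m + (img - m) * rng.uniform(0.8, 1.2)
    return np.clip(img, 0, 255)


def _design_matrix(images) -> np.ndarray:
    X = np.stack([np.asarray(im, dtype=float).ravel() for im in images])
    return X / 255.0


@dataclass
class ClassifierHandle:
    """A trained (or to-be-trained) backbone plus its bookkeeping.

    The principal-subspace embedding is fitted once, on the first training
    batch, and then frozen so warm-started rounds keep a consistent input
    space for the MLP head.
    """

    spec: ClassifierSpec
    n_classes: int
    mlp: MLPClassifier = None  # type: ignore[assignment]
    pca: PCA | None = None
    fitted: bool = False

    def __post_init__(self) -> None:
        if self.mlp is None:
            s = self.spec
            self.mlp = MLPClassifier(
                hidden_layer_sizes=BACKBONES[s.backbone_id][1],
                solver="adam",
                alpha=s.l2_penalty,
                learning_rate_init=s.learning_rate,
                beta_1=s.adam_beta1,
                beta_2=s.adam_beta2,
                epsilon=s.adam_eps,
                batch_size=32,  # adjusted per training-set size at fit time
                random_state=s.seed,
            )

    def _fit_embedding(self, X: np.ndarray) -> None:
        n_comp = min(BACKBONES[self.spec.backbone_id][0], *X.shape)
        self.pca = PCA(n_components=n_comp, svd_solver="full", whiten=True)
        self.pca.fit(X)

    def _embed(self, X: np.ndarray) -> np.ndarray:
        if self.pca is None:  # pragma: no cover - train always fits it first
            raise RuntimeError("embedding not fitted")
        return self.pca.transform(X)

    def predict_proba(self, images) -> np.ndarray:
        """Per-class probability simplex for each image.

        An untrained handle returns the uniform distribution — maximally
        uncertain, so it never passes a confidence threshold.
        """
        n = len(images)
        if not self.fitted:
            return np.full((n, self.n_classes), 1.0 / self.n_classes)
        proba = self.mlp.predict_proba(self._embed(_design_matrix(images)))
        if proba.shape[1] != self.n_classes:  # pragma: no cover - guarded
            raise RuntimeError("class count drifted between fit and predict")
        return proba


def train_classifier(spec: ClassifierSpec, images, labels,
                     augment_prob: float = 0.5,
                     val_images=None, val_labels=None,
                     handle: ClassifierHandle | None = None,
                     n_classes: int | None = None):
    """Train (or warm-start) one backbone under cross-entropy with Adam.

    Each epoch every training image has ``augment_prob`` probability of
    being replaced by a random augmentation before the pass.  Per-epoch loss
    and validation macro-precision are recorded (validation defaults to the
    training data).  Deterministic for a fixed spec/seed/data.

    Passing an existing ``handle`` continues training from its current
    weights (warm start across self-training rounds).
    """
    from .metrics import confusion_matrix, macro_precision

    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("training set is empty")
    classes_present = np.unique(labels)
    if n_classes is None:
        n_classes = int(classes_present.max()) + 1
    if len(classes_present) < 2:
        raise ValueError("training requires at least two classes present")
    if handle is None:
        handle = ClassifierHandle(spec=spec, n_classes=n_classes)
    if val_images is None:
        val_images, val_labels = images, labels

    rng = np.random.default_rng(spec.seed + 1)
    trace = TrainingTrace()
    all_classes = np.arange(handle.n_classes)
    if handle.pca is None:
        handle._fit_embedding(_design_matrix(images))
    # keep the minibatch count per pass high enough that Adam (fixed step
    # scale ~ learning rate) makes real progress inside a small epoch budget
    handle.mlp.batch_size = int(np.clip(len(images) // 24, 4, 32))
    for _ in range(spec.epochs):
        batch = []
        for im in images:
            if rng.random() < augment_prob:
                batch.append(augment_image(im, rng))
            else:
                batch.append(np.asarray(im, dtype=float))
        X = handle._embed(_design_matrix(batch))
        handle.mlp.partial_fit(X, labels, classes=all_classes)
        handle.fitted = True
        trace.losses.append(float(handle.mlp.loss_))
        pred = handle.predict_proba(val_images).argmax(axis=1)
        cm = confusion_matrix(np.asarray(val_labels), pred, handle.n_classes)
        trace.val_macro_p.append(macro_precision(cm))
    return handle, trace


def predict(handle: ClassifierHandle, images) -> np.ndarray:
    """Confidence vectors (rows on the probability simplex), one per image."""
    return handle.predict_proba(images)


def fuse(weights, confidences) -> np.ndarray:
    """Weighted average of classifier confidence vectors.

    ``confidences`` is a list of m arrays of identical shape (n_items,
    n_classes) — or m single vectors; ``weights`` has m non-negative entries
    with a positive sum.  The result lies on the simplex row-wise.
    """
    w = weights.weights if isinstance(weights, EnsembleWeights) else \
        np.asarray(weights, dtype=float)
    mats = [np.atleast_2d(np.asarray(c, dtype=float)) for c in confidences]
    if len(mats) != len(w):
        raise ValueError("one weight per confidence vector required")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("confidence vectors must agree in shape")
    out = sum(wi * m for wi, m in zip(w, mats)) / w.sum()
    return out[0] if np.asarray(confidences[0]).ndim == 1 else out


def ensemble_weights(validation_scores) -> EnsembleWeights:
    """Fusion weights = validation macro-precision, used unnormalized
    (fusion is invariant to positive rescaling)."""
    return EnsembleWeights(weights=np.asarray(validation_scores, dtype=float))
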