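"""Similarity-guided class balancing of the (real + pseudo) training set.

Pseudo-labeling expands classes unevenly, so before each retraining round
every class is resampled to a common target ``c_mean`` — the mean class
count excluding the largest and smallest classes, rounded to the nearest
integer:

* rich classes (count > c_mean) are *downsampled* over several rounds of
  random non-repeating pairing: a pair whose centred-cosine angle falls
  below the similarity threshold is redundant, so one member (seeded coin
  flip) is returned to the unlabeled pool — never deleted.  The number of
  rounds is ``N = ceil(c_i / (k * c_min))`` with k drawn from {1/2, 1/3,
  1/4}, and no round removes more than ``floor(c_min / 2)`` items;
* rare classes (count < c_mean) are *upsampled* by self-replication plus
  random rotation and grey-value transforms (stretch, inversion, log,
  inverse-log, gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rotate

from .optics import cosine_angle_degrees

__all__ = [
    "TrainItem",
    "ClassCounts",
    "BalanceConfig",
    "class_counts",
    "downsample_rounds",
    "downsample_class",
    "upsample_class",
    "balance",
]

_K_CHOICES = (1 / 2, 1 / 3, 1 / 4)


@dataclass
class TrainItem:
    """One training-set member: an image with its (real or pseudo) label."""

    id: str
    image: np.ndarray
    label: int
    origin: str = "real"  # "real" | "pseudo" | "augmented"


@dataclass(frozen=True)
class ClassCounts:
    """Per-class tallies with the balancing target c_mean."""

    counts: tuple
    c_max_class: int
    c_min_class: int
    c_mean: int

    @property
    def l(self) -> int:  # noqa: E743 - field name from the balancing rule
        return len(self.counts)

    @property
    def c_max(self) -> int:
        return self.counts[self.c_max_class]

    @property
    def c_min(self) -> int:
        return self.counts[self.c_min_class]


@dataclass(frozen=True)
class BalanceConfig:
    """Balancing knobs: similarity threshold (degrees), k, and the seed."""

    similarity_angle_threshold: float = 15.0
    k: float | None = None  # None -> seeded draw from {1/2, 1/3, 1/4}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k is not None and not any(math.isclose(self.k, c)
                                          for c in _K_CHOICES):
            raise ValueError("k must be one of 1/2, 1/3, 1/4")


def class_counts(labels, n_classes: int | None = None) -> ClassCounts:
    """Tally labels and derive c_max / c_min / c_mean.

    The trimmed mean excludes the largest and smallest classes (ties broken
    by lowest class index) and is rounded half-up; it needs at least three
    classes to be defined.
    """
    labels = np.asarray(labels)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    if n_classes < 3:
        raise ValueError("c_mean needs at least three label categories")
    counts = np.bincount(labels, minlength=n_classes)
    c_max_class = int(np.argmax(counts))
    c_min_class = int(np.argmin(counts))
    rest = [c for i, c in enumerate(counts)
            if i not in (c_max_class, c_min_class)]
    c_mean = int(np.floor(np.mean(rest) + 0.5))
    return ClassCounts(counts=tuple(int(c) for c in counts),
                       c_max_class=c_max_class, c_min_class=c_min_class,
                       c_mean=c_mean)


def downsample_rounds(c_i: int, c_min: int, k: float) -> int:
    """Number of downsampling rounds ``N = ceil(c_i / (k * c_min))``."""
    if not any(math.isclose(k, c) for c in _K_CHOICES):
        raise ValueError("k must be one of 1/2, 1/3, 1/4")
    if c_min <= 0:
        raise ValueError("c_min must be positive")
    return max(1, math.ceil(c_i / (k * c_min)))


def downsample_class(member_ids, features: dict, c_mean: int, c_min: int,
                     config: BalanceConfig = BalanceConfig(),
                     rng: np.random.Generator | None = None,
                     origins: dict | None = None):
    """Reduce one rich class to exactly ``c_mean`` members.

    Over N similarity rounds, members are randomly paired without
    repetition; of each pair closer than the angle threshold to each other
    (centred on the class centroid), a seeded coin flip sends one to the
    unlabeled stream.  Rounds stop early at ``c_mean``; a round removes at
    most ``floor(c_min / 2)`` items; any residue after N rounds is removed
    uniformly at random.  Returns ``(kept_ids, moved_to_unlabeled_ids)``.

    When ``origins`` marks one member of a similar pair as pseudo-labelled
    and the other as real, the pseudo member is the one returned to the
    unlabeled pool: a real annotation is never traded for a model guess.
    """
    member_ids = list(member_ids)
    if len(member_ids) <= c_mean:
        raise ValueError("downsample_class requires |members| > c_mean")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.k if config.k is not None else float(rng.choice(_K_CHOICES))
    n_rounds = downsample_rounds(len(member_ids), c_min, k)
    cap = max(1, c_min // 2)
    centroid = np.mean([np.asarray(features[m], dtype=float)
                        for m in member_ids], axis=0)

    kept, moved = list(member_ids), []
    for _ in range(n_rounds):
        if len(kept) <= c_mean:
            break
        order = rng.permutation(len(kept))
        removed_this_round = 0
        drop = set()
        for a, b in zip(order[::2], order[1::2]):
            if len(kept) - len(drop) <= c_mean or removed_this_round >= cap:
                break
            ia, ib = kept[a], kept[b]
            angle = cosine_angle_degrees(features[ia], features[ib], centroid)
            if angle < config.similarity_angle_threshold:
                if origins is not None and origins.get(ia) != origins.get(ib):
                    victim = ia if origins.get(ia) == "pseudo" else ib
                else:
                    victim = ia if rng.random() < 0.5 else ib
                drop.add(victim)
                removed_this_round += 1
        moved.extend(sorted(drop))
        kept = [m for m in kept if m not in drop]

    if len(kept) > c_mean:  # similarity rounds did not converge
        excess = len(kept) - c_mean
        idx = rng.choice(len(kept), size=excess, replace=False)
        drop = {kept[i] for i in idx}
        moved.extend(sorted(drop))
        kept = [m for m in kept if m not in drop]
    return kept, moved


_LOG_C = 255.0 / np.log(256.0)


# Draw weights for the upsampling palette: replication and rotation carry
# most of the mass because the grey-value transforms (stretch, inversion,
# log, inverse-log, gamma) perturb the stain-darkness signal that the
# IOD features and the classifiers read; they stay available but rare.
_UPSAMPLE_WEIGHTS = (0.30, 0.40, 0.06, 0.06, 0.06, 0.06, 0.06)


def _grey_transform(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random upsampling transform of a grey image."""
    op = rng.choice(7, p=_UPSAMPLE_WEIGHTS)
    if op == 0:  # self-replication
        out = img
    elif op == 1:  # random rotation
        out = rotate(img, rng.uniform(-180, 180), preserve_range=True,
                     cval=255.0, order=1)
    elif op == 2:  # grey stretching (min-max to full range)
        lo, hi = img.min(), img.max()
        out = img if hi == lo else (img - lo) * (255.0 / (hi - lo))
    elif op == 3:  # inversion
        out = 255.0 - img
    elif op == 4:  # log transform
        out = _LOG_C * np.log1p(img)
    elif op == 5:  # inverse-log (exponential) transform
        out = np.exp(img / _LOG_C) - 1.0
    else:  # gamma transform
        gamma = rng.uniform(0.5, 2.0)
        out = 255.0 * (img / 255.0) ** gamma
    return np.clip(out, 0, 255)


def upsample_class(members, target: int,
                   rng: np.random.Generator | int = 0):
    """Grow one rare class to ``target`` items with augmented copies.

    ``members`` are :class:`TrainItem`; the deficit is filled by seeded
    draws of a source member and a transform.  The originals are returned
    first, augmented items after.
    """
    members = list(members)
    if not members:
        raise ValueError("cannot upsample an empty class")
    if target < len(members):
        raise ValueError("target must be at least the current class size")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # replicate from real-labelled members when any exist: a pseudo-label
    # may be wrong, and augmentation would multiply that error
    sources = [m for m in members if m.origin == "real"] or members
    out = list(members)
    for j in range(target - len(members)):
        src = sources[int(rng.integers(len(sources)))]
        img = _grey_transform(np.asarray(src.image, dtype=float), rng)
        out.append(TrainItem(id=f"{src.id}~aug{j}",
                             image=np.round(img).astype(np.uint8),
                             label=src.label, origin="augmented"))
    return out


def balance(items, features: dict, config: BalanceConfig = BalanceConfig(),
            n_classes: int | None = None):
    """Equalize every class of a training set at c_mean items.

    Parameters
    ----------
    items : list of TrainItem
    features : dict id -> feature vector (needed for rich classes)

    Returns
    -------
    balanced : list of TrainItem, exactly ``l * c_mean`` items
    moved_to_unlabeled : list of item ids returned to the unlabeled pool
    """
    items = list(items)
    labels = [it.label for it in items]
    stats = class_counts(labels, n_classes)
    by_class: dict[int, list] = {c: [] for c in range(stats.l)}
    for it in items:
        by_class[it.label].append(it)

    balanced, moved = [], []
    rng = np.random.default_rng(config.seed)
    for c in range(stats.l):
        members = by_class[c]
        count = len(members)
        if count == stats.c_mean:
            balanced.extend(members)
        elif count > stats.c_mean:
            kept_ids, moved_ids = downsample_class(
                [m.id for m in members], features, stats.c_mean,
                stats.c_min, config, rng,
                origins={m.id: m.origin for m in members})
            keep = set(kept_ids)
            balanced.extend(m for m in members if m.id in keep)
            moved.extend(moved_ids)
        else:
            if count == 0:
                raise ValueError(f"class {c} has no members to upsample from")
            balanced.extend(upsample_class(members, stats.c_mean, rng))
    return balanced, moved
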