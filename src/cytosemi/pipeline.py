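"""Self-training orchestration: the full screen-split-train-filter-balance
loop behind statsmodels-style model / results objects.

:class:`SelfTrainingModel` holds the images, labels and a :class:`RunConfig`;
``fit()`` executes the rounds and returns a :class:`SelfTrainingResults`
carrying round logs, the fused ensemble, the held-out confusion matrix and a
``summary()`` table.

One round comprises: (re)train every backbone on the balanced real+pseudo
training set (warm start), weight them by validation macro-precision,
pseudo-label the unlabeled pool in two passes (per-classifier pass at the
current trust threshold, then the fused pass), update the pool, discard the
stragglers once the pool is nearly drained, and re-balance.  The trust
threshold decays 0.9 -> 0.5 by 0.1 per round.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import balancing, metrics, models, optics, pseudolabel, quality

__all__ = [
    "RunConfig",
    "RoundLog",
    "SelfTrainingModel",
    "SelfTrainingResults",
    "split_dataset",
    "standard_benchmark_config",
    "standard_benchmark_dataset",
]


def _largest_remainder(n: int, ratios) -> list:
    """Split n into len(ratios) integer cells proportional to ratios."""
    ratios = np.asarray(ratios, dtype=float)
    quota = n * ratios / ratios.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    for i in np.argsort(-rem, kind="stable")[: n - base.sum()]:
        base[i] += 1
    return base.tolist()


def split_dataset(labels, seed: int = 0, ratios=(5, 1, 1),
                  unlabeled_to_labeled=(4, 1)):
    """Stratified train/validation/test split, then unlabeled/labeled split.

    Sizes follow the ratios with largest-remainder rounding applied per
    class; deterministic given the seed.  Returns a dict of index arrays
    with keys ``labeled``, ``unlabeled``, ``val``, ``test``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < len(ratios):
        raise ValueError("pool smaller than the number of split cells")
    rng = np.random.default_rng(seed)
    out = {"labeled": [], "unlabeled": [], "val": [], "test": []}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_train, n_val, n_test = _largest_remainder(len(idx), ratios)
        train, val, test = (idx[:n_train], idx[n_train:n_train + n_val],
                            idx[n_train + n_val:])
        n_unl, n_lab = _largest_remainder(n_train, unlabeled_to_labeled)
        out["unlabeled"].append(train[:n_unl])
        out["labeled"].append(train[n_unl:])
        out["val"].append(val)
        out["test"].append(test)
    return {k: np.sort(np.concatenate(v)) if v else np.array([], dtype=int)
            for k, v in out.items()}


@dataclass(frozen=True)
class RunConfig:
    """Everything one self-training run needs.

    Defaults follow the full-scale protocol: 5:1:1 split with a 4:1
    unlabeled:labeled sub-split, 4 rounds of 50 epochs (200 total), trust
    threshold decaying 0.9 -> 0.5, stop/discard fraction 10%.
    """

    split_ratios: tuple = (5, 1, 1)
    unlabeled_to_labeled: tuple = (4, 1)
    rounds: int = 4
    epochs_per_round: int = 50
    schedule: pseudolabel.ThresholdSchedule = pseudolabel.ThresholdSchedule()
    first_pass_schedule: pseudolabel.ThresholdSchedule | None = None
    stop_fraction: float = 0.1
    classifier_specs: tuple = (
        models.ClassifierSpec(backbone_id="vgg19"),
        models.ClassifierSpec(backbone_id="resnet18"),
        models.ClassifierSpec(backbone_id="resnet50"),
        models.ClassifierSpec(backbone_id="resnext29_2x64d"),
        models.ClassifierSpec(backbone_id="resnext29_4x64d"),
    )
    balance_config: balancing.BalanceConfig = balancing.BalanceConfig()
    deblur_settings: quality.DeblurSettings = quality.DeblurSettings()
    augment_prob: float = 0.5
    screen: bool = True
    warm_start: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be at least 1")
        if any(r <= 0 for r in self.split_ratios + self.unlabeled_to_labeled):
            raise ValueError("split ratios must be positive")


@dataclass
class RoundLog:
    """Per-round record mirroring the run's training table."""

    round_index: int
    threshold: float
    n_labeled: int       # real + pseudo after this round's update
    n_unlabeled: int
    n_discarded: int
    accepted_first: int
    accepted_second: int
    classifier_val_macro_p: tuple
    fused_val_macro_p: float


class SelfTrainingResults:
    """Fitted ensemble plus diagnostics of one self-training run."""

    def __init__(self, model, handles, weights, round_logs, pool,
                 confusion_matrix, traces, screen_summary):
        self.model = model
        self.handles = handles
        self.weights = weights
        self.round_logs = round_logs
        self.pool = pool
        self.confusion_matrix = confusion_matrix
        self.traces = traces
        self.screen_summary = screen_summary
        self.per_class_precision = metrics.precision_per_class(confusion_matrix) \
            if confusion_matrix is not None else None
        self.macro_p = metrics.macro_precision(confusion_matrix) \
            if confusion_matrix is not None else None

    @property
    def logs_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.round_logs]
        return pd.DataFrame(rows)

    def predict_proba(self, images) -> np.ndarray:
        """Fused confidence vectors for new images."""
        confs = [models.predict(h, images) for h in self.handles]
        return models.fuse(self.weights, confs)

    def predict(self, images) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def evaluate(self, images, labels):
        """Confusion matrix and macro-precision on an arbitrary labelled set."""
        pred = self.predict(images)
        cm = metrics.confusion_matrix(np.asarray(labels), pred,
                                      self.model.n_classes)
        return cm, metrics.macro_precision(cm)

    def summary(self) -> str:
        lines = ["Self-training run summary",
                 "=" * 60,
                 f"classes: {self.model.n_classes}   "
                 f"items after screening: {self.pool.total}",
                 f"screening: {self.screen_summary}",
                 f"pool: labeled={len(self.pool.labeled)} "
                 f"pseudo={len(self.pool.pseudo)} "
                 f"unlabeled={len(self.pool.unlabeled)} "
                 f"discarded={len(self.pool.discarded)}",
                 "",
                 "round  threshold  labeled  unlabeled  fused val macro-P"]
        for r in self.round_logs:
            lines.append(f"{r.round_index:>5}  {r.threshold:>9.2f}  "
                         f"{r.n_labeled:>7}  {r.n_unlabeled:>9}  "
                         f"{r.fused_val_macro_p:>17.4f}")
        if self.macro_p is not None:
            lines += ["", f"test macro-P: {self.macro_p:.4f}"]
            lines.append("per-class precision: "
                         + " ".join(f"{p:.3f}"
                                    for p in self.per_class_precision))
        return "\n".join(lines)


class SelfTrainingModel:
    """Semi-supervised self-training classifier over single-cell crops.

    Parameters
    ----------
    images : sequence of 2-D uint8 arrays
        The full pool of cell crops.
    labels : sequence of int
        Ground-truth class per image.  Labels of items landing in the
        unlabeled split are hidden from training and only used to score
        validation/test sets.
    config : RunConfig
    """

    def __init__(self, images, labels, config: RunConfig = RunConfig()):
        self.images = [np.asarray(im) for im in images]
        self.labels = np.asarray(labels)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must align")
        self.config = config
        self.n_classes = int(self.labels.max()) + 1

    @classmethod
    def from_dataframe(cls, manifest: pd.DataFrame, images,
                       config: RunConfig = RunConfig()):
        """Build from a manifest with a ``label`` column plus aligned images."""
        return cls(images, manifest["label"].to_numpy(), config)

    # ------------------------------------------------------------------ fit

    def _screen(self):
        """Clarity screen with deblur-and-rescreen; returns surviving indices."""
        report, passing, failing = quality.clarity_screen(self.images)
        recovered, discarded, outputs = quality.rescreen_after_deblur(
            [self.images[i] for i in failing], report.mean_threshold,
            self.config.deblur_settings)
        keep = list(passing)
        images = {i: self.images[i] for i in passing}
        for j in recovered:
            orig = failing[j]
            keep.append(orig)
            images[orig] = np.clip(np.round(outputs[j]), 0,
                                   255).astype(np.uint8)
        keep = sorted(keep)
        summary = (f"{len(passing)} passed, {len(recovered)} recovered, "
                   f"{len(discarded)} discarded")
        return keep, [images[i] for i in keep], summary

    def fit(self, use_pseudo_labels: bool = True) -> SelfTrainingResults:
        """Run the self-training rounds (or a labeled-only baseline).

        With ``use_pseudo_labels=False`` the same backbones train for the
        same epoch budget on the balanced labelled data alone — the
        supervised baseline the semi-supervised run is compared against.
        """
        cfg = self.config
        if cfg.screen:
            keep, imgs, screen_summary = self._screen()
        else:
            keep = list(range(len(self.images)))
            imgs = list(self.images)
            screen_summary = "disabled"
        imgs = quality.standardize_size(imgs)
        labels = self.labels[keep]

        split = split_dataset(labels, seed=cfg.seed,
                              ratios=cfg.split_ratios,
                              unlabeled_to_labeled=cfg.unlabeled_to_labeled)
        ids = [f"i{j:06d}" for j in range(len(imgs))]
        image_of = dict(zip(ids, imgs))
        label_of = dict(zip(ids, labels))
        val_ids = [ids[j] for j in split["val"]]
        test_ids = [ids[j] for j in split["test"]]
        val_images = [image_of[i] for i in val_ids]
        val_labels = np.array([label_of[i] for i in val_ids])

        pool = pseudolabel.DataPool(
            labeled={ids[j] for j in split["labeled"]},
            unlabeled={ids[j] for j in split["unlabeled"]},
        )
        features = {i: optics.cell_feature_vector(image_of[i]).as_array()
                    for i in ids}

        handles = [None] * len(cfg.classifier_specs)
        traces = [[] for _ in cfg.classifier_specs]
        round_logs = []
        first_schedule = cfg.first_pass_schedule or cfg.schedule
        weights = None

        for r in range(cfg.rounds):
            # -- assemble and balance the training set
            items = [balancing.TrainItem(i, image_of[i], int(label_of[i]),
                                         "real")
                     for i in sorted(pool.labeled)]
            items += [balancing.TrainItem(i, image_of[i],
                                          pool.pseudo_labels[i].label,
                                          "pseudo")
                      for i in sorted(pool.pseudo)]
            if self.n_classes >= 3:
                bal_cfg = dataclasses.replace(cfg.balance_config,
                                              seed=cfg.balance_config.seed
                                              + cfg.seed * 101 + r)
                items, moved = balancing.balance(items, features, bal_cfg,
                                                 self.n_classes)
                for i in moved:
                    (pool.labeled if i in pool.labeled else
                     pool.pseudo).discard(i)
                    pool.pseudo_labels.pop(i, None)
                    pool.unlabeled.add(i)
                pool.check()

            # -- train every backbone on the balanced set
            train_images = [it.image for it in items]
            train_labels = [it.label for it in items]
            val_macro = []
            for ci, spec in enumerate(cfg.classifier_specs):
                spec_r = dataclasses.replace(spec, seed=spec.seed
                                             + cfg.seed * 1009 + ci,
                                             epochs=cfg.epochs_per_round)
                handles[ci], trace = models.train_classifier(
                    spec_r, train_images, train_labels,
                    augment_prob=cfg.augment_prob,
                    val_images=val_images, val_labels=val_labels,
                    handle=handles[ci] if cfg.warm_start else None,
                    n_classes=self.n_classes)
                traces[ci].append(trace)
                val_macro.append(trace.val_macro_p[-1] if trace.val_macro_p
                                 else 0.0)
            weights = models.ensemble_weights(val_macro)
            fused_val = models.fuse(
                weights, [models.predict(h, val_images) for h in handles])
            fused_val_macro = metrics.macro_precision(metrics.confusion_matrix(
                val_labels, fused_val.argmax(axis=1), self.n_classes))

            # filtering stops once the unlabeled pool is drained below the
            # stop fraction, but training continues so every run spends the
            # same rounds * epochs_per_round budget
            threshold = cfg.schedule.value(r)
            n_first = n_second = 0
            still_filtering = (
                pool.initial_unlabeled_count == 0
                or len(pool.unlabeled)
                >= cfg.stop_fraction * pool.initial_unlabeled_count)
            if use_pseudo_labels and pool.unlabeled and still_filtering:
                unl = sorted(pool.unlabeled)
                unl_images = [image_of[i] for i in unl]
                per_clf = [models.predict(h, unl_images) for h in handles]
                acc1, remaining = pseudolabel.first_pass_filter(
                    per_clf, first_schedule.value(r), unl,
                    classifier_ids=[s.backbone_id
                                    for s in cfg.classifier_specs],
                    round_index=r)
                rem_rows = [unl.index(i) for i in remaining]
                fused_rem = models.fuse(
                    weights, [p[rem_rows] for p in per_clf]) \
                    if remaining else np.zeros((0, self.n_classes))
                acc2, _ = pseudolabel.second_pass_filter(
                    fused_rem, threshold, remaining, round_index=r)
                pseudolabel.update_pool(pool, acc1, acc2)
                pseudolabel.maybe_discard(pool, cfg.stop_fraction)
                n_first, n_second = len(acc1), len(acc2)

            round_logs.append(RoundLog(
                round_index=r, threshold=threshold,
                n_labeled=len(pool.labeled) + len(pool.pseudo),
                n_unlabeled=len(pool.unlabeled),
                n_discarded=len(pool.discarded),
                accepted_first=n_first, accepted_second=n_second,
                classifier_val_macro_p=tuple(val_macro),
                fused_val_macro_p=float(fused_val_macro)))

        test_images = [image_of[i] for i in test_ids]
        test_labels = np.array([label_of[i] for i in test_ids])
        results = SelfTrainingResults(
            model=self, handles=handles, weights=weights,
            round_logs=round_logs, pool=pool, confusion_matrix=None,
            traces=traces, screen_summary=screen_summary)
        if len(test_ids):
            cm, _ = results.evaluate(test_images, test_labels)
            results.confusion_matrix = cm
            results.per_class_precision = metrics.precision_per_class(cm)
            results.macro_p = metrics.macro_precision(cm)
        return results


# --------------------------------------------------------------- benchmark

#: Families of the standard 6-class synthetic benchmark.
BENCHMARK_CLASSES = ("single_round", "paired", "lobed", "pyknotic",
                     "abnormal", "garbage_dark")


def standard_benchmark_dataset(seed: int = 0, per_class: int = 300):
    """The standard synthetic benchmark: 6 families, 300 crops each.

    Clean (unblurred) images with mild grey noise; the morphological spread
    between families is large relative to focus effects, so the clarity
    screen is exercised by dedicated single-family fixtures instead and the
    benchmark feeds the loop directly.
    """
    from .synthetic import DEFAULT_CLASS_DEFS, SyntheticConfig, generate_dataset
    spec = tuple(DEFAULT_CLASS_DEFS[name] for name in BENCHMARK_CLASSES)
    config = SyntheticConfig(class_spec=spec,
                             per_class_counts=(per_class,) * len(spec),
                             blur_fraction=0.0, noise_sigma=2.0, seed=seed)
    return generate_dataset(config)


def standard_benchmark_config(seed: int = 0, epochs_per_round: int = 50,
                              rounds: int = 4) -> RunConfig:
    """Scaled-down run configuration for the synthetic benchmark.

    Three small backbones keep single-CPU wall time modest while retaining
    ensemble diversity; the 4 x 50 epoch budget, decaying trust-threshold
    schedule and the 5:1:1 / 4:1 splits match the full-scale protocol.  The
    single-classifier first pass uses a fixed high confidence bar (0.95) so
    the fused second pass — the ensemble vote — carries the decaying trust
    schedule.
    """
    specs = tuple(models.ClassifierSpec(backbone_id=b,
                                        epochs=epochs_per_round, seed=seed)
                  for b in ("vgg19", "resnet18", "resnext29_2x64d"))
    return RunConfig(rounds=rounds, epochs_per_round=epochs_per_round,
                     classifier_specs=specs,
                     first_pass_schedule=pseudolabel.ThresholdSchedule(
                         0.95, 0.0, 0.95),
                     screen=False, seed=seed)
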