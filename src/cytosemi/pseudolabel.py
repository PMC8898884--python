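"""Two-pass pseudo-label filtering, the decaying trust threshold, and the
four-way data-pool bookkeeping.

Each self-training round, unlabeled items are screened twice:

* first pass — any *single* classifier whose top confidence exceeds the
  current trust threshold may pseudo-label the item (different backbones are
  sensitive to different cell classes when data is scarce); conflicts go to
  the most confident classifier, ties to the lowest classifier index;
* second pass — the remaining items are screened against the *fused*
  classifier's confidence; rejects return to the unlabeled pool.

The trust threshold starts at 0.9 and drops by 0.1 per round to a floor of
0.5.  When the unlabeled pool shrinks below a fraction (default 10%) of its
initial size, the remaining low-confidence items are discarded outright.
The pool invariant — labeled + pseudo + unlabeled + discarded is constant
and the sets are disjoint — holds across every operation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdSchedule",
    "PseudoLabel",
    "DataPool",
    "schedule_value",
    "first_pass_filter",
    "second_pass_filter",
    "update_pool",
    "maybe_discard",
]


@dataclass(frozen=True)
class ThresholdSchedule:
    """Linear decay of the trust threshold over rounds, clamped at a floor."""

    start: float = 0.9
    step: float = 0.1
    floor: float = 0.5

    def __post_init__(self) -> None:
        if self.step < 0:
            raise ValueError("step must be non-negative")
        if self.floor > self.start:
            raise ValueError("floor must not exceed start")

    def value(self, round_index: int) -> float:
        return max(self.start - self.step * round_index, self.floor)


def schedule_value(round_index: int,
                   schedule: ThresholdSchedule = ThresholdSchedule()) -> float:
    """Trust threshold for a round: ``max(start - step*round, floor)``."""
    return schedule.value(round_index)


@dataclass(frozen=True)
class PseudoLabel:
    """A pseudo-label with its accepting confidence and provenance."""

    label: int
    confidence: float
    provenance: str  # classifier id or "fused"
    round_index: int


@dataclass
class DataPool:
    """Disjoint four-way partition of all items, tracked by item id."""

    labeled: set = field(default_factory=set)
    pseudo: set = field(default_factory=set)
    unlabeled: set = field(default_factory=set)
    discarded: set = field(default_factory=set)
    initial_unlabeled_count: int = 0
    pseudo_labels: dict = field(default_factory=dict)  # id -> PseudoLabel

    def __post_init__(self) -> None:
        self.labeled = set(self.labeled)
        self.pseudo = set(self.pseudo)
        self.unlabeled = set(self.unlabeled)
        self.discarded = set(self.discarded)
        if self.initial_unlabeled_count == 0:
            self.initial_unlabeled_count = len(self.unlabeled)
        self.check()

    @property
    def total(self) -> int:
        return (len(self.labeled) + len(self.pseudo)
                + len(self.unlabeled) + len(self.discarded))

    def check(self) -> None:
        """Assert disjointness of the four sets."""
        sets = [self.labeled, self.pseudo, self.unlabeled, self.discarded]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("pool sets must be disjoint")

    def to_frame(self):
        """Serialize pool membership as a manifest DataFrame
        (id, set, pseudo_label, pseudo_confidence, provenance, round)."""
        import pandas as pd
        rows = []
        for name, ids in (("labeled", self.labeled), ("pseudo", self.pseudo),
                          ("unlabeled", self.unlabeled),
                          ("discarded", self.discarded)):
            for i in sorted(ids):
                pl = self.pseudo_labels.get(i)
                rows.append({"id": i, "set": name,
                             "pseudo_label": pl.label if pl else None,
                             "pseudo_confidence": pl.confidence if pl else None,
                             "provenance": pl.provenance if pl else None,
                             "round": pl.round_index if pl else None})
        return pd.DataFrame(rows)


def _top(conf_row: np.ndarray):
    label = int(np.argmax(conf_row))
    return label, float(conf_row[label])


def first_pass_filter(per_classifier_predictions, max_threshold: float,
                      item_ids, classifier_ids=None, round_index: int = 0):
    """Accept items any single classifier labels above the threshold.

    Parameters
    ----------
    per_classifier_predictions : sequence of (n_items, n_classes) arrays
        One confidence matrix per classifier, rows aligned with ``item_ids``.
    max_threshold : float
        First-pass ("maximum") confidence threshold; acceptance is strict.

    Returns
    -------
    accepted : dict mapping item id -> PseudoLabel
    remaining : list of item ids not accepted, in input order
    """
    preds = [np.atleast_2d(np.asarray(p, dtype=float))
             for p in per_classifier_predictions]
    if not preds:
        raise ValueError("at least one classifier's predictions are required")
    n_items = preds[0].shape[0]
    if any(p.shape[0] != n_items for p in preds) or n_items != len(item_ids):
        raise ValueError("prediction rows must align with item_ids")
    if classifier_ids is None:
        classifier_ids = [f"clf{i}" for i in range(len(preds))]

    accepted, remaining = {}, []
    for row, item in enumerate(item_ids):
        best = None  # (confidence, clf_index, label)
        for ci, p in enumerate(preds):
            label, conf = _top(p[row])
            if conf > max_threshold and (best is None or conf > best[0]):
                best = (conf, ci, label)
        if best is None:
            remaining.append(item)
        else:
            conf, ci, label = best
            accepted[item] = PseudoLabel(label=label, confidence=conf,
                                         provenance=classifier_ids[ci],
                                         round_index=round_index)
    return accepted, remaining


def second_pass_filter(fused_predictions, min_threshold: float, item_ids,
                       round_index: int = 0):
    """Accept items the fused classifier labels above the threshold.

    Returns ``(accepted, returned_to_unlabeled)``; rejects go back to the
    unlabeled pool.
    """
    fused = np.atleast_2d(np.asarray(fused_predictions, dtype=float))
    if fused.shape[0] != len(item_ids):
        raise ValueError("prediction rows must align with item_ids")
    accepted, returned = {}, []
    for row, item in enumerate(item_ids):
        label, conf = _top(fused[row])
        if conf > min_threshold:
            accepted[item] = PseudoLabel(label=label, confidence=conf,
                                         provenance="fused",
                                         round_index=round_index)
        else:
            returned.append(item)
    return accepted, returned


def update_pool(pool: DataPool, accepted_first: dict,
                accepted_second: dict) -> DataPool:
    """Move accepted items from unlabeled to pseudo (in place).

    An item accepted by both passes is counted once with its first-pass
    provenance.  Total count is conserved.
    """
    merged = dict(accepted_second)
    merged.update(accepted_first)  # first pass wins on overlap
    for item, pl in merged.items():
        if item not in pool.unlabeled:
            raise KeyError(f"item {item!r} is not in the unlabeled pool")
        pool.unlabeled.remove(item)
        pool.pseudo.add(item)
        pool.pseudo_labels[item] = pl
    pool.check()
    return pool


def maybe_discard(pool: DataPool, discard_fraction: float = 0.1) -> DataPool:
    """Discard all remaining unlabeled items once the pool is nearly drained.

    Fires when ``|unlabeled| < discard_fraction * initial_unlabeled_count``;
    items move to the discarded set (never deleted), conserving the total.
    """
    if len(pool.unlabeled) < discard_fraction * pool.initial_unlabeled_count:
        pool.discarded |= pool.unlabeled
        pool.unlabeled = set()
        pool.check()
    return pool
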