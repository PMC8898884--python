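import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytosemi import BalanceConfig, TrainItem, balance, class_counts
from cytosemi.balancing import (downsample_class, downsample_rounds,
                                upsample_class)


class TestClassCounts:
    def test_trimmed_mean_exclusion_rule(self):
        labels = [0] * 10 + [1] * 20 + [2] * 30 + [3] * 40
        cc = class_counts(labels)
        assert cc.counts == (10, 20, 30, 40)
        assert cc.c_min == 10 and cc.c_max == 40
        assert cc.c_mean == 25

    def test_all_equal_counts(self):
        cc = class_counts([0] * 7 + [1] * 7 + [2] * 7)
        assert cc.c_mean == 7

    def test_fewer_than_three_classes_rejected(self):
        with pytest.raises(ValueError):
            class_counts([0, 0, 1, 1])

    def test_ties_broken_by_lowest_class_index(self):
        cc = class_counts([0] * 5 + [1] * 5 + [2] * 5 + [3] * 9)
        assert cc.c_min_class == 0 and cc.c_max_class == 3


class TestDownsampleRounds:
    def test_hand_case(self):
        assert downsample_rounds(6000, 1000, 1 / 2) == 12

    def test_small_class_rounds_to_one(self):
        assert downsample_rounds(400, 1000, 1 / 2) == 1

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            downsample_rounds(100, 10, 0.4)

    def test_zero_c_min_rejected(self):
        with pytest.raises(ValueError):
            downsample_rounds(100, 0, 1 / 2)

    @given(st.integers(1, 5000), st.integers(1, 500),
           st.sampled_from([1 / 2, 1 / 3, 1 / 4]))
    @settings(max_examples=100, deadline=None)
    def test_matches_ceiling_oracle(self, c_i, c_min, k):
        assert downsample_rounds(c_i, c_min, k) == \
            max(1, math.ceil(c_i / (k * c_min)))


def _features_identical(ids):
    return {i: np.array([10.0, 5.0, 2.0]) for i in ids}


class TestDownsampleClass:
    def test_precondition_enforced(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError):
            downsample_class(ids, _features_identical(ids), c_mean=2, c_min=2)

    def test_identical_members_drain_to_c_mean(self):
        ids = [f"m{k}" for k in range(20)]
        kept, moved = downsample_class(ids, _features_identical(ids),
                                       c_mean=8, c_min=8,
                                       config=BalanceConfig(seed=1))
        assert len(kept) == 8
        assert sorted(kept + moved) == sorted(ids)

    def test_dissimilar_clusters_protected_until_fallback(self):
        """Cross-cluster pairs (orthogonal centred features) never count as
        similar, so similarity rounds alone remove nothing."""
        ids = [f"m{k}" for k in range(10)]
        feats = {}
        for k, i in enumerate(ids):
            feats[i] = (np.array([50.0, 0.0, 0.0]) if k % 2 == 0
                        else np.array([0.0, 50.0, 0.0]))
        cfg = BalanceConfig(seed=0, k=1 / 2,
                            similarity_angle_threshold=15.0)
        kept, moved = downsample_class(ids, feats, c_mean=6, c_min=6,
                                       config=cfg)
        # the uniform fallback still enforces the target
        assert len(kept) == 6
        assert sorted(kept + moved) == sorted(ids)

    def test_per_round_cap_half_c_min(self):
        ids = [f"m{k}" for k in range(40)]
        cfg = BalanceConfig(seed=3, k=1 / 2)
        c_min = 10
        n_rounds = downsample_rounds(len(ids), c_min, 1 / 2)
        # replicate with a counting wrapper: cap is floor(c_min/2) = 5
        kept, moved = downsample_class(ids, _features_identical(ids),
                                       c_mean=10, c_min=c_min, config=cfg)
        assert len(kept) == 10
        # 30 removals at <= 5 per similarity round cannot exceed rounds * cap
        assert len(moved) <= n_rounds * (c_min // 2) + (len(ids) - 10)


class TestUpsampleClass:
    def _members(self, n, label=0):
        rng = np.random.default_rng(0)
        return [TrainItem(f"x{k}", rng.integers(0, 255, (8, 8)).astype(
            np.uint8), label) for k in range(n)]

    def test_target_equal_size_is_identity(self):
        members = self._members(4)
        out = upsample_class(members, 4, 0)
        assert out == members

    def test_deficit_filled_from_members(self):
        members = self._members(3)
        out = upsample_class(members, 10, 1)
        assert len(out) == 10
        assert all(it.origin == "augmented" for it in out[3:])
        roots = {it.id.split("~")[0] for it in out[3:]}
        assert roots <= {m.id for m in members}

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            upsample_class([], 5, 0)

    def test_inversion_is_involution(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        assert np.allclose(255 - (255 - img), img)

    def test_gamma_one_is_identity(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        assert np.allclose(255.0 * (img / 255.0) ** 1.0, img)


class TestBalance:
    def _items_and_features(self, counts, seed=0):
        rng = np.random.default_rng(seed)
        items, feats = [], {}
        for label, n in enumerate(counts):
            for k in range(n):
                iid = f"c{label}_{k}"
                img = rng.integers(0, 255, (8, 8)).astype(np.uint8)
                items.append(TrainItem(iid, img, label))
                feats[iid] = rng.uniform(0, 30, 3)
        return items, feats

    def test_already_balanced_identity(self):
        items, feats = self._items_and_features((5, 5, 5))
        balanced, moved = balance(items, feats)
        assert balanced == items and moved == []

    def test_counts_10_20_30_40_all_reach_25(self):
        items, feats = self._items_and_features((10, 20, 30, 40))
        balanced, moved = balance(items, feats, BalanceConfig(seed=2))
        out_counts = np.bincount([it.label for it in balanced], minlength=4)
        assert out_counts.tolist() == [25, 25, 25, 25]
        assert len(balanced) == 4 * 25

    def test_conservation_including_moved_stream(self):
        items, feats = self._items_and_features((10, 20, 30, 40))
        balanced, moved = balance(items, feats, BalanceConfig(seed=2))
        original_ids = {it.id for it in items}
        kept_original = {it.id for it in balanced if it.origin != "augmented"}
        assert kept_original | set(moved) == original_ids
        assert not kept_original & set(moved)

    def test_idempotent_under_fixed_seed(self):
        items, feats = self._items_and_features((10, 20, 30, 40))
        once, _ = balance(items, feats, BalanceConfig(seed=5))
        for it in once:
            feats.setdefault(it.id, np.zeros(3))
        twice, moved = balance(once, feats, BalanceConfig(seed=5))
        assert [it.id for it in twice] == [it.id for it in once]
        assert moved == []

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            BalanceConfig(k=0.4)
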