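"""SF/MF fusion arithmetic and the mining/balancing machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stablewatch.core import BehaviorLabel, Task
from stablewatch.fusion import (fuse_interval, mine_hard_examples,
                                rebalance_upsample, sample_balanced,
                                split_train_val)

from conftest import D, O, S, U


def pred(sf_label_idx, mf_label_idx, conf=0.9, interval=0, night="n1"):
    """Prediction with controlled SF/MF argmaxes and fused confidence."""
    k = 4
    sf = np.full(k, (1 - conf) / (k - 1))
    sf[sf_label_idx] = conf
    mf = np.full(k, (1 - conf) / (k - 1))
    mf[mf_label_idx] = conf
    return fuse_interval(np.tile(sf, (4, 1)), mf, Task.TOTAL,
                         interval_index=interval, night_id=night)


class TestFuseInterval:
    def test_average_of_sf_aggregate_and_mf(self):
        sf = np.tile([0.8, 0.1, 0.1, 0.0], (4, 1))
        mf = [0.6, 0.3, 0.1, 0.0]
        p = fuse_interval(sf, mf, Task.TOTAL)
        assert np.allclose(p.fused_probs, [0.7, 0.2, 0.1, 0.0])
        assert p.fused_label is S
        assert p.confidence == pytest.approx(0.7)

    def test_identical_inputs_fuse_to_themselves(self):
        v = [0.25, 0.25, 0.4, 0.1]
        p = fuse_interval(np.tile(v, (4, 1)), v, Task.TOTAL)
        assert np.allclose(p.fused_probs, v)

    def test_tie_broken_by_class_order(self):
        p = fuse_interval(np.tile([0.5, 0.5, 0, 0], (4, 1)),
                          [0.5, 0.5, 0, 0], Task.TOTAL)
        assert p.fused_label is S  # Standing precedes LHU in class order

    def test_all_black_bypasses_to_out(self):
        p = fuse_interval(None, None, Task.TOTAL, all_black=True)
        assert p.fused_label is O and p.confidence == 1.0

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            fuse_interval(np.tile([0.5, 0.2, 0.2, 0.0], (4, 1)),
                          [1, 0, 0, 0], Task.TOTAL)

    def test_fused_vector_sums_to_one_and_is_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sf = rng.dirichlet(np.ones(4), size=4)
            mf = rng.dirichlet(np.ones(4))
            a = fuse_interval(sf, mf, Task.TOTAL).fused_probs
            # swap roles: use mf as every frame's SF vector and sf mean as MF
            b = fuse_interval(np.tile(mf, (4, 1)), sf.mean(axis=0),
                              Task.TOTAL).fused_probs
            assert abs(a.sum() - 1) < 1e-9
            assert np.allclose(a, b)


class TestHardExamples:
    def test_disagreement_is_hard(self):
        assert len(mine_hard_examples([pred(1, 2)], 0.5).refs) == 1

    def test_low_confidence_is_hard(self):
        p = pred(0, 0, conf=0.6)
        assert len(mine_hard_examples([p], tau=0.75).refs) == 1

    def test_confident_agreement_is_not_hard(self):
        p = pred(0, 0, conf=0.99)
        assert mine_hard_examples([p], tau=0.75).refs == ()

    def test_hard_set_monotone_in_tau(self):
        rng = np.random.default_rng(2)
        preds = [pred(int(rng.integers(0, 4)), int(rng.integers(0, 4)),
                      conf=float(rng.uniform(0.3, 0.99)), interval=i)
                 for i in range(100)]
        sizes = [len(mine_hard_examples(preds, t).refs)
                 for t in (0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes)


class TestSampleBalanced:
    def _preds(self, counts):
        preds = []
        i = 0
        for label_idx, n in counts.items():
            for _ in range(n):
                preds.append(pred(label_idx, label_idx, conf=0.97, interval=i,
                                  night=f"n{i % 3}"))
                i += 1
        return preds

    def test_quota_met_when_available(self):
        preds = self._preds({0: 50, 1: 40, 2: 30})
        sel = sample_balanced(preds, 20, seed=0)
        per_class = {}
        for r in sel.refs:
            per_class[r.label] = per_class.get(r.label, 0) + 1
        assert per_class == {S: 20, U: 20, D: 20}
        assert sel.shortfall == {}

    def test_scarcity_capped_and_reported(self):
        preds = self._preds({0: 50, 2: 5})
        sel = sample_balanced(preds, 10, seed=0)
        assert sel.shortfall == {D: 5}

    def test_deterministic_per_seed(self):
        preds = self._preds({0: 30, 1: 30})
        assert sample_balanced(preds, 10, 7).refs == \
            sample_balanced(preds, 10, 7).refs

    def test_no_duplicates_and_spread_over_nights(self):
        preds = self._preds({0: 60})
        sel = sample_balanced(preds, 30, seed=1)
        assert len(set(sel.refs)) == 30
        nights = {}
        for r in sel.refs:
            nights[r.night_id] = nights.get(r.night_id, 0) + 1
        assert max(nights.values()) - min(nights.values()) <= 1


class TestUpsample:
    def test_minority_upsampled_to_majority(self):
        plan = rebalance_upsample({S: list(range(100)), U: list(range(50))},
                                  seed=0)
        assert len(plan[S]) == 0 and len(plan[U]) == 50
        assert set(plan[U]) <= set(range(50))

    def test_balanced_input_gives_empty_plan(self):
        plan = rebalance_upsample({S: [1, 2], U: [3, 4]}, seed=0)
        assert all(len(v) == 0 for v in plan.values())

    def test_three_class_plan_sizes(self):
        plan = rebalance_upsample({S: [1, 2, 3], U: [4], D: [5, 6]}, seed=0)
        assert {k: len(v) for k, v in plan.items()} == {S: 0, U: 2, D: 1}

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            rebalance_upsample({S: [1], U: []}, seed=0)


class TestSplit:
    def test_90_10_split(self):
        train, val = split_train_val(list(range(100)), [0] * 100, 0.10, 0)
        assert len(train) == 90 and len(val) == 10

    def test_95_5_on_small_set(self):
        train, val = split_train_val(list(range(20)), [0] * 20, 0.05, 0)
        assert len(train) == 19 and len(val) == 1

    def test_disjoint_exhaustive_and_deterministic(self):
        examples = list(range(57))
        labels = [i % 3 for i in examples]
        t1, v1 = split_train_val(examples, labels, 0.2, 3)
        t2, v2 = split_train_val(examples, labels, 0.2, 3)
        assert (t1, v1) == (t2, v2)
        assert set(t1) | set(v1) == set(examples)
        assert set(t1) & set(v1) == set()

    def test_stratified_per_class(self):
        examples = list(range(100))
        labels = [0] * 80 + [1] * 20
        _, val = split_train_val(examples, labels, 0.10, 0)
        val_minority = sum(1 for e in val if labels[e] == 1)
        assert val_minority == 2

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_val([1], [0], 1.5, 0)
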