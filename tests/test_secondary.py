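"""Fold bookkeeping, false-positive harvesting set algebra, discard rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuffseg.preprocess import PatchSpec
from cuffseg.secondary import (
    FoldAssignment,
    build_secondary_labelmap,
    false_positive_mask,
    generate_secondary_dataset,
    make_folds,
    predict_refined,
)
from cuffseg.segnet import NetworkConfig, TrainConfig, build_network
from cuffseg.volio import LabelMap


def _lm(arr, n_classes=5):
    a = np.asarray(arr, dtype=np.int16).reshape(1, 1, -1)
    return LabelMap(labels=a, spacing_mm=(1, 1, 1), n_classes=n_classes)


class TestMakeFolds:
    def test_balanced_partition_10_by_5(self):
        fa = make_folds([f"c{i}" for i in range(10)], k=5, seed=1)
        sizes = sorted(len(fa.fold_ids(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 2]
        assert sorted(sum((fa.fold_ids(f) for f in range(5)), [])) == sorted(
            f"c{i}" for i in range(10)
        )

    def test_7_cases_5_folds(self):
        fa = make_folds([f"c{i}" for i in range(7)], k=5, seed=0)
        assert sorted(len(fa.fold_ids(f)) for f in range(5)) == [1, 1, 1, 2, 2]

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(9)]
        assert make_folds(ids, 3, seed=5).membership == make_folds(ids, 3, seed=5).membership

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=3, seed=0)

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(2, 60), k=st.integers(2, 8), seed=st.integers(0, 10**6))
    def test_partition_property(self, n, k, seed):
        if n < k:
            with pytest.raises(ValueError):
                make_folds([f"c{i}" for i in range(n)], k, seed)
            return
        fa = make_folds([f"c{i}" for i in range(n)], k, seed)
        all_ids = sum((fa.fold_ids(f) for f in range(k)), [])
        assert sorted(all_ids) == sorted(f"c{i}" for i in range(n))
        sizes = [len(fa.fold_ids(f)) for f in range(k)]
        assert max(sizes) - min(sizes) <= 1

    def test_unbalanced_assignment_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            FoldAssignment(k=2, membership={"a": 0, "b": 0, "c": 0, "d": 1, "e": 0})


class TestFalsePositiveMask:
    def test_background_fp_harvested(self):
        truth = _lm([3, 0, 0, 1])
        pred = _lm([3, 3, 0, 1])
        np.testing.assert_array_equal(
            false_positive_mask(truth, pred, 3).ravel(), [False, True, False, False]
        )

    def test_perfect_prediction_empty_mask(self, default_case):
        mask = false_positive_mask(default_case.truth, default_case.truth, 3)
        assert not mask.any()

    def test_foreground_truth_excluded(self):
        # prediction says tendon where truth says muscle: ground truth wins
        truth = _lm([1, 0])
        pred = _lm([3, 0])
        assert not false_positive_mask(truth, pred, 3).any()

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            false_positive_mask(_lm([0]), _lm([0, 0]), 3)


class TestBuildSecondaryLabelmap:
    def test_empty_mask_identity_with_extra_class(self, default_case):
        out = build_secondary_labelmap(
            default_case.truth, np.zeros(default_case.truth.shape, bool)
        )
        assert out.n_classes == 6
        np.testing.assert_array_equal(out.labels, default_case.truth.labels)

    def test_mask_becomes_auxiliary_class(self):
        truth = _lm([3, 0, 0])
        mask = np.array([False, True, False]).reshape(1, 1, 3)
        out = build_secondary_labelmap(truth, mask)
        np.testing.assert_array_equal(out.labels.ravel(), [3, 5, 0])

    def test_masking_auxiliary_recovers_truth(self, default_case):
        mask = (default_case.truth.labels == 0) & default_case.confuser_mask
        out = build_secondary_labelmap(default_case.truth, mask)
        recovered = out.labels.copy()
        recovered[recovered == 5] = 0
        np.testing.assert_array_equal(recovered, default_case.truth.labels)

    def test_overlap_with_foreground_rejected(self):
        truth = _lm([3, 0])
        mask = np.array([True, False]).reshape(1, 1, 2)
        with pytest.raises(ValueError, match="2 voxel|1 voxel"):
            build_secondary_labelmap(truth, np.array([True, True]).reshape(1, 1, 2))
        with pytest.raises(ValueError, match="voxel"):
            build_secondary_labelmap(truth, mask)


class TestPredictRefined:
    def test_output_label_set_excludes_auxiliary(self, small_cohort):
        from cuffseg.preprocess import normalize_intensity

        net = build_network(
            NetworkConfig(dimensionality=3, n_classes=6, base_channels=2, depth=1), seed=0
        )
        img = normalize_intensity(small_cohort[0].image)
        out = predict_refined(net, img, PatchSpec(patch_shape=(8, 32, 32)))
        assert out.n_classes == 5
        assert set(np.unique(out.labels)) <= {0, 1, 2, 3, 4}

    def test_adversarial_argmax_remapped_to_background(self, small_cohort, monkeypatch):
        """A model whose argmax is everywhere the auxiliary class must yield
        pure background after the discard."""
        from cuffseg.preprocess import normalize_intensity

        net = build_network(
            NetworkConfig(dimensionality=3, n_classes=6, base_channels=2, depth=1), seed=0
        )
        logits = np.array([0, 1, 2, 3, 4, 50], dtype=np.float32)

        def fake_forward(x):
            out = np.zeros((x.shape[0], 6) + x.shape[2:], dtype=np.float32)
            out += logits.reshape(1, 6, 1, 1, 1)
            return out

        monkeypatch.setattr(net, "forward", fake_forward)
        img = normalize_intensity(small_cohort[0].image)
        out = predict_refined(net, img, PatchSpec(patch_shape=(8, 32, 32)))
        assert np.all(out.labels == 0)

    def test_class_count_mismatch_rejected(self, small_cohort):
        net = build_network(
            NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1), seed=0
        )
        with pytest.raises(ValueError, match="classes"):
            predict_refined(net, small_cohort[0].image, PatchSpec(), original_n_classes=5)


@pytest.fixture(scope="module")
def tiny_secondary(small_cohort):
    """k=2 secondary dataset with deliberately short fold trainings."""
    net_cfg = NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1)
    tr_cfg = TrainConfig(batch_size=2, max_epochs=2, steps_per_epoch=2,
                         learning_rate=0.05, patience=5, seed=3)
    return generate_secondary_dataset(
        small_cohort[:4], k=2, net_cfg=net_cfg, train_cfg=tr_cfg,
        patch_spec=PatchSpec(patch_shape=(4, 16, 16), foreground_bias=0.7),
    )


class TestGenerateSecondaryDataset:
    def test_truth_preserved_bit_exactly(self, small_cohort, tiny_secondary):
        for (cid, _img, sec), case in zip(tiny_secondary.cases, small_cohort[:4]):
            recovered = sec.labels.copy()
            recovered[recovered == tiny_secondary.auxiliary_class] = 0
            np.testing.assert_array_equal(recovered, case.truth.labels)

    def test_auxiliary_never_on_foreground(self, small_cohort, tiny_secondary):
        for (cid, _img, sec), case in zip(tiny_secondary.cases, small_cohort[:4]):
            aux = sec.labels == tiny_secondary.auxiliary_class
            assert not np.any(aux & (case.truth.labels != 0))

    def test_no_leakage_fold_bookkeeping(self, tiny_secondary):
        """Every case's auxiliary label must come from the fold that held the
        case out of training."""
        for cid, meta in tiny_secondary.provenance.items():
            assert tiny_secondary.folds.membership[cid] == meta["fold"]

    def test_requires_at_least_k_cases(self, small_cohort):
        with pytest.raises(ValueError):
            generate_secondary_dataset(
                small_cohort[:1], k=2,
                net_cfg=NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1),
                train_cfg=TrainConfig(), patch_spec=PatchSpec(),
            )
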