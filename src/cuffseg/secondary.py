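"""Secondary labelling: cross-validated false-positive harvesting.

The procedure reduces systematic false positives of one target class (here
the cuff tendon, confused with the unlabelled tendon-like biceps analogue):

1. split the training cohort into k folds; for each fold, train a baseline
   model on the *other* folds and predict the fold's cases, so every case is
   predicted by a model that never saw it;
2. harvest each case's false positives of the target class — voxels the
   model called tendon where the ground truth is *background* (voxels where
   the truth carries another foreground class are left untouched: the
   original labels are preserved bit-exactly);
3. add those voxels as a new auxiliary class, yielding a (k+1)-class
   dataset, and retrain;
4. at inference, voxels whose argmax is the auxiliary class are remapped to
   background — the model may explain the confuser away as "not tendon"
   without the tendon channel having to absorb it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PatchSpec, normalize_intensity
from .segnet import NetworkConfig, TrainConfig, UNet, predict, train
from .volio import ImageVolume, LabelMap

__all__ = [
    "FoldAssignment",
    "SecondaryDataset",
    "make_folds",
    "false_positive_mask",
    "build_secondary_labelmap",
    "generate_secondary_dataset",
    "predict_refined",
]

TARGET_CLASS_DEFAULT = 3  # cuff tendon


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of case ids into k cross-validation folds."""

    k: int
    membership: dict  # case_id -> fold index in [0, k)

    def __post_init__(self) -> None:
        folds = np.array(list(self.membership.values()))
        if folds.size and (folds.min() < 0 or folds.max() >= self.k):
            raise ValueError("fold indices out of range")
        sizes = np.bincount(folds, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError(f"fold sizes must differ by at most 1, got {sizes.tolist()}")

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.membership.items() if f == fold]


@dataclass
class SecondaryDataset:
    """(k+1)-class relabelled cohort plus the provenance of every auxiliary label."""

    cases: list  # (case_id, ImageVolume, secondary LabelMap)
    target_class: int
    auxiliary_class: int
    folds: FoldAssignment
    provenance: dict  # case_id -> {"fold": int, "fp_voxels": int}


def make_folds(case_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded balanced partition of case ids into ``k`` folds."""
    case_ids = list(case_ids)
    n = len(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} cases, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    membership = {case_ids[int(i)]: int(pos % k) for pos, i in enumerate(perm)}
    return FoldAssignment(k=k, membership=membership)


def false_positive_mask(truth: LabelMap, predicted: LabelMap, target_class: int) -> np.ndarray:
    """Voxels predicted as the target class where the truth is *background*.

    Voxels where the prediction says target but the truth carries another
    foreground class are excluded: existing ground-truth labels are never
    turned into auxiliary voxels.
    """
    if truth.shape != predicted.shape:
        raise ValueError(f"grid mismatch: truth {truth.shape} vs predicted {predicted.shape}")
    return (predicted.labels == target_class) & (truth.labels == 0)


def build_secondary_labelmap(truth: LabelMap, fp_mask: np.ndarray) -> LabelMap:
    """Merge harvested false positives into the truth as a new last class."""
    fp_mask = np.asarray(fp_mask, dtype=bool)
    if fp_mask.shape != truth.shape:
        raise ValueError("fp_mask grid mismatch")
    overlap = int(np.count_nonzero(fp_mask & (truth.labels != 0)))
    if overlap:
        raise ValueError(
            f"fp_mask overlaps ground-truth foreground on {overlap} voxel(s); "
            "secondary labels may only annotate background"
        )
    out = truth.labels.copy()
    out[fp_mask] = truth.n_classes  # the newly appended auxiliary class
    return LabelMap(labels=out, spacing_mm=truth.spacing_mm, n_classes=truth.n_classes + 1)


def generate_secondary_dataset(
    cases,
    k: int,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    patch_spec: PatchSpec,
    target_class: int = TARGET_CLASS_DEFAULT,
    fold_seed: int | None = None,
) -> SecondaryDataset:
    """Cross-validated construction of the (k+1)-class secondary dataset.

    For each fold a fresh model (seed = base seed + fold index) is trained on
    all out-of-fold cases and predicts the in-fold cases, so every case's
    auxiliary label comes from exactly the model that did not see it.  One
    out-of-fold case doubles as the tuning case for early stopping.
    """
    cases = list(cases)
    if len(cases) < k:
        raise ValueError(f"need at least k={k} cases")
    by_id = {c.case_id: c for c in cases}
    folds = make_folds(
        [c.case_id for c in cases], k,
        seed=train_cfg.seed if fold_seed is None else fold_seed,
    )

    out_cases: dict = {}
    provenance: dict = {}
    for f in range(k):
        in_ids = folds.fold_ids(f)
        out_ids = [cid for cid in by_id if cid not in in_ids]
        fold_cfg = TrainConfig(
            batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            steps_per_epoch=train_cfg.steps_per_epoch,
            learning_rate=train_cfg.learning_rate,
            momentum=train_cfg.momentum,
            patience=train_cfg.patience,
            epsilon=train_cfg.epsilon,
            class_weights=train_cfg.class_weights,
            seed=train_cfg.seed + f,
        )
        # last out-of-fold case serves as the tuning case
        train_ids, tune_ids = out_ids[:-1], out_ids[-1:]
        try:
            model, _ = train(
                [by_id[i] for i in train_ids],
                [by_id[i] for i in tune_ids],
                net_cfg, fold_cfg, patch_spec,
            )
        except Exception as exc:  # noqa: BLE001 - annotate which fold failed
            raise RuntimeError(f"training failed for fold {f}") from exc

        for cid in in_ids:
            case = by_id[cid]
            img = normalize_intensity(case.image)
            pred = predict(model, img, patch_spec)
            fp = false_positive_mask(case.truth, pred.argmax_labels, target_class)
            sec = build_secondary_labelmap(case.truth, fp)
            out_cases[cid] = (cid, case.image, sec)
            provenance[cid] = {"fold": f, "fp_voxels": int(fp.sum())}

    ordered = [out_cases[c.case_id] for c in cases]
    return SecondaryDataset(
        cases=ordered,
        target_class=target_class,
        auxiliary_class=cases[0].truth.n_classes,
        folds=folds,
        provenance=provenance,
    )


def predict_refined(refined_model: UNet, vol: ImageVolume, patch_spec: PatchSpec,
                    original_n_classes: int | None = None) -> LabelMap:
    """Predict with a refined ((k+1)-class) model and discard the auxiliary class.

    The auxiliary class competes in the softmax/argmax like any other; voxels
    it wins are then remapped to background, so it can never appear in the
    output.  The returned map carries the *original* class count.
    """
    n_model = refined_model.cfg.n_classes
    if original_n_classes is None:
        original_n_classes = n_model - 1
    if n_model != original_n_classes + 1:
        raise ValueError(
            f"model has {n_model} classes, expected {original_n_classes + 1} "
            "(original classes plus one auxiliary)"
        )
    pred = predict(refined_model, vol, patch_spec)
    labels = pred.argmax_labels.labels.copy()
    labels[labels == n_model - 1] = 0  # discard the auxiliary class
    return LabelMap(labels=labels, spacing_mm=vol.spacing_mm, n_classes=original_n_classes)
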