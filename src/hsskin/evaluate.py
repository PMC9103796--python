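"""Metrics and the slice-half / leave-one-out experiments.

The slice-half experiment trains one classifier on windows sampled from
the left halves of every scene (balanced by over-sampling, then flip-
augmented) and evaluates on the right halves: per-class precision,
recall/sensitivity, F1 and supports, plus per-scene accuracies.

Leave-one-out retrains the model once per scene with that scene's windows
withheld and tests each fold on the held-out scene's right-side windows —
the probe for whether the slice-half split flatters the model.  A scene
whose lesion carries features no other scene has (emulated here by an
atypical spectral template) should score clearly worse under leave-one-out
than under slice-half; per-scene accuracy is the plain fraction correct
over that scene's test windows (no per-lesion majority voting — a voting
summary is available separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .classify import ModelConfig, TrainedModel, build_model, predict_pixels, train
from .pipeline import process_measurement
from .preprocess import (
    SubCubeSet,
    augment_flips,
    balance_oversample,
    extract_windows,
    slice_half_sample,
)

__all__ = [
    "MetricsReport",
    "SliceHalfResult",
    "LooResult",
    "classification_report",
    "confusion_matrices",
    "prepare_scene_sets",
    "run_slice_half_experiment",
    "run_leave_one_out",
    "majority_vote",
]

CLASS_NAMES = ("healthy", "id_nevus", "bcc")
LABELS = (0, 1, 2)


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1/support plus averages and accuracy."""

    precision: np.ndarray  # (3,)
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float

    def as_dict(self) -> dict:
        d = {}
        for i, name in enumerate(CLASS_NAMES):
            d[name] = {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "support": int(self.support[i]),
            }
        d["macro avg"] = {
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
        }
        d["weighted avg"] = {
            "precision": self.weighted_precision,
            "recall": self.weighted_recall,
            "f1": self.weighted_f1,
        }
        d["accuracy"] = self.accuracy
        return d


def _check_labels(y_true, y_pred):
    yt = np.asarray(y_true).ravel()
    yp = np.asarray(y_pred).ravel()
    if yt.size == 0:
        raise ValueError("empty label vectors")
    if yt.size != yp.size:
        raise ValueError(f"label vectors differ in length: {yt.size} vs {yp.size}")
    return yt, yp


def classification_report(y_true, y_pred) -> MetricsReport:
    """Three-class report; weighted recall equals overall accuracy."""
    yt, yp = _check_labels(y_true, y_pred)
    p, r, f1, s = precision_recall_fscore_support(
        yt, yp, labels=list(LABELS), zero_division=0
    )
    mp, mr, mf1, _ = precision_recall_fscore_support(
        yt, yp, labels=list(LABELS), average="macro", zero_division=0
    )
    wp, wr, wf1, _ = precision_recall_fscore_support(
        yt, yp, labels=list(LABELS), average="weighted", zero_division=0
    )
    return MetricsReport(
        precision=p,
        recall=r,
        f1=f1,
        support=s,
        macro_precision=float(mp),
        macro_recall=float(mr),
        macro_f1=float(mf1),
        weighted_precision=float(wp),
        weighted_recall=float(wr),
        weighted_f1=float(wf1),
        accuracy=float((yt == yp).mean()),
    )


def confusion_matrices(y_true, y_pred):
    """Counts and row-normalized 3x3 confusion matrices.

    counts[i, j] = #(true i, predicted j).  Normalized rows sum to 1;
    rows with zero support are returned as NaN (flagged, not silently 0).
    """
    yt, yp = _check_labels(y_true, y_pred)
    counts = _sk_confusion(yt, yp, labels=list(LABELS))
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, np.nan)
    return counts, normalized


@dataclass
class SceneSets:
    """Per-scene windowed train (left) and test (right) sub-cube sets."""

    train: SubCubeSet
    test: SubCubeSet
    stack: object = None  # FeatureStack, kept only when maps are requested


def prepare_scene_sets(
    dataset,
    n_lesion: int = 250,
    n_healthy: int = 100,
    seed: int = 0,
    tv_weight: float = 10.0,
    keep_stacks: bool = False,
    log=None,
) -> list[SceneSets]:
    """Process every scene and window its slice-half samples.

    Runs the full raw pipeline per scene, samples ``n_lesion`` lesion and
    ``n_healthy`` healthy pixel centers on each side of the lesion midline
    and extracts their 30 x 30 x 34 windows.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(dataset))]
    out = []
    for i, ((meas, gt), sc_seed) in enumerate(zip(dataset, seeds)):
        result = process_measurement(meas, tv_weight=tv_weight, log=log)
        left, right = slice_half_sample(
            gt.class_mask,
            gt.healthy_mask,
            n_lesion=n_lesion,
            n_healthy=n_healthy,
            seed=sc_seed,
            scene_id=i,
        )
        out.append(
            SceneSets(
                train=extract_windows(result.stack, left),
                test=extract_windows(result.stack, right),
                stack=result.stack if keep_stacks else None,
            )
        )
    return out


def _concat_sets(sets) -> SubCubeSet:
    return SubCubeSet(
        cubes=np.concatenate([s.cubes for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        scene_ids=np.concatenate([s.scene_ids for s in sets]),
        provenance=np.concatenate([s.provenance for s in sets]),
    )


def _fit_on(train_set: SubCubeSet, config: ModelConfig, seed: int) -> TrainedModel:
    balanced = balance_oversample(train_set, seed=seed)
    augmented = augment_flips(balanced)
    model = build_model(config)
    return train(model, augmented)


@dataclass
class SliceHalfResult:
    report: MetricsReport
    per_scene_accuracy: dict  # scene_id -> fraction correct on right side
    model: TrainedModel
    n_train_windows: int = 0
    n_test_windows: int = 0
    confusion: tuple = ()


def run_slice_half_experiment(
    scene_sets: list[SceneSets],
    model_config: ModelConfig,
    seed: int = 0,
) -> SliceHalfResult:
    """Train on all left-side windows (balanced + augmented), test right."""
    if len(scene_sets) < 2:
        raise ValueError("need at least 2 scenes")
    cfg = replace(model_config, seed=seed)
    train_all = _concat_sets([s.train for s in scene_sets])
    model = _fit_on(train_all, cfg, seed=seed)

    y_true, y_pred, per_scene = [], [], {}
    for i, s in enumerate(scene_sets):
        labels, _ = predict_pixels(model, s.test)
        truth = np.asarray(s.test.labels)
        per_scene[i] = float((labels == truth).mean())
        y_true.append(truth)
        y_pred.append(labels)
    yt = np.concatenate(y_true)
    yp = np.concatenate(y_pred)
    return SliceHalfResult(
        report=classification_report(yt, yp),
        per_scene_accuracy=per_scene,
        model=model,
        n_train_windows=len(train_all),
        n_test_windows=int(yt.size),
        confusion=confusion_matrices(yt, yp),
    )


@dataclass
class LooResult:
    """Per-scene leave-one-out vs. slice-half accuracies."""

    per_scene: list = field(default_factory=list)
    # entries: dict(scene_id, loo_accuracy, slice_half_accuracy, group)
    n_models: int = 0

    def mean_loo(self) -> float:
        return float(np.mean([e["loo_accuracy"] for e in self.per_scene]))

    def mean_slice_half(self) -> float:
        return float(np.mean([e["slice_half_accuracy"] for e in self.per_scene]))


def run_leave_one_out(
    scene_sets: list[SceneSets],
    model_config: ModelConfig,
    seed: int = 0,
    folds=None,
    slice_half: SliceHalfResult | None = None,
    groups: dict | None = None,
) -> LooResult:
    """One model per (requested) scene, trained with that scene held out.

    Every fold asserts via provenance that no training window originates
    from the held-out scene.  Each fold is tested on the held-out scene's
    right-side windows and paired with the slice-half model's accuracy on
    the same windows (computed here if not supplied).  ``groups`` maps
    scene id to a label such as "typical" or "unique".
    """
    if len(scene_sets) < 2:
        raise ValueError("need at least 2 scenes")
    if slice_half is None:
        slice_half = run_slice_half_experiment(scene_sets, model_config, seed=seed)
    fold_ids = list(range(len(scene_sets))) if folds is None else list(folds)

    result = LooResult()
    for fold, held_out in enumerate(fold_ids):
        train_all = _concat_sets(
            [s.train for i, s in enumerate(scene_sets) if i != held_out]
        )
        if np.any(train_all.scene_ids == held_out):
            raise AssertionError(
                f"fold {held_out}: training set contains held-out scene windows"
            )
        cfg = replace(model_config, seed=seed + 1000 + fold)
        model = _fit_on(train_all, cfg, seed=seed + 1000 + fold)
        test = scene_sets[held_out].test
        labels, _ = predict_pixels(model, test)
        result.per_scene.append(
            {
                "scene_id": held_out,
                "loo_accuracy": float((labels == np.asarray(test.labels)).mean()),
                "slice_half_accuracy": slice_half.per_scene_accuracy[held_out],
                "group": (groups or {}).get(held_out, "typical"),
            }
        )
        result.n_models += 1
    return result


def majority_vote(labels: np.ndarray) -> int:
    """Single per-lesion diagnosis by majority over window labels.

    Provided as a clearly separate summary; the reported per-scene
    accuracies never use it.
    """
    counts = np.bincount(np.asarray(labels), minlength=3)
    return int(counts.argmax())
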