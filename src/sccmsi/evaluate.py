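"""Leave-one-group-out validation and the evaluation metrics.

One fold per dataset: the fold's model is trained on every other dataset's
labelled pixels and evaluated on the held-out dataset.  Confusion counts are
pooled over folds and include the Unclassified state (pixels whose best
scaled probability never exceeded 0.5).  Sensitivity, specificity and
accuracy use only tp/fn/tn/fp, with Tumor as the positive class; the variant
counting Unclassified tissue pixels in the accuracy denominator is reported
alongside.  Area-based predictive power compares misclassified region areas
to the total tissue area.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sccmsi.classify import decide, normalize, scaled_probabilities, train_ovr
from sccmsi.msi_io import BACKGROUND, NONTUMOR, TUMOR, UNCLASSIFIED, UNLABELED
from sccmsi.preprocess import FeatureMatrix


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero."""


@dataclass
class ConfusionCounts:
    """Pooled pixel bookkeeping over labelled tissue pixels.

    Tumor is the positive class.  ``unclassified_pos``/``unclassified_neg``
    are labelled tissue pixels that no class claimed with scaled
    probability > 0.5.  Background-labelled pixels are tracked separately;
    they enter none of the three tissue metrics.
    """

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    unclassified_pos: int = 0
    unclassified_neg: int = 0
    background_total: int = 0
    background_correct: int = 0
    background_unclassified: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(**{k: getattr(self, k) + getattr(other, k) for k in asdict(self)})

    @property
    def n_tumor_labelled(self) -> int:
        return self.tp + self.fn + self.unclassified_pos

    @property
    def n_nontumor_labelled(self) -> int:
        return self.tn + self.fp + self.unclassified_neg

    @property
    def n_labelled(self) -> int:
        return self.n_tumor_labelled + self.n_nontumor_labelled + self.background_total


def confusion_counts(predicted: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Count prediction outcomes over labelled pixels.

    ``predicted`` and ``labels`` are parallel class-code arrays (images or
    flat); Unlabeled pixels are ignored.  A Tumor-labelled pixel predicted as
    anything classified but Tumor counts as a false negative; symmetrically
    for Non-tumor and false positives.
    """
    pred = np.asarray(predicted).ravel()
    lab = np.asarray(labels).ravel()
    if pred.shape != lab.shape:
        raise ValueError("predicted and labels must be parallel")
    pos = lab == TUMOR
    neg = lab == NONTUMOR
    bg = lab == BACKGROUND
    unc = pred == UNCLASSIFIED
    return ConfusionCounts(
        tp=int(np.sum(pos & (pred == TUMOR))),
        fn=int(np.sum(pos & ~unc & (pred != TUMOR))),
        tn=int(np.sum(neg & (pred == NONTUMOR))),
        fp=int(np.sum(neg & ~unc & (pred != NONTUMOR))),
        unclassified_pos=int(np.sum(pos & unc)),
        unclassified_neg=int(np.sum(neg & unc)),
        background_total=int(np.sum(bg)),
        background_correct=int(np.sum(bg & (pred == BACKGROUND))),
        background_unclassified=int(np.sum(bg & unc)),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from the confusion counts.

    sensitivity = tp / (tp + fn); specificity = tn / (tn + fp);
    accuracy = (tp + tn) / (tp + fn + tn + fp).  Unclassified pixels appear
    in none of these denominators.
    """
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no classified Tumor-labelled pixels")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no classified Non-tumor-labelled pixels")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    acc = (counts.tp + counts.tn) / (counts.tp + counts.fn + counts.tn + counts.fp)
    return sens, spec, acc


def accuracy_including_unclassified(counts: ConfusionCounts) -> float:
    """Correctly classified tissue pixels over all labelled tissue pixels
    (Unclassified pixels count against the model)."""
    denom = counts.n_tumor_labelled + counts.n_nontumor_labelled
    if denom == 0:
        raise UndefinedMetricError("accuracy undefined: no labelled tissue pixels")
    return (counts.tp + counts.tn) / denom


@dataclass
class LabelledDataset:
    """One cohort member: its feature matrix and transferred labels."""

    features: FeatureMatrix
    labels: np.ndarray  # class codes aligned with feature rows
    grid_shape: tuple[int, int] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).ravel()
        if len(self.labels) != self.features.n_pixels:
            raise ValueError(f"dataset {self.name!r}: labels not aligned with features")


@dataclass
class EvalReport:
    """Pooled LOGO results plus per-fold counts for inspection."""

    pooled: ConfusionCounts
    per_fold: list[ConfusionCounts] = field(default_factory=list)
    fold_names: list[str] = field(default_factory=list)
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    accuracy: float = float("nan")
    accuracy_incl_unclassified: float = float("nan")
    # per-fold classifiers, kept for inspection/auditing; not serialized
    fold_classifiers: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "pooled": asdict(self.pooled),
            "per_fold": {n: asdict(c) for n, c in zip(self.fold_names, self.per_fold)},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "accuracy_incl_unclassified": self.accuracy_incl_unclassified,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    def confusion_table(self) -> pd.DataFrame:
        """Pooled confusion matrix with the Unclassified column."""
        c = self.pooled
        return pd.DataFrame(
            {
                "predicted Tumor": [c.tp, c.fp],
                "predicted Non-tumor": [c.fn, c.tn],
                "Unclassified": [c.unclassified_pos, c.unclassified_neg],
            },
            index=["labelled Tumor", "labelled Non-tumor"],
        )


def logo_cv(
    cohort: list[LabelledDataset],
    l2_lambda: float = 1e-2,
    threshold: float = 0.5,
) -> EvalReport:
    """Leave-one-group-out cross-validation at the dataset level.

    For each of the n datasets, a model is trained on the labelled pixels of
    the other n-1 and evaluated on the held-out dataset's labelled pixels;
    counts are pooled across folds.  Deterministic given the cohort.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-group-out needs at least 2 datasets")
    pooled = ConfusionCounts()
    per_fold: list[ConfusionCounts] = []
    names: list[str] = []
    fold_classifiers = []
    for i, test in enumerate(cohort):
        train = [d for j, d in enumerate(cohort) if j != i]
        x_train = np.vstack([d.features.values for d in train])
        y_train = np.concatenate([d.labels for d in train])
        fold_name = test.name or f"fold{i}"
        try:
            clf = train_ovr(x_train, y_train, feature_mzs=train[0].features.mzs, l2_lambda=l2_lambda, threshold=threshold)
        except ValueError as err:
            raise ValueError(f"fold {fold_name!r}: {err}") from err
        labelled = test.labels != UNLABELED
        x_test, _ = normalize(test.features.values[labelled])
        pred = decide(scaled_probabilities(clf, x_test), threshold)
        counts = confusion_counts(pred, test.labels[labelled])
        per_fold.append(counts)
        names.append(fold_name)
        fold_classifiers.append(clf)
        pooled = pooled + counts
    sens, spec, acc = metrics(pooled)
    return EvalReport(
        pooled=pooled,
        per_fold=per_fold,
        fold_names=names,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        accuracy_incl_unclassified=accuracy_including_unclassified(pooled),
        fold_classifiers=fold_classifiers,
    )


def area_based_power(
    pred,
    fp_region_mask: np.ndarray,
    fn_region_mask: np.ndarray,
    tissue_mask: np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """Area-based predictive power from externally annotated error regions.

    power = 1 - (area(FP regions) + area(FN regions)) / area(tissue), with
    areas in pixels.  Returns the power and a relative-area confusion table
    (percent of the tissue area per category).
    """
    tissue = np.asarray(tissue_mask, bool)
    fp = np.asarray(fp_region_mask, bool) & tissue
    fn = np.asarray(fn_region_mask, bool) & tissue
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise UndefinedMetricError("predictive power undefined: empty tissue mask")
    power = 1.0 - (int(fp.sum()) + int(fn.sum())) / n_tissue
    class_image = pred.class_image if hasattr(pred, "class_image") else np.asarray(pred)
    pred_tumor = (class_image == TUMOR) & tissue
    tp_area = int((pred_tumor & ~fp).sum())
    tn_area = n_tissue - tp_area - int(fp.sum()) - int(fn.sum())
    table = pd.DataFrame(
        {
            "area_px": [tp_area, int(fp.sum()), int(fn.sum()), tn_area],
            "percent_of_tissue": [
                100.0 * tp_area / n_tissue,
                100.0 * fp.sum() / n_tissue,
                100.0 * fn.sum() / n_tissue,
                100.0 * tn_area / n_tissue,
            ],
        },
        index=["true positive", "false positive", "false negative", "true negative"],
    )
    return power, table
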