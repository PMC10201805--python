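"""Confusion-matrix metrics and the repeated-split experiment runner.

Metrics follow the standard binary definitions with positive class 1:

    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)

A zero denominator yields an explicit ``None`` marker, never a silent 0.
`run_case` repeats a stratified 3:1 split, fitting feature selection and
the CNN on the training fold only, and reports per-repeat and mean
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .classify import CNNClassifier, CNNSpec
from .io import FeatureMatrix
from .pipeline import OOBPermutationRFE, SubbandEntropyFeaturizer, featurize_segments
from .segments import EEGSegment


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Binary confusion counts, positive class = 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not labels <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(labels)}")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class MetricsReport:
    """The four ratio metrics plus the counts they were computed from."""

    counts: ConfusionCounts
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    case_id: str = ""

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "MetricsReport":
        d = dict(d)
        d["counts"] = ConfusionCounts(**d["counts"])
        return cls(**d)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts, case_id: str = "") -> MetricsReport:
    """Accuracy/sensitivity/specificity/precision from confusion counts."""
    if c.total == 0:
        raise ValueError("metrics of all-zero confusion counts")
    return MetricsReport(
        counts=c,
        accuracy=_ratio(c.TP + c.TN, c.total),
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.TN + c.FP),
        precision=_ratio(c.TP, c.TP + c.FP),
        case_id=case_id,
    )


@dataclass
class CaseReport:
    """Aggregate over repeated stratified splits of one classification case."""

    case_id: str
    n_repeats: int
    repeats: List[MetricsReport]
    mean_accuracy: float
    sd_accuracy: float
    mean_sensitivity: Optional[float]
    mean_specificity: Optional[float]
    mean_precision: Optional[float]
    selected_features: List[List[str]] = field(default_factory=list)

    def to_dict(self) -> Dict:
        d = {
            "case_id": self.case_id,
            "n_repeats": self.n_repeats,
            "repeats": [r.to_dict() for r in self.repeats],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "mean_precision": self.mean_precision,
            "selected_features": self.selected_features,
        }
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "CaseReport":
        d = dict(d)
        d["repeats"] = [MetricsReport.from_dict(r) for r in d["repeats"]]
        return cls(**d)


def _mean_defined(values: Sequence[Optional[float]]) -> Optional[float]:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def evaluate_feature_matrix(
    fm: FeatureMatrix,
    case_id: str = "",
    n_repeats: int = 10,
    seed: int = 0,
    k_final: int = 10,
    n_trees: int = 200,
    epochs: int = 100,
    selection_scope: str = "fold",
) -> CaseReport:
    """Repeated stratified 3:1 splits over a precomputed feature matrix.

    Each repeat draws a fresh seeded split; feature selection and CNN
    training see only the training fold (``selection_scope="fold"``, the
    strict default).  ``selection_scope="global"`` selects once on all
    rows before splitting — a laxer protocol some studies use; it is
    provided for comparison and labeled in the report's feature lists.
    """
    if selection_scope not in ("fold", "global"):
        raise ValueError(f"unknown selection_scope {selection_scope!r}")
    y = np.asarray(fm.labels)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("case labels must be binary 0/1")

    global_selected: Optional[List[str]] = None
    if selection_scope == "global":
        sel = OOBPermutationRFE(
            k_final=k_final, n_trees=n_trees, seed=seed, feature_names=fm.feature_names
        ).fit(fm.values, y)
        global_selected = sel.selected_names_

    reports: List[MetricsReport] = []
    selected_per_repeat: List[List[str]] = []
    for rep in range(n_repeats):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        idx = np.arange(fm.n_segments)
        train_idx, test_idx = train_test_split(
            idx, test_size=0.25, stratify=y, random_state=rep_seed
        )
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"repeat {rep}: a fold contains a single class")

        if global_selected is not None:
            selected = global_selected
        else:
            sel = OOBPermutationRFE(
                k_final=k_final,
                n_trees=n_trees,
                seed=rep_seed,
                feature_names=fm.feature_names,
            ).fit(fm.values[train_idx], y[train_idx])
            selected = sel.selected_names_
        selected_per_repeat.append(list(selected))

        sub = fm.restrict(selected)
        clf = CNNClassifier(
            spec=CNNSpec(input_len=k_final, n_classes=2),
            epochs=epochs,
            seed=rep_seed,
        )
        clf.fit(sub.values[train_idx], y[train_idx])
        y_pred = clf.predict(sub.values[test_idx])
        reports.append(metrics(confusion(y[test_idx], y_pred), case_id=case_id))

    accs = [r.accuracy for r in reports]
    return CaseReport(
        case_id=case_id,
        n_repeats=n_repeats,
        repeats=reports,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs)),
        mean_sensitivity=_mean_defined([r.sensitivity for r in reports]),
        mean_specificity=_mean_defined([r.specificity for r in reports]),
        mean_precision=_mean_defined([r.precision for r in reports]),
        selected_features=selected_per_repeat,
    )


def run_case(
    segments: Sequence[EEGSegment],
    case_id: str = "",
    featurizer: Optional[SubbandEntropyFeaturizer] = None,
    **kwargs,
) -> CaseReport:
    """End-to-end: featurize labeled segments once, then repeated splits.

    Featurization is per-segment and stateless, so computing it before
    the split leaks nothing; all fitted stages (selection, CNN) run
    inside each training fold via :func:`evaluate_feature_matrix`.
    """
    if not segments:
        raise ValueError("no segments given")
    if any(s.label is None for s in segments):
        raise ValueError("all segments must be labeled")
    fm = featurize_segments(segments, featurizer=featurizer)
    return evaluate_feature_matrix(fm, case_id=case_id, **kwargs)
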