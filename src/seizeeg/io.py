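"""Readers and writers for EEG segment files and feature tables.

Two on-disk dialects are supported: plain-ASCII records with one sample
value per line (the Bonn distribution format, nominally 4097 samples at
173.61 Hz) and MATLAB v5 MAT files each holding a single 1024-sample
vector at 200 Hz (the New Delhi distribution format).  Case definitions
(which sets form the negative and positive class of each binary task)
ship as packaged YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import yaml

from .segments import EEGSegment

BONN_FS = 173.61
DELHI_FS = 200.0

__all__ = [
    "BONN_FS",
    "DELHI_FS",
    "CaseSpec",
    "FeatureMatrix",
    "load_case_specs",
    "read_bonn_segment",
    "read_delhi_segment",
    "assemble_case",
    "read_feature_table",
    "write_feature_table",
]


class SegmentParseError(ValueError):
    """A segment file exists but its contents do not parse."""


@dataclass(frozen=True)
class CaseSpec:
    """One binary classification task: which sets are labeled 0 and 1."""

    case_id: str
    negative_sets: tuple
    positive_sets: tuple
    task: str = ""
    dataset: str = ""

    def __post_init__(self) -> None:
        pos, neg = set(self.positive_sets), set(self.negative_sets)
        if not pos or not neg:
            raise ValueError(f"{self.case_id}: both label groups must be non-empty")
        if pos & neg:
            raise ValueError(f"{self.case_id}: sets {pos & neg} appear in both label groups")

    @property
    def all_sets(self) -> tuple:
        """Referenced sets in listing order: negatives first, then positives."""
        return tuple(self.negative_sets) + tuple(self.positive_sets)


def load_case_specs() -> Dict[str, CaseSpec]:
    """Load the 18 packaged case definitions, keyed by case id."""
    text = resources.files("seizeeg").joinpath("data/cases.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        cid: CaseSpec(
            case_id=cid,
            negative_sets=tuple(d["negative_sets"]),
            positive_sets=tuple(d["positive_sets"]),
            task=d.get("task", ""),
            dataset=d.get("dataset", ""),
        )
        for cid, d in raw.items()
    }


def read_bonn_segment(path, fs: float = BONN_FS) -> EEGSegment:
    """Read one plain-ASCII segment (one sample value per line).

    Blank lines are ignored; integer, decimal and scientific notation are
    accepted.  Segment length is not enforced here — the nominal 4097 is a
    property of the public distribution, not of the format.
    """
    path = Path(path)
    values: List[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise SegmentParseError(
                    f"{path}: line {lineno} is not a number: {text!r}"
                ) from None
    if len(values) < 2:
        raise SegmentParseError(f"{path}: fewer than 2 sample values")
    return EEGSegment(np.asarray(values), fs=fs, source_id=path.stem)


def read_delhi_segment(path, fs: float = DELHI_FS) -> EEGSegment:
    """Read one MAT-file segment holding exactly one numeric vector.

    The vector is flattened regardless of row/column orientation.  A file
    with zero or several numeric arrays is rejected rather than guessed at.
    """
    path = Path(path)
    mat = sio.loadmat(str(path))
    numeric = {
        k: v
        for k, v in mat.items()
        if not k.startswith("__") and isinstance(v, np.ndarray) and np.issubdtype(v.dtype, np.number)
    }
    if len(numeric) != 1:
        raise SegmentParseError(
            f"{path}: expected exactly one numeric variable, found "
            f"{sorted(numeric) or 'none'}"
        )
    (samples,) = numeric.values()
    return EEGSegment(np.asarray(samples, dtype=float).ravel(), fs=fs, source_id=path.stem)


def assemble_case(
    case_id: str, segments_by_set: Mapping[str, Sequence[EEGSegment]]
) -> List[EEGSegment]:
    """Label and concatenate the sets referenced by one case definition.

    Ordering is deterministic: sets in the case's listing order (negatives
    then positives), segments within a set by source_id — so downstream
    seeded splits are reproducible from the seed alone.
    """
    specs = load_case_specs()
    if case_id not in specs:
        raise KeyError(f"unknown case id {case_id!r}; known: case1..case{len(specs)}")
    spec = specs[case_id]
    missing = [s for s in spec.all_sets if s not in segments_by_set]
    if missing:
        raise KeyError(f"{case_id}: missing referenced set(s) {missing}")
    out: List[EEGSegment] = []
    for set_name in spec.all_sets:
        label = 1 if set_name in spec.positive_sets else 0
        members = sorted(segments_by_set[set_name], key=lambda s: s.source_id)
        out.extend(seg.with_label(label) for seg in members)
    return out


@dataclass
class FeatureMatrix:
    """Segments-by-features table with an aligned label vector."""

    feature_names: List[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (segments x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must equal row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def restrict(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order (used after feature selection)."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(list(names), self.values[:, idx], self.labels)


def write_feature_table(fm: FeatureMatrix, path) -> None:
    """Write a feature matrix as RFC-4180 CSV, header = names + 'label'."""
    fm.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise SegmentParseError(f"{path}: feature table has no 'label' column")
    labels = df.pop("label").to_numpy()
    return FeatureMatrix(list(df.columns), df.to_numpy(dtype=float), labels)
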