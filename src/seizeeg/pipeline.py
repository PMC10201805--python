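"""Sklearn-style estimators tying the stages together.

`SubbandEntropyFeaturizer` is a stateless transformer: segment in, the
20-element subband feature vector out.  `OOBPermutationRFE` is a fitted
selector exposing ``support_`` like sklearn's RFE but driven by the
out-of-bag permutation importance.  Both compose with sklearn pipelines;
the module-level helpers return the richer domain containers.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, EntropyParams, extract_features
from .io import BONN_FS, FeatureMatrix
from .segments import EEGSegment
from .selection import recursive_select
from .wavelets import dwt_decompose, preprocess


class SubbandEntropyFeaturizer(BaseEstimator, TransformerMixin):
    """Band-pass + denoise + 4-level DWT + 20 subband features per row.

    Accepts either a sequence of :class:`EEGSegment` or a 2-D array of raw
    sample rows (then ``fs`` applies to every row).  Stateless: ``fit`` is
    a no-op, present for pipeline compatibility.
    """

    def __init__(
        self,
        fs: float = BONN_FS,
        low: float = 0.01,
        high: Optional[float] = None,
        order: int = 4,
        denoise: bool = True,
        wavelet: str = "db4",
        levels: int = 4,
        representation: str = "reconstructed",
        m: int = 2,
        r: float = 0.2,
        fuzzy_n: float = 2.0,
    ):
        self.fs = fs
        self.low = low
        self.high = high
        self.order = order
        self.denoise = denoise
        self.wavelet = wavelet
        self.levels = levels
        self.representation = representation
        self.m = m
        self.r = r
        self.fuzzy_n = fuzzy_n

    def fit(self, X=None, y=None) -> "SubbandEntropyFeaturizer":
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def _as_segments(self, X) -> List[EEGSegment]:
        if len(X) and isinstance(X[0], EEGSegment):
            return list(X)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a list of segments or a 2-D sample array")
        return [EEGSegment(row, fs=self.fs, source_id=f"row{i}") for i, row in enumerate(arr)]

    def transform_segment(self, seg: EEGSegment) -> dict:
        """Feature dict for a single segment (the per-row worker)."""
        conditioned = preprocess(
            seg,
            low=self.low,
            high=self.high,
            order=self.order,
            denoise=self.denoise,
            wavelet=self.wavelet,
            levels=self.levels,
        )
        subbands = dwt_decompose(
            conditioned,
            wavelet=self.wavelet,
            levels=self.levels,
            representation=self.representation,
        )
        params = EntropyParams(m=self.m, r=self.r, n=self.fuzzy_n)
        return extract_features(subbands, params)

    def transform(self, X) -> np.ndarray:
        segs = self._as_segments(X)
        rows = [self.transform_segment(s) for s in segs]
        return np.array([[row[name] for name in FEATURE_NAMES] for row in rows])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


def featurize_segments(
    segments: Sequence[EEGSegment], featurizer: Optional[SubbandEntropyFeaturizer] = None
) -> FeatureMatrix:
    """Feature matrix + aligned labels for a labeled segment collection."""
    f = featurizer or SubbandEntropyFeaturizer()
    values = f.fit().transform(segments)
    labels = np.array([-1 if s.label is None else s.label for s in segments])
    return FeatureMatrix(list(FEATURE_NAMES), values, labels)


class OOBPermutationRFE(SelectorMixin, BaseEstimator):
    """Recursive feature elimination ranked by OOB permutation importance.

    Fits K bootstrap CART trees per round, scores each surviving feature
    by its mean out-of-bag accuracy drop under within-OOB permutation, and
    drops the least important feature until ``k_final`` remain.
    """

    def __init__(
        self,
        k_final: int = 10,
        n_trees: int = 200,
        seed: int = 0,
        feature_names: Optional[Sequence[str]] = None,
    ):
        self.k_final = k_final
        self.n_trees = n_trees
        self.seed = seed
        self.feature_names = feature_names

    def fit(self, X, y) -> "OOBPermutationRFE":
        X = np.asarray(X, dtype=float)
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
        fm = FeatureMatrix(names, X, np.asarray(y))
        selected, trace = recursive_select(
            fm, k_final=self.k_final, n_trees=self.n_trees, seed=self.seed
        )
        self.selected_names_ = selected
        self.trace_ = trace
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.array([n in set(selected) for n in names])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
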