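"""Subband features: standard deviation and three regularity entropies.

Twenty features per segment: {STD, SampEn, ApEn, FuzzyEn} on each of the
five DWT subbands D1-D4, A4.  Conventions:

* **ApEn(m, r)** (Pincus): Phi^m - Phi^{m+1} with
  Phi^m = mean_i ln C_i^m(r), where C_i^m is the *fraction* of templates
  within Chebyshev distance r of template i, self-match included;
  N-m+1 templates at dimension m.
* **SampEn(m, r)** (Richman & Moorman): -ln(A/B) where B and A count
  matched template *pairs* at dimensions m and m+1, self-matches excluded
  and N-m templates used at both dimensions (so pattern counts are
  comparable).  A zero count makes the statistic undefined and raises
  :class:`SampEnUndefined`; callers may substitute the conventional cap
  ln(N-m) + ln(N-m-1) - ln 2 (the value for a single matched pair).
* **FuzzyEn(m, r, n)** (Chen): templates are baseline-removed (each minus
  its own mean); hard matching is replaced by the fuzzy membership
  mu(d) = exp(-(d/r)^n); result = ln phi^m - ln phi^{m+1} with phi the
  mean pairwise membership excluding self-pairs, N-m templates at both
  dimensions.

All three use the Chebyshev (max-norm) distance, and r is resolved per
analysed signal as ``r * SD`` when relative (the default, r = 0.2).
The implementations here are vectorised with chunked pairwise distance
blocks; :mod:`seizeeg.oracles` keeps naive O(N^2) loops as the arbiter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .wavelets import SubbandSet

#: Table-order feature names: feature type varies slowest, subband fastest.
SUBBAND_ORDER = ("D1", "D2", "D3", "D4", "A4")
FEATURE_TYPES = ("STD", "SampEn", "ApEn", "FuzzyEn")
FEATURE_NAMES = tuple(f"{sb} {ft}" for ft in FEATURE_TYPES for sb in SUBBAND_ORDER)



class SampEnUndefined(ValueError):
    """SampEn has no matched pairs at one of the two dimensions."""


@dataclass(frozen=True)
class EntropyParams:
    """Shared entropy policy: embedding dimension m, tolerance r, fuzzy exponent n.

    With ``relative=True`` (default) r is a fraction of the analysed
    signal's SD; otherwise it is in signal units.
    """

    m: int = 2
    r: float = 0.2
    n: float = 2.0
    relative: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def resolve_r(self, x: np.ndarray) -> float:
        return self.r * float(np.std(x)) if self.relative else self.r


def std(x) -> float:
    """Population standard deviation (divisor N)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("std of empty sequence")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def _check_length(x: np.ndarray, m: int) -> None:
    if x.size <= m + 1:
        raise ValueError(f"sequence of length {x.size} too short for m={m}")


def _embed(x: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    return sliding_window_view(x, m)[:n_templates]


def _cheb_distances(x: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    """Pairwise Chebyshev template distances via lag-wise max accumulation.

    d[i, j] = max_{t < m} |x[i+t] - x[j+t]|, computed as a running maximum
    over the m shifted scalar-difference matrices — one O(T^2) pass per
    lag instead of materialising the (T, T, m) window tensor.
    """
    d = np.abs(x[:n_templates, None] - x[None, :n_templates])
    for t in range(1, m):
        shifted = x[t : t + n_templates]
        np.maximum(d, np.abs(shifted[:, None] - shifted[None, :]), out=d)
    return d


def apen(x, p: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy; lower values mean a more regular signal."""
    x = np.asarray(x, dtype=float)
    _check_length(x, p.m)
    r = p.resolve_r(x)
    if not r > 0:
        raise ValueError("resolved tolerance r must be positive")

    def phi(m: int) -> float:
        n_templates = x.size - m + 1
        counts = (_cheb_distances(x, m, n_templates) <= r).sum(axis=1)
        return float(np.mean(np.log(counts / n_templates)))

    return phi(p.m) - phi(p.m + 1)


def _pair_counts(x: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Matched unordered template pairs (i<j) at dimension m."""
    total = int((_cheb_distances(x, m, n_templates) <= r).sum())
    return (total - n_templates) // 2  # drop self-matches, halve ordered pairs


def sampen(x, p: EntropyParams = EntropyParams()) -> float:
    """Sample entropy -ln(A/B); raises :class:`SampEnUndefined` when A or B is 0."""
    x = np.asarray(x, dtype=float)
    _check_length(x, p.m)
    r = p.resolve_r(x)
    if not r > 0:
        raise ValueError("resolved tolerance r must be positive")
    n_templates = x.size - p.m
    B = _pair_counts(x, p.m, r, n_templates)
    A = _pair_counts(x, p.m + 1, r, n_templates)
    if A == 0 or B == 0:
        raise SampEnUndefined(
            f"no matched pairs at dimension {'m+1' if A == 0 else 'm'} "
            f"(A={A}, B={B}); entropy undefined"
        )
    return float(-np.log(A / B))


def sampen_cap(n_samples: int, m: int) -> float:
    """Conventional upper bound substituted for undefined SampEn values."""
    return float(np.log(n_samples - m) + np.log(n_samples - m - 1) - np.log(2.0))


def _fuzzy_phi(x: np.ndarray, m: int, r: float, n: float, n_templates: int) -> float:
    emb = _embed(x, m, n_templates)
    emb = emb - emb.mean(axis=1, keepdims=True)  # baseline removal
    d = np.abs(emb[:, None, 0] - emb[None, :, 0])
    for t in range(1, m):
        np.maximum(d, np.abs(emb[:, None, t] - emb[None, :, t]), out=d)
    total = float(np.exp(-((d / r) ** n)).sum())
    total -= n_templates  # self-pairs contribute exp(0) each
    return total / (n_templates * (n_templates - 1))


def fuzzyen(x, p: EntropyParams = EntropyParams()) -> float:
    """Fuzzy entropy ln phi^m - ln phi^{m+1}; always finite for r > 0."""
    x = np.asarray(x, dtype=float)
    _check_length(x, p.m)
    r = p.resolve_r(x)
    if not r > 0:
        # a constant signal has zero SD; every distance is 0 so the entropy is 0
        if np.ptp(x) == 0:
            return 0.0
        raise ValueError("resolved tolerance r must be positive")
    n_templates = x.size - p.m
    phi_m = _fuzzy_phi(x, p.m, r, p.n, n_templates)
    phi_m1 = _fuzzy_phi(x, p.m + 1, r, p.n, n_templates)
    return float(np.log(phi_m) - np.log(phi_m1))


def _entropy_or_zero(func, x, p):
    """Entropies of an (effectively) constant signal are 0 by convention.

    Subbands of a constant input carry only floating-point dust; treating
    them as constant avoids reporting the entropy of rounding noise.
    """
    if p.relative and np.std(x) <= 1e-12 * (1.0 + np.abs(np.mean(x))):
        return 0.0
    return func(x, p)


def extract_features(
    sb: SubbandSet,
    p: EntropyParams = EntropyParams(),
    cap_undefined_sampen: bool = True,
) -> Dict[str, float]:
    """The 20-feature vector for one decomposed segment, in table order.

    r is resolved per subband from that subband's own SD (each subband has
    its own amplitude scale).  Undefined SampEn values are mapped to the
    conventional cap when ``cap_undefined_sampen`` (default) rather than
    dropping the segment.
    """
    missing = [n for n in SUBBAND_ORDER if n not in sb.subbands]
    if missing:
        raise ValueError(f"SubbandSet lacks subbands {missing}")
    out: Dict[str, float] = {}
    for name in FEATURE_NAMES:
        sb_name, ft = name.split(" ")
        x = sb.subbands[sb_name]
        if ft == "STD":
            out[name] = std(x)
        elif ft == "ApEn":
            out[name] = _entropy_or_zero(apen, x, p)
        elif ft == "SampEn":
            try:
                out[name] = _entropy_or_zero(sampen, x, p)
            except SampEnUndefined:
                if not cap_undefined_sampen:
                    raise
                out[name] = sampen_cap(len(x), p.m)
        else:
            out[name] = _entropy_or_zero(fuzzyen, x, p)
    return out
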