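"""Band-pass filtering, wavelet denoising, and 4-level DWT subband analysis.

A segment is decomposed with the db4 wavelet into four detail subbands
D1-D4 and the deepest approximation A4.  Each level halves the band, so
for a sampling rate fs the subbands occupy (half-open intervals)
D1 = [fs/4, fs/2), D2 = [fs/8, fs/4), D3 = [fs/16, fs/8),
D4 = [fs/32, fs/16), A4 = [0, fs/32).  At the 173.61 Hz rate of the
classic single-channel epilepsy recordings these are the familiar
43.4-86.8, 21.7-43.4, 10.8-21.7, 5.4-10.8 and 0-5.4 Hz bands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Literal, Tuple

import numpy as np
import pywt
import scipy.signal

from .segments import EEGSegment

SUBBAND_NAMES = ("D1", "D2", "D3", "D4", "A4")

Representation = Literal["coefficients", "reconstructed"]


@dataclass(frozen=True)
class SubbandSet:
    """The named signals derived from one segment by an L-level DWT.

    For the canonical 4-level decomposition the names are exactly
    D1, D2, D3, D4, A4.
    """

    subbands: Dict[str, np.ndarray]
    fs: float
    representation: Representation

    def __post_init__(self) -> None:
        levels = sum(1 for n in self.subbands if n.startswith("D"))
        expected = {f"D{k}" for k in range(1, levels + 1)} | {f"A{levels}"}
        if levels < 1 or set(self.subbands) != expected:
            raise ValueError(
                f"subband names must be D1..D{levels} plus A{levels}, "
                f"got {sorted(self.subbands)}"
            )
        if any(len(v) == 0 for v in self.subbands.values()):
            raise ValueError("empty subband sequence")
        if self.representation not in ("coefficients", "reconstructed"):
            raise ValueError(f"unknown representation {self.representation!r}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.subbands[name]


def band_edges(fs: float, levels: int = 4) -> Dict[str, Tuple[float, float]]:
    """Dyadic subband frequency intervals [low, high) for an L-level DWT.

    D1 = [fs/4, fs/2); each deeper detail halves both edges; the final
    approximation covers [0, fs/2^(L+1)).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    edges = {}
    for k in range(1, levels + 1):
        edges[f"D{k}"] = (fs / 2 ** (k + 1), fs / 2**k)
    edges[f"A{levels}"] = (0.0, fs / 2 ** (levels + 1))
    return edges


def truncate_hz(x: float, decimals: int = 1) -> float:
    """Truncate a frequency to the given number of decimals (display form).

    Published subband tables for the 173.61 Hz rate print e.g. 10.8 Hz for
    fs/16 = 10.850625 — truncation, not round-half-even.
    """
    factor = 10.0**decimals
    return math.floor(x * factor) / factor


def bandpass(seg: EEGSegment, low: float, high: float, order: int = 4) -> EEGSegment:
    """Zero-phase Butterworth band-pass (forward-backward, order doubled in effect).

    When the upper edge reaches the Nyquist frequency (high >= 0.99 * fs/2)
    a band-pass design is degenerate; the filter degrades gracefully to a
    high-pass at `low`, which preserves the intent of "full band minus
    slow drift" and is logged as a warning.

    The signal is linearly detrended first and the forward-backward pass
    uses minimal-transient (Gust) initial conditions: with sub-0.1 Hz
    cutoffs the filter's impulse response outlasts a typical segment, and
    reflection padding would otherwise inject boundary transients of the
    same order as the signal itself.
    """
    if not 0 <= low < high:
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    if order < 1:
        raise ValueError("order must be >= 1")
    nyq = seg.fs / 2.0
    if low >= nyq:
        raise ValueError(f"low={low} Hz is at or above Nyquist ({nyq} Hz)")
    if high >= 0.99 * nyq:
        if low <= 0:
            return seg.with_samples(seg.samples.copy())  # all-pass request
        warnings.warn(
            f"upper edge {high} Hz is at/near Nyquist ({nyq} Hz); "
            f"using high-pass at {low} Hz instead",
            stacklevel=2,
        )
        b, a = scipy.signal.butter(order, low, btype="highpass", fs=seg.fs)
    elif low <= 0:
        b, a = scipy.signal.butter(order, high, btype="lowpass", fs=seg.fs)
    else:
        b, a = scipy.signal.butter(order, [low, high], btype="bandpass", fs=seg.fs)
    x = scipy.signal.detrend(seg.samples, type="linear") if low > 0 else seg.samples
    filtered = scipy.signal.filtfilt(b, a, x, method="gust")
    return seg.with_samples(filtered)


def wavelet_denoise(
    seg: EEGSegment, wavelet: str = "db4", levels: int = 4, mode: str = "symmetric"
) -> EEGSegment:
    """Wavelet-shrinkage denoising with the universal threshold.

    Multilevel DWT, then soft thresholding of every detail level at
    sigma * sqrt(2 ln N) where sigma is the robust noise estimate
    median(|D1|) / 0.6745 from the finest detail coefficients, then
    reconstruction.  A noise-free input yields near-zero thresholds and is
    passed through essentially unchanged.
    """
    x = seg.samples
    if len(x) < 2**levels:
        raise ValueError(f"segment of {len(x)} samples too short for {levels} levels")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode=mode)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    threshold = sigma * np.sqrt(2.0 * np.log(len(x)))
    if threshold > 0:
        denoised = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    else:  # noise estimate is zero: nothing to shrink
        denoised = coeffs
    rec = pywt.waverec(denoised, wavelet, mode=mode)
    return seg.with_samples(rec[: len(x)])


def dwt_decompose(
    seg: EEGSegment,
    wavelet: str = "db4",
    levels: int = 4,
    representation: Representation = "reconstructed",
    mode: str = "periodization",
) -> SubbandSet:
    """Decompose a segment into detail subbands D1..D{levels} and A{levels}.

    ``coefficients`` mode returns the raw filter-bank coefficient
    sequences; ``reconstructed`` mode inverts the transform with all other
    subbands zeroed, giving five full-length time-domain signals whose
    elementwise sum equals the input (linearity of the inverse transform).
    The default periodization boundary keeps the db4 filter bank
    orthonormal, so squared coefficient norms partition the signal energy.
    """
    x = seg.samples
    if len(x) < 2**levels:
        raise ValueError(f"segment of {len(x)} samples too short for {levels} levels")
    if representation not in ("coefficients", "reconstructed"):
        raise ValueError(f"unknown representation {representation!r}")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode=mode)
    # wavedec order: [A_L, D_L, D_{L-1}, ..., D_1]
    names = [f"A{levels}"] + [f"D{k}" for k in range(levels, 0, -1)]
    if representation == "coefficients":
        subbands = {n: np.asarray(c) for n, c in zip(names, coeffs)}
    else:
        subbands = {}
        for i, n in enumerate(names):
            isolated = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
            subbands[n] = pywt.waverec(isolated, wavelet, mode=mode)[: len(x)]
    return SubbandSet(subbands, fs=seg.fs, representation=representation)


def preprocess(
    seg: EEGSegment,
    low: float = 0.01,
    high: float | None = None,
    order: int = 4,
    denoise: bool = True,
    wavelet: str = "db4",
    levels: int = 4,
) -> EEGSegment:
    """Standard conditioning chain: Butterworth band-pass then db4 denoising.

    The default band is 0.01 Hz up to the Nyquist frequency, i.e. drift
    removal over the full recorded band.
    """
    if high is None:
        high = seg.fs / 2.0
    out = bandpass(seg, low, high, order=order)
    if denoise:
        out = wavelet_denoise(out, wavelet=wavelet, levels=levels)
    return out
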