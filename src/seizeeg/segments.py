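"""Core container for single-channel EEG recording windows."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

Label = Union[int, str, None]


@dataclass(frozen=True)
class EEGSegment:
    """One single-channel EEG window.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in µV, in recording order.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : int, str or None
        Optional class tag (0/1 or a named state such as ``"ictal"``).
    source_id : str
        Opaque identifier of the record (file stem, synth seed tag, ...).
    """

    samples: np.ndarray
    fs: float
    label: Label = None
    source_id: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", arr)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if arr.size < 2:
            raise ValueError(f"segment needs at least 2 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("segment contains non-finite samples")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Window length in seconds."""
        return len(self) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EEGSegment":
        """Copy of this segment with new sample values (same fs/label/id)."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def with_label(self, label: Label) -> "EEGSegment":
        return replace(self, label=label)
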