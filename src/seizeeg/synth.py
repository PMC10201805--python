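"""Synthetic EEG-like segment generator.

Emulates the qualitative contrasts between seizure and non-seizure
recordings: ictal-like traces carry a high-amplitude ~3 Hz spike-and-wave
oscillation (the classic absence-seizure signature) with reduced-variance
background, interictal-like traces show sparse biphasic spikes over
broadband background, and background traces are band-limited 1/f^beta
Gaussian noise.  Everything is deterministic from (config, seed), with a
hierarchical seed scheme so datasets can be extended without reshuffling
existing segments.  Fixture trees can be written in either on-disk dialect
understood by :mod:`seizeeg.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import scipy.io as sio
import scipy.signal

from .io import BONN_FS, DELHI_FS
from .segments import EEGSegment

CLASS_NAMES = ("background", "interictal_like", "ictal_like")

#: per-class default amplitude scale; the ictal/background ratio of 4 keeps
#: the classes well separated (the seizure trace visibly dominates), matching
#: the qualitative amplitude contrast between seizure and background EEG.
DEFAULT_AMPLITUDE = {"background": 1.0, "interictal_like": 1.2, "ictal_like": 4.0}


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic segment.

    amplitude_scale multiplies the class's dominant component; spike_rate
    (events/s) only applies to interictal_like; oscillation_hz is the
    spike-and-wave fundamental of ictal_like; noise_exponent is the spectral
    slope beta of the 1/f^beta background (1 = pink noise).
    """

    fs: float = BONN_FS
    n_samples: int = 4096
    class_name: str = "background"
    amplitude_scale: Optional[float] = None  # None -> class default
    spike_rate: float = 0.5
    oscillation_hz: float = 3.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"unknown class_name {self.class_name!r}; expected one of {CLASS_NAMES}"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.n_samples < 64:
            raise ValueError("n_samples must be >= 64")
        amp = self.resolved_amplitude
        if not amp > 0:
            raise ValueError("amplitude_scale must be positive")

    @property
    def resolved_amplitude(self) -> float:
        if self.amplitude_scale is not None:
            return self.amplitude_scale
        return DEFAULT_AMPLITUDE[self.class_name]


def _pink_noise(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """Band-limited 1/f^beta Gaussian noise via spectral shaping, unit SD."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    shaping = np.zeros_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _biphasic_spike(fs: float) -> np.ndarray:
    """~70 ms biphasic (positive-then-negative) epileptiform spike template."""
    width = max(int(0.07 * fs), 5)
    t = np.linspace(-1.0, 1.0, width)
    return np.exp(-((t + 0.3) ** 2) / 0.04) - 0.8 * np.exp(-((t - 0.3) ** 2) / 0.08)


def _spike_wave(fs: float, n: int, hz: float, rng: np.random.Generator) -> np.ndarray:
    """Spike-and-wave train: sawtooth 'wave' plus a sharp Gaussian 'spike'
    template convolved with a periodic impulse train at the fundamental."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    wave = scipy.signal.sawtooth(2 * np.pi * hz * t + phase, width=0.5)
    period = int(round(fs / hz))
    impulses = np.zeros(n)
    offset = int((phase / (2 * np.pi)) * period) % period
    impulses[offset::period] = 1.0
    spike_t = np.linspace(-1, 1, max(int(0.05 * fs), 3))
    spike = np.exp(-(spike_t**2) / 0.05)
    spikes = np.convolve(impulses, spike, mode="same")
    x = wave + 1.5 * spikes
    return x / x.std()


def generate_segment(cfg: SynthConfig) -> EEGSegment:
    """Generate one segment; identical cfg (incl. seed) gives bit-identical output."""
    rng = np.random.default_rng(cfg.seed)
    amp = cfg.resolved_amplitude
    n, fs = cfg.n_samples, cfg.fs

    if cfg.class_name == "background":
        x = amp * _pink_noise(rng, n, fs, cfg.noise_exponent)
    elif cfg.class_name == "interictal_like":
        x = _pink_noise(rng, n, fs, cfg.noise_exponent)
        template = _biphasic_spike(fs)
        n_spikes = rng.poisson(cfg.spike_rate * n / fs)
        for _ in range(n_spikes):
            pos = rng.integers(0, max(n - template.size, 1))
            x[pos : pos + template.size] += 4.0 * rng.uniform(0.7, 1.3) * template
        x = amp * x / max(x.std(), 1e-12)
    else:  # ictal_like: dominant oscillation, reduced-variance noise floor
        osc = _spike_wave(fs, n, cfg.oscillation_hz, rng)
        noise = _pink_noise(rng, n, fs, cfg.noise_exponent)
        x = amp * (osc + 0.15 * noise)

    label = 1 if cfg.class_name == "ictal_like" else 0
    return EEGSegment(
        x,
        fs=fs,
        label=label,
        source_id=f"{cfg.class_name}_seed{cfg.seed}",
        meta={"class_name": cfg.class_name},
    )


def generate_dataset(
    n_per_class: int,
    classes: Sequence[str] = ("background", "ictal_like"),
    base_cfg: Optional[SynthConfig] = None,
    seed: int = 0,
    labels: Optional[dict] = None,
) -> List[EEGSegment]:
    """Generate a labeled dataset, n_per_class segments per class.

    Per-segment seeds are spawned deterministically from (seed, class index,
    replicate index) so adding classes or replicates never reshuffles
    existing segments.  By default ictal_like is labeled 1 and all other
    classes 0; pass ``labels={class_name: tag}`` to override.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_cfg or SynthConfig()
    out: List[EEGSegment] = []
    for ci, cls in enumerate(classes):
        for rep in range(n_per_class):
            child_seed = int(
                np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0] % (2**31)
            )
            cfg = replace(base, class_name=cls, seed=child_seed)
            seg = generate_segment(cfg)
            if labels is not None and cls in labels:
                seg = seg.with_label(labels[cls])
            seg = replace(seg, source_id=f"{cls}_{rep:04d}")
            out.append(seg)
    return out


def write_fixture_tree(dataset: Sequence[EEGSegment], root, dialect: str) -> List[Path]:
    """Write segments as a directory tree in the Bonn-ASCII or MAT dialect.

    One subdirectory per class name (from segment meta, falling back to the
    label), one file per segment, readable back via :mod:`seizeeg.io`.
    """
    root = Path(root)
    if dialect not in ("bonn", "delhi"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'bonn' or 'delhi'")
    written = []
    for seg in dataset:
        sub = seg.meta.get("class_name", str(seg.label))
        d = root / sub
        d.mkdir(parents=True, exist_ok=True)
        if dialect == "bonn":
            path = d / f"{seg.source_id}.txt"
            np.savetxt(path, seg.samples, fmt="%.8g")
        else:
            path = d / f"{seg.source_id}.mat"
            sio.savemat(str(path), {"eeg": seg.samples.reshape(1, -1)})
        written.append(path)
    return written
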