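"""Synthetic three-class EEG generator.

Emulates the class structure of the Bonn corpus so the whole pipeline can
be exercised without external data:

* ``normal`` — unit-amplitude alpha-band sinusoid (8-13 Hz, frequency drawn
  per segment) plus white noise;
* ``interictal`` — the same background with Poisson-timed biphasic spikes
  (difference of two Gaussians, a standard surrogate for epileptiform
  transients);
* ``ictal`` — a high-amplitude 3 Hz spike-wave rhythm (fundamental plus
  decaying harmonics, giving the sharp non-sinusoidal shape) plus noise.

The classes differ in how energy distributes over wavelet sub-bands, which
is exactly what the classifier's features measure.  These are stylized
waveforms, not a physiological simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_eeg import DEFAULT_SAMPLING_RATE, EEGDataset, EEGSegment, write_segment

__all__ = ["SyntheticSpec", "CLASS_NAMES", "generate_segment", "generate_dataset", "write_dataset_tree"]

CLASS_NAMES: tuple[str, ...] = ("normal", "interictal", "ictal")

#: Amplitude of the background sinusoid (arbitrary µV-like units).
_BACKGROUND_AMPLITUDE = 1.0


@dataclass
class SyntheticSpec:
    """Generator settings.

    Parameters
    ----------
    n_per_class : int
        Segments generated per class.
    n_samples : int
        Samples per segment; default 4096 (divisible by 2^4, so the
        level-4 periodized transform is orthonormal).
    sampling_rate : float
        Hz; default matches the Bonn corpus.
    noise_sd : float
        White-noise standard deviation, in units of the background
        amplitude.
    spike_rate : float
        Mean interictal spike rate (spikes/s).
    ictal_freq : float
        Spike-wave fundamental (Hz); must be below Nyquist.
    ictal_amp_ratio : float
        Ictal rhythm amplitude as a multiple of the background sd.
    seed : int
        Root seed for the dataset generator.
    """

    n_per_class: int = 100
    n_samples: int = 4096
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    noise_sd: float = 1.8
    spike_rate: float = 0.8
    ictal_freq: float = 3.0
    ictal_amp_ratio: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_samples < 16:
            raise ValueError("n_samples must be >= 16 (level-4 decomposition)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 < self.ictal_freq < self.sampling_rate / 2:
            raise ValueError("ictal_freq must lie below Nyquist")
        if not self.ictal_amp_ratio > 1:
            raise ValueError("ictal_amp_ratio must be > 1")

    @property
    def background_sd(self) -> float:
        """RMS of the noiseless background sinusoid (amplitude/√2)."""
        return _BACKGROUND_AMPLITUDE / np.sqrt(2.0)


def _background(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    freq = rng.uniform(8.0, 13.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    return _BACKGROUND_AMPLITUDE * np.sin(2 * np.pi * freq * t + phase)


def _biphasic_spike(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    # difference of two slightly offset Gaussians -> sharp up-down transient
    s = width / 4.0
    return amp * (
        np.exp(-0.5 * ((t - center) / s) ** 2)
        - np.exp(-0.5 * ((t - center - 1.5 * s) / s) ** 2)
    )


def generate_segment(
    class_kind: str, spec: SyntheticSpec, rng: np.random.Generator
) -> EEGSegment:
    """Generate one segment of the requested class.

    Deterministic given ``(class_kind, spec, rng state)``.
    """
    if class_kind not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_kind!r}; expected one of {CLASS_NAMES}")
    t = np.arange(spec.n_samples) / spec.sampling_rate
    noise = rng.normal(0.0, spec.noise_sd * _BACKGROUND_AMPLITUDE, spec.n_samples)
    if class_kind == "normal":
        x = _background(t, rng) + noise
    elif class_kind == "interictal":
        x = _background(t, rng)
        duration = spec.n_samples / spec.sampling_rate
        n_spikes = rng.poisson(spec.spike_rate * duration)
        amp = 5.0 * spec.background_sd
        for _ in range(n_spikes):
            center = rng.uniform(0.0, duration)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            x += _biphasic_spike(t, center, width=0.06, amp=sign * amp)
        x += noise
    else:  # ictal
        phase = rng.uniform(0.0, 2 * np.pi)
        w = 2 * np.pi * spec.ictal_freq * t + phase
        shape = np.sin(w) + 0.5 * np.sin(2 * w) + 0.25 * np.sin(3 * w)
        shape /= np.sqrt(0.5 * (1 + 0.25 + 0.0625))  # unit RMS
        x = spec.ictal_amp_ratio * spec.background_sd * shape + noise
    return EEGSegment(
        x, sampling_rate=spec.sampling_rate, segment_id=class_kind, label=class_kind
    )


def generate_dataset(spec: SyntheticSpec) -> EEGDataset:
    """Balanced three-class dataset; byte-identical on repeat for one seed."""
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(3)
    segments: list[EEGSegment] = []
    for class_kind, stream in zip(CLASS_NAMES, streams):
        rng = np.random.default_rng(stream)
        for i in range(spec.n_per_class):
            seg = generate_segment(class_kind, spec, rng)
            seg.segment_id = f"{class_kind}_{i:03d}"
            segments.append(seg)
    return EEGDataset(segments, set_name="synthetic", class_names=CLASS_NAMES)


def write_dataset_tree(dataset: EEGDataset, out_dir: str | Path) -> None:
    """Write one Bonn-style ASCII directory per class under ``out_dir``."""
    out_dir = Path(out_dir)
    for seg in dataset.segments:
        class_dir = out_dir / str(seg.label)
        class_dir.mkdir(parents=True, exist_ok=True)
        write_segment(seg, class_dir / f"{seg.segment_id}.txt")
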