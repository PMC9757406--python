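"""Level-4 Daubechies-2 wavelet decomposition and per-sub-band statistics.

A segment is split by a cascade of filter-and-downsample steps into detail
sub-bands D1 (finest) ... D4 and the final approximation A4.  With the
default periodization extension and a signal length divisible by 2^level,
the transform is orthonormal: coefficient count and energy both equal the
signal's.  Six statistics per sub-band — mean absolute value, average
power, standard deviation, skewness, excess kurtosis and Shannon sub-band
entropy — give 5 bands x 6 statistics = 30 features per segment, the
classifier's input dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .io_eeg import LABEL_COLUMN, EEGDataset, EEGSegment

__all__ = [
    "WaveletSpec",
    "DecompositionResult",
    "FeatureVector",
    "STATISTIC_NAMES",
    "db2_filters",
    "decompose",
    "reconstruct",
    "band_statistics",
    "extract_features",
    "build_feature_table",
]

_SQRT2 = np.sqrt(2.0)
_SQRT3 = np.sqrt(3.0)


def db2_filters() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form db2 filter bank.

    Returns ``(analysis_lo, analysis_hi, synthesis_lo, synthesis_hi)``.
    The analysis low-pass is ``((1+√3), (3+√3), (3−√3), (1−√3)) / (4√2)``;
    the high-pass is its quadrature mirror and the synthesis filters are
    the time-reverses.  The low-pass satisfies Σg = √2 and Σg² = 1.
    """
    lo = np.array([1 + _SQRT3, 3 + _SQRT3, 3 - _SQRT3, 1 - _SQRT3]) / (4 * _SQRT2)
    hi = np.array([(-1) ** k * lo[len(lo) - 1 - k] for k in range(len(lo))])
    return lo, hi, lo[::-1].copy(), hi[::-1].copy()


@dataclass
class WaveletSpec:
    """Wavelet decomposition settings.

    ``extension_mode`` is "periodization" (default; makes the transform
    orthonormal on dyadic lengths) or "symmetric" (half-sample mirror, the
    common toolbox default, with slightly redundant coefficient counts).
    """

    wavelet_name: str = "db2"
    level: int = 4
    extension_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.extension_mode not in ("periodization", "symmetric"):
            raise ValueError(f"unsupported extension mode {self.extension_mode!r}")
        g = np.asarray(self.wavelet.dec_lo)
        if abs(g.sum() - _SQRT2) > 1e-10 or abs((g**2).sum() - 1.0) > 1e-10:
            raise ValueError(
                f"{self.wavelet_name!r} analysis low-pass violates the "
                "orthonormal Daubechies identities"
            )

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.wavelet_name)

    @property
    def min_length(self) -> int:
        return 2**self.level


@dataclass
class DecompositionResult:
    """Wavelet coefficients of one segment.

    ``details`` holds D1 (finest) ... DL; ``approximation`` holds A_L.
    """

    details: list[np.ndarray]
    approximation: np.ndarray

    def __post_init__(self) -> None:
        self.details = [np.asarray(d, dtype=float) for d in self.details]
        self.approximation = np.asarray(self.approximation, dtype=float)
        for band in (*self.details, self.approximation):
            if not np.all(np.isfinite(band)):
                raise ValueError("non-finite wavelet coefficients")

    @property
    def level(self) -> int:
        return len(self.details)

    def bands(self) -> list[tuple[str, np.ndarray]]:
        """Named sub-bands in the fixed order D1..DL, A_L."""
        out = [(f"D{i + 1}", d) for i, d in enumerate(self.details)]
        out.append((f"A{self.level}", self.approximation))
        return out

    def total_coefficients(self) -> int:
        return sum(len(d) for d in self.details) + len(self.approximation)

    def energy(self) -> float:
        return float(
            sum(np.sum(d**2) for d in self.details) + np.sum(self.approximation**2)
        )


def _as_samples(segment: EEGSegment | np.ndarray) -> np.ndarray:
    if isinstance(segment, EEGSegment):
        return segment.samples
    return np.asarray(segment, dtype=float)


def decompose(
    segment: EEGSegment | np.ndarray, spec: WaveletSpec | None = None
) -> DecompositionResult:
    """Level-L wavelet decomposition of a segment.

    Raises ``ValueError`` if the signal is shorter than ``2**level``.
    """
    spec = spec or WaveletSpec()
    x = _as_samples(segment)
    if len(x) < spec.min_length:
        raise ValueError(
            f"signal of length {len(x)} too short for level {spec.level}; "
            f"minimum length is {spec.min_length}"
        )
    coeffs = pywt.wavedec(x, spec.wavelet, mode=spec.extension_mode, level=spec.level)
    approximation = coeffs[0]
    details = list(reversed(coeffs[1:]))  # wavedec returns coarse->fine
    return DecompositionResult(details=details, approximation=approximation)


def reconstruct(
    result: DecompositionResult,
    spec: WaveletSpec | None = None,
    length: int | None = None,
) -> np.ndarray:
    """Inverse cascade; ``reconstruct(decompose(x))`` recovers ``x``.

    With periodization and a length divisible by ``2**level`` the
    round-trip is exact to floating-point accuracy.
    """
    spec = spec or WaveletSpec()
    if result.level != spec.level:
        raise ValueError(
            f"decomposition level {result.level} does not match spec level {spec.level}"
        )
    coeffs = [result.approximation] + list(reversed(result.details))
    for lvl in range(1, len(coeffs)):  # A_L, D_L, ..., D1
        expected = len(coeffs[lvl])
        got = len(coeffs[lvl - 1])
        # periodization halves exactly; symmetric allows filter overhang
        if spec.extension_mode == "periodization" and lvl > 1 and expected * 2 < got:
            raise ValueError("inconsistent coefficient lengths across levels")
    x = pywt.waverec(coeffs, spec.wavelet, mode=spec.extension_mode)
    if length is not None:
        if len(x) < length:
            raise ValueError(
                f"coefficients reconstruct only {len(x)} samples, need {length}"
            )
        x = x[:length]
    return x


STATISTIC_NAMES: tuple[str, ...] = (
    "mav",
    "power",
    "sd",
    "skewness",
    "kurtosis",
    "entropy",
)


def band_statistics(coeffs: Sequence[float] | np.ndarray) -> np.ndarray:
    """Six summary statistics of one coefficient sub-band.

    Returns ``(mav, power, sd, skewness, kurtosis, entropy)`` where

    * mav — mean absolute value,
    * power — mean of squares,
    * sd — population standard deviation (divisor n),
    * skewness — population skewness, 0 for zero-variance bands,
    * kurtosis — population excess kurtosis, 0 for zero-variance bands,
    * entropy — Shannon entropy (nats) of p_k = c_k²/Σc², 0 if Σc² = 0.

    The degenerate rules keep every statistic finite on constant or
    all-zero bands.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("cannot summarize an empty coefficient sequence")
    mav = float(np.mean(np.abs(c)))
    power = float(np.mean(c**2))
    sd = float(np.std(c))  # population (ddof=0)
    if sd > 0:
        z = (c - c.mean()) / sd
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4) - 3.0)
    else:
        skewness = 0.0
        kurtosis = 0.0
    total = float(np.sum(c**2))
    if total > 0:
        p = c**2 / total
        p = p[p > 0]
        entropy = float(-np.sum(p * np.log(p)))
    else:
        entropy = 0.0
    return np.array([mav, power, sd, skewness, kurtosis, entropy])


@dataclass
class FeatureVector:
    """Ordered per-band statistics of one segment."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


def feature_names(spec: WaveletSpec | None = None) -> tuple[str, ...]:
    """Column names "D1:mav" ... "A4:entropy" in the fixed band order."""
    spec = spec or WaveletSpec()
    bands = [f"D{i + 1}" for i in range(spec.level)] + [f"A{spec.level}"]
    return tuple(f"{b}:{s}" for b in bands for s in STATISTIC_NAMES)


def extract_features(
    segment: EEGSegment | np.ndarray, spec: WaveletSpec | None = None
) -> FeatureVector:
    """Statistics of D1..DL and A_L concatenated in that fixed order.

    For the default level-4 decomposition this is a 30-dimensional vector.
    """
    spec = spec or WaveletSpec()
    result = decompose(segment, spec)
    values = np.concatenate([band_statistics(band) for _, band in result.bands()])
    return FeatureVector(values=values, names=feature_names(spec))


def build_feature_table(
    dataset: EEGDataset, spec: WaveletSpec | None = None
) -> pd.DataFrame:
    """One feature row per segment, in dataset order, label column last."""
    spec = spec or WaveletSpec()
    names = feature_names(spec)
    rows = np.empty((len(dataset), len(names)))
    labels = []
    for i, seg in enumerate(dataset.segments):
        rows[i] = extract_features(seg, spec).values
        labels.append(seg.label)
    table = pd.DataFrame(rows, columns=list(names))
    table[LABEL_COLUMN] = labels
    return table
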