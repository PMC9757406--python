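"""Reading Bonn-style ASCII EEG segments and CSV feature tables.

The public Bonn epilepsy corpus distributes each 23.6 s single-channel
segment as a plain-text file with one amplitude sample per line (~4097
samples at 173.61 Hz).  Five sets of 100 segments each (A-E) are combined
into three labelled experiment sets:

* ``SET1`` = A + D + E  (healthy eyes-open / interictal / ictal)
* ``SET2`` = B + D + E
* ``SET3`` = C + D + E

Labels are the source-set letters; their clinical meaning is documentation,
not code.  The sampling rate is carried as metadata only — nothing in the
pipeline depends on it numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EEGSegment",
    "EEGDataset",
    "SET_COMPOSITION",
    "DEFAULT_SAMPLING_RATE",
    "read_segment",
    "write_segment",
    "assemble_set",
    "read_feature_table",
    "write_feature_table",
]

#: Documented sampling rate of the public Bonn distribution (Hz).
DEFAULT_SAMPLING_RATE = 173.61

#: Source-set letters composing each experiment set.
SET_COMPOSITION: dict[str, tuple[str, ...]] = {
    "SET1": ("A", "D", "E"),
    "SET2": ("B", "D", "E"),
    "SET3": ("C", "D", "E"),
}


@dataclass
class EEGSegment:
    """One single-channel EEG recording segment.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples (µV), in recording order.  Must be finite.
    sampling_rate : float
        Sampling rate in Hz; metadata only.
    segment_id : str
        Identifier, typically derived from the source file name.
    label : str or None
        Class name; ``None`` until the segment is assembled into a dataset.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    segment_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EEGDataset:
    """An ordered collection of labelled segments sharing one sampling rate."""

    segments: list[EEGSegment]
    set_name: str = "custom"
    class_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.class_names:
            seen: list[str] = []
            for seg in self.segments:
                if seg.label is not None and seg.label not in seen:
                    seen.append(seg.label)
            self.class_names = tuple(seen)
        rates = {seg.sampling_rate for seg in self.segments}
        if len(rates) > 1:
            raise ValueError(f"segments have mixed sampling rates: {sorted(rates)}")
        for seg in self.segments:
            if seg.label not in self.class_names:
                raise ValueError(
                    f"segment {seg.segment_id!r} label {seg.label!r} "
                    f"not in class_names {self.class_names}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def labels(self) -> list[str]:
        return [seg.label for seg in self.segments]  # type: ignore[misc]

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.class_names}


def read_segment(
    path: str | Path, sampling_rate: float = DEFAULT_SAMPLING_RATE
) -> EEGSegment:
    """Read one Bonn-style ASCII segment (one real number per line).

    Blank lines are ignored.  The segment id is the file stem; the label is
    left unset until :func:`assemble_set` assigns one.

    Raises
    ------
    ValueError
        If the file is empty or a non-blank line fails to parse; the error
        names the offending line number.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: cannot parse {text!r} as a number"
                ) from None
    if not values:
        raise ValueError(f"{path}: no samples found (empty file)")
    return EEGSegment(np.array(values), sampling_rate=sampling_rate, segment_id=path.stem)


def write_segment(segment: EEGSegment, path: str | Path) -> None:
    """Write a segment in the Bonn ASCII dialect (one value per line)."""
    np.savetxt(path, segment.samples, fmt="%.10g")


def assemble_set(
    set_name: str,
    roots: Mapping[str, str | Path],
    pattern: str = "*",
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> EEGDataset:
    """Assemble one of the three experiment sets from per-letter directories.

    Parameters
    ----------
    set_name : {"SET1", "SET2", "SET3"}
        Which composition to build (see :data:`SET_COMPOSITION`).
    roots : mapping
        Source-set letter -> directory containing that letter's segment
        files.  Only the letters the composition needs must be present.
    pattern : str
        Glob matching segment files inside each directory; files are read
        in sorted order so assembly is deterministic.

    Returns
    -------
    EEGDataset
        One class per source letter, class name = letter, segments
        concatenated in letter order then sorted file order.
    """
    try:
        letters = SET_COMPOSITION[set_name]
    except KeyError:
        raise ValueError(
            f"unknown set {set_name!r}; expected one of {sorted(SET_COMPOSITION)}"
        ) from None
    segments: list[EEGSegment] = []
    for letter in letters:
        if letter not in roots:
            raise ValueError(f"no directory configured for set letter {letter!r}")
        root = Path(roots[letter])
        if not root.is_dir():
            raise ValueError(f"directory for set letter {letter!r} not found: {root}")
        files = sorted(p for p in root.glob(pattern) if p.is_file())
        if not files:
            raise ValueError(f"no segment files in {root} for set letter {letter!r}")
        for f in files:
            seg = read_segment(f, sampling_rate=sampling_rate)
            seg.label = letter
            segments.append(seg)
    return EEGDataset(segments, set_name=set_name, class_names=letters)


LABEL_COLUMN = "label"


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a sample x feature table as CSV with the label column last."""
    if table.columns.duplicated().any():
        raise ValueError("feature table has duplicate column names")
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"feature table lacks a {LABEL_COLUMN!r} column")
    cols = [c for c in table.columns if c != LABEL_COLUMN] + [LABEL_COLUMN]
    table[cols].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path)
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"{path}: missing {LABEL_COLUMN!r} column")
    if table.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate column names")
    feature_cols = [c for c in table.columns if c != LABEL_COLUMN]
    bad = [c for c in feature_cols if not np.issubdtype(table[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric feature columns {bad}")
    return table
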