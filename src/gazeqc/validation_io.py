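"""Reading and writing validation-session recordings.

A validation recording is a tab-separated UTF-8 text file with a header and
the columns

    timestamp  left_x  left_y  right_x  right_y  target_id  tar_x  tar_y

where one of the eye column pairs may be absent.  ``timestamp`` is in seconds
(a millisecond dialect can be rescaled on read), gaze and target positions are
either screen pixels or Fick degrees, and ``target_id`` labels the per-target
measurement intervals, with -1 (or an empty cell) meaning "not in a
measurement interval".  Empty gaze cells and configured vendor sentinel pairs
(e.g. (0, 0)) are normalised to NaN on read; NaN is written back as an empty
cell, so read-after-write reproduces finite values exactly and preserves the
NaN pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .geometry import ScreenGeometry, mm_to_angles, pixels_to_mm

__all__ = ["ValidationRecording", "read_validation_file",
           "write_validation_file", "to_angles",
           "TARGET_SENTINEL", "COLUMNS"]

TARGET_SENTINEL = -1
COLUMNS = ("timestamp", "left_x", "left_y", "right_x", "right_y",
           "target_id", "tar_x", "tar_y")
_EYE_COLS = {"left": ("left_x", "left_y"), "right": ("right_x", "right_y")}


@dataclass
class ValidationRecording:
    """One validation session: per-sample gaze, target labels and metadata.

    ``samples`` holds the tabular data with the pinned column names; only eye
    column pairs actually present are stored.  ``units`` says whether gaze and
    target positions are screen pixels or degrees; pixel recordings need a
    ``screen`` geometry before metrics can be computed.
    """

    samples: pd.DataFrame
    units: Literal["pixels", "degrees"] = "degrees"
    screen: ScreenGeometry | None = None
    nominal_frequency: float | None = None
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("timestamp", "target_id", "tar_x", "tar_y")
                   if c not in self.samples.columns]
        if missing:
            raise FormatError(f"recording is missing mandatory column(s): {missing}")
        if not self.eyes:
            raise FormatError("recording has no eye gaze column pair "
                              "(left_x/left_y or right_x/right_y)")
        if self.units not in ("pixels", "degrees"):
            raise ConfigError(f"unknown units {self.units!r}; "
                              "expected 'pixels' or 'degrees'")
        ts = self.samples["timestamp"].to_numpy(dtype=float)
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            raise FormatError("timestamps are not non-decreasing")

    @property
    def eyes(self) -> list[str]:
        """Eyes present in the recording, in (left, right) order."""
        return [eye for eye, (cx, cy) in _EYE_COLS.items()
                if cx in self.samples.columns and cy in self.samples.columns]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Recording duration in seconds.

        n samples span n sampling periods, so one nominal period is added to
        the timestamp span when the nominal frequency is known; otherwise the
        bare span is returned.
        """
        ts = self.samples["timestamp"].to_numpy(dtype=float)
        if ts.size == 0:
            return 0.0
        span = float(ts[-1] - ts[0])
        if self.nominal_frequency:
            span += 1.0 / self.nominal_frequency
        return span

    def gaze(self, eye: str) -> tuple[np.ndarray, np.ndarray]:
        """Horizontal and vertical gaze arrays for one eye."""
        if eye not in self.eyes:
            raise ValueError(f"eye {eye!r} not present; have {self.eyes}")
        cx, cy = _EYE_COLS[eye]
        return (self.samples[cx].to_numpy(dtype=float),
                self.samples[cy].to_numpy(dtype=float))


def read_validation_file(
    path: str | Path,
    screen: ScreenGeometry | None = None,
    *,
    units: Literal["pixels", "degrees"] = "degrees",
    timestamp_unit: Literal["s", "ms"] = "s",
    invalid_values: Sequence[tuple[float, float]] = (),
    nominal_frequency: float | None = None,
) -> ValidationRecording:
    """Parse a validation TSV file into a :class:`ValidationRecording`.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    screen
        Screen geometry, required later for pixel-unit recordings.
    units
        Unit of the gaze/target position columns.
    timestamp_unit
        ``"ms"`` rescales the timestamp column to seconds on read.
    invalid_values
        Vendor sentinel ``(h, v)`` pairs to normalise to NaN, applied per eye.
    nominal_frequency
        The tracker's advertised sampling rate, if known.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=float,
                         float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: cannot parse as validation TSV: {exc}") from exc
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {unknown}; "
                          f"expected a subset of {list(COLUMNS)}")
    for col in ("timestamp", "target_id", "tar_x", "tar_y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if timestamp_unit == "ms":
        df["timestamp"] = df["timestamp"] / 1000.0
    elif timestamp_unit != "s":
        raise ConfigError(f"unknown timestamp_unit {timestamp_unit!r}")

    for cx, cy in _EYE_COLS.values():
        if cx not in df.columns:
            continue
        for h_sent, v_sent in invalid_values:
            bad = (df[cx] == h_sent) & (df[cy] == v_sent)
            df.loc[bad, [cx, cy]] = np.nan

    df["target_id"] = df["target_id"].fillna(TARGET_SENTINEL).astype(int)
    try:
        return ValidationRecording(samples=df, units=units, screen=screen,
                                   nominal_frequency=nominal_frequency,
                                   source=str(path))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_validation_file(rec: ValidationRecording, path: str | Path) -> None:
    """Write a recording in the same TSV dialect ``read_validation_file`` parses.

    NaN cells are written empty.  Finite floats are written with shortest
    round-trip precision, so a read-back reproduces them bit-exactly.
    """
    path = Path(path)
    df = rec.samples[[c for c in COLUMNS if c in rec.samples.columns]]
    try:
        df.to_csv(path, sep="\t", index=False, na_rep="")
    except OSError as exc:
        raise OSError(f"failed writing validation file {path}: {exc}") from exc


def to_angles(rec: ValidationRecording) -> ValidationRecording:
    """Return the recording with gaze and target positions in Fick degrees.

    A degrees-unit recording is returned unchanged.  Pixel recordings require
    a screen geometry; the conversion preserves sample count, target labels
    and the NaN pattern.
    """
    if rec.units == "degrees":
        return rec
    if rec.screen is None:
        raise ConfigError("pixel-unit recording needs a ScreenGeometry "
                          "to convert to degrees")
    df = rec.samples.copy()
    pairs = [(cx, cy) for cx, cy in _EYE_COLS.values() if cx in df.columns]
    pairs.append(("tar_x", "tar_y"))
    for cx, cy in pairs:
        x_mm, y_mm = pixels_to_mm(df[cx].to_numpy(dtype=float),
                                  df[cy].to_numpy(dtype=float), rec.screen)
        azi, ele = mm_to_angles(x_mm, y_mm, rec.screen.viewing_distance_mm)
        df[cx] = azi
        df[cy] = ele
    return replace(rec, samples=df, units="degrees")
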