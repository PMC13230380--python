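"""Data-loss and effective-sampling-frequency operationalisations.

Three related quantities are provided:

* loss as the fraction of received samples that are invalid;
* loss as the shortfall of valid samples against the count expected from the
  recording duration and the tracker's nominal sampling frequency;
* the effective sampling frequency, valid samples per second of recording.

Invalid samples must be encoded as NaN; a sample counts as invalid when its
horizontal or vertical coordinate is NaN.  The units and coordinate system of
the inputs are irrelevant.  Other vendor encodings of invalidity (sentinel
coordinate pairs, dropped samples) are normalised to NaN at the I/O layer,
not here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataQualityWarning

__all__ = [
    "RecordingInfo",
    "data_loss_from_invalid",
    "data_loss_from_expected",
    "effective_frequency",
]


@dataclass
class RecordingInfo:
    """Recording duration (s) and the tracker's nominal sampling rate (Hz)."""

    duration: float
    nominal_frequency: float | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.nominal_frequency is not None and not self.nominal_frequency > 0:
            raise ValueError(
                f"nominal_frequency must be > 0, got {self.nominal_frequency}")


def _validate_coords(h, v) -> tuple[np.ndarray, np.ndarray]:
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    if h.shape != v.shape:
        raise ValueError("h and v must have the same length")
    if h.size == 0:
        raise ValueError("empty gaze coordinate input")
    return h, v


def _n_valid(h: np.ndarray, v: np.ndarray) -> int:
    return int(np.count_nonzero(np.isfinite(h) & np.isfinite(v)))


def data_loss_from_invalid(h, v) -> float:
    """Percentage of received samples that are invalid (NaN in h or v)."""
    h, v = _validate_coords(h, v)
    return 100.0 * (h.size - _n_valid(h, v)) / h.size


def data_loss_from_expected(h, v, info: RecordingInfo) -> float:
    """Percentage shortfall of valid samples against the expected count.

    The expected count is ``duration * nominal_frequency``, used as a real
    number without rounding.  If more valid samples arrive than expected the
    result is negative and returned as-is, with a warning.
    """
    h, v = _validate_coords(h, v)
    if info.nominal_frequency is None:
        raise ValueError("data_loss_from_expected requires a nominal_frequency")
    expected = info.duration * info.nominal_frequency
    loss = 100.0 * (1.0 - _n_valid(h, v) / expected)
    if loss < -1e-9:  # tolerate rounding noise at exactly the expected count
        warnings.warn(
            f"more valid samples than expected ({_n_valid(h, v)} vs "
            f"{expected:g}); negative data loss {loss:.3g}%",
            DataQualityWarning, stacklevel=2)
    return loss


def effective_frequency(h, v, duration: float) -> float:
    """Valid samples delivered per second of recording, in Hz."""
    h, v = _validate_coords(h, v)
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    return _n_valid(h, v) / duration
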