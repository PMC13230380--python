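"""Inaccuracy and imprecision measures for segments of gaze data.

All operations take gaze expressed as Fick azimuth/elevation angles in
degrees.  Invalid samples are encoded as NaN in azimuth and/or elevation and
are ignored; a sample is valid only when both components are finite.

The measures implemented are

* ``accuracy`` — angular offset between a representative gaze direction and a
  fixation-target direction, via the arccos of the inner product of the two
  unit vectors;
* ``rms_s2s`` — root mean (or median) square of the Euclidean displacement in
  (azimuth, elevation) space between successive samples; a velocity-like noise
  measure;
* ``rms_s2s_sliding_window`` — the median of per-window RMS-S2S values from a
  window slid one sample at a time; robust to sparse spikes and saccades;
* ``std`` — radial spatial spread, sqrt(STD_x^2 + STD_y^2) with population
  (1/n) normalisation;
* ``bcea`` — bivariate contour ellipse area, the area of the ellipse that
  contains a fraction P of the samples under a bivariate-Gaussian model,
  together with the ellipse orientation, axis radii and anisotropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DataQualityWarning
from .geometry import AngularPosition, angles_to_direction

__all__ = [
    "GazeSegment",
    "PrecisionParams",
    "BCEAResult",
    "accuracy",
    "rms_s2s",
    "rms_s2s_sliding_window",
    "std",
    "bcea",
]

CentralTendency = Literal["mean", "median"]


@dataclass
class GazeSegment:
    """A time-stamped segment of monocular (or averaged-eye) gaze angles.

    Attributes
    ----------
    timestamps
        Sample times in seconds, non-decreasing.
    azimuth, elevation
        Gaze angles in degrees; NaN marks an invalid sample.
    eye
        Which eye the segment belongs to: ``"left"``, ``"right"`` or
        ``"average"``.
    """

    timestamps: np.ndarray
    azimuth: np.ndarray
    elevation: np.ndarray
    eye: str = "left"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if not (len(self.timestamps) == len(self.azimuth) == len(self.elevation)):
            raise ValueError("timestamps, azimuth and elevation must have equal length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of samples with both components finite."""
        return np.isfinite(self.azimuth) & np.isfinite(self.elevation)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass
class PrecisionParams:
    """Tunable parameters for the precision measures.

    ``P`` is the fraction of gaze samples the BCEA ellipse should contain
    (0.68 by convention); ``window_length_ms`` the length of the sliding
    RMS-S2S window; ``central_tendency`` how a segment's gaze vectors are
    reduced to one representative direction for the accuracy measure.
    """

    P: float = 0.68
    window_length_ms: float = 200.0
    central_tendency: CentralTendency = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.P < 1:
            raise ValueError(f"P must lie in (0, 1), got {self.P}")
        if not self.window_length_ms > 0:
            raise ValueError("window_length_ms must be > 0")
        if self.central_tendency not in ("mean", "median"):
            raise ValueError("central_tendency must be 'mean' or 'median'")


@dataclass
class BCEAResult:
    """BCEA ellipse parameters.

    ``area`` equals ``pi * major_radius * minor_radius`` whenever the sample
    covariance is non-degenerate.  ``orientation`` is the angle of the major
    axis relative to the azimuth axis, in degrees in (-90, 90].
    """

    area: float
    std_x: float
    std_y: float
    rho: float
    orientation: float = field(default=np.nan)
    major_radius: float = field(default=np.nan)
    minor_radius: float = field(default=np.nan)
    anisotropy: float = field(default=np.nan)


def _central_direction(azi: np.ndarray, ele: np.ndarray,
                       central_tendency: CentralTendency) -> np.ndarray:
    """Reduce valid gaze angles to one representative direction vector."""
    x, y, z = angles_to_direction(azi, ele)
    reduce = np.mean if central_tendency == "mean" else np.median
    return np.array([reduce(x), reduce(y), reduce(z)])


def accuracy(segment: GazeSegment, target: AngularPosition,
             params: PrecisionParams | None = None) -> float:
    """Angular offset (degrees) of a gaze segment from a fixation target.

    Valid samples are converted to unit gaze vectors, reduced component-wise
    by the configured central tendency (mean by default) to a representative
    gaze direction, and the angle between that direction and the target
    direction is returned via the arccos of the normalised inner product.

    Returns NaN (with a :class:`DataQualityWarning`) when the segment holds no
    valid sample.  Raises ``ValueError`` if the representative vector is
    degenerate (norm below 1e-12), which cannot occur for on-screen data.
    """
    if params is None:
        params = PrecisionParams()
    ok = segment.valid
    if not ok.any():
        warnings.warn("accuracy: segment has no valid samples; returning NaN",
                      DataQualityWarning, stacklevel=2)
        return float("nan")
    v_gaze = _central_direction(segment.azimuth[ok], segment.elevation[ok],
                                params.central_tendency)
    norm = np.linalg.norm(v_gaze)
    if norm < 1e-12:
        raise ValueError("degenerate mean gaze vector (norm < 1e-12)")
    v_tgt = np.array(angles_to_direction(target.azimuth, target.elevation))
    cos_angle = np.dot(v_gaze / norm, v_tgt / np.linalg.norm(v_tgt))
    return float(np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0))))


def _squared_displacements(segment: GazeSegment) -> np.ndarray:
    """Squared Euclidean displacement between successive valid sample pairs.

    Pairs in which either sample is invalid are dropped, never bridged: a
    pair spanning a blink gap would otherwise fabricate a large displacement.
    """
    dx = np.diff(segment.azimuth)
    dy = np.diff(segment.elevation)
    sq = dx * dx + dy * dy
    return sq[np.isfinite(sq)]


def rms_s2s(segment: GazeSegment,
            aggregate: Literal["mean", "median"] = "mean") -> float:
    """RMS of sample-to-sample displacement, in degrees.

    ``aggregate="mean"`` gives the classic root *mean* square; ``"median"``
    replaces the mean of the squared displacements with their median, which is
    robust to occasional spikes.  Returns NaN with a warning when no valid
    successive pair exists.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    sq = _squared_displacements(segment)
    if sq.size == 0:
        warnings.warn("rms_s2s: no valid successive sample pair; returning NaN",
                      DataQualityWarning, stacklevel=2)
        return float("nan")
    agg = np.mean if aggregate == "mean" else np.median
    return float(np.sqrt(agg(sq)))


def rms_s2s_sliding_window(segment: GazeSegment, params: PrecisionParams,
                           sampling_frequency: float) -> float:
    """Median across windows of the per-window RMS-S2S, in degrees.

    The window length in samples is ``round(window_length_ms / 1000 * fs)``
    (half-up) and the window is slid one sample at a time.  Only windows in
    which every sample is valid contribute; returns NaN with a warning when
    no fully valid window exists.
    """
    if not sampling_frequency > 0:
        raise ValueError("sampling_frequency must be > 0")
    # round half-up so that e.g. 2.5 samples -> 3
    n_win = int(np.floor(params.window_length_ms / 1000.0 * sampling_frequency + 0.5))
    if n_win < 2:
        raise ValueError(
            f"window of {params.window_length_ms} ms at {sampling_frequency} Hz "
            f"holds {n_win} sample(s); need at least 2")
    if len(segment) < n_win:
        raise ValueError("segment shorter than one window")
    dx = np.diff(segment.azimuth)
    dy = np.diff(segment.elevation)
    sq = dx * dx + dy * dy  # length n-1; NaN where either sample invalid
    windows = np.lib.stride_tricks.sliding_window_view(sq, n_win - 1)
    with np.errstate(invalid="ignore"):
        per_window = np.sqrt(np.mean(windows, axis=1))
    per_window = per_window[np.isfinite(per_window)]
    if per_window.size == 0:
        warnings.warn("rms_s2s_sliding_window: no fully valid window; returning NaN",
                      DataQualityWarning, stacklevel=2)
        return float("nan")
    return float(np.median(per_window))


def std(segment: GazeSegment) -> float:
    """Radial spatial spread sqrt(STD_x^2 + STD_y^2), in degrees.

    Component standard deviations use population (1/n) normalisation over the
    valid samples.  Returns NaN with a warning for an all-invalid segment.
    """
    ok = segment.valid
    if not ok.any():
        warnings.warn("std: segment has no valid samples; returning NaN",
                      DataQualityWarning, stacklevel=2)
        return float("nan")
    sx = np.std(segment.azimuth[ok])   # population (ddof=0)
    sy = np.std(segment.elevation[ok])
    return float(np.hypot(sx, sy))


def bcea(segment: GazeSegment, params: PrecisionParams | None = None) -> BCEAResult:
    """Bivariate contour ellipse area and derived ellipse descriptors.

    The area is ``2 k pi sigma_x sigma_y sqrt(1 - rho^2)`` with
    ``k = -ln(1 - P)``; under a bivariate-Gaussian model the ellipse with
    squared Mahalanobis radius ``2k`` contains a fraction ``P`` of the
    samples.  Orientation and axis radii come from the eigen-decomposition of
    the 2x2 population covariance scaled by ``2k``; anisotropy is the
    major/minor radius ratio.

    A degenerate cloud (sigma_x or sigma_y zero, or |rho| = 1) yields zero
    area; an undefined correlation is reported as 0 with a warning.
    """
    if params is None:
        params = PrecisionParams()
    ok = segment.valid
    n = int(np.count_nonzero(ok))
    if n < 2:
        warnings.warn("bcea: fewer than 2 valid samples; returning NaN area",
                      DataQualityWarning, stacklevel=2)
        return BCEAResult(area=float("nan"), std_x=float("nan"),
                          std_y=float("nan"), rho=float("nan"))
    x = segment.azimuth[ok]
    y = segment.elevation[ok]
    k = -np.log1p(-params.P)
    sx = float(np.std(x))
    sy = float(np.std(y))
    cov_xy = float(np.mean((x - x.mean()) * (y - y.mean())))
    if sx == 0.0 or sy == 0.0:
        warnings.warn("bcea: degenerate sample cloud; correlation undefined, "
                      "reported as 0", DataQualityWarning, stacklevel=2)
        rho = 0.0
    else:
        rho = cov_xy / (sx * sy)
        rho = float(np.clip(rho, -1.0, 1.0))
    area = float(2.0 * k * np.pi * sx * sy * np.sqrt(max(0.0, 1.0 - rho * rho)))

    cov = np.array([[sx * sx, cov_xy], [cov_xy, sy * sy]])
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending eigenvalues
    eigvals = np.clip(eigvals, 0.0, None)
    minor_r = float(np.sqrt(2.0 * k * eigvals[0]))
    major_r = float(np.sqrt(2.0 * k * eigvals[1]))
    major_vec = eigvecs[:, 1]
    orientation = float(np.degrees(np.arctan2(major_vec[1], major_vec[0])))
    if orientation <= -90.0:
        orientation += 180.0
    elif orientation > 90.0:
        orientation -= 180.0
    anisotropy = major_r / minor_r if minor_r > 0 else float("inf")
    return BCEAResult(area=area, std_x=sx, std_y=sy, rho=rho,
                      orientation=orientation, major_radius=major_r,
                      minor_radius=minor_r, anisotropy=anisotropy)
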