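"""Per-recording pipeline: segment extraction and the data-quality table.

A validation recording is cut into per-eye, per-target gaze segments using
the target-assignment column (every contiguous run of one target id is a
measurement interval), and each segment is scored with the full set of
quality measures.  The result is one tidy table row per eye and fixation
target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataloss import data_loss_from_invalid, effective_frequency
from .errors import DataQualityWarning, FormatError
from .geometry import AngularPosition
from .metrics import (GazeSegment, PrecisionParams, accuracy, bcea, rms_s2s,
                      std)
from .validation_io import TARGET_SENTINEL, ValidationRecording, to_angles

__all__ = ["TargetSegment", "QUALITY_COLUMNS", "extract_target_segments",
           "compute_data_quality_from_validation", "summarize_over_targets"]

QUALITY_COLUMNS = ["eye", "target_id", "target_azimuth", "target_elevation",
                   "n_samples", "accuracy_deg", "rms_s2s_deg",
                   "rms_s2s_median_deg", "std_deg", "bcea_deg2",
                   "data_loss_pct", "effective_frequency_hz"]


@dataclass
class TargetSegment:
    """One eye's gaze during one measurement interval of one fixation target."""

    eye: str
    target_id: int
    segment: GazeSegment
    target: AngularPosition


def _target_runs(target_id: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous runs of non-sentinel target ids as (id, start, stop)."""
    runs = []
    n = len(target_id)
    i = 0
    while i < n:
        tid = target_id[i]
        j = i
        while j < n and target_id[j] == tid:
            j += 1
        if tid != TARGET_SENTINEL:
            runs.append((int(tid), i, j))
        i = j
    return runs


def _eye_angles(rec: ValidationRecording, eye: str) -> tuple[np.ndarray, np.ndarray]:
    if eye == "average":
        la, le = rec.gaze("left")
        ra, re_ = rec.gaze("right")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            azi = np.nanmean(np.vstack([la, ra]), axis=0)
            ele = np.nanmean(np.vstack([le, re_]), axis=0)
        # require both eyes valid for the averaged signal
        both = (np.isfinite(la) & np.isfinite(le)
                & np.isfinite(ra) & np.isfinite(re_))
        azi = np.where(both, azi, np.nan)
        ele = np.where(both, ele, np.nan)
        return azi, ele
    return rec.gaze(eye)


def extract_target_segments(rec: ValidationRecording,
                            include_average_eye: bool = False,
                            ) -> list[TargetSegment]:
    """Cut a degrees-unit recording into per-eye, per-target-run segments.

    The target direction of a run is its constant target position; a target
    position that varies within a run (beyond 1e-9 deg) is a format error.
    An optional synthetic "average" eye (per-sample mean of the two eyes
    where both are valid) can be added when both eyes are present.
    """
    if rec.units != "degrees":
        raise ValueError("recording must be in degrees units; "
                         "use validation_io.to_angles first")
    ts = rec.samples["timestamp"].to_numpy(dtype=float)
    tid = rec.samples["target_id"].to_numpy()
    tar_x = rec.samples["tar_x"].to_numpy(dtype=float)
    tar_y = rec.samples["tar_y"].to_numpy(dtype=float)
    runs = _target_runs(tid)
    if not runs:
        warnings.warn("recording contains no measurement interval "
                      "(all target ids are sentinel)", DataQualityWarning,
                      stacklevel=2)
        return []
    eyes = list(rec.eyes)
    if include_average_eye and len(eyes) == 2:
        eyes.append("average")
    segments = []
    for eye in eyes:
        azi, ele = _eye_angles(rec, eye)
        for target_id, i, j in runs:
            tx, ty = tar_x[i:j], tar_y[i:j]
            if np.isnan(tx).any() or np.isnan(ty).any():
                raise FormatError(
                    f"target {target_id}: missing target position inside a "
                    "measurement interval")
            if (np.ptp(tx) > 1e-9) or (np.ptp(ty) > 1e-9):
                raise FormatError(
                    f"target {target_id}: target position varies within a "
                    "measurement interval")
            segments.append(TargetSegment(
                eye=eye, target_id=target_id,
                segment=GazeSegment(timestamps=ts[i:j], azimuth=azi[i:j],
                                    elevation=ele[i:j], eye=eye),
                target=AngularPosition(float(tx[0]), float(ty[0]))))
    return segments


def _merge_runs(segments: list[TargetSegment]) -> list[TargetSegment]:
    """Concatenate multiple runs of the same (eye, target_id) into one segment."""
    merged: dict[tuple[str, int], TargetSegment] = {}
    for seg in segments:
        key = (seg.eye, seg.target_id)
        if key not in merged:
            merged[key] = seg
        else:
            prev = merged[key]
            if (abs(prev.target.azimuth - seg.target.azimuth) > 1e-9
                    or abs(prev.target.elevation - seg.target.elevation) > 1e-9):
                raise FormatError(
                    f"target {seg.target_id}: position differs between runs")
            merged[key] = TargetSegment(
                eye=seg.eye, target_id=seg.target_id,
                segment=GazeSegment(
                    timestamps=np.concatenate([prev.segment.timestamps,
                                               seg.segment.timestamps]),
                    azimuth=np.concatenate([prev.segment.azimuth,
                                            seg.segment.azimuth]),
                    elevation=np.concatenate([prev.segment.elevation,
                                              seg.segment.elevation]),
                    eye=seg.eye),
                target=prev.target)
    return list(merged.values())


def _segment_effective_frequency(seg: GazeSegment) -> float:
    """Valid samples per second over the segment's time span.

    The span is the timestamp range plus one median sampling period, so that
    a gap-free regularly sampled segment recovers its sampling rate exactly.
    """
    if len(seg) < 2:
        return float("nan")
    dt = np.diff(seg.timestamps)
    span = float(seg.timestamps[-1] - seg.timestamps[0] + np.median(dt))
    if span <= 0:
        return float("nan")
    return effective_frequency(seg.azimuth, seg.elevation, span)


def compute_data_quality_from_validation(
    rec: ValidationRecording,
    params: PrecisionParams | None = None,
    include_average_eye: bool = False,
) -> pd.DataFrame:
    """Compute the full quality table of a validation recording.

    Returns one row per (eye, fixation target), ordered by eye then target
    id, with the angular offset from the target (accuracy), the mean- and
    median-aggregated sample-to-sample RMS, the radial STD, the BCEA area,
    the within-segment invalid-sample data loss and the segment effective
    sampling frequency.  A pixel-unit recording is converted to degrees first
    (requires its screen geometry).
    """
    if params is None:
        params = PrecisionParams()
    rec = to_angles(rec)
    segments = _merge_runs(
        extract_target_segments(rec, include_average_eye=include_average_eye))
    rows = []
    eye_order = {"left": 0, "right": 1, "average": 2}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        for ts in sorted(segments,
                         key=lambda s: (eye_order[s.eye], s.target_id)):
            seg = ts.segment
            rows.append({
                "eye": ts.eye,
                "target_id": ts.target_id,
                "target_azimuth": ts.target.azimuth,
                "target_elevation": ts.target.elevation,
                "n_samples": len(seg),
                "accuracy_deg": accuracy(seg, ts.target, params),
                "rms_s2s_deg": rms_s2s(seg, "mean"),
                "rms_s2s_median_deg": rms_s2s(seg, "median"),
                "std_deg": std(seg),
                "bcea_deg2": bcea(seg, params).area,
                "data_loss_pct": data_loss_from_invalid(seg.azimuth,
                                                        seg.elevation),
                "effective_frequency_hz": _segment_effective_frequency(seg),
            })
    if not rows:
        warnings.warn("no measurement intervals found; returning empty table",
                      DataQualityWarning, stacklevel=2)
        return pd.DataFrame(columns=QUALITY_COLUMNS)
    return pd.DataFrame(rows, columns=QUALITY_COLUMNS)


def summarize_over_targets(table: pd.DataFrame,
                           statistic: str = "mean") -> pd.DataFrame:
    """Reduce a quality table to one row per eye across fixation targets.

    ``statistic`` is ``"mean"`` or ``"median"``; NaN entries are ignored.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if table.empty:
        raise ValueError("cannot summarize an empty quality table")
    measures = [c for c in QUALITY_COLUMNS
                if c not in ("eye", "target_id", "target_azimuth",
                             "target_elevation")]
    if table[measures].isna().all().any():
        bad = [m for m in measures if table[m].isna().all()]
        warnings.warn(f"measure(s) {bad} are all-NaN across targets",
                      DataQualityWarning, stacklevel=2)
    grouped = table.groupby("eye", sort=False)[measures]
    out = grouped.mean() if statistic == "mean" else grouped.median()
    return out.reset_index()
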