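"""Seeded generator of validation sessions with known ground truth.

The generator emulates a multi-target validation protocol: fixation targets
from a grid are visited one at a time in seed-shuffled random order; during
each measurement interval the simulated gaze sits at the target plus a
constant angular offset (the injected inaccuracy) plus i.i.d. isotropic
Gaussian noise per axis (the injected imprecision).  Between targets,
optional "flight" samples are emitted with the sentinel target id, linearly
interpolated between target positions — they stand in for the pursuit of the
moving target and are not physiologically modelled.  Blink-like data loss is
injected as NaN runs in both eyes, either by a seeded Poisson process or, in
deterministic mode, evenly spaced so the injected loss is exact.

The returned :class:`GroundTruth` records everything a parameter-recovery
test needs: the true offset, the shuffled target order, per-target sample
and invalid-sample counts, and the realised loss fractions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import AngularPosition
from .validation_io import (TARGET_SENTINEL, ValidationRecording,
                            write_validation_file)

__all__ = ["SyntheticConfig", "GroundTruth", "default_target_grid",
           "generate_validation_recording", "write_ground_truth",
           "write_session"]


def default_target_grid() -> list[AngularPosition]:
    """The default 9-point validation grid: 3x3 spanning +/-10 degrees."""
    return [AngularPosition(float(a), float(e))
            for e in (10.0, 0.0, -10.0) for a in (-10.0, 0.0, 10.0)]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic validation session.

    Defaults describe a typical desktop validation: a 9-point grid within
    +/-10 deg, 1-s measurement intervals at 600 Hz, tracker noise of
    0.05 deg per axis, and blinks at 20 per minute lasting 300 ms each —
    the upper end of normal spontaneous blinking, which by itself produces
    about 10% data loss.
    """

    target_grid: Sequence[AngularPosition] = field(
        default_factory=default_target_grid)
    interval_duration: float = 1.0
    sampling_frequency: float = 600.0
    offset: AngularPosition = field(
        default_factory=lambda: AngularPosition(0.0, 0.0))
    noise_sigma: float = 0.05
    blink_rate: float = 20.0
    blink_duration: float = 0.3
    blink_mode: Literal["poisson", "deterministic"] = "poisson"
    flight_duration: float = 0.5
    eyes: Sequence[str] = ("left", "right")
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_frequency > 0:
            raise ConfigError("sampling_frequency must be > 0")
        if not self.interval_duration > 0:
            raise ConfigError("interval_duration must be > 0")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.blink_rate < 0 or self.blink_duration < 0:
            raise ConfigError("blink_rate and blink_duration must be >= 0")
        if self.blink_rate > 0 and self.blink_duration >= self.interval_duration:
            raise ConfigError("blink_duration must be shorter than "
                              "interval_duration")
        if self.flight_duration < 0:
            raise ConfigError("flight_duration must be >= 0")
        if not self.target_grid:
            raise ConfigError("target_grid must hold at least one target")
        bad = [e for e in self.eyes if e not in ("left", "right")]
        if bad or not self.eyes:
            raise ConfigError(f"eyes must be a subset of (left, right), "
                              f"got {tuple(self.eyes)}")


@dataclass
class GroundTruth:
    """The injected session parameters, for parameter-recovery checks."""

    offset_azimuth: float
    offset_elevation: float
    noise_sigma: float
    target_order: list[int]
    n_samples_total: int
    n_invalid_total: int
    loss_pct_overall: float
    per_target_n_samples: dict[int, int]
    per_target_n_invalid: dict[int, int]
    loss_pct_measurement: float


def _blink_starts(cfg: SyntheticConfig, n_total: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample indices at which blink gaps start."""
    duration = n_total / cfg.sampling_frequency
    blink_len = int(round(cfg.blink_duration * cfg.sampling_frequency))
    if cfg.blink_rate == 0 or blink_len == 0:
        return np.empty(0, dtype=int)
    if cfg.blink_mode == "deterministic":
        n_blinks = int(round(cfg.blink_rate * duration / 60.0))
        if n_blinks == 0:
            return np.empty(0, dtype=int)
        spacing = n_total / n_blinks
        starts = np.floor(np.arange(n_blinks) * spacing
                          + (spacing - blink_len) / 2.0).astype(int)
        return np.clip(starts, 0, max(0, n_total - blink_len))
    n_blinks = rng.poisson(cfg.blink_rate * duration / 60.0)
    if n_blinks == 0:
        return np.empty(0, dtype=int)
    latest = max(0, n_total - blink_len)
    return np.sort(rng.integers(0, latest + 1, size=n_blinks))


def generate_validation_recording(
        cfg: SyntheticConfig) -> tuple[ValidationRecording, GroundTruth]:
    """Simulate one validation session.

    Identical configurations (including ``random_seed``) produce
    bit-identical recordings.
    """
    rng = np.random.default_rng(cfg.random_seed)
    fs = cfg.sampling_frequency
    n_int = int(round(cfg.interval_duration * fs))
    n_fl = int(round(cfg.flight_duration * fs))
    order = [int(i) for i in rng.permutation(len(cfg.target_grid))]

    tid_parts, tx_parts, ty_parts, base_x, base_y = [], [], [], [], []
    prev: AngularPosition | None = None
    for idx in order:
        tgt = cfg.target_grid[idx]
        if prev is not None and n_fl > 0:
            frac = np.linspace(0.0, 1.0, n_fl, endpoint=False)
            base_x.append(prev.azimuth + frac * (tgt.azimuth - prev.azimuth))
            base_y.append(prev.elevation + frac * (tgt.elevation - prev.elevation))
            tid_parts.append(np.full(n_fl, TARGET_SENTINEL))
            tx_parts.append(np.full(n_fl, np.nan))
            ty_parts.append(np.full(n_fl, np.nan))
        base_x.append(np.full(n_int, tgt.azimuth))
        base_y.append(np.full(n_int, tgt.elevation))
        tid_parts.append(np.full(n_int, idx))
        tx_parts.append(np.full(n_int, tgt.azimuth))
        ty_parts.append(np.full(n_int, tgt.elevation))
        prev = tgt

    base_x = np.concatenate(base_x)
    base_y = np.concatenate(base_y)
    target_id = np.concatenate(tid_parts).astype(int)
    tar_x = np.concatenate(tx_parts)
    tar_y = np.concatenate(ty_parts)
    n_total = base_x.size
    timestamps = np.arange(n_total) / fs

    data = {"timestamp": timestamps}
    for eye in cfg.eyes:
        noise_x = rng.normal(0.0, cfg.noise_sigma, n_total)
        noise_y = rng.normal(0.0, cfg.noise_sigma, n_total)
        data[f"{eye}_x"] = base_x + cfg.offset.azimuth + noise_x
        data[f"{eye}_y"] = base_y + cfg.offset.elevation + noise_y

    invalid = np.zeros(n_total, dtype=bool)
    blink_len = int(round(cfg.blink_duration * fs))
    for start in _blink_starts(cfg, n_total, rng):
        invalid[start:start + blink_len] = True
    for eye in cfg.eyes:  # a blink closes both eyes
        data[f"{eye}_x"][invalid] = np.nan
        data[f"{eye}_y"][invalid] = np.nan

    data["target_id"] = target_id
    data["tar_x"] = tar_x
    data["tar_y"] = tar_y
    rec = ValidationRecording(samples=pd.DataFrame(data), units="degrees",
                              nominal_frequency=fs)

    in_measurement = target_id != TARGET_SENTINEL
    per_target_n = {idx: int(np.count_nonzero(target_id == idx))
                    for idx in order}
    per_target_bad = {idx: int(np.count_nonzero(invalid & (target_id == idx)))
                      for idx in order}
    n_meas = int(np.count_nonzero(in_measurement))
    n_meas_bad = int(np.count_nonzero(invalid & in_measurement))
    truth = GroundTruth(
        offset_azimuth=cfg.offset.azimuth,
        offset_elevation=cfg.offset.elevation,
        noise_sigma=cfg.noise_sigma,
        target_order=order,
        n_samples_total=n_total,
        n_invalid_total=int(np.count_nonzero(invalid)),
        loss_pct_overall=100.0 * np.count_nonzero(invalid) / n_total,
        per_target_n_samples=per_target_n,
        per_target_n_invalid=per_target_bad,
        loss_pct_measurement=100.0 * n_meas_bad / n_meas,
    )
    return rec, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground truth as a JSON sidecar file."""
    with open(path, "w", encoding="utf-8") as f:
        json.dump(asdict(truth), f, indent=2)


def write_session(cfg: SyntheticConfig, tsv_path: str | Path,
                  truth_path: str | Path | None = None
                  ) -> tuple[ValidationRecording, GroundTruth]:
    """Generate a session and write the TSV plus its ground-truth sidecar."""
    rec, truth = generate_validation_recording(cfg)
    write_validation_file(rec, tsv_path)
    if truth_path is not None:
        write_ground_truth(truth, truth_path)
    return rec, truth
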