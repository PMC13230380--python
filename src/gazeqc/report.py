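"""Across-recording aggregation and publication-ready report text.

Each recording's quality table is first reduced to a single value per
measure (mean over eyes and fixation targets, ignoring NaN); the per-measure
mean, standard deviation and range across recordings are then collected in a
:class:`SummaryStats`, from which a ready-to-paste report paragraph is
rendered.

Note on conventions: the across-recording standard deviation here uses the
sample (n-1) normalisation, since it describes a sample of recordings, while
the STD precision measure inside each recording uses population (1/n)
normalisation, since it describes the spread of a complete signal segment.
Printed values are rounded half-even at the printed precision: inaccuracy to
2 decimals, RMS-S2S/STD precision to 3, data loss to 1 decimal with a
trailing ".0" dropped, and frequency to integer Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SummaryStats", "summarize_quality_tables",
           "report_data_quality_text", "MEASURES"]

MEASURES = ["accuracy_deg", "rms_s2s_deg", "rms_s2s_median_deg", "std_deg",
            "bcea_deg2", "data_loss_pct", "effective_frequency_hz"]


@dataclass
class SummaryStats:
    """Per-measure mean/STD/min/max across a set of recordings.

    ``stats`` is indexed by measure name with columns ``mean``, ``std``,
    ``min``, ``max``.
    """

    stats: pd.DataFrame
    n_recordings: int

    def __getitem__(self, measure: str) -> pd.Series:
        return self.stats.loc[measure]

    def to_csv(self, path) -> None:
        self.stats.rename_axis("measure").to_csv(path)


def summarize_quality_tables(tables: list[pd.DataFrame]) -> SummaryStats:
    """Aggregate per-recording quality tables into across-recording statistics.

    Each table is reduced to one value per measure (NaN-ignoring mean over
    its eye x target rows) before computing the across-recording mean,
    sample standard deviation (0 for a single recording) and range.
    """
    if not tables:
        raise ValueError("need at least one quality table to summarize")
    per_recording = []
    for table in tables:
        row = {}
        for m in MEASURES:
            vals = table[m].to_numpy(dtype=float) if m in table.columns else []
            row[m] = float(np.nanmean(vals)) if np.isfinite(vals).any() \
                else float("nan")
        per_recording.append(row)
    df = pd.DataFrame(per_recording, columns=MEASURES)
    stats = pd.DataFrame({
        "mean": df.mean(),
        "std": df.std(ddof=1) if len(df) > 1 else pd.Series(0.0, index=MEASURES),
        "min": df.min(),
        "max": df.max(),
    })
    return SummaryStats(stats=stats, n_recordings=len(tables))


def _fmt(x: float, decimals: int) -> str:
    """Format at fixed precision (IEEE round-half-even via float formatting)."""
    return f"{x:.{decimals}f}"


def _fmt_pct(x: float) -> str:
    """Data-loss percentage: one decimal, trailing '.0' dropped."""
    s = f"{x:.1f}"
    return s[:-2] if s.endswith(".0") else s


def _fmt_hz(x: float) -> str:
    return f"{x:.0f}"


def _triplet(s: pd.Series, fmt, unit: str) -> str:
    return (f"{fmt(s['mean'])}{unit} (STD {fmt(s['std'])}{unit}, "
            f"range {fmt(s['min'])}{unit}–{fmt(s['max'])}{unit})")


def report_data_quality_text(summary: SummaryStats) -> str:
    """Render the report paragraph for a set of validation recordings.

    The sentences follow the customary reporting phrasing for eye-tracking
    data quality, e.g. inaccuracy as "0.80° (STD 0.28°, range 0.46°–1.11°)".
    The tool and version are cited so readers know how the values were
    derived.
    """
    from . import __version__

    s = summary.stats
    deg = "°"
    acc = _triplet(s.loc["accuracy_deg"], lambda x: _fmt(x, 2), deg)
    rms = _triplet(s.loc["rms_s2s_deg"], lambda x: _fmt(x, 3), deg)
    std_ = _triplet(s.loc["std_deg"], lambda x: _fmt(x, 3), deg)
    loss = _triplet(s.loc["data_loss_pct"], _fmt_pct, "%")
    freq = _triplet(s.loc["effective_frequency_hz"], _fmt_hz, " Hz")
    n = summary.n_recordings
    return (
        f"For {n} recording(s), the average inaccuracy of the gaze data, "
        f"determined from a validation procedure using gazeqc {__version__}, "
        f"was {acc}. Average RMS-S2S precision was {rms} and STD precision "
        f"{std_}. The average data loss was {loss}. The average effective "
        f"frequency was {freq}."
    )
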