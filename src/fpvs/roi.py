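"""ROI aggregation, significance flags and group summary tables.

Channel-level summed-harmonic z-scores are averaged over the three a-priori
electrode clusters (MO, LOP, ROP), flagged against the one-tailed 1.64
criterion, and collected into a tidy long-format table: one row per
participant x notation x condition x ROI x target, plus group rows holding
the mean and standard error over participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import ROI_CHANNELS
from .spectral import SIGNIFICANCE_Z, ZScoreResult

__all__ = ["ROIDef", "DEFAULT_ROIS", "roi_zscore", "channel_z_to_rows",
           "significance_flags", "group_summary"]


@dataclass(frozen=True)
class ROIDef:
    name: str
    channels: tuple[str, ...]


DEFAULT_ROIS = tuple(ROIDef(name, chans) for name, chans in ROI_CHANNELS.items())


def roi_zscore(result: ZScoreResult, roi: ROIDef) -> float:
    """Unweighted mean of the ROI channels' z values.

    z is computed per channel first and averaged after — the aggregation
    order behind "averaged z-scores" summaries. Raises if an ROI channel is
    absent from the result.
    """
    if result.channel_labels is None:
        raise ValueError("ZScoreResult carries no channel labels")
    index = {lab: i for i, lab in enumerate(result.channel_labels)}
    vals = []
    for ch in roi.channels:
        if ch not in index:
            raise KeyError(f"ROI {roi.name} channel {ch!r} missing from result")
        vals.append(result.z[index[ch]])
    return float(np.mean(vals))


def roi_zscore_on_segments(segments, hset, roi: ROIDef, channel_labels, win=None):
    """Alternative aggregation order: average the summed segments over the ROI
    channels, then z-score once (sensitivity analysis; not the default)."""
    from .spectral import NoiseWindowSpec, harmonic_zscore

    win = win or NoiseWindowSpec()
    index = {lab: i for i, lab in enumerate(channel_labels)}
    rows = [index[ch] for ch in roi.channels]
    seg = np.asarray(segments)[rows].mean(axis=0, keepdims=True)
    return float(harmonic_zscore(seg, hset, win=win).z[0])


def channel_z_to_rows(result: ZScoreResult, participant, notation, condition,
                      rois=DEFAULT_ROIS) -> list[dict]:
    """One tidy row per ROI for a channel-level z result."""
    return [
        {"participant": participant, "notation": notation, "condition": condition,
         "roi": roi.name, "target": result.target,
         "z": roi_zscore(result, roi)}
        for roi in rois
    ]


def significance_flags(table: pd.DataFrame, criterion: float = SIGNIFICANCE_Z) -> pd.DataFrame:
    """Add a boolean ``significant`` column: z strictly greater than 1.64."""
    out = table.copy()
    out["significant"] = out["z"] > criterion
    return out


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean z and standard error over participants per
    (notation, condition, roi, target) cell.

    SE = sd / sqrt(n) with the sample sd; with a single participant the SE
    is reported as NaN (unavailable).
    """
    grouped = table.groupby(["notation", "condition", "roi", "target"], sort=True)["z"]
    summary = grouped.agg(mean_z="mean", n="count",
                          sd=lambda x: x.std(ddof=1)).reset_index()
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    summary.loc[summary["n"] < 2, "se"] = np.nan
    summary["significant"] = summary["mean_z"] > SIGNIFICANCE_Z
    return summary.drop(columns="sd")
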