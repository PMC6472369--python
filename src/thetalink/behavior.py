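"""Behavioral metrics and LFP-alignment epochs.

Covers the three tasks the pipeline analyses: rewarded-alternation T-maze
performance and decision-zone windows, open-field locomotion binning, and
Y-maze arm bouts with the spatial novelty preference ratio (novel-arm time /
total goal-arm time over the first minute of the test phase, chance = 0.5).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from shapely import contains_xy
from shapely.geometry import Polygon

from .dataio import EpochTable, TrackingTrace, ValidationError

logger = logging.getLogger("thetalink")

__all__ = [
    "swm_performance",
    "decision_epochs",
    "locomotion_bins",
    "arm_bouts",
    "preference_ratio",
    "speed_control",
    "CHANCE_PREFERENCE",
]

CHANCE_PREFERENCE = 0.5  # reference line for preference-ratio plots


def swm_performance(
    trials: pd.DataFrame, last_blocks: int | None = None
) -> tuple[pd.Series, float]:
    """Fraction of correct choice runs per block, plus a block average.

    ``last_blocks`` restricts the average to the final k blocks (the usual
    summary is the mean over the last four testing blocks).
    """
    if len(trials) < 1:
        raise ValidationError("need at least one trial")
    per_block = trials.groupby("block")["correct"].mean()
    blocks = per_block if last_blocks is None else per_block.iloc[-last_blocks:]
    return per_block, float(blocks.mean())


def decision_epochs(trials: pd.DataFrame, window_s: float = 1.2) -> EpochTable:
    """One [exit - window, exit) epoch per phase per trial.

    Exits earlier than ``window_s`` after session start cannot host a full
    window and are skipped with a warning.
    """
    rows = []
    for tr in trials.itertuples(index=False):
        for phase, exit_t in (
            ("sample", tr.sample_exit_s),
            ("choice", tr.choice_exit_s),
        ):
            if exit_t < window_s:
                logger.warning(
                    "trial %s %s exit at %.2f s precedes a full %.1f s window; "
                    "skipped",
                    tr.trial_id,
                    phase,
                    exit_t,
                    window_s,
                )
                continue
            rows.append((exit_t - window_s, exit_t, "decision", tr.trial_id, phase))
    return EpochTable(
        pd.DataFrame(rows, columns=["onset", "offset", "label", "trial_id", "phase"])
    )


def locomotion_bins(
    track: TrackingTrace, bin_s: float = 60.0
) -> tuple[pd.Series, float, pd.DataFrame]:
    """Distance per time bin, total distance, and a speed series.

    Distance is the sum of Euclidean steps whose *starting* sample falls in
    the bin; speed is step length over step time, median-filtered over three
    samples to suppress tracking jitter.
    """
    if len(track) < 2:
        raise ValidationError("need at least two tracking samples")
    t = track.t
    xy = track.xy
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(t)
    speed = steps / dt
    if speed.size >= 3:
        speed = medfilt(speed, 3)
    bin_idx = np.floor((t[:-1] - t[0]) / bin_s).astype(int)
    dist = pd.Series(steps).groupby(bin_idx).sum()
    dist.index = dist.index * bin_s + t[0]
    dist.index.name = "bin_onset"
    speed_df = pd.DataFrame({"t": t[:-1], "speed": speed})
    return dist, float(steps.sum()), speed_df


def _as_polygon(poly) -> Polygon:
    return poly if isinstance(poly, Polygon) else Polygon(np.asarray(poly))


def arm_bouts(
    track: TrackingTrace,
    arm_polygons: dict[str, object],
    min_bout_s: float = 1.0,
) -> pd.DataFrame:
    """Maximal runs of consecutive samples inside one arm polygon.

    Samples inside no polygon are labelled "none" and break bouts.  Runs
    shorter than ``min_bout_s`` are discarded (tracking jitter).  Returns a
    frame (onset, offset, arm, mean_speed) with non-overlapping bouts.
    """
    t = track.t
    xy = track.xy
    labels = np.full(len(track), "none", dtype=object)
    for name, poly in arm_polygons.items():
        inside = contains_xy(_as_polygon(poly), xy[:, 0], xy[:, 1])
        labels[inside] = name
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(t)
    rows = []
    start = 0
    median_dt = float(np.median(dt))
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            if labels[start] != "none":
                onset = t[start]
                offset = t[i] if i < len(labels) else t[-1] + median_dt
                if offset - onset >= min_bout_s:
                    seg = slice(start, min(i, len(steps)))
                    sp = steps[seg] / dt[seg]
                    rows.append(
                        (onset, offset, labels[start],
                         float(sp.mean()) if sp.size else np.nan)
                    )
            start = i
    return pd.DataFrame(rows, columns=["onset", "offset", "arm", "mean_speed"])


def preference_ratio(
    bouts: pd.DataFrame,
    window: tuple[float, float] = (0.0, 60.0),
    novel_label: str = "novel",
    familiar_label: str = "familiar",
) -> float:
    """Novel-arm seconds / (novel + familiar seconds) within a window.

    Bouts are intersected with the half-open window.  Returns NaN when no
    goal-arm time falls inside the window (undefined, reported missing).
    """
    lo, hi = window
    times = {novel_label: 0.0, familiar_label: 0.0}
    for b in bouts.itertuples(index=False):
        if b.arm not in times:
            continue
        overlap = min(b.offset, hi) - max(b.onset, lo)
        if overlap > 0:
            times[b.arm] += overlap
    total = times[novel_label] + times[familiar_label]
    if total <= 0:
        logger.warning("no goal-arm time in window [%s, %s); ratio undefined", lo, hi)
        return float("nan")
    return times[novel_label] / total


def speed_control(bouts: pd.DataFrame) -> pd.Series:
    """Mean running speed per arm (duration-weighted across bouts).

    Arms with no bouts are simply absent; callers decide how to propagate
    missing values into paired tests.
    """
    if bouts.empty:
        return pd.Series(dtype=float, name="mean_speed")
    d = bouts.assign(dur=bouts["offset"] - bouts["onset"])
    out = d.groupby("arm").apply(
        lambda g: float(np.average(g["mean_speed"], weights=g["dur"])),
        include_groups=False,
    )
    out.name = "mean_speed"
    return out
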