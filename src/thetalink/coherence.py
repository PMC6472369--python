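"""Multitaper magnitude coherence between two channels.

Coherence is reported in the magnitude convention |C(f)| =
|Sxy| / sqrt(Sxx * Syy) (the Chronux ``coherencyc`` convention), *not* the
squared coherence; an analytic squared-coherence oracle must therefore be
square-rooted before comparison.  Cross- and auto-spectra are averaged over
tapers and sliding windows before normalization, so pooling epochs weights
each window equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import EpochTable, TimeSeriesRecording, ValidationError
from .spectral import band_summary, tapered_ffts

logger = logging.getLogger("thetalink")

__all__ = [
    "CoherenceEstimate",
    "Coherogram",
    "multitaper_coherence",
    "coherogram",
    "band_coherence",
    "fractional_change",
    "binned_coherence",
    "first_last_bins",
    "epoch_coherence",
]


@dataclass
class CoherenceEstimate:
    """Magnitude coherence spectrum with degrees-of-freedom bookkeeping."""

    frequencies: np.ndarray
    coherence: np.ndarray  # |C(f)| in [0, 1]
    window_s: float
    nw: float
    k: int
    n_windows: int

    @property
    def dof(self) -> int:
        """Nominal degrees of freedom, 2 * windows * tapers."""
        return 2 * self.n_windows * self.k


@dataclass
class Coherogram:
    times: np.ndarray  # bin centers, s
    frequencies: np.ndarray
    coherence: np.ndarray  # [time x freq]
    window_s: float
    bin_s: float
    nw: float
    k: int


def _coherence_from_ffts(Ja: np.ndarray, Jb: np.ndarray) -> np.ndarray:
    sab = (Ja * np.conj(Jb)).mean(axis=(0, 1))
    saa = (np.abs(Ja) ** 2).mean(axis=(0, 1))
    sbb = (np.abs(Jb) ** 2).mean(axis=(0, 1))
    denom = np.sqrt(saa * sbb)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(sab) / denom
    return np.clip(np.nan_to_num(c), 0.0, 1.0)


def multitaper_coherence(
    rec: TimeSeriesRecording,
    ch_a: str,
    ch_b: str,
    window_s: float = 2.0,
    step_s: float = 0.5,
    nw: float = 3.0,
    k: int = 5,
) -> CoherenceEstimate:
    """Magnitude coherence between two channels of one recording."""
    if ch_a not in rec.channel_names or ch_b not in rec.channel_names:
        raise ValidationError("both channels must be present in the recording")
    fa, Ja = tapered_ffts(rec.channel(ch_a), rec.fs, window_s, step_s, nw, k)
    _, Jb = tapered_ffts(rec.channel(ch_b), rec.fs, window_s, step_s, nw, k)
    coh = _coherence_from_ffts(Ja, Jb)
    return CoherenceEstimate(fa, coh, window_s, nw, k, Ja.shape[0])


def band_coherence(
    est: CoherenceEstimate, band: tuple[float, float]
) -> tuple[float, float, float]:
    """(mean, peak, peak_frequency) of coherence within a band."""
    return band_summary(est.frequencies, est.coherence, band)


def fractional_change(choice_value: float, sample_value: float) -> float:
    """(choice - sample) / sample; undefined for non-positive sample values."""
    if not sample_value > 0:
        raise ValidationError("fractional change undefined for sample value <= 0")
    return (choice_value - sample_value) / sample_value


def binned_coherence(
    rec: TimeSeriesRecording,
    ch_a: str,
    ch_b: str,
    band: tuple[float, float],
    bin_s: float = 10.0,
    window_s: float = 2.0,
    step_s: float = 0.5,
    nw: float = 3.0,
    k: int = 5,
    band_label: str = "",
) -> pd.DataFrame:
    """Coherence within non-overlapping time bins, summarised per band.

    Returns a tidy frame (bin_onset, bin_offset, band, metric, value) with
    mean_coherence, peak_coherence and peak_frequency per bin; the trailing
    partial bin is dropped.
    """
    if bin_s < window_s:
        raise ValidationError("bin_s must be at least one analysis window")
    n_bins = int(np.floor(rec.duration / bin_s + 1e-9))
    rows = []
    for b in range(n_bins):
        lo = rec.t0 + b * bin_s
        seg = rec.slice(lo, lo + bin_s)
        est = multitaper_coherence(seg, ch_a, ch_b, window_s, step_s, nw, k)
        mean_c, peak_c, peak_f = band_coherence(est, band)
        for metric, value in (
            ("mean_coherence", mean_c),
            ("peak_coherence", peak_c),
            ("peak_frequency", peak_f),
        ):
            rows.append((lo, lo + bin_s, band_label, metric, value))
    return pd.DataFrame(
        rows, columns=["bin_onset", "bin_offset", "band", "metric", "value"]
    )


def first_last_bins(binned: pd.DataFrame, metric: str) -> tuple[float, float]:
    """(first-bin, last-bin) values of one metric from a binned table."""
    sel = binned[binned["metric"] == metric].sort_values("bin_onset")
    if sel.empty:
        raise ValidationError(f"no rows for metric {metric!r}")
    return float(sel["value"].iloc[0]), float(sel["value"].iloc[-1])


def coherogram(
    rec: TimeSeriesRecording,
    ch_a: str,
    ch_b: str,
    bin_s: float = 10.0,
    window_s: float = 2.0,
    step_s: float = 0.5,
    nw: float = 3.0,
    k: int = 5,
) -> Coherogram:
    """Coherence spectra on a uniform time-bin grid."""
    if bin_s < window_s:
        raise ValidationError("bin_s must be at least one analysis window")
    n_bins = int(np.floor(rec.duration / bin_s + 1e-9))
    rows, times = [], []
    freqs = None
    for b in range(n_bins):
        lo = rec.t0 + b * bin_s
        est = multitaper_coherence(
            rec.slice(lo, lo + bin_s), ch_a, ch_b, window_s, step_s, nw, k
        )
        freqs = est.frequencies
        rows.append(est.coherence)
        times.append(lo + bin_s / 2.0)
    return Coherogram(
        np.asarray(times), freqs, np.vstack(rows), window_s, bin_s, nw, k
    )


def epoch_coherence(
    rec: TimeSeriesRecording,
    epochs: EpochTable,
    ch_a: str,
    ch_b: str,
    window_s: float = 2.0,
    step_s: float = 0.5,
    nw: float = 3.0,
    k: int = 5,
    short_nw: float = 2.0,
    short_k: int = 3,
    min_epoch_s: float = 0.5,
    label_field: str = "auto",
) -> dict[str, CoherenceEstimate]:
    """Per-label pooled coherence across epochs.

    Tapered FFT coefficients from all windows of all epochs sharing a label
    are pooled *before* normalization, so short bouts contribute
    proportionally to their duration.  Epochs shorter than the window get a
    single epoch-length window with the reduced taper family.  Labels with no
    usable epoch are absent from the result (missing, not zero).
    """
    pools: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    meta: dict[str, list[int]] = {}
    for row in epochs:
        dur = row.offset - row.onset
        if label_field == "auto":
            label = row.phase if isinstance(row.phase, str) else row.label
        else:
            label = getattr(row, label_field)
        if dur < min_epoch_s - 1e-9:
            logger.warning("skipping short epoch [%.3f, %.3f)", row.onset, row.offset)
            continue
        seg = rec.slice(row.onset, row.offset)
        if dur < window_s:
            w, s, nw_, k_ = dur, dur, short_nw, short_k
        else:
            w, s, nw_, k_ = window_s, step_s, nw, k
        # zero-pad short-epoch windows onto the standard frequency grid so
        # bouts of unequal length pool into one estimate
        nfft = int(round(window_s * seg.fs))
        fa, Ja = tapered_ffts(seg.channel(ch_a), seg.fs, w, s, nw_, k_, nfft=nfft)
        _, Jb = tapered_ffts(seg.channel(ch_b), seg.fs, w, s, nw_, k_, nfft=nfft)
        pools.setdefault(str(label), []).append((fa, Ja, Jb))
        meta.setdefault(str(label), []).append(Ja.shape[0])

    out: dict[str, CoherenceEstimate] = {}
    for label, items in pools.items():
        ks = {j.shape[1] for _, j, _ in items}
        if len(ks) == 1:
            Ja = np.concatenate([j for _, j, _ in items], axis=0)
            Jb = np.concatenate([j for _, _, j in items], axis=0)
            n_win, k_used = Ja.shape[0], Ja.shape[1]
        else:
            # mixed taper counts (short + long epochs): pool window-taper
            # products individually
            Ja = np.concatenate(
                [j.reshape(-1, j.shape[2]) for _, j, _ in items], axis=0
            )[:, None, :]
            Jb = np.concatenate(
                [j.reshape(-1, j.shape[2]) for _, _, j in items], axis=0
            )[:, None, :]
            n_win, k_used = Ja.shape[0], 1
        coh = _coherence_from_ffts(Ja, Jb)
        freqs = items[0][0]
        out[label] = CoherenceEstimate(
            freqs, coh, float(window_s), nw, k_used, n_win
        )
    return out
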