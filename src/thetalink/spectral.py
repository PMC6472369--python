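"""Multitaper power spectra, spectrograms and band summaries.

Direct spectral estimates use Slepian (DPSS) tapers averaged over tapers and
sliding windows.  Densities are one-sided, scaled so that integrating the PSD
over [0, Nyquist] recovers the signal variance (Parseval).  Band summaries
report mean power, peak power and peak frequency with ties broken toward the
lowest frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss

from .dataio import EpochTable, TimeSeriesRecording, ValidationError

logger = logging.getLogger("thetalink")

__all__ = [
    "SpectralEstimate",
    "Spectrogram",
    "multitaper_psd",
    "spectrogram",
    "band_summary",
    "binned_band_metrics",
    "peak_variability_cv",
    "epoch_psd",
]


@dataclass
class SpectralEstimate:
    """One-sided multitaper PSD with estimator metadata."""

    frequencies: np.ndarray
    power: np.ndarray  # units^2 / Hz
    window_s: float
    nw: float
    k: int
    n_windows: int
    channel: str = ""


@dataclass
class Spectrogram:
    """Per-window PSDs on a uniform time grid (window-center convention)."""

    times: np.ndarray  # window centers, s
    frequencies: np.ndarray
    power: np.ndarray  # [time x freq]
    window_s: float
    step_s: float
    nw: float
    k: int
    channel: str = ""


def _window_starts(n: int, nper: int, nstep: int) -> np.ndarray:
    if nper > n:
        raise ValidationError("analysis window longer than the signal")
    return np.arange(0, n - nper + 1, nstep)


@lru_cache(maxsize=32)
def _dpss_cached(nper: int, nw: float, k: int) -> np.ndarray:
    return dpss(nper, nw, k)


def tapered_ffts(
    x: np.ndarray,
    fs: float,
    window_s: float,
    step_s: float,
    nw: float,
    k: int,
    nfft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window tapered Fourier coefficients.

    Returns (frequencies, J) with J shaped (n_windows, k, n_freq).  Each
    window is demeaned before tapering; tapers have unit energy so
    E|J|^2 equals the process variance for white input.  ``nfft`` >= window
    length zero-pads every window onto a common frequency grid (used when
    pooling epochs of unequal length).
    """
    x = np.asarray(x, dtype=np.float64)
    nper = int(round(window_s * fs))
    nstep = max(int(round(step_s * fs)), 1)
    if k < 1 or k > int(2 * nw - 1):
        raise ValidationError("need 1 <= K <= 2*NW - 1")
    nfft = max(nfft or 0, nper)
    starts = _window_starts(x.size, nper, nstep)
    segs = sliding_window_view(x, nper)[starts]  # (n_win, nper)
    segs = segs - segs.mean(axis=1, keepdims=True)
    tapers = _dpss_cached(nper, float(nw), int(k))  # (k, nper), unit energy
    tapered = segs[:, None, :] * tapers[None, :, :]
    J = np.fft.rfft(tapered, n=nfft, axis=-1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, J


def _psd_from_ffts(J: np.ndarray, fs: float, nper: int) -> np.ndarray:
    """One-sided PSD averaged over windows and tapers."""
    p = (np.abs(J) ** 2).mean(axis=(0, 1)) / fs
    scale = np.full(p.shape, 2.0)
    scale[0] = 1.0
    if nper % 2 == 0:
        scale[-1] = 1.0
    return p * scale


def multitaper_psd(
    rec: TimeSeriesRecording,
    channel: str,
    window_s: float = 2.0,
    step_s: float = 0.5,
    nw: float = 3.0,
    k: int = 5,
    nfft: int | None = None,
) -> SpectralEstimate:
    """Multitaper PSD of one channel, averaged over tapers and windows."""
    x = rec.channel(channel)
    freqs, J = tapered_ffts(x, rec.fs, window_s, step_s, nw, k, nfft=nfft)
    nper = max(nfft or 0, int(round(window_s * rec.fs)))
    power = _psd_from_ffts(J, rec.fs, nper)
    return SpectralEstimate(freqs, power, window_s, nw, k, J.shape[0], channel)


def spectrogram(
    rec: TimeSeriesRecording,
    channel: str,
    window_s: float = 2.0,
    step_s: float = 0.5,
    nw: float = 3.0,
    k: int = 5,
) -> Spectrogram:
    """Time-resolved multitaper PSD (one column per sliding window)."""
    x = rec.channel(channel)
    nper = int(round(window_s * rec.fs))
    nstep = max(int(round(step_s * rec.fs)), 1)
    freqs, J = tapered_ffts(x, rec.fs, window_s, step_s, nw, k)
    p = (np.abs(J) ** 2).mean(axis=1) / rec.fs  # (n_win, n_freq)
    scale = np.full(p.shape[1], 2.0)
    scale[0] = 1.0
    if nper % 2 == 0:
        scale[-1] = 1.0
    starts = _window_starts(x.size, nper, nstep)
    times = rec.t0 + (starts + nper / 2.0) / rec.fs
    return Spectrogram(times, freqs, p * scale, window_s, step_s, nw, k, channel)


def band_summary(
    frequencies: np.ndarray, power: np.ndarray, band: tuple[float, float]
) -> tuple[float, float, float]:
    """(mean_power, peak_power, peak_frequency) over in-band samples.

    The band is inclusive at both edges; equal peak powers resolve to the
    lowest frequency.
    """
    f = np.asarray(frequencies)
    p = np.asarray(power)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise ValidationError(f"no frequency samples inside band ({lo}, {hi}) Hz")
    pin, fin = p[mask], f[mask]
    imax = int(np.argmax(pin))  # argmax returns the first (lowest-f) maximum
    return float(pin.mean()), float(pin[imax]), float(fin[imax])


def binned_band_metrics(
    sgram: Spectrogram, band: tuple[float, float], bin_s: float, band_label: str = ""
) -> pd.DataFrame:
    """Average spectrogram columns in non-overlapping bins, then summarise.

    Returns a tidy frame (bin_onset, bin_offset, band, metric, value) with
    metrics mean_power, peak_power and peak_frequency per bin.  A trailing
    partial bin is dropped.
    """
    if bin_s < sgram.step_s:
        raise ValidationError("bin_s must be >= spectrogram step")
    t_start = sgram.times[0] - sgram.window_s / 2.0  # session-relative origin
    span = (sgram.times[-1] + sgram.window_s / 2.0) - t_start
    n_bins = int(np.floor(span / bin_s + 1e-9))
    rows = []
    for b in range(n_bins):
        lo_t, hi_t = b * bin_s, (b + 1) * bin_s
        mask = (sgram.times - t_start >= lo_t) & (sgram.times - t_start < hi_t)
        if not mask.any():
            continue
        mean_p, peak_p, peak_f = band_summary(
            sgram.frequencies, sgram.power[mask].mean(axis=0), band
        )
        for metric, value in (
            ("mean_power", mean_p),
            ("peak_power", peak_p),
            ("peak_frequency", peak_f),
        ):
            rows.append((t_start + lo_t, t_start + hi_t, band_label, metric, value))
    return pd.DataFrame(
        rows, columns=["bin_onset", "bin_offset", "band", "metric", "value"]
    )


def peak_variability_cv(values) -> float:
    """Coefficient of variation (sample SD / mean) of per-bin values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("CV needs at least 2 bins")
    m = v.mean()
    if m == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m)


@dataclass
class EpochSpectra:
    """Per-epoch PSDs plus per-label means (label = phase when present)."""

    per_epoch: list[tuple[str, SpectralEstimate]]
    by_label: dict[str, SpectralEstimate]
    n_by_label: dict[str, int]


def epoch_psd(
    rec: TimeSeriesRecording,
    epochs: EpochTable,
    channel: str,
    window_s: float = 2.0,
    nw: float = 3.0,
    k: int = 5,
    short_nw: float = 2.0,
    short_k: int = 3,
    min_epoch_s: float = 0.5,
) -> EpochSpectra:
    """Per-epoch PSD with per-(phase|label) averaging.

    Epochs shorter than the analysis window are estimated with a single
    window spanning the whole epoch using the reduced taper family
    (NW=short_nw, K=short_k) — appropriate for 1.2-s decision windows where
    sliding averaging is impossible.  Epochs under ``min_epoch_s`` are
    skipped with a warning.
    """
    per_epoch: list[tuple[str, SpectralEstimate]] = []
    pools: dict[str, list[SpectralEstimate]] = {}
    for row in epochs:
        dur = row.offset - row.onset
        label = row.phase if isinstance(row.phase, str) else row.label
        if dur < min_epoch_s - 1e-9:
            logger.warning(
                "skipping epoch [%.3f, %.3f) %r: shorter than %.2f s",
                row.onset,
                row.offset,
                label,
                min_epoch_s,
            )
            continue
        seg = rec.slice(row.onset, row.offset)
        nfft = int(round(window_s * seg.fs))  # common grid across epoch lengths
        if dur < window_s:
            est = multitaper_psd(seg, channel, dur, dur, short_nw, short_k, nfft=nfft)
        else:
            est = multitaper_psd(
                seg, channel, window_s, window_s / 4.0, nw, k, nfft=nfft
            )
        per_epoch.append((str(label), est))
        pools.setdefault(str(label), []).append(est)

    by_label: dict[str, SpectralEstimate] = {}
    n_by_label: dict[str, int] = {}
    for label, ests in pools.items():
        n_f = {e.frequencies.size for e in ests}
        if len(n_f) != 1:
            raise ValidationError(
                f"epochs under label {label!r} have unequal window lengths; "
                "cannot average spectra on different frequency grids"
            )
        mean_p = np.mean([e.power for e in ests], axis=0)
        e0 = ests[0]
        by_label[label] = SpectralEstimate(
            e0.frequencies,
            mean_p,
            e0.window_s,
            e0.nw,
            e0.k,
            sum(e.n_windows for e in ests),
            channel,
        )
        n_by_label[label] = len(ests)
    return EpochSpectra(per_epoch, by_label, n_by_label)
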