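"""Theta-gamma phase-amplitude coupling.

The slow band's instantaneous phase and the fast band's instantaneous
amplitude come from zero-phase FIR band-pass filtering followed by the
analytic signal (Hilbert transform).  Coupling strength is the
Kullback-Leibler modulation index of Tort et al.: amplitudes are binned by
phase into 18 equal bins over (-pi, pi], the bin means are normalized to a
distribution P, and MI = (log N - H(P)) / log N, i.e. the KL divergence of P
from uniform scaled to [0, 1].  A mean-vector-length alternative is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin, hilbert

from .dataio import TimeSeriesRecording, ValidationError

logger = logging.getLogger("thetalink")

__all__ = [
    "PACResult",
    "bandpass_phase_amp",
    "modulation_index",
    "mean_vector_length",
    "pac_timecourse",
]


@dataclass
class PACResult:
    """Phase-binned amplitude distribution and modulation index."""

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    n_bins: int
    bin_amplitude: np.ndarray  # normalized to sum 1
    mi: float
    span_s: float
    bin_onset: float = 0.0
    n_cycles: float = float("nan")


def _fir_bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
                  transition_hz: float = 2.0) -> np.ndarray:
    lo, hi = band
    if hi + transition_hz >= fs / 2.0:
        raise ValidationError(f"band {band} too close to Nyquist ({fs / 2} Hz)")
    numtaps = int(round(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    if x.size < 3 * numtaps + 1:
        raise ValidationError("signal too short for the band-pass transient")
    taps = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    # a symmetric FIR delayed by (numtaps-1)/2 samples is exactly zero-phase,
    # so one FFT convolution plus shift replaces forward-backward filtering
    delay = (numtaps - 1) // 2
    padded = np.concatenate([x[:numtaps][::-1], x, x[-numtaps:][::-1]])
    y = fftconvolve(padded, taps, mode="full")
    start = numtaps + delay
    return y[start : start + x.size]


def bandpass_phase_amp(
    rec: TimeSeriesRecording,
    channel: str,
    phase_band: tuple[float, float] = (6.0, 12.0),
    amp_band: tuple[float, float] = (30.0, 48.0),
    edge_trim_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (slow band) and envelope (fast band).

    Both series are trimmed by ``edge_trim_s`` at each end to discard filter
    and Hilbert transients.  Phase 0 corresponds to the peak of the slow-band
    oscillation; values lie in (-pi, pi].
    """
    x = rec.channel(channel)
    slow = _fir_bandpass(x, rec.fs, phase_band)
    fast = _fir_bandpass(x, rec.fs, amp_band)
    phase = np.angle(hilbert(slow))
    amp = np.abs(hilbert(fast))
    trim = int(round(edge_trim_s * rec.fs))
    if 2 * trim >= x.size:
        raise ValidationError("recording shorter than twice the edge trim")
    sl = slice(trim, x.size - trim) if trim else slice(None)
    return phase[sl], amp[sl]


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18
) -> PACResult:
    """Tort KL-divergence modulation index of amplitude over phase bins.

    Empty phase bins contribute zero amplitude (0*log 0 = 0 in the entropy).
    MI is 0 for a phase-uniform amplitude and 1 when all amplitude mass falls
    in a single bin.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValidationError("phase and amplitude must have equal length")
    if not (amplitude > 0).any():
        raise ValidationError("all-zero amplitude series")
    # half-open bins (-pi, pi]: shift -pi itself into the last bin
    idx = np.ceil((phase + np.pi) / (2 * np.pi) * n_bins).astype(int) - 1
    idx = np.where(idx < 0, n_bins - 1, idx)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    p = means / means.sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    mi = (np.log(n_bins) - entropy) / np.log(n_bins)
    n_cycles = float(np.abs(np.unwrap(phase)[-1] - np.unwrap(phase)[0]) / (2 * np.pi))
    if n_cycles < 50:
        logger.warning("only %.1f phase cycles; MI estimate may be noisy", n_cycles)
    return PACResult(
        (float("nan"), float("nan")),
        (float("nan"), float("nan")),
        n_bins,
        p,
        float(mi),
        float("nan"),  # span unknown without a sampling rate; set by callers
        n_cycles=n_cycles,
    )


def mean_vector_length(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """Amplitude-normalized mean resultant vector length |<A e^{i phi}>|/<A>."""
    amplitude = np.asarray(amplitude, dtype=float)
    if not (amplitude > 0).any():
        raise ValidationError("all-zero amplitude series")
    return float(
        np.abs((amplitude * np.exp(1j * np.asarray(phase))).mean())
        / amplitude.mean()
    )


def pac_timecourse(
    rec: TimeSeriesRecording,
    channel: str,
    bin_s: float = 60.0,
    phase_band: tuple[float, float] = (6.0, 12.0),
    amp_band: tuple[float, float] = (30.0, 48.0),
    n_bins: int = 18,
    edge_trim_s: float = 1.0,
) -> list[PACResult]:
    """Modulation index in non-overlapping time bins (default 1 min).

    Filtering and the analytic signal are computed once over the whole
    recording (minimizing edge transients), then phase/amplitude samples are
    split into bins.  The trailing partial bin is dropped.
    """
    phase, amp = bandpass_phase_amp(rec, channel, phase_band, amp_band, edge_trim_s)
    fs = rec.fs
    n_per = int(round(bin_s * fs))
    # bins are positioned on the untrimmed session clock
    total = rec.n_samples
    n_bins_t = int(np.floor(total / n_per + 1e-9))
    if n_bins_t < 1:
        raise ValidationError("recording shorter than one PAC bin")
    trim = int(round(edge_trim_s * fs))
    out: list[PACResult] = []
    for b in range(n_bins_t):
        i0, i1 = b * n_per - trim, (b + 1) * n_per - trim
        i0, i1 = max(i0, 0), min(i1, phase.size)
        if i1 <= i0:
            continue
        res = modulation_index(phase[i0:i1], amp[i0:i1], n_bins)
        res.phase_band = tuple(phase_band)
        res.amp_band = tuple(amp_band)
        res.span_s = (i1 - i0) / fs
        res.bin_onset = rec.t0 + b * bin_s
        out.append(res)
    return out
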