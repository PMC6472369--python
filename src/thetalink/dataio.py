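"""Readers, writers and configuration for on-disk artifacts.

Recordings live in HDF5 (one file per session: ``/lfp`` matrix plus ``fs``,
``channel_names`` and ``t0`` attributes); epochs and tracking are
tab-separated text so they stay human-inspectable; analysis configuration is
YAML with explicit defaults.  All times are seconds, zero-based from the
recording start, and intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import signal

logger = logging.getLogger("thetalink")

__all__ = [
    "FormatError",
    "ValidationError",
    "TimeSeriesRecording",
    "EpochTable",
    "TrackingTrace",
    "AnalysisConfig",
    "DEFAULT_BANDS",
    "read_recording",
    "write_recording",
    "read_epochs",
    "write_epochs",
    "read_tracking",
    "write_tracking",
    "load_config",
    "downsample",
]


class FormatError(ValueError):
    """A file does not have the expected layout (missing dataset/column)."""


class ValidationError(ValueError):
    """Data violate an invariant (NaN samples, inverted epochs, ...)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesRecording:
    """Multi-channel LFP segment.

    samples : float array, shape (n_samples, n_channels), arbitrary units.
    fs : sampling rate in Hz.
    channel_names : unique labels, e.g. ("dHipp", "PFC").
    t0 : start time in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValidationError("samples must be a non-empty 2-D array")
        if not np.isfinite(self.samples).all():
            raise ValidationError("recording contains NaN/Inf samples")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValidationError("one channel name per column required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.samples[:, idx]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def slice(self, onset: float, offset: float) -> "TimeSeriesRecording":
        """Extract samples in [onset, offset) seconds (absolute times)."""
        i0 = int(round((onset - self.t0) * self.fs))
        i1 = int(round((offset - self.t0) * self.fs))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        if i1 <= i0:
            raise ValidationError("empty slice requested")
        return TimeSeriesRecording(
            self.samples[i0:i1], self.fs, self.channel_names, self.t0 + i0 / self.fs
        )


_EPOCH_COLUMNS = ["onset", "offset", "label", "trial_id", "phase"]
_VALID_PHASES = {"sample", "choice", "test", "habituation"}


class EpochTable:
    """Labelled half-open time intervals (trial phases, bouts, bins).

    Wraps a DataFrame with columns onset, offset, label and optional
    trial_id / phase.  Epochs sharing a (trial_id, phase) pair must not
    overlap; offsets must exceed onsets.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        for col in ("trial_id", "phase"):
            if col not in df.columns:
                df[col] = pd.NA
        missing = [c for c in ("onset", "offset", "label") if c not in df.columns]
        if missing:
            raise FormatError(f"epoch table missing columns: {missing}")
        df = df[_EPOCH_COLUMNS].reset_index(drop=True)
        df["onset"] = df["onset"].astype(float)
        df["offset"] = df["offset"].astype(float)
        if (df["offset"] <= df["onset"]).any():
            raise ValidationError("every epoch must satisfy offset > onset")
        bad_phase = df["phase"].dropna().map(lambda p: p not in _VALID_PHASES)
        if bad_phase.any():
            raise ValidationError(f"phase labels must be one of {_VALID_PHASES}")
        for (tid, ph), grp in df.dropna(subset=["trial_id", "phase"]).groupby(
            ["trial_id", "phase"]
        ):
            g = grp.sort_values("onset")
            if (g["onset"].values[1:] < g["offset"].values[:-1]).any():
                raise ValidationError(
                    f"overlapping epochs for trial {tid!r}, phase {ph!r}"
                )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        return iter(self.data.itertuples(index=False))

    def durations(self) -> np.ndarray:
        return (self.data["offset"] - self.data["onset"]).to_numpy()


class TrackingTrace:
    """Video-tracking positions: strictly increasing t (s), x/y in cm."""

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ("t", "x", "y") if c not in data.columns]
        if missing:
            raise FormatError(f"tracking table missing columns: {missing}")
        df = data[["t", "x", "y"]].astype(float).reset_index(drop=True)
        if not np.isfinite(df.to_numpy()).all():
            raise ValidationError("tracking contains non-finite values")
        if not (np.diff(df["t"].to_numpy()) > 0).all():
            raise ValidationError("tracking time must be strictly increasing")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy()


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (6.0, 12.0),
    "beta": (20.0, 30.0),
    "gamma": (30.0, 48.0),
}


@dataclass
class AnalysisConfig:
    """All tunables of the spectral/coherence/PAC pipeline.

    Defaults: 2-s windows stepped by 0.5 s, time-bandwidth NW = 3 with
    K = 5 Slepian tapers; 1.2-s decision windows analysed with a single
    window (NW = 2, K = 3); signals downsampled to 1 kHz before analysis.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    window_s: float = 2.0
    step_s: float = 0.5
    nw: float = 3.0
    k: int = 5
    decision_window_s: float = 1.2
    decision_nw: float = 2.0
    decision_k: int = 3
    bin_s: float = 10.0
    pac_phase_band: tuple[float, float] = (6.0, 12.0)
    pac_amp_band: tuple[float, float] = (30.0, 48.0)
    pac_n_bins: int = 18
    pac_bin_s: float = 60.0
    downsample_hz: float = 1000.0
    notch_50hz: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.downsample_hz / 2.0
        self.bands = {
            str(k): (float(v[0]), float(v[1])) for k, v in self.bands.items()
        }
        for name, (lo, hi) in list(self.bands.items()) + [
            ("pac_phase", tuple(self.pac_phase_band)),
            ("pac_amp", tuple(self.pac_amp_band)),
        ]:
            if not (0.0 < lo < hi < nyq):
                raise ValidationError(
                    f"band {name!r}=({lo}, {hi}) must satisfy 0 < lo < hi < "
                    f"Nyquist ({nyq} Hz)"
                )
        if not (self.window_s >= self.step_s > 0):
            raise ValidationError("need window_s >= step_s > 0")
        if self.k > int(2 * self.nw - 1):
            raise ValidationError("need K <= 2*NW - 1 tapers")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML/JSON config; absent keys fall back to the defaults.

    The effective configuration (after defaulting) is logged at INFO level so
    every run records exactly what it used.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise FormatError("config file must contain a mapping")
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    for key in ("bands",):
        if key in raw:
            raw[key] = {k: tuple(v) for k, v in raw[key].items()}
    for key in ("pac_phase_band", "pac_amp_band"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = AnalysisConfig(**raw)
    overridden = sorted(raw)
    if overridden:
        logger.info("config overrides: %s", overridden)
    logger.info("effective config hash %s: %s", cfg.config_hash(), asdict(cfg))
    return cfg


# ---------------------------------------------------------------------------
# recordings (HDF5)
# ---------------------------------------------------------------------------


def write_recording(path: str | Path, rec: TimeSeriesRecording) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("lfp", data=rec.samples)
        dset.attrs["fs"] = float(rec.fs)
        dset.attrs["channel_names"] = list(rec.channel_names)
        dset.attrs["t0"] = float(rec.t0)


def read_recording(path: str | Path) -> TimeSeriesRecording:
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise FormatError(f"{path}: missing /lfp dataset")
        dset = f["lfp"]
        for attr in ("fs", "channel_names", "t0"):
            if attr not in dset.attrs:
                raise FormatError(f"{path}: /lfp missing attribute {attr!r}")
        samples = dset[()]
        names = tuple(
            n.decode() if isinstance(n, bytes) else str(n)
            for n in dset.attrs["channel_names"]
        )
        return TimeSeriesRecording(
            samples, float(dset.attrs["fs"]), names, float(dset.attrs["t0"])
        )


# ---------------------------------------------------------------------------
# epochs / tracking (TSV)
# ---------------------------------------------------------------------------


def write_epochs(path: str | Path, epochs: EpochTable) -> None:
    epochs.data.to_csv(path, sep="\t", index=False)


def read_epochs(path: str | Path) -> EpochTable:
    df = pd.read_csv(path, sep="\t")
    return EpochTable(df)


def write_tracking(path: str | Path, track: TrackingTrace) -> None:
    track.data.to_csv(path, sep="\t", index=False)


def read_tracking(path: str | Path) -> TrackingTrace:
    df = pd.read_csv(path, sep="\t")
    return TrackingTrace(df)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def downsample(
    rec: TimeSeriesRecording,
    target_hz: float = 1000.0,
    antialias_hz: float | None = None,
) -> TimeSeriesRecording:
    """Anti-alias low-pass then decimate to ``target_hz``.

    The acquisition band of interest ends well below 400 Hz, so the default
    anti-alias corner is min(400 Hz, 0.4 * target).  Integer decimation
    factors keep samples on the original grid; non-integer ratios fall back
    to polyphase resampling.
    """
    if target_hz >= rec.fs:
        return rec
    corner = antialias_hz if antialias_hz is not None else min(400.0, 0.4 * target_hz)
    sos = signal.butter(8, corner, btype="low", fs=rec.fs, output="sos")
    low = signal.sosfiltfilt(sos, rec.samples, axis=0)
    ratio = rec.fs / target_hz
    if abs(ratio - round(ratio)) < 1e-9:
        out = low[:: int(round(ratio))]
        fs = rec.fs / int(round(ratio))
    else:
        from fractions import Fraction

        frac = Fraction(target_hz / rec.fs).limit_denominator(1000)
        out = signal.resample_poly(low, frac.numerator, frac.denominator, axis=0)
        fs = rec.fs * frac.numerator / frac.denominator
    return TimeSeriesRecording(out, fs, rec.channel_names, rec.t0)
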