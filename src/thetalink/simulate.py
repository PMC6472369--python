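"""Ground-truth synthetic sessions: paired dHipp/PFC LFP plus behavior.

No public recordings accompany the experimental design this pipeline
analyses, so every analysis stage is validated against sessions generated
here, where band power, inter-regional coherence, phase-amplitude coupling
depth, habituation time constants and behavioral preferences are all known
exactly.

The LFP model is a sum of shared narrowband sources plus independent
broadband noise:

    x_a(t) = sum_b g_ab * s_b(t) + n_a(t)

where each s_b is white noise passed through a zero-phase order-4 Butterworth
band-pass (so spectral peaks have realistic width) and n_a, n_b are
independent white noises.  The closed-form magnitude-squared coherence of
this model,

    C(f) = (g_a g_b P(f))^2 / ((g_a^2 P(f) + N_a)(g_b^2 P(f) + N_b)),

is exposed by :func:`analytic_coherence` and serves as the oracle for the
coherence estimators.  Theta-gamma coupling is injected as a gamma carrier
whose amplitude is modulated by the theta source's instantaneous phase,
giving a brute-force-computable modulation-index target.

All randomness flows from a single seed through named substreams (lfp,
behavior, outcomes), so identical specs and seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal import hilbert

from .dataio import EpochTable, TimeSeriesRecording, TrackingTrace, ValidationError

__all__ = [
    "BandSource",
    "SharedSourceSpec",
    "PACSpec",
    "HabituationProfile",
    "GroupSpec",
    "GroupStudySpec",
    "default_session_spec",
    "generate_lfp_pair",
    "analytic_coherence",
    "generate_open_field_session",
    "generate_tmaze_session",
    "generate_ymaze_session",
    "ymaze_arm_polygons",
    "habituation_cohort",
    "simulate_open_field_cohort",
]

_STREAMS = {"lfp": 0, "behavior": 1, "outcomes": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandSource:
    """One shared narrowband source.

    ``source_power`` is the one-sided PSD (units^2/Hz) of the source at its
    center frequency; ``gain_a``/``gain_b`` are the per-channel mixing gains.
    """

    center_hz: float
    bandwidth_hz: float
    source_power: float
    gain_a: float = 1.0
    gain_b: float = 1.0

    @property
    def band(self) -> tuple[float, float]:
        half = self.bandwidth_hz / 2.0
        return (self.center_hz - half, self.center_hz + half)


@dataclass(frozen=True)
class SharedSourceSpec:
    """Shared-source mixing model for a two-channel session."""

    bands: tuple[BandSource, ...]
    noise_power_a: float = 1.0  # one-sided PSD, units^2/Hz
    noise_power_b: float = 1.0

    def __post_init__(self):
        for b in self.bands:
            if b.source_power < 0 or b.band[0] <= 0:
                raise ValidationError("source powers must be >= 0, bands positive")
            if not (math.isfinite(b.gain_a) and math.isfinite(b.gain_b)):
                raise ValidationError("gains must be finite")
        if self.noise_power_a < 0 or self.noise_power_b < 0:
            raise ValidationError("noise powers must be >= 0")

    def theta_index(self) -> int | None:
        """Index of the band whose center is nearest 8 Hz (theta), if any."""
        if not self.bands:
            return None
        centers = [b.center_hz for b in self.bands]
        i = int(np.argmin([abs(c - 8.0) for c in centers]))
        return i if abs(centers[i] - 8.0) <= 6.0 else None


@dataclass(frozen=True)
class PACSpec:
    """Theta-phase modulated gamma carrier added to channel a (dHipp)."""

    f_theta: float = 8.0
    f_gamma: float = 40.0
    carrier_amp: float = 1.0
    depth: float = 0.5

    def __post_init__(self):
        if not self.f_gamma > self.f_theta:
            raise ValidationError("gamma frequency must exceed theta frequency")
        if not 0.0 <= self.depth <= 1.0:
            raise ValidationError("modulation depth must be in [0, 1]")


@dataclass(frozen=True)
class HabituationProfile:
    """Exponentially decaying theta amplitude; tau = inf means sustained."""

    initial_amplitude: float = 1.0
    decay_tau_s: float = math.inf

    def __post_init__(self):
        if self.initial_amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if not self.decay_tau_s > 0:
            raise ValidationError("decay constant must be positive (or inf)")

    def envelope(self, t: np.ndarray) -> np.ndarray:
        if math.isinf(self.decay_tau_s):
            return np.full_like(t, self.initial_amplitude, dtype=float)
        return self.initial_amplitude * np.exp(-t / self.decay_tau_s)


@dataclass(frozen=True)
class GroupSpec:
    """One virtual group: habituation profile plus behavior parameters."""

    label: str
    n_animals: int
    profile: HabituationProfile
    amplitude_cv: float = 0.1  # between-animal CV of theta amplitude
    pac: PACSpec | None = None
    swm_p_correct: float = 0.85
    preference: float = 0.8
    locomotion_cm_s: float = 8.0

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValidationError("each group needs at least one animal")
        if not 0.0 <= self.swm_p_correct <= 1.0:
            raise ValidationError("p_correct must be in [0, 1]")


@dataclass(frozen=True)
class GroupStudySpec:
    """Virtual cohort mirroring a WT / knockout / rescue design."""

    groups: tuple[GroupSpec, ...]
    duration_s: float = 300.0
    fs: float = 1000.0
    seed: int = 0


def default_session_spec(
    theta_power: float = 4.0,
    beta_power: float = 0.6,
    gamma_power: float = 0.3,
    noise_power: float = 1.0,
    pfc_gain: float = 0.7,
) -> SharedSourceSpec:
    """Typical two-channel session: a dominant theta peak plus weaker
    beta/gamma shared sources over broadband noise."""
    return SharedSourceSpec(
        bands=(
            BandSource(8.0, 4.0, theta_power, 1.0, pfc_gain),
            BandSource(25.0, 10.0, beta_power, 1.0, pfc_gain),
            BandSource(40.0, 14.0, gamma_power, 1.0, pfc_gain),
        ),
        noise_power_a=noise_power,
        noise_power_b=noise_power,
    )


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------


def _band_sos(band: tuple[float, float], fs: float):
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValidationError(f"band {band} outside (0, Nyquist) at fs={fs}")
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _source_series(
    bs: BandSource, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Narrowband Gaussian source with one-sided PSD ~source_power at center."""
    if bs.source_power == 0:
        return np.zeros(n)
    white = rng.standard_normal(n) * math.sqrt(bs.source_power * fs / 2.0)
    sos = _band_sos(bs.band, fs)
    return signal.sosfiltfilt(sos, white)


def generate_lfp_pair(
    spec: SharedSourceSpec,
    pac: PACSpec | None = None,
    duration_s: float = 300.0,
    fs: float = 1000.0,
    seed: int = 0,
    band_envelopes: dict[int, np.ndarray] | None = None,
    channel_names: tuple[str, str] = ("dHipp", "PFC"),
    min_windows_s: float = 4.0,
) -> TimeSeriesRecording:
    """Two-channel LFP with known shared-source coherence structure.

    ``band_envelopes`` optionally maps a band index to a per-sample amplitude
    multiplier (used for habituation decay, trial-phase coupling modulation
    and novelty gains).  Deterministic given spec + seed.
    """
    n = int(round(duration_s * fs))
    if duration_s < min_windows_s:
        raise ValidationError(
            f"duration {duration_s}s shorter than {min_windows_s}s "
            "(need at least two analysis windows)"
        )
    rng = _rng(seed, "lfp")
    a = rng.standard_normal(n) * math.sqrt(spec.noise_power_a * fs / 2.0)
    b = rng.standard_normal(n) * math.sqrt(spec.noise_power_b * fs / 2.0)
    theta_src = None
    theta_i = spec.theta_index()
    for i, bs in enumerate(spec.bands):
        s = _source_series(bs, n, fs, rng)
        if band_envelopes and i in band_envelopes:
            env = np.asarray(band_envelopes[i], dtype=float)
            if env.size != n:
                raise ValidationError("band envelope length must match samples")
            s = s * env
        if i == theta_i:
            theta_src = s
        a += bs.gain_a * s
        b += bs.gain_b * s
    if pac is not None:
        t = np.arange(n) / fs
        if theta_src is not None and np.any(theta_src):
            phase = np.angle(hilbert(theta_src))
        else:
            phase = 2 * np.pi * pac.f_theta * t  # pure-phase fallback
            a += 0.5 * np.cos(phase)  # make the phase carrier visible
            phase = np.angle(np.exp(1j * phase))
        psi = rng.uniform(0, 2 * np.pi)
        carrier = np.cos(2 * np.pi * pac.f_gamma * t + psi)
        a += pac.carrier_amp * (1.0 + pac.depth * np.cos(phase)) * carrier
    return TimeSeriesRecording(np.column_stack([a, b]), fs, channel_names)


def _gain4(band: tuple[float, float], f: float, fs: float) -> float:
    """PSD gain |H(f)|^4 of the zero-phase order-4 Butterworth band-pass."""
    sos = _band_sos(band, fs)
    _, h = signal.sosfreqz(sos, worN=[f], fs=fs)
    return float(np.abs(h[0]) ** 4)


def analytic_coherence(spec: SharedSourceSpec, f: float, fs: float = 1000.0) -> float:
    """Closed-form magnitude-*squared* coherence of the shared-source model.

    Estimators in :mod:`thetalink.coherence` report magnitude coherence, so
    compare them to the square root of this value.  Frequencies outside every
    defined band return 0.
    """
    if not any(b.band[0] <= f <= b.band[1] for b in spec.bands):
        return 0.0
    cross = 0.0
    pa = spec.noise_power_a
    pb = spec.noise_power_b
    for bs in spec.bands:
        p_f = bs.source_power * _gain4(bs.band, f, fs)
        cross += bs.gain_a * bs.gain_b * p_f
        pa += bs.gain_a**2 * p_f
        pb += bs.gain_b**2 * p_f
    if pa <= 0 or pb <= 0:
        return 1.0 if cross > 0 else 0.0
    return float(cross**2 / (pa * pb))


# ---------------------------------------------------------------------------
# open field (novelty-induced locomotion / habituation)
# ---------------------------------------------------------------------------


def _bounded_walk(
    speeds_cm_s: np.ndarray,
    fps: float,
    box_cm: float,
    rng: np.random.Generator,
    turn_sd: float = 0.8,
) -> np.ndarray:
    """Correlated random walk with reflecting walls; per-frame speeds given."""
    n = speeds_cm_s.size
    xy = np.empty((n, 2))
    pos = np.array([box_cm / 2.0, box_cm / 2.0])
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(n):
        heading += rng.normal(0, turn_sd)
        step = speeds_cm_s[i] / fps
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        for d in range(2):
            if pos[d] < 0:
                pos[d] = -pos[d]
                heading = np.pi - heading if d == 0 else -heading
            elif pos[d] > box_cm:
                pos[d] = 2 * box_cm - pos[d]
                heading = np.pi - heading if d == 0 else -heading
        xy[i] = pos
    return xy


def generate_open_field_session(
    profile: HabituationProfile,
    spec: SharedSourceSpec | None = None,
    duration_s: float = 300.0,
    fs: float = 1000.0,
    seed: int = 0,
    pac: PACSpec | None = None,
    box_cm: float = 40.0,
    fps: float = 25.0,
    base_speed_cm_s: float = 8.0,
) -> tuple[TimeSeriesRecording, TrackingTrace]:
    """Novel-environment session: decaying (or sustained) theta + tracking.

    The theta source amplitude follows the habituation profile; the
    locomotor step rate scales with the instantaneous theta amplitude, so
    behavior habituates together with the oscillation (a generator
    convenience making habituation visible in both readouts, not a
    mechanistic claim).
    """
    if spec is None:
        spec = default_session_spec()
    theta_i = spec.theta_index()
    if theta_i is None:
        raise ValidationError("open-field spec needs a theta-range band source")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    env = profile.envelope(t)
    rec = generate_lfp_pair(
        spec, pac, duration_s, fs, seed, band_envelopes={theta_i: env}
    )
    rng = _rng(seed, "behavior")
    n_frames = int(round(duration_s * fps))
    tf = np.arange(n_frames) / fps
    rel_env = profile.envelope(tf)
    rel = rel_env / max(profile.initial_amplitude, 1e-12)
    speeds = base_speed_cm_s * rel * rng.gamma(4.0, 0.25, size=n_frames)
    xy = _bounded_walk(speeds, fps, box_cm, rng)
    track = TrackingTrace(pd.DataFrame({"t": tf, "x": xy[:, 0], "y": xy[:, 1]}))
    return rec, track


# ---------------------------------------------------------------------------
# T-maze rewarded alternation
# ---------------------------------------------------------------------------


def generate_tmaze_session(
    p_correct: float,
    n_trials: int = 10,
    blocks: int = 7,
    spec: SharedSourceSpec | None = None,
    seed: int = 0,
    fs: float = 1000.0,
    choice_gain: float = 1.0,
    trial_len_s: float = 20.0,
    decision_occupancy_s: float = 2.0,
) -> tuple[TimeSeriesRecording, EpochTable, pd.DataFrame]:
    """Rewarded-alternation session: LFP + decision-zone epochs + outcomes.

    Each trial contributes a sample and a choice decision-zone exit; choice
    correctness is Bernoulli(p_correct) (correct = entering the arm not
    visited on the sample run).  ``choice_gain`` multiplies the shared-source
    amplitude during choice decision windows, emulating a sample-to-choice
    coherence modulation.
    """
    if not 0.0 <= p_correct <= 1.0:
        raise ValidationError("p_correct must be in [0, 1]")
    if spec is None:
        spec = default_session_spec()
    total = n_trials * blocks
    rng = _rng(seed, "outcomes")
    arms = np.array(["left", "right"])
    duration_s = total * trial_len_s
    rows, epochs = [], []
    n = int(round(duration_s * fs))
    env = np.ones(n)
    for trial in range(total):
        t0 = trial * trial_len_s
        sample_exit = t0 + 0.4 * trial_len_s
        choice_exit = t0 + 0.8 * trial_len_s
        sample_arm = arms[rng.integers(2)]
        correct = bool(rng.random() < p_correct)
        chosen = (
            arms[arms != sample_arm][0] if correct else sample_arm
        )  # alternation is rewarded
        rows.append(
            (
                trial + 1,
                trial // n_trials + 1,
                sample_arm,
                chosen,
                correct,
                sample_exit,
                choice_exit,
            )
        )
        for phase, exit_t in (("sample", sample_exit), ("choice", choice_exit)):
            onset = exit_t - decision_occupancy_s
            epochs.append((onset, exit_t, "decision_zone", trial + 1, phase))
            if phase == "choice" and choice_gain != 1.0:
                i0, i1 = int(onset * fs), int(exit_t * fs)
                env[i0:i1] = choice_gain
    band_envelopes = {i: env for i in range(len(spec.bands))}
    if choice_gain == 1.0:
        band_envelopes = None
    rec = generate_lfp_pair(
        spec, None, duration_s, fs, seed, band_envelopes=band_envelopes
    )
    trials = pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "block",
            "sample_arm",
            "chosen_arm",
            "correct",
            "sample_exit_s",
            "choice_exit_s",
        ],
    )
    table = EpochTable(
        pd.DataFrame(
            epochs, columns=["onset", "offset", "label", "trial_id", "phase"]
        )
    )
    return rec, table, trials


# ---------------------------------------------------------------------------
# Y-maze spatial novelty preference
# ---------------------------------------------------------------------------

_ARM_ANGLES = {"start": 90.0, "novel": 210.0, "familiar": 330.0}


def ymaze_arm_polygons(
    arm_length_cm: float = 30.0, arm_width_cm: float = 8.0, hub_cm: float = 5.0
) -> dict[str, np.ndarray]:
    """Three rectangular arm polygons (vertex arrays) around a central hub."""
    polys = {}
    for label, ang in _ARM_ANGLES.items():
        th = math.radians(ang)
        u = np.array([math.cos(th), math.sin(th)])
        v = np.array([-math.sin(th), math.cos(th)])
        w = arm_width_cm / 2.0
        p0 = hub_cm * u - w * v
        p1 = hub_cm * u + w * v
        p2 = (hub_cm + arm_length_cm) * u + w * v
        p3 = (hub_cm + arm_length_cm) * u - w * v
        polys[label] = np.array([p0, p1, p2, p3])
    return polys


def generate_ymaze_session(
    pref_target: float,
    spec: SharedSourceSpec | None = None,
    seed: int = 0,
    duration_s: float = 300.0,
    fs: float = 1000.0,
    novel_theta_gain: float = 1.0,
    novel_speed_gain: float = 1.0,
    bout_mean_s: float = 8.0,
    transit_s: float = 1.5,
    fps: float = 25.0,
    include_lfp: bool = True,
) -> tuple[TimeSeriesRecording | None, TrackingTrace, dict[str, np.ndarray]]:
    """Test phase of the spatial novelty preference task.

    The virtual mouse alternates hub transits with goal-arm bouts; each bout
    picks the novel arm with probability ``pref_target`` and lasts an
    exponential time with the *same* mean for both arms, so the expected
    first-minute preference ratio equals the target (and 0.5 is the
    indifferent null).  During novel-arm bouts the theta source amplitude is
    multiplied by ``novel_theta_gain`` (raising both theta power and
    dHipp-PFC theta coherence); bout running speed scales with
    ``novel_speed_gain``.
    """
    if not 0.0 <= pref_target <= 1.0:
        raise ValidationError("pref_target must be in [0, 1]")
    if spec is None:
        spec = default_session_spec()
    rng = _rng(seed, "behavior")
    polys = ymaze_arm_polygons()
    n_frames = int(round(duration_s * fps))
    tf = np.arange(n_frames) / fps
    arm_of_frame = np.full(n_frames, "none", dtype=object)

    # --- bout schedule ----------------------------------------------------
    t = 0.0
    schedule: list[tuple[float, float, str]] = []
    while t < duration_s:
        t_hub = t + transit_s
        if t_hub >= duration_s:
            break
        arm = "novel" if rng.random() < pref_target else "familiar"
        dur = rng.exponential(bout_mean_s)
        schedule.append((t_hub, min(t_hub + dur, duration_s), arm))
        t = t_hub + dur

    # --- tracking ---------------------------------------------------------
    xy = np.zeros((n_frames, 2))
    base_speed = 8.0
    r = np.full(n_frames, 2.0)  # hub radius by default
    ang = np.zeros(n_frames)
    for onset, offset, arm in schedule:
        m = (tf >= onset) & (tf < offset)
        ang[m] = math.radians(_ARM_ANGLES[arm])
        gain = novel_speed_gain if arm == "novel" else 1.0
        # random walk along the arm's long axis, clipped inside the polygon
        steps = np.cumsum(rng.normal(0, gain * base_speed / fps / 0.8, m.sum()))
        r[m] = np.clip(12.0 + steps, 7.0, 32.0)
        arm_of_frame[m] = arm
    lateral = np.clip(np.cumsum(rng.normal(0, 0.15, n_frames)), -3.0, 3.0)
    xy[:, 0] = r * np.cos(ang) - lateral * np.sin(ang)
    xy[:, 1] = r * np.sin(ang) + lateral * np.cos(ang)
    track = TrackingTrace(pd.DataFrame({"t": tf, "x": xy[:, 0], "y": xy[:, 1]}))

    rec = None
    if include_lfp:
        theta_i = spec.theta_index()
        if theta_i is None:
            raise ValidationError("Y-maze spec needs a theta-range band source")
        n = int(round(duration_s * fs))
        env = np.ones(n)
        for onset, offset, arm in schedule:
            if arm == "novel" and novel_theta_gain != 1.0:
                env[int(onset * fs) : int(offset * fs)] = novel_theta_gain
        rec = generate_lfp_pair(
            spec, None, duration_s, fs, seed, band_envelopes={theta_i: env}
        )
    return rec, track, polys


# ---------------------------------------------------------------------------
# virtual cohorts
# ---------------------------------------------------------------------------


def habituation_cohort(
    n_per_group: int = 8,
    effect_sd: float = 2.0,
    amplitude_cv: float = 0.1,
    duration_s: float = 300.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> GroupStudySpec:
    """WT-like decaying vs knockout-like sustained theta, two groups.

    The decaying profile's time constant is set so the group separation in
    theta-band *power* at the end of the session equals ``effect_sd`` times
    the between-animal power SD.  Power scales as amplitude squared, so a
    between-animal amplitude CV of ``amplitude_cv`` gives a power CV of
    about 2 * amplitude_cv, and the end-of-session power ratio is
    1 - effect_sd * 2 * amplitude_cv.
    """
    power_drop = effect_sd * 2.0 * amplitude_cv
    if not 0 < power_drop < 1:
        raise ValidationError("effect_sd * 2 * amplitude_cv must be in (0, 1)")
    tau = -duration_s / math.log(math.sqrt(1.0 - power_drop))
    wt = GroupSpec(
        "WT", n_per_group, HabituationProfile(1.0, tau), amplitude_cv=amplitude_cv
    )
    ko = GroupSpec(
        "KO",
        n_per_group,
        HabituationProfile(1.0, math.inf),
        amplitude_cv=amplitude_cv,
    )
    return GroupStudySpec(groups=(wt, ko), duration_s=duration_s, fs=fs, seed=seed)


@dataclass
class AnimalSession:
    animal_id: str
    group: str
    recording: TimeSeriesRecording
    tracking: TrackingTrace
    truth: dict


def simulate_open_field_cohort(study: GroupStudySpec, spec: SharedSourceSpec | None = None):
    """Yield one open-field session per virtual animal (lazily)."""
    if spec is None:
        spec = default_session_spec()
    rng = _rng(study.seed, "outcomes")
    animal_no = 0
    for g in study.groups:
        for _ in range(g.n_animals):
            animal_no += 1
            amp = g.profile.initial_amplitude * max(
                float(rng.normal(1.0, g.amplitude_cv)), 0.2
            )
            profile = replace(g.profile, initial_amplitude=amp)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            rec, track = generate_open_field_session(
                profile,
                spec,
                duration_s=study.duration_s,
                fs=study.fs,
                seed=sub_seed,
                pac=g.pac,
                base_speed_cm_s=g.locomotion_cm_s,
            )
            yield AnimalSession(
                f"m{animal_no:03d}",
                g.label,
                rec,
                track,
                {
                    "theta_amplitude": amp,
                    "decay_tau_s": profile.decay_tau_s,
                    "seed": sub_seed,
                },
            )
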