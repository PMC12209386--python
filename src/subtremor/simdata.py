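"""Seeded synthetic three-sensor tremor recordings.

Stands in for the (non-deposited) clinical dataset: each recording carries
three quaternion streams (hand, forearm, upperarm) whose relative rotations
are built from four generated joint-angle series (WFE, WAA, EPS, EFE), so
the ground-truth joint kinematics are known by construction.  Class signal
models place the dominant oscillation in the clinically reported bands —
Parkinsonian rest tremor around 3-9 Hz (default narrowed to 4-6 Hz, with a
harmonic and larger cycle-to-cycle frequency jitter, reflecting the lower
regularity of low-amplitude PD tremor), essential tremor around 4-14 Hz
(default 8-11 Hz), and physiological tremor as reduced-power broadband
around 8-12 Hz.  Amplitudes are calibrated by bisection so the rating
regression lands strictly below the 0.5 subclinical threshold, and
transmission loss is emulated by seeded random sample dropout (endpoints
always kept, so interpolation is interior).

Presets
-------
``separable`` (default) : narrowed, well-separated PD/ET bands.
``overlapping``         : the full cited 3-9 / 4-14 Hz clinical bands.
``null``                : all classes share one signal model (leakage guard).
``paper``               : the study's composition of 122 normal / 83 PD /
                          30 ET readings, up to two per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import (JointAngleSet, QuaternionStream, TremorRatingModel,
                         compose_joint_angles, quat_multiply,
                         mean_square_power, tremor_rating)
from .preprocess import PreprocessConfig, bandpass

__all__ = [
    "ClassSignalModel",
    "SimConfig",
    "Recording",
    "PD_MODEL",
    "ET_MODEL",
    "NORMAL_MODEL",
    "class_models",
    "generate_angle_signal",
    "encode_quaternion_stream",
    "calibrate_subclinical",
    "apply_dropout",
    "generate_recording",
    "generate_dataset",
]


@dataclass
class ClassSignalModel:
    """Spectral-temporal model of one tremor class.

    freq_band : band (Hz) the dominant frequency is drawn from, per recording.
    freq_jitter : std (Hz) of the slow instantaneous-frequency wander;
        larger means less regular cycle-to-cycle behaviour.
    amplitude : base oscillation amplitude (rad) before subclinical calibration.
    am_depth : depth of the slow random-walk amplitude modulation (0..1).
    harmonics : list of (multiple, relative amplitude) pairs.
    noise_white / noise_pink : additive noise floors relative to amplitude.
    """

    freq_band: tuple[float, float]
    freq_jitter: float = 0.3
    amplitude: float = 0.02
    am_depth: float = 0.3
    harmonics: list[tuple[int, float]] = field(default_factory=list)
    noise_white: float = 0.05
    noise_pink: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.freq_band
        if not (0 < lo <= hi < 50):
            raise ValueError("frequency band must lie inside (0, 50) Hz")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


PD_MODEL = ClassSignalModel(freq_band=(4.0, 6.0), freq_jitter=0.5,
                            harmonics=[(2, 0.3)], am_depth=0.4)
ET_MODEL = ClassSignalModel(freq_band=(8.0, 11.0), freq_jitter=0.25,
                            am_depth=0.25)
NORMAL_MODEL = ClassSignalModel(freq_band=(8.0, 12.0), freq_jitter=1.5,
                                amplitude=0.008, am_depth=0.5,
                                noise_white=0.4, noise_pink=0.3)


def class_models(preset: str = "separable") -> dict[int, ClassSignalModel]:
    """Per-label signal models for a named preset (labels 0/1/2 =
    normal/PD/ET)."""
    if preset in ("separable", "paper"):
        return {0: NORMAL_MODEL, 1: PD_MODEL, 2: ET_MODEL}
    if preset == "overlapping":
        return {0: NORMAL_MODEL,
                1: replace(PD_MODEL, freq_band=(3.0, 9.0)),
                2: replace(ET_MODEL, freq_band=(4.0, 14.0))}
    if preset == "null":
        return {0: NORMAL_MODEL, 1: NORMAL_MODEL, 2: NORMAL_MODEL}
    raise ValueError(f"unknown preset {preset!r}")


@dataclass
class SimConfig:
    """Generator configuration.

    duration, rate : recording length (>= 13 s) and sampling rate (100 Hz).
    dropout_fraction : fraction of samples removed to emulate transmission
        loss (endpoints kept).
    rating_range : interval the calibrated tremor rating is steered into;
        must sit strictly below the 0.5 subclinical threshold.
    upperarm_axis : rotation axis of the proximal base motion.
    """

    duration: float = 14.0
    rate: float = 100.0
    dropout_fraction: float = 0.02
    rating_range: tuple[float, float] = (0.1, 0.45)
    max_recordings_per_subject: int = 2
    upperarm_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.duration * self.rate < 1300:
            raise ValueError("duration * rate must cover the 13 s standard")
        if not (0 <= self.dropout_fraction < 0.5):
            raise ValueError("dropout fraction must be in [0, 0.5)")
        lo, hi = self.rating_range
        if not (0 < lo < hi < 0.5):
            raise ValueError("rating range must sit inside (0, 0.5)")


@dataclass
class Recording:
    """One labeled measurement: three sensor streams + ground truth."""

    recording_id: str
    subject_id: str
    label: int
    hand: QuaternionStream
    forearm: QuaternionStream
    upperarm: QuaternionStream
    joint_angles_truth: JointAngleSet | None = None
    rating: float | None = None

    @property
    def streams(self) -> dict[str, QuaternionStream]:
        return {"hand": self.hand, "forearm": self.forearm,
                "upperarm": self.upperarm}


def generate_angle_signal(model: ClassSignalModel, duration: float = 14.0,
                          rate: float = 100.0,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Phase-continuous jittered oscillator with AM, harmonics and noise.

    The instantaneous frequency wanders (low-pass filtered Gaussian steps,
    std `freq_jitter`) around a dominant frequency drawn uniformly from the
    model's band, and is clipped to that band; the phase is its integral,
    so the oscillation is continuous.  Amplitude follows a slow positive
    random walk of depth `am_depth`; optional harmonics ride on the same
    phase; white plus 1/f noise tops it off.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    dt = 1.0 / rate
    f0 = rng.uniform(*model.freq_band)
    # slow frequency wander: smoothed white noise, ~1 s correlation length
    wander = rng.standard_normal(n)
    kernel = np.exp(-np.arange(0, 3 * rate) / rate)
    wander = np.convolve(wander, kernel / kernel.sum(), mode="same")
    wander *= model.freq_jitter / max(wander.std(), 1e-12)
    f_inst = np.clip(f0 + wander, *model.freq_band)
    phase = 2 * np.pi * np.cumsum(f_inst) * dt
    # slow amplitude modulation, kept positive
    walk = np.cumsum(rng.standard_normal(n)) * dt
    walk = walk - walk.mean()
    am = 1.0 + model.am_depth * np.tanh(walk)
    signal = am * np.sin(phase)
    for mult, rel in model.harmonics:
        signal = signal + rel * am * np.sin(mult * phase + rng.uniform(0, 2 * np.pi))
    noise = model.noise_white * rng.standard_normal(n)
    if model.noise_pink > 0:
        spectrum = np.fft.rfft(rng.standard_normal(n))
        freqs = np.fft.rfftfreq(n, dt)
        freqs[0] = freqs[1]
        pink = np.fft.irfft(spectrum / np.sqrt(freqs), n)
        noise = noise + model.noise_pink * pink / max(pink.std(), 1e-12)
    return model.amplitude * (signal + noise)


def encode_quaternion_stream(angles: np.ndarray, axis, rate: float = 100.0,
                             site: str = "hand") -> QuaternionStream:
    """Encode an angle series as rotations about a fixed unit axis:
    q(t) = (cos(theta/2), axis * sin(theta/2))."""
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("rotation axis must be unit length")
    angles = np.asarray(angles, dtype=float)
    if np.any(np.abs(angles) >= np.pi):
        raise ValueError("angles must stay within (-pi, pi)")
    half = angles / 2.0
    quats = np.column_stack([np.cos(half), *(np.sin(half) * a for a in axis)])
    times = np.arange(len(angles)) / rate
    return QuaternionStream(times=times, quats=quats, rate=rate, site=site)


def _band_limited_powers(angles: dict[str, np.ndarray],
                         pp: PreprocessConfig) -> dict[str, float]:
    return {j: mean_square_power(bandpass(a, pp)) for j, a in angles.items()}


def rating_of_angles(angles: dict[str, np.ndarray],
                     pp: PreprocessConfig | None = None,
                     model: TremorRatingModel | None = None) -> float:
    """Tremor rating of raw joint-angle series: 3-30 Hz bandpass, mean
    square, then the log-power regression."""
    pp = pp or PreprocessConfig()
    return tremor_rating(_band_limited_powers(angles, pp), model)


def calibrate_subclinical(angles: dict[str, np.ndarray],
                          target_rating: float,
                          pp: PreprocessConfig | None = None,
                          model: TremorRatingModel | None = None,
                          tol: float = 0.005) -> tuple[dict[str, np.ndarray], float]:
    """Rescale all four angle series by one factor until the rating hits
    `target_rating` (bisection on the log scale).

    Returns the scaled angle dict and the achieved rating.  The rating is
    monotone in the common scale (all regression coefficients positive),
    so bisection always converges; an insensitive rating (degenerate
    signals) raises a calibration error.
    """
    pp = pp or PreprocessConfig()
    model = model or TremorRatingModel()
    filtered = {j: bandpass(a, pp) for j, a in angles.items()}

    def rating_at(log_s: float) -> float:
        s = 10.0 ** log_s
        return tremor_rating({j: mean_square_power(s * f)
                              for j, f in filtered.items()}, model)

    lo, hi = -8.0, 8.0
    if not rating_at(lo) < target_rating < rating_at(hi):
        raise RuntimeError("rating is insensitive to amplitude; cannot calibrate")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = rating_at(mid)
        if abs(r - target_rating) < tol:
            break
        if r < target_rating:
            lo = mid
        else:
            hi = mid
    s = 10.0 ** mid
    return {j: s * a for j, a in angles.items()}, rating_at(mid)


def apply_dropout(stream: QuaternionStream, fraction: float,
                  seed: int | np.random.Generator = 0) -> QuaternionStream:
    """Remove round(fraction * N) seeded-random samples, never the first
    or last, emulating transmission loss."""
    if not (0 <= fraction < 0.5):
        raise ValueError("dropout fraction must be in [0, 0.5)")
    n = len(stream)
    n_drop = int(round(fraction * n))
    if n_drop == 0:
        return stream
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drop = rng.choice(np.arange(1, n - 1), size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return QuaternionStream(times=stream.times[keep], quats=stream.quats[keep],
                            rate=stream.rate, site=stream.site)


# relative joint amplitudes: flexion-extension dominates at the wrist
_JOINT_WEIGHTS = {"WFE": 1.0, "WAA": 0.5, "EPS": 0.7, "EFE": 0.6}


def generate_recording(model: ClassSignalModel, label: int, config: SimConfig,
                       recording_id: str, subject_id: str,
                       seed: int | np.random.Generator = 0) -> Recording:
    """One recording: joint-angle series from the class model, calibrated
    subclinical, composed into the three sensor orientation streams, with
    transmission dropout applied."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = {
        j: w * generate_angle_signal(model, config.duration, config.rate, rng)
        for j, w in _JOINT_WEIGHTS.items()
    }
    target = rng.uniform(*config.rating_range)
    angles, rating = calibrate_subclinical(angles, target)

    # proximal base motion: a weaker oscillation of the same class model
    base = 0.3 * generate_angle_signal(model, config.duration, config.rate, rng)
    base = base * (0.02 / max(np.abs(base).max(), 1e-12))
    upperarm = encode_quaternion_stream(base, config.upperarm_axis,
                                        config.rate, site="upperarm")
    r_wrist, r_elbow = compose_joint_angles(angles["WFE"], angles["WAA"],
                                            angles["EFE"], angles["EPS"])
    q_forearm = quat_multiply(upperarm.quats, r_elbow)
    q_hand = quat_multiply(q_forearm, r_wrist)
    times = upperarm.times
    forearm = QuaternionStream(times=times.copy(), quats=q_forearm,
                               rate=config.rate, site="forearm")
    hand = QuaternionStream(times=times.copy(), quats=q_hand,
                            rate=config.rate, site="hand")
    truth = JointAngleSet(times=times.copy(), wfe=angles["WFE"],
                          waa=angles["WAA"], eps=angles["EPS"],
                          efe=angles["EFE"])
    streams = {}
    for site, s in (("hand", hand), ("forearm", forearm), ("upperarm", upperarm)):
        streams[site] = apply_dropout(s, config.dropout_fraction, rng)
    return Recording(recording_id=recording_id, subject_id=subject_id,
                     label=label, hand=streams["hand"],
                     forearm=streams["forearm"], upperarm=streams["upperarm"],
                     joint_angles_truth=truth, rating=rating)


_PAPER_COUNTS = {0: 122, 1: 83, 2: 30}


def generate_dataset(n_per_class: int | dict[int, int] | None = None,
                     config: SimConfig | None = None, seed: int = 0,
                     preset: str = "separable") -> list[Recording]:
    """Generate a labeled multi-subject dataset.

    `preset="paper"` emits the study's composition (122 normal, 83 PD,
    30 ET readings); otherwise `n_per_class` recordings per class (an int
    or a {label: count} dict).  Subjects contribute one or two recordings
    each (seeded), and every recording is calibrated subclinical.
    """
    config = config or SimConfig()
    models = class_models(preset)
    if preset == "paper":
        counts = dict(_PAPER_COUNTS)
    elif isinstance(n_per_class, dict):
        counts = dict(n_per_class)
    elif n_per_class is not None:
        counts = {lbl: int(n_per_class) for lbl in models}
    else:
        raise ValueError("n_per_class required unless preset='paper'")
    rng = np.random.default_rng(seed)
    recordings: list[Recording] = []
    for label, n in sorted(counts.items()):
        if n <= 0:
            raise ValueError("recording counts must be positive")
        made = 0
        subj = 0
        while made < n:
            per_subject = 1
            if (config.max_recordings_per_subject > 1 and made + 2 <= n
                    and rng.random() < 0.4):
                per_subject = 2
            subject_id = f"S{label}{subj:03d}"
            for k in range(per_subject):
                rec_id = f"R{label}-{subject_id}-{k}"
                recordings.append(
                    generate_recording(models[label], label, config, rec_id,
                                       subject_id, rng))
                made += 1
            subj += 1
    return recordings
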