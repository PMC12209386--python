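"""STFT magnitude features for the sequence classifier.

Each sensor's scalar displacement-magnitude series (1300 samples at 100 Hz)
is transformed with a 128-sample periodic-Hann STFT hopped by 32 samples,
giving the standardized resolution of 100/128 = 0.78125 Hz (printed 0.78 Hz)
on the frequency axis and 320 ms on the time axis.  Only the one-sided
magnitude is kept; bins with centers inside the 3-30 Hz tremor band are
selected (35 bins) and the three sensors are concatenated per frame, so the
default feature sequence is 37 frames x 105 features.  Time frames are the
sequence steps fed to the classifier; the 105 magnitudes per frame form the
per-step input vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

__all__ = [
    "SpectrogramConfig",
    "Spectrogram",
    "FeatureSequence",
    "stft_magnitude",
    "band_select",
    "assemble_features",
]

CLASS_NAMES = {0: "normal", 1: "PD", 2: "ET"}


@dataclass
class SpectrogramConfig:
    rate: float = 100.0
    n_fft: int = 128          # -> bin spacing 0.78125 Hz
    hop: int = 32             # -> 320 ms frame step
    window: str = "hann"      # periodic Hann
    band: tuple[float, float] = (3.0, 30.0)

    @property
    def bin_spacing(self) -> float:
        return self.rate / self.n_fft

    def make_window(self) -> np.ndarray:
        if self.window == "hann":
            return hann(self.n_fft, sym=False)
        if self.window == "boxcar":
            return np.ones(self.n_fft)
        raise ValueError(f"unknown window {self.window!r}")


@dataclass
class Spectrogram:
    """One-sided STFT magnitudes: frames x bins, all non-negative."""

    magnitudes: np.ndarray
    frequencies: np.ndarray  # bin center frequencies, Hz
    frame_times: np.ndarray  # frame start times, s
    site: str = ""


@dataclass
class FeatureSequence:
    """Per-recording classifier input: frames x (3 sensors x in-band bins)."""

    values: np.ndarray
    columns: list[tuple[str, float]]  # (site, bin frequency) per column
    label: int | None = None
    recording_id: str | None = None
    subject_id: str | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def stft_magnitude(series: np.ndarray, config: SpectrogramConfig | None = None,
                   site: str = "") -> Spectrogram:
    """Windowed one-sided STFT magnitude, no padding.

    Frame count is ``floor((N - n_fft)/hop) + 1``; with N = 1300 and the
    default config, 37 frames.
    """
    config = config or SpectrogramConfig()
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < config.n_fft:
        raise ValueError(f"series of length {n} shorter than one window ({config.n_fft})")
    n_frames = (n - config.n_fft) // config.hop + 1
    window = config.make_window()
    starts = np.arange(n_frames) * config.hop
    frames = np.stack([series[s:s + config.n_fft] * window for s in starts])
    mags = np.abs(np.fft.rfft(frames, axis=1))
    freqs = np.fft.rfftfreq(config.n_fft, d=1.0 / config.rate)
    return Spectrogram(magnitudes=mags, frequencies=freqs,
                       frame_times=starts / config.rate, site=site)


def band_select(spec: Spectrogram,
                band: tuple[float, float] = (3.0, 30.0)) -> Spectrogram:
    """Keep bins whose center frequency lies inside [low, high] inclusive.

    At the default 0.78125 Hz spacing on [3, 30] Hz this retains bin
    indices 4-38, i.e. 35 bins.
    """
    low, high = band
    keep = (spec.frequencies >= low) & (spec.frequencies <= high)
    if not np.any(keep):
        raise ValueError(f"band [{low}, {high}] Hz selects no bins")
    return Spectrogram(
        magnitudes=spec.magnitudes[:, keep],
        frequencies=spec.frequencies[keep],
        frame_times=spec.frame_times,
        site=spec.site,
    )


def assemble_features(hand: Spectrogram, forearm: Spectrogram,
                      upperarm: Spectrogram, label: int | None = None,
                      recording_id: str | None = None,
                      subject_id: str | None = None) -> FeatureSequence:
    """Concatenate the three sensors' in-band bins per frame.

    The column order is [hand bins | forearm bins | upperarm bins], so the
    feature count is threefold the per-sensor bin count (105 by default).
    """
    specs = {"hand": hand, "forearm": forearm, "upperarm": upperarm}
    frames = {k: s.magnitudes.shape[0] for k, s in specs.items()}
    if len(set(frames.values())) != 1:
        raise ValueError(f"frame-count mismatch across sensors: {frames}")
    for k, s in specs.items():
        if not np.array_equal(s.frequencies, hand.frequencies):
            raise ValueError(f"bin grid of {k} differs from hand")
    values = np.concatenate([s.magnitudes for s in specs.values()], axis=1)
    columns = [(site, float(f)) for site, s in specs.items() for f in s.frequencies]
    return FeatureSequence(values=values, columns=columns, label=label,
                           recording_id=recording_id, subject_id=subject_id)
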