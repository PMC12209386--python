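"""Stream repair and signal conditioning ahead of featurization.

Wireless transmission occasionally drops samples; gaps are located on the
nominal 100 Hz grid and repaired by shape-preserving piecewise cubic Hermite
interpolation (PCHIP) of each quaternion component, followed by per-sample
renormalization.  Scalar series (displacement magnitude, joint angles) are
band-passed to 3-30 Hz with a zero-phase 4th-order Butterworth filter and
every recording is standardized to the 13 s minimum measurement duration
(1300 samples at 100 Hz).

The fixed composition order is: gap repair -> displacement conversion ->
bandpass -> duration standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

from .kinematics import QuaternionStream

__all__ = [
    "PreprocessConfig",
    "TooShortError",
    "detect_gaps",
    "fill_gaps_pchip",
    "bandpass",
    "standardize_duration",
    "preprocess_scalar",
]


class TooShortError(ValueError):
    """Raised when a recording is shorter than the standard duration."""

    def __init__(self, actual_duration: float, required: float):
        self.actual_duration = actual_duration
        self.required = required
        super().__init__(
            f"recording lasts {actual_duration:.2f} s, "
            f"shorter than the {required:.2f} s standard"
        )


@dataclass
class PreprocessConfig:
    """Conditioning parameters.

    rate : sampling rate, Hz.
    band : passband edges (low, high), Hz; tremor band 3-30 Hz.
    duration : standard duration, s; 13 s is the minimum measurement period.
    filter_order : Butterworth order (applied forward-backward, zero phase).
    truncate_offset : sample offset of the standardization window.
    """

    rate: float = 100.0
    band: tuple[float, float] = (3.0, 30.0)
    duration: float = 13.0
    filter_order: int = 4
    truncate_offset: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.rate / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")

    @property
    def n_samples(self) -> int:
        n = self.duration * self.rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * rate must be an integer sample count")
        return int(round(n))


def _grid_indices(times: np.ndarray, rate: float) -> np.ndarray:
    """Map timestamps onto the uniform grid anchored at the first sample."""
    return np.round((times - times[0]) * rate).astype(int)


def detect_gaps(stream: QuaternionStream) -> list[tuple[int, int]]:
    """Locate missing samples on the nominal uniform grid.

    A gap is flagged wherever consecutive timestamps differ by more than
    1.5x the nominal period.  Returns inclusive ``(start, stop)`` index
    ranges of grid positions absent from the stream.
    """
    times = stream.times
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    period = 1.0 / stream.rate
    idx = _grid_indices(times, stream.rate)
    gaps: list[tuple[int, int]] = []
    dt = np.diff(times)
    for k in np.nonzero(dt > 1.5 * period)[0]:
        gaps.append((int(idx[k]) + 1, int(idx[k + 1]) - 1))
    return gaps


def fill_gaps_pchip(stream: QuaternionStream) -> QuaternionStream:
    """Repair dropped samples by component-wise PCHIP onto the uniform grid.

    Each quaternion component is interpolated independently with a
    shape-preserving piecewise cubic Hermite, then the quaternion is
    renormalized per sample.  Retained samples are reproduced exactly.
    """
    if len(stream) < 4:
        raise ValueError("need at least 4 samples for cubic Hermite interpolation")
    idx = _grid_indices(stream.times, stream.rate)
    n_grid = idx[-1] + 1
    if idx.size == n_grid:  # no gaps
        return stream
    grid_times = stream.times[0] + np.arange(n_grid) / stream.rate
    quats = np.empty((n_grid, 4))
    for c in range(4):
        quats[:, c] = PchipInterpolator(stream.times, stream.quats[:, c])(grid_times)
    quats[idx] = stream.quats  # knots are exact by construction; enforce bitwise
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    return QuaternionStream(times=grid_times, quats=quats, rate=stream.rate,
                            site=stream.site)


def _design_sos(config: PreprocessConfig) -> np.ndarray:
    return butter(config.filter_order, config.band, btype="bandpass",
                  fs=config.rate, output="sos")


def bandpass(series: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    config = config or PreprocessConfig()
    series = np.asarray(series, dtype=float)
    if series.shape[-1] <= 3 * (2 * config.filter_order + 1):
        raise ValueError("series too short for stable zero-phase filtering")
    return sosfiltfilt(_design_sos(config), series, axis=-1)


def standardize_duration(series: np.ndarray,
                         config: PreprocessConfig | None = None) -> np.ndarray:
    """Truncate to the standard duration (first 1300 samples by default)."""
    config = config or PreprocessConfig()
    series = np.asarray(series)
    n = config.n_samples
    start = config.truncate_offset
    if series.shape[-1] - start < n:
        raise TooShortError(series.shape[-1] / config.rate, config.duration)
    return series[..., start:start + n]


def preprocess_scalar(series: np.ndarray,
                      config: PreprocessConfig | None = None) -> np.ndarray:
    """Bandpass then standardize a scalar series (displacement magnitude or
    joint angle) — the conditioning applied before featurization and before
    the mean-square power of the rating model."""
    config = config or PreprocessConfig()
    return standardize_duration(bandpass(series, config), config)
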