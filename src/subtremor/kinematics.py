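"""Quaternion kinematics and the subclinical tremor-rating gate.

Orientation streams from three arm-mounted AHRS units (hand dorsum, distal
forearm, distal upper arm) are converted to the displacement of a reference
point initially at P = (1, 0, 0): the rotated point is the vector part of
``q* P q`` and the tremor displacement at time t is the difference from the
rotated point at t0.  Relative wrist/elbow rotations yield four joint-angle
series (WFE, WAA, EPS, EFE) whose band-limited mean-square powers enter a
linear regression on log power that predicts an observational tremor rating;
a rating strictly below 0.5 gates a recording as *subclinical*.

Conjugation convention
----------------------
The rotated point is computed literally as ``q* P q``.  This is the reverse
of the more common active convention ``q P q*``; the two differ only by the
sense of rotation, which flips the displacement sign globally and leaves
magnitudes (and hence everything downstream) unchanged.

Euler convention for joint angles
---------------------------------
Relative rotations are decomposed as intrinsic Z-Y-X Euler angles.  The
anatomical mapping is: wrist flexion-extension (WFE) = Z, wrist
abduction-adduction (WAA) = Y for the forearm->hand rotation; elbow
flexion-extension (EFE) = Z, elbow pronation-supination (EPS) = X for the
upperarm->forearm rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Quaternion",
    "QuaternionStream",
    "DisplacementSeries",
    "JointAngleSet",
    "TremorRatingModel",
    "REFERENCE_POINT",
    "quat_multiply",
    "quat_conjugate",
    "quat_normalize",
    "rotate_reference",
    "displacement_series",
    "joint_angles",
    "mean_square_power",
    "tremor_rating",
    "is_subclinical",
]

#: Reference point rotated by each orientation sample (unit vector).
REFERENCE_POINT = np.array([1.0, 0.0, 0.0])

# scalar-first quaternion layout: (w, x, y, z) == (q0, q1, q2, q3)
Quaternion = np.ndarray


@dataclass
class QuaternionStream:
    """Timestamped unit quaternions from one sensor site.

    Parameters
    ----------
    times : array of sample times in seconds, strictly increasing.
    quats : (n, 4) array, scalar-first (w, x, y, z).
    rate : nominal sampling rate in Hz (default 100).
    site : sensor site tag, one of {"hand", "forearm", "upperarm"}.
    """

    times: np.ndarray
    quats: np.ndarray
    rate: float = 100.0
    site: str = "hand"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.quats = np.asarray(self.quats, dtype=float)
        if self.quats.ndim != 2 or self.quats.shape[1] != 4:
            raise ValueError("quats must be an (n, 4) array, scalar-first")
        if self.times.shape[0] != self.quats.shape[0]:
            raise ValueError("times and quats length mismatch")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.shape[0]


@dataclass
class DisplacementSeries:
    """Displacement of the reference point relative to the first sample."""

    times: np.ndarray
    vectors: np.ndarray  # (n, 3), first row exactly zero
    site: str = "hand"

    @property
    def magnitude(self) -> np.ndarray:
        """Per-sample Euclidean norm of the displacement (dimensionless)."""
        return np.linalg.norm(self.vectors, axis=1)


@dataclass
class JointAngleSet:
    """Four joint-angle time series (radians) on a shared time base."""

    times: np.ndarray
    wfe: np.ndarray  # wrist flexion-extension
    waa: np.ndarray  # wrist abduction-adduction
    eps: np.ndarray  # elbow pronation-supination
    efe: np.ndarray  # elbow flexion-extension

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"WFE": self.wfe, "WAA": self.waa, "EPS": self.eps, "EFE": self.efe}


@dataclass
class TremorRatingModel:
    """Linear regression of observational tremor rating on log joint powers.

    ``rating = intercept + sum_j coef_j * log(theta_j_MS)`` where theta_j_MS
    is the mean square of the band-limited joint-angle series j.  The
    coefficients come from a published fit of six doctors' average ratings
    against sensor measurements and are taken as given.  A rating < 0.5
    (strict) defines subclinical tremor.
    """

    intercept: float = 2.6496
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "WFE": 0.3071,
            "WAA": 0.0731,
            "EPS": 0.1843,
            "EFE": 0.0988,
        }
    )
    subclinical_threshold: float = 0.5
    log_base: float = 10.0


def _check_finite(q: np.ndarray, name: str = "quaternion") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError(f"{name} has non-finite components")
    return q


def quat_multiply(a: Quaternion, b: Quaternion) -> Quaternion:
    """Hamilton product a (x) b, scalar-first layout; broadcasts over rows."""
    a = _check_finite(a)
    b = _check_finite(b)
    aw, ax, ay, az = np.moveaxis(np.atleast_2d(a), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.atleast_2d(b), -1, 0)
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    if a.ndim == 1 and b.ndim == 1:
        return out[0]
    return out


def quat_conjugate(q: Quaternion) -> Quaternion:
    """Conjugate q* = q0 - q1 i - q2 j - q3 k (vector part negated)."""
    q = _check_finite(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_normalize(q: Quaternion, warn_tol: float = 1e-3) -> Quaternion:
    """Renormalize to unit norm; warn above `warn_tol` deviation, error at zero."""
    q = _check_finite(q)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-norm quaternion cannot be normalized")
    if np.any(np.abs(norm - 1.0) > warn_tol):
        warnings.warn(
            "quaternion norm deviates from 1 by more than "
            f"{warn_tol:g}; renormalizing",
            stacklevel=2,
        )
    return q / norm


def rotate_reference(q: Quaternion) -> np.ndarray:
    """Rotate the reference point P = (1,0,0): vector part of q* P q.

    Accepts a single quaternion or an (n, 4) stack.  The input is
    renormalized internally; the result is a unit vector.
    """
    q = quat_normalize(q)
    p = np.zeros(q.shape[:-1] + (4,))
    p[..., 1:] = REFERENCE_POINT
    rotated = quat_multiply(quat_multiply(quat_conjugate(q), p), q)
    return rotated[..., 1:]


def displacement_series(stream: QuaternionStream) -> DisplacementSeries:
    """Displacement X(t) - X(t0) of the rotated reference point.

    The first sample is exactly zero by construction.
    """
    if len(stream) == 0:
        raise ValueError("empty quaternion stream")
    points = rotate_reference(stream.quats)
    vectors = points - points[0]
    vectors[0] = 0.0
    return DisplacementSeries(times=stream.times.copy(), vectors=vectors, site=stream.site)


# intrinsic Euler sequences for the anatomical mapping (scipy is intrinsic
# for uppercase axes); wrist: Z=WFE, Y=WAA; elbow: Z=EFE, X=EPS
_WRIST_SEQ = "ZYX"
_ELBOW_SEQ = "ZXY"


def _relative_quat(q_parent: np.ndarray, q_child: np.ndarray) -> np.ndarray:
    return quat_multiply(quat_conjugate(quat_normalize(q_parent)), quat_normalize(q_child))


def _euler_from_quat(q: np.ndarray, seq: str) -> np.ndarray:
    # scipy Rotation wants scalar-last
    r = Rotation.from_quat(np.atleast_2d(q)[:, [1, 2, 3, 0]])
    return r.as_euler(seq)


def joint_angles(hand: QuaternionStream, forearm: QuaternionStream,
                 upperarm: QuaternionStream) -> JointAngleSet:
    """Extract WFE, WAA, EPS, EFE from the three sensor streams.

    Wrist angles come from the forearm->hand relative rotation
    ``conj(q_forearm) (x) q_hand``, elbow angles from the upperarm->forearm
    relative rotation, each decomposed into intrinsic Euler angles per the
    module-level convention.
    """
    for other in (forearm, upperarm):
        if len(other) != len(hand) or not np.allclose(other.times, hand.times):
            raise ValueError("sensor streams do not share a time base")
    r_wrist = _relative_quat(forearm.quats, hand.quats)
    r_elbow = _relative_quat(upperarm.quats, forearm.quats)
    wrist = _euler_from_quat(r_wrist, _WRIST_SEQ)   # columns: Z, Y, X
    elbow = _euler_from_quat(r_elbow, _ELBOW_SEQ)   # columns: Z, X, Y
    return JointAngleSet(
        times=hand.times.copy(),
        wfe=wrist[:, 0],
        waa=wrist[:, 1],
        efe=elbow[:, 0],
        eps=elbow[:, 1],
    )


def compose_joint_angles(wfe: np.ndarray, waa: np.ndarray,
                         efe: np.ndarray, eps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`joint_angles`: build wrist and elbow relative
    quaternions from angle series (third Euler angle zero).

    Returns (r_wrist, r_elbow) as (n, 4) scalar-first arrays.
    """
    n = len(wfe)
    zeros = np.zeros(n)
    rw = Rotation.from_euler(_WRIST_SEQ, np.column_stack([wfe, waa, zeros]))
    re = Rotation.from_euler(_ELBOW_SEQ, np.column_stack([efe, eps, zeros]))
    return rw.as_quat()[:, [3, 0, 1, 2]], re.as_quat()[:, [3, 0, 1, 2]]


def mean_square_power(series: np.ndarray) -> float:
    """Mean of squared samples, theta_MS — the regressor of the rating model."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return float(np.mean(series**2))


def tremor_rating(powers: dict[str, float],
                  model: TremorRatingModel | None = None) -> float:
    """Evaluate the tremor-rating regression on the four joint powers.

    Parameters
    ----------
    powers : mapping with keys WFE, WAA, EPS, EFE to strictly positive
        mean-square powers (radians^2 under the default convention).
    model : rating model; defaults to the published coefficients, log base 10.
    """
    model = model or TremorRatingModel()
    rating = model.intercept
    log_base = np.log(model.log_base)
    for joint, coef in model.coefficients.items():
        theta = powers[joint]
        if not (theta > 0):
            raise ValueError(f"mean-square power for {joint} must be positive, got {theta}")
        rating += coef * np.log(theta) / log_base
    return float(rating)


def is_subclinical(rating: float, model: TremorRatingModel | None = None) -> bool:
    """True iff the rating is strictly below the subclinical threshold (0.5)."""
    if not np.isfinite(rating):
        raise ValueError("rating must be finite")
    threshold = (model or TremorRatingModel()).subclinical_threshold
    return bool(rating < threshold)
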