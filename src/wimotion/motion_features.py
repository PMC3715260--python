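"""Accelerometer calibration and spherical-angle feature extraction.

Raw counts are converted to g-units, each sensor is aligned to a common
body reference frame using the gravity vector measured while the wearer
stands still, and the signals are re-expressed in spherical coordinates.
The polar angle θ of each sensor's acceleration vector, measured from
the vertical body axis +Z, together with its time derivative dθ/dt, is
the feature set used for pose recognition: in the standing calibration
posture every calibrated sensor reads (0, 0, −1 g) — gravity pointing to
the floor — i.e. θ = 180°.

Angles are always degrees; θ ∈ [0°, 180°].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

#: raw counts per g at the ±6 g full scale (sensor-family convention;
#: configuration-overridable everywhere it is used).
COUNTS_PER_G = 340.0

#: per-axis standard deviation (g) below which a window counts as static
STATIC_THRESHOLD_G = 0.05

#: default moving-average window (s) for the θ-derivative smoothing
DERIVATIVE_SMOOTH_S = 0.25

#: body-frame direction of gravity in the standing posture
GRAVITY_DOWN = np.array([0.0, 0.0, -1.0])


def counts_to_g(counts: np.ndarray, counts_per_g: float = COUNTS_PER_G) -> np.ndarray:
    """Convert raw accelerometer counts to g-units."""
    return np.asarray(counts, dtype=float) / counts_per_g


def g_to_counts(g: np.ndarray, counts_per_g: float = COUNTS_PER_G) -> np.ndarray:
    """Quantise g-unit values to integer raw counts."""
    return np.rint(np.asarray(g, dtype=float) * counts_per_g).astype(np.int16)


def motion_level(window_g: np.ndarray, sampling_rate_hz: float = 160.0,
                 smooth_s: float = 0.25) -> float:
    """Largest per-axis standard deviation (g) of the smoothed window.

    A ``smooth_s`` moving average is applied first so that white sensor
    noise does not register as motion: the statistic responds to actual
    orientation change (trends), which survives the low-pass, rather
    than to sample-to-sample noise, which averages away.
    """
    w = np.atleast_2d(np.asarray(window_g, dtype=float))
    win = int(round(smooth_s * sampling_rate_hz))
    if win > 1 and w.shape[0] > win:
        kernel = np.ones(win) / win
        w = np.column_stack([
            np.convolve(w[:, a], kernel, mode="valid") for a in range(w.shape[1])
        ])
    return float(w.std(axis=0).max())


def is_static(window_g: np.ndarray,
              threshold_g: float = STATIC_THRESHOLD_G,
              sampling_rate_hz: float = 160.0) -> bool:
    """True if every axis of the window is quieter than ``threshold_g``."""
    return motion_level(window_g, sampling_rate_hz) < threshold_g


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Per-sensor rotation into the body frame, from the standing posture.

    ``rotation`` is the proper orthonormal 3×3 matrix that maps the
    sensor's measured mean gravity direction onto (0, 0, −1) of the body
    frame; ``residual_deg`` is the angle left between the rotated mean
    vector and straight-down after calibration (0 up to numerics).
    """

    rotation: np.ndarray
    residual_deg: float
    counts_per_g: float = COUNTS_PER_G

    def apply(self, xyz_g: np.ndarray) -> np.ndarray:
        """Rotate an (n, 3) g-unit series into the body frame."""
        return np.asarray(xyz_g, dtype=float) @ self.rotation.T


class CalibrationError(ValueError):
    pass


def minimal_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Smallest-angle rotation matrix taking unit vector ``v_from`` to ``v_to``."""
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    dot = float(np.clip(a @ b, -1.0, 1.0))
    axis = np.cross(a, b)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis /= norm
    angle = np.arctan2(norm, dot)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def calibrate(
    standing_window_g: np.ndarray,
    sampling_rate_hz: float = 160.0,
    min_duration_s: float = 1.0,
    static_threshold_g: float = STATIC_THRESHOLD_G,
    counts_per_g: float = COUNTS_PER_G,
) -> CalibrationResult:
    """Estimate the sensor→body rotation from a static standing window.

    The wearer stands with arms relaxed along the body; gravity then
    defines the vertical. The minimal (axis–angle) rotation that takes
    the window's mean acceleration direction to (0, 0, −1) aligns the
    sensor with the body frame, giving θ = 180° in standing regardless
    of how the sensor was mounted. A window shorter than
    ``min_duration_s`` or with motion above ``static_threshold_g`` is
    rejected.
    """
    w = np.atleast_2d(np.asarray(standing_window_g, dtype=float))
    if w.shape[0] < min_duration_s * sampling_rate_hz:
        raise CalibrationError(
            f"standing window of {w.shape[0]} samples is shorter than "
            f"{min_duration_s} s at {sampling_rate_hz} Hz"
        )
    level = motion_level(w, sampling_rate_hz)
    if level >= static_threshold_g:
        raise CalibrationError(
            f"standing window is not static: motion level {level:.3f} g "
            f"exceeds {static_threshold_g} g"
        )
    mean_vec = w.mean(axis=0)
    if np.linalg.norm(mean_vec) < 1e-9:
        raise CalibrationError("mean acceleration vector is null")
    rot = minimal_rotation(mean_vec, GRAVITY_DOWN)
    rotated = rot @ (mean_vec / np.linalg.norm(mean_vec))
    residual = np.degrees(
        np.arccos(np.clip(rotated @ GRAVITY_DOWN, -1.0, 1.0))
    )
    return CalibrationResult(rot, float(residual), counts_per_g)


# ---------------------------------------------------------------------------
# Spherical features
# ---------------------------------------------------------------------------

@dataclass
class SphericalSeries:
    """Per-sensor (r, θ, φ) series plus optional dθ/dt, angles in degrees."""

    r: np.ndarray
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    sampling_rate_hz: float
    dtheta_dt: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.r)


def to_spherical(xyz_g: np.ndarray,
                 sampling_rate_hz: float = 160.0) -> SphericalSeries:
    """Cartesian (n, 3) series → spherical (r, θ, φ).

    θ = arccos(z/r) is the polar angle from +Z (degrees, in [0, 180]);
    φ = atan2(y, x). Where r = 0, θ and φ are undefined and propagate
    as NaN gaps.
    """
    v = np.atleast_2d(np.asarray(xyz_g, dtype=float))
    r = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, v[:, 2] / np.where(r > 0, r, 1.0), np.nan)
        theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        phi = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    theta = np.where(r > 0, theta, np.nan)
    phi = np.where(r > 0, phi, np.nan)
    return SphericalSeries(r, theta, phi, sampling_rate_hz)


def spherical_to_cartesian(r: np.ndarray, theta_deg: np.ndarray,
                           phi_deg: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_spherical` (used for round-trip checks)."""
    t = np.radians(theta_deg)
    p = np.radians(phi_deg)
    return np.column_stack([
        r * np.sin(t) * np.cos(p),
        r * np.sin(t) * np.sin(p),
        r * np.cos(t),
    ])


def derivative(
    theta_deg: np.ndarray,
    sampling_rate_hz: float = 160.0,
    smooth_window_s: float = DERIVATIVE_SMOOTH_S,
) -> np.ndarray:
    """Smoothed derivative of a θ series, degrees per second.

    A centred moving average of ``smooth_window_s`` is applied before a
    central-difference gradient (one-sided at the edges); output length
    equals input length. Set ``smooth_window_s=0`` to disable smoothing.
    """
    theta = np.asarray(theta_deg, dtype=float)
    n = theta.size
    win = max(1, int(round(smooth_window_s * sampling_rate_hz)))
    if win > n:
        raise ValueError(
            f"smoothing window of {win} samples exceeds series length {n}"
        )
    if win > 1:
        kernel = np.ones(win) / win
        # edge-pad so the average stays centred at the boundaries
        padded = np.pad(theta, (win // 2, win - 1 - win // 2), mode="edge")
        theta = np.convolve(padded, kernel, mode="valid")
    return np.gradient(theta, 1.0 / sampling_rate_hz)


def extract_features(
    streams_g: Dict[int, np.ndarray],
    calibrations: Dict[int, CalibrationResult],
    sampling_rate_hz: float = 160.0,
    smooth_window_s: float = DERIVATIVE_SMOOTH_S,
) -> Dict[int, SphericalSeries]:
    """Calibrate each sensor stream and compute (θ, dθ/dt) features."""
    out: Dict[int, SphericalSeries] = {}
    for sensor_id, xyz in streams_g.items():
        cal = calibrations[sensor_id]
        sph = to_spherical(cal.apply(xyz), sampling_rate_hz)
        sph.dtheta_dt = derivative(
            np.nan_to_num(sph.theta_deg, nan=180.0),
            sampling_rate_hz, smooth_window_s,
        )
        out[sensor_id] = sph
    return out


# ---------------------------------------------------------------------------
# Placement verification (four-posture check)
# ---------------------------------------------------------------------------

def _signed_permutations() -> Sequence[np.ndarray]:
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for i, (j, s) in enumerate(zip(perm, signs)):
                m[i, j] = s
            mats.append(m)
    return mats


_SIGNED_PERMS = _signed_permutations()


def describe_mismounting(perm: np.ndarray) -> str:
    """Human-readable description of a signed axis permutation."""
    axes = "XYZ"
    parts = []
    for i in range(3):
        j = int(np.argmax(np.abs(perm[i])))
        sign = "-" if perm[i, j] < 0 else "+"
        parts.append(f"{axes[i]}←{sign}{axes[j]}")
    return ", ".join(parts)


@dataclass
class PlacementResult:
    """Outcome of the four-posture placement check for one sensor."""

    sensor_id: int
    passed: bool
    deviations_deg: np.ndarray  # per posture, measured vs expected
    suspected_mounting: np.ndarray  # signed permutation, identity if correct
    description: str


def verify_placement(
    posture_windows: Dict[int, np.ndarray],
    expected_references: np.ndarray,
    tolerance_deg: float = 25.0,
) -> Dict[int, PlacementResult]:
    """Check sensor mounting against four reference postures.

    Each sensor contributes the mean acceleration vector of a short
    static window in four pre-established postures (shape (4, 3), or raw
    windows of shape (4, n, 3)); ``expected_references`` holds the
    corresponding expected g-vectors in the correct mounting. A sensor
    passes when every measured vector is within ``tolerance_deg`` of its
    reference; otherwise the best-fitting signed axis permutation names
    the suspected swap/flip. The boundary decision is deterministic:
    deviations strictly below the tolerance pass, at or above fail.
    """
    expected = np.asarray(expected_references, dtype=float)
    if expected.shape[0] != 4:
        raise ValueError("exactly four reference postures are required")
    exp_unit = expected / np.linalg.norm(expected, axis=1, keepdims=True)

    results: Dict[int, PlacementResult] = {}
    for sensor_id, measured in posture_windows.items():
        m = np.asarray(measured, dtype=float)
        if m.ndim == 3:  # raw windows: reduce to mean vectors
            m = m.mean(axis=1)
        if m.shape != (4, 3):
            raise ValueError(
                f"sensor {sensor_id}: need four posture vectors, got "
                f"shape {m.shape}"
            )
        m_unit = m / np.linalg.norm(m, axis=1, keepdims=True)

        best_perm, best_err = None, np.inf
        for perm in _SIGNED_PERMS:
            corrected = m_unit @ perm.T
            err = float(
                np.degrees(
                    np.arccos(np.clip((corrected * exp_unit).sum(axis=1),
                                      -1.0, 1.0))
                ).max()
            )
            if err < best_err:
                best_perm, best_err = perm, err

        direct_dev = np.degrees(
            np.arccos(np.clip((m_unit * exp_unit).sum(axis=1), -1.0, 1.0))
        )
        passed = bool(direct_dev.max() < tolerance_deg)
        perm = np.eye(3) if passed else best_perm
        desc = "correct mounting" if passed else (
            f"suspected mis-mounting: {describe_mismounting(best_perm)}"
        )
        results[sensor_id] = PlacementResult(
            sensor_id=sensor_id,
            passed=passed,
            deviations_deg=direct_dev,
            suspected_mounting=perm,
            description=desc,
        )
    return results
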