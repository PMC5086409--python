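"""Rotate raw device axes into the uniform anatomical frame.

Every archived signal uses one axis convention regardless of device and
mounting: x = vertical (positive up, so quiet upright standing reads about
+9.81 m/s^2 on x), y = medio-lateral, z = anterior-posterior (positive
anterior; a supine lier reads about +9.81 m/s^2 on z).  The transform is a
signed axis permutation declared from the reported sensor placement (L5 or
thigh); since contributing studies perform no calibration, an optional
*gravity refinement* estimates the true vertical from a quiet segment and
applies one additional static rotation.  All three sensors (accelerometer,
gyroscope, magnetometer) are rotated by the same matrix, so vector norms are
preserved sample by sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .signal_io import GRAVITY, SensorRecording

__all__ = [
    "MountingSpec",
    "QuietWindowNotFound",
    "to_uniform_frame",
    "estimate_vertical",
    "posture_angle",
]

#: uniform-frame basis: columns/axis indices
VERTICAL, MEDIO_LATERAL, ANTERIOR_POSTERIOR = 0, 1, 2


class QuietWindowNotFound(ValueError):
    """No low-dynamics segment available for gravity refinement."""


def _check_signed_permutation(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.isin(m, (-1.0, 0.0, 1.0)).all():
        raise ValueError("axis_map must be a 3x3 matrix with entries in {-1, 0, 1}")
    if not np.allclose(m @ m.T, np.eye(3)):
        raise ValueError("axis_map must be orthogonal (a signed permutation)")
    return m


@dataclass
class MountingSpec:
    """Declared device-to-anatomical axis mapping for one placement."""

    placement: str = "L5"
    axis_map: np.ndarray = field(default_factory=lambda: np.eye(3))
    refinement: str = "declared-only"

    def __post_init__(self) -> None:
        self.axis_map = _check_signed_permutation(self.axis_map)
        if self.refinement not in ("declared-only", "gravity-refined"):
            raise ValueError(f"unknown refinement {self.refinement!r}")

    def to_dict(self) -> dict:
        return {
            "placement": self.placement,
            "axis_map": [[int(v) for v in row] for row in self.axis_map],
            "refinement": self.refinement,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MountingSpec":
        return cls(
            placement=d.get("placement", "L5"),
            axis_map=np.asarray(d.get("axis_map", np.eye(3)), dtype=float),
            refinement=d.get("refinement", "declared-only"),
        )

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.axis_map, np.eye(3))) and self.refinement == "declared-only"


def _apply_rotation(recording: SensorRecording, rot: np.ndarray) -> np.ndarray:
    out = recording.channels.copy()
    for lo in (0, 3, 6):
        block = recording.channels[:, lo:lo + 3]
        if np.isnan(block).all():
            continue
        out[:, lo:lo + 3] = block @ rot.T
    return out


def to_uniform_frame(recording: SensorRecording, mounting: MountingSpec) -> SensorRecording:
    """Rotate a raw recording into the uniform anatomical frame.

    Acc, gyro and mag are all rotated by the declared signed permutation; if
    ``mounting.refinement`` is ``"gravity-refined"`` and a quiet window can be
    found, a further static rotation aligns the measured quiet-stance gravity
    direction with the vertical axis.  Falls back to declared-only when no
    quiet window exists.
    """
    if recording.frame == "uniform":
        if mounting.is_identity:
            return recording  # already uniform; identity transform is idempotent
        raise ValueError("recording is already in the uniform frame")
    rot = mounting.axis_map
    if mounting.refinement == "gravity-refined":
        permuted = recording.with_channels(_apply_rotation(recording, rot), frame="raw")
        try:
            v = estimate_vertical(permuted)
            align, _ = Rotation.align_vectors([[1.0, 0.0, 0.0]], [v])
            rot = align.as_matrix() @ rot
        except QuietWindowNotFound:
            pass  # refinement unavailable; keep the declared mapping
    return recording.with_channels(_apply_rotation(recording, rot), frame="uniform")


def estimate_vertical(
    recording: SensorRecording,
    window: tuple[float, float] | None = None,
    min_duration_s: float = 2.0,
    max_dynamics: float = 0.6,
) -> np.ndarray:
    """Mean acceleration direction over a quiet window, as a unit 3-vector.

    ``window`` is (start, stop) in seconds relative to the recording start;
    when omitted, the quietest ``min_duration_s`` stretch is searched for.  A
    window qualifies as quiet when the standard deviation of the acceleration
    magnitude stays below ``max_dynamics`` (m/s^2).  Raises
    :class:`QuietWindowNotFound` otherwise.
    """
    fs = recording.sample_rate
    mag = np.linalg.norm(recording.acc, axis=1)
    w = max(2, int(round(min_duration_s * fs)))
    if window is not None:
        i0 = recording.index_at(window[0])
        i1 = recording.index_at(window[1]) + 1
        if i1 - i0 < w:
            raise QuietWindowNotFound(
                f"window shorter than {min_duration_s} s of samples"
            )
        seg = slice(i0, i1)
        if float(np.std(mag[seg])) > max_dynamics:
            raise QuietWindowNotFound("window dynamics exceed the quiet threshold")
        best = seg
    else:
        if mag.size < w:
            raise QuietWindowNotFound("recording shorter than the minimum quiet window")
        # rolling std via cumulative sums, O(n)
        c1 = np.concatenate([[0.0], np.cumsum(mag)])
        c2 = np.concatenate([[0.0], np.cumsum(mag * mag)])
        s1 = c1[w:] - c1[:-w]
        s2 = c2[w:] - c2[:-w]
        var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
        i = int(np.argmin(var))
        if float(np.sqrt(var[i])) > max_dynamics:
            raise QuietWindowNotFound("no quiet window below the dynamics threshold")
        best = slice(i, i + w)
    mean = recording.acc[best].mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm == 0.0:
        raise QuietWindowNotFound("zero mean acceleration in quiet window")
    return mean / norm


def gravity_lowpass(acc: np.ndarray, fs: float, cutoff_hz: float = 0.25, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass isolating the gravity component."""
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, acc, axis=0)


def posture_angle(
    recording: SensorRecording,
    cutoff_hz: float = 0.25,
) -> np.ndarray:
    """Per-sample trunk tilt (degrees) from the uniform vertical axis.

    The acceleration is low-pass filtered (4th-order zero-phase Butterworth)
    to keep only the gravity component; the returned angle is between that
    vector and the vertical axis: ~0 deg upright-stationary, ~90 deg lying.
    """
    if recording.frame != "uniform":
        raise ValueError("posture_angle requires a uniform-frame recording")
    # sosfiltfilt needs > 3 * (2*order) samples of warm-up padding
    if recording.n_samples <= 24:
        raise ValueError("recording too short for the posture filter warm-up")
    g = gravity_lowpass(recording.acc, recording.sample_rate, cutoff_hz)
    norm = np.linalg.norm(g, axis=1)
    norm[norm == 0.0] = np.finfo(float).eps
    cos = np.clip(g[:, VERTICAL] / norm, -1.0, 1.0)
    return np.degrees(np.arccos(cos))
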