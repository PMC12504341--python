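"""Constant-velocity Kalman filter on (cx, cy, a, h) box measurements.

The 8-dimensional state is (cx, cy, a, h, vx, vy, va, vh): box centre,
aspect ratio (width/height), height, and their velocities. Noise standard
deviations scale with the object's pixel height h, the standard choice for
tracking-by-detection: a box twice as tall is allowed to move and resize
twice as fast in pixels. The aspect ratio gets small fixed stds since it is
nearly constant for rigid targets seen from a fixed viewpoint.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = ["KalmanFilter"]

_NDIM = 4


class KalmanFilter:
    """Predict/update/gating for one track's (mean, covariance) pair.

    Parameters
    ----------
    std_weight_position, std_weight_velocity
        Multipliers on the height h that set the position and velocity
        noise stds (defaults 1/20 and 1/160).
    process_noise_scale, measurement_noise_scale
        Global scale factors on Q and R; setting either to 0 gives the
        noise-free limit used in consistency checks.
    """

    def __init__(
        self,
        std_weight_position: float = 1.0 / 20,
        std_weight_velocity: float = 1.0 / 160,
        process_noise_scale: float = 1.0,
        measurement_noise_scale: float = 1.0,
    ) -> None:
        self._wp = std_weight_position
        self._wv = std_weight_velocity
        self._q_scale = process_noise_scale
        self._r_scale = measurement_noise_scale
        self._motion = np.eye(2 * _NDIM)
        for i in range(_NDIM):
            self._motion[i, _NDIM + i] = 1.0  # dt = 1 frame
        self._measure = np.eye(_NDIM, 2 * _NDIM)

    def initiate(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """New track state from an unassociated measurement; zero velocity."""
        z = np.asarray(z, dtype=float)
        h = float(z[3])
        if h <= 0 or z[2] <= 0:
            raise ValueError(f"measurement must have positive a and h, got {z}")
        mean = np.concatenate([z, np.zeros(_NDIM)])
        std = [
            2 * self._wp * h, 2 * self._wp * h, 1e-2, 2 * self._wp * h,
            10 * self._wv * h, 10 * self._wv * h, 1e-5, 10 * self._wv * h,
        ]
        return mean, np.diag(np.square(std))

    def _process_cov(self, h: float) -> np.ndarray:
        std = [
            self._wp * h, self._wp * h, 1e-2, self._wp * h,
            self._wv * h, self._wv * h, 1e-5, self._wv * h,
        ]
        return self._q_scale * np.diag(np.square(std))

    def _measurement_cov(self, h: float) -> np.ndarray:
        std = [self._wp * h, self._wp * h, 1e-1, self._wp * h]
        return self._r_scale * np.diag(np.square(std))

    def predict(self, mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One frame ahead: position += velocity, covariance inflated by Q."""
        q = self._process_cov(float(mean[3]))
        mean = self._motion @ mean
        cov = self._motion @ cov @ self._motion.T + q
        return mean, (cov + cov.T) / 2.0

    def project(self, mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """State -> measurement space: (Hx, HPH' + R)."""
        r = self._measurement_cov(float(mean[3]))
        return self._measure @ mean, self._measure @ cov @ self._measure.T + r

    def update(
        self, mean: np.ndarray, cov: np.ndarray, z: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Standard Kalman correction with measurement z = (cx, cy, a, h)."""
        z = np.asarray(z, dtype=float)
        proj_mean, s = self.project(mean, cov)
        try:
            chol = scipy.linalg.cho_factor(s, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise FloatingPointError("innovation covariance is not PSD") from exc
        gain = scipy.linalg.cho_solve(chol, (cov @ self._measure.T).T, check_finite=False).T
        new_mean = mean + gain @ (z - proj_mean)
        new_cov = cov - gain @ s @ gain.T
        return new_mean, (new_cov + new_cov.T) / 2.0

    def gating_distance(
        self, mean: np.ndarray, cov: np.ndarray, measurements: np.ndarray
    ) -> np.ndarray:
        """Squared Mahalanobis distance of each measurement to the prediction."""
        measurements = np.atleast_2d(np.asarray(measurements, dtype=float))
        proj_mean, s = self.project(mean, cov)
        try:
            chol = np.linalg.cholesky(s)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(
                f"singular innovation covariance (diag={np.diag(s)})"
            ) from exc
        d = measurements - proj_mean
        z = scipy.linalg.solve_triangular(chol, d.T, lower=True, check_finite=False)
        return np.sum(z * z, axis=0)
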