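"""The moving feature system: egomotion from ground-plane optic flow.

Per frame, the angular velocities (optic flow) of the visible ground
features determine the forward speed ``v_z`` and yaw rate via a linear
least-squares fit of the two-parameter planar-motion flow model; the
estimates are then path-integrated into a location estimate. Because the
flow of ground features carries no information about wall positions, this
stream is insensitive to barrier shifts by construction -- but it
accumulates any velocity error over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import projection
from .config import NoiseSpec
from .environment import Environment
from .series import LocationEstimateSeries
from .trajectory import Trajectory


@dataclass
class GroundObservations:
    """Optic-flow observations of ground features along a trajectory.

    Row ``j`` holds the angles at the pre-step pose (sample ``j-1``) and
    the flow generated by the step velocities ``(v[j], omega[j])``; row 0
    is unused padding so that indices align with the trajectory. ``mask``
    flags features that are visible (configuration and vertical field of
    view) at each frame. ``omega_y`` is the camera-frame yaw (positive
    rightward turn, the negative of the trajectory's ccw yaw).
    """

    theta: np.ndarray       # (n, k) rad
    phi: np.ndarray         # (n, k) rad
    theta_dot: np.ndarray   # (n, k) rad/s
    phi_dot: np.ndarray     # (n, k) rad/s
    mask: np.ndarray        # (n, k) bool
    eye_height: float


def observe_ground_flow(env: Environment, traj: Trajectory) -> GroundObservations:
    """Project the ground features and evaluate the analytic flow model."""
    g_idx = np.flatnonzero(env.surface == "ground")
    pts = env.positions[g_idx]                      # (k, 3)
    d = env.config.eye_height

    x, y, phi = traj.x[:-1], traj.y[:-1], traj.phi[:-1]   # pre-step poses
    rel = pts[None, :, :] - np.stack(
        [x, y, np.full_like(x, d)], axis=1
    )[:, None, :]                                    # (n-1, k, 3)
    s, c = np.sin(phi)[:, None], np.cos(phi)[:, None]
    X = rel[:, :, 0] * s - rel[:, :, 1] * c
    Y = rel[:, :, 2]
    Z = rel[:, :, 0] * c + rel[:, :, 1] * s
    theta = np.arctan2(X, Z)
    elev = np.arctan2(Y, np.hypot(X, Z))

    v_z = traj.v[1:, None]
    omega_y = -traj.omega[1:, None]  # camera yaw is clockwise-positive
    theta_dot, phi_dot = projection.flow_ground(theta, elev, v_z, omega_y, d)

    half_vfov = np.deg2rad(env.camera.v_fov_deg / 2.0)
    mask = env.visible[g_idx][None, :] & (np.abs(elev) <= half_vfov)

    pad = np.zeros((1, len(g_idx)))
    return GroundObservations(
        theta=np.vstack([pad, theta]),
        phi=np.vstack([pad, elev]),
        theta_dot=np.vstack([pad, theta_dot]),
        phi_dot=np.vstack([pad, phi_dot]),
        mask=np.vstack([np.zeros((1, len(g_idx)), dtype=bool), mask]),
        eye_height=d,
    )


def estimate_velocity(
    theta: np.ndarray,
    phi: np.ndarray,
    theta_dot: np.ndarray,
    phi_dot: np.ndarray,
    d: float,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (v_z, omega_y) from ground-feature flow.

    Accepts ``(k,)`` arrays for a single frame or ``(n, k)`` for a batch.
    Each azimuth rate contributes the residual
    ``theta_dot - (A_i v_z - omega_y)`` and each elevation rate
    ``phi_dot - B_i v_z`` with ``A_i = -tan(phi) sin(theta) / d`` and
    ``B_i = -sin(phi)^2 cos(theta) / d``; the stationarity conditions of
    the summed squares give a 2x2 normal-equation system per frame.

    Raises if any frame has fewer than two usable features or a singular
    system (all features on the horizon).
    """
    theta = np.atleast_2d(theta)
    phi = np.atleast_2d(phi)
    theta_dot = np.atleast_2d(theta_dot)
    phi_dot = np.atleast_2d(phi_dot)
    if mask is None:
        mask = np.ones_like(theta, dtype=bool)
    mask = np.atleast_2d(mask)
    m = mask.astype(float)

    A = -np.tan(phi) * np.sin(theta) / d
    B = -np.sin(phi) ** 2 * np.cos(theta) / d
    A = np.where(mask, A, 0.0)
    B = np.where(mask, B, 0.0)
    td = np.where(mask, theta_dot, 0.0)
    pd_ = np.where(mask, phi_dot, 0.0)

    n_feat = m.sum(axis=1)
    if np.any(n_feat < 2):
        raise ValueError("need at least two ground features per frame")
    saa = (A * A + B * B).sum(axis=1)
    sa = A.sum(axis=1)
    r1 = (A * td + B * pd_).sum(axis=1)
    r2 = -td.sum(axis=1)
    det = saa * n_feat - sa * sa
    if np.any(np.abs(det) < 1e-30):
        raise ValueError("singular flow system (features on the horizon?)")
    v_hat = (n_feat * r1 - (-sa) * r2) / det
    w_hat = (saa * r2 - (-sa) * r1) / det
    return np.squeeze(v_hat), np.squeeze(w_hat)


def integrate_path(
    v_hat: np.ndarray,
    omega_hat: np.ndarray,
    x0: float,
    y0: float,
    phi0: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Path-integrate speed and (ccw) yaw estimates into a pose series.

    Mirrors the trajectory's own scheme: the heading is the running sum of
    the yaw estimates (the current step's yaw included), and the position
    the running sum of ``dt * v * (cos phi, sin phi)``. Inputs are the
    per-step estimates for steps ``1..n-1``; outputs have length ``n``
    and start at ``(x0, y0, phi0)``.
    """
    v_hat = np.asarray(v_hat)
    omega_hat = np.asarray(omega_hat)
    if v_hat.shape != omega_hat.shape:
        raise ValueError("speed and yaw series must have equal length")
    phi = phi0 + dt * np.cumsum(omega_hat)
    x = x0 + dt * np.cumsum(v_hat * np.cos(phi))
    y = y0 + dt * np.cumsum(v_hat * np.sin(phi))
    return (
        np.concatenate([[x0], x]),
        np.concatenate([[y0], y]),
        np.concatenate([[phi0], phi]),
    )


def run_moving_system(
    env: Environment,
    traj: Trajectory,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> LocationEstimateSeries:
    """Full moving-feature pipeline: observe, perturb, estimate, integrate."""
    obs = observe_ground_flow(env, traj)
    theta_dot, phi_dot = obs.theta_dot, obs.phi_dot
    if noise is not None and noise.sigma + abs(noise.mu) > 0:
        from .noise import perturb_rates

        theta_dot, phi_dot = perturb_rates(theta_dot, phi_dot, noise, rng)
    v_hat, w_hat = estimate_velocity(
        obs.theta[1:],
        obs.phi[1:],
        theta_dot[1:],
        phi_dot[1:],
        obs.eye_height,
        obs.mask[1:],
    )
    x, y, phi = integrate_path(
        v_hat, -np.atleast_1d(w_hat), traj.x[0], traj.y[0], traj.phi[0], traj.dt
    )
    return LocationEstimateSeries(t=traj.t, x=x, y=y, phi=phi, source="moving")
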