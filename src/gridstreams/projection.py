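"""Spherical-camera geometry and ground-plane optic flow.

Frames
------
World frame: right-handed, x east, y north, z up. The camera (eye) sits at
``(x, y, eye_height)`` and looks horizontally along the heading. The camera
frame follows the computer-vision convention: z along the direction of
travel, y up, x to the right (azimuth is therefore positive to the right of
the heading, i.e. clockwise when seen from above).

Projection maps a camera-frame point (X, Y, Z) to azimuth
``theta = arctan2(X, Z)`` and elevation ``phi = arctan(Y / hypot(X, Z))``;
both are invariant to the distance of the point. Elevation is positive
upward, so ground features (below the eye) have ``phi < 0``.

Flow sign convention
--------------------
The analytic ground-plane flow implemented here is the one consistent with
differentiating the projected angles along the motion (the finite-difference
oracle in the test-suite): for a camera translating with forward speed
``v_z`` and yawing at ``omega_y`` above a ground plane at eye height ``d``,

    theta_dot = -(v_z / d) * tan(phi) * sin(theta) - omega_y
    phi_dot   = -(v_z / d) * sin(phi)**2 * cos(theta)

Printed renderings of this model elsewhere differ in the sign of the
translational term (they describe feature motion rather than camera
motion); since the same model is used both to synthesize flow and to invert
it, the choice cancels in every estimate, and the convention here is the
physically consistent one.
"""

from __future__ import annotations

import numpy as np


def rotation_world_to_camera(heading_rad: float) -> np.ndarray:
    """Rows are the camera axes (right, up, forward) in world coordinates."""
    c, s = np.cos(heading_rad), np.sin(heading_rad)
    return np.array(
        [
            [s, -c, 0.0],  # camera x: right of heading
            [0.0, 0.0, 1.0],  # camera y: up
            [c, s, 0.0],  # camera z: forward
        ]
    )


def world_to_camera(
    points_world: np.ndarray, x: float, y: float, heading_rad: float, eye_height: float
) -> np.ndarray:
    """Express world points in the camera frame of the given pose."""
    rel = np.asarray(points_world, dtype=float) - np.array([x, y, eye_height])
    return rel @ rotation_world_to_camera(heading_rad).T


def camera_to_world(
    points_cam: np.ndarray, x: float, y: float, heading_rad: float, eye_height: float
) -> np.ndarray:
    """Inverse of :func:`world_to_camera`."""
    back = np.asarray(points_cam, dtype=float) @ rotation_world_to_camera(heading_rad)
    return back + np.array([x, y, eye_height])


def project(points_cam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project camera-frame points to (azimuth, elevation) in radians.

    Raises for points at the camera origin, where the direction is
    undefined.
    """
    p = np.asarray(points_cam, dtype=float)
    X, Y, Z = p[..., 0], p[..., 1], p[..., 2]
    horiz = np.hypot(X, Z)
    if np.any((horiz == 0) & (Y == 0)):
        raise ValueError("point at the camera origin has no direction")
    theta = np.arctan2(X, Z)
    phi = np.arctan2(Y, horiz)
    return theta, phi


def allocentric_bearing(theta: np.ndarray, heading_rad) -> np.ndarray:
    """World-frame direction angle (ccw from +x east) of an observed ray.

    Camera azimuth is clockwise-positive, so the allocentric bearing is
    ``heading - theta``, wrapped to (-pi, pi].
    """
    psi = np.asarray(heading_rad) - np.asarray(theta)
    return wrap_angle(psi)


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return -np.mod(-np.asarray(a) + np.pi, 2 * np.pi) + np.pi


def ground_distance(
    theta: np.ndarray,
    phi: np.ndarray,
    normal: tuple[float, float, float] = (0.0, -1.0, 0.0),
    d: float = 2.5,
) -> np.ndarray:
    """Distance along a viewing ray to a plane ``n . P = d`` (camera frame).

    For the ground plane seen from eye height ``d`` the camera-frame normal
    is (0, -1, 0) and the result reduces to ``-d / sin(phi)``, positive for
    rays below the horizon. Grazing rays (denominator near zero) yield inf.
    """
    nx, ny, nz = normal
    denom = (
        nx * np.sin(theta) * np.cos(phi)
        + ny * np.sin(phi)
        + nz * np.cos(theta) * np.cos(phi)
    )
    with np.errstate(divide="ignore"):
        return np.where(denom != 0, d / denom, np.inf)


def flow_ground(
    theta: np.ndarray,
    phi: np.ndarray,
    v_z: float,
    omega_y: float,
    d: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic angular velocities of ground features under planar motion.

    ``v_z`` is forward speed (cm/s), ``omega_y`` yaw rate (rad/s, positive
    turning right, matching the clockwise-positive azimuth), ``d`` the eye
    height (cm). Degenerate at ``phi == 0`` (the horizon; infinite ground
    distance).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    tan_phi = np.tan(phi)
    theta_dot = -(v_z / d) * tan_phi * np.sin(theta) - omega_y
    phi_dot = -(v_z / d) * np.sin(phi) ** 2 * np.cos(theta)
    return theta_dot, phi_dot


def flow_general(
    theta: np.ndarray,
    phi: np.ndarray,
    dist: np.ndarray,
    v: tuple[float, float, float],
    omega: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Angular velocities for arbitrary 3D camera motion.

    The full six-degree-of-freedom flow model; with ``v = (0, 0, v_z)``,
    ``omega = (0, omega_y, 0)`` and ``dist`` from :func:`ground_distance`
    it reduces to :func:`flow_ground` (a test-suite identity). Points move
    relative to the camera as ``P_dot = -v - omega x P``.
    """
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    # Unit direction and its angular partials (camera frame).
    u = np.stack([st * cp, sp, ct * cp], axis=-1)
    P = dist[..., None] * u
    v = np.asarray(v, dtype=float)
    omega = np.asarray(omega, dtype=float)
    P_dot = -v - np.cross(np.broadcast_to(omega, P.shape), P)
    X, Y, Z = P[..., 0], P[..., 1], P[..., 2]
    Xd, Yd, Zd = P_dot[..., 0], P_dot[..., 1], P_dot[..., 2]
    rho2 = X**2 + Z**2
    rho = np.sqrt(rho2)
    D2 = rho2 + Y**2
    theta_dot = (Xd * Z - X * Zd) / rho2
    phi_dot = (Yd * rho - Y * (X * Xd + Z * Zd) / rho) / D2
    return theta_dot, phi_dot
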