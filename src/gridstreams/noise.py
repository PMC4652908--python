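"""Gaussian observation noise, SNR matching and error-accumulation statistics.

Noise is injected in the natural domain of each stream: angular-velocity
noise (deg/s) on the optic-flow rates feeding the moving system, angle
noise (deg) on the landmark bearings feeding the static system. Because
the two domains are incommensurable, noise strengths are compared through
a domain-independent signal-to-noise ratio,

    SNR[dB] = 20 * log10( sum s_i^2 / sum (m_i - s_i)^2 ),

computed exactly in this (power-ratio inside a 20 log10) form because the
published dB figures follow from it. The azimuth components carry the
signal in both domains: the flow estimate weighs azimuth rates, and the
triangulation consumes azimuths only. Elevation components can be included
via ``components="both"``.

Directly integrated speed and yaw errors form a Brownian-motion model:
the mean squared error after ``n`` steps of i.i.d. per-step increment
errors with mean ``mu`` and std ``sigma`` is ``n sigma^2 + (n mu)^2`` --
linear growth for bias-free noise, parabolic under bias. The Cartesian
position estimate (polar-to-Cartesian transform before summation) does
not follow this model; its Euclidean error is studied empirically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NoiseSpec
from .environment import Environment
from .moving import observe_ground_flow
from .static import observe_wall_bearings
from .trajectory import Trajectory


def perturb_rates(
    theta_dot: np.ndarray,
    phi_dot: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Add i.i.d. Gaussian noise (deg/s) to angular-velocity observations."""
    if spec.domain != "angular_velocity":
        raise ValueError("rate perturbation requires an angular_velocity spec")
    if rng is None:
        rng = np.random.default_rng()
    mu, sigma = np.deg2rad(spec.mu), np.deg2rad(spec.sigma)
    return (
        theta_dot + rng.normal(mu, sigma, np.shape(theta_dot)),
        phi_dot + rng.normal(mu, sigma, np.shape(phi_dot)),
    )


def perturb_angles(
    theta: np.ndarray,
    phi: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Add i.i.d. Gaussian noise (deg) to angle observations."""
    if spec.domain != "angle":
        raise ValueError("angle perturbation requires an angle spec")
    if rng is None:
        rng = np.random.default_rng()
    mu, sigma = np.deg2rad(spec.mu), np.deg2rad(spec.sigma)
    return (
        theta + rng.normal(mu, sigma, np.shape(theta)),
        phi + rng.normal(mu, sigma, np.shape(phi)),
    )


def snr_db(signal: np.ndarray, measured: np.ndarray) -> float:
    """Domain-independent SNR, ``20 log10(sum s^2 / sum (m - s)^2)``."""
    s = np.asarray(signal, dtype=float).ravel()
    m = np.asarray(measured, dtype=float).ravel()
    if s.shape != m.shape:
        raise ValueError("signal and measurement must have equal length")
    noise_power = np.sum((m - s) ** 2)
    if noise_power == 0.0:
        return np.inf
    return float(20.0 * np.log10(np.sum(s**2) / noise_power))


def velocity_noise_snr(
    env: Environment,
    traj: Trajectory,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> float:
    """SNR of noisy optic-flow observations on ``traj``.

    The signal is the azimuthal angular velocity of every visible ground
    feature at every timestep; the measurement adds the spec's Gaussian
    noise per feature and timestep.
    """
    obs = observe_ground_flow(env, traj)
    noisy_td, _ = perturb_rates(obs.theta_dot, obs.phi_dot, spec, rng)
    m = obs.mask[1:]
    return snr_db(obs.theta_dot[1:][m], noisy_td[1:][m])


def angle_noise_snr(
    env: Environment,
    traj: Trajectory,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
    components: str = "azimuth",
) -> float:
    """SNR of noisy wall-landmark bearings on ``traj``.

    The signal is the camera azimuth of every visible wall feature at
    every timestep (``components="both"`` additionally concatenates the
    elevation angles); noise is added per feature, component and timestep.
    """
    if rng is None:
        rng = np.random.default_rng()
    d = env.config.eye_height
    half_vfov = np.deg2rad(env.camera.v_fov_deg / 2.0)
    widx = np.flatnonzero(np.isin(env.surface, ("north", "south", "west", "east")))
    pts = env.positions[widx]
    rel = pts[None, :, :] - np.stack(
        [traj.x, traj.y, np.full_like(traj.x, d)], axis=1
    )[:, None, :]
    s, c = np.sin(traj.phi)[:, None], np.cos(traj.phi)[:, None]
    X = rel[:, :, 0] * s - rel[:, :, 1] * c
    Y = rel[:, :, 2]
    Z = rel[:, :, 0] * c + rel[:, :, 1] * s
    theta = np.arctan2(X, Z)
    elev = np.arctan2(Y, np.hypot(X, Z))
    mask = env.visible[widx][None, :] & (np.abs(elev) <= half_vfov)

    theta_n, elev_n = perturb_angles(theta, elev, spec, rng)
    if components == "azimuth":
        return snr_db(theta[mask], theta_n[mask])
    if components == "both":
        sig = np.concatenate([theta[mask], elev[mask]])
        meas = np.concatenate([theta_n[mask], elev_n[mask]])
        return snr_db(sig, meas)
    raise ValueError("components must be 'azimuth' or 'both'")


@dataclass
class BrownianErrorStats:
    """Empirical vs. model error accumulation for directly integrated series."""

    lags: np.ndarray            # s
    empirical_msq: np.ndarray   # mean squared error per lag across trials
    model_msq: np.ndarray       # n sigma^2 + (n mu)^2
    mu_step: float              # per-step increment error mean
    sigma_step: float           # per-step increment error std


def brownian_stats(errors: np.ndarray, dt: float) -> BrownianErrorStats:
    """Compare accumulated-error trials against the Brownian-motion model.

    ``errors``: (n_trials, n_steps) accumulated error (estimate minus
    truth) of a directly integrated quantity (radial distance or angle),
    starting at zero. The per-step increment statistics are measured from
    the data; the model predicts mean squared error
    ``n sigma^2 + (n mu)^2`` at lag ``n``.
    """
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    if errors.shape[0] < 2:
        raise ValueError("need at least two trials for variance statistics")
    increments = np.diff(errors, axis=1, prepend=0.0)
    mu = float(np.mean(increments))
    sigma = float(np.std(increments, ddof=1))
    n = np.arange(1, errors.shape[1] + 1)
    model = n * sigma**2 + (n * mu) ** 2
    empirical = np.mean(errors**2, axis=0)
    return BrownianErrorStats(
        lags=n * dt,
        empirical_msq=empirical,
        model_msq=model,
        mu_step=mu,
        sigma_step=sigma,
    )
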