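"""End-to-end experiment orchestration.

Two experiments mirror the study design:

* the *compression experiment* runs both estimator streams in the square
  (A: 150 x 150 cm) and barrier-shifted (B: 150 x 100 cm) boxes, feeds the
  location estimates to a grid-cell generator, and scans the rate-map
  compression percentage that best matches B to A;
* the *noise experiment* perturbs the observations of both streams with
  bias-free and biased Gaussian noise on the square-box trajectory,
  reports the domain-independent SNRs, the Euclidean-error statistics
  over repeated trials, and grid maps of single noisy trials.

A single master seed spawns independent child streams for the
environment, each trajectory, the attractor initialization and every
noise channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import analysis, gridcells, moving, static
from .config import (
    ATTRACTOR_GAIN_MOVING,
    ATTRACTOR_GAIN_STATIC,
    CONFIG_A,
    CONFIG_B,
    AttractorParams,
    ExperimentConfig,
    MovementParams,
    NoiseSpec,
    RateMapParams,
    VCOParams,
    NOISE_ANG_BIAS_FREE,
    NOISE_ANG_BIASED,
    NOISE_VEL_BIAS_FREE,
    NOISE_VEL_BIASED,
)
from .environment import build_environment, derive_configuration_b
from .noise import angle_noise_snr, brownian_stats, velocity_noise_snr
from .series import LocationEstimateSeries
from .trajectory import Trajectory, synthesize_trajectory

BARRIER_SHIFT = 50.0  # cm, the A -> B displacement of the far wall


def spawn_seeds(master: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _estimates(
    env, traj, system: str, alpha: float, mem_length: float, mem_width: float
) -> LocationEstimateSeries:
    if system == "moving":
        return moving.run_moving_system(env, traj)
    if system == "static":
        return static.run_static_system(env, traj, mem_length, mem_width, alpha)
    raise ValueError(f"unknown system {system!r}")


def _spikes(
    est: LocationEstimateSeries,
    dt: float,
    grid_model: str,
    system: str,
    cfg: ExperimentConfig,
    seed: int,
) -> np.ndarray:
    if grid_model == "vco":
        params = cfg.vco_moving if system == "moving" else cfg.vco_static
        return gridcells.vco_spikes(est.positions(), est.t, params)
    if grid_model == "attractor":
        gain = ATTRACTOR_GAIN_MOVING if system == "moving" else ATTRACTOR_GAIN_STATIC
        import dataclasses

        params = dataclasses.replace(cfg.attractor, gain=gain)
        return gridcells.attractor_spikes(est.velocities(dt), params, seed)
    raise ValueError(f"unknown grid model {grid_model!r}")


@dataclass
class CompressionResult:
    """Per-system outcome of the compression experiment."""

    scan: analysis.CompressionScan
    map_a: analysis.RateMap
    map_b: analysis.RateMap
    best_percent: float
    gridness_a: float
    gridness_b: float


def run_compression_experiment(
    seed: int = 0,
    grid_model: Literal["vco", "attractor"] = "vco",
    systems: tuple[str, ...] = ("moving", "static"),
    config: ExperimentConfig | None = None,
    n_sample: int | None = None,
) -> dict[str, CompressionResult]:
    """Run configurations A and B end to end and scan the compression."""
    cfg = config or ExperimentConfig(seed=seed)
    mp = cfg.movement
    if n_sample is not None:
        import dataclasses

        mp = dataclasses.replace(mp, n_sample=n_sample)
    # one grid-model seed for both configurations: the attractor's spatial
    # phase is set by its random initial bump, and the A/B rate-map match
    # presumes the same cell (same phase) in both configurations
    s_env, s_ta, s_tb, s_grid = spawn_seeds(seed, 4)

    env_a = build_environment(cfg.box_a, s_env)
    env_b = derive_configuration_b(env_a, cfg.box_b)
    traj_a = synthesize_trajectory(env_a, mp, s_ta)
    traj_b = synthesize_trajectory(env_b, mp, s_tb)
    extent_a = (0.0, cfg.box_a.width_x, 0.0, cfg.box_a.length_y)
    extent_b = (0.0, cfg.box_b.width_x, 0.0, cfg.box_b.length_y)

    out: dict[str, CompressionResult] = {}
    for system in systems:
        est_a = _estimates(env_a, traj_a, system, cfg.alpha, cfg.box_a.length_y, cfg.box_a.width_x)
        est_b = _estimates(env_b, traj_b, system, cfg.alpha, cfg.box_a.length_y, cfg.box_a.width_x)
        spk_a = _spikes(est_a, traj_a.dt, grid_model, system, cfg, s_grid)
        spk_b = _spikes(est_b, traj_b.dt, grid_model, system, cfg, s_grid)
        map_a = analysis.rate_map(spk_a, traj_a.x, traj_a.y, traj_a.dt, extent_a, cfg.rate_map)
        map_b = analysis.rate_map(spk_b, traj_b.x, traj_b.y, traj_b.dt, extent_b, cfg.rate_map)
        scan = analysis.compression_scan(
            map_a, map_b, axis="y", shift=BARRIER_SHIFT, symmetric=True
        )
        out[system] = CompressionResult(
            scan=scan,
            map_a=map_a,
            map_b=map_b,
            best_percent=scan.best_percent,
            gridness_a=analysis.gridness(map_a),
            gridness_b=analysis.gridness(map_b),
        )
    return out


@dataclass
class NoiseCellResult:
    """One cell of the noise design (system x noise parameterization)."""

    spec: NoiseSpec
    mean_error: np.ndarray
    std_error: np.ndarray
    single_trial_error: np.ndarray
    map_: analysis.RateMap | None = None
    gridness: float | None = None


@dataclass
class NoiseExperimentResult:
    snr: dict[str, float]
    cells: dict[str, NoiseCellResult]
    brownian: dict[str, object] = field(default_factory=dict)
    t: np.ndarray | None = None


def moving_error_trials(
    env,
    traj: Trajectory,
    spec: NoiseSpec,
    n_trials: int,
    seeds: list[int],
    keep_polar: bool = False,
):
    """Repeated noisy runs of the moving system against one trajectory.

    Returns the (n_trials, n) Euclidean-error array, and when
    ``keep_polar`` also the directly integrated radial-distance and angle
    errors used by the Brownian-motion comparison.
    """
    obs = moving.observe_ground_flow(env, traj)
    errors = np.empty((n_trials, len(traj)))
    l_err = np.empty((n_trials, len(traj) - 1)) if keep_polar else None
    p_err = np.empty((n_trials, len(traj) - 1)) if keep_polar else None
    true_l = np.cumsum(traj.v[1:]) * traj.dt
    true_p = np.cumsum(traj.omega[1:]) * traj.dt
    from .noise import perturb_rates

    for k in range(n_trials):
        rng = np.random.default_rng(seeds[k])
        td, pd_ = perturb_rates(obs.theta_dot, obs.phi_dot, spec, rng)
        v_hat, w_hat = moving.estimate_velocity(
            obs.theta[1:], obs.phi[1:], td[1:], pd_[1:], obs.eye_height, obs.mask[1:]
        )
        omega_ccw = -np.atleast_1d(w_hat)
        x, y, _ = moving.integrate_path(
            v_hat, omega_ccw, traj.x[0], traj.y[0], traj.phi[0], traj.dt
        )
        errors[k] = analysis.euclidean_error(x, y, traj.x, traj.y)
        if keep_polar:
            l_err[k] = np.cumsum(v_hat) * traj.dt - true_l
            p_err[k] = np.cumsum(omega_ccw) * traj.dt - true_p
    if keep_polar:
        return errors, l_err, p_err
    return errors


def static_error_trials(
    env, traj: Trajectory, spec: NoiseSpec, n_trials: int, seeds: list[int],
    mem_length: float = 150.0, mem_width: float = 150.0, alpha: float | None = None,
):
    """Repeated noisy runs of the static system; (n_trials, n) errors."""
    from .config import TRIANGULATION_ALPHA

    alpha = TRIANGULATION_ALPHA if alpha is None else alpha
    errors = np.empty((n_trials, len(traj)))
    for k in range(n_trials):
        rng = np.random.default_rng(seeds[k])
        est = static.run_static_system(
            env, traj, mem_length, mem_width, alpha, noise=spec, rng=rng
        )
        errors[k] = analysis.euclidean_error(est.x, est.y, traj.x, traj.y)
    return errors


def run_noise_experiment(
    seed: int = 0,
    n_trials: int = 100,
    config: ExperimentConfig | None = None,
    n_sample: int | None = None,
    grid_model: Literal["vco", "attractor"] = "vco",
    with_maps: bool = True,
    with_brownian: bool = True,
) -> NoiseExperimentResult:
    """The four-cell noise design on the configuration-A trajectory."""
    cfg = config or ExperimentConfig(seed=seed)
    mp = cfg.movement
    if n_sample is not None:
        import dataclasses

        mp = dataclasses.replace(mp, n_sample=n_sample)
    s_env, s_traj, s_snr, s_grid, *trial_master = spawn_seeds(seed, 6)
    env = build_environment(cfg.box_a, s_env)
    traj = synthesize_trajectory(env, mp, s_traj)
    extent = (0.0, cfg.box_a.width_x, 0.0, cfg.box_a.length_y)

    rng_snr = np.random.default_rng(s_snr)
    snr = {
        "moving_bias_free": velocity_noise_snr(env, traj, NOISE_VEL_BIAS_FREE, rng_snr),
        "static_bias_free": angle_noise_snr(env, traj, NOISE_ANG_BIAS_FREE, rng_snr),
        "moving_biased": velocity_noise_snr(env, traj, NOISE_VEL_BIASED, rng_snr),
        "static_biased": angle_noise_snr(env, traj, NOISE_ANG_BIASED, rng_snr),
    }

    cells: dict[str, NoiseCellResult] = {}
    brownian: dict[str, object] = {}
    design = {
        "moving_bias_free": ("moving", NOISE_VEL_BIAS_FREE),
        "moving_biased": ("moving", NOISE_VEL_BIASED),
        "static_bias_free": ("static", NOISE_ANG_BIAS_FREE),
        "static_biased": ("static", NOISE_ANG_BIASED),
    }
    for name, (system, spec) in design.items():
        seeds = spawn_seeds(trial_master[0] + hash(name) % 10_000, n_trials)
        if system == "moving":
            if with_brownian:
                errors, l_err, p_err = moving_error_trials(
                    env, traj, spec, n_trials, seeds, keep_polar=True
                )
                brownian[f"{name}_distance"] = brownian_stats(l_err, traj.dt)
                brownian[f"{name}_angle"] = brownian_stats(np.rad2deg(p_err), traj.dt)
            else:
                errors = moving_error_trials(env, traj, spec, n_trials, seeds)
        else:
            errors = static_error_trials(
                env, traj, spec, n_trials, seeds,
                cfg.box_a.length_y, cfg.box_a.width_x, cfg.alpha,
            )
        mean_err, std_err = analysis.trial_error_band(errors)
        cell = NoiseCellResult(
            spec=spec,
            mean_error=mean_err,
            std_error=std_err,
            single_trial_error=errors[0],
        )
        if with_maps:
            rng = np.random.default_rng(seeds[0])
            if system == "moving":
                est = moving.run_moving_system(env, traj, noise=spec, rng=rng)
            else:
                est = static.run_static_system(
                    env, traj, cfg.box_a.length_y, cfg.box_a.width_x, cfg.alpha,
                    noise=spec, rng=rng,
                )
            spk = _spikes(est, traj.dt, grid_model, system, cfg, s_grid)
            cell.map_ = analysis.rate_map(
                spk, traj.x, traj.y, traj.dt, extent, cfg.rate_map
            )
            try:
                cell.gridness = analysis.gridness(cell.map_)
            except ValueError:
                cell.gridness = np.nan
        cells[name] = cell

    return NoiseExperimentResult(snr=snr, cells=cells, brownian=brownian, t=traj.t)


def noise_tolerance_sweep(
    seed: int,
    system: Literal["moving", "static"],
    sigmas: np.ndarray,
    mu: float = 0.0,
    config: ExperimentConfig | None = None,
    n_sample: int | None = None,
) -> dict[float, float]:
    """Gridness of the VCO map as the noise std grows; the tolerance limit
    is where recognizable grid structure (positive gridness) is lost."""
    cfg = config or ExperimentConfig(seed=seed)
    mp = cfg.movement
    if n_sample is not None:
        import dataclasses

        mp = dataclasses.replace(mp, n_sample=n_sample)
    s_env, s_traj, s_noise = spawn_seeds(seed, 3)
    env = build_environment(cfg.box_a, s_env)
    traj = synthesize_trajectory(env, mp, s_traj)
    extent = (0.0, cfg.box_a.width_x, 0.0, cfg.box_a.length_y)
    domain = "angular_velocity" if system == "moving" else "angle"
    out = {}
    for i, sigma in enumerate(np.atleast_1d(sigmas)):
        spec = NoiseSpec(domain, mu, float(sigma))
        rng = np.random.default_rng(s_noise + i)
        if system == "moving":
            est = moving.run_moving_system(env, traj, noise=spec, rng=rng)
        else:
            est = static.run_static_system(
                env, traj, cfg.box_a.length_y, cfg.box_a.width_x, cfg.alpha,
                noise=spec, rng=rng,
            )
        spk = _spikes(est, traj.dt, "vco", system, cfg, seed)
        m = analysis.rate_map(spk, traj.x, traj.y, traj.dt, extent, cfg.rate_map)
        try:
            out[float(sigma)] = analysis.gridness(m)
        except ValueError:
            out[float(sigma)] = np.nan
    return out
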