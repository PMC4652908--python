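"""Default parameter sets for the simulated box-foraging experiments.

All defaults mirror the standard study conditions: a 150 cm square arena with
50 cm walls, 54 visual features (9 per surface), a 41.67 min (50,000 sample)
session at 20 Hz, and the two grid-cell generators (oscillatory interference
and twisted-torus attractor) with their published parameter values.

Angles are degrees in configuration and file formats, radians internally.
Lengths are centimetres unless a field name says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class BoxConfig:
    """Geometry of the box arena.

    Configuration A is the 150 x 150 cm square; configuration B is the same
    box with the far (north) barrier shifted inward to 100 cm. The reference
    (0, 0) corner is held fixed across configurations.
    """

    width_x: float = 150.0
    length_y: float = 150.0
    wall_height: float = 50.0
    eye_height: float = 2.5
    features_per_surface: int = 9
    label: str = "A"

    def __post_init__(self) -> None:
        if self.width_x <= 0 or self.length_y <= 0 or self.wall_height <= 0:
            raise ValueError("box dimensions must be positive")
        if not 0 < self.eye_height < self.wall_height:
            raise ValueError("eye height must lie between floor and wall top")
        if self.features_per_surface < 1:
            raise ValueError("need at least one feature per surface")


#: The two published box configurations.
CONFIG_A = BoxConfig(label="A")
CONFIG_B = BoxConfig(length_y=100.0, label="B")


@dataclass(frozen=True)
class MovementParams:
    """Movement statistics for trajectory synthesis.

    Forward speeds are Rayleigh distributed with peak (mode) ``beta_v``;
    yaw rates are normal with mean ``mu_omega`` and std ``sigma_omega``
    (deg/s). Collision avoidance engages within ``collision_distance`` of a
    barrier, reducing speed toward ``min_speed`` and turning away.
    """

    beta_v: float = 13.25            # cm/s, Rayleigh peak of forward speed
    mu_omega: float = 0.0            # deg/s
    sigma_omega: float = 337.93      # deg/s
    f_sample: float = 20.0           # Hz
    n_sample: int = 50_000
    min_speed: float = 5.0           # cm/s
    collision_distance: float = 15.0  # cm
    x0: float = 0.0
    y0: float = 0.0
    phi0: float = 0.0                # deg, initial head direction

    def __post_init__(self) -> None:
        if self.beta_v <= 0 or self.sigma_omega <= 0:
            raise ValueError("beta_v and sigma_omega must be positive")
        if self.f_sample <= 0 or self.n_sample < 2:
            raise ValueError("invalid sampling configuration")

    @property
    def dt(self) -> float:
        return 1.0 / self.f_sample


@dataclass(frozen=True)
class CameraParams:
    """Spherical camera model. The focal length cancels in every angular
    computation and is retained for documentation only."""

    h_fov_deg: float = 360.0
    v_fov_deg: float = 120.0
    f_sphere: float = 1.0  # cm


@dataclass(frozen=True)
class VCOParams:
    """Oscillatory-interference (velocity controlled oscillator) model.

    ``beta`` sets the grid spacing via the inter-band distance 1/(beta*f);
    the dorsal (moving-system) module uses 0.004, the ventral
    (static-system) module 0.003.
    """

    f_theta: float = 7.38    # Hz, theta rhythm
    beta: float = 0.004      # 1/cm spacing parameter
    threshold: float = 1.8


@dataclass(frozen=True)
class AttractorParams:
    """Twisted-torus attractor network defaults.

    ``gain`` maps the 2D velocity (m/s) onto the bump shift; grid spacing
    shrinks as the gain grows. The read-out cell is the published linear
    index n_x*n_y - n_y//2 (1-based), stored 0-based here.
    """

    n_x: int = 9
    n_y: int = 10
    intensity: float = 0.3     # peak synaptic strength I
    inhibition: float = 0.05   # weight offset T
    gain: float = 1.4e-3       # velocity input gain (moving system default)
    sigma: float = 0.24        # m, Gaussian field width
    orientation_deg: float = 0.0
    tau: float = 0.8
    spike_threshold: float = 0.1

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def readout_index(self) -> int:
        return self.n_x * self.n_y - self.n_y // 2 - 1


#: Alternate attractor parameterization that circulates alongside the
#: defaults (stronger synapses, ten-fold smaller ventral gain); shipped for
#: completeness, the defaults above are the reference conditions.
ATTRACTOR_ALT_VARIANT = AttractorParams(n_x=9, n_y=10, intensity=0.8, gain=0.9e-4)

#: Gains for the two modules (attractor model).
ATTRACTOR_GAIN_MOVING = 1.4e-3
ATTRACTOR_GAIN_STATIC = 0.9e-3

#: VCO spacing parameters for the two modules.
VCO_BETA_MOVING = 0.004
VCO_BETA_STATIC = 0.003

#: Regularization weight of the box-dimension constraint in the
#: static-system triangulation.
TRIANGULATION_ALPHA = 1e-4


@dataclass(frozen=True)
class RateMapParams:
    bin_size: float = 3.0        # cm
    smooth_sigma: float = 3.0    # cm
    min_occupancy: float = 0.1   # s per bin


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian perturbation, i.i.d. per feature and timestep.

    ``domain`` is ``"angular_velocity"`` (applied to optic-flow rates,
    units deg/s) or ``"angle"`` (applied to landmark bearings, units deg).
    """

    domain: str = "angular_velocity"
    mu: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.domain not in ("angular_velocity", "angle"):
            raise ValueError(f"unknown noise domain {self.domain!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


#: Published noise parameterizations used in the noise study.
NOISE_VEL_BIAS_FREE = NoiseSpec("angular_velocity", 0.0, 1.75)
NOISE_VEL_BIASED = NoiseSpec("angular_velocity", 1.0, 1.75)
NOISE_ANG_BIAS_FREE = NoiseSpec("angle", 0.0, 1.0)
NOISE_ANG_BIASED = NoiseSpec("angle", 0.8, 1.0)


@dataclass
class ExperimentConfig:
    """Bundle of all parameter blocks plus the master seed."""

    box_a: BoxConfig = field(default_factory=lambda: CONFIG_A)
    box_b: BoxConfig = field(default_factory=lambda: CONFIG_B)
    movement: MovementParams = field(default_factory=MovementParams)
    camera: CameraParams = field(default_factory=CameraParams)
    vco_moving: VCOParams = field(default_factory=lambda: VCOParams(beta=VCO_BETA_MOVING))
    vco_static: VCOParams = field(default_factory=lambda: VCOParams(beta=VCO_BETA_STATIC))
    attractor: AttractorParams = field(default_factory=AttractorParams)
    rate_map: RateMapParams = field(default_factory=RateMapParams)
    alpha: float = TRIANGULATION_ALPHA
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment configuration from YAML, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    mapping = {
        "box_a": BoxConfig,
        "box_b": BoxConfig,
        "movement": MovementParams,
        "camera": CameraParams,
        "vco_moving": VCOParams,
        "vco_static": VCOParams,
        "attractor": AttractorParams,
        "rate_map": RateMapParams,
    }
    for key, cls in mapping.items():
        if key in raw:
            kwargs[key] = cls(**raw[key])
    for key in ("alpha", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return ExperimentConfig(**kwargs)
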