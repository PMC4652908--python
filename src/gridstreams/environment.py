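"""Box world: surfaces, visual features and geometric availability.

The arena is an axis-aligned box in a right-handed world frame (x east,
y north, z up) with the reference corner at the origin. Nine point features
are scattered uniformly over each of the six surfaces (ground, ceiling and
four walls), 54 in total. When the far barrier is shifted inward
(configuration B), features sitting on that barrier move rigidly with it,
and features that end up outside the compressed volume become invisible --
no ray-cast occlusion among features is modelled.

Ceiling features exist (they count toward the 54) but are consumed by
neither location estimator: the moving system reads ground features, the
static system reads wall features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BoxConfig, CameraParams, CONFIG_A, CONFIG_B
from . import projection

SURFACES = ("ground", "ceiling", "north", "south", "west", "east")
WALLS = ("north", "south", "west", "east")


@dataclass
class Environment:
    """A box configuration with its feature set.

    ``positions`` are world-frame coordinates (cm) of each feature in the
    *current* configuration; ``memorized_positions`` are the coordinates the
    same features had in configuration A (identical for configuration A
    itself). ``visible`` flags features occluded by a shifted barrier.
    """

    config: BoxConfig
    surface: np.ndarray          # (n,) str labels
    positions: np.ndarray        # (n, 3) float, current configuration
    memorized_positions: np.ndarray  # (n, 3) float, configuration-A frame
    visible: np.ndarray          # (n,) bool
    camera: CameraParams = field(default_factory=CameraParams)

    @property
    def n_features(self) -> int:
        return len(self.surface)

    def mask(self, *surfaces: str, visible_only: bool = True) -> np.ndarray:
        m = np.isin(self.surface, surfaces)
        if visible_only:
            m &= self.visible
        return m

    @property
    def ground_mask(self) -> np.ndarray:
        return self.mask("ground")

    @property
    def wall_mask(self) -> np.ndarray:
        return self.mask(*WALLS)

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) lies inside the box footprint."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= 0) & (x <= self.config.width_x) & (y >= 0) & (y <= self.config.length_y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_features),
                "surface": self.surface,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "x_mem": self.memorized_positions[:, 0],
                "y_mem": self.memorized_positions[:, 1],
                "z_mem": self.memorized_positions[:, 2],
                "visible": self.visible,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _surface_points(config: BoxConfig, surface: str, uv: np.ndarray) -> np.ndarray:
    """Map unit-square samples ``uv`` onto a surface plane."""
    w, l, h = config.width_x, config.length_y, config.wall_height
    u, v = uv[:, 0], uv[:, 1]
    if surface == "ground":
        return np.column_stack([u * w, v * l, np.zeros_like(u)])
    if surface == "ceiling":
        return np.column_stack([u * w, v * l, np.full_like(u, h)])
    if surface == "north":
        return np.column_stack([u * w, np.full_like(u, l), v * h])
    if surface == "south":
        return np.column_stack([u * w, np.zeros_like(u), v * h])
    if surface == "west":
        return np.column_stack([np.zeros_like(u), u * l, v * h])
    if surface == "east":
        return np.column_stack([np.full_like(u, config.width_x), u * l, v * h])
    raise ValueError(f"unknown surface {surface!r}")


def build_environment(config: BoxConfig = CONFIG_A, seed: int = 0) -> Environment:
    """Scatter features uniformly over the six surfaces of ``config``.

    Reproducible from ``seed``. For configuration B, call
    :func:`derive_configuration_b` on the configuration-A environment
    instead, so that both configurations share one feature set.
    """
    rng = np.random.default_rng(seed)
    k = config.features_per_surface
    surfaces, positions = [], []
    for s in SURFACES:
        uv = rng.random((k, 2))
        surfaces.append(np.full(k, s))
        positions.append(_surface_points(config, s, uv))
    pos = np.concatenate(positions)
    return Environment(
        config=config,
        surface=np.concatenate(surfaces),
        positions=pos,
        memorized_positions=pos.copy(),
        visible=np.ones(k * len(SURFACES), dtype=bool),
    )


def derive_configuration_b(env_a: Environment, config_b: BoxConfig = CONFIG_B) -> Environment:
    """Shift the far (north) barrier inward, keeping the (0, 0) corner.

    Features on the moved barrier translate rigidly with it (keeping their
    within-wall offsets); all other features keep their positions. A feature
    is invisible in B iff it lies outside the compressed box volume.
    """
    if config_b.width_x != env_a.config.width_x:
        raise ValueError("only a shift of the north barrier (y) is modelled")
    shift = env_a.config.length_y - config_b.length_y
    if shift < 0:
        raise ValueError("configuration B must be a compression of A")
    pos = env_a.positions.copy()
    on_barrier = env_a.surface == "north"
    pos[on_barrier, 1] -= shift
    eps = 1e-9
    inside = (
        (pos[:, 0] >= -eps)
        & (pos[:, 0] <= config_b.width_x + eps)
        & (pos[:, 1] >= -eps)
        & (pos[:, 1] <= config_b.length_y + eps)
        & (pos[:, 2] >= -eps)
        & (pos[:, 2] <= config_b.wall_height + eps)
    )
    return Environment(
        config=config_b,
        surface=env_a.surface.copy(),
        positions=pos,
        memorized_positions=env_a.memorized_positions.copy(),
        visible=env_a.visible & inside,
        camera=env_a.camera,
    )


def available_features(
    env: Environment,
    x: float,
    y: float,
    heading_rad: float,
) -> dict[str, np.ndarray]:
    """Indices of features geometrically available from a pose.

    A feature is available if it is visible in the current configuration and
    falls within the vertical field of view (120 deg, i.e. |elevation| <=
    60 deg). The full 360 deg of azimuth is always available (bearings are
    assumed to be held in short-term memory across head turns), so azimuth
    never excludes a feature.

    Returns a dict with ``ground`` and ``wall`` index arrays.
    """
    if not np.all(env.contains(x, y)):
        raise ValueError(f"pose ({x:.2f}, {y:.2f}) lies outside the box")
    cam = projection.world_to_camera(env.positions, x, y, heading_rad, env.config.eye_height)
    _, elev = projection.project(cam)
    half_vfov = np.deg2rad(env.camera.v_fov_deg / 2.0)
    in_fov = np.abs(elev) <= half_vfov
    ok = env.visible & in_fov
    return {
        "ground": np.flatnonzero(ok & (env.surface == "ground")),
        "wall": np.flatnonzero(ok & np.isin(env.surface, WALLS)),
    }
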