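"""Shared container for per-timestep location estimates."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LocationEstimateSeries:
    """Estimated planar pose per trajectory sample.

    ``source`` is ``"moving"`` (optic-flow path integration) or
    ``"static"`` (per-frame landmark triangulation). ``phi`` is the
    estimated heading in radians where the source provides one (the static
    system does not; it carries the true heading for bookkeeping).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    source: str

    def __len__(self) -> int:
        return len(self.t)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def velocities(self, dt: float) -> np.ndarray:
        """Temporal difference of the location estimates, cm/s, shape (n, 2).

        The first row repeats zero (no preceding sample). This is the
        velocity signal handed to the attractor grid model.
        """
        d = np.diff(self.positions(), axis=0) / dt
        return np.vstack([np.zeros((1, 2)), d])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x_hat": self.x,
                "y_hat": self.y,
                "phi_hat": np.rad2deg(self.phi),
                "source": self.source,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
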