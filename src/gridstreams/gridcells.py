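"""Grid-cell spike generators: oscillatory interference and attractor.

Two standard generators turn a location (or velocity) signal into grid-cell
spike trains. The oscillatory-interference model multiplies three
phase-offset theta-band oscillations whose phases are driven by the
location projected onto basis vectors at 0, 120 and 240 degrees; the
product crosses the spike threshold at the vertices of a hexagonal
lattice with spacing 2 / (sqrt(3) * beta * f) (inter-band distance
1/(beta*f)). The attractor model is a twisted-torus network whose activity
bump is shifted by a gained velocity input; a single read-out cell's
thresholded activity provides the spike train.

The compression phenomenology studied here does not depend on which
generator is used; both are provided so that this can be demonstrated.
"""

from __future__ import annotations

import numpy as np

from .config import AttractorParams, VCOParams


def vco_spikes(xy: np.ndarray, t: np.ndarray, params: VCOParams = VCOParams()) -> np.ndarray:
    """Oscillatory-interference spike train from a 2D location signal.

    ``xy`` in cm, shape (n, 2); ``t`` in seconds, shape (n,). A spike is
    emitted where the product over the three basis directions of
    ``cos(w t) + cos(w t + w beta x . b_k)`` exceeds the threshold,
    with ``w = 2 pi f``.
    """
    xy = np.asarray(xy, dtype=float)
    t = np.asarray(t, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) != len(t):
        raise ValueError("xy must be (n, 2) aligned with t")
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite location input")
    w = 2.0 * np.pi * params.f_theta
    angles = np.deg2rad([0.0, 120.0, 240.0])
    basis = np.column_stack([np.cos(angles), np.sin(angles)])  # (3, 2)
    proj = xy @ basis.T                                        # (n, 3)
    wt = (w * t)[:, None]
    interference = np.prod(np.cos(wt) + np.cos(wt + w * params.beta * proj), axis=1)
    return interference > params.threshold


def vco_grid_spacing(params: VCOParams = VCOParams()) -> float:
    """Hexagonal field spacing (cm) implied by the interference bands."""
    return 2.0 / (np.sqrt(3.0) * params.beta * params.f_theta)


def torus_cell_positions(params: AttractorParams) -> np.ndarray:
    """Cell coordinates on the unit twisted torus, shape (n_cells, 2).

    ``x_i = (i - 0.5)/n_x``, ``y_j = sqrt(3)/2 * (j - 0.5)/n_y``; the
    linear index runs j fastest (k = j + i * n_y).
    """
    i = np.arange(1, params.n_x + 1)
    j = np.arange(1, params.n_y + 1)
    x = (i - 0.5) / params.n_x
    y = np.sqrt(3.0) / 2.0 * (j - 0.5) / params.n_y
    xx, yy = np.meshgrid(x, y, indexing="ij")  # (n_x, n_y), j fastest
    return np.column_stack([xx.ravel(), yy.ravel()])


#: Offsets of the seven torus copies implementing the half-row twist.
_TORUS_OFFSETS = np.array(
    [
        [0.0, 0.0],
        [-1.0, 0.0],
        [1.0, 0.0],
        [-0.5, np.sqrt(3.0) / 2.0],
        [0.5, np.sqrt(3.0) / 2.0],
        [-0.5, -np.sqrt(3.0) / 2.0],
        [0.5, -np.sqrt(3.0) / 2.0],
    ]
)


def twisted_torus_sqdist(delta: np.ndarray) -> np.ndarray:
    """Squared twisted-torus distance of displacement vectors ``delta``.

    The minimum over the seven shifted copies of the plane; the half-unit
    x-offset of the vertical copies implements the twist that makes the
    wrapped lattice triangular.
    """
    delta = np.asarray(delta, dtype=float)
    shifted = delta[..., None, :] + _TORUS_OFFSETS  # (..., 7, 2)
    return np.min((shifted**2).sum(axis=-1), axis=-1)


def attractor_weights(
    params: AttractorParams, velocity: np.ndarray
) -> np.ndarray:
    """Synaptic weight matrix for one timestep given the 2D velocity (m/s)."""
    c = torus_cell_positions(params)
    gamma = np.deg2rad(params.orientation_deg)
    R = np.array([[np.cos(gamma), -np.sin(gamma)], [np.sin(gamma), np.cos(gamma)]])
    shift = params.gain * (R @ np.asarray(velocity, dtype=float))
    delta = c[:, None, :] - c[None, :, :] + shift
    sq = twisted_torus_sqdist(delta)
    return params.intensity * np.exp(-sq / params.sigma**2) - params.inhibition


def attractor_run(
    velocity: np.ndarray,
    params: AttractorParams = AttractorParams(),
    seed: int = 0,
    readout: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the twisted-torus network on a velocity series.

    ``velocity`` in cm/s, shape (n, 2). Returns ``(spikes,
    readout_activity)`` for the read-out cell. Activities are initialized
    uniformly in ``[0, 1/sqrt(n_cells)]`` and updated by
    ``b(t+1) = W(t) a(t)`` followed by half-wave-rectified mixing of the
    raw and activity-normalized drive,

        a(t+1) = [ (1 - tau) b(t+1) + tau b(t+1) / sum_i a_i(t) ]+

    Of the possible readings of this update, this is the one that is both
    dynamically stable (the population activity has an attracting fixed
    point) and tracks the commanded kernel shift at full gain, so that the
    grid spacing is ``dt / gain`` length units: 35.7 cm at the default
    20 Hz and gain 1.4e-3 (velocities in cm/s). Normalizing the whole
    mixture by the past total diverges; normalizing only a one-step-old
    drive anchors the bump and slows its tracking fivefold.
    """
    vel = np.asarray(velocity, dtype=float)
    if vel.ndim != 2 or vel.shape[1] != 2:
        raise ValueError("velocity must be (n, 2) in m/s")
    if not np.all(np.isfinite(vel)):
        raise ValueError("non-finite velocity input")
    n_steps = len(vel)
    n = params.n_cells
    if readout is None:
        readout = params.readout_index

    rng = np.random.default_rng(seed)
    a = rng.uniform(0.0, 1.0 / np.sqrt(n), size=n)

    c = torus_cell_positions(params)
    delta7 = (
        c[:, None, None, :] - c[None, :, None, :] + _TORUS_OFFSETS[None, None, :, :]
    )  # (n, n, 7, 2), velocity-independent
    gamma = np.deg2rad(params.orientation_deg)
    R = np.array([[np.cos(gamma), -np.sin(gamma)], [np.sin(gamma), np.cos(gamma)]])
    shifts = (R @ vel.T).T * params.gain  # (n_steps, 2)

    activity = _attractor_loop(
        np.ascontiguousarray(delta7),
        np.ascontiguousarray(shifts),
        a,
        params.intensity,
        params.inhibition,
        1.0 / params.sigma**2,
        params.tau,
        readout,
    )
    return activity > params.spike_threshold, activity


def _attractor_loop_py(delta7, shifts, a, intensity, inhibition, inv_sigma2, tau, readout):
    n_steps = len(shifts)
    activity = np.empty(n_steps)
    for step in range(n_steps):
        d = delta7 + shifts[step]
        sq = np.min((d**2).sum(axis=-1), axis=-1)
        W = intensity * np.exp(-sq * inv_sigma2) - inhibition
        b = W @ a
        total = max(a.sum(), 1e-12)
        a = np.maximum((1.0 - tau) * b + tau * b / total, 0.0)
        activity[step] = a[readout]
    return activity


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(fastmath=True)
    def _attractor_loop(delta7, shifts, a, intensity, inhibition, inv_sigma2, tau, readout):
        n = a.shape[0]
        n_steps = shifts.shape[0]
        activity = np.empty(n_steps)
        b = np.empty(n)
        for step in range(n_steps):
            sx, sy = shifts[step, 0], shifts[step, 1]
            total = 0.0
            for k in range(n):
                total += a[k]
            if total < 1e-12:
                total = 1e-12
            for k in range(n):
                acc = 0.0
                for l in range(n):
                    best = 1e30
                    for m in range(7):
                        dx = delta7[k, l, m, 0] + sx
                        dy = delta7[k, l, m, 1] + sy
                        sq = dx * dx + dy * dy
                        if sq < best:
                            best = sq
                    w = intensity * np.exp(-best * inv_sigma2) - inhibition
                    acc += w * a[l]
                b[k] = acc
            for k in range(n):
                mixed = (1.0 - tau) * b[k] + tau * b[k] / total
                a[k] = mixed if mixed > 0.0 else 0.0
            activity[step] = a[readout]
        return activity

except ImportError:  # pragma: no cover
    _attractor_loop = _attractor_loop_py


def attractor_spikes(
    velocity: np.ndarray,
    params: AttractorParams = AttractorParams(),
    seed: int = 0,
) -> np.ndarray:
    """Spike train of the read-out cell (see :func:`attractor_run`)."""
    spikes, _ = attractor_run(velocity, params, seed)
    return spikes
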