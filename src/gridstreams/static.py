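"""The static feature system: regularized triangulation of wall landmarks.

Per frame, the allocentric bearings of the visible wall features are
matched against the *memorized* (configuration-A) feature positions. Two
compression factors absorb conflicts between sensed angles and memorized
geometry: ``eta`` scales the memorized x-coordinates of the west/east
features and ``xi`` the memorized y-coordinates of the north/south
features. The fit minimizes

    E(x_s, y_s, eta, xi, lambda_i) =
        (1-a)/(nN+nS) * sum_{i in N,S} |(x_i, xi*y_i) - p - lambda_i u_i|^2
      + (1-a)/(nW+nE) * sum_{i in W,E} |(eta*x_i, y_i) - p - lambda_i u_i|^2
      + a/(nN*nS) * sum_{k,l} [(x_k - x_s) t_k - (x_l - x_s) t_l - xi*L]^2
      + a/(nW*nE) * sum_{m,n} [(y_n - y_s) c_n - (y_m - y_s) c_m - eta*W]^2

where ``p = (x_s, y_s)``, ``u_i`` is the observed ray direction,
``lambda_i`` the free range along it, ``t = tan(psi)`` for north/south
bearings, ``c = cot(psi)`` for west/east bearings, and ``L``, ``W`` the
memorized box dimensions. The pair terms constrain every opposite-wall
feature pair to triangulate a box of (compressed) length ``xi*L`` and
width ``eta*W``; this opposite-barrier pairing is what produces the
large-scale apparent expansion when a barrier moves.

Each ``lambda_i`` appears quadratically in exactly one term; solving its
stationarity condition replaces the term with the squared perpendicular
distance of the (compressed) memorized point from the observed ray,
reducing the problem to a symmetric 4x4 linear system per frame. The
final location estimate rescales the solution by the compression factors:
``(x_s / eta, y_s / xi)``.

In an unchanged box with noise-free bearings the functional has the exact
root ``(x_s, y_s) = truth``, ``eta = xi = 1``; after the north barrier
moves from 150 to 100 cm it has the exact root ``xi = 2/3`` with the
rescaled estimate filling the memorized 150 cm range -- the apparent
expansion. Estimation is frame-by-frame: no error accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NoiseSpec, TRIANGULATION_ALPHA
from .environment import Environment
from .projection import wrap_angle
from .series import LocationEstimateSeries
from .trajectory import Trajectory

_NS = ("north", "south")
_WE = ("west", "east")


@dataclass
class TriangulationSolution:
    """Per-frame solution of the regularized triangulation."""

    x_s: np.ndarray
    y_s: np.ndarray
    eta: np.ndarray
    xi: np.ndarray

    @property
    def x_rescaled(self) -> np.ndarray:
        return self.x_s / self.eta

    @property
    def y_rescaled(self) -> np.ndarray:
        return self.y_s / self.xi


def transform_wall_angles(psi: np.ndarray, wall: str) -> np.ndarray:
    """Per-wall transformed bearing angles (published convention).

    ``psi`` is the allocentric bearing (ccw from east) of the ray toward
    the feature. North keeps the angle, south negates it, west subtracts
    90 deg, east negates and subtracts 90 deg. The tangents of the
    transformed north/south angles and of the transformed west/east
    angles are the coefficients of the opposite-wall pair constraints.
    """
    psi = np.asarray(psi)
    if wall == "north":
        out = psi
    elif wall == "south":
        out = -psi
    elif wall == "west":
        out = psi - np.pi / 2
    elif wall == "east":
        out = -psi - np.pi / 2
    else:
        raise ValueError(f"feature not on a wall: {wall!r}")
    return wrap_angle(out)


def _pair_moments(t: np.ndarray, a: np.ndarray, m: np.ndarray):
    """Masked per-wall sums used by the pair-term expansion.

    ``t``: (n, k) tangent/cotangent coefficients; ``a``: (k,) memorized
    coordinate; ``m``: (n, k) mask. Returns (count, S1, S2, Sa, Sat) with
    S1 = sum t, S2 = sum t^2, Sa = sum a t, Sat = sum a t^2.
    """
    t = np.where(m, t, 0.0)
    cnt = m.sum(axis=1)
    return (
        cnt,
        t.sum(axis=1),
        (t * t).sum(axis=1),
        (a[None, :] * t).sum(axis=1),
        (a[None, :] * t * t).sum(axis=1),
    )


def triangulate_frames(
    psi: dict[str, np.ndarray],
    mask: dict[str, np.ndarray],
    mem_xy: dict[str, np.ndarray],
    length: float,
    width: float,
    alpha: float = TRIANGULATION_ALPHA,
) -> TriangulationSolution:
    """Solve the 4x4 triangulation system for a batch of frames.

    Parameters
    ----------
    psi : dict of (n, k_wall) allocentric bearings per wall
    mask : dict of (n, k_wall) usable-feature flags per wall
    mem_xy : dict of (k_wall, 2) memorized feature coordinates per wall
    length, width : memorized box dimensions (cm)
    alpha : regularization weight of the box-dimension pair constraints

    Raises if any frame lacks features on one of the four walls or yields
    a singular system.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = next(iter(psi.values())).shape[0]
    A = np.zeros((n, 4, 4))
    rhs = np.zeros((n, 4))

    counts = {w: mask[w].sum(axis=1) for w in (*_NS, *_WE)}
    for w in (*_NS, *_WE):
        if np.any(counts[w] == 0):
            bad = int(np.flatnonzero(counts[w] == 0)[0])
            raise ValueError(f"frame {bad}: no visible feature on the {w} wall")
    w_tri_ns = (1.0 - alpha) / (counts["north"] + counts["south"])
    w_tri_we = (1.0 - alpha) / (counts["west"] + counts["east"])

    # --- triangulation terms (lambda eliminated -> ray projections) ---
    for walls, w_tri, is_ns in ((_NS, w_tri_ns, True), (_WE, w_tri_we, False)):
        for wname in walls:
            m = mask[wname]
            p = psi[wname]
            cx = np.where(m, np.cos(p), 0.0)
            sx = np.where(m, np.sin(p), 0.0)
            # projector orthogonal to the ray: I - u u^T
            pxx = np.where(m, 1.0, 0.0) - cx * cx
            pxy = -cx * sx
            pyy = np.where(m, 1.0, 0.0) - sx * sx
            a = mem_xy[wname][:, 0][None, :]
            b = mem_xy[wname][:, 1][None, :]
            Sxx, Sxy, Syy = pxx.sum(1), pxy.sum(1), pyy.sum(1)
            A[:, 0, 0] += w_tri * Sxx
            A[:, 0, 1] += w_tri * Sxy
            A[:, 1, 1] += w_tri * Syy
            if is_ns:
                # unknown xi scales memorized y
                A[:, 0, 3] += w_tri * (-(b * pxy).sum(1))
                A[:, 1, 3] += w_tri * (-(b * pyy).sum(1))
                A[:, 3, 3] += w_tri * (b * b * pyy).sum(1)
                rhs[:, 0] -= w_tri * (-(a * pxx).sum(1))
                rhs[:, 1] -= w_tri * (-(a * pxy).sum(1))
                rhs[:, 3] -= w_tri * (a * b * pxy).sum(1)
            else:
                # unknown eta scales memorized x
                A[:, 0, 2] += w_tri * (-(a * pxx).sum(1))
                A[:, 1, 2] += w_tri * (-(a * pxy).sum(1))
                A[:, 2, 2] += w_tri * (a * a * pxx).sum(1)
                rhs[:, 0] -= w_tri * (-(b * pxy).sum(1))
                rhs[:, 1] -= w_tri * (-(b * pyy).sum(1))
                rhs[:, 2] -= w_tri * (a * b * pxy).sum(1)

    # --- opposite-wall pair terms, expanded into per-wall moments ---
    with np.errstate(divide="ignore", invalid="ignore"):
        t_n = np.tan(psi["north"])
        t_s = np.tan(psi["south"])
        c_w = np.cos(psi["west"]) / np.sin(psi["west"])
        c_e = np.cos(psi["east"]) / np.sin(psi["east"])

    # Both pair families share one algebraic pattern,
    #   (a_F - pos) g_F - (a_G - pos) g_G - comp * size
    # over pairs (F, G) of opposite-wall features: north/south with
    # g = tan(psi), position coordinate x_s and compression xi; west/east
    # with g = -cot(psi), position coordinate y_s and compression eta.
    mN = _pair_moments(t_n, mem_xy["north"][:, 0], mask["north"])
    mS = _pair_moments(t_s, mem_xy["south"][:, 0], mask["south"])
    mW = _pair_moments(-c_w, mem_xy["west"][:, 1], mask["west"])
    mE = _pair_moments(-c_e, mem_xy["east"][:, 1], mask["east"])

    for (nF, F1, F2, Fa, Fa2), (nG, G1, G2, Ga, Ga2), pos, comp, size in (
        (mN, mS, 0, 3, length),
        (mW, mE, 1, 2, width),
    ):
        w_pair = alpha / (nF * nG)
        A[:, pos, pos] += w_pair * (nG * F2 + nF * G2 - 2 * F1 * G1)
        A[:, pos, comp] += w_pair * (-size) * (nF * G1 - nG * F1)
        A[:, comp, comp] += w_pair * size**2 * nF * nG
        rhs[:, pos] -= w_pair * (G1 * Fa - nF * Ga2 - nG * Fa2 + F1 * Ga)
        rhs[:, comp] -= w_pair * (-size) * (nG * Fa - nF * Ga)

    # symmetrize
    iu = np.triu_indices(4, k=1)
    A[:, iu[1], iu[0]] = A[:, iu[0], iu[1]]

    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(rhs)):
        raise ValueError("non-finite triangulation system (degenerate bearing)")
    try:
        sol = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as err:
        raise ValueError("singular triangulation system") from err
    return TriangulationSolution(
        x_s=sol[:, 0], y_s=sol[:, 1], eta=sol[:, 2], xi=sol[:, 3]
    )


def triangulate(
    psi: np.ndarray,
    walls: np.ndarray,
    mem_xy: np.ndarray,
    length: float,
    width: float,
    alpha: float = TRIANGULATION_ALPHA,
) -> TriangulationSolution:
    """Single-frame triangulation from flat per-feature arrays.

    ``psi``: allocentric bearings; ``walls``: wall name per feature;
    ``mem_xy``: memorized planar coordinates, shape (k, 2).
    """
    psi_d, mask_d, mem_d = {}, {}, {}
    for w in (*_NS, *_WE):
        sel = np.asarray(walls) == w
        if not np.any(sel):
            raise ValueError(f"no feature on the {w} wall")
        psi_d[w] = np.asarray(psi)[sel][None, :]
        mask_d[w] = np.ones((1, sel.sum()), dtype=bool)
        mem_d[w] = np.asarray(mem_xy)[sel]
    return triangulate_frames(psi_d, mask_d, mem_d, length, width, alpha)


def observe_wall_bearings(
    env: Environment,
    traj: Trajectory,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
):
    """Allocentric bearings of wall features along a trajectory.

    Returns per-wall dicts (psi, mask, memorized xy) ready for
    :func:`triangulate_frames`. Angle-domain noise perturbs the observed
    camera azimuth and elevation; only the azimuth reaches the
    triangulation, the elevation perturbation matters for the
    signal-to-noise bookkeeping.
    """
    d = env.config.eye_height
    half_vfov = np.deg2rad(env.camera.v_fov_deg / 2.0)
    if rng is None:
        rng = np.random.default_rng()
    psi_d, mask_d, mem_d = {}, {}, {}
    for w in (*_NS, *_WE):
        idx = np.flatnonzero(env.surface == w)
        pts = env.positions[idx]
        rel = pts[None, :, :] - np.stack(
            [traj.x, traj.y, np.full_like(traj.x, d)], axis=1
        )[:, None, :]
        s, c = np.sin(traj.phi)[:, None], np.cos(traj.phi)[:, None]
        X = rel[:, :, 0] * s - rel[:, :, 1] * c
        Y = rel[:, :, 2]
        Z = rel[:, :, 0] * c + rel[:, :, 1] * s
        theta = np.arctan2(X, Z)
        elev = np.arctan2(Y, np.hypot(X, Z))
        if noise is not None and noise.sigma + abs(noise.mu) > 0:
            if noise.domain != "angle":
                raise ValueError("static system expects angle-domain noise")
            theta = theta + np.deg2rad(rng.normal(noise.mu, noise.sigma, theta.shape))
        psi_d[w] = wrap_angle(traj.phi[:, None] - theta)
        mask_d[w] = env.visible[idx][None, :] & (np.abs(elev) <= half_vfov)
        mem_d[w] = env.memorized_positions[idx][:, :2]
    return psi_d, mask_d, mem_d


def run_static_system(
    env: Environment,
    traj: Trajectory,
    length: float = 150.0,
    width: float = 150.0,
    alpha: float = TRIANGULATION_ALPHA,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    return_solution: bool = False,
):
    """Full static-feature pipeline: per-frame regularized triangulation.

    ``length`` and ``width`` are the memorized box dimensions (the
    configuration-A geometry, regardless of the current configuration).
    """
    psi_d, mask_d, mem_d = observe_wall_bearings(env, traj, noise, rng)
    sol = triangulate_frames(psi_d, mask_d, mem_d, length, width, alpha)
    est = LocationEstimateSeries(
        t=traj.t, x=sol.x_rescaled, y=sol.y_rescaled, phi=traj.phi.copy(),
        source="static",
    )
    if return_solution:
        return est, sol
    return est
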