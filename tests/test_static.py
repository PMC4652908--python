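"""Regularized triangulation: fixed points, oracle equivalence, compression."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gridstreams import (
    CONFIG_A,
    BoxConfig,
    MovementParams,
    NoiseSpec,
    build_environment,
    derive_configuration_b,
    synthesize_trajectory,
    transform_wall_angles,
)
from gridstreams.static import (
    observe_wall_bearings,
    run_static_system,
    triangulate,
    triangulate_frames,
)

ALPHA = 1e-4


def test_transform_wall_angles_branches():
    assert transform_wall_angles(0.3, "north") == pytest.approx(0.3)
    assert transform_wall_angles(0.3, "south") == pytest.approx(-0.3)
    assert transform_wall_angles(np.pi / 2, "west") == pytest.approx(0.0)
    # east: tangent equals the cotangent of the bearing
    psi = 0.7
    te = np.tan(transform_wall_angles(psi, "east"))
    assert te == pytest.approx(1 / np.tan(psi))
    with pytest.raises(ValueError):
        transform_wall_angles(0.1, "ground")


def _frame_inputs(env, x, y):
    """Bearings/masks/memorized positions for a single standing pose."""
    d = env.config.eye_height
    psi_d, mask_d, mem_d = {}, {}, {}
    for w in ("north", "south", "west", "east"):
        idx = np.flatnonzero(env.surface == w)
        pts = env.positions[idx]
        psi = np.arctan2(pts[:, 1] - y, pts[:, 0] - x)
        horiz = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
        elev = np.arctan2(pts[:, 2] - d, horiz)
        psi_d[w] = psi[None, :]
        mask_d[w] = (env.visible[idx] & (np.abs(elev) <= np.deg2rad(60)))[None, :]
        mem_d[w] = env.memorized_positions[idx][:, :2]
    return psi_d, mask_d, mem_d


def test_configuration_a_fixed_point(env_a, rng):
    """Consistent observations: exact position, eta = xi = 1."""
    for _ in range(5):
        x, y = rng.uniform(20, 130, 2)
        psi_d, mask_d, mem_d = _frame_inputs(env_a, x, y)
        sol = triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, ALPHA)
        assert sol.x_rescaled[0] == pytest.approx(x, abs=1e-8)
        assert sol.y_rescaled[0] == pytest.approx(y, abs=1e-8)
        assert sol.eta[0] == pytest.approx(1.0, abs=1e-10)
        assert sol.xi[0] == pytest.approx(1.0, abs=1e-10)


def test_configuration_b_apparent_expansion(env_b):
    """Compressed box: xi = 2/3 and the rescaled estimate maps the true
    position onto the memorized (uncompressed) range."""
    psi_d, mask_d, mem_d = _frame_inputs(env_b, 75.0, 50.0)
    sol = triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, ALPHA)
    assert sol.xi[0] == pytest.approx(2.0 / 3.0, abs=1e-8)
    assert sol.eta[0] == pytest.approx(1.0, abs=1e-8)
    assert sol.y_rescaled[0] == pytest.approx(75.0, abs=1e-6)
    assert sol.x_rescaled[0] == pytest.approx(75.0, abs=1e-6)


def _functional(env, psi_d, mask_d, mem_d, length, width, alpha):
    """Independent construction of the full objective with explicit ranges."""
    feats = []
    for w in ("north", "south"):
        for j in np.flatnonzero(mask_d[w][0]):
            feats.append(("ns", psi_d[w][0, j], mem_d[w][j]))
    for w in ("west", "east"):
        for j in np.flatnonzero(mask_d[w][0]):
            feats.append(("we", psi_d[w][0, j], mem_d[w][j]))
    n_ns = sum(1 for f in feats if f[0] == "ns")
    n_we = len(feats) - n_ns
    pn = [(psi_d["north"][0, j], mem_d["north"][j])
          for j in np.flatnonzero(mask_d["north"][0])]
    ps = [(psi_d["south"][0, j], mem_d["south"][j])
          for j in np.flatnonzero(mask_d["south"][0])]
    pw = [(psi_d["west"][0, j], mem_d["west"][j])
          for j in np.flatnonzero(mask_d["west"][0])]
    pe = [(psi_d["east"][0, j], mem_d["east"][j])
          for j in np.flatnonzero(mask_d["east"][0])]

    def E(params):
        xs, ys, eta, xi = params[:4]
        lam = params[4:]
        val = 0.0
        for i, (kind, psi, (mx, my)) in enumerate(feats):
            c, s = np.cos(psi), np.sin(psi)
            if kind == "ns":
                rx = mx - xs - lam[i] * c
                ry = xi * my - ys - lam[i] * s
                val += (1 - alpha) / n_ns * (rx**2 + ry**2)
            else:
                rx = eta * mx - xs - lam[i] * c
                ry = my - ys - lam[i] * s
                val += (1 - alpha) / n_we * (rx**2 + ry**2)
        for psi_k, (xk, _) in pn:
            for psi_l, (xl, _) in ps:
                r = (xk - xs) * np.tan(psi_k) - (xl - xs) * np.tan(psi_l) - xi * length
                val += alpha / (len(pn) * len(ps)) * r**2
        for psi_m, (_, ym) in pw:
            for psi_n, (_, yn) in pe:
                r = (yn - ys) / np.tan(psi_n) - (ym - ys) / np.tan(psi_m) - eta * width
                val += alpha / (len(pw) * len(pe)) * r**2
        return val

    return E, len(feats)


@pytest.mark.parametrize("seed", [0, 1])
def test_closed_form_matches_brute_force(env_a, seed):
    """The 4x4 solution (ranges eliminated analytically) minimizes the
    full functional: verified against numerical minimization over all
    4 + n unknowns on noisy scenes."""
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(30, 120, 2)
    psi_d, mask_d, mem_d = _frame_inputs(env_a, x, y)
    for w in psi_d:
        psi_d[w] = psi_d[w] + rng.normal(0, np.deg2rad(2.0), psi_d[w].shape)
    sol = triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, ALPHA)
    E, n_feat = _functional(env_a, psi_d, mask_d, mem_d, 150.0, 150.0, ALPHA)

    x0 = np.concatenate([[x, y, 1.0, 1.0], np.full(n_feat, 60.0)])
    res = minimize(E, x0, method="Powell",
                   options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 200000})
    assert sol.x_s[0] == pytest.approx(res.x[0], abs=1e-3)
    assert sol.y_s[0] == pytest.approx(res.x[1], abs=1e-3)
    assert sol.eta[0] == pytest.approx(res.x[2], abs=1e-5)
    assert sol.xi[0] == pytest.approx(res.x[3], abs=1e-5)
    # and the closed form is at least as good as the optimizer's endpoint
    lam_opt = np.full(n_feat, 0.0)
    assert E(np.concatenate([[sol.x_s[0], sol.y_s[0], sol.eta[0], sol.xi[0]],
                             res.x[4:]])) <= res.fun * (1 + 1e-6) + 1e-12


def test_alpha_limit_consistent_scene(env_a):
    """With self-consistent angles the solution is alpha-independent."""
    psi_d, mask_d, mem_d = _frame_inputs(env_a, 60.0, 90.0)
    s1 = triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, 1e-8)
    s2 = triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, 1e-2)
    assert s1.x_rescaled[0] == pytest.approx(s2.x_rescaled[0], abs=1e-6)
    assert s1.y_rescaled[0] == pytest.approx(s2.y_rescaled[0], abs=1e-6)


@pytest.mark.parametrize("c", [0.7, 0.85])
def test_compression_factor_recovery(c):
    """A box compressed in y by factor c yields median xi ~ c and
    estimates filling the memorized range."""
    env_a = build_environment(CONFIG_A, seed=21)
    env_c = derive_configuration_b(env_a, BoxConfig(length_y=150.0 * c, label="B"))
    traj = synthesize_trajectory(env_c, MovementParams(n_sample=2000), 5)
    est, sol = run_static_system(env_c, traj, 150.0, 150.0, ALPHA, return_solution=True)
    assert np.median(sol.xi) == pytest.approx(c, abs=0.01)
    ratio = est.y[traj.y > 5] / traj.y[traj.y > 5]
    assert np.median(ratio) == pytest.approx(1.0 / c, rel=0.02)


def test_frame_independence(env_a, traj_short):
    """Perturbing one frame's observation changes only that frame."""
    psi_d, mask_d, mem_d = observe_wall_bearings(env_a, traj_short)
    base = triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, ALPHA)
    t_hit = 100
    psi_mod = {w: p.copy() for w, p in psi_d.items()}
    psi_mod["north"][t_hit] += 0.05
    mod = triangulate_frames(psi_mod, mask_d, mem_d, 150.0, 150.0, ALPHA)
    others = np.arange(len(traj_short)) != t_hit
    np.testing.assert_allclose(mod.x_s[others], base.x_s[others], atol=1e-12)
    assert abs(mod.y_s[t_hit] - base.y_s[t_hit]) > 1e-6


def test_missing_wall_raises(env_a):
    psi_d, mask_d, mem_d = _frame_inputs(env_a, 75.0, 75.0)
    mask_d["east"][:] = False
    with pytest.raises(ValueError, match="east"):
        triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, ALPHA)
    with pytest.raises(ValueError):
        triangulate_frames(psi_d, mask_d, mem_d, 150.0, 150.0, alpha=0.0)


def test_single_frame_wrapper(env_a):
    psi_d, mask_d, mem_d = _frame_inputs(env_a, 40.0, 110.0)
    psi, walls, mem = [], [], []
    for w in ("north", "south", "west", "east"):
        keep = mask_d[w][0]
        psi.extend(psi_d[w][0][keep])
        walls.extend([w] * keep.sum())
        mem.extend(mem_d[w][keep])
    sol = triangulate(np.array(psi), np.array(walls), np.array(mem), 150.0, 150.0)
    assert sol.x_rescaled[0] == pytest.approx(40.0, abs=1e-6)
    assert sol.y_rescaled[0] == pytest.approx(110.0, abs=1e-6)


def test_noise_in_angles_only_perturbs_locally(env_a, traj_short):
    """Angle noise leaves the error series stationary (no accumulation)."""
    spec = NoiseSpec("angle", 0.0, 1.0)
    rng = np.random.default_rng(77)
    est = run_static_system(env_a, traj_short, noise=spec, rng=rng)
    err = np.hypot(est.x - traj_short.x, est.y - traj_short.y)
    n = len(err)
    early, late = err[: n // 3].mean(), err[-n // 3:].mean()
    assert late < 3 * early + 0.5  # no growth trend
    assert err.mean() < 5.0
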