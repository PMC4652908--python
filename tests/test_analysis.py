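"""Rate maps, gridness scoring and the compression scan."""

import numpy as np
import pytest

from gridstreams import RateMapParams, VCOParams, compression_scan, gridness, rate_map
from gridstreams.analysis import (
    RateMap,
    euclidean_error,
    grid_spacing_from_map,
    trial_error_band,
)
from gridstreams.gridcells import vco_spikes


def _hex_map(extent, bin_size=3.0, spacing=40.0, phase=(0.0, 0.0), noise=0.0, rng=None):
    x0, x1, y0, y1 = extent
    nx, ny = int((x1 - x0) / bin_size), int((y1 - y0) / bin_size)
    xc = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    yc = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    k = 4 * np.pi / (np.sqrt(3) * spacing)
    rate = sum(
        np.cos(k * ((X - phase[0]) * np.cos(a) + (Y - phase[1]) * np.sin(a)))
        for a in (0, np.pi / 3, 2 * np.pi / 3)
    ) + 3.0
    if noise:
        rate = rate + rng.normal(0, noise, rate.shape)
    return RateMap(rate=rate, extent=extent, bin_size=bin_size)


def test_rate_map_flat_and_empty(rng):
    n = 20000
    x = rng.uniform(0, 60, n)
    y = rng.uniform(0, 60, n)
    spikes = rng.random(n) < 0.2  # position-independent spiking
    m = rate_map(spikes, x, y, 0.05, (0, 60, 0, 60), RateMapParams(smooth_sigma=6.0))
    vals = m.rate[np.isfinite(m.rate)]
    expected = 0.2 / 0.05
    assert np.nanmean(vals) == pytest.approx(expected, rel=0.05)
    assert np.nanstd(vals) / np.nanmean(vals) < 0.2
    m0 = rate_map(np.zeros(n, bool), x, y, 0.05, (0, 60, 0, 60))
    assert np.nanmax(m0.rate) == 0.0
    with pytest.raises(ValueError):
        rate_map(np.zeros(0, bool), x[:0], y[:0], 0.05, (0, 60, 0, 60))


def test_vco_map_is_hexagonal_with_expected_spacing(env_a, traj_short):
    """VCO spikes on a real trajectory produce a hexagonal map whose
    autocorrelogram peak distance matches the interference spacing."""
    from gridstreams import MovementParams, synthesize_trajectory

    traj = synthesize_trajectory(env_a, MovementParams(n_sample=20000), 31)
    p = VCOParams(beta=0.004)
    spikes = vco_spikes(traj.positions(), traj.t, p)
    m = rate_map(spikes, traj.x, traj.y, traj.dt, (0, 150, 0, 150))
    assert gridness(m) > 0.8
    expected = 2 / (np.sqrt(3) * p.beta * p.f_theta)
    assert grid_spacing_from_map(m) == pytest.approx(expected, rel=0.12)


def test_gridness_orderings(rng):
    hexmap = _hex_map((0, 150, 0, 150))
    assert gridness(hexmap) > 1.0
    # square lattice scores negative
    xc = (np.arange(50) + 0.5) * 3.0
    X, Y = np.meshgrid(xc, xc, indexing="ij")
    sq = np.cos(2 * np.pi * X / 40) + np.cos(2 * np.pi * Y / 40) + 2
    assert gridness(RateMap(sq, (0, 150, 0, 150), 3.0)) < -0.3
    # white-noise map scores near zero on average
    scores = []
    for s in range(6):
        g = np.random.default_rng(s).random((50, 50))
        scores.append(gridness(RateMap(g, (0, 150, 0, 150), 3.0)))
    assert abs(np.mean(scores)) < 0.25
    with pytest.raises(ValueError):
        gridness(RateMap(np.ones((50, 50)), (0, 150, 0, 150), 3.0))


def test_compression_scan_identity():
    m = _hex_map((0, 150, 0, 150), phase=(7, 11))
    scan = compression_scan(m, m, axis="y", shift=50.0)
    assert abs(scan.best_percent) < 1.0
    assert np.nanmax(scan.r2) > 0.99


@pytest.mark.parametrize("p_true", [30.0, 100.0])
def test_compression_scan_known_compression(p_true, rng):
    """Maps whose underlying locations were compressed by a known fraction
    of the shift are recovered by the scan argmax."""
    extent_a = (0.0, 150.0, 0.0, 150.0)
    extent_b = (0.0, 150.0, 0.0, 100.0)
    g = (100.0 + 0.5 * p_true) / 100.0  # apparent y-magnification in B
    map_a = _hex_map(extent_a, noise=0.3, rng=rng)
    x0, x1, y0, y1 = extent_b
    nx, ny = 50, 33
    xc = (np.arange(nx) + 0.5) * 3.0
    yc = (np.arange(ny) + 0.5) * (100.0 / ny)
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    k = 4 * np.pi / (np.sqrt(3) * 40.0)
    rate = sum(
        np.cos(k * (X * np.cos(a) + g * Y * np.sin(a)))
        for a in (0, np.pi / 3, 2 * np.pi / 3)
    ) + 3.0 + rng.normal(0, 0.3, X.shape)
    map_b = RateMap(rate, extent_b, 3.0)
    scan = compression_scan(map_a, map_b, axis="y", shift=50.0)
    assert scan.best_percent == pytest.approx(p_true, abs=3.0)


def test_scan_direction_symmetry(rng):
    """Compressing A toward B and expanding B toward A agree."""
    extent_a = (0.0, 150.0, 0.0, 150.0)
    extent_b = (0.0, 150.0, 0.0, 100.0)
    map_a = _hex_map(extent_a, noise=0.2, rng=rng)
    # B records the same field pattern over the smaller area
    full = _hex_map((0.0, 150.0, 0.0, 100.0), noise=0.2, rng=rng)
    scan_ba = compression_scan(map_a, full, axis="y", shift=50.0)
    # reverse role: treat A as the map to rescale toward B's frame
    scan_ab = compression_scan(full, map_a, axis="y", shift=-50.0)
    # same geometry, opposite sign convention; both should sit near zero
    assert abs(scan_ba.best_percent) < 2.0
    assert abs(scan_ab.best_percent) < 2.0


def test_degenerate_scan_and_errors():
    m = RateMap(np.ones((50, 50)), (0, 150, 0, 150), 3.0)
    scan = compression_scan(m, m, axis="y", shift=50.0)
    with pytest.raises(ValueError):
        scan.best_percent
    with pytest.raises(ValueError):
        compression_scan(m, m, axis="z")


def test_euclidean_error_and_band(rng):
    x = rng.uniform(0, 100, 500)
    y = rng.uniform(0, 100, 500)
    assert np.all(euclidean_error(x, y, x, y) == 0)
    e = euclidean_error(x + 3, y + 4, x, y)
    np.testing.assert_allclose(e, 5.0)
    with pytest.raises(ValueError):
        euclidean_error(x[:10], y[:10], x, y)
    trials = rng.normal(10, 1, (20, 500))
    mean, std = trial_error_band(trials)
    assert mean.shape == (500,)
    assert np.all(std >= 0)
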