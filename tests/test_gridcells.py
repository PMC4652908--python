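"""Oscillatory-interference and twisted-torus attractor generators."""

import numpy as np
import pytest

from gridstreams import AttractorParams, VCOParams, attractor_spikes, vco_spikes
from gridstreams.gridcells import (
    attractor_run,
    attractor_weights,
    torus_cell_positions,
    twisted_torus_sqdist,
    vco_grid_spacing,
)

P = VCOParams()  # f = 7.38 Hz, beta = 0.004, threshold 1.8


def test_vco_origin_spikes_at_theta_peaks():
    """At the origin all phase offsets vanish: the product is (2cos wt)^3,
    crossing threshold once per theta cycle."""
    t = np.arange(0, 20, 0.0025)
    spikes = vco_spikes(np.zeros((len(t), 2)), t, P)
    # spike bursts at the theta frequency
    burst_starts = np.flatnonzero(np.diff(spikes.astype(int)) == 1)
    rate = len(burst_starts) / t[-1]
    assert rate == pytest.approx(P.f_theta, rel=0.02)
    # and exactly where (2 cos wt)^3 > threshold
    expect = (2 * np.cos(2 * np.pi * P.f_theta * t)) ** 3 > P.threshold
    np.testing.assert_array_equal(spikes, expect)


def test_vco_band_spacing():
    """Band geometry along a basis vector.

    The inter-band distance of a single oscillator pair is 1/(beta*f)
    (~33.9 cm), but along the axis itself only every other band crossing
    survives the three-way interference (the other two oscillators are in
    antiphase there), so spike-rate peaks appear every 2/(beta*f). The
    hexagonal nearest-neighbour spacing 2/(sqrt(3) beta f) lies 30 deg
    off-axis and is checked on rate maps in the analysis tests.
    """
    L = 300.0
    rng = np.random.default_rng(8)
    x = np.linspace(0, L, 60000)
    t = rng.uniform(0, 2500, 60000)  # random phases decouple space and time
    spikes = vco_spikes(np.column_stack([x, np.zeros_like(x)]), t, P)
    # spike density vs position, band peaks
    hist, edges = np.histogram(x[spikes], bins=150, range=(0, L))
    centers = (edges[:-1] + edges[1:]) / 2
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(hist, height=hist.max() * 0.3, distance=10)
    spacing = np.mean(np.diff(centers[peaks]))
    assert spacing == pytest.approx(2.0 / (P.beta * P.f_theta), rel=0.05)
    assert vco_grid_spacing(P) == pytest.approx(2 / (np.sqrt(3) * P.beta * P.f_theta))


def test_vco_lattice_translation_invariance(rng):
    """Shifting all locations by a full lattice vector leaves the spike
    pattern unchanged."""
    t = np.arange(0, 100, 0.05)
    xy = rng.uniform(0, 150, (len(t), 2))
    period = 1.0 / (P.beta * P.f_theta)  # inter-band distance
    shift = np.array([2 * period, 0.0])  # lattice vector of the band system
    s1 = vco_spikes(xy, t, P)
    s2 = vco_spikes(xy + shift, t, P)
    np.testing.assert_array_equal(s1, s2)


def test_vco_input_validation():
    with pytest.raises(ValueError):
        vco_spikes(np.full((5, 2), np.nan), np.arange(5) * 0.05, P)
    with pytest.raises(ValueError):
        vco_spikes(np.zeros((5, 3)), np.arange(5) * 0.05, P)


def test_torus_geometry():
    p = AttractorParams()
    c = torus_cell_positions(p)
    assert c.shape == (90, 2)
    assert p.readout_index == 84  # n_x*n_y - n_y/2, zero-based
    # twisted-torus distance symmetry and identity
    assert twisted_torus_sqdist(np.zeros(2)) == pytest.approx(0.0)
    d_ab = twisted_torus_sqdist(c[3] - c[40])
    d_ba = twisted_torus_sqdist(c[40] - c[3])
    assert d_ab == pytest.approx(d_ba)
    # wrap-around: a full x-period is distance zero
    assert twisted_torus_sqdist(np.array([1.0, 0.0])) == pytest.approx(0.0)
    # the twist: half an x-period combined with a y-period is also zero
    assert twisted_torus_sqdist(
        np.array([0.5, np.sqrt(3) / 2])
    ) == pytest.approx(0.0)


def test_zero_velocity_symmetric_weights_and_stable_bump():
    p = AttractorParams()
    W = attractor_weights(p, np.zeros(2))
    np.testing.assert_allclose(W, W.T, atol=1e-12)
    spikes, act = attractor_run(np.zeros((400, 2)), p, seed=0)
    assert np.all(act >= 0)
    # activity settles (bump array is a fixed point)
    assert np.std(act[-50:]) < 1e-6


def test_bump_tracks_velocity():
    """Constant velocity displaces the bump at gain * v per step."""
    p = AttractorParams()
    c = torus_cell_positions(p)
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 1 / np.sqrt(p.n_cells), p.n_cells)

    def run(a, vel, steps):
        for _ in range(steps):
            W = attractor_weights(p, vel)
            b = W @ a
            a = np.maximum((1 - p.tau) * b + p.tau * b / max(a.sum(), 1e-12), 0)
        return a

    a = run(a, np.zeros(2), 300)

    def centroid_x(a):
        ang = np.angle(np.sum(a * np.exp(2j * np.pi * c[:, 0])))
        return (ang / (2 * np.pi)) % 1.0

    x0 = centroid_x(a)
    v = np.array([13.0, 0.0])  # cm/s
    steps = 20
    a = run(a, v, steps)
    moved = (centroid_x(a) - x0) % 1.0
    expected = (-p.gain * v[0] * steps) % 1.0  # kernel shift convention
    err = min(abs(moved - expected), 1 - abs(moved - expected))
    assert err < 0.05


def test_attractor_spike_output(env_a):
    rng = np.random.default_rng(3)
    vel = rng.normal(0, 10, (3000, 2))
    p = AttractorParams()
    spikes = attractor_spikes(vel, p, seed=1)
    assert spikes.dtype == bool and len(spikes) == 3000
    s2 = attractor_spikes(vel, p, seed=1)
    np.testing.assert_array_equal(spikes, s2)  # seed determinism
    with pytest.raises(ValueError):
        attractor_spikes(np.full((10, 2), np.inf), p, seed=1)
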