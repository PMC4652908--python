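"""Quantitative read-outs: rate maps, compression matching, gridness, errors.

The compression scan is the central analysis: the rate map recorded in the
compressed box (configuration B) is rescaled along the shifted dimension by
candidate percentages of the 50 cm barrier shift (100% = the full shift,
i.e. B's 100 cm stretched back to 150 cm), resampled onto the
configuration-A map grid, and correlated with the configuration-A map over
the bins valid in both; the argmax of the squared Pearson correlation is
the best-match compression percentage.

Rate maps use standard rodent-ephys conventions: occupancy-normalized
spike counts on 3 cm bins, Gaussian-smoothed (3 cm), with low-occupancy
bins masked. The gridness score is the standard annulus-based rotational
autocorrelation statistic (min of the 60/120 deg correlations minus max
of the 30/90/150 deg correlations, maximized over the annulus outer
radius); it is used for noise-tolerance sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .config import RateMapParams
from .trajectory import Trajectory


@dataclass
class RateMap:
    """Occupancy-normalized firing-rate map. ``rate`` is (nx, ny), indexed
    [x_bin, y_bin]; masked (low-occupancy) bins are NaN. ``bin_size`` is
    the nominal request; the exact per-axis widths (the extent divided
    into a whole number of bins) are ``dx`` and ``dy``."""

    rate: np.ndarray
    extent: tuple[float, float, float, float]  # x0, x1, y0, y1
    bin_size: float

    @property
    def dx(self) -> float:
        x0, x1, _, _ = self.extent
        return (x1 - x0) / self.rate.shape[0]

    @property
    def dy(self) -> float:
        _, _, y0, y1 = self.extent
        return (y1 - y0) / self.rate.shape[1]

    @property
    def x_centers(self) -> np.ndarray:
        return self.extent[0] + self.dx * (np.arange(self.rate.shape[0]) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.extent[2] + self.dy * (np.arange(self.rate.shape[1]) + 0.5)


def rate_map(
    spikes: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    extent: tuple[float, float, float, float],
    params: RateMapParams = RateMapParams(),
) -> RateMap:
    """Bin spikes and occupancy over space and return their smoothed ratio.

    Spike counts and occupancy time are smoothed separately before
    division; bins whose raw occupancy falls below the floor are NaN.
    """
    spikes = np.asarray(spikes, dtype=bool)
    if not (len(spikes) == len(x) == len(y)):
        raise ValueError("spikes and positions must be aligned")
    if len(spikes) == 0:
        raise ValueError("empty trajectory")
    x0, x1, y0, y1 = extent
    nx = max(int(round((x1 - x0) / params.bin_size)), 1)
    ny = max(int(round((y1 - y0) / params.bin_size)), 1)
    edges_x = np.linspace(x0, x1, nx + 1)
    edges_y = np.linspace(y0, y1, ny + 1)
    occ, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    occ *= dt
    spk, _, _ = np.histogram2d(x[spikes], y[spikes], bins=[edges_x, edges_y])
    sig = params.smooth_sigma / params.bin_size
    # zero-padded smoothing: the spike/occupancy ratio then self-normalizes
    # at the arena boundary instead of reflecting fields into the map
    occ_s = ndimage.gaussian_filter(occ, sig, mode="constant")
    spk_s = ndimage.gaussian_filter(spk, sig, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = spk_s / occ_s
    rate[occ < params.min_occupancy] = np.nan
    return RateMap(rate=rate, extent=extent, bin_size=params.bin_size)


@dataclass
class CompressionScan:
    """Result of the rate-map rescaling scan."""

    percents: np.ndarray
    r2: np.ndarray

    @property
    def best_percent(self) -> float:
        """Location of the r2 maximum, refined to sub-grid precision by a
        quadratic fit through the three points around the argmax."""
        valid = np.isfinite(self.r2)
        if not np.any(valid):
            raise ValueError("no valid correlation in scan range")
        idx = np.flatnonzero(valid)[np.argmax(self.r2[valid])]
        if 0 < idx < len(self.percents) - 1 and np.all(
            np.isfinite(self.r2[idx - 1 : idx + 2])
        ):
            y0, y1, y2 = self.r2[idx - 1 : idx + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                step = float(self.percents[idx + 1] - self.percents[idx])
                return float(self.percents[idx] + 0.5 * step * (y0 - y2) / denom)
        return float(self.percents[idx])


def _resample(map_b: RateMap, xq: np.ndarray, yq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear sample of map B (and its validity) at query coordinates."""
    x0, _, y0, _ = map_b.extent
    ci = (xq - x0) / map_b.dx - 0.5
    cj = (yq - y0) / map_b.dy - 0.5
    filled = np.nan_to_num(map_b.rate, nan=0.0)
    valid = np.isfinite(map_b.rate).astype(float)
    coords = np.stack([ci.ravel(), cj.ravel()])
    vals = ndimage.map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    ok = ndimage.map_coordinates(valid, coords, order=1, mode="constant", cval=0.0)
    return vals.reshape(ci.shape), ok.reshape(ci.shape) > 0.99


def _scan_r2(
    map_ref: RateMap,
    map_mov: RateMap,
    percents: np.ndarray,
    factors: np.ndarray,
    axis: str,
    invert: bool,
    edge_margin: float,
    min_bins: int,
) -> np.ndarray:
    """r2 curve of ``map_mov`` resampled onto ``map_ref``'s grid.

    ``factors`` are the per-percentage magnifications of the moving map's
    content; with ``invert`` the reference grid is divided (stretching the
    moving map toward the reference), otherwise multiplied (compressing
    the reference's frame onto the moving map). The comparison region is
    the intersection of the valid overlaps over the whole scan, so the
    compared bin set cannot change with the candidate percentage.
    """
    rx, ry = np.meshgrid(map_ref.x_centers, map_ref.y_centers, indexing="ij")
    ref_valid = np.isfinite(map_ref.rate)
    x0, x1, y0, y1 = map_ref.extent
    ref_valid &= (
        (rx >= x0 + edge_margin)
        & (rx <= x1 - edge_margin)
        & (ry >= y0 + edge_margin)
        & (ry <= y1 - edge_margin)
    )
    mx0, mx1, my0, my1 = map_mov.extent

    all_vals, all_ok = [], []
    usable = np.zeros(len(percents), dtype=bool)
    for i, f in enumerate(factors):
        if f <= 0:
            all_vals.append(None)
            all_ok.append(None)
            continue
        g = 1.0 / f if invert else f
        xq = rx * g if axis == "x" else rx
        yq = ry * g if axis == "y" else ry
        vals, ok = _resample(map_mov, xq, yq)
        ok &= (
            (xq >= mx0 + edge_margin)
            & (xq <= mx1 - edge_margin)
            & (yq >= my0 + edge_margin)
            & (yq <= my1 - edge_margin)
        )
        all_vals.append(vals)
        all_ok.append(ok)
        usable[i] = True

    common = ref_valid.copy()
    for i in np.flatnonzero(usable):
        common &= all_ok[i]

    r2 = np.full(len(percents), np.nan)
    if common.sum() >= min_bins:
        vr = map_ref.rate[common]
        if np.std(vr) > 0:
            for i in np.flatnonzero(usable):
                vm = all_vals[i][common]
                if np.std(vm) == 0:
                    continue
                r = np.corrcoef(vr, vm)[0, 1]
                r2[i] = r * r
    return r2


def compression_scan(
    map_a: RateMap,
    map_b: RateMap,
    axis: str = "y",
    shift: float = 50.0,
    percents: np.ndarray | None = None,
    min_bins: int = 20,
    edge_margin: float | None = None,
    symmetric: bool = False,
) -> CompressionScan:
    """Best-match rescaling of map B toward map A.

    For each candidate percentage ``p`` the B map is stretched along
    ``axis`` by ``p/100 * shift`` (as a fraction of its own extent) and
    correlated with map A over the overlapping valid bins; ``r2`` is the
    squared Pearson correlation. 0% compares the maps as recorded; 100%
    stretches B by the full barrier shift.

    ``edge_margin`` (cm, default one smoothing width) excludes a band
    along each map's boundary from the correlation. The comparison region
    is additionally held *fixed* across the scan (the intersection of the
    valid overlaps over the entire percentage range): wall-adjacent bins
    are poorly occupied and noisy, and when the compared set changes with
    the rescaling, the argmax systematically profits from percentages
    that push such bins out of the overlap.

    With ``symmetric=True`` the r2 curves of the two scan directions
    (stretching B onto A's grid, and compressing A's frame onto B's grid)
    are averaged on the same percentage axis before taking the argmax,
    roughly halving the sampling variance of the best-match percentage.
    """
    if percents is None:
        percents = np.arange(-20.0, 120.0 + 0.25, 0.5)
    percents = np.asarray(percents, dtype=float)
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if edge_margin is None:
        edge_margin = map_a.bin_size
    bx0, bx1, by0, by1 = map_b.extent
    len_b = (bx1 - bx0) if axis == "x" else (by1 - by0)
    factors = (len_b + percents / 100.0 * shift) / len_b

    r2 = _scan_r2(map_a, map_b, percents, factors, axis, True, edge_margin, min_bins)
    if symmetric:
        r2_rev = _scan_r2(
            map_b, map_a, percents, factors, axis, False, edge_margin, min_bins
        )
        both = np.isfinite(r2) & np.isfinite(r2_rev)
        r2 = np.where(both, (r2 + r2_rev) / 2.0, np.nan)
    return CompressionScan(percents=percents, r2=r2)


def autocorrelogram(map_: RateMap) -> np.ndarray:
    """NaN-aware 2D Pearson spatial autocorrelation of a rate map."""
    rate = map_.rate
    mask = np.isfinite(rate).astype(float)
    z = np.nan_to_num(rate, nan=0.0)

    def corr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = corr(mask, mask)
    sx = corr(z, mask)
    sy = corr(mask, z)
    sxy = corr(z, z)
    sxx = corr(z**2, mask)
    syy = corr(mask, z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        var_a = np.maximum(n * sxx - sx**2, 0.0)
        var_b = np.maximum(n * syy - sy**2, 0.0)
        den = np.sqrt(var_a) * np.sqrt(var_b)
        ac = num / den
    # overlap too small or (near-)degenerate variance -> no estimate
    bad = (n < 20) | (den <= 1e-8 * np.nanmax(den))
    ac[bad] = np.nan
    return np.clip(ac, -1.0, 1.0)


def gridness(map_: RateMap) -> float:
    """Annulus-based rotational gridness score.

    Correlates the autocorrelogram with itself rotated by 30..150 deg
    over an annulus that excludes the central peak, maximized over the
    annulus outer radius; hexagonal maps score positive (up to ~2),
    square lattices negative, featureless maps near zero.
    """
    rate = map_.rate
    if not np.any(np.isfinite(rate)) or np.nanstd(rate) == 0:
        raise ValueError("constant or empty rate map")
    ac = autocorrelogram(map_)
    cy, cx = (np.array(ac.shape) - 1) // 2
    yy, xx = np.indices(ac.shape)
    r = np.hypot(xx - cx, yy - cy)

    # central-peak radius: first radius where the azimuthal mean drops
    # below 0.2 (fallback: 10% of the map radius)
    r_int = r.astype(int)
    finite = np.isfinite(ac)
    prof = np.array(
        [
            np.mean(ac[sel]) if np.any(sel := (r_int == k) & finite) else np.nan
            for k in range(int(r.max()) + 1)
        ]
    )
    below = np.flatnonzero(prof < 0.2)
    r_in = float(below[0]) if len(below) else max(2.0, 0.1 * r.max())
    r_max = min(cx, cy)

    filled = np.nan_to_num(ac, nan=0.0)
    rotations = {}
    for ang in (30, 60, 90, 120, 150):
        rotations[ang] = ndimage.rotate(filled, ang, reshape=False, order=1)

    best = -np.inf
    outer_candidates = np.linspace(r_in + 3, r_max, 8)
    for r_out in outer_candidates:
        annulus = (r >= r_in) & (r <= r_out) & np.isfinite(ac)
        if annulus.sum() < 50:
            continue
        base = ac[annulus]
        cors = {}
        for ang, rot in rotations.items():
            rot_vals = rot[annulus]
            if np.std(base) == 0 or np.std(rot_vals) == 0:
                cors[ang] = 0.0
            else:
                cors[ang] = np.corrcoef(base, rot_vals)[0, 1]
        score = min(cors[60], cors[120]) - max(cors[30], cors[90], cors[150])
        best = max(best, score)
    if not np.isfinite(best):
        raise ValueError("map too small for a gridness annulus")
    return float(best)


def grid_spacing_from_map(map_: RateMap) -> float:
    """Median distance (cm) of the six inner autocorrelogram peaks."""
    ac = autocorrelogram(map_)
    filled = np.nan_to_num(ac, nan=-1.0)
    cy, cx = (np.array(ac.shape) - 1) // 2
    peaks = ndimage.maximum_filter(filled, size=3) == filled
    yy, xx = np.indices(ac.shape)
    r = np.hypot(xx - cx, yy - cy)
    cand = peaks & (r > 2) & (filled > 0.1)
    if not np.any(cand):
        raise ValueError("no off-center autocorrelation peak found")
    dists = np.sort(r[cand])
    # cluster: take peaks within 1.5x the nearest peak distance
    inner = dists[dists <= dists[0] * 1.5]
    return float(np.median(inner) * (map_.dx + map_.dy) / 2.0)


def euclidean_error(
    est_x: np.ndarray, est_y: np.ndarray, true_x: np.ndarray, true_y: np.ndarray
) -> np.ndarray:
    """Per-timestep Euclidean distance between estimate and truth."""
    est_x, est_y = np.asarray(est_x), np.asarray(est_y)
    if est_x.shape != np.asarray(true_x).shape:
        raise ValueError("estimate and truth must be aligned")
    return np.hypot(est_x - true_x, est_y - true_y)


def trial_error_band(errors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial mean and std of per-timestep error curves."""
    errors = np.atleast_2d(errors)
    return errors.mean(axis=0), errors.std(axis=0, ddof=1)
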