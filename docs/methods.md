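# Methods

`gridstreams` simulates a foraging rat in a box arena whose visual input
feeds two parallel localization streams, and asks what each stream's
location estimate does to downstream grid-cell firing when a barrier of
the arena is moved. This note records the model, its assumptions, the
parameter choices, and the numerical decisions — including the places
where the design was genuinely open and what was chosen there.

## World, camera and trajectories

The arena is an axis-aligned box (configuration A: 150 × 150 cm,
configuration B: the far barrier moved inward to 150 × 100 cm; walls
50 cm high). Nine point features are scattered uniformly on each of the
six surfaces (54 total). When the barrier moves, its features move
rigidly with it; features left outside the compressed volume become
invisible (a point-in-box test — no feature-on-feature ray casting).
Ceiling features exist but feed neither estimator.

The observer is a spherical camera at eye height d = 2.5 cm looking
horizontally along the heading (no pitch or roll). Azimuth
θ = arctan2(X, Z) and elevation φ = arctan(Y/√(X²+Z²)) in a camera frame
with z forward, y up, x right; elevation is positive upward, so ground
features have φ < 0. The vertical field of view is 120° (|φ| ≤ 60°);
azimuth never excludes a feature — bearings over the full 360° are
assumed available through short-term memory across head turns.

Trajectories are synthesized at 20 Hz for 50,000 samples (41.67 min).
Forward speeds are i.i.d. Rayleigh with peak β_v = 13.25 cm/s; yaw rates
i.i.d. normal with σ_ω = 337.93 deg/s — values fitted to recorded rat
foraging. Within 15 cm of a barrier, when the heading points into it, a
two-step avoidance maneuver replaces the drawn sample: the speed drops
halfway toward the 5 cm/s minimum, and the heading rotates away by the
heading-to-normal angle plus a randomized extra rotation drawn once per
avoidance event. The extra rotation's distribution is a free choice; we
use U[0°, 20°]: it suffices to break periodic corner cycling while
keeping the fitted yaw std of synthesized sessions (~372 deg/s in A,
larger in B) as close to the reference measured values (342.49 / 357.07)
as the stated maneuver structure allows — the deterministic part of the
rotation already accounts for most of the excess over the generative σ_ω.
Integration: heading first (φ_j = φ_{j−1} + ω_j Δt), then a position step
along the new heading; collision checks use the current position; a step
that would still exit the box is clamped 0.1 cm inside the wall and that
step's recorded speed/yaw are re-derived from the realized displacement,
so the velocity series always reintegrates to the positions exactly.

## The moving feature system (optic flow → path integration)

Ground features at distance D below the horizon obey the planar-motion
flow model (derived from the projection equations and validated, sign by
sign, against finite differences of the projected angles — the printed
renderings of this model differ in the sign of the translational term,
which describes feature motion rather than camera motion and cancels
anyway since generation and inversion share one model):

    θ̇ = −(v_z/d)·tanφ·sinθ − ω_y,      φ̇ = −(v_z/d)·sin²φ·cosθ,

with ω_y the clockwise-positive camera yaw. Per frame, (v_z, ω_y) are the
linear least-squares solution over the visible ground features' rates
(2×2 normal equations; ≥2 features and a non-degenerate geometry
required). Estimates are path-integrated with the same scheme the
trajectory uses, starting from the true initial pose. Noise-free, the
estimate overlays the truth to float round-off; the system is blind to
wall positions by construction, but any velocity error accumulates.

## The static feature system (regularized triangulation)

Each frame, the allocentric bearings ψ of the visible wall features are
matched against *memorized* configuration-A feature positions under two
compression factors: ξ scales the memorized y of north/south-wall
features, η the memorized x of west/east-wall features. The objective
combines, with weights (1−α) and α = 10⁻⁴:

* per-feature triangulation terms |q_i(ξ,η) − p − λ_i u_i|², u_i the
  observed ray, λ_i a free range (eliminated exactly: each term becomes
  the squared perpendicular distance of the compressed memorized point
  from the ray);
* pairwise opposite-wall constraints, for every (north k, south l) pair
  (x_k−x_s)tanψ_k − (x_l−x_s)tanψ_l = ξL and the analogous west/east
  form with cotangents and ηW, L = W = 150 cm the memorized dimensions.

The stationarity conditions give a symmetric 4×4 linear system per frame
(solved in batch across 50,000 frames); the final estimate rescales the
solution by the factors, (x̃, ỹ) = (x̂/η̂, ŷ/ξ̂). In an unchanged box the
exact root is the true position with η̂ = ξ̂ = 1; after the 150→100 cm
barrier shift the exact root has ξ̂ = 2/3 and the rescaled estimate maps
the true position onto the memorized 150 cm range — the apparent
expansion that drives grid-field compression. Estimation is
frame-by-frame: errors never accumulate. Near-degenerate bearings
(tangents blowing up for features almost due north/south) are kept — the
quadratic form stays finite; only a fully singular system raises.
Elevations are observed (and perturbed by angle noise) but the objective
consumes azimuths only.

## Grid-cell generators

**Oscillatory interference (VCO).** A spike is emitted at sample j iff
∏_{k=1..3} [cos(ωt_j) + cos(ωt_j + ωβ x⃗_j·b⃗_k)] > Θ with ω = 2πf,
f = 7.38 Hz, Θ = 1.8, and basis vectors at 0°/120°/240°. The location
input x⃗ (cm) is the stream's estimate. β = 0.004 (moving-system module)
gives hexagonal spacing 2/(√3βf) = 39.1 cm; β = 0.003 (static-system
module) gives 52.1 cm. Along a basis axis only every other band crossing
spikes (the other two oscillators are in antiphase there), so axis-wise
peak spacing is 2/(βf); the nearest-neighbour spacing lies 30° off-axis.

**Twisted-torus attractor.** 9 × 10 cells on a unit torus with a
half-row twist (distance = minimum over seven shifted plane copies).
Per step the weight kernel w_kl = I·exp(−‖c_k−c_l+gain·R_γ v⃗‖²/σ²) − T
(I = 0.3, T = 0.05, σ = 0.24, γ = 0°) is applied, b = Wa, followed by

    a ← [ (1−τ)·b + τ·b / Σa_prev ]⁺ ,   τ = 0.8.

Of the candidate readings of this update, this is the only one that is
both dynamically stable (the population activity has an attracting fixed
point near Σa ≈ 2.7) and moves the bump at the full commanded shift;
normalizing the whole mixture diverges, and normalizing a one-step-old
drive slows bump tracking fivefold. The read-out cell (linear index
n_x·n_y − n_y/2) spikes above activity 0.1. The velocity input is the
temporal difference of the location estimates in cm/s; the grid spacing
is then Δt/gain: 35.7 cm at gain 1.4e-3 (moving module) and 55.6 cm at
0.9e-3 (static module), matching the VCO modules. Because the attractor's
spatial phase is set by its random initial bump, A/B comparisons use one
RNG seed for both runs; residual phase drift still makes attractor-based
compression scans several times noisier than VCO-based ones. An alternate
published parameterization (stronger synapses, ten-fold smaller ventral
gain) ships as `ATTRACTOR_ALT_VARIANT`; the defaults are the reference.

## Noise model and SNR

Velocity-domain noise adds i.i.d. N(μ_v, σ_v) (deg/s) to both angular
rates of every ground feature at every step; angle-domain noise adds
i.i.d. N(μ_l, σ_l) (deg) to both observed angles of every wall feature.
The domain-independent SNR is computed exactly as
20·log₁₀(Σs²/Σ(m−s)²) — a power ratio inside a 20·log₁₀, which is the
definition the reference dB figures follow. The signal is the azimuth
component in both domains (azimuth rates of ground features; azimuth
angles of wall features): with bearings nearly uniform over ±180°, one
degree of angle noise gives ≈ 80.3 dB, and the biased variant
(μ = 0.8°) ≈ 75.6 dB, both matching the reference values to well under
1 dB. An option includes elevations (which dilutes the angle-domain
signal by ~6 dB). The velocity-domain values are dominated by the yaw
term of the azimuth rate (RMS ≈ σ_ω), which puts them at ~93 dB for
σ_v = 1.75 deg/s under this definition; the reference values (~79.9 dB)
would require a signal RMS near half the yaw std and are not reproducible
from the stated construction — they are reported as computed.

Directly integrated speed and yaw errors follow a Brownian-motion model:
mean squared error after n steps of i.i.d. increment errors (μ, σ) is
nσ² + (nμ)² — linear for bias-free noise, parabolic under bias. The
measured per-step increment statistics under the standard
parameterizations (σ_l ≈ 4.7×10⁻² cm, σ_φ ≈ 3.2×10⁻² deg, biased
μ_φ ≈ 5.0×10⁻² deg) match the reference study's measured values to ~10%.
Integrated over a full session these imply Cartesian errors of order
10 cm for bias-free noise — the bias-free moving-system Euclidean error
plateaus near 7–8 cm, not near 100 cm; the larger figure sometimes quoted
for this condition is inconsistent with the per-step statistics (and with
the intact grid pattern the same condition produces). Under biased noise
the moving system's heading error grows linearly (~1 deg/s of bias), the
estimate decorrelates from the truth and the mean error climbs past
150 cm toward (and, since the estimate may leave the box, occasionally
past) the √2·150 = 212.13 cm in-box bound, while the static system's
error stays at a few cm, wide-sense stationary.

## Rate maps, compression scan, gridness

Rate maps: 3 cm bins, spike counts and occupancy (occupancy floor
100 ms) smoothed separately with a 3 cm Gaussian using zero-padded
convolution — the ratio then self-normalizes at the walls instead of
reflecting fields into the map. Maps are built against the *true*
trajectory, with spikes driven by the estimates.

The compression scan stretches the configuration-B map along the shifted
axis by p% of the 50 cm barrier shift (p from −20 to 120 in 0.5 steps;
100% restores the full 150 cm), resamples it bilinearly onto the A map's
grid and computes the squared Pearson correlation over valid overlapping
bins; the reported best match is the argmax refined by a three-point
quadratic fit. Two estimator details matter at this noise level, both
calibrated against synthetic maps with *known* imposed compressions
(0/20/50/100% by construction): a one-bin band along each map's boundary
is excluded, and the correlation region is held fixed across the entire
scan (the intersection of the valid overlaps over all p). Without the
fixed region the argmax systematically profits from rescalings that push
poorly-occupied wall-adjacent bins out of the overlap — a reproducible
−2.5-point bias. The experiment pipeline additionally averages the r²
curves of the two scan directions (stretching B onto A's grid and
compressing A's frame onto B's), which roughly halves the argmax's
sampling noise. With these, known compressions are recovered without
bias to within ±1 point, and the full pipeline yields best-match
percentages of 0.0 ± 0.3 (moving) and 99.5 ± 0.9 (static) across seeds;
the reproduction script reports the median over five independent session
pairs.

Gridness is the standard annulus statistic on the NaN-aware spatial
autocorrelogram: min(corr at 60°, 120°) − max(corr at 30°, 90°, 150°),
maximized over the annulus outer radius, with the inner radius at the
central peak's edge. It is our own definition (used for noise-tolerance
sweeps and qualitative checks); no literature grid-score values are
asserted against it.

## What the synthetic data does and does not emulate

The generator reproduces the *statistics* of rat foraging (speed and yaw
distributions, wall avoidance) and an idealized visual front end:
correspondence between features and observations is given, observations
are available over 360° of azimuth, and noise is i.i.d. Gaussian in a
single domain at a time. Real data differ in ways that matter: head
direction decouples from running direction, optic flow must be extracted
from images (with occlusions, correlated errors and outliers), landmark
identity must be maintained over time, and vestibular/proprioceptive
input contributes to self-motion estimates. Passing tests therefore show
that the two-stream mechanism produces the barrier-compression
dissociation and the error-accumulation contrast under its stated
assumptions — not that these estimators would survive raw sensory input.

## Problem sizes and numerics

Default runs use the full 50,000-sample sessions; unit tests use 2,000 to
20,000-sample sessions, which preserve every qualitative behaviour. The
noise protocol uses 100 trials. The 4×4 triangulation systems are solved
in batch (np.linalg.solve); frames missing a wall raise rather than
degrade silently. The attractor loop is numba-compiled when numba is
importable, with an equivalent pure-numpy fallback. All randomness flows
from a single master seed through named child streams (environment,
trajectories, grid model, each noise channel), so identical seeds give
byte-identical outputs.
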