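# Methods

## Model

Each fiber is a discrete 2D random walk `r_{n+1} = r_n + xi_n` whose
increments `xi_n` are two-component fractional Gaussian noise: independent
x and y sequences, each stationary, zero-mean Gaussian with autocovariance
`gamma(n) = (sigma^2/2)(|n+1|^{2H} - 2|n|^{2H} + |n-1|^{2H})`. The Hurst
index `H ∈ (0, 1)` sets the increment memory — `2^{2H-1} - 1` for adjacent
steps — and the free-path mean-square displacement scales as `n^{2H}`.
`H = 1/2` recovers ordinary Brownian motion. Fibers do not interact, have no
width, and do not branch; the model's claim is that domain geometry plus
increment persistence alone reproduce the qualitative density structure.

Confinement uses the rejected-step rule: a proposal landing outside the
allowed region is skipped — the walker keeps its position and the increment
index still advances. Rejected increments are *consumed, never resampled*;
resampling would condition the noise on the boundary and destroy the
prescribed covariance. Acceptance is decided on the joint 2D proposal (a
diagonal step into a corner dies whole). Alternative reflection rules
(mirroring, soft repulsive potentials) differ from this one only within a
boundary layer a few steps wide and are out of scope.

## Noise generation

The default generator is circulant embedding (Davies–Harte): the covariance
sequence `gamma(0..n)` is embedded in a circulant of size 2n whose
eigenvalues are obtained by FFT; a Hermitian-symmetric complex spectrum with
those variances transforms back to a Gaussian sequence with *exactly* the
target covariance. For fGn with `0 < H < 1` the eigenvalues are
non-negative; the code still checks and raises rather than silently
clipping a materially negative spectrum.

A spectral "Fourier-filtering" generator is provided as an alternative:
white noise is filtered through the square root of the power spectrum
obtained by DFT of the autocovariance periodised on a ring of length 2n,
and the first n samples are kept. Its covariance differs from the target
only by the wrap-around term `gamma(2n - l)` = O(n^{2H-2}), negligible at
any lag a test inspects for the series lengths used here. Covariance
agreement — not bit-level agreement between the two methods — is the
contract, and both methods pass the same covariance tests.

Ensembles draw randomness from `numpy` `SeedSequence` sub-streams: the
master seed spawns one child per fiber, and each fiber child spawns
(noise-x, noise-y, start-position) streams. Results are therefore
bit-reproducible and independent of execution order, and any fiber can be
regenerated in isolation.

Sampling-statistics note: when testing the generator, the sample
autocovariance is computed *without* subtracting the sample mean. The
process has exactly zero mean by construction, while subtracting the sample
mean of a long-range-correlated series biases low-lag covariances downward
by O(n^{2H-2}) — about 0.013 at H = 0.8, n = 2^16 — which would swamp a
±0.01 tolerance for spurious reasons.

## Domains

The allowed region is **closed** (boundary points are allowed); inner
forbidden regions are **open** sets, so obstacle boundaries remain
reachable. This removes zero-measure ambiguity from the rejection rule.

Three domain families:

* **Row-interval domains** encode a digitized closed contour as an N×2
  integer matrix: for each consecutive integer row Y, the leftmost and
  rightmost allowed X. A continuous position maps to the nearest integer
  row (ties away from zero, which keeps the convention mirror-symmetric)
  after division by the lattice scale. Y-axis concavities cannot be encoded
  and must be supplied as separate inner contours; all inner contours act
  as impenetrable obstacles regardless of their anatomical nature.
* **Lobed ring**: `R_inner = 50 <= r <= R_outer(phi) = 100 (1 + 0.5 cos^2(4 phi))`
  — eight lobes, apices of radius 150 at `phi = k pi/4` (high curvature)
  and valleys of radius 100 at `phi = pi/8 + k pi/4`. An abstraction of a
  neural-tube cross-section whose hollow is the ventricular space.
* **Crowded disk**: radius 100, packed with 1013 non-overlapping obstacles
  of radius 2 placed entirely inside radius 90 (center distance
  ≤ 88), leaving an outer rim of width 10 free — an abstracted cortical
  patch whose rim plays the role of the soma-free layer I. "Inside radius
  90" is read as the whole obstacle inside, since the rim is stated to be
  unoccupied; obstacles are distinct cell bodies, hence non-overlapping
  (touching allowed). Placement is random sequential packing with a
  neighbour grid; the requested density (~52 % area fraction) sits close to
  the 2D jamming limit (~54.7 %), so placement needs a few times 10^4
  candidate draws — an explicit attempt budget plus a hexagonal-packing
  area bound turn impossible requests into immediate errors.

### Contour digitization

The pipeline mirrors how hand-traced section contours become row-interval
matrices: coordinates are divided by an integer reduction factor,
rasterised at integer rows, re-enlarged by the same factor, and the rows
introduced by the enlargement are filled by linear interpolation between
the nearest available rows. Each reduced row must be supported by at least
four sampled vertices, otherwise the factor is declared too coarse for the
shape and the error says to lower it. Inputs are densified along edges
(spacing 0.25 reduced units by default) so sparse vertex lists — a
four-corner rectangle — digitize correctly.

Design choice: row extremes are computed where the reduced contour *crosses*
each integer row, and a lattice X belongs to the row iff it lies inside the
crossing interval (center-sampling rasterization, `ceil(min)`/`floor(max)`
with a 1e-6 snap for float fuzz). Rounding band extremes to the nearest
integer instead would dilate every shape by about half a cell; with center
sampling, convex polygons reproduce scanline min/max intersections exactly
and a radius-50 lattice circle digitizes with 99.9 % lattice agreement,
every disagreement lying exactly on the true boundary.

`smooth_and_symmetrize` extracts the half of a closed contour right of the
chosen sagittal axis between its bottom and top axis crossings, smooths it
with a centred moving average (window 1 = identity; the window is a free
parameter, default 9 for the synthetic brain-like fixture), pins the ends
to the axis, and mirrors it, so the output point set is *exactly* invariant
under reflection — compensating tracing and sectioning asymmetry the way a
digitized section contour would be.

## Density grids and the optical transform

The simulated density `d_s` of a cell is the number of walk positions in it
— the start plus every post-step position, *including* rejected-step
repeats. (Counting geometric segment–cell crossings instead would change
counts by O(1) per crossing; occupancy is simpler, deterministic, and is
the measure whose stationary profile the theory addresses.) Cells are
square, half-open, lower-left anchored; grid totals obey the conservation
law `n_fibers * (n_steps + 1)` on every run.

For image comparison, counts map to `d_o = 1 - exp(-k d_s)` ∈ [0, 1). The
attenuation `k` is fitted by bracketing + Brent so that the mean of `d_o`
over in-domain cells (cells outside the domain have no pixel analog)
matches a target mean to 1e-9; the mean is strictly increasing in `k` and
its supremum is the fraction of cells with positive counts, so infeasible
targets fail fast. Density cuts sample bilinear interpolation of
cell-center values along a segment.

## Validation statistics

**MSD / Hurst.** Free-path MSD averages over fibers *and* time origins
(valid under stationary increments; FFT-based, O(n log n)). The Hurst
estimate is half the log–log slope over lags 10–1000, fitted on log-spaced
lags so each decade weighs equally. Recovery at desk scale (64 × 2^15) is
accurate to ~0.005 for H ∈ {0.3, 0.5, 0.8}.

**Boundary index.** Mean occupancy of in-domain cells whose center lies
within a band of the outer boundary, divided by the mean over the remaining
in-domain cells. Distances to the outer boundary come from a Euclidean
distance transform of the outer-contour mask (inner obstacles ignored),
with half a cell subtracted because the transform measures center-to-center
distance. The band width defaults to two step standard deviations — the
boundary layer is only a few steps wide — but never less than one cell
layer. Note a resolution artifact: cells straddling the boundary are only
partially accessible, so even a perfectly uniform process measures an index
slightly below 1 (≈ 0.84–0.9 for reflected BM at unit cells); the regime
signatures (≈ 18 at H = 0.8, ≈ 0.06 at H = 0.3) dwarf it.

**Uniformity.** Occupancy counts are heavily autocorrelated (a walker
lingers where it has been), so a naive Pearson chi-square on pooled cell
counts is invalid — its design effect at ring scale is ~10^4 and it rejects
uniform reflected BM with certainty. The package instead tests uniformity
on coarse sectors using fibers as independent replicates: the between-fiber
variance of per-bin occupancy shares gives a first-order (Rao–Scott-style)
design-effect correction to the pooled statistic, compared against
chi-square(K−1). The correction factor is clipped at ≥ 1, so it can only
deflate the naive statistic, never manufacture significance.

**Steady state.** Convergence is probed by run lengthening: nested
checkpoints of the same ensemble (e.g. 2^18 and 2^19 steps) are each
normalised to probability maps over in-domain cells and compared by
half-L1 distance, with 0.05 as the default convergence threshold (an
artifact choice — no principled criterion exists for "no longer changes").
Caveat: at desk scale this statistic is dominated by its sampling floor.
With 24 fibers the nested 2^18-vs-2^19 distance measures ≈ 0.06–0.07 even
though the H = 0.8 relaxation time in the ring (~10^4 steps) is far
exceeded; the distance between two *independent, equally long* ensembles —
reported alongside as a noise-floor reference — is larger still (≈ 0.08).
The floor scales as `1/sqrt(n_fibers * n_steps)`; reference-scale runs
(hundreds of fibers, ≥ 2^20 steps) fall well below 0.05.

**Crowding.** In the crowded disk, cells are classed as obstacle *halo*
(within 1 unit of an obstacle boundary), outer *rim* (beyond the obstacle
placement radius), and *bulk* (the halo's complement below the rim; at 52 %
packing almost no cell is farther than ~3 units from an obstacle, so a
wider bulk margin would leave almost no cells). At H = 0.8 the halo/bulk
ratio is ≈ 1.8–2 (thin high-density layers around each obstacle) while the
rim/bulk ratio is ≈ 6 and the global boundary index stays ≫ 1: crowding
decorates, but does not reverse, boundary accumulation.

## Default study conditions and problem sizes

Reference runs in the source setting used 960 fibers × 2^22 steps of
σ = 1.29 μm binned at 12.9 μm cells (brain sections), 100 × 2^20 at σ = 0.4
in the ring (unit cells), and 192 × 2^25 at σ = 0.4 in the crowded disk
(0.5-unit cells). This package's defaults are desk-scale reductions chosen
once: 24 fibers × 2^18–2^19 steps for the ring and 48 × 2^20 for the
crowded disk, sizes at which every qualitative signature (regime ordering,
curvature dependence, halos) is unambiguous on one CPU in minutes.
Config-driven runs accept the reference-scale parameters and echo them in
the manifest without executing (`--no-execute`) for use on larger machines.
In the anti-persistent regime (H < 1/2) exploration is so slow that the
default step size is raised to 1 domain unit to reach the stationary
regime within these run lengths; this is exposed in the config.

## What the synthetic domains do and do not capture

The fixtures reproduce the *geometry classes* of the study — lobed outer
boundaries with varying curvature, a ventricular hole, obstacle crowding
with a free rim, and mirror-symmetric digitized contours — but not real
anatomy: no region-specific H, no soft (penetrable) white-matter
boundaries, no fiber width, branching, or interaction, and strictly 2D
motion. Passing tests certify the stochastic model and its statistics on
these geometries; agreement with real fiber-density images is qualitative
(boundary accumulation, curvature dependence, obstacle halos), not
pixelwise.

## Numerical choices

- Row lookup and digitizer rounding: nearest integer, ties away from zero
  (mirror-symmetric); digitizer extremes: center sampling with 1e-6 snap.
- fGn eigenvalue clip tolerance: 1e-8 relative; larger negativity raises.
- Attenuation fit: Brent with k-tolerance 1e-14 so the mean residual is
  well below the 1e-9 contract; residual re-checked after the solve.
- Series length cap 2^26 (FFT work arrays); beyond it the error advises
  splitting the run.
- Obstacle packing: candidate budget max(200000, 500 n); area-bound
  prefilter at the hexagonal limit.
- Optical values are clipped to the largest float below 1 so the [0, 1)
  invariant survives float saturation at huge counts.
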