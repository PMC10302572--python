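# Methods

## Geometry

Cells are modelled as spherocylinders: a cylinder of diameter W (µm) with
hemispherical caps, pole-to-pole length L ≥ W. Volume and projected
(stadium) area are closed forms, exact at machine precision. Two volume
entry points are deliberately distinct: `spherocylinder_volume` applied
per cell to its own (L, W), and `volume_from_summary` applied to
population-mean dimensions. On realistic size distributions the two differ
by a Jensen gap of a few percent, and conflating them silently biases any
cross-condition comparison. Inputs with L < W raise rather than being
swapped: in practice they indicate an upstream segmentation failure.

## Synthetic scene generator

The generator emulates the *geometry and threshold sensitivity* of
phase-contrast imagery, not its optics. Per condition, (L, W) pairs are
drawn from a bivariate normal truncated to L ≥ W > 0 (rejection; a model
rejecting over half its draws is treated as misconfigured). The
length–width correlation is not reported for the reference populations;
the default 0.3 (longer cells slightly wider) is a package choice and is
configurable. Cells are placed by rejection sampling with a minimum
axis-to-axis clearance (default 0.3 µm) so cells never touch — splitting
touching cells is explicitly out of scope.

Rendering: a pixel belongs to a cell iff its center lies inside the
stadium outline (so with blur and noise off, the thresholded footprint
reproduces the analytic area to within a one-pixel boundary band); a
bright halo ring of Gaussian cross-section (default amplitude 1500 counts,
width 0.15 µm) is added just outside the boundary; the field is Gaussian-
blurred (default σ = 1 px) and given additive Gaussian read noise
(default SD 150 counts). Defaults: background 10000 counts, cell interior
3000 counts, pixel size 0.065 µm/px (a 100× objective on an sCMOS
sensor); 16-bit TIFF output. The halo is the load-bearing feature: it is
what makes measured width grow monotonically with the threshold offset,
the mechanism behind software-setting-dependent cell sizes. Features of
real data deliberately not emulated: true phase-contrast PSF and
shade-off, uneven illumination, touching/overlapping cells, curved or
dividing cells, focus drift. Passing tests therefore demonstrate
correctness of the measurement pipeline and of the threshold-bias
mechanism, not segmentation robustness on real micrographs.

All randomness flows from one integer root seed through named substreams
(`bacsize.rng.substream`), so stages can be re-run independently and all
outputs are byte-reproducible.

## Segmentation

Smoothing (default σ = 1 px) → global Otsu threshold → foreground =
pixels *below* (Otsu + offset) → connected components → area filter
(defaults 0.2–25 µm²), optional mean-intensity filter, optional border
exclusion → per-component sub-pixel contour by marching squares at the
effective threshold level. The sign convention (offset *added* to the
Otsu value, foreground below it) makes positive offsets enlarge cells;
offsets are in raw intensity counts, and with the default contrast
(7000 counts) a ±1500-count offset swings mean width by roughly ±0.1 µm —
comparable to the spread between real tools' settings. Otsu is computed
on an exact integer histogram for integer rasters (256 equal bins for
float rasters), with ties broken toward the lower threshold; the test
suite checks it against exhaustive between-class-variance search.
"Manual correction" of outliers is not implemented; only the automatic
area/intensity filters are.

## Morphometry

Poles are the farthest contour vertex pair (found on the convex hull).
The contour is split at the poles, both sides resampled to 50 nodes by
arclength, and the midline is the moving-average-smoothed (window 5)
midpoint sequence anchored at the poles; the width sample at node i is
the distance between the paired side points. Length is the midline
arclength. The published tools disagree on what "width" means, so three
definitions are provided: `mean` (mean over interior samples — biased
low by the caps, as mean-width tools are), `max` (maximum sample), and
`fitted` (median of samples in the central region excluding one cap
radius W/2 at each pole — the default, and the stablest against cap
falloff). The exact interpolation scheme behind published "fitted mean
width" values is not specified anywhere; equal-count side resampling +
midpoint pairing + median-of-central-samples is this package's stated
reading, one of several valid ones. Area is the shoelace area of the
sub-pixel contour. Cells with pole-to-pole extent < 1.2× their width
have no stable pole pair and are flagged `degenerate` (with coarse
extent-based fallback dimensions) rather than trusted; population
summaries exclude them by default. Summary SDs use the population
convention (ddof = 0) so fixture summaries are bit-reproducible.

## Cell cycle and run-out

Steady-state age density on [0, τ]: f(a) = (2 ln2/τ)·2^(−a/τ) (newborns
twice as frequent as dividers), sampled by inverse CDF. With
(C+D)/τ = n + x, cells older than τ(1−x) carry 2^(n+1) origins and the
rest 2^n, so the mean is 2^((C+D)/τ); the closed form serves as the
analytic oracle for the simulator. Initiation-timing noise is ignored
(deterministic Cooper–Helmstetter timing) and every ongoing round
completes during run-out, so counts are exact powers of two by
construction. The DNA histogram model multiplies each cell's chromosome
count by (1 + Gaussian noise of CV), and the analysis assigns events to
the nearest 2^k in log₂ fluorescence (multiplicative noise is symmetric
there); estimates with within-peak log₂ spread > 0.25 (~4σ peak
separation) are flagged low-confidence. Gating and instrument effects
are abstracted into the single CV parameter.

Only the fastest/slowest-condition origin *ratio* (2-fold, glucose vs
glutamine) is available as a measured anchor; per-condition ō values are
generated from the steady-state model with an effective C+D calibrated
to that ratio (`calibrated_c_plus_d`: C+D = ln2·log₂(ratio)/(λ_hi−λ_lo)
≈ 50.7 min for ratio 2 over 0.11–0.93 h⁻¹), never read off plots. With
the textbook C = 40, D = 20 min the ratio would be 2.27 instead; the
calibrated form is used wherever the measured anchor matters.

## Workflow and trend classification

Growth rates are least-squares slopes of ln(value) vs time; serial
dilutions are stitched by multiplying back the cumulative dilution
factor before fitting. Steady state requires ≥ 10 generations spanned,
both fits log-linear (R² ≥ 0.99) and |λ_OD − λ_count| ≤ 0.05 h⁻¹
(defaults, all configurable). m̄ = OD600/count is reported in
OD600·mL per 10⁹ cells; m_i = proxy/(ō·ln2) keeps the proxy's units.

A series of initiation masses across conditions is labelled
`growth-rate-dependent` iff its largest pairwise percent difference
exceeds 25% *and* it is monotone in growth rate; otherwise `constant`
(ties break toward constant). The 25% threshold is this package's
operationalisation, placed between the ~10% variation conventionally
read as constancy and the ~50% increase read as clear dependence; it is
a parameter, not a law. `compare_settings` applies this per setting and
raises a conflict flag when labels disagree — the package's core
diagnostic.

## Problem sizes and tolerances

Stochastic checks use 10⁵ cells/events for run-out and histogram round
trips (agreement within 3 SE / 2%), 10⁴ draws for sampling-mean checks
(3 SE), and 500+ rendered cells across ~1000×1000 px fields for
ground-truth recovery (mean length error ≤ 0.1 µm, width ≤ 0.05 µm at a
calibrated offset). These sizes give comfortable statistical margins
while keeping the whole suite in the tens of seconds.

## Known limitations

Straight rods only (no curvature, branching or constriction analysis);
no deep-learning segmentation; no watershed splitting; rifamycin-
resistant re-initiation and flow-cytometer FSC comparability are out of
scope; the generator's noise model is additive Gaussian rather than a
physical camera model.
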