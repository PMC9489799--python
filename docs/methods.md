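# Methods note

This note records the models, parameter choices, and numerical conventions
behind `aggremorph`, so that every number the package produces can be traced
to a stated decision.

## Scope

`aggremorph` analyses single-molecule localization microscopy (SMLM) data of
protein aggregates acquired with transient-binding reporters
(thioflavin-X or DNA/aptamer-PAINT): it filters localization tables,
corrects stage drift against fiducial beads, groups localizations into
aggregates with a from-scratch DBSCAN, measures per-aggregate length and
eccentricity, and compares length distributions between samples.  Two
companion read-outs are included: per-liposome dye-influx quantification
(membrane permeabilization) and calibrated diffraction-limited spot counting
(single-molecule pulldown).  A synthetic-data generator provides ground
truth for all of it.

## Synthetic data model

An aggregate is a rod (length L, width 10 nm, uniform binding sites at
0.2 sites/nm along the axis) or a disk (diameter L, 12 uniformly placed
sites).  Lengths are lognormal:

- *Fraction presets* (`fraction20` … `fraction50`) are parametrized by the
  arithmetic mean and SD of the target population
  (190±30, 240±30, 290±30, 390±90 nm) via
  σ² = ln(1 + s²/m²), μ = ln m − σ²/2.  They are rods only, with binding
  probability p = 5·10⁻⁴ per site per frame.
- *Brain presets* (`pd_brain`, `hc_brain`) are parametrized by the median
  (55 and 68 nm) with σ_log = 0.6 — chosen a priori so that most aggregates
  are below 100 nm and the two populations differ by roughly ten percent of
  cumulative mass near 74 nm, the qualitative regime these presets emulate.
  They are a 70/30 rod/disk mixture with p = 2.5·10⁻⁴ (sparser
  aptamer-PAINT event rates).

Per acquisition, each (site, frame) pair binds independently with
probability p; the field realization is drawn exactly as a
Binomial(n_sites·n_frames, p) total with a uniform sample of distinct
(site, frame) pairs — equivalent to the row-by-row Bernoulli process but
vectorized.  Each event produces one localization at the site position plus
isotropic Gaussian noise of SD σ_loc = 20 nm scaled by photon count
(photons are Exponential with mean 1000; precision = σ_loc·√(mean/photons)).
Background localizations arrive at β = 5·10⁻⁴ per µm² per frame.  Defaults:
20 µm field, 8000 frames of 50 ms.

The generator deliberately does **not** model: reporter photophysics
(blinking kinetics beyond the per-frame Bernoulli), multiple simultaneous
emitters merging into one fit, depth-dependent aberrations, sample-specific
labeling efficiency, or camera artifacts other than Poisson shot noise in
the rendered image stacks.

Stage drift is a linear ramp at a random angle or a Gaussian random walk
(per-frame step scale `drift_mag`), always zero at frame 0.  Fiducials are
bright (10⁵ photon) beads visible in every frame with optional position
noise.

Image stacks (for the localization, influx, and pulldown paths) are
rendered with a pixel-integrated Gaussian PSF (CDF differences, so photons
are conserved exactly), a constant baseline, and Poisson noise.

## Analysis conventions

**Filtering.** Keep localizations with fitted photon count ≥ `min_signal`
and precision ≤ `max_precision`.  Presets: `thx` (100 photons, 20 nm,
ε = 75 nm, minPts = 9, super-resolution pixel 98.8 nm) and `paint`
(60 photons, 40 nm, ε = 200 nm, minPts = 10).  "Signal" is interpreted as
the fitted photon count; the original composite quantity is not publicly
defined.

**Spot fitting.** Local maxima above (median + 5·robust SD) seed 7×7-pixel
ROIs fitted with a symmetric 2D Gaussian plus constant background
(bounded least squares).  Precision uses the Thompson closed form
σ² = (s² + a²/12)/N + 8πs⁴b²/(a²N²).

**Drift correction.** Each fiducial is tracked by nearest-neighbour
matching against its position predicted from the previous frame's drift;
per-frame drift is the mean displacement of matched fiducials from their
frame-0 positions, interpolated across gaps and smoothed with a symmetric,
edge-shrinking 100-frame moving average (exact on linear ramps), anchored
to zero at frame 0.  The residual fiducial RMS — the RMS over frames of the
per-frame mean fiducial displacement remaining after correction — is
~10⁻¹² nm for noiseless linear drift and ~7 nm at 10 nm bead noise with
4 beads.

**Clustering.** DBSCAN is implemented from scratch: a point is core iff its
*closed* ε-ball (including itself) holds ≥ minPts points; clusters are
connected components of the core-core ε-graph; border points go to the
cluster of their first core neighbour in ascending row order (deterministic
tie rule); cluster ids follow first-member row order.  A cKDTree provides
the neighbour queries; correctness is checked against an O(n²) brute-force
reference that must agree element-for-element.

**Morphometry.** Eccentricity is the ellipse convention
e = √(1 − λ₂/λ₁) from the second central moments of the cluster (the focal
distance over the major axis of the moment ellipse); a circle scores 0,
collinear clouds exactly 1.  Length is by default the maximum pairwise
distance between member localizations (max Feret diameter; convex-hull
reduction above 60 points), with the major-axis projection extent available
as an alternative.  Raw measurements are reported; an optional correction
subtracting 2·σ_loc can be enabled.

**Statistics.** Two-sample KS: D is the sup of the pooled-ECDF difference;
p from the asymptotic Kolmogorov distribution with effective
n = nm/(n+m) (small-sample exactness is a non-goal at these sample sizes).
Mann–Whitney: U = #{x>y} + ½·ties, reported as min(U, nm−U); the p-value is
exact by full permutation enumeration (ties included) for n·m ≤ 400, else a
tie-corrected normal approximation with continuity correction.  Group
comparisons use unit-mass histograms on shared 10 nm bins; difference
curves are (a − b), so negative values mean the feature is more abundant in
group b.

**Influx.** Per liposome, influx% = 100·(F_s − F_b)/(F_i − F_b) from spot
intensities under background, sample, and ionophore conditions, matched
across conditions by mutual nearest neighbours within 474 nm (two
diffraction-limited pixels).  The ratio is invariant under affine intensity
rescaling, so gain and offset cancel; values are not clamped, and spots
with F_i ≤ F_b are flagged invalid rather than scored.

**Pulldown counting.** The intensity threshold is calibrated as the
smallest value at which the mean negative-control count per field drops to
a budget (default 2 spots/field); specificity is the target/control mean
count ratio with first-order error propagation.

## Known measurement limitations

The max-Feret length of a cluster has a hard noise floor: with minPts ≥ 9
every cluster holds ≥ 9–10 localizations, and the largest pairwise distance
among ≥ 10 points carrying 20 nm isotropic noise is ~90–110 nm even for a
point-like object (a 74 nm rod measured with 10/15/20 localizations yields
median Feret lengths of roughly 96/106/112 nm).  Consequently, measured
medians of sub-100 nm populations are inflated to ~150–170 nm and the
location of the maximal cumulative-distribution gap between two such
populations shifts from ~74 nm in truth space to ~105–130 nm in measured
space.  Group ordering and significance are unaffected (the inflation is
common to both groups), but absolute sizes and gap locations below ~100 nm
should be read as upper bounds.  The optional 2·σ_loc correction reduces,
but does not remove, this floor; it is off by default because raw
measurements are the reported quantity.

## Problem sizes and runtimes

The verification suite runs, on one CPU: 200+ DBSCAN oracle instances
(n ≤ 300) in seconds; four 150-aggregate length-recovery populations in
~10 s; twenty seeds of two 5000-aggregate brain populations in ~1 min;
ten 100-liposome influx experiments in ~5 s; 8000-frame drift correction
in ~2 s.  `scripts/acceptance.py` completes in well under a minute.
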