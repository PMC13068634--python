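# Methods

## Morphometric descriptors

Objects enter the pipeline as simple closed polygons (0-based pixel-center
coordinates, counterclockwise) or as labels in a 2-D integer mask. On the
polygon path, area is the shoelace formula, perimeter the arc length, the
centroid and central second moments come from the Green's-theorem closed
forms, and the aspect ratio is the axis ratio of the ellipse with identical
second central moments (the same convention region-measurement software uses
for its "fitted ellipse"). The radius ratio is max/min distance from the
centroid to the boundary, with the minimum evaluated against edges, not just
vertices. All descriptors are validated to be finite and positive; degenerate
polygons (<3 vertices, zero area) raise an error naming the object.

On the mask path, area is the pixel count (times `pixel_size²`) and the
boundary is the sub-pixel marching-squares contour. Raw marching-squares
contours carry a half-pixel staircase that inflates perimeter — and hence
roundness and the irregularity index — by several percent (pixel-edge
perimeters are worse, overestimating by up to 4/π), so the contour is
smoothed with a short circular moving average (window 5, shrunk for tiny
regions) before perimeter, radius-ratio and bounding-box measurements. After
smoothing, a rasterized disc of radius 25 px measures irregularity ≈ 0.03
against the analytic 0, and polygon- vs mask-path measurements of rendered
objects agree within 5% on area. Aspect on the mask path uses pixel second
moments with the +1/12 per-axis correction (moments of the unit pixel), so a
filled square matches its continuous counterpart.

### Irregularity index (NII/CII)

The composite

```
irr = (aspect − 1) + (radius_ratio − 1) + (roundness − 1) + max(0, 1 − area_box/(π/4))
```

scores 0 for a perfect circle and each additive term is monotone in one
distinct irregularity mode: elongation (aspect), lobedness (radius ratio),
boundary roughness (roundness), and bounding-box fill (a circle fills π/4 of
its box; concave shapes fill less). The same formula serves nuclei (NII) and
cells (CII): the two indices are treated as parallel. Because all gating
thresholds are calibrated on control populations, classifications depend only
on the index's ordering, not its absolute scale; absolute values are
therefore not comparable to other irregularity-index implementations.

## Normal-ellipse gating

The gating model is fitted once on a designated control condition and frozen:

1. **Ellipse.** Center = control mean of (area, irregularity); shape = control
   sample covariance; radius = the empirical Mahalanobis quantile closest to
   the containment target (default 0.925), constrained to contain between 90%
   and 95% of controls. Containment is calibrated empirically rather than by
   a parametric chi-square quantile because control distributions need not be
   Gaussian. Fewer than 50 controls, or a singular covariance (constant
   feature), is an error.
2. **Area thresholds.** The upper/lower area extremes attained on the ellipse
   boundary: center ± radius·SD(area).
3. **Irregularity threshold.** Manual if supplied (with a warning if it falls
   inside the normal region), else automatic: a Gaussian KDE of irregularity
   among objects *outside* the ellipse is evaluated on a log scale
   (irregularity is strictly positive and heavy-tailed; a linear-scale KDE
   lets spurious tail minima win), and the threshold is the deepest density
   minimum *between the two tallest modes* — minima beyond the outer modes are
   tail artifacts, not subpopulation boundaries. When no interior valley
   exists the control 97.5th percentile is used. The chosen value and its
   provenance (`kde-valley` / `control-percentile` / `manual`) are recorded on
   the model and echoed to the log; classification quality improves when the
   pool passed for threshold placement is enriched with treated conditions,
   mirroring gating practice. For a bimodal pool with modes at 1 and 6 the
   automatic threshold lands in the valley near 3.
4. **Classes.** Inside the ellipse → N; above the upper area threshold →
   LR/LI by the irregularity threshold; below the lower → SR/SI; the
   remaining band → I if irregular, else N (the thresholds, not the ellipse
   boundary, delimit the extreme classes). Ties at exact threshold values
   resolve toward the less extreme class. Objects with area >
   control mean + k·SD (k = 6 by default, configurable) carry a `very_large`
   flag restricted to LR/LI. Edge-flagged objects (touching the image border)
   are excluded before gating by default and logged.

## Trajectories and plasticity

Tracks come from provided track IDs; records are sorted by timepoint, gaps
are retained and logged, and duplicate (track, timepoint) pairs are an error.
Per-track statistics use the sample variance (n−1) and successive-difference
delta series. Classes condense to morphotypes as LI→E, LR→F, N→N, other→other;
transition counting tallies adjacent-frame changes (self-transitions excluded)
together with per-state exposure counts, so `frequency(src, dst)` estimates
the per-frame transition probability. "Mostly E→F" is a cohort-level
statistical property, not a per-cell constraint. A greedy mutual-nearest
centroid linker (max-displacement capped) is included as a convenience for
mask time series but ID-based tracks are the supported path; division,
appearance and disappearance end a track — no lineage trees.

## Fluorescence integration

FUCCI calls: red-only G1, double-positive S, green-only G2/M, neither →
unclassified; all three phases are kept distinct (any merging is left to the
report layer). Default channel cutoffs are the 97.5th percentile of
background pixels, overridable. GFP-LC3 puncta are connected components of
supra-threshold pixels inside the cell mask, size-filtered (defaults
3–400 px); a cell is autophagic at ≥5 puncta. pH3-style positive/negative
markers use the same thresholding mechanism as FUCCI channels rather than a
dedicated operation. Percent-autophagic tables omit empty groups rather than
reporting 0%. The circularity median split assigns ties to the high group and
returns the mirrored split by marker level; marker–morphometry correlations
default to Spearman rank because marker intensities are heavy-tailed
(Pearson available). Total cell fluorescence is area × mean intensity.

## Population metrics

PD between counts is log₂(N(t)/N(t₀)) — the printed form "[ln N(t) − ln
N(t₀)]/log 2" is read as division by ln 2, the only reading under which one
literal doubling equals one PD — and CPD is the running per-passage sum.
CV uses the sample SD (n−1); whether the original figures used sample or
population SD is not stated, so sample SD was chosen and documented here.
Group comparisons run Shapiro–Wilk per group (groups with n < 3 force the
non-parametric branch, logged), then t-test / ANOVA + Tukey HSD or
Mann–Whitney / Kruskal–Wallis + Bonferroni-corrected pairwise Mann–Whitney;
proportions use chi-square. All tests are delegated to scipy/statsmodels.

## Synthetic data generator

The generator defines the study conditions the pipeline is tested under.
Defaults (all exposed on `SyntheticScenario`):

| state | area model (px², lognormal mean / σ_log) | outline | role |
|---|---|---|---|
| N | 2000 / 0.15 (nuclei ×0.25) | mild ellipse, aspect 1.05–1.35, 2% Fourier noise | control/normal |
| small | 900 / 0.15 | as N | proliferative small cells |
| E | 5000 / 0.20 | 3–6 spiky extensions, length 1–3 body radii, spread around the body | extension-rich senescent |
| F | 7000 / 0.20 | smooth, aspect 1.0–1.2 | flattened senescent |

Outlines are radial (star-shaped) constructions — guaranteeing simple
polygons — rescaled isotropically so the enclosed area equals the drawn
ground-truth area exactly. Extension centers are jittered-evenly spaced so
the centroid stays near the body center (clustered one-sided extensions would
send the radius-ratio term to extreme outliers no real cell shows).
Condition presets encode the treatment time-course ordinally (E dominant
early, F accumulating, a small dividing subpopulation at intermediate times):
control 100/0/0/0, day5 45/35/15/5, day12 35/15/35/15, day19 30/5/55/10
(N/E/F/small). Within a condition, state counts follow the mixture *exactly*
(largest-remainder apportionment, shuffled): the generated composition equals
the requested one, so downstream recovery error measures the pipeline rather
than multinomial sampling noise.

Fluorescence defaults encode the ordinal claims of the biology, not measured
magnitudes: LC3 puncta Poisson means 8 (E) vs 1 (F, N, small); p16 mean 2×
higher in E than F; Bcl-2 lowest in F; FUCCI phase probabilities strongly
G1-shifted in E/F; CFSE starts at a fixed integrated intensity and halves per
division (3 divisions for N/small, 0 for E/F, so non-dividers retain 8× the
signal); multiplicative intensity noise defaults to 10%. Time-lapses follow a
per-frame condensed-state Markov chain (default rows N: 0.90/0.08/0.02,
E: 0/0.60/0.40, F: 0/0.05/0.95 — E→F dominant, F→E rare) at 12 h/frame, with
a per-track lognormal scale, AR(1) within-track area noise (ρ = 0.7), and a
+5%/frame compounding area drift while in F (progressive enlargement). The
growth model for CPD scenarios is a passage-wise factor sequence
(2,2,2,1,1,1,1.6,2 at 3-day passages from 10⁴ seeded cells): growth, arrest
plateau, regrowth.

Rendering places each object in its own grid tile (no overlaps, no border
contact), fills channels with the object's generated mean intensity plus
pixel noise on a background of 10 ± 2, and draws LC3 puncta as Gaussian spots
(amplitude 200, σ 1.5 px) at logged coordinates, spaced ≥8 px apart and ≥4 px
from the boundary so rendered spots match the ground-truth count under
default detection settings. One seed drives everything through named
substreams (shapes, fluorescence, transitions, placement, growth), so tables
are bit-identical per seed and adding a channel never perturbs geometry.

**What the generator does not emulate:** touching/overlapping cells,
segmentation errors, illumination gradients, photobleaching, focus drift,
3-D shape, or realistic texture. Passing tests therefore demonstrate that the
measurement→gating→tracking→integration chain is correct and calibrated on
clean segmentations with the assumed statistical structure — not that the
pipeline is robust to segmentation artifacts in real micrographs.

## Numerical choices and problem sizes

Covariance singularity is declared at det ≤ 1e-12·trace²; KDE uses
`scipy.stats.gaussian_kde` (Scott bandwidth) on a 512-point grid; ellipse
boundaries are evaluated at 256 points via Cholesky. Tables serialize floats
at %.6g for platform-stable byte-identical reruns. Tests and the acceptance
script use 500–1,000 objects per population, 100 tracks × 10 frames, and
render at most ~500 objects per canvas — sizes at which calibration
(containment 90–95%), mixture recovery (±5 points) and transition-rate
recovery (3 binomial SE) are all comfortably resolved.

## Known limitations

- The irregularity index's absolute scale is implementation-specific; only
  ordering and control-calibrated gating transfer across implementations.
- One irregularity threshold is fitted (the six-class scheme); analyses that
  need several vertical thresholds must supply them manually per run.
- The automatic threshold requires a bimodal irregular/regular structure
  outside the ellipse; on unimodal pools it falls back to a control
  percentile, which is conservative.
- Mask-path irregularity retains a small positive bias (~0.03 for a
  25-px-radius disc) from residual rasterization roughness.
- The centroid linker is greedy and single-hypothesis; crowded fields need
  real tracking software.
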