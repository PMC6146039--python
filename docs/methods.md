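# Methods

This note documents the models, parameter choices and numerical decisions
behind `platephen`, and what the synthetic-data generators do and do not
emulate.

## Well coordinate system

Wells are located by a declared parametric grid — centre of well A1
(`origin_px`), centre-to-centre pitch, well radius — rather than by circle
detection. Plates in fixed scanner/camera positions make a parametric grid
deterministic and testable; a whole-grid pixel offset can be applied if a
batch is translated. Conventions: image row 0 is the top, well A1 the top
left, labels are row letter + 1-based column; well regions are disks (or
squares) around the grid centres and must be pairwise disjoint
(`pitch ≥ 2·radius` is enforced). Images are normalised to float RGB in
[0, 1] at load (8- and 16-bit linearly), which makes all colour-index
arithmetic scale-free by construction.

## Seed counting

Seeds are darker than the agarose background in all three channels.
Segmentation thresholds each channel inside the well region; by default the
threshold is Otsu's, then re-centred at the midpoint of the two class means.
The re-centring matters: with two well-separated colour modes, Otsu's
criterion is nearly flat across the gap and the returned threshold can sit
at the edge of the dark mode, silently dropping seeds whose colour jitters
slightly brighter. An empty-well guard rejects segmentations whose
foreground is not clearly darker than the background (default contrast
0.08), since Otsu always splits something.

Objects are 8-connected components after hole filling; components below
`0.25 × avg_seed_area` are discarded as debris. Classification uses
solidity = area / convex-hull-area with threshold 0.9: at or above it an
object is one seed; below it, a cluster contributing
`max(2, round(area / avg_seed_area))` seeds, half-counts rounding away from
zero. The floor of 2 encodes that sub-threshold solidity itself asserts
multiplicity. The reference seed area is the median area of high-solidity
objects across the plate (≥ 10 required), so a plate self-calibrates; a
manual value can be supplied instead.

A caveat of digital geometry: the solidity of a rasterised convex shape is
below 1 because the hull image adds a boundary rim (≈ 0.93 for a radius-10
disk, rising with size). The 0.9 threshold already accounts for this at
realistic seed sizes (~90–100 px at the scales generated here).

## MTT germination scoring

Net absorbance is A570 − A690 per well. Since the formazan signal is the sum
of per-seed contributions, the well reading confounds germination activity
with the dispensed seed number (CV ≈ 25 % with suspension pipetting);
dividing by the counted seeds removes that factor exactly. Summaries use the
sample (n−1) standard deviation and CV% = 100·sd/mean. Wells with zero
counted seeds are excluded (flagged, never imputed); negative net values are
kept but enter summaries only on request.

A calibration from per-seed absorbance to germination % is a user-supplied
OLS fit (predictions clamped to [0, 100]); the package ships no default
coefficients because they are assay-specific.

Limitation worth knowing: with independent additive reader noise ε, the
per-seed quantity is s̄ + ε/n, and low-count wells amplify ε/n. If the
per-seed cohort CV is pushed to ~9 % through reader noise alone, the
achievable CV(net)/CV(per-seed) ratio saturates just *below* 3 (measured
2.85 at n = 20 000 wells); at a realistic reader repeatability of 0.01 OD the
ratio is ~5–7. The ≥ 3-fold reduction therefore holds at the simulated
operating point used by the tests, but it is not an unconditional identity
of the normalisation.

## Rosette growth

Segmentation is excess-green (2G − R − B) > 0.10 on [0, 1] channels, largest
8-connected component, holes filled. The prior segmentation algorithm used
with the original imaging platform is not public; this rule is a standard,
parameter-exposed stand-in with the same output contract (a per-well binary
mask and green-area pixel count).

RGR is computed per consecutive imaging interval as
`(ln Aᵢ − ln Aᵢ₋₁)/(tᵢ − tᵢ₋₁)` with natural logs; the twice-daily schedule
(10:00, 16:00) gives exact 6 h/18 h denominators and no resampling. The
per-day value is exactly 24× the per-hour value. `mean_rgr` is the
unweighted mean over intervals (a time-weighted mean would equal the
end-to-end log-ratio divided by the span; the unweighted version preserves
the diel fluctuation signal the schedule exists to capture). Zero or
negative areas at retained points are an error naming the well and time.

Mortality: a plant is dead when its area sits below `min_alive_area`
(default 25 px) for the final ≥ 2 timepoints; the trailing points are
truncated so growth statistics see only the live trajectory, and dead plants
are excluded from RGR/colour means but countable as a mortality fraction.
A single low final point is noise, not death.

Seedling establishment is the green area at the earliest timepoint (the
moment of transfer into the 48-well plate), reported regardless of later
death.

## Colour indices

Per-pixel NGRDI, GLI, VARI with denominators guarded at |den| < 1e-9. The
VARI singularity (G + R = B) excludes the pixel from the VARI mean and
tallies it — no clipping, so the undefined count is visible in output.
Aggregation is per-pixel index → per-plant mean → per-plate unweighted mean
of plant means; pixel pooling across plants was rejected because it would
weight large plants more.

## PBC index and mode of action

Per trait, log2(variant value / matched same-condition control value),
summed per variant × condition. Under control conditions four traits enter
(germination proxy, establishment area, final growth area, GLI); under salt
stress three (establishment is only meaningful where transfer size is the
baseline), so scores are compared within a condition only and radar exports
group by condition. Trait values are means over replicate wells before the
ratio (ratio of means). The germination trait is the measured per-seed
absorbance; any linear zero-intercept calibration to germination % cancels
in the ratio.

Labels use a dead-zone ε = 0.1 log2 units (≈ ±7 %) around zero: measurement
noise makes a hard sign split unstable. Mode of action from the score
pattern across conditions: benefit (> ε) only without stress → growth
promotor; only under stress → stress alleviator; both → combined; deficit
(< −ε) without stress and no stress benefit → growth inhibitor; otherwise
none. When the control score is below −ε *and* some stress score is above
+ε, the rule prefers stress alleviator (the stress benefit is the
operationally interesting signal); the published narrative never needed to
break this tie, so it is a package decision.

## Synthetic data

The generators state a world and stick to it; every stochastic draw comes
from one seeded generator per scenario, so equal seeds give bit-identical
artifacts, and every ground-truth quantity is stored in a manifest.

**Seed scans.** Per-well counts ~ round(trunc≥0 Normal(21, 5.4²)) — the
dispensing distribution achieved with agarose-suspension pipetting. Seeds
are filled ellipses (semi-axes ≈ 6.0 × 5.0 px ≈ 94 px², jittered and
clipped at ±2 SD); 15 % of seeds land in clusters of two (80 %) or three,
rendered as chains with gaps scaled to the members' semi-axes and lobes
perpendicular to the chain so the waist stays concave. Singles sit on a
jittered hexagonal lattice with rejection-sampled stragglers. What this does
not emulate: debris, uneven illumination, focus blur, or seeds straddling
the well rim — a green counting test establishes the solidity/area logic,
not robustness to dirty scans.

**MTT plates.** Germinated seeds each contribute Normal(0.019, 0.002²) OD at
24 h (0.041, 0.003² at 48 h); the reader adds Normal(0, 0.01) repeatability
noise and a shared A690 baseline (0.06 ± 0.004) that cancels in the net
value exactly.

**Growth series.** Areas are exponential with piecewise day/night rates
(defaults 0.010/0.008 h⁻¹, day window 06:00–18:00), salt suppression
factors (1.0 / 0.7 / 0.45) and optional mortality (25 % under severe salt).
Rosettes are rendered as star-convex lobed blobs made of the N pixels
nearest the well centre under an angular distance modulation, with
N = round(A(t)) — the rendered pixel count equals the planned area exactly,
so segmentation error is isolated from rasterisation error and the
image-path RGR bound (±0.002 h⁻¹) is meaningful. Plant colour is solved
numerically (bisection on a yellow→green blend) to hit a target GLI, which
makes planted colour-trait ratios exact. Not emulated: leaf shape, overlap
between neighbouring plants, specular highlights, diurnal colour change.

**End-to-end experiment.** 4 compounds × 4 concentrations × 3 conditions
with planted per-trait multipliers patterned on the screening narrative
(putrescine/spermidine as combined promotor+alleviator, spermine as promotor
only, proline inhibitory when dilute and alleviating at 1 mM). Scale per
condition: two 96-well MTT plates read at 24 h and 48 h (5 wells/variant
each), two 48-well growth plates (three under severe salt, mirroring the
design's extra replication against mortality; 2 wells/variant/plate,
16 control wells). Noise: 3 % lognormal on initial area, 1.5 % on rate.
Salt acts on germination mostly through graded per-seed signal suppression
(×1.0/0.75/0.5) with activation fractions 0.98/0.96/0.94 — a binary
non-germination model at severe salt is equally plausible biologically but
its binomial well-to-well noise is several times larger, which is worth
remembering when transferring the recovery bounds to real data. At this
scale the pipeline recovers every planted PBC score within ±0.15 log2 units
and classifies every unambiguously planted mode correctly.

## Statistics

Pearson correlation (t-based two-sided p), OLS, Kruskal–Wallis and one-way
ANOVA come from scipy. Dunn's post hoc uses the tie-corrected rank-based z
statistic with Šidák correction (implemented here; no maintained
implementation was available in the environment), and the ANOVA branch uses
pooled-variance pairwise t tests with Šidák correction. Both the
Kruskal–Wallis and the ANOVA entry points are provided because the source
protocols name both; neither is asserted as canonical. A log-linearisation
helper (OLS on ln y) supports exponential fits; it is one choice of
linearisation, not the only one.
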