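# Methods

`orrquant` quantifies heterogeneous photoreceptor degeneration in layered
retinal cross-sections with an eccentricity-agnostic thickness ratio, and
relates local degeneration severity to marker remodeling and to the
efficacy of electrical stimulation measured in visual cortex.  This note
describes the models and procedures the package implements, the choices
made where the design was open, and what the synthetic validation does and
does not establish.

## The Outer Retina ratio

For a cross-section annotated with the eight boundary surfaces ILM,
GCL/IPL, IPL/INL, INL/OPL, OPL/ONL, ONL/IS, IS/OS and the outer OS edge,
the Outer Retina ratio at lateral position x is

    ORr(x) = (OS + IS + ONL + OPL) / (total thickness from ILM to OS edge)

Thicknesses are measured along the image column (row 0 is the vitread/ILM
side), not the local surface normal: because ORr is a ratio of nested
extents along the same column, it is exactly invariant to uniform scaling
of thicknesses, which absorbs oblique sectioning and normal
eccentricity-dependent thickness variation.  The ILM is treated as the
inner bounding surface and contributes no thickness band of its own — it
is a membrane, and defining total thickness *up to* it keeps the
denominator measurable and monotone.

Sections are segmented into adjacent, non-overlapping 250 μm regions,
left-aligned to the section start; a trailing remainder shorter than one
region is discarded and logged.  Within a region, ORr is sampled at the
midpoints of consecutive 50 μm bins (x_start + 25, 75, 125, 175, 225 μm)
and averaged.  Midpoint placement was chosen over fence posts so adjacent
regions never share a sample; both the interval and the scheme are
configurable.  A region where any sample has zero total thickness is
flagged unmeasurable and excluded from group statistics (this mimics the
delineation failure of severely degenerated tissue).

Boundary input is either an integer label mask (one label per layer,
converted to boundary curves by a per-column extremal scan) or polyline
JSON in micron coordinates.

## Normative threshold and degeneration groups

Control regions define a normative model: threshold = mean − 2·SD of all
pooled control-region ORr values, using the sample (n−1) SD — the standard
estimator of a population SD; at several hundred control regions the
difference from the n-denominator is negligible.  Under a normal model
this threshold sits at 100·Φ(−2) ≈ 2.3rd percentile of control data.
Control regions are always group 0.  Treated regions are graded:

| group | name | rule (mean ORr) |
|---|---|---|
| 1 | none | ≥ threshold |
| 2 | mild | threshold > ORr ≥ 0.35 |
| 3 | moderate | 0.35 > ORr ≥ 0.2 |
| 4 | severe | ORr < 0.2 |

Lower bounds are closed (ORr exactly 0.35 is mild; exactly 0.2 is
moderate).  The 0.35/0.2 cutoffs are conventional and configurable.  The
threshold is carried at full precision internally; printed reports round
to 2–3 decimals.

## ONL density model

ONL nuclei density CD (cells per mm of retina length) is modelled in
decibel space, 10·log10(CD) = A + B·ORr, fitted by OLS.  Diagnostics are
computed on the dB scale: R² = 1 − SSE/SST, RMSE with an n denominator by
default (an n−2 option exists; the convention matters little at n in the
hundreds).  Two fold-scale diagnostics translate dB error into
interpretable factors:

* F = 10^(RMSE/10), the multiplicative RMSE factor;
* S = mean over residuals r of 10^(r/10), Duan's smearing factor.

The naive back-transform 10^((A+B·ORr)/10) estimates the conditional
median under symmetric dB residuals; multiplying by S retargets it to the
conditional mean.  S ≥ 1 for any least-squares fit with an intercept
(Jensen's inequality on mean-zero residuals), and for Gaussian residuals
of SD σ dB, S → exp((σ·ln10/10)²/2) ≈ 1.107 at σ = 1.96.  Both the
smeared and unsmeared predictions are exposed and labelled, rather than
asserting which one a given figure shows.

## Marker quantification

* **Fluorescence intensity** is the mean over a layer mask minus the mean
  over a choroid mask (the background reference), making the measure
  invariant to constant offsets.  Values below background are retained and
  flagged, not clamped, so distributional statistics stay unbiased.
  Per-animal normalisation divides by the mean of that animal's
  background-subtracted control-eye values; subtracting background before
  averaging keeps the normalisation offset-invariant.  Interactive
  region selection ("magic wand") is deliberately replaced by layer-mask
  means — the interactive tool is not reproducible.
* **Nuclei counting** thresholds the DAPI channel by Otsu's method on the
  masked band (an explicit threshold can be supplied), splits touching
  nuclei with a distance-transform watershed seeded at distance peaks, and
  filters components by area and circularity 4πA/P².  With size 0–∞ and
  circularity 0–1 (the permissive defaults) no shape filtering occurs.
  Counts are normalised by the lateral mask length in mm.
* **Marker-positive nuclei**: a nucleus is positive when ≥ 50% (default)
  of its pixels exceed an intensity threshold on the co-registered marker
  channel.
* **DAB-positive area** classifies brown chromogen pixels by colour
  deconvolution with the standard hematoxylin–DAB stain matrix and an
  optical-density threshold (default 0.15 OD); a plain HSV hue-window rule
  is available as an alternative.  Deconvolution is the default because it
  is reproducible and standard, whereas ad hoc RGB thresholds are
  operator-specific.  Positive area (μm²) is divided by the lateral mask
  length (μm).
* **RBPMS/GCL ratio**: marker-positive GCL nuclei over total GCL nuclei.
* Photoreceptor markers (ONL counts, opsin intensity) are refused for
  group-4 and indeterminate regions, and skipped for regions inside the
  suprachoroidal pocket, where implantation damage confounds them.

## Cortical metrics

Per-channel threshold is the injected current eliciting 50% of the
channel's maximum spike count in the 3–20 ms post-stimulus window.  The
default estimator least-squares fits a monotone logistic with floor 0,
fitted ceiling and fitted slope, returning its midpoint; a slope-free
two-parameter form cannot track sigmoids of varying steepness, so the
slope is fitted as a nuisance parameter.  When the fit fails, the
estimator falls back to linear interpolation between the bracketing
current levels; an explicit interpolation mode is also exposed.  Channels
whose maximum stays below a noise floor (default 5 spikes) are
unresponsive (NaN).  The electrode's best threshold is the minimum finite
channel threshold across hemispheres.

d′ spatial selectivity is implemented literally from its verbal
definition: firing at an evaluation current is max-normalised to the best
channel and regressed on Euclidean distance (mm) from the best channel
within the best channel's hemisphere; d′ is the negative slope.  The
evaluation current defaults to twice the best threshold (configurable) —
high enough to sit on the response plateau without leaving the calibrated
range.  Equivalence with more elaborate d′ constructions in the
literature is not claimed.  Both metrics are invariant to uniform scaling
of spike counts.

## Statistics

Group comparisons use the tie-corrected Kruskal–Wallis test followed by
Dunn's pairwise z tests on pooled midranks with the textbook tie
correction, two-sided p-values, and Holm–Bonferroni step-down adjustment.
The adjustment family is all pairwise comparisons within one
marker × layer analysis (10 pairs for 5 groups), not across markers; the
family is recorded in the output.  α = 0.05 with conventional star
rendering.  Retina–cortex relationships are reported as both Pearson r
and Spearman ρ with pairwise deletion; zero-variance columns yield
missing correlations rather than errors.

## Synthetic data

The generator provides ground truth for every stage; its defaults encode
the study conditions the analysis targets.

* **Geometry**: the inner retina (INL+IPL+GCL) has fixed thickness
  total·(1−0.55); the outer compartment is sized per column so that
  outer/total equals the target ORr field — degeneration thins the outer
  retina and the total shrinks with it.  Band fractions are OS/IS/ONL/OPL
  = 0.2/0.2/0.4/0.2 of the outer and INL/IPL/GCL = 0.3/0.5/0.2 of the
  inner compartment.  Pixels are assigned to the band containing their
  centre, so rendered per-column thicknesses match the target field within
  half a pixel.
* **ORr fields**: control regions draw mean ORr from Normal(0.55, 0.05)
  truncated to [0.39, 0.69].  Treated regions are assigned groups 1–4
  from a target mixture (default 272:220:263:79 ∝ the observed treated
  split); spatial arrangement comes from rank-ordering a Gaussian-filtered
  white-noise field (correlation length 500 μm — a free parameter, since
  within-eye patch statistics are not available), so severe and intact
  patches adjoin realistically while region-level group truth stays exact.
  Group ORr values are drawn uniformly within each group's interval with
  a small safety margin at the boundaries so sub-pixel measurement error
  cannot flip a region's true group.
* **Nuclei**: ONL counts are deterministic given the model draw,
  round(10^((20.86 + 25.56·ORr + ε)/10) · length), ε ~ N(0, 1.96²) dB per
  region, so the rendered density is exactly the model's draw.  INL and
  GCL nuclei follow fixed per-mm Poisson densities (420 and 120 /mm).
  Nuclei are anti-aliased disks (default radius 2 μm) placed uniformly in
  their band with hard-core thinning that caps pairwise overlap at 60% of
  a disk's area, so watershed splitting is exercised but solvable; every
  centre lies inside its declared band.
* **Channels**: the opsin-like marker renders the OS band at
  choroid-background + 150 × (per-group effect), so background subtraction
  and control normalisation recover the effect exactly; ectopic
  marker-positive nuclei are flagged per group and rendered into the
  marker channel (ONL ectopic-opsin rates 0.01–0.30; GCL RBPMS fractions
  0.60 control, 0.336 treated — a 44% drop).  The DAB channel is built in
  optical-density space from the standard H-DAB stain matrix (hematoxylin
  0.35 OD everywhere in tissue, DAB 0.6 OD patches painted in the IPL to a
  per-group target area per length), so chromatic classification has an
  exact ground truth.  No photorealistic H&E texture or scanner PSF/noise
  is modelled.
* **Cortical responses**: channels form two rectangular grids (contra and
  ipsi hemisphere, 0.4 mm spacing).  The best channel's true threshold is
  drawn from Normal(group mean, 20 μA) with group means 82.43, 88.64,
  98.25, 117.25, 124.26 μA for groups 0–4.  Other channels respond at
  currents rising with distance from the activation centre (gain
  0.25/mm + positive jitter), which keeps the lowest-threshold channel
  coincident with the strongest-responding one; ipsilateral channels get
  +30 μA and 0.6× amplitude (strong binocular asymmetry).  Spike counts
  follow a monotone logistic of current (slope 15 μA) saturating at a
  channel maximum that falls off linearly with distance at the
  ground-truth d′ rate; counts are means of Poisson draws over 10 trials
  at 25 μA current steps over 0–750 μA.

## Pipeline

The end-to-end driver simulates paired control/treated eyes per animal,
measures and grades all regions, flags alternating regions as overlying a
stimulating electrode in the suprachoroidal pocket, fits the density
model, quantifies markers, simulates and analyses one cortical battery
per electrode (with the electrode's graded group selecting the generator's
threshold/d′ condition), runs the group tests and correlation matrix, and
writes a CSV/JSON/markdown bundle that is byte-reproducible from
(config, seed).  Defaults (2 animals, 3 mm sections at 2 px/μm, electrodes
on every other region) keep a full run around a minute on one core; tests
use smaller scenes.

## Numerical and degenerate-input conventions

Output tables use micron, 0-based, half-open region intervals
[x_start, x_start+250).  Coordinates of nuclei are micron with pixel
centres at (k+0.5)/px_per_um.  Classification comparisons use full
precision.  Zero-variance inputs are rejected where a quantity is
unidentifiable (density slope, normative percentile) and reported as
missing where a downstream summary can proceed (correlations).  All
generators are pure functions of (spec, seed) under NumPy's
default_rng; identical seeds give bit-identical images and tables.

## What the synthetic validation shows — and does not

Passing tests establish that the measurement operators recover the
generator's ground truth under its idealised imaging: exact layer
rendering, flat-textured bands, disk nuclei, noiseless stain vectors.
They do not establish performance on real histology, where boundary
annotation error, stain variability, and sectioning artefacts dominate.
Two limitations are explicit:

* At realistic ONL densities (>2000 nuclei/mm) the 2-D flat-disk
  rendering merges touching nuclei into solid bands, and watershed
  counting saturates — an undercount that worsens with density.  The
  pipeline therefore fits the density model on the generator's per-region
  counts (the synthetic analogue of counted data) and reports
  image-derived counts in a separate column; the counting operator itself
  is validated on resolvable-density fixtures.
* The d′ implementation follows the verbal definition (normalised-firing
  falloff slope); published variants with additional machinery may differ
  by a scale factor.
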