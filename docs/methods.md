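# Methods

## Coordinate and sign conventions

All spatial quantities are in micrometres in image space: origin at the
top-left of the field, x rightward, y downward. Areas are in mm². Signed
distance to the invasive margin is **negative inside the tumor
parenchyma**, positive in host tissue and zero on the margin, so the
distance-class histogram reads tumor on the left and host on the right.
A cell exactly on the margin is intratumoral, and distance bands are
half-open `(lo, hi]`; the tissue never places cells exactly on these
measure-zero boundaries, but the convention makes worked examples exact.

## Margin geometry and band areas

Margins are simple polygons (shapely). Circles are 512-gon
approximations; irregular margins use a radial Fourier perturbation
r(θ) = R·(1 + Σₖ aₖ cos(kθ+φₖ)) over harmonics k = 2–5 with
Σ|aₖ| ≤ 0.2 by default, which keeps the curve star-shaped and therefore
always a simple polygon with computable area.

The set at signed distance ≤ d is obtained by buffering (d > 0) or
eroding (d < 0) the margin polygons with round joins, which is exactly
the Euclidean distance level set; a band area is the clipped difference
of two offsets. With 64 buffer segments per quarter-circle the
discretization error of a band area at the scales used here is below
10⁻⁵ mm² (the tests check circular annuli against πr² arithmetic at
10⁻⁴ mm²). Erosions that collapse to the empty set yield area 0 and a
`degenerate` flag rather than an error, since deep inner bands
legitimately vanish for small tumors. Band areas and compartment areas
are intersected with the field rectangle so densities remain unbiased
near image edges. Interior holes in a tumor polygon count as host
tissue. Per-cell distances use exact point-to-boundary distance with a
point-in-polygon sign, and are validated against a brute-force oracle
(nearest of 10⁵ densely sampled boundary points) to 0.1 µm.

The peritumoral compartment defaults to the 500 µm band strictly
*outside* the margin. The phrase "centered on the border with an extent
of 500 µm" admits a ±250 µm reading, so an `inner_extent_um` option can
move part of the band inside; the default keeps the intratumoral
compartment intact. The "1 mm² thick bands" of the original description
are read as density normalization to per-mm² units, not as a geometric
constraint on band construction — the text does not resolve this, and
normalization is the only reading that leaves the histogram independent
of band geometry.

## Tissue-scene generator

Cells of each marker (CD8, CD163, NEG) are independent inhomogeneous
Poisson processes with intensity

    λ_m(p) = max(0, λ_base(m, side(p)) + slope_m · d(p))

sampled by thinning against a constant envelope; expected counts
therefore equal intensity integrated over area, which the tests verify
by Monte-Carlo over 200 seeds. Clamping at zero is the simplest
well-defined extension of a linear gradient. Defaults (intratumoral
CD8 300, CD163 700, NEG 1500 cells/mm²; peritumoral CD8 600, CD163 400,
NEG 1500; zero slopes) emulate an immune-infiltrated melanoma with T
cells enriched outside and macrophages inside the margin — plausible
magnitudes for lymphocyte/macrophage infiltrates, chosen once since no
distributional description of the original tissue exists. Marker
processes carry no cell–cell exclusion; an optional greedy hard-core
thinning (`min_spacing_um`) produces the non-overlapping scenes used by
the rendering tests. A margin that does not fit the field is allowed but
flagged (`clipped`) and clipped in all area computations.

The pseudo-IHC renderer draws each cell as a hematoxylin-blue nucleus
disk (default radius 3 µm) and each positive cell additionally as a
fast-red disk (default 4 µm, covering its own nucleus so positives
present as single red objects), over a bright background, with optional
additive Gaussian channel noise. It refuses scales at which a nucleus
falls below one pixel. The renderer keeps a noise-free label raster and
the generating cell list as ground truth for detection benchmarking. It
does not emulate pigment, necrosis, stain gradients, overlapping or
fused cells, or tissue texture — so detection scores on rendered scenes
certify the geometry and bookkeeping of the detector, not its robustness
to real-slide artifacts.

## Cell detection and densitometry

Pixel classification uses channel dominance: red-positive when
R − max(G,B) exceeds a threshold (default 60 on the 0–255 scale),
nuclear when B − max(R,G) does, background otherwise. This transparent
rule replaces an unpublished proprietary pattern-recognition step; a
stain-deconvolution backend could be added behind the same interface.
Connected components (8-connectivity) of each class become cells if
their area lies within 20–400 µm² (lymphocyte-to-macrophage range);
red components take the slide's marker — one marker per slide, as with
serially sectioned tissue — and blue-only components are NEG. Touching
cells are not split (no watershed) in v1.

Field densitometry counts positive cells in five non-overlapping square
fields of 10⁻³ mm² (side ≈ 31.6 µm; square shape is a convention, the
field shape being otherwise unspecified) and reports density as the mean
count over the field area. Hotspot placement emulates a pathologist
selecting the densest areas: candidate squares on a 10 µm grid, chosen
greedily by positive count with ties broken at the smallest (x, y).

## Scoring

The scored quantity is the positive-cell fraction — the marker's share
of all nucleated cells in the compartment, in percent. The original
grading reports percent categories without naming a denominator; the
all-cells fraction is the natural choice for a count-based pipeline, and
density thresholds can be substituted upstream without touching the
scoring rules. Cut-points: 0 ⇔ exactly 0 %, 1+ below 10 %, 2+ in
[10, 50), 3+ in [50, 100]. The stated ranges "10–50 %" and "50–100 %"
overlap at 50, so intervals are left-closed. High means 2+/3+. PD-L1 and
PD-L2 are positive at ≥ 5 % (the ≥ matches the combination-group
definitions); β-catenin is overexpressed strictly above the cohort
median of evaluable membranous percentages (strict >, matching an
"overexpression > 60 %" reading where 60 is the median), with a fixed
cut-off override. Not-evaluable values propagate: any dichotomy or
combination group with an NE input is NE, and NE patients drop out of
models using that marker.

## Cohort simulator

Patients draw a three-level CD8×CD163 group (default probabilities
0.25/0.50/0.25, generated as independent 50/50 CD8 and CD163 dichotomies
resolved through the combination rule, so single-marker contrasts are
also defined), binary covariates (M1c stage 60 %, ECOG ≥ 1 30 %,
elevated LDH 40 %, BRAFi+MEKi 40 %, subsequent immunotherapy 25 % —
cohort-level frequencies of the population being emulated), a best
response, and PFS/OS times. Response is a Bernoulli draw from a logistic
linear predictor (coefficients keyed by design column; defaults: group-3
intercept logit⁻¹ ≈ 35 %, group-1 log-odds log 9.91, group-2 log 3),
then split CR|responder = 0.26 and SD|non-responder = 0.44. Event times
follow a proportional-hazards law with Weibull baseline
H(t) = (ht)^k — k = 1 (exponential) by default for closed-form checks,
the shape exposed for sensitivity work. Baseline hazards correspond to
reference-group medians of 13.7 (OS) and 8.3 (PFS) months; censoring is
independent exponential, defaulting to ≈ 30 % censored against the
reference OS hazard. PFS is modelled directly as the composite
progression-or-death time; the two endpoints are marginal draws sharing
covariates, sufficient for parameter recovery though not jointly
consistent patient by patient (a known simplification).

## Association models

Responder means best response CR or PR; NE responses are excluded from
response models. Categorical terms are dummy-coded against explicit
reference levels — group 3 (low CD8 / high CD163), "low", "negative",
"no", "BRAFi" — so reported contrasts read directly as
favorable-vs-hostile. Logistic fits use maximum likelihood with Wald
95 % CIs; complete separation or non-convergence yields a non-estimable
result object with a diagnostic message instead of an exception. Cox
fits use the partial likelihood with Efron tie handling; OS models
additionally adjust for subsequent immunotherapy. Both models are
complete-case per fit and report the n used. Kaplan–Meier quantiles use
the first-time-S(t)≤q convention (median at S ≤ 0.5, quartile times at
S ≤ 0.75 / 0.25), with unreached quantiles reported as infinity. The
χ² test is Pearson without continuity correction (optionally enabled),
flagging expected counts below 1; Kruskal–Wallis is tie-corrected, with
the all-identical degenerate case defined as H = 0, p = 1. No
multiple-testing adjustment is applied anywhere, by design.

## Simulation-based validation

`immunocontext.validation` regenerates known-truth cohorts and refits
the models: geometric-mean recovery of the headline effects (true OR
9.91 for response and HR 0.34 for OS, group 1 vs 3; HR 0.14 for a
binary intratumoral-CD8 contrast at prevalence 0.5 with
stage/treatment/subsequent-immunotherapy adjustment) over 500 cohorts
of n = 800, and empirical 95 % CI coverage under null biomarker effects.
Replicate seeds derive deterministically from one base seed. The same
routines back `scripts/acceptance.py`. Problem sizes (500 × 800) give
Monte-Carlo standard errors on the geometric means of about 1–2 % while
keeping a full run to roughly a minute on one CPU.

## Known limitations

* Detection is validated only on synthetic renders; real slides add
  pigment, blur, stain variability and touching cells that the v1
  classifier does not address.
* The scene generator has no spatial interaction between markers and no
  anisotropy along the margin.
* The cohort simulator draws PFS and OS marginally and treats covariates
  as independent Bernoulli variables; correlations seen in real cohorts
  (e.g. LDH with stage) are not modelled.
* No 3D/z-stack support, no whole-slide formats, and no nearest-neighbor
  spatial statistics beyond densities.
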