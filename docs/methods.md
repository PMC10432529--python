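# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, and what the synthetic-data generators do and
do not emulate.

## Logistic growth kinetics

Curves are modelled as `N(t) = K / (1 + ((K − N0)/N0) e^(−μt))` with μ the
intrinsic growth rate (h⁻¹), K the carrying capacity (same units as the
measurements, OD600 or RFU) and N0 the initial value. Fitting is bounded
nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective). Initialisation: K from the maximum observed value, N0 from
the first positive value, μ from the log-linear slope of the rising
segment (values between 5% and 80% of the maximum); K is bounded in
(0, 2·max]. Curves whose range is below 5% of their maximum, or whose fit
explains nothing beyond a flat mean, are reported `converged=False` with
μ = K = 0; downstream code treats these as no-growth conditions.

AUC is the analytic integral of the *fitted* logistic over the observed
interval, `(K/μ)[ln(A + e^{μt₁}) − ln(A + e^{μt₀})]` with
`A = (K − N0)/N0`, evaluated via `logaddexp`. Using the model AUC rather
than an empirical trapezoid keeps the quantity stable under sparse (24 h)
sampling; both 24 h and 5 min grids are supported without resampling.

Blank correction subtracts the carbon-free medium curve pointwise (with
linear interpolation onto the sample grid when grids differ) and clips
negative results to zero.

### Carbon profiles and dissimilarity

The profile matrix has one row per strain and one column per
(carbon source × parameter) pair, parameters being μ and K. Columns are
z-scored independently with the sample SD (ddof = 1); whether μ and K
should be scaled jointly is genuinely open, and per-column scaling was
chosen because it gives each carbon×parameter equal weight regardless of
units. Non-growth conditions contribute μ = K = 0 before scaling.
Zero-variance columns are dropped with a logged warning. Dissimilarity is
the Euclidean distance between profile rows; complete-linkage clustering
of the full distance matrix is exposed alongside the focal strain's
distance vector, and the dendrogram can be serialised as newick.

## Constraint-based resource overlap

Models are held in a light container (metabolites, reactions with
stoichiometry and bounds, exchange→compound map, biomass reaction) and
round-trip through SBML L3/FBC (via COBRApy) and a JSON dialect. FBA
closes uptake on all exchanges outside the medium, caps uptake of medium
compounds at `uptake_bound` (default 10 flux units per compound), and
maximises biomass with HiGHS. Infeasibility is reported as zero growth;
an unbounded LP is reported as a model defect.

Minimal media solve a MILP: one binary per medium compound gating its
uptake (`v_ex + uptake_bound·y ≥ 0`), biomass ≥ `threshold_fraction`
(default 0.1) of the full-medium optimum, objective `min Σy`. Alternative
optima of the same cardinality are enumerated with integer cuts
(`Σ_{c∈S} y_c ≤ |S| − 1`), capped at 50 alternatives to bound solve time.
Because every enumerated set has minimum cardinality, no proper subset can
support growth, so each is a genuine minimal medium. An exhaustive
subset-search implementation over the same FBA serves as an independent
oracle for small models.

MRO uses the union of a species' alternative minimal sets as its
requirement set — the union captures the *maximal possible* overlap
between two species' options. The default normalisation divides the
intersection by the mean set size, with a min-normalised variant behind a
flag; both are recorded in the result. Inorganics are included by default
(whole-medium overlap); the `carbon_only` flag restricts to carbon sources
because the shared mineral base compresses the index towards 1. Published
per-pair MRO values are kept as packaged reference context rather than
recomputation targets, since they depend on genome-derived models that are
out of scope here.

Media presets: M5C (glucose, fructose, malate, sorbitol, methanol), L10C
(fumarate, sucrose, aspartate, malate, citrate, glutamate, alanine,
fructose, threonine, methanol) and L8C (L10C without citrate, alanine,
threonine, plus glucose), each over a mineral base of ammonium, phosphate,
sulfate, magnesium and a lumped trace-element pseudo-compound. Other leaf
compositions (L13C/L18C/L26C) must be supplied as explicit `MediumSpec`
configurations.

## Competitive ability score

`score = (μ_i − 1)/√(a_ii·a_ij)` with `a = 1/K`. The numerator subtracts
the dimensionless constant 1 from a rate in h⁻¹; the formula is
implemented literally as defined, with μ in the units produced by the
logistic fit, and the score's sign therefore follows `sign(μ_i − 1)`.
z-scaling is applied across all scores within one experimental context
(in vitro or in planta); whether to pool replicates or strain means into
the cohort is a caller choice — both are supported because neither
convention is canonical.

## CUSPER single-cell pipeline

Background correction subtracts the per-field-of-view mean background
from each cell's green intensity. Corrected intensities ≤ 0 are floored
at 1 a.u. and flagged: such cells are dimmer than background and thus at
or beyond the detection limit (they end up censored in RS_>4).

`RS = log2(x̄_0 / x)`, with x̄_0 the mean background-corrected intensity
of the time-zero population of the same experiment. The limit of
detection is the lower 5% empirical quantile (linear ECDF interpolation)
of RS values computed on background readings — the RS below which only 5%
of pure-background readings fall; the working LOD for binning snaps down
to the nearest bin edge (x.5). Bins are half-open unit intervals centred
on integer division counts: RS_0 < 0.5 ≤ RS_1 < 1.5 ≤ … < 4.5 ≤ RS_>4,
with everything at or above the LOD pooled and flagged censored; negative
RS (cells brighter than the t₀ mean) counts into RS_0 and is logged.

Founder reconstruction inverts clonal expansion: observed fraction `f_k`
of cells in division class k represents `f_k·2^(−k)` founders, so
`g_k = f_k 2^(−k) / Σ_j f_j 2^(−j)` and the population fold increase is
`1/Σ_j f_j 2^(−j)`. The censored RS_>4 class is assigned 5 divisions by
default — its lower bound, making the fold increase conservative; the
value is configurable.

PERMANOVA uses the Gower-centred matrix `G = −½ J D² J` and sequential
(Type-I) sums of squares `tr(H_k G) − tr(H_{k−1} G)` for factors in the
given column order (time before treatment), with pseudo-F against the
full-model residual and unrestricted permutation of sample labels;
`p = (1 + #{F* ≥ F_obs})/(n_perm + 1)`. The one-factor case agrees with
scikit-bio's implementation, which serves as a cross-check in the tests.
Compositions with all mass in RS_0/RS_1 (initial populations) can be
excluded from multivariate comparison by the caller.

## Image quantification

Intermodes thresholding smooths the 256-bin histogram with a running
3-bin mean until exactly two local maxima remain (endpoint bins may be
modes) and takes the floor of the modes' midpoint; unimodal histograms
raise after a bounded iteration count so callers can fall back to a manual
threshold. For 16-bit images the histogram spans [min, max] and the bin
midpoint maps back to an intensity. Components are 8-connected; particles
outside 0.5–2.5 µm² or touching any border are discarded. The size window
is interpreted as *area* in µm² (particle-analysis semantics) — length
along the major axis is the plausible alternative reading, and the choice
is flagged here. The default pixel size (0.045 µm/px) is a configuration
value. Manual phase-contrast curation of false positives is out of scope;
an optional red-intensity floor can stand in for it. Background is the
mean of one randomly placed, seed-deterministic, mask-free square patch
per image.

## Synthetic data: what it emulates, what it does not

Noise is multiplicative lognormal (unit mean, specified CV) for both OD
and fluorescence — errors scale with signal and positivity is preserved.
Division counts are capped at 8 (beyond instrument resolvability; the LOD
censors at 4.5 regardless). The cell-to-cell GFP CV at time zero is a
free parameter with default 0.05; no measured value anchors it.
CUSPER scenes report measured green intensity as signal plus the
field-of-view background, so background correction is a real operation on
synthetic data too. Toy metabolic models route each usable carbon through
transport and catabolism into one precursor consumed by a single lumped
biomass reaction (0.1 stoichiometry per inorganic), giving growth iff at
least one usable carbon plus all inorganics are available and making
minimal media exactly enumerable. Image cells are axis-aligned ellipses
of constant red intensity.

Not emulated: plant physiology and leaf spatial structure, CFU sampling
noise beyond a lognormal multiplier, diauxic growth, cross-feeding,
illumination-field artefacts, or cell overlap in images. Passing tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every artefact of real microscopy or
plate-reader data.

## Problem sizes

The simulation studies use sizes chosen to make sampling error small
relative to the tested tolerances while keeping the suite quick: 200
simulated curves for fit-bias estimates, 2000 founders for the dilution
round trip (binomial SE per bin ≲ 1%), 500 null datasets × 199
permutations for PERMANOVA type-I calibration, 999 permutations for power
checks, and 50–100 random scenes for image-recovery rates.
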