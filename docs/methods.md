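# Methods

This note documents the statistical machinery in `trapnest`: the models
and indices, the numerical choices behind them, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Reproductive traits and offspring production

The unit of observation is one occupied nesting tube. Its phenotype is the
3-vector (total brood cells *T*, proportion parasite-free
*p*<sub>pf</sub> = (T − parasitized)/T, proportion non-emerged
*p*<sub>ne</sub> = non_emerged/T). "Non-emerged" counts only
parasite-free failures, so the three cell fates partition the tube and

    emerged = T (p_pf − p_ne) = T − parasitized − non_emerged

is an exact identity in rational arithmetic. The package stores counts and
derives proportions on demand — never the reverse — so the identity can
never be degraded by rounding (`emerged_identity_holds` verifies it with
`fractions.Fraction`). Offspring production of a site is the arithmetic
mean of emerged cells per tube.

Traits are z-scored (sample sd, n−1 denominator) so the three axes carry
equal weight in the diversity indices. The scope of the z-transform is
all analysed tubes of one taxon — i.e. tubes at sites that pass the
eligibility filter — so that (a) every site's cloud lives on one common
scale and (b) sites excluded from the analysis cannot influence it.
Pooling bees and wasps into one scale is available as a config switch
(`z_scope="pooled"`), but bees and wasps are otherwise always analysed
separately. Traits are deliberately limited to these three: they describe
per-tube reproductive output, not lifetime fitness, and sex ratio,
paternal care, and nest defense are out of scope.

## Trait-diversity indices

All indices treat each tube as one point in the z-scored 3-space; there
is no abundance weighting.

**TOP (richness).** Compute the convex hull of the cloud, add its
d-dimensional measure (area in 2-D, volume in 3-D), delete the hull's
vertices, repeat; stop when fewer than d+1 points remain or the remainder
is affinely degenerate (a degenerate layer has measure zero and
terminates peeling). Summing over layers makes interior structure count,
unlike a single-hull range measure. Hulls come from Qhull
(`scipy.spatial.ConvexHull`); the test suite checks the peeling against a
from-scratch gift-wrapping + shoelace enumeration.

**TED (evenness).** Compare the cloud's n(n−1)/2 pairwise Euclidean
distances with those of a maximally even reference arrangement of the
same n and d. Both multisets are divided by their own mean (making the
index scale-, translation- and rotation-invariant), binned into a shared
histogram of ⌈√(n(n−1)/2)⌉ equal bins over the pooled range, and
TED = 1 − ½·Σ|p<sub>i</sub> − q<sub>i</sub>| on the relative frequencies.
TED is 1 when the two distributions coincide. If every pairwise distance
is equal (to within 1e−12 relative), both normalised multisets are the
constant 1 and TED is 1 by convention. A cloud with all points coincident
has no defined distance distribution and raises; inside the bootstrap
such a draw contributes NaN and is excluded from the average.

*Reference construction.* "Maximally even" is formalised as the
maximin-distance packing: n points in the unit d-cube maximising the
minimum pairwise distance. The relaxation maximises an auxiliary
separation variable subject to all pairwise squared distances exceeding
it (SLSQP), started from a scrambled Halton set and seeded random
restarts, keeping the candidate with the largest final separation. An
earlier inverse-power repulsion energy was rejected because its optimum
is not the even packing (for n=3 in a square it prefers one pair at
distance 1 over three equal sides of 1.035). The SLSQP construction
recovers known packing optima (n=3: equilateral of side √6−√2; n=4:
the corners; n=5: 0.7071; n=7, d=2: 0.5359) and is cached and
bit-reproducible per (n, d, seed). Because the reference is a documented
construction rather than a published standard, absolute TED values are
comparable only within one construction; orderings between clouds are
what the analysis uses.

**FDis (divergence).** Mean Euclidean distance of the points from their
unweighted centroid. Zero iff all points coincide.

## Site bootstrap

Indices are sample-size sensitive and occupancy varies roughly 8–64
tubes per site, so effort is standardised: per taxon, keep sites with at
least `min_tubes` = 8 occupied tubes, and for each kept site average each
statistic over `reps` = 999 subsamples of `draw_size` = 7 distinct tubes.
Seven exceeds the trait dimension (so hulls are generically
full-dimensional) while keeping the eligibility bar low. Draws are
without replacement: with replacement, duplicate points would collapse
TOP and TED degenerately. A draw whose seven points are affinely
degenerate contributes TOP = 0 and is not redrawn (redrawing would bias
the average). Mean traits and offspring production are bootstrap-averaged
like the indices by default; `mean_traits="all_tubes"` computes them once
from every tube instead (the two agree in expectation).

Reproducibility: each site × taxon draws from its own substream,
`SeedSequence(master_seed, spawn_key=(crc32(site_id|taxon),))`, so results
are bit-identical regardless of processing order or the presence of other
sites; tubes are processed in nest_id order for the same reason.
For a site with n tubes the bootstrap average converges to the exact mean
over all C(n, 7) subsamples; the suite verifies this exhaustively for
n = 8–12.

## Model ladder and AICc

For each predictor x and response y, four OLS variants are fitted:

    (a) linear                 y ~ x
    (b) interaction            y ~ x + UGS + x:UGS
    (c) quadratic              y ~ xc + xc²            (xc = x − mean)
    (d) interaction+quadratic  y ~ xc + xc² + UGS + xc:UGS + xc²:UGS

Variant (d) is the full second-order form — the natural composition of
(b) and (c); whether the squared term should also interact is a genuinely
open design point, and the full form was chosen for symmetry with (b).
Quadratic terms use the centered predictor, which changes no fitted value
but tames collinearity. UGS enters as treatment coding with home gardens
(the most frequent type) as reference. An interaction variant is dropped
with a warning when some observed UGS level has fewer than two sites.

AICc uses the Gaussian profile likelihood with k counting all regression
coefficients plus the residual variance (simple linear model: k = 3):

    AIC  = n ln(RSS/n) + n(ln 2π + 1) + 2k
    AICc = AIC + 2k(k+1)/(n − k − 1)

Only AICc differences matter; the convention is fixed so tables are
comparable. The winner is the smallest AICc, with near-ties
(|Δ| < 1e−8) resolved toward fewer parameters. Each predictor's winning
term set is inherited by the multivariate model (UGS main effect entering
once). The overall p-value is the F-test of the full model against
intercept-only; R² is unadjusted; stars mark p < 0.05 / 0.01 / 0.001 with
no multiple-testing correction.

Two statistical properties of this procedure are worth stating plainly.
First, strict minimum-AICc selection accepts a one-extra-parameter
variant spuriously with probability P(χ²₁ > ≈2.08) ≈ 0.15 regardless of
effect size, so when the truth is the simple linear model the ladder
recovers it only ≈80% of the time (the other variants, having distinctive
strong terms, are recovered ≥90%). Second, F-tests read off a model
*selected* on the same data are anti-conservative: under a pure-noise
null the nominal 5% test on the selected multivariate model rejects at
≈16%. The F-test is calibrated for a pre-specified term plan (verified in
the suite); reported p-values after selection must be read as conditional
on the selected terms. Proportions are modelled untransformed.

## Landscape metrics

Cover rasters are plain-text ESRI ASCII grids over an 8-class legend
(forest, open green, bare soil, water, buildings, roads, other paved,
agriculture). A site's buffer is the set of cells whose centers lie
within the radius (inclusive; 250 m by convention). Open green area is
that class's fraction of the buffer; impervious surface is the summed
fraction of buildings, roads, and other paved surfaces. Edge density uses
4-neighbourhood adjacency and interior edges only: every pair of
in-buffer neighbouring cells with different classes contributes one cell
edge (length = cell size), and the total is divided by buffer area. The
buffer outline itself is not an edge. Consequences: density is invariant
to class relabeling, bounded by 2/cell_size, doubles when the same cell
array is read at half the cell size, and is unchanged when the same
geometry is subdivided into finer cells.

## Synthetic generator

`GeneratorConfig` emulates a multi-season trap-nest survey across the
four UGS types (default 15 community gardens, 70 home gardens, 48 parks,
20 green roofs):

* **Environment.** Per site, (open green, impervious, other) is a
  Dirichlet draw with UGS-specific concentrations (green roofs impervious-
  heavy, parks green-heavy) and edge density a gamma draw (home gardens
  highest). Proportion constraints hold by construction.
* **Occupancy.** Tubes per site × taxon: negative binomial, mean 20,
  capped at 64 — spanning the eligibility threshold so the filter is
  exercised.
* **Brood size.** Zero-truncated negative binomial (shape 2) whose
  *truncated* mean equals `mu_total`; the untruncated mean is solved by
  root-finding and sampling is by inverse CDF, so the configured mean is
  exact. Defaults echo the observed study-wide means: 6.68 (bees), 4.16
  (wasps). The right tail occasionally exceeds the observed maxima
  (~24/20) since the counts are not truncated above.
* **Fates.** One trinomial draw per tube over (emerged, parasitized,
  non-emerged) with cell probabilities p_par and p_fail — defaults
  0.068/0.257 (bees) and 0.098/0.307 (wasps) — so every count invariant
  holds exactly. Environment links are optional on both channels: log-link
  coefficients on brood size (linear, quadratic-impervious, UGS-specific
  impervious slopes) and logit-link on fates; all zero by default (the
  null generator).
* **Evenness-coupled scenario** (`evenness_coupling=True`). Each site
  gets a latent quality q ~ U(0,1). Every tube interpolates, with weight
  q, between a "clumped" position (one of two tight blobs: extreme brood
  sizes 1–2 or 21–24 with blob-specific parasitism 0.30/0.01) and an
  "even" position (distinct mid-band brood sizes 5–19, wide per-tube fate
  bands). Non-emergence probability falls with q (0.55 → 0.15), so
  high-q sites both produce more offspring and present evenly spread
  trait clouds. The mid band's mean (12) matches the blob mixture's mean
  so brood size itself carries no regime signal into offspring counts.
  The scenario produces a positive TED–offspring association and negative
  TOP/FDis–offspring associations — the qualitative pattern the analysis
  is designed to detect.

What the generator does *not* emulate: spatial autocorrelation of sites,
year effects and phenology, species-specific trait distributions
(species labels are decoration), correlations between brood size and fate
probabilities within the null mode (hence the null generator's mean
emerged per nest equals μ·(1 − p_par − p_fail), slightly below a field
mean where larger nests also fail less), and the real land-cover geometry
of any city. Passing tests therefore demonstrate correctness of the
machinery and sensitivity under the stated structure, not field realism.

## Problem sizes used in the checks

The shipped verification uses a ~1e5-nest survey for the exact-identity
sweep, 1,000 random small clouds for the geometry oracle, exhaustive
C(n,7) enumeration for sites of 8–12 tubes against 999-replicate
bootstraps, 200 replicates per generating variant (n = 200) for ladder
recovery, and 500 pure-noise replicates (n = 100) for F-test calibration.
The acceptance script runs the full pipeline (999 bootstrap replicates,
study-sized surveys) twice, once per generator mode.

## Known limitations

* TED values depend on the documented reference construction; compare
  TED across studies only under the same construction.
* TOP in 3-D sums hull volumes; clouds that are nearly coplanar give
  small volumes and TOP approaches 0 before the point count runs out.
* The ladder's selected-model p-values are anti-conservative (see above);
  no correction is applied, matching the reporting convention the
  package mirrors.
* CSV is the only interchange format; converting publisher supplements to
  the nest/site schemas (a column-name dialect map is provided) is a
  manual step.
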