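# Methods

## Spore geometry and mass

Species descriptions report spore diameters as ranges: an *inner* range
covering most spores and an optional *outer* range with extremes. One
diameter per axis is taken as the midpoint of the chosen range (the only
reading of "mean of the two range limits" that yields a single diameter per
axis), with the inner range as the default basis — inner limits describe
the typical spore rather than outliers. Globose spores are spheres,
V = (π/6)d³; sub-globose spores are prolate spheroids with the short axis
duplicated, V = (π/6)·d_long·d_short². If the axes come in swapped
(short > long, an occasional inconsistency in descriptions), they are
reordered rather than rejected.

Volume converts to dry mass at 3.64 × 10⁻⁷ µg/µm³, the only published
joint measurement of spore volume and weight for an AM fungus
(*Funneliformis caledonium*). The conversion is linear, so distribution
comparisons are identical in volume or mass units.

Dimorphic Ambisporaceae species (distinct "glomoid" and "acaulosporoid"
spore types) are stored as two records keyed by morph; single-trait
analyses select one morph set explicitly and the pipeline runs the signal
analysis once per morph set, reporting both.

Cross-taxa comparisons summarize each group by quantiles and log₁₀ span and
report pairwise fold differences as ratios of *geometric* means (primary;
everything downstream is analyzed on logs) with arithmetic-mean ratios as a
secondary column.

## Biomass conversion chain

Colonization measurements arrive in three currencies and are converted to a
common mass unit (µg):

* root ergosterol E (µg/g root) → root hyphal length via the inverted
  calibration L = (E − 0.18)/0.4 m. Values below the 0.18 intercept would
  invert to negative lengths and clamp to 0 with a logged warning — lengths
  cannot be negative, and such values indicate colonization below the
  calibration's sensitivity.
* hyphal length → dry mass assuming cylindrical hyphae of radius 4 µm
  (mid-value of the 1–10 µm range reported for AM hyphae; one radius for
  all species) and dry density 0.23 g/cm³. One meter of such hyphae weighs
  0.23·π·16 ≈ 11.56 µg.
* body size W_α = dry mass of root plus soil hyphal length; allocation to
  reproduction A = R·W₀ with R the spore density (spores/g soil) and W₀
  the single-spore mass.

Replicates (5 per species × host by design) are averaged to species × host
means *before* model fitting — each fitted point represents one fungal
species growing with one host — and the whole conversion chain is affine,
so averaging commutes with conversion; per-replicate fitting is available
via a flag. All constants live in one overridable `ConversionConstants`
record; non-default values are logged.

Spore output is normalized per gram of soil while body size sums
compartments normalized per gram of root and of soil respectively; the
denominators are kept as measured. Log-scale slopes are invariant to any
per-species rescaling common to both axes, so this bookkeeping choice does
not move the fitted exponents.

## Pagel's λ

Under Brownian motion the tip values are MVN with covariance σ²C, C_ij the
root-to-MRCA path length. Pagel's λ multiplies off-diagonal entries of C
while fixing the diagonal. The fit profiles λ on [0, λ_max], where λ_max
keeps every implied terminal branch nonnegative (smallest tip-depth /
parent-depth ratio; > 1 on ultrametric trees). At each λ the root state and
σ² have closed-form GLS solutions via a Cholesky solve; the outer search is
a 21-point grid pre-scan (the profile can be multimodal) followed by
bounded scalar refinement, and the optimum is verified in tests against a
dense 2001-point grid to 10⁻⁶ log-units.

The test of λ̂ against λ = 0 is a likelihood-ratio test. λ = 0 lies on the
boundary, so the asymptotic null is the 50:50 mixture of χ²₀ and χ²₁. With
the *ML* profile this mixture is measurably conservative at the study's
scale: on 200-tip Yule trees with λ_true = 0 the ML estimate hits the
boundary far more than half the time and the empirical level drops to
~0.015. Profiling the *restricted* (REML) likelihood — the standard remedy
for boundary tests of variance structure, since it accounts for estimating
the root state — restores near-nominal behavior (~0.04–0.06 across seed
sets), so `reml_mixture` is the default. `ml_mixture` and `ml_chi2` (the
plain-χ²₁ ML test that R's `phytools::phylosig` reports; the package's ML
λ̂ and log-likelihoods match `phylosig` to at least five decimals) remain
available. REML also slightly reduces the familiar downward bias of λ̂ at
intermediate truth.

λ is invariant to affine trait changes, so analyzing log₁₀ trait values is
a presentation choice only. Non-ultrametric trees (e.g. ML trees with
substitution-rate branch lengths) are accepted; nothing assumes equal tip
depths except where noted in the synthetic generator.

Independent contrasts follow Felsenstein's pruning recursion
((x₁−x₂)/√(v₁+v₂), inverse-variance-weighted ancestral states, parent
branch extended by v₁v₂/(v₁+v₂)). Polytomies are resolved to zero-length
bifurcations first, with a logged count; a contrast node whose combined
branch length is zero is an error rather than an infinite contrast.
Contrast correlations and regressions are forced through the origin
(contrast signs are arbitrary) with n−1 degrees of freedom.

## SMA regression and the trade-off

The SMA slope is sign(r)·sd(y)/sd(x); it minimizes the summed
triangle areas between points and line, is symmetric under swapping axes
(slope → 1/slope), and relates to OLS by |b_OLS| = |r|·|b_SMA| — OLS
attenuates allometric slopes whenever |r| < 1, which is why SMA is the
primary estimator and OLS is reported only for that comparison. The 95% CI
uses B = F₀.₉₅(1, n−2)(1−r²)/(n−2) with limits b(√(B+1) ± √B); the test of
a hypothesized slope b₀ checks zero correlation between the rotated axes
y − b₀x and y + b₀x (exact under normality, n−2 df). Rotated axes that are
constant to within 10⁻⁹ of the data scale are treated as exactly constant,
so noiseless inverse-proportional data yield p = 1 rather than a
rounding-noise p.

The trade-off is fitted on base-10 logs in three variants sharing the same
species × host points: uncorrected log R ~ log W₀; output per meter of
extraradical mycelium; and output per unit total mycelium mass — ratio
normalization, matching the interpretation "spores produced per meter of
hyphae / per gram of mycelium". log A ~ log W₀ is fitted alongside; under
an exactly constant budget that relation is degenerate (zero variance) and
is reported as absent rather than fitted. Every variant is tested against
−1. Points are pooled across hosts into a single fit; two-sided tests at
95% throughout, no multiple-testing correction. When the uncorrected
correlation is significant at α = 0.05 and a tree is supplied, an
independent-contrast correlation on per-species mean logs is attached to
distinguish a physical constraint from phylogenetically clustered
covariation.

Scaling fits log W₀ ~ log W_α and log R ~ log W_α, plus log(R·W₀) ~ log W_α
whose slope is the scaling exponent β̂ and intercept the log₁₀
proportionality constant.

## Synthetic data

The generator emulates the study design with everything known: a Yule tree
(n_species tips, deterministic given the seed); a λ-Brownian trait drawn
from the transformed covariance; and an allocation experiment built
generatively from R = A/W₀^b. Per species, W₀ and A are lognormal
(optionally W₀ Brownian-evolved on the tree so trait signal and trade-off
can be studied jointly); body mass W_α is lognormal with configurable
correlation to A; hosts contribute a multiplicative lognormal effect on
output; replicates get mean-one multiplicative lognormal noise
(σ²_ln = ln(1+cv²)) on output and body size. Body mass is split
root/soil by a fixed fraction and encoded back through the *forward*
ergosterol calibration, so consuming the CSV exercises the inversion code
path. Lognormal choices keep the trade-off exactly linear in logs, which
is what makes the noiseless recovery checks exact.

Defaults are the study conditions: 14 species × 4 hosts × 5 replicates;
log₁₀ W₀ mean −0.5, sd 0.75 (≈0.3 µg spores spanning roughly the 3–4
observed decades); log₁₀ A mean 1, sd 0.5 (≈10 µg spores per g soil);
log₁₀ W_α mean 2, sd 0.5 (≈100 µg mycelium per g); replicate CV 0.3 and
host-effect sd 0.2 log₁₀-units, plausible greenhouse variability. One
global seed fans out to named per-stage substreams.

What the generator does *not* emulate: measurement floors and zeros
(non-sporulating pots), host × species interaction structure beyond a
multiplicative host effect, per-species hyphal radii, intraspecific spore
size variation, and non-ultrametric branch lengths. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to those real-data features.

## Problem sizes and numerics

Recovery and calibration experiments use 200 simulations of 200-tip trees
per condition for λ (estimator mean, LRT level), 500 replicates of n = 200
for the slope-test level, and 100 random datasets for the SMA-vs-oracle
agreement — sizes at which Monte-Carlo error is a few per cent while a
full run stays around a minute. Covariance factorizations use Cholesky
decomposition; the λ search bound is shaved by a relative 10⁻¹⁰ because
the covariance is singular exactly at λ_max; estimates below 10⁻⁸ are
reported as exactly 0.

## Known limitations

* Ergosterol is an imperfect biomass proxy for some AM fungi; the chain
  takes the calibration at face value.
* A single hyphal radius for all species; a radius sensitivity scan is a
  config choice, not automated.
* The SMA slope is |r|-inflated relative to the structural slope when both
  axes carry independent noise of different magnitude; interpretation of
  slopes under heavy noise should lean on the CIs.
* The boundary-mixture LRT is asymptotic even in its REML form; levels a
  point or two from nominal remain possible on small trees.
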