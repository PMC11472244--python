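# Methods

`hzmhc` implements a comparative test for adaptive introgression of MHC
(major histocompatibility complex) genes across vertebrate hybrid zones.
Because MHC amplicon genotyping yields multilocus allele pools without
locus assignment or copy number, all empirical analyses operate on binary
presence/absence matrices (individuals × alleles).  The package provides
the three zone-level tests (allele sharing, geographic clines, genomic
clines), the cross-zone phylogenetic synthesis, and a forward simulator
used to validate the binary-coding treatment.  This note records the
models, the defaults and why, and the choices made where the design was
genuinely open.

## Admixture filters

Genome-wide admixture Q-scores (from external clustering software) are
consumed as input.  An individual's admixture is `min(q, 1 − q)` — its
distance from its own species' pure end — since a single Q in [0, 1]
serves both species.  Individuals with admixture strictly above 3%
(`admixed_threshold = 0.03`) are treated as admixed; the allele-sharing
test additionally uses only localities whose mean admixture is strictly
below 5% (`pure_locality_threshold = 0.05`).  Both comparisons are read
strictly at the boundary (0.031 is admixed; 0.030 is not).  Individuals
from pure localities lacking a Q-score may be supplied with an assigned q
of 0 or 1 and a `q_inferred` flag.

## Allele sharing and the permutation SES

Interspecific sharing within a geographic category is the Jaccard
similarity of the two species' pooled allele sets.  The exact sharing
statistic is not critical because the test standardizes against its own
permutation null, but Jaccard was chosen for being symmetric in species
and bounded in [0, 1]; a directional variant (fraction of one species'
alleles found in the other) is available.  The test statistic is
`sharing_near − sharing_far`; the null distribution is obtained by
shuffling near/far labels within each species (category sizes preserved),
default 1,000 permutations.  The p-value is one-sided toward near-excess —
the adaptive-introgression hypothesis is directional — with the add-one
estimator `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, so the smallest
attainable p at 1,000 permutations is 1/1001; a two-sided option exists.
The standardized effect size `SES = (obs − mean(perm)) / sd(perm)` (sample
sd) is Cohen's d with a single observed "group"; its sign is positive when
near sharing exceeds the null expectation.  Under a calibrated null
generator the SES variance across datasets is ≈ 1, which is why the
comparative layer treats SES responses with unit weights.

## Hybrid index for dominant binary markers

Each allele column is treated as an independent dominant biallelic marker.
Reference presence-phenotype frequencies `x_k` per species come from "far"
individuals; the Hardy–Weinberg back-transform `a = 1 − sqrt(1 − x)` gives
allele frequencies, clamped to `[1/(2n+2), 1 − 1/(2n+2)]` so that
likelihoods remain finite (the clamp vanishes as reference panels grow).
At hybrid index h the mixed allele frequency is `a(h) = h·a1 + (1−h)·a2`
and `P(presence) = 1 − (1 − a(h))²`.  The log-likelihood is summed over
allele columns; alleles absent from both reference panels are ignored.
Marker independence is knowingly false — alleles at one locus compete —
but mirrors exactly the binary coding of the data; the simulation
experiment below is the guard that this bias is immaterial at the
population level.  ĥ maximizes the likelihood on [0, 1] (201-point grid
with bounded refinement); the support interval is the set of h within 2
log-likelihood units of the maximum.  A flat likelihood returns h = 0.5,
interval [0, 1], and a flag.

## Geographic clines

Population mean ancestry along a transect is modeled with the tanh cline
`p(x) = pmin + (pmax − pmin)(1 + tanh(2(x − c)/w))/2`; width w is the
inverse maximum slope.  Three models ("none": ends fixed at 0/1; "fixed":
equal end admixture e; "free": separate pmin, pmax) plus a flat null are
compared by AIC; when the null wins, the transect is excluded from cline
comparisons.  The likelihood treats a population of n diploids as 2n
effective ancestry draws (quasi-binomial on the mean).  This was chosen
over a Gaussian on means with empirical variances after the latter proved
biased: monomorphic tail populations have zero sample variance, and any
variance floor hands them extreme weight, shrinking the estimated width by
~20% on simulated transects.  The Gaussian option (variance `sd²/n`
floored at 1e-4) remains available.  Optimization is multi-start bounded
L-BFGS-B (centers seeded at position quantiles and the 0.5-crossing;
widths at 2–30% of the span) because cline likelihoods are multimodal.
Decreasing transects are detected by the sign of the position–ancestry
correlation and fitted on the mirrored axis.  Support intervals are
profile likelihoods at a 2-unit drop, expanded by bracketing plus Brent
root-finding.

Cross-zone contrasts: Hedges-g-style standardized width difference, with
standard deviations recovered from the 2-log-likelihood intervals read as
95% CIs (`sd = (hi − lo)/(2·1.96)`); no small-sample correction is applied
since each "group" is one estimate.  The CI of g comes from a parametric
bootstrap (10,000 seeded draws of the two estimates from their Gaussian
sampling distributions, pooled sd fixed) rather than a delta
approximation.  The center shift is signed positive toward the less
MHC-diverse species, given the configured orientation of the transect.

## Genomic clines

Barton's concordance curve `pMHC = p̄ + 2p̄q̄(α + (p̄ − q̄)β)`, `q̄ = 1 − p̄`,
is anchored at (0,0) and (1,1); individuals with p̄ at exactly 0 or 1
carry no information and are excluded (a 3%/97% admixture window applied
symmetrically is the configurable default).  α and β are estimated by
maximum likelihood with Gaussian residuals and profiled-out ML variance —
the minimal error model for a continuous hybrid-index response; a
beta-distributed alternative was considered out of scope.  Curve values
are clamped to [0, 1] during evaluation and parameters boxed at |α|, |β| ≤ 2
(beyond which the quadratic folds severely).  Support intervals are
2-unit profile likelihoods.  α is reported oriented so that positive
values mean excess ancestry from the more MHC-diverse species; species
relabeling maps (α, β) → (−α, β), so β needs no orientation.

## Forward simulation and the binary-coding experiment

The simulator is an individual-based Wright–Fisher model: N diploids
(default 500), an MHC block of 5 completely linked loci, each under the
infinite-alleles model (per-locus mutation rate μ = θ/4N, default θ = 0.6,
every mutation a brand-new identifier) and negative frequency-dependent
selection with per-allele fitness `w = 1 + s/2 − f·s` (default s = 0.5;
range [1 − s/2, 1 + s/2]).  Allele frequencies f are computed per locus in
the parental generation.  Individual fitness is the arithmetic mean of its
2·n_loci allele-copy fitnesses — the mean keeps individual fitness inside
the printed per-allele range and preserves its interpretability; a
multiplicative alternative would change only the selection intensity
scale.  Parents are drawn proportionally to fitness; each transmits one
intact haplotype (no recombination); mutation follows transmission.  The
ancestral population (size N) burns in for 20N generations from a
monomorphic start, then splits into two independent size-N copies
("species") evolved in isolation, with snapshots at 0.5N, 1N and 4N
generations.  The same θ applies throughout burn-in and divergence.

The transect builder does not simulate cline formation.  It samples
haplotypes from the two parental pools against a fixed sigmoid
expected-admixture curve (fixed-ends cline, center 100 km, width 6 km on a
200-km transect): 15 populations across the 6-km core, 10 along each
97-km tail, 10 individuals each, every haplotype drawn from species B with
the cline probability at its population's position, true origin recorded.
Reference panels are 30 individuals per pure species.

The experiment estimates the cline width per replicate three ways: known
ancestry (fitting the generating fixed-ends model), hybrid index from full
per-locus genotypes, and hybrid index from binary-coded matrices (both
fitted with AIC model selection, since hybrid-index estimates carry a
noise floor at the transect ends that the tail parameters absorb —
exactly as in the empirical analyses).  Default 20 replicates at the 1N
time point.  Agreement of the three mean widths, and of the paired
per-replicate differences, is the evidence that binary coding does not
distort cline estimation.

A separate parametric generator calibrates the sharing test: each
species' allele pool has a shared and a private half, and every allele an
individual carries comes from the shared pool with its category's sharing
probability.  Equal near/far sharing makes individuals exchangeable
within species, so the permutation null holds exactly; the default null
conditions are 20 individuals per species per category, 30-allele pools,
6 alleles per individual.

What the generators do not emulate: real MHC data have two linked gene
classes, copy-number variation among individuals, genotyping dropout, and
spatially autocorrelated sampling; the transect sampler has no migration,
drift, or ongoing selection across the zone.  Passing tests therefore
show the estimators are correct under their stated models, not that those
models capture every feature of empirical hybrid zones.

## Comparative synthesis

Units are hybridizing species pairs.  The pair-correlation matrix comes
from a time-calibrated tree: each pair maps to its MRCA node, the
path-length distance d between two nodes is normalized by the maximum
tip-to-tip cophenetic distance, and `corr = 1 − d/d_max` (so coincident
ancestors give correlation 1).  This transform is an interpretation — a
normalized distance admits several mappings — and is not guaranteed
positive semidefinite; negative eigenvalues are clipped to zero and the
diagonal renormalized, with a flag.  Pagel's λ scales off-diagonals and is
estimated by profile ML on a 101-point grid with bounded local refinement.
Observations of the two MHC classes are assumed phylogenetically
uncorrelated (block-diagonal correlation).  Estimation variances (from
2-log-likelihood intervals) enter as inverse-variance weights, except for
SES responses (variance ≈ 1 by construction, unit weights).  Replicate
transects of one species pair are pre-averaged (means of estimates and of
variances).  Models with and without the MHC-class × divergence-time
interaction are compared by likelihood-ratio χ² with df equal to the
parameter difference.  With few pairs, λ is weakly identified and its ML
estimate frequently hits a boundary; coefficients remain unbiased.

## Numerical notes and problem sizes

Degenerate inputs: all-zero allele columns are dropped on load; zero
permutation sd flags the SES undefined; a flat hybrid-index likelihood is
flagged rather than producing an arbitrary estimate; GLS ML variance is
floored at 1e-10 so near-perfect fits cannot destabilize λ profiling or
LRTs (statistics within optimizer tolerance of zero are clipped).

Default study sizes used by the shipped analyses and checks: 20 forward
simulation replicates at N = 500 for the binary-coding experiment; 500
null datasets × 1,000 permutations for SES calibration; 100 replicates for
support-interval coverage; 10,000 bootstrap draws for Hedges g CIs.  All
stochastic components take explicit seeds and are bit-reproducible.
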