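# hzmhc

Tests of adaptive MHC introgression across hybrid zones.

Balancing selection through rare-allele advantage should make major
histocompatibility complex (MHC) alleles unusually prone to crossing
species barriers: an allele new to a recipient species is rare, hence
advantageous, and can establish even against a strong genomic barrier.
`hzmhc` is a toolkit for population geneticists testing this prediction
from the data MHC amplicon studies actually produce — binary
presence/absence allele matrices (individuals × alleles, no locus
assignment, no copy number) plus genome-wide admixture Q-scores — across
one or many hybrid zones.

It implements three complementary zone-level tests and a cross-zone
synthesis:

- **Allele sharing** — is interspecific MHC allele sharing elevated
  "near" the contact (but outside the hybrid zone itself) relative to
  "far"?  Jaccard sharing of pooled allele sets, a within-species
  permutation test (n labels shuffled between categories), and the
  standardized effect size SES = (obs − mean(null)) / sd(null).
- **Geographic clines** — ML fits of the tanh cline
  p(x) = pmin + (pmax − pmin)(1 + tanh(2(x − c)/w))/2 to population means
  of genome-wide admixture and of the MHC hybrid index, with AIC model
  selection ("none" / "fixed" / "free" / flat null), 2-log-likelihood
  support intervals, Hedges-g width contrasts, and the center shift
  signed toward the less MHC-diverse species.
- **Genomic clines** — Barton's concordance curve
  pMHC = p̄ + 2p̄q̄(α + (p̄ − q̄)β) fitted to admixed individuals; α
  measures cline shift (excess ancestry from the more MHC-diverse
  species), β < 0 a slower MHC transition, i.e. excess MHC admixture.
- **Comparative synthesis** — phylogenetic GLS over species pairs, with a
  pair-correlation matrix derived from MRCA distances on a
  time-calibrated tree, Pagel's λ, inverse-variance weights, and LRTs for
  the MHC-class × divergence-time interaction.

The MHC hybrid index comes from an ML estimator for dominant binary
markers (Hardy–Weinberg back-transform of reference presence frequencies,
mixed frequency linear in h).  Because treating alleles as independent
dominant loci is an approximation, the package ships a forward simulator
— Wright–Fisher diploids, five fully linked infinite-alleles loci under
negative frequency-dependent selection (allele fitness w = 1 + s/2 − fs)
— that rebuilds the whole inference chain on transects with known
ancestry and shows that binary coding does not distort estimated cline
widths.

## Worked example

```python
import numpy as np, pandas as pd
from hzmhc import (generate_parametric_zone, near_far_test,
                   fit_geographic_cline, barton_curve, fit_genomic_cline)
from hzmhc.simulate import transect_positions, fixed_ends_cline

# 1. allele sharing: a zone with elevated sharing near the contact
matrix, records = generate_parametric_zone(sharing_near=0.6, sharing_far=0.2, seed=7)
res = near_far_test(matrix, records, n_perm=1000, seed=7)
print(f"sharing near = {res.sharing_near:.3f}, far = {res.sharing_far:.3f}")
print(f"SES = {res.ses:.2f}, p = {res.p_value:.4g}")

# 2. geographic cline from noisy population mean ancestry
rng = np.random.default_rng(7)
x = transect_positions()
mean = rng.binomial(20, fixed_ends_cline(x, 100, 6)) / 20
fit = fit_geographic_cline(pd.DataFrame({"x": x, "mean": mean, "n": 10, "sd": 0.0}), "none")
print(f"width = {fit.width:.2f} km", tuple(round(v, 2) for v in fit.support_intervals["width"]))

# 3. genomic cline with excess MHC admixture (beta < 0)
p = rng.uniform(0.05, 0.95, 120)
y = np.clip(barton_curve(p, 0.4, -0.6) + rng.normal(0, 0.06, 120), 0, 1)
g = fit_genomic_cline(np.column_stack([p, y]))
print(f"alpha = {g.alpha:.3f}, beta = {g.beta:.3f}")
```

prints

```
sharing near = 0.349, far = 0.289
SES = 2.22, p = 0.01798
width = 7.40 km (5.74, 10.06)
alpha = 0.378, beta = -0.590
```

The SES of 2.2 with p ≈ 0.02 detects the constructed near-excess of
interspecific sharing; the fitted width's support interval (5.7–10.1 km)
covers the generating 6 km; and the recovered (α, β) ≈ (0.38, −0.59)
match the curve the data were drawn from, the negative β meaning MHC
ancestry transitions more slowly than the genome-wide average — the
genomic signature of MHC introgression.

A command-line interface mirrors the stages (`hzmhc simulate`,
`hzmhc hybrid-index`, `hzmhc allele-sharing`, `hzmhc geo-clines`,
`hzmhc genomic-clines`, `hzmhc run-all --config zones.yaml --out out/`).

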