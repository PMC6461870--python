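# sporetrade

Comparative reproductive ecology of arbuscular mycorrhizal (AM) fungi:
offspring (spore) size, spore output, and body-size allometry on a species
phylogeny.

AM fungi (Glomeromycotina) reproduce through unusually large asexual spores,
yet their reproductive ecology has rarely been analyzed with the models
routinely applied to plants or animals. `sporetrade` provides a tested
pipeline for three questions about the spore-size trait:

1. **How big are AM spores, and how variable?** Taxonomic descriptions give
   spore diameter *ranges*; the package converts them to volumes (sphere for
   "globose" spores, prolate spheroid for "sub-globose", with the short axis
   duplicated) and to dry biomass at 3.64 × 10⁻⁷ µg/µm³, and compares size
   distributions across taxa (quantiles, log₁₀ span, geometric-mean fold
   differences).
2. **Is spore size phylogenetically conserved?** Pagel's λ — a multiplier on
   the off-diagonal of the Brownian-motion tip covariance (λ = 0: no signal;
   λ = 1: pure Brownian motion) — is estimated by profile likelihood on a
   rooted tree, with a boundary-corrected likelihood-ratio test, plus
   Felsenstein's independent contrasts for phylogenetically robust
   correlations.
3. **Do size and number trade off?** Under a Smith–Fretwell budget
   *R = A / W₀ᵇ* (spore output *R*, reproductive budget *A*, spore size
   *W₀*), log *R* is linear in log *W₀* with slope −*b*; *b* = 1 means exact
   inverse proportionality. Slopes are fitted by standardized major axis
   (SMA) regression — appropriate when both axes carry error — with 95% CIs
   and tests against the slope −1, across three body-size corrections
   (uncorrected, per meter of extraradical hyphae, per unit mycelium mass),
   and body-size scaling *R·W₀ = σ·W_α^β* is fitted the same way.

A seeded synthetic-data module generates trees (Yule), λ-Brownian traits,
and full allocation experiments (default design: 14 fungal species × 4
plant hosts × 5 replicates) with known ground truth, so every stage is
testable without any downloads.

## Worked example

Simulate a study with known truth (λ = 0.7, b = 1, 30% replicate noise) and
run the full analysis:

```bash
sporetrade simulate --seed 42 --lambda-true 0.7 --b-true 1.0 \
    --noise-cv 0.3 --out-dir bundle
sporetrade run-all --traits bundle/spore_traits.csv \
    --colonization bundle/colonization.csv \
    --tree bundle/tree.newick --out-dir reports
```

Reading the reports back:

```
slope a: -1.177  CI (-1.339, -1.035)  p_corr 3.22e-19  p_vs_-1 0.014
lambda (glomoid): 0.922  p 0.0001
beta_hat: 1.463
```

The uncorrected SMA trade-off slope is −1.18: spore output falls slightly
faster than inverse proportionality with spore mass in this noisy draw (the
test vs −1 is marginal at p = 0.014; SMA slopes are pushed away from −1 by
replicate noise, which inflates the spread of log *R*). The λ estimate of
0.92 recovers strong phylogenetic signal in log spore volume (mixture-LRT
p = 10⁻⁴), and spore production scales positively with mycelium mass
(β̂ ≈ 1.5). Reports land as CSV/JSON files (`spore_sizes.csv`,
`taxa_comparison.csv`, `lambda_report.json`, `allocation.csv`,
`tradeoff_report.json`, `scaling_report.json`, `run_log.json`).

Each stage is also a plain library call (`parse_trait_table`,
`build_allocation_table`, `fit_pagel_lambda`, `tradeoff_analysis`, ...);
see `docs/methods.md` for the model details and design choices.

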