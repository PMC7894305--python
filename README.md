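# sfsflow

Demographic inference for a pair of diverging populations from the
unfolded joint site-frequency spectrum (SFS), built for the question
that recurs in depth-segregated marine ecotypes: did the two forms
diverge with continuous gene flow, in strict isolation, or through
transient isolation followed by secondary contact — and how much of the
genome sits in "islands" of restricted exchange?

The package takes a multi-sample genotype VCF plus an outgroup allele
per site, applies a conservative SNP filter chain (depth, quality,
missingness, allele balance, an exact Hardy–Weinberg test, indel
proximity, 1-per-kb thinning), polarizes sites against the outgroup,
projects them into an unfolded joint SFS by hypergeometric
downsampling, and fits a catalog of **107 two-population models** — up
to three epochs, per-epoch symmetric/asymmetric migration, optional
ancestral size change, and a genomic-island locus class with fraction
`P` per epoch and migration scaled by a factor `b`. Models are ranked
by AIC: delta-AIC, Akaike weights, and evidence ratios (safe to 1e300
and beyond in log space). Uncertainty comes from a SNP-resampling
bootstrap, and fitted parameters are scaled to individuals and years.

## The model and likelihood in brief

Time is measured in units of `2·N_ref` generations and migration as
`M = 2·N_ref·m`. The expected spectrum per unit `θ = 4·N_ref·μ·L` is
computed by integrating the closed moment ODE of the two-population
Wright–Fisher diffusion at the sample sizes: tridiagonal drift
operators per population, migration terms closed by a
projection-consistent jackknife, and an infinite-sites mutation influx
(equilibrium `ξ_i = θ/i`). Cells of the observed spectrum are treated
as independent Poisson counts with mean `θ·model`; `θ̂ = Σdata/Σmodel`
is analytic, and the remaining parameters are optimized by multi-start
Nelder–Mead on log scale. `N_ref = θ̂/(4μL)` then converts epochs to
years (`2·N_ref·T·gen_time`) and sizes to individuals. Defaults
`μ = 1.02×10⁻⁹` per site per generation and a 5-year generation time
follow the octocoral literature. Details: [docs/methods.md](docs/methods.md).

## Worked example

The `analysis/` drivers run a complete scaled-down study on synthetic
data: a three-epoch secondary-contact history (symmetric flow →
isolation → asymmetric recontact with growing islands) simulated for
27 + 32 diploids ("Deep", "Shallow") on 500 short scaffolds.

```bash
python analysis/01_simulate_dataset.py   # coalescent VCF + outgroup alleles
python analysis/02_filter_and_polarize.py
python analysis/03_build_sfs.py
python analysis/04_fit_models.py         # fits 6 competing model families
python analysis/05_select_and_scale.py   # AIC table, bootstrap, years/individuals
```

Output from steps 01–03 (seed 20201120):

```
wrote 11288 candidate SNPs on 500 scaffolds (125 island-class)
filter chain: 11288 SNP records in, 9346 retained (drops: {'indel_proximity': 0,
  'biallelic_snp': 0, 'min_qual': 12, 'max_missing': 1911, 'allele_balance': 18,
  'hwe': 1}), 8862 polarized, 1463 after 1-per-kb thinning
joint SFS mass 599 SNPs at projection (16, 20); pi(Deep) = 0.000363,
  pi(Shallow) = 0.000375
```

Reading: most losses come from the ≥90%-per-population call-rate rule;
per-base diversity π ≈ 3.7×10⁻⁴ matches the simulated 4·N_ref·μ
scale; projection to (16, 20) alleles absorbs the remaining missing
genotypes. Step 05 prints the selection table and the best model in
natural units:

```
    model  log_likelihood  k     AIC  delta_AIC   weight  log10_evidence_ratio
     e1ma        -263.30   5  536.60       0.00  8.2e-01                  0.00
    e2m0a        -261.89   8  539.78       3.18  1.7e-01                  0.69
   e2m0ai        -261.91  11  545.81       9.21  8.2e-03                  2.00
     e1ms        -269.54   4  547.09      10.48  4.3e-03                  2.28
sc3ielsm1        -262.18  16  556.36      19.76  4.2e-05                  4.29
     e1m0        -283.66   3  573.32      36.72  8.7e-09                  7.97

best model e1ma: N_ref = 13,862 individuals
  epoch 1:    136.0 ->      0.0 Kya   N = (12,323, 17,851)
```

Reading: with only ~600 projected SNPs the data reject strict
isolation decisively (ΔAIC ≈ 37, evidence ratio ~10⁸) and recover the
asymmetry of recent exchange (bootstrap means m12 ≈ 0.42 into Deep vs
m21 ≈ 0.09 — the simulated truth flows Shallow→Deep), but the
parsimony penalty leaves continuous asymmetric migration on top: the
full three-epoch island history that generated the data is not
resolvable at this SNP count. That is the expected power behaviour —
the test suite shows island fractions and secondary contact become
identifiable at ~15,000 SNPs and 20+ alleles per population.

The same stages are available as a CLI for real data
(`sfsflow filter | build-sfs | fit | select | bootstrap | simulate |
report`), with every run emitting its resolved configuration and seed
alongside the outputs.

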