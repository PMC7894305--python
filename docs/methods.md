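# Methods

`sfsflow` infers the divergence history of two populations — sizes,
split time, per-epoch gene flow and its asymmetry, and a class of
genomic loci with restricted exchange — from the unfolded joint
site-frequency spectrum (SFS) of SNPs called against an outgroup.
This note records the model, the numerics, and the choices made where
the design was genuinely open.

## The demographic model space

A model is an ancestral population at mutation-drift equilibrium
(optionally passing through a pre-split size change `nu_A` for a time
`T_A`), a split, and one to three *epochs*, each with constant relative
sizes `nu1, nu2`, duration `T`, and migration that is absent, symmetric
(`m`), or asymmetric (`m12`, `m21`). Time is in units of `2·N_ref`
generations; migration rates are `2·N_ref·m` with `m` the per-generation
fraction of the recipient population replaced. Models may add a
*genomic island* locus class: a fraction `P_e` of loci (free per epoch)
whose migration rates are multiplied by a single factor `b ∈ [0, 1]`.
Islands are a migration mixture only — no selection term. The island
class is given one shared factor `b` rather than its own free rates:
this keeps the class interpretable as "the same history with reduced
exchange" and adds one parameter instead of up to six.

The shipped catalog holds exactly 107 models: a systematic grammar
(`[a]e<K>m<modes>[i]` — ancestral size change; 1–3 epochs; per-epoch
migration mode `0/s/a`; island class, which requires migration in at
least one epoch; the no-migration single-epoch ancestral-change variant
is excluded) plus eleven named exemplars from the literature on
depth-segregated coral ecotypes (`sc3ielsm1`, `iMi`, `IMisc`, …), whose
epoch structures follow their published descriptions. Two of the named
ids (`sc3ielsm1`, `sc3imilm1`) are alternative published names for the
same three-epoch structure and are both kept.

Free-parameter counts `k` (for AIC) are audited automatically: 3 per
epoch (T, nu1, nu2) + 0/1/2 per epoch by migration mode + (#epochs + 1)
for islands + 2 for an ancestral size change.

## The expected-SFS engine

The expected unfolded joint SFS per unit `theta = 4·N_ref·mu·L` is
computed from the closed moment system of the two-population
Wright–Fisher diffusion evaluated directly at the sample sizes — the
moment-ODE approach to SFS computation:

* **Drift** contributes, per population, the tridiagonal operator
  `(D phi)_i = ½[(i−1)(n−i+1) phi_{i−1} − 2i(n−i) phi_i +
  (i+1)(n−i−1) phi_{i+1}]` scaled by `1/nu`; it closes at the sample
  order. Its equilibrium with the infinite-sites influx (`n/2` per unit
  theta into the single-copy class of each population) is exactly
  `theta/i`, which anchors the closed-form checks.
* **Migration** couples the two indices and requires the spectrum at
  one extra sample in the source population. The exact coefficients
  follow from Bernstein-polynomial degree raising; the order-(n+1)
  spectrum is estimated by a jackknife that is exact for locally
  quadratic allele-frequency densities and is then **projected onto the
  manifold of extensions consistent with exact hypergeometric downward
  projection** (the extension is determined by consistency up to a
  single degree of freedom). This correction is the engine's key
  numerical ingredient: on the `1/x`-singular SFS density the plain
  quadratic fit errs by tens of percent at the boundary entries, while
  the consistency-corrected closure is accurate to ~1e-3 and handles
  the point masses of fixed differences that accumulate on the spectrum
  boundary.
* **Ancestral state**: the 1-D equilibrium at `n1+n2` alleles,
  optionally integrated through the ancestral size change, is split
  hypergeometrically into the joint spectrum.
* **Islands** use a mixture applied at epoch boundaries: the state at
  an epoch's end is `(1−P_e)·[state evolved at m] + P_e·[state evolved
  at b·m]`, both branches from the mixed state at the epoch's start.
  For single-epoch models this coincides exactly with a fixed
  locus-class mixture, which is how the coalescent cross-check
  simulates it. With `P = 0` or `b = 1` the mixture reduces exactly to
  the plain model (regression-tested identities).

The system is integrated at an internal order `n + buffer` (default
buffer 5) and projected down exactly: the true moment hierarchy is
sampling-consistent, so closure error enters only at the top order,
where the jackknife is most accurate.

Two integration schemes are provided:

* `scheme="cn"`: Crank–Nicolson on the full operator with a prefactored
  LU. A-stable and free of splitting error; used for high-accuracy
  comparisons (closed forms, coalescent oracle).
* `scheme="split"` (default): Strang splitting — implicit tridiagonal
  Crank–Nicolson half-steps for each population's drift (the two drift
  operators commute, so their ordering is exact), with migration +
  mutation influx advanced by explicit midpoint (RK2) steps between
  them, subcycled to stay within the explicit method's stability region
  (the subcycle count comes from power-iteration estimates of the
  migration operators' spectral radii). The kernel is numba-compiled.
  The drift–migration splitting error grows as `m·dt²`, so the step is
  `dt_fac · min(nu1, nu2, 1) / (1 + m12 + m21)`; at the default
  `dt_fac = 0.02` the two schemes agree to a few parts in 1e3
  entrywise, and to ~1–2% at the loosened `dt_fac = 0.06` used inside
  optimization loops, where Poisson sampling noise dominates.

Engine accuracy is validated against an independent oracle: branch-mode
allele-frequency spectra averaged over msprime coalescent replicates of
the same demography, entrywise within 3 Monte-Carlo standard errors
(60,000 replicates per draw in the shipped suite) for draws spanning
strict isolation, IM, secondary contact and island models. Negative
entries beyond `neg_tol` (relative, default 1e-2) raise; smaller
round-off is clipped to zero. Likelihood model entries are floored at
1e-300 before logs.

## Filtering

The VCF chain applies, in a fixed logged order: indel-proximity removal
(reference footprint ± 30 bp), biallelic SNPs only, per-genotype depth
masking (DP < 5 → missing), site quality (QUAL ≥ 30), per-population
missingness (≥ 90% genotypes present — the vcftools `--max-missing`
convention, i.e. the threshold is the *present* fraction), pooled
heterozygote allele balance (each allele ≥ 20% of het reads, the vcflib
convention), and a per-population exact Hardy–Weinberg test
(two-sided, sum of heterozygote configurations no more probable than
observed, no mid-p; exclusion at p < 0.001). Under-sequenced
individuals (< 50% of sites called) are removed first. Where the
standard tools leave a choice open, the report logs the one taken:
depth is applied per-genotype (vcftools `--minDP` semantics) and the
HWE test is exact rather than chi-square. Polarization uses a per-site outgroup allele
(TSV or `AA` INFO tag); sites whose outgroup allele is missing or
matches neither REF nor ALT are dropped and counted. Thinning keeps the
first SNP per 1,000 bp per scaffold (greedy, position order —
deterministic).

Missing data are then absorbed by hypergeometric projection
(easySFS-style expected contributions, not random subsampling): a site
with `c` called and `d` derived alleles contributes the expected
spectrum of an `n_target`-allele subsample; sites with `c < n_target`
are dropped. Projection necessarily moves some mass of rare variants
into the masked `(0,0)` cell (a subsample can miss every derived copy);
that mass is excluded from all statistics, as are both monomorphic
corners.

## Likelihood, optimization, ranking, uncertainty, scaling

Cells of the observed spectrum are independent Poisson counts with mean
`theta·model`; `theta_hat = Σdata/Σmodel` over unmasked cells is the
analytic maximizer, so the optimizer works on shape parameters only
(a multinomial alternative was considered and not implemented; the
Poisson form is the standard composite likelihood of this framework).
Fitting is multi-start Nelder–Mead on log parameters (default 10
starts) with starts drawn log-uniformly within ×3 of a typical-scale
init (`nu = 1, T = 0.3, m = 1, P = 0.1, b = 0.1`) or a user-supplied
vector; the best start is polished by up to two fresh Nelder–Mead
restarts (a restarted simplex escapes degenerate simplices). Bounds are
enforced by clipping plus a quadratic log-distance penalty; `T` and
migration may be exactly 0 in bound values (isolation epochs), with a
small positive floor (1e-3; 1e-4 for P and b) substituted inside the
log-space optimizer. Everything is reproducible from the seed.

Ranking follows the information-theoretic workflow: AIC = 2k − 2LL,
delta-AIC, relative likelihood `exp(−Δ/2)`, Akaike weights, and the
evidence ratio of the best model against each alternative, computed in
log space so ratios of order 1e300 are finite in `log10_evidence_ratio`
(the linear column overflows to `inf` beyond 1e300 by design). Plain
AIC is used, not AICc.

Uncertainty is a nonparametric bootstrap over SNPs: site-table rows are
resampled with replacement to the original count, the spectrum rebuilt,
and the model refit (default 5 replicates, per-parameter mean and SD).
A single optimizer seed is shared across replicates so identical
resamples yield identical fits and the SD reflects data variation only.

Fitted parameters convert to natural units via
`N_ref = theta_hat / (4·mu·L)`; an epoch of duration `T` spans
`2·N_ref·T·gen_time` years, stacked backward from the present;
migration is reported both as fraction replaced per generation
(`M/(2·N_ref)`) and migrants per generation; island fractions as
percentages. The effective sequence length `L` is a required user
input — it cannot be recovered from a SNP-only spectrum. Defaults
`mu = 1.02e-9` and `gen_time = 5` years are the octocoral
transcriptome rate and the growth-rate-based generation time used in
this literature.

## Synthetic data

`simulate_sfs` draws Poisson counts around `theta·expected` (engine
self-consistency; used by recovery and selection-power tests).
`simulate_vcf` is an independent route: msprime coalescent genotypes
for the two populations plus one outgroup diploid, under the same
epoch structure translated to a backward-time demography (the
forward-migration convention was validated against the engine —
swapping directions produces ~160 MC-SE disagreements, the correct
orientation agrees within noise). It writes standard VCF 4.2 with
GT:DP:AD fields (negative-binomial depth, binomial allele split for
heterozygotes), gamma-distributed site qualities, injected missingness,
REF/ALT randomly swapped relative to ancestral/derived (so polarization
is exercised both ways), and the outgroup allele in the `AA` INFO tag.
The outgroup splits 8·2·N_ref generations before the root by default,
deep enough that ingroup polymorphism is never shared; a polarization
error knob exists and defaults to 0. Island models are simulated as two
fixed locus classes with the island fraction taken from the newest
epoch.

What the generator does *not* emulate: linkage within loci beyond
complete linkage of a scaffold's SNPs, reference/mapping bias,
genotype-calling error models beyond depth dropout, paralogy, or
selection. Passing tests therefore validate the statistical machinery
(filter arithmetic, spectrum construction, likelihood, model
selection), not robustness to those artifacts in real data.

`fixture_vcf` is a hand-designed 10-SNP VCF (24 diploids, two
populations) in which each record violates exactly one filter rule —
including a homozygote-excess site whose exact HWE p-value (~3.4e-4)
sits below the 1e-3 threshold while remaining attainable at 12
diploids — with a manifest of expected per-rule drops used to pin the
chain.

## Validation problem sizes

The shipped suite runs on one CPU in tens of minutes; sizes were chosen
as the smallest with clear statistical resolution, and are the
package's laptop-scale validation conditions:

* coalescent oracle: five family-spanning draws at 6×6 alleles, 60,000
  branch-mode replicates each, entrywise |z| < 3;
* parameter recovery: divergence-with-asymmetric-flow island model
  (`e1mai`, truth T = 0.4, m12 = 2.0, m21 = 0.5, P = 0.3, b = 0.05),
  ~15,000-SNP Poisson spectra at 20×20 alleles, 10 seeds × 10 starts
  (perturb-and-refit inits), median split time and migration rates
  within 15%, island fraction within 0.05;
* model-selection power: secondary-contact data (isolation 0.8, brief
  strong recontact) at 10×10 alleles and ~20,000 SNPs; SC outranks
  strict isolation and IM in ≥ 8/10 seeded runs (observed margins are
  hundreds of AIC units);
* the analysis drivers and acceptance script run a full synthetic twin
  (27 + 32 diploids, hundreds of 2–3 kb scaffolds, `N_ref = 10^4`,
  locus mutation rates scaled up so desk-scale scaffold counts carry
  enough SNPs) projected to 14–20 alleles per population.

## Known limitations

* Two populations only; no linkage-aware likelihood (composite Poisson
  over cells); no selection; islands are a migration class, not linked
  sweeps.
* The island mixture is applied at epoch boundaries; for multi-epoch
  island models this is an explicit modelling convention (documented
  above), not the unique possible reading, though it reduces to the
  exact locus-class mixture for single-epoch models.
* `P` and `b` are weakly identified at small sample sizes: at 16×16
  alleles and 15k SNPs the maximum-likelihood island fraction scatters
  by ±0.07 across data realizations; 20×20 or larger is needed for the
  tolerances above. Real-data island fractions should be read with
  bootstrap intervals, not as point values.
* The split-scheme spectra differ from the unsplit Crank–Nicolson
  reference by up to ~1–2% on the smallest cells at the loosened
  optimizer settings; final reported fits should use (and the analysis
  drivers do use) tighter `dt_fac` or the `cn` scheme when in doubt.
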