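# Methods

`selfkit` implements the computational core of a population-genomic
analysis of a predominantly selfing plant that has invaded a new range as
several genetically distinct lineages: how to estimate how selfing each
population is, how the lineages are structured and admixed, and whether
admixed individuals descend from recent or historical hybridization.

## The mixed-mating model and identity disequilibrium

All selfing machinery rests on one latent-variable model. Under mixed
mating with selfing rate `s`, an individual's number of consecutive
selfing generations in its ancestry, `G`, is geometric at equilibrium:

    P(G = g) = (1 - s) s^g,  g = 0, 1, 2, ...

An individual with depth `G` is heterozygous at a locus with probability
`H_E * (1/2)^G`: each selfing generation halves heterozygosity. Averaging
over `G` gives the classical inbreeding coefficient

    F_IS = s / (2 - s),

but the *variance* of `G` across individuals does something more useful:
it makes heterozygosity covary across loci *within* individuals. The
standardized two-locus statistic

    g2 = E[h_l h_m] / (E[h_l] E[h_m]) - 1   (l != m)

equals, under the geometric model,

    g2(s) = s / ((1 - s)(4 - s)),

which is zero under random mating regardless of the base heterozygosity,
and — unlike `F_IS` — does not require knowing `H_E`. The estimator
(`selfing.multilocus_g2`) evaluates the ratio of within-individual to
between-individual cross-locus co-heterozygosity in closed form from the
heterozygosity-indicator row sums, column sums, and total, and
`g2_to_selfing` inverts `g2(s)` through its quadratic. Negative `g2`
estimates map to `s = 0` with a flag; a zero denominator (no
between-individual co-heterozygosity, e.g. fewer than two individuals with
any heterozygous locus) is reported as undefined, never coerced.

The simulator (`simulate.simulate_mixed_mating_population`) draws `G` once
per individual — shared across loci, which is precisely what creates
identity disequilibrium — then samples one allele from the population
frequency and copies it (identical by descent) with probability
`1 - (1/2)^G`. A locus-independent variant that redraws `G` per locus is
provided purely as a test fixture: it has the same heterozygote deficit
but `g2 = 0`, and the suite uses it to confirm the estimator reads
cross-locus structure rather than the deficit. `G` is capped at 50
(residual heterozygosity `2^-50` is far below measurability), which also
keeps `s = 1` finite (with a warning).

### Inference details

- **Permutation test.** The null of no identity disequilibrium is built by
  permuting each locus's heterozygosity column independently across
  individuals, preserving per-locus heterozygote counts while destroying
  cross-locus association; the one-sided p-value uses the finite-sample
  convention `(1 + exceedances) / (1 + n_perm)` and can never be 0.
- **Bootstrap SD.** The SD of `s_hat` resamples *individuals*, not loci.
  We measured both: at `s = 0.905, n = 18, L = 1000` the replicate SD of
  `s_hat` is ~0.033 while a locus bootstrap reports ~0.003, because the
  dominant noise is the finite draw of `G` across individuals, which locus
  resampling holds fixed. The individual bootstrap reproduces the replicate
  SD. To avoid spread compression from the pile-up of bootstrap draws at
  `s = 0`, the SD is computed on a signed extension of the `g2 -> s` map
  (`sign(g2) * s(|g2|)`, smooth through 0 since `s ~ 4 g2` near 0).
- **Missing data.** Loci with more than 20% missingness within the group
  are dropped, after which missing heterozygosity indicators contribute 0
  to every closed-form sum (complete-case masking). This is a simplification
  relative to RMES's full missing-data weighting; the simulator's
  missingness levels (~6.5%) make the difference negligible here, but
  heavy, non-random missingness would bias `g2` downward.
- **Known limits** (kept deliberately, and visible as red checks in the
  acceptance suite): at `n ~ 9` and low `s`, datasets whose individuals
  happen to draw near-identical `G` show no disequilibrium and produce
  confidently near-zero estimates, so ±2SD intervals cover the truth in
  ~85% rather than 95% of replicates; at near-complete selfing
  (`s = 0.985`, `n = 10`, `L = 1000`) usually fewer than two individuals
  carry any heterozygous locus and the estimate is undefined in roughly
  60% of replicates. Both are identifiability limits of the data sizes,
  not of the implementation; the mean of defined estimates is unbiased at
  all three published-scale scenarios.

## Genotype statistics

- `H_O` per individual is the heterozygous fraction of called loci; group
  `H_E` is Nei's unbiased gene diversity
  `(2 n_l / (2 n_l - 1)) (1 - p^2 - q^2)` per locus (small per-population
  samples, 7-18 individuals, make the small-sample correction matter), and
  `F_IS = 1 - mean(H_O) / mean(H_E)`.
- Kinship is KING-robust:
  `phi = (N_hetHet - 2 N_oppHom) / (N_het,i + N_het,j)` over jointly-called
  loci, computed within populations by default to avoid allele-frequency
  confounding across differentiated populations. Clones give `phi = 0.5`
  by construction of the formula; the pipeline flags `phi > 0.45` as
  duplicate/clone and `phi >= 0.177` as a close relative (standard KING
  bins). Pairs with no heterozygous loci are undefined, never silently 0.
- The folded SFS uses complete-data loci by default; the optional
  hypergeometric projection redistributes each locus's minor-allele count
  to a smaller even allele number, retaining loci with at least that many
  called alleles (counts then real-valued, total mass = loci used).

## Synthetic data: what the generator emulates, and what it does not

The study-scale preset (`simulate.simulate_study("paper_like")`) mirrors
the emulated survey's design: 26 invasive populations in three lineages
(sample sizes 1-18 and per-population selfing rates 0.233-0.940 taken from
the survey's published table), four native populations including one
diverse, mostly outcrossing lineage ("BLUE"), 6,000 unlinked SNPs,
individual missingness Beta-distributed with mean 6.5% and concentration
4.3 (median ~1.6%, matching the survey's right-skewed profile), and
planted hybrids: eight historical F1s (RED x YELLOW, followed by 4-8
selfing generations) plus one recent backcross forming one population, and
eight recent hybrids (F1 and first backcross, RED x BLUE) scattered across
invasive populations. The survey reports no admixture-event rate, so the
planted counts are a fixed, configurable choice.

Lineage allele frequencies follow the Balding-Nichols law around a shared
ancestral pool (star-shaped divergence; ancestral frequencies
Uniform(0.05, 0.95) as in SNP-discovery panels; frequencies clipped at
1e-6). Divergence parameters are 0.45 for the invasive lineages, 0.35 for
the native selfing lineages and 0.08 for the diverse native lineage —
chosen so invasive lineages are strongly drifted and genetically poor
while the native outcrosser retains diversity, the qualitative contrast
the survey reports.

Not emulated: linkage and recombination (loci are exchangeable and
unlinked), mutation, explicit forward demography, within-lineage
population substructure, and the survey's absolute heterozygosity scale
(its `H_O` ~ 0.002-0.1 reflects genome-wide SNP ascertainment; the
synthetic panel is fully polymorphic, so absolute `H_O` is higher while
all *relative* structure — lineage contrasts, selfing decay, hybrid
elevation — is preserved). Passing tests therefore validate estimator
behavior under the model's assumptions, not robustness to real-data
artifacts such as allele dropout or null alleles.

## Ancestry inference

`ancestry.admixture_em` maximizes the standard admixture log-likelihood
(each of an individual's two alleles per locus drawn from K cluster
frequency vectors according to membership fractions `q_ik`) by EM with
seeded restarts: Q rows initialized symmetric-Dirichlet(1), P entries
Uniform(0.05, 0.95), best restart by log-likelihood with ties broken by
index; missing genotypes are skipped with per-individual normalization by
called alleles. This is a deliberate maximum-likelihood substitution for
Bayesian MCMC clustering — same likelihood family, equivalent Q/P outputs,
orders of magnitude cheaper and deterministic given seeds. The likelihood
is non-decreasing along every EM path (asserted in tests). Model choice is
reported, never auto-selected: the Evanno delta-K table
(`mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / SD_r(L_r(K))`) and the
log-likelihood trajectory are both emitted, since the two criteria can
legitimately disagree (on the synthetic study, delta-K picks K = 2 while
the likelihood keeps rising toward the seven simulated lineages — the same
tension the emulated survey reports).

One behavior worth knowing: on data dominated by a large, highly selfing
lineage, the ML admixture model (which assumes within-cluster
Hardy-Weinberg) can prefer splitting that lineage over separating small
diverged ones, because splitting absorbs the homozygote excess. The
hybrid-recency stage therefore never relies on the global K-cluster fit
(below).

The admixture degree of an individual is the population SD (divisor K) of
its Q row: 0 for uniform (maximally admixed) rows, `sqrt(K-1)/K` for pure
rows; the survey does not specify the divisor, so sample SD is available
via the underlying numpy call but population SD is the default. PCA
imputes missing genotypes with the per-locus mean, centers columns without
scaling, and takes the SVD; scores are deterministic up to sign.

## Hybrid classes and recency of admixture

Parental allele pools are per-locus frequencies of individuals with
cluster membership >= 0.999 (>= 3 required per pool). Eight classes are
simulated genealogically per locus: F1 (one allele from each pool), F2
(gametes of two independent F1s), first-generation backcrosses F1xA /
F1xB, and second-generation backcrosses F1AxA, F1AxB, F1BxB, F1BxA. The
survey's figure legend names eight classes while its text says six; all
eight are implemented with a class-subset option. Every simulated
individual gets `H_O` and a supervised ancestry coefficient `q`
(1-D bounded ML under the two-pool binomial likelihood) — the *same*
estimator and pools used for empirical individuals, so classification is
internally consistent.

Post-hybridization selfing (`selfing_decay`) halves `H_O` per generation
in expectation and leaves `q` unchanged, which separates the two
hypotheses on the (q, H_O) plane: a historical hybrid sits far below the
heterozygosity of any recent class with comparable ancestry. The survey
classified by visual comparison; the operationalization here pools all
simulated individuals with `|q_sim - q| <= window` (window doubling from
0.05 until >= 20 matches or 0.5), takes the [2.5, 97.5] percentile
envelope of their `H_O`, and calls the point *recent* at or above the
lower edge, *historical* below it, *unresolved* if matches never suffice.
Whether the survey used a window or nearest-class rule is unstated; the
adaptive window is one defensible choice and every knob is exposed.

In the pipeline, each parental pair is analyzed by a dedicated two-cluster
fit restricted to the pair's populations (plus any populations of
unassigned ancestry), exactly as reference-panel hybrid analyses rerun
their clustering per pair; this sidesteps the global-K instability noted
above. On the study preset this recovers 100% of planted recent and
historical hybrids across five seeds (the acceptance suite requires 90%).

## Divergence times and the pipeline

`pipeline.divergence_time` converts coalescent divergence to years via
`t = generation_time * tau / (2 mu)` with defaults `mu = 7.0e-9` per site
per generation (a plant calibration) and one-year generations.
`run_pipeline` sequences filter -> kinship screen -> diversity -> selfing
(per population, then per cluster of pure individuals) -> K sweep with
Evanno -> per-cluster SFS export -> pair-restricted hybrid recency ->
divergence conversions, all seeded from one config seed; reruns are
byte-identical, and the config hash, package versions and stage notices
are recorded beside the tables. Group comparisons of diversity (rank
tests) are deliberately left to standard statistical libraries.

## Problem sizes used by the test and acceptance suites

Equilibrium laws are checked at n = 200 individuals, L = 2,000 loci with
replicate-based Monte-Carlo SEs; recovery at the three published-scale
scenarios uses L = 1,000 and 100 replicates; the permutation-test
calibration uses 500 replicates of n = 20, L = 500 with 1,000 permutations
(the survey's production analyses used 10,000); the recency check runs the
full 6,000-locus preset over 5 seeds with a 1,000-locus subsample inside
each pair fit. These sizes keep every statistical property measurable with
comfortable margins while the whole suite stays desk-scale.
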