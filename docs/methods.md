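# Methods

This note documents the models, priors, numerical conventions and design
choices behind `mbherit`, and what the synthetic-data experiments do and
do not demonstrate.

## Study design being emulated

The analysis targets pedigreed livestock cohorts: two generations, with
full-sib families produced by pairs of parents and half-sib families by
sires mated to several dams; offspring are randomly grouped into pens of
7–8 animals and sampled in batches.  Hosts are genotyped at genome-wide
SNPs and their gut communities profiled as OTU count tables with
taxonomy and a phylogeny.  Because family structure is what makes
variance components identifiable at a few hundred animals, all
estimation experiments use pedigreed cohorts; heritability estimated
from a few hundred *unrelated* samples is essentially unidentified and
is not a supported use.

## Synthetic cohorts (`simdata`)

- **Pedigree.** `simulate_pedigree` builds founders plus one offspring
  generation.  Litter sizes and the pen protocol are parameters
  (`offspring_per_mating`, `n_pens`); by default pens are filled to 7–8
  animals by random assignment.  Sexes are female or castrated male,
  batches uniform.
- **Genotypes.** Founder dosages are binomial(2, f) with per-SNP
  f ~ U(maf_low, maf_high); offspring receive one Bernoulli(dosage/2)
  allele per parent, so Mendelian consistency holds exactly.  Designated
  QC artifacts are injected: SNPs with no heterozygotes at intermediate
  frequency (an extreme Hardy–Weinberg departure) and all-reference
  monomorphic SNPs; these bypass transmission and are expected to fail
  QC.  Missingness is uniform at `missing_rate`.
- **Traits.** `simulate_traits` draws y = μ₀ + Xβ + u + e on the
  log-abundance scale (μ₀ = −4, i.e. a baseline relative abundance of
  ~1.8%).  The polygenic term is u ~ N(0, K); when causal SNPs are
  present the sparse and polygenic components get equal generative
  variance.  The noise is rescaled so the realized
  var(Xβ+u)/var(y−μ₀) equals `pve_target` *exactly* in every draw — the
  estimand of the downstream heritability fit is therefore the nominal
  target, not a noisy realization of it.  Presence/absence comes from a
  Gaussian liability thresholded at the empirical quantile matching
  `zero_inflation_rate`; optionally one SNP shifts the liability by 0.75
  per alternate allele, giving the logistic GWAS part a planted signal.
- **Ecosystem.** Heritable taxa contribute exp(y)·presence to a
  composition vector; the remaining OTUs are per-sample log-normal noise
  with log-mean U(−6, −2).  Rows are renormalized and counts drawn
  multinomially at a uniform random depth.  Renormalization deliberately
  couples taxa: "null" taxa acquire a small heritable component through
  the shared denominator, exactly as relative-abundance data do in
  practice.  Consequences: at small n (e.g. the 120-animal demo) some
  nominally null taxa exceed the h² > 0.15 call threshold; at n ≈ 300
  the false-call rate is near zero.  What passing tests show is that the
  *estimators* recover generative parameters on data satisfying the
  generative model; they say nothing about sequencing error, copy-number
  variation, or compositional artifacts beyond simple renormalization,
  none of which are simulated.
- The taxonomy nests OTUs into shared genera/families (≈10% left
  unassigned below family) to exercise aggregation; the phylogeny is a
  random bifurcating join with exponential branch lengths.

## Genotype QC (`io_qc`)

Filters are applied per SNP in the fixed order call rate → MAF → HWE so
that the report attributes each failure to exactly one rule.  MAF is
computed on non-missing calls only.  The Hardy–Weinberg test is the
two-sided exact test: all heterozygote counts compatible with the
observed allele counts are enumerated in log space and tables no more
probable than the observed one are summed; a SNP is kept when
P > 5×10⁻⁶.  Missing dosages are mean-imputed per SNP after QC
(fractional dosages are carried in a dedicated container so the
{0,1,2}-domain invariant still guards raw data).

## Relatedness and diversity

Kinship is the centered (unstandardized) relationship matrix
K = (1/p) X̃X̃ᵀ with column-centered X̃ — the covariance-type GRM
convention; the same formula on the samples × OTU relative-abundance
matrix gives the composition kinship (no log transform, matching the
"OTU compositions and relative abundances" the comparison is defined
on).  The Mantel test correlates upper-triangle entries, permutes one
matrix's rows/columns jointly, and reports the add-one two-sided p
(1 + #{|r*| ≥ |r|})/(n_perm + 1); similarities (kinships) are tested
directly rather than converting to distances.

Unweighted UniFrac is unique/total branch length over the union of
present tips; weighted UniFrac is Σ b_ℓ |A_ℓ − B_ℓ| (raw by default;
the normalized variant divides by Σ b_ℓ (A_ℓ + B_ℓ) and is exposed as a
flag, since β-diversity pipelines differ on this point).  Group
comparisons pool within-group pair distances and re-partition them at
random to form the Monte-Carlo null of the two-sample t statistic; ties
|t*| = |t| count as exceedances (conservative).  Pair-level distances
are not independent (each animal appears in many pairs), so these
Monte-Carlo p-values are calibrated against label exchange of pair
values, not of animals — the same convention as the nonparametric
t-tests in standard 16S pipelines, and a known limitation.

## Heritability (`heritability`)

The BSLMM is y = 1ₙμ + Xβ + u + e with βᵢ ~ π N(0, σ_a²τ⁻¹) +
(1−π) δ₀ and u ~ N(0, σ_b²τ⁻¹K).  Hyperparameters use the model's
standard (h, ρ, log π) parametrization — h ~ U(0,1) the expected
genetic fraction of variance, ρ ~ U(0,1) the sparse share,
log π ~ U(log 1/p, 0) — with σ_a² = hρ/((1−h)πp s̄) and
σ_b² = h(1−ρ)/((1−h)k̄), where s̄ is the mean SNP dosage variance and
k̄ = tr(K)/n.

The sampler works in the eigenbasis of K, where the
polygenic-plus-residual covariance is diagonal.  μ (diffuse Gaussian
prior, variance 10⁶ relative to τ⁻¹), the included effects β_γ, and τ
(Jeffreys prior) are integrated analytically, so Metropolis–Hastings
only explores (γ, h, ρ, log π): one add/remove/swap move on the
inclusion set and one joint reflected-random-walk move on the
hyperparameters per iteration.  Retained draws resample τ ~ Γ(n/2, q/2),
the coefficients from their exact Gaussian conditional, and the
polygenic vector from its diagonal conditional; per-draw
PVE = var(Xβ+u)/(var(Xβ+u)+τ⁻¹) with the empirical variance over
samples.  The point estimate is the posterior median (switchable to the
mean by the caller); the 95% interval trims the lowest and highest 2.5%
of draws.  Default chain length is 20,000 iterations (burn-in one
quarter, ~500 retained draws) — a desk-scale default; production runs
typically use 10⁵ iterations, available via `BslmmConfig`.  Chains are
deterministic given the seed.

Zero-abundance samples are excluded from heritability traits (the trait
is the covariate-adjusted log abundance over present samples, mirroring
the quantitative GWAS part); including them as zeros is possible by
constructing the trait vector by hand.

`reml_pve_oracle` is an independent polygenic-only check: REML over the
variance ratio on the same eigenbasis, with K rescaled to unit mean
diagonal so the returned σ_u²/(σ_u²+σ_e²) is on the same per-sample
scale as the BSLMM PVE.  On purely polygenic simulations the two agree
within 0.1.

## Two-part GWAS (`mbgwas`)

Quantitative part: the trait is pre-residualized on sex, batch and the
top three genetic PCs; the score statistic is χ² = n·r²(g, y) with 1 df
(equivalent to the standard fast score test; matches the OLS LRT to
within 5% at n = 1,000).  SNPs constant in the tested subsample are
flagged untestable and excluded from λ.  Binary part: logistic
regression by Newton–Raphson with covariates in both models and a 1-df
LRT for the SNP; complete separation (degenerate weights or diverging
coefficients) flags the SNP untestable.

Genomic control divides χ² by max(λ, 1) by default — deflating
significance when λ > 1 but never inflating it when λ < 1; the
unconditional division is available behind a flag (the λ filter at
[0.99, 1.06] makes the difference marginal).  The two parts are reported
separately; no omnibus combination is applied by default because the
combination rule is analysis-specific (a weighted-Z combination can be
formed from the per-part outputs if wanted).  Presence is defined as
count > 0; no minimum-count detection threshold is applied.

LD is the squared Pearson correlation of unphased dosages (composite
LD), deterministic and phase-free.  Locus definition is greedy clumping:
the smallest-p significant SNP seeds a locus (ties broken by lower
position), the interval spans all same-chromosome SNPs with r² ≥ 0.8 to
the top SNP, and significant SNPs inside that LD set seed no further
loci.  Nearest-gene annotation measures distance from the top SNP to
BED (0-based half-open) intervals, distance 0 inside, ties toward the
smaller start coordinate.

## Pipeline and problem sizes

`pipeline.run_pipeline` chains simulate → QC → taxa → relatedness →
diversity → heritability → GWAS → report, with one derived seed per
stage (all below 2³¹) so a fixed config is bit-identical across runs.
All thresholds default to the reference values (QC 0.95/0.05/5×10⁻⁶;
prevalence 0.95/0.20 with exactly-0.95 and exactly-0.20 classed as
random; h² > 0.15 strict; λ ∈ [0.99, 1.06] inclusive).  The demo
configuration (120 animals, 1,500 SNPs, 60 OTUs, 4,000-iteration
chains, 15 taxa fitted) runs in well under a minute; the numbered
analysis drivers use 240–300 animals and 2,000 SNPs, and the
parameter-recovery experiments use n = 300, p = 2,000 with
20,000-iteration chains — sizes chosen so the full study runs on a
single CPU in minutes while keeping the variance-component estimates
identifiable.

## Known limitations

- The microbiome kinship and UniFrac stages assume the OTU table is an
  unbiased multinomial sample of the community; no rarefaction or
  copy-number correction is applied.
- The Monte-Carlo group comparison treats pair distances as exchangeable
  units (see above).
- The BSLMM assumes a Gaussian trait after log transformation and
  covariate adjustment; heavy-tailed taxa may need additional
  transformation upstream.
- Mixed-model (LMM score) GWAS, conditional analysis and cross-cohort
  meta-analysis are out of scope; family structure in the GWAS is
  handled only through genomic control and PC covariates, which is why
  the λ filter matters on pedigreed cohorts.
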