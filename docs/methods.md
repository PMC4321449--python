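# Methods

This note records the models, parameter choices and numerical decisions
behind `dosaqtl`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohorts (`dosaqtl.synthetic`)

The generator emulates the *outputs* of a low-pass sequencing + imputation
pipeline — phased haplotypes, hard genotypes, dosages with a reported
imputation quality — not the pipeline itself (no reads, no alignment, no
phasing, no coalescent genealogy).

**Allele-frequency spectrum.** A two-component mixture: with probability
`low_fraction` (default 0.5) a variant draws its frequency from a Beta(0.7,
1.4) stretched over [0.003, 0.05) — skewed toward rare — otherwise from a
Beta(0.9, 0.9) over [0.05, 0.5]. The default equal split mirrors call sets
in which low-frequency variants are roughly as numerous as common ones.
Requested frequencies are realized exactly as carrier counts
`round(af * n_haplotypes)` (clipped so low-component variants stay below 5%),
so the emitted spectrum's low-frequency fraction is binomial around
`low_fraction`.

**LD blocks.** Within each `block_len` window (default 50 kb) every
haplotype belongs to one of `n_founders` (default 20) balanced founder
lineages; a variant's carriers are the first m haplotypes of a per-variant
random ordering of whole lineages. Carrier sets of variants in the same
block are unions of (prefixes of) the same lineages, which elevates r²
within blocks to roughly the founder-count scale (~1/n_founders and above),
while blocks re-draw lineages independently, pushing cross-block r² to the
~1/n_samples null. Low-frequency variants occupy a prefix of a single
lineage — a recent mutation on one founder background. This produces the
qualitative feature the multiplicity and clumping stages need (binnable
within-block correlation, independence across blocks) but not realistic
recombination gradients; r² does not decay smoothly with distance inside a
block.

**Relatedness.** `SibshipSpec(n_sib_pairs)` adds full-sib pairs: four
parental haplotypes per pair, each sib re-drawing its inherited haplotype
per LD block, so realized sharing averages the pedigree expectation. The
returned kinship matrix is the *pedigree* coefficient-of-relationship matrix
(self 1.0, sibs 0.5, unrelated 0): that is the scale a one-variance-component
mixed model consumes, and any global rescaling is absorbed by the genetic
variance component.

**Dosage degradation.** An imputed dosage with reported variance-ratio
quality q is emulated in two steps: (1) each entry keeps the true genotype
with probability √q and is otherwise replaced by an independent
Hardy–Weinberg draw at the variant's frequency (carrier miscalls — the
dominant error mode for rare variants); (2) the result is shrunk toward the
variant mean 2p with a per-variant scale solved in closed form so the
realized ratio `var(d, ddof=1) / 2p̂(1−p̂)` equals q exactly. The emitted
mean equals the true frequency (MAF and MAC are preserved), dosages stay in
[0, 2] without clipping, squared correlation with the true genotype is ~q,
and q = 1 returns the genotypes bit-for-bit. An earlier additive-Gaussian
scheme with [0, 2] clipping was rejected: clipping is asymmetric for rare
variants and inflated their means (a monomorphic variant could acquire MAF
≈ 0.19 at q = 0.9). The MAF-dependence of quality in real data is not
modelled; `QualitySpec` accepts a per-variant array when a curve is wanted.

**Traits.** Each trait is `β(g − 2p) + Σ√vⱼ zⱼ + polygenic + ε` with
β = √(V / 2p(1−p)) at the causal's realized frequency, standardized
covariates (age, sex, two binary batches), an optional polygenic component
drawn MVN(0, h²K) via the Cholesky factor of the pedigree kinship, and
Gaussian noise topping the variance to 1. Variance bookkeeping is enforced
(components must sum below 1) and converges empirically: the causal's
realized r² approaches V at large n (tested at n = 20 000, ±0.01).

**Planted tag architecture.** `simulate_tagged_locus` builds the
two-variant configuration the conditional classifier must recognise: a
low-frequency causal (MAF 0.04) whose haplotype carriers are nested inside a
common variant's carriers (MAF 0.12), giving r² = p₁(1−p₂)/(p₂(1−p₁)) ≈ 0.31
— the common "signal" is pure tagging. The control configuration inverts
the roles: a common causal plus an *independent* null low-frequency variant.
The default variance explained for these loci is 0.20 (a ~1.6 SD per-allele
effect at MAF 4%, inside the range observed for low-frequency index
variants), chosen so the tag's apparent variance (r²·V ≈ 0.06) is reliably
discoverable at the 10⁻⁴ threshold used in the recovery checks; at smaller
planted effects the common tag frequently fails discovery and the
architecture question does not arise.

## Inclusion rules and formats (`dosaqtl.io_filters`)

Variants enter association testing if biallelic, MAC ≥ 4 (inclusive) and
imputation r² > 0.7 (strict); bins are common (MAF ≥ 5%, inclusive),
low-frequency (< 5%), with a rare flag below 1%. MAC is counted on dosages
rounded to hard genotypes (stable under dosage noise); MAF is the folded
mean dosage / 2. Imputation quality is the MaCH-style variance ratio
`var(dosage)/2p̂(1−p̂)` clipped to [0, 1]; no separate recalibration function
is applied since no published mapping exists for the ratio definition used
here. Coordinates are 1-based inclusive (VCF convention). Dosage VCFs carry
a per-sample `DS` FORMAT field and an `RSQ` INFO key (with `R2`/`DR2`
fallbacks on read); multi-allelic sites are readable but flagged and
excluded by the default filter rather than split.

## Phenotype preparation (`dosaqtl.phenotype`)

Normal scores use `Φ⁻¹((rank − c)/(n − 2c + 1))` with Blom's offset
c = 3/8 (the standard choice in genetics pipelines; van der Waerden and
Tukey offsets are selectable) and average ranks for ties (deterministic,
order-independent). The double transform — inverse-normalize, regress out
covariates by least squares, inverse-normalize the residuals — keeps the
residual ordering (the second pass is monotone) while restoring normal
margins; residual correlation with each covariate is below 0.02 at n = 450
(the second transform perturbs the exact-zero least-squares orthogonality
slightly). Rank-deficient covariate designs raise an error naming the
redundant columns. Missing values pass through untouched.

## Association engine (`dosaqtl.association`)

Dosages enter regressions as-is, never rounded. OLS tests report the simple
regression slope in phenotype-SD units, its standard error, and a two-sided
p from the t distribution with n − 2 df (no normal approximation at these
sample sizes). Constant dosages yield an `untestable` result rather than an
exception. The cis window is TSS ± 1 Mb, clipped at position 1; index
variants break p ties by larger |β|, then lower position.

The mixed model is the two-step (EMMAX-style) approximation: the null
`y ~ N(μ, σ²g K + σ²e I)` is fitted once by REML — profiling the total
variance and maximizing the restricted likelihood over h² = σ²g/(σ²g+σ²e)
on the eigenbasis of K with bounded scalar optimization (xatol 1e-8, h²
∈ [0, 1), explicit boundary check at 0) — and every variant is then tested
by GLS on the decorrelated data with the variance components held fixed,
two-sided t with n − 2 df. With K = I the whitening transform is orthogonal
and mixed p-values equal OLS p-values to machine precision; with sib-pair
kinship the REML h² estimate is unbiased but noisy (SE ≈ 0.13 with 225
pairs), so recovery checks average over replicate cohorts. Non-PSD kinship
(eigenvalue < −10⁻⁶) is rejected; a fit pinned at h² = 0 is flagged.

## Multiplicity (`dosaqtl.multiplicity`)

Pairwise LD is squared Pearson correlation of dosages (not phased
haplotypes — it is the quantity the association tests actually see).
The greedy binning repeatedly takes the unbinned variant with the most
unbinned companions at r² **>** threshold (default 0.8), removes the bin,
and counts singletons as bins; ties on companion count break to the lowest
genomic position, making the result invariant to input order, and each
variant joins exactly one bin. Window sampling draws one window per
chromosome (or n from a single chromosome, flagged), includes only
quality > 0.7 variants, and bins the full window plus the low-frequency and
common strata separately (the strata are binned independently, so their
counts can exceed the joint count). Totals: cis mode multiplies the
per-window count by the number of phenotypes (each trait is scanned over one
±1 Mb window); genome mode multiplies by ~1500 (a 2 Mb window is ~1/1500 of
the genome) and then by the phenotype count. The FDR estimate is expected
false positives (threshold × independent tests) over observed hits; at
threshold 10⁻⁶ with 31 675 456 tests and 1314 hits this is 2.4%, not the
~5% sometimes quoted for that configuration — the package reports the
arithmetic value.

## Conditional classifier (`dosaqtl.conditional`)

Regions are the trait's cis window for expression signals and index ± 1 Mb
for genome-wide signals; proxies in the detection comparison are sought
within ± 250 kb. Single-best conditioning uses the minimum-p variant of the
opposing MAF bin (ties to lower position); full conditioning uses all
opposing-bin variants surviving greedy p-ordered clumping (p < 10⁻⁴,
survivors mutually r² < 0.2, same r² estimator as the multiplicity module).
Classification: conditional p > 0.05 → fully explained; ≤ the discovery
threshold → retained; otherwise attenuated. A conditioner with r² > 0.999
against the index makes the contrast unidentifiable and the signal is
labelled `collinear` and excluded from counts; conditioners collinear among
themselves are dropped from the design; conditioning on the index itself is
refused. Both conditioning analyses (single-best and full) are reported
separately — neither subsumes the other.

## Concordance QC (`dosaqtl.concordance`)

Genotype classes come from dosages rounded to the nearest integer (the
comparison target is hard calls from a chip or deep sequencing). Site
filters, applied in order to both call sets: region mask (BED-style,
0-based half-open), removal of sites where *any* truth genotype sits below
the depth threshold (default 20×), removal of non-biallelic sites. TP is
the confirmed fraction of query sites, FN the missed fraction of truth
sites. Non-reference concordance drops the truth-hom-ref/query-hom-ref cell
from numerator and denominator. Sample exclusion requires concordance
strictly above 0.98; excluded samples with concordance in [0.4, 0.6] — the
band around the ~50% agreement two unrelated genomes show — are labelled
swap-like.

## Power model (`dosaqtl.power`)

`V = β²·2p(1−p)` links effect and variance explained; the round trip is
exact to machine precision. Analytic power uses the noncentral
distribution of the 1-df test with noncentrality nV/(1−V). The default
reference distribution is the noncentral F(1, n−2) — the exact finite-sample
distribution of the squared regression t — which reproduces the package's
n = 450, α = 10⁻⁶ reference powers within ±0.012; the large-sample
noncentral chi-square (with either nV/(1−V) or nV) is available via
`convention` but deviates by up to ~0.03 at these n. The Monte-Carlo
cross-check (`empirical_power`) regenerates Hardy–Weinberg genotypes each
replicate, so it carries genotype-sampling dispersion of the realized
variance explained on top of binomial error; comparisons against the
fixed-ncp analytic value allow ±0.025 where the power curve is concave.
Expected discoveries are rate × count, rounded half away from zero, with the
unrounded value retained.

## Problem sizes in the default suite

The test suite and acceptance script run entirely on generated data, sized
so the statistical assertions have the intended resolution: pools of 2000
haplotypes × 3000–4000 variants, cohorts of 450 (the cis-scan design),
20 000 individuals for variance-bookkeeping convergence, 10⁴ permutations
for type-I calibration, 2000 replicates per power cell, 100 + 100 loci for
the planted-architecture recovery, 8 replicate cohorts of 225 sib pairs for
heritability recovery, and 150 randomized instances of ≤ 15 variants against
brute-force oracles for the greedy procedures.

## Known limitations

* LD is block-wise exchangeable, with no distance decay inside blocks and
  no inter-block correlation; effective-test counts on synthetic genomes are
  not calibrated to any real genome's value.
* The mixed model has a single genetic variance component and no fixed-effect
  covariates beyond the intercept (covariates are residualized out upstream).
* Dosage degradation preserves the true allele frequency exactly, whereas
  real imputation biases rare-variant frequencies; quality is constant per
  variant unless a per-variant array is supplied.
* Conditional analysis implements the two-stage opposing-bin procedure only;
  no stepwise forward selection of additional independent signals.
* Case-control power is out of scope; the discovery-expectation arithmetic
  is the only extrapolation provided.
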