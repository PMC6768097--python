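# Methods

This note documents the models, the simulator's scope, the numerical
choices, and the design decisions behind `herniaqtl`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The study design being emulated

The package targets the analysis of a four-generation pig resource
population: two White Duroc boars crossed to seventeen Erhualian sows, an
F1, a large F2 bred in six batches while avoiding full-sib matings, and two
F3 cohorts — an ordinary random-mated one and a "designed" one whose
matings involve healthy full- or half-sibs of affected F2 males. Scrotal
hernia is scored as a binary trait in males only. The designed cohort's
purpose is to raise the frequency of a susceptibility haplotype, and with
it disease incidence, enough for a case/control GWAS to work at a few
hundred animals.

## Simulator (`popsim`)

**Founders.** Each variant receives an ancestral allele frequency uniform
on [0.05, 0.95]; each breed's frequency is Beta-distributed around it with
an Fst-like divergence parameter F (Balding–Nichols): Beta(p(1−F)/F,
(1−p)(1−F)/F). Default F = 0.3, a realistic figure for a European–Chinese
breed pair. Founder haplotypes are drawn independently per breed. The
causal variant is special-cased: the designated founder haplotype(s) carry
the alternate (Q) allele and every other founder chromosome carries the
reference allele, so IBS at the causal site equals IBD with the planted
haplotype and ground truth stays crisp.

**Transmission.** Gene dropping with Haldane (no-interference) crossovers:
the per-meiosis crossover count is Poisson with mean equal to the map
length in Morgans, breakpoints uniform in physical position, at a fixed
1 cM/Mb. No mutation, no genotyping error, no polygenic background beyond
the single planted locus — the reported heritability of ~0.4 is matched
only qualitatively through the major locus.

**Disease model.** Dominant single-locus incomplete penetrance: a male
with ≥1 Q copy is affected with probability f1, a non-carrier with f0
(defaults 0.5 / 0.005). Females are generated for mating but never scored.
F2 males are phenotyped before the F3 is constructed, because the designed
matings depend on knowing who is affected. A liability-threshold
alternative was considered and rejected: the penetrance model realizes the
"susceptibility haplotype" narrative directly and makes carrier status
exactly testable.

**Designed F3 matings.** Each designed parent is drawn by first sampling a
random affected F2 male and then one of *his* unaffected sibs; both
parents of a mating are drawn this way, falling back to a random F2
partner when no opposite-sex sib is available. With `designed_sib_type =
"any"` (the default) full sibs are preferred when the affected male has
any, half sibs otherwise; `"full"`/`"half"` restrict the pool. Two details
matter and were verified by measurement during development. First, the
selection must be *per affected male*: qualifying globally ("shares a
parent with any affected animal") makes nearly every F2 eligible when
there are few F1 sires, and the designed cohort shows no enrichment.
Second, drawing both parents from sib pools (rather than one sib × one
random partner) is what produces an incidence contrast of the magnitude
the design is meant to achieve; the acceptance script reports the realized
designed/ordinary incidence ratio (typically around 2× at the published
penetrance contrast).

**Evaluation design.** `desk_design()` is the package's workstation-scale
study: one SSC8-like 140-Mb chromosome with 2,000 variants, 2 sires × 8
dams, 8 + 24 F1, 300 F2, 200 ordinary and 520 designed F3 (≈250 designed
F3 males analyzed), causal locus at 70 Mb, f1 = 0.5, f0 = 0.01. These
problem sizes are the package's own choice of a realistic desk-scale
analogue of the published 246-male analysis panel; parameter-recovery
statements in the tests refer to this design. The optional
`n_reference_per_breed` field adds same-breed individuals outside the
pedigree (generation "REF"), emulating a diverse sequenced reference panel
unrelated to the cross.

## I/O and QC (`genio`)

Coordinates are 1-based inclusive (VCF convention) everywhere. Biallelic
SNPs only; the missing-allele sentinel is −1 internally, `./.` in VCF and
`0 0` in ped files. VCF reading goes through cyvcf2; a panel is flagged
unphased as soon as one non-missing call lacks phase, and phase-requiring
stages reject unphased input. The ped/map writer stores literal ref/alt
allele characters; ped input is always flagged unphased because the format
carries no phase.

QC order follows PLINK convention: individuals with more than 10% missing
genotypes are removed first, then variant filters (position present, call
rate ≥ 90%, MAF ≥ 1%) are applied with statistics recomputed on the
remaining individuals. The `QcReport` totals are exact by construction and
the filter is idempotent. Cross-chip harmonization (needed before tracing
haplotypes across generations genotyped on different chips) is an explicit
`intersect_variants` step on (chromosome, position) keys.

## Mixed-model GWAS (`lmm`)

The model is y = Wα + xβ + u + ε, u ~ MVN(0, λτ⁻¹K), ε ~ MVN(0, τ⁻¹I);
case/control labels are treated as a quantitative 0/1 response with no
liability transformation. K is the centered GRM with VanRaden method-1
scaling (divide the accumulated outer products by Σ 2pⱼ(1−pⱼ)), which puts
the diagonal mean near 1 and makes PVE = λ/(1+λ) directly interpretable;
allele frequencies come from the analysis subset and missing dosages are
mean-imputed.

The null REML fit eigendecomposes K once, profiles τ and the fixed effects
analytically, and maximizes the restricted likelihood over log₁₀λ ∈
[−5, 5] by bounded scalar search (tolerance 10⁻⁶), evaluating the λ = 0
boundary explicitly. λ̂ is then held fixed for every per-variant
generalized-least-squares Wald test (EMMAX-style); per-variant
re-optimization was rejected as orders slower for no benefit at this
scale. Monomorphic, all-missing, and covariate-collinear variants are
skipped with explicit reasons. The significance threshold is fixed at
5×10⁻⁸; λ_GC is the median Wald statistic over the χ²₁ median.

The conditional scan appends the conditioning variant's dosage to the
covariates, refits the null, and reports whether any variant within a
window (default 5 Mb) of the conditioner stays significant. The bootstrap
resamples affected and unaffected individuals with replacement within
strata and recomputes the GRM and null fit per replicate; duplicated
individuals therefore enter K and y consistently. A known consequence is
that duplicate pairs push λ̂ toward its upper bound, which makes the
bootstrap conservative for moderate effects — strong signals (the regime
the stability check is meant for) survive it, as the forced-detection test
demonstrates.

## Fst scan (`fstscan`)

MSG = Σnᵢpᵢ(1−pᵢ)/Σ(nᵢ−1), MSP = Σnᵢ(pᵢ−p̄)²/(s−1), n_c = (Σnᵢ −
Σnᵢ²/Σnᵢ)/(s−1), Fst = (MSP−MSG)/(MSP+(n_c−1)MSG), clamped to [0, 1].
Sample sizes are counted in **alleles** (2 per diploid with a non-missing
genotype), consistently across all three terms; the choice is documented
because individuals-vs-alleles only matters with unequal group sizes.
Frequencies use observed alleles only; a variant with an unobserved group
is flagged untestable. Candidate loci are those at or above the empirical
(1 − top-fraction) quantile, ties included. `multilocus_fst` provides the
standard ratio-of-sums genome-wide combination, which is the right
estimator for recovering a simulated divergence (the mean of per-locus
ratios is downward-biased at small allele counts).

## LDLA (`ldla`)

Windowed exact-match clustering replaces DAG-based localized haplotype
models: within each non-overlapping window (default 10 variants ≈ 0.7 Mb
at desk scale), identical chromosome strings form clusters; clusters rarer
than `min_cluster_freq` (default 0.02) merge into the Hamming-nearest
retained cluster, ties to the lowest label; labels order by descending
frequency with lexicographic tie-break, so the assignment is deterministic
and invariant to individual order. The two granularity knobs were
calibrated on a small pilot grid: heavier merging folds recombinant
near-copies of the susceptibility haplotype into its cluster and dilutes
the signal, while no merging inflates the per-window degrees of freedom.

Each window's pseudomarkers (all clusters but the most frequent, which
serves as reference — a pure reparameterization, since the dosages sum
to 2) enter the mixed model as fixed effects. Variance components come
from the no-pseudomarker null and are held fixed across windows, keeping
likelihood ratios comparable; LOD = LR/(2 ln 10), defined as 0 for
single-cluster windows. The support interval extends contiguously from
the peak through windows with LOD ≥ peak − drop (default 2), closing at
the first crossing; bounds are reported at the **outer edges** of the
boundary windows (midpoint bounds can exclude a locus that sits inside
the peak window itself), with censoring flags when the profile rises into
an edge. The 2-LOD rule is implemented as a support-interval convention
without endorsing any exact coverage claim. Pseudomarkers as fixed effects
(rather than haplotype effects as random) is the implemented reading; the
random-effects alternative is noted as a possible extension.

## Imputation (`imputelite`)

A deterministic Li–Stephens forward–backward replaces MCMC
haplotype-cluster samplers — this is the module's central substitution:
seedless, desk-scale, and exactly checkable against exhaustive path
enumeration on tiny instances. States are reference haplotypes; between
adjacent reference sites at genetic distance d cM the switch probability
is 1 − exp(−ρKd) with the switch landing uniformly (including self);
emission matches the state's allele with probability 1 − ε; untyped and
missing sites emit uninformatively, so the posterior at untyped sites
comes from the flanking typed sites through the smoothed state
distribution. Defaults ρ = 4×10⁻⁴ per cM per reference haplotype and
ε = 3×10⁻³. Targets are taken as already phased (simulator truth);
re-phasing chip data is out of scope, so accuracy numbers are an
optimistic bound.

Mask-and-reimpute evaluation deletes locus-columns across all target
individuals (the per-individual alternative is noted as ambiguous in the
source protocol), reimputes, and reports allele-level concordance and
per-variant dosage R² averaged over variants with defined variance; the
filtered mean additionally drops MAF < 0.03 and R² = 0 variants,
mirroring the usual post-imputation filter. Within-pedigree references
make imputation nearly perfect by construction (targets are literal
founder mosaics); the qualitative behaviours of interest — related
reference beats an equal-size unrelated one, and R² falls with MAF — are
exhibited against the same-breed unrelated "REF" panel.

## Haplotype sharing (`haploshare`)

Sharing is exact identity-by-state over the interval; an individual
carries a candidate if either chromosome matches it exactly. A mismatch
budget exists but defaults to 0 — no tolerance is defensible a priori.
Candidates are strings carried by at least `min_share_fraction` (default
0.8, motivated by a 15-of-18 sharing pattern) of affected individuals,
ordered by carrier count then lexicographically. Tracing walks each
carrier up the pedigree to whichever parent also carries the string;
both-parent matches are followed as ambiguous branches, and a step with no
matching parent marks the string as created by recombination inside the
interval. The carrier test is a Pearson chi-square on the 2×2
affected/unaffected × carrier/non-carrier table with **no Yates
correction** — the plain statistic is what reproduces published worked
examples from their printed counts — pooling all candidate haplotypes into
one carrier class; a zero margin raises rather than returning a value.

## Null calibration choices

Two calibration checks use deliberately chosen conditions. The
permutation-uniformity KS test runs on an unrelated panel with independent
variants, because the KS test assumes independent draws and LD-correlated
p-values would test dependence rather than calibration. The f1 = f0 null
replicates use a shared penetrance of 0.2: the design must still be
constructible (the designed cohort needs affected F2 males), and a
near-degenerate case count at a few hundred animals would probe the
known instability of the 0/1-response Wald test at rare variants instead
of null calibration.

## Known limitations

- Single planted locus; no polygenic background, genotyping error,
  mutation, or crossover interference.
- Case/control labels as a linear (not liability/logistic) response,
  matching the emulated analysis; p-values at very unbalanced case counts
  rely on the MAF ≥ 1% QC filter for stability.
- The stratified bootstrap with per-replicate GRM refits is conservative
  when resampling duplicates dominate (λ̂ boundary), as discussed above.
- Imputation accuracy against within-pedigree references is near-ceiling
  by construction and should not be read as a field-data estimate.
- IBS founder tracing reports ambiguity rather than resolving it
  probabilistically (no Lander–Green style inference).
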