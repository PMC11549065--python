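# Methods

## Demographic model

The population is age-structured with integer ages 0–39 (pups are age 0;
nobody survives past the 40-year lifespan) and a post-breeding census.
Natural survival follows the reduced additive Weibull (RAW) model:
cumulative survivorship to exact age *a* is

    S(a) = exp(−[(η₁ a)^{η₂} + (η₁ a)^{1/η₂} + η₃ a])

and annual survival is φ_a = S(a+1)/S(a), which produces the bathtub shape
expected for phocids (φ₀ ≈ 0.65, young-adult φ ≈ 0.87, declining again past
age ~20 at the default η = (0.055 yr⁻¹, 2.80, 0.076 yr⁻¹), the prior means
from a phocid mortality meta-analysis). The lifespan cap is implemented as
φ₃₉ = 0.

Reproduction: a female aged *a* alive in year *t* whelps one pup with
probability f_a; pup sex is Bernoulli(½). A male's relative reproductive
weight at age is m_a. The published fecundity/maturity-at-age tables behind
the original analysis are not printed anywhere we can read them, so the
package ships configurable schedules with documented defaults — logistic
ogives, female fecundity midpoint 5 yr, slope 1 yr, asymptote 0.95; male
maturity midpoint 6 yr, slope 1 yr, asymptote 1.0; both forced to 0 at age
0 — and accepts user tables or knife-edge schedules (the power-analysis
convention: 0 below age 4, 1 at 4+). All kernels read the schedules only
through `LifeHistorySchedules`.

The recruitment bookkeeping is N_{t,0} = ½ Σ_a N^F_{t,a} f_a with aging
N^F_{t,a} = N^F_{t−1,a−1} φ_{a−1}; equivalently a female Leslie matrix with
fertility elements ½ φ_a f_{a+1} (survive the year, then breed at the new
age). This convention was chosen because it makes the deterministic
trajectory, the kinship kernels, and the individual-based simulator exactly
consistent with one another; the growth rate λ is its dominant eigenvalue,
and trajectories are geometric on the stable age distribution with the
total abundance anchored at a reference year. Density dependence, space,
and harvest mortality are outside the model.

## Kinship probability kernels

All kernels condition on lethal sampling (sampling year = death year) and
on the expected trajectory N^F_{t,a} = N^M_{t,a}.

* **Parent–offspring.** A candidate mother aged *a* in the offspring's
  birth year *b* has probability f_a / Σ_{a'} N^F_{b,a'} f_{a'}; fathers use
  m_a and the male sum. The male breeding fraction π cancels for POPs: a
  random mature male is a breeder with probability π, but each breeder's
  paternity share is 1/(π Σ N m). Candidates dead before *b* score zero.
* **Half-siblings.** The unobserved shared mother must be drawn from the
  age distribution of successful mothers in the older sibling's birth year
  (∝ N^F f), survive the birth gap δ, and win the maternity lottery again:
  P = Σ_a w_a · (Π_{t<δ} φ_{a+t}) · f_{a+δ} / Σ N^F_{b_j} f. Same-cohort
  maternal half-sibs are impossible (one pup per female per year); paternal
  ones are allowed (δ ≥ 0) and carry the 1/π confirmed-breeder factor.
* **Grandparent–grandchild.** Summed over the intermediate parent's sex and
  birth year c ∈ (b_i, b_j): the grandparent's expected offspring of that
  sex born at c (requires being alive at c), the intermediate's survival
  from birth to age b_j − c, and the intermediate's share of that year's
  reproductive output. For male links the breeder probability π and the
  π-deflated pool cancel algebraically, as they must — the expected number
  of grandchildren through sons does not depend on reproductive skew.
* **mtDNA conditioning.** Haplotypes are maternal, so maternal half-sibs
  always share one, paternal half-sibs never do, and grandparent chains
  share only along grandmother → daughter. Chance sharing of haplotypes is
  neglected in the kernels (the simulator produces it, and the test suite
  bounds the induced bias through the recovery checks).
* The observable second-order class is the HSP+GGP mixture discounted by
  the kin-calling false-negative rate, applied to the pooled mixture
  because the PLOD threshold acts on the pooled second-order score.

## Pseudo-likelihood

Ordered pairs are parent–offspring Bernoulli trials (pairs sampled in the
same year are omitted as dependent mother/pup captures); unordered pairs
are one second-order trial each with a multinomial outcome {no kin, kin
sharing mtDNA, kin not sharing}, so unrelated pairs are never conditioned
on chance haplotype sharing. Pairs with identical covariate keys are
grouped; grouping is an exact refactoring (tested to 1e−10).

The objective adds Gaussian log-penalties: ½ Σ ((η_k − η̄_k)/σ_k)² with
defaults σ = (0.01, 0.3, 0.02) standing in for the prior, and
w_λ (λ(η) − λ₀)² with w_λ = 10⁴ per unit², stiff enough to hold λ ≈ λ₀
(λ₀ = 1 unless profiling trend). Abundance is parameterized as log N in a
reference year (default: the last sampling year; the trend profile reports
the 1990–2020 trajectory mean instead); π is logit-parameterized and η
log-parameterized. Optimization is L-BFGS-B from three dispersed abundance
starts; standard errors come from the inverse central finite-difference
Hessian (step 1e−4 on the working scale), with CV(N̂) = SE(log N̂) by the
delta method. AIC is computed on the kin-only likelihood (penalties act as
priors and are excluded), with k the number of freely estimated parameters.
Non-positive-definite Hessians and observed kin in zero-probability groups
are flagged, never silently absorbed.

## Kin identification from genotypes

Loci are biallelic with a heritable null allele (p + q + ν = 1); observed
classes are AA* (AA or A∅), AB, BB* (BB or B∅), and FAIL (∅∅ or technical
failure, the latter separable via a configurable rate). Allele frequencies
are estimated by maximum likelihood with a closed-form moment start (exact
when the class frequencies sit on the model).

QC alternates locus screens (MALF < 0.05 removed; NALF ≥ 0.45 removed;
HWE-with-nulls chi-square, df = 1, α = 0.05 per locus by default with an
optional Benjamini–Hochberg mode) and sample screens (heterozygosity
z-score beyond ±4; duplicate detection at >0.95 called-genotype
concordance), re-testing previously rejected items against refreshed
frequencies each round until a fixed point; the loop is deterministic and
idempotent. The chi-square is evaluated at the MLE for borderline loci
because the moment estimator inflates the statistic.

PLOD scores sum per-locus log likelihood-ratios of the observed class pair
under a kinship hypothesis versus unrelated, using Cotterman mixtures over
0/1/2 IBD alleles computed on true three-allele genotypes and marginalized
to observed classes. FAIL loci are skipped (raw sum, no rescaling). With
ν = 0 everywhere this reduces exactly to the textbook biallelic kinship
likelihood ratio (tested against an independent nine-state enumeration).
First-order pairs are called first (POP vs FSP by the larger score, ties to
POP, against a threshold at half the theoretical POP mean); remaining pairs
are called HSP-GGP at the second-order threshold. The false-negative rate
is Φ((threshold − μ_HSP)/σ̂) with μ_HSP theoretical and σ̂ folded from the
observed scores at or above μ_HSP; fewer than five upper scores flags the
estimate unreliable. Genetic sex is a majority vote over male-specific
presence markers.

Deterministic covariate repair handles the structurally impossible called
pairs that exact-age assumptions produce: a POP whose parent was harvested
before the recorded birth gets the offspring's age incremented (at most 2
years, else the pair is excluded and flagged), and a same-cohort pair
observed to share mtDNA gets the older member's age incremented by 1. Every
edit is logged.

## Synthetic data generator

The individual-based simulator realizes the model's assumptions exactly:
yearly survival draws by φ_a with the age-39 cap, one whelping Bernoulli
per mature female, fathers drawn with probability ∝ m_a among living
breeder males, lifelong breeder flags assigned Bernoulli(π) at birth
(equivalent in distribution to assignment at maturity, since the flag is
independent of everything else; an annual-reassignment switch exists for
sensitivity only), maternal mtDNA from a 40-haplotype Dirichlet(1) founder
spectrum, and Mendelian transmission of three-allele genotypes with
technical failures. Defaults emulate the Bering–Chukchi–Beaufort
bearded-seal study system: 3×10⁵ animals, π = 0.34, 1998–2020 harvests
ramping from <10 to ~100 per year (1484 total), 46% pups / 19.3% ages 1–3 /
34.7% ages 4+, 2569 SNPs including seven male-specific sexing markers,
visible minor-allele frequencies U(0.05, 0.5), null frequencies U(0, 0.2),
1% technical failure.

Harvest removal happens inside the yearly loop — sampling is lethal, and a
post hoc draw would leave sampled females whelping after death — so the
harvest design is part of the simulation configuration; `sample_harvest`
extracts the records and enumerates every true kin pair (POP, FSP,
MHSP/PHSP, GGP, FTP/HTP) among the samples. Founders lack parent links, so
simulations begin one burn-in (default 45 years ≥ one lifespan) before
sampling, which guarantees all first/second-order relations among samples
are traceable.

What the simulator does *not* emulate: aging error (ages are exact by
construction), spatial structure and village-level sampling heterogeneity,
environmental stochasticity in vital rates, and non-random mate fidelity.
Passing tests therefore demonstrate internal consistency of the estimator
with its own assumptions at realistic scales, not robustness to these
real-data features.

## Problem sizes and numerical choices

Routine tests run scaled-down populations (N ≈ 3,500–20,000, a few hundred
to 800 samples) with expectations rescaled analytically; kin probabilities
scale as 1/N, so these sizes give the same relative structure as the full
3×10⁵ scenario while keeping each simulation replicate under a second. The
kernel-vs-pedigree agreement check uses N = 5,000 with 40 replicates and
3 empirical Monte-Carlo SEs (the empirical SE absorbs demographic
stochasticity and the small harvest-removal feedback the deterministic
trajectory ignores). Parameter-recovery coverage uses 100 replicates at
N = 20,000, π = 0.4 with survival fixed at truth. The power analysis for
the 3×10⁵ scenario draws kin counts parametrically group-by-group
(survival treated as known, population held at λ = 1), which is the
design-stage computation; the pedigree route is available behind
`method="pedigree"`.

Convergence: L-BFGS-B with ftol 1e−12 on the penalized objective; infinite
objective values are clamped to 1e10 during line searches and re-checked
exactly at the optimum. Eigen-decompositions fall back to a uniform age
structure for degenerate (zero-fecundity) schedules. Ties in pair ordering
(same birth year) break on sample id so grouping is invariant to input
order.

## Known limitations and documented discrepancies

* λ = 1.04 from the prior survival schedule cannot be verified without the
  external fecundity/maturity tables; the package's default ogives give
  λ ≈ 1.005 and the knife-edge power schedules λ ≈ 1.037.
* The published sex-ratio chi-square (1.9) is not reproducible from the
  printed inputs; direct Pearson computation on observed 15/7 vs expected
  11.3/9.1 gives 1.7, which the reporting module returns as computed.
* The published mean birth gaps 6.2/3.3 years refer to a 25-pair set whose
  three extra gaps are untabulated; the shipped 22-pair table gives 6.9/4.0
  and the comparison is treated as qualitative (paternal > maternal).
* Fits to the archived study genotypes require that archive; the test suite
  wires them in under `data/dryad/` but cannot pass without it.
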