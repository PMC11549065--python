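# sealkin

Close-kin mark-recapture (CKMR) for lethally sampled pinniped populations.

## The problem

Abundance estimates for wide-ranging ice seals are hard to obtain from
aerial surveys, but subsistence-harvest monitoring programs accumulate
tissue samples for decades. CKMR turns those samples into an abundance
estimate: each genotyped animal "marks" its parents, and every kin
relationship found between two sampled animals is a recapture of a shared
parent. Small populations yield kin pairs at a higher rate than large ones,
and the expected number of kin pairs grows with the *square* of the sample
size. `sealkin` implements the full workflow for a bearded-seal-like system
— long-lived, one pup per female per year, polygynous males, sampled
lethally with known ages — for population biologists who have genotypes,
ages, sexes, and mtDNA haplotypes from harvested animals.

## What is inside

* **Kin discovery** (`genotypes`, `qc`, `plod`): biallelic SNPs with
  heritable *null alleles* (frequencies `p + q + ν = 1`; observed classes
  AA\*, AB, BB\*, FAIL with HWE probabilities `p²+2pν, 2pq, q²+2qν, ν²`),
  iterative panel QC (MALF/NALF filters, HWE-with-nulls goodness of fit,
  heterozygosity and duplicate screens with re-introduction), and
  pseudo-log-odds (PLOD) scores
  `Σ_loci log P(g_i,g_j|K)/P(g_i,g_j|UP)` with Cotterman coefficients
  κ(POP)=(0,1,0), κ(FSP)=(¼,½,¼), κ(HSP/GGP)=(½,½,0), plus
  threshold-based calling, false-negative estimation, and genetic sexing.
* **Demography** (`demography`): reduced additive Weibull (RAW) survival
  `S(a) = exp(−[(η₁a)^{η₂} + (η₁a)^{1/η₂} + η₃a])` (a bathtub hazard),
  fecundity/maturity ogives, post-breeding-census Leslie projection, growth
  rate λ and stable age structure.
* **Kinship kernels** (`kernels`): P(POP), P(MHSP), P(PHSP), and P(GGP)
  conditional on birth/death years, sex, the population trajectory, mtDNA
  sharing, and the male breeding fraction π (a fraction π of mature males
  sires all pups; a confirmed father shrinks the competing pool by π, so
  paternal half-sib probabilities scale as 1/π).
* **Pseudo-likelihood** (`likelihood`): grouped Bernoulli/multinomial
  likelihood `L = L_pop · L_hsp/ggp · f(η) · Λ_λ` with Gaussian penalties on
  η about its prior and on λ about an imposed λ₀; scikit-learn-style
  `CkmrModel` estimator with `fit`, finite-difference Hessian standard
  errors, AIC on the kin-only likelihood, and trend profiling over λ₀.
* **Synthetic data** (`simulate`): an individual-based pedigree, harvest,
  and genotype simulator realizing exactly the model's assumptions, plus
  analytic expected kin counts and the simulation-based power analysis.
* **Reporting** (`reporting`): the exact binomial mtDNA test, sex-ratio
  chi-square, birth-gap summaries, and a shipped 22-pair reference kin
  table.

## Worked example

Simulate a 20,000-animal population with strong male reproductive skew
(π = 0.4), harvest 800 animals over 20 years, and refit the generating
parameters from the true kin labels:

```python
import numpy as np
from sealkin import (
    LifeHistorySchedules, SimConfig, HarvestDesign, CkmrModel,
    simulate_pedigree, sample_harvest, build_comparisons,
)
from sealkin.kinference import annotate_kin_strata, repair_covariates

sched = LifeHistorySchedules.from_raw()          # RAW prior + default ogives
years = np.arange(2000, 2020)
design = HarvestDesign(years=years, n_per_year=np.full(20, 40))
cfg = SimConfig(n_initial=20_000, schedules=sched, pi=0.4, harvest=design)

ped = simulate_pedigree(cfg, seed=7)
records, kin = sample_harvest(ped)
kin = annotate_kin_strata(kin, records)
records = repair_covariates(kin, records).records
comps = build_comparisons(records, kin=kin)

model = CkmrModel(pi_free=True, eta_free=False, ref_year=1955).fit(comps)
print(round(model.n_hat_), round(model.n_hat_cv_, 2), round(model.pi_, 2))
```

This prints `21771 0.18 0.45`: an abundance estimate of ~21,800 (CV 0.18,
truth 20,000 in the reference year) and a breeding fraction of 0.45
(SE ≈ 0.11, truth 0.4), recovered from 6 parent–offspring and 71
second-order kin pairs among 319,600 pairwise comparisons.

The same pipeline runs from the shell:

```bash
sealkin --seed 3 simulate --n-initial 4000 --total-samples 220 --out-prefix run
sealkin qc --genotypes run.geno.tsv --out run.qc.tsv
sealkin findkin --genotypes run.qc.tsv --samples run.samples.csv \
    --mtdna run.mtdna.csv --threshold 8 --out run.kin.csv
sealkin fit --samples run.samples.csv --kin run.truekin.csv --out run.fit.json
```

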