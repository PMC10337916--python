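# hetvar

Heterogeneity-of-variance (HV) analysis for milk production in dairy
cattle: pedigree-based Bayesian repeatability animal models fitted by
Gibbs sampling, with the full data-consistency pipeline, standard-deviation
(SD) herd classes, Geweke convergence diagnostics, and breeding-value
re-ranking summaries. A synthetic-data module generates multi-herd,
multi-parity lactation records with known genetic truth, so every stage
has a parameter-recovery test.

## Who this is for

Animal breeders and quantitative geneticists who want a self-contained,
tested implementation of the classical SD-class approach to
genotype-by-environment interaction in dairy evaluations: herd-years are
split into low- and high-production strata from their standardized means,
and milk yield expressed in the two strata is treated as two correlated
traits. If the between-stratum genetic correlation r_g is high and sire
rankings are stable across strata, HV can safely be ignored in routine
evaluation; if not, it re-ranks sires.

## The model

General (single-trait) analysis — a repeatability animal model:

    y = Xb + Za + Wp + e
    a ~ N(0, A σ²a),  p ~ N(0, I σ²p),  e ~ N(0, I σ²e)

with `y` the 305-day milk yields (MY305), `b` the fixed effects
(contemporary group = herd × calving year × season, plus linear/quadratic
age at calving and linear direct-heterozygosity covariates), `a` additive
genetic effects over the pedigree relationship matrix A, and `p`
permanent-environment effects per cow.

HV (two-trait) analysis — each record carries the trait of its herd-year's
SD class (low iff the standardized herd-year mean z = (X − μ)/σ ≤ 0):

    yᵢ = Xᵢbᵢ + Zᵢaᵢ + Wᵢpᵢ + eᵢ ,   (a₁, a₂) ~ N(0, G₀ ⊗ A)

with trait-specific permanent-environment and residual variances (their
cross-trait covariances are zero by design: no cow has records in both
classes). Variance components get conjugate priors (scaled inverse
chi-square; inverse-Wishart for G₀) and are sampled by Gibbs; reported
parameters are h² = σ²a/(σ²a+σ²p+σ²e), repeatability
rep = (σ²a+σ²p)/(σ²a+σ²p+σ²e), and r_g = G₀₁₂/√(G₀₁₁G₀₂₂).

EBV accuracy is r = √(1 − PEV/σ²a) with PEV the posterior variance of an
animal's breeding-value chain. Re-ranking across the general/low/high
analyses is summarized by Spearman correlations (all animals and the top
20% by general-analysis EBV) and top-10 overlap counts.

## Worked example

```python
from hetvar import synthetic_data as sd, data_prep as dp
from hetvar import pedigree as pm, gibbs_engine as ge

truth = sd.TrueParameters(seed=11, r_g=0.9)          # known generative truth
ds = sd.simulate(truth, n_sires=40, daughters_per_sire=30)
res = dp.prepare(ds.records, ds.pedigree)            # DH, MY305, CGs, filters, SD classes
rs = pm.renumber(ds.pedigree); pm.compute_inbreeding(rs)
ainv = pm.build_a_inverse(rs)                        # sparse Henderson A^-1
mm = ge.assemble(res.records, rs, mode="two_trait")
model = ge.GibbsAnimalModel(mode="two_trait", n_iter=30_000, burn_in=3_000,
                            thin=10, seed=1).fit(mm, ainv)
for name, s in model.params_["summaries"].items():
    print(f"{name:9s} {s.mean:6.3f} +/- {s.sd:5.3f}   HPD95 [{s.hpd95_low:6.3f}, {s.hpd95_high:6.3f}]")
```

prints

```
h2_low     0.116 +/- 0.064   HPD95 [ 0.016,  0.240]
rep_low    0.392 +/- 0.036   HPD95 [ 0.322,  0.466]
h2_high    0.061 +/- 0.038   HPD95 [ 0.007,  0.135]
rep_high   0.266 +/- 0.038   HPD95 [ 0.191,  0.337]
r_g        0.520 +/- 0.337   HPD95 [-0.182,  0.963]
```

The generative truth here is h² ≈ 0.11 per stratum and r_g = 0.9. With 40
sire families of 30 daughters and heritability this low, the data carry
little information about the genetic (co)variance: the posteriors are
wide (the r_g interval spans most of its range and covers the truth), and
posterior means shrink toward the weakly informative prior. That is the
expected behaviour at this scale, not a defect — see `docs/methods.md`.

The same run end-to-end, from the shell:

```bash
hetvar run --config run.yaml --out runs/demo     # simulate→prep→fit×2→diagnose→rank
hetvar simulate --seed 1 --out data/             # or stage by stage
hetvar prep --records data/records.csv --pedigree data/pedigree.csv --out prep/
```

`run.yaml` holds the seed, chain preset (`desk` = 30,000/3,000/10 or
`full` = 300,000/30,000/10, which retains exactly 27,000 draws), edit
thresholds (MY305 cap 25,000 kg, age cap 120 months, minimum contemporary
group size 4, minimum 2 daughters per sire per SD class), and prior
overrides.

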