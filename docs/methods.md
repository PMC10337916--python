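# Methods

This note documents the statistical models, the numerical choices behind
the sampler, the design of the synthetic-data generator, and the known
limitations — the decisions a maintainer or reviewer would want spelled
out. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Data-consistency pipeline

Raw inputs are a pedigree (animal, sire, dam, birth date, two-breed
composition fractions) and lactation records (cow, sire, herd, calving
date, age at calving in months, lactation length LL in days, total milk
yield MY in kg). The pipeline applies, in a fixed, documented order:

1. **Direct heterozygosity.** DH = a₁ᵗa₂ᵛ + a₂ᵗa₁ᵛ from the sire's and
   dam's breed fractions; it is recomputed from the pedigree, never read
   from the record file, so the breed-composition path is exercised
   end-to-end. Cows with unknown parents get no DH and are removed by the
   ancestry filter.
2. **Seasons and contemporary groups.** Calving months April–September are
   the dry season, October–March the rainy season; the contemporary group
   (CG) is herd × calving year × season.
3. **305-day standardization.** MY305 = MY + b₁(LL − 305), applied
   two-sided (records with LL > 305 move up, LL < 305 move down). b₁ is
   the OLS slope of MY on LL. `prepare()` estimates that slope *within
   contemporary groups* (pooled within-group OLS) by default: the pooled
   overall slope — available as `b1_basis="overall"` — picks up
   herd-to-herd and age variation as regression noise, and any slope error
   δ injects δ²·Var(LL) of spurious variance into MY305. Within-group
   estimation is the standard practice for adjustment factors once
   management groups are known.
4. **Filters**, in order: (i) records of cows lacking a known sire, dam or
   birth date; (ii) MY305 above 25,000 kg (optionally LL below a floor —
   off by default, short lactations are kept); (iii) age at calving above
   120 months; (iv) contemporary groups left with fewer than 4 records,
   applied once after the record-level rules. A `FilterReport` accounts
   for every input record (retained + removed per rule = input).
5. **SD classes.** For each herd-year, the class mean X of MY305 is
   standardized as z = (X − μ)/σ; the herd-year (and its records) is
   `low` iff z ≤ 0, else `high`. μ and σ are the record-level mean and SD
   of MY305 over all retained records by default ("general average of
   production"); `z_basis="class-means"` switches to the mean/SD of the
   herd-year means. Consequently the mean of z over herd-years is *not*
   zero under the default basis.
6. **Cow class consistency.** The SD class is a herd-year property, so a
   cow recorded over several years in a herd whose realized herd-year
   means straddle the boundary can have records in both classes. The
   two-trait model treats the permanent-environment effect as
   trait-specific and requires each cow in one class, so minority-class
   records of such cows are dropped (ties: the class of the earliest
   calving), counted as their own filter rule.
7. **Connectedness.** Sires must have at least two distinct daughters with
   retained records in *each* class; other sires' records are removed.
   The rule iterates to a fixed point, but because the daughter counts are
   per-sire and classes are frozen, one sire's removal cannot demote
   another — the second pass is a no-op check. CG sizes are deliberately
   not re-checked after class-based removals (fixed pipeline order).

## 2. Models

**Single-trait repeatability animal model** (general analysis):
y = Xb + Za + Wp + e with a ~ N(0, A σ²a), p ~ N(0, I σ²p),
e ~ N(0, I σ²e). Fixed effects: one level per CG (no explicit intercept)
plus covariates age, age², and DH. Age and age² are centered at their
means (per trait in the two-trait model) — a pure reparameterization that
improves mixing without changing fitted values or variance draws; DH
enters as-is.

**Two-trait HV model:** milk yield in the low and high SD classes as
distinct traits. Each animal carries two breeding values with
Var(a) = G₀ ⊗ A; CG levels and covariate coefficients are nested within
trait; permanent-environment and residual variances are trait-specific
with cross-trait covariances fixed at zero — they are not estimable
because no cow (after the class-consistency rule) has records in both
classes. Assembly asserts both structural preconditions (no CG spans
traits; no cow spans traits).

**Pedigree machinery.** Deterministic topological renumbering (parents
first, ties by original id; cycles and sire=dam are rejected with the
offending ids). Inbreeding F by the Meuwissen–Luo row-tracing recursion
(with an O(1) shortcut for the common founder-parents case); Henderson's
rules assemble sparse A⁻¹ with inbreeding accounted for in the Mendelian
variance d_i = 0.5 − 0.25(F_s + F_d) (a flag disables this for
comparison). The dense recursive tabular A (diagonal 1 + F) serves as the
small-pedigree oracle: Henderson's A⁻¹ must equal its dense inverse.

**Priors.** Conjugate throughout: scaled inverse chi-square for scalar
variances, inverse-Wishart for G₀, with ν = dim + 2 (3 for scalars, 4 for
the 2×2 G₀). Default scale parameters put the scale at a 10/20/70
additive/permanent/residual split of the phenotypic variance *net of all
fixed effects* (CG means and covariates); using the raw within-CG variance
would inflate the scales several-fold with age-covariate variance, and —
because a large diagonal inverse-Wishart scale penalizes high
correlations through tr(V₀G₀⁻¹) — would silently push the posterior of
r_g toward zero. All hyperparameters are overridable per run.

## 3. Gibbs sampler

Location effects are updated one equation at a time (Gauss–Seidel style)
against a running residual, which keeps each update O(records at that
level + pedigree row) and makes 30,000-iteration chains tractable on one
CPU (numba kernels). Three accelerations, each leaving the posterior
exactly invariant:

* **Trait-blocked breeding values.** In the two-trait model the two
  breeding values of an animal are drawn jointly from their bivariate
  conditional (2×2 solve + Cholesky). Single-site updates mix hopelessly
  when the genetic correlation is high, because the conditional variance
  is O(1 − r_g²) times the marginal.
* **Group scale moves** (generalized Gibbs in the Liu–Sabatti sense): a
  multiplicative group element c rescales an entire random-effect block
  together with its variance — (a, σ²a) → (ca, c²σ²a), per-trait
  (a_t, G₀ row/column t), and (p_t, σ²p_t). The 1-D density of c (prior,
  likelihood, Jacobian and Haar measure folded in) is sampled by slice
  sampling. This replaces the notoriously slow random walk of variance
  components under weak identification with direct scale traversal. The
  moves require proper priors (ν > 0) and are skipped otherwise.
* **Shear moves**: a_t ← a_t + γ a_u with the congruent update
  G₀ ← TG₀T'. The group action has unit Jacobian and the conditional of γ
  is exactly Gaussian; it mixes the genetic covariance g₁₂ directly.

Validation: chains with the moves enabled reproduce the variance-component
and r_g quantiles of plain single-site chains run 5–20× longer
(`tests/test_gibbs_engine.py::TestGroupMoveInvariance` and the acceptance
oracles); the conjugate toy posterior matches its closed-form scaled
inverse chi-square (Kolmogorov–Smirnov), and fixed-variance runs reproduce
the GLS solution of the fixed effects.

G₀ is drawn from its inverse-Wishart conditional via a closed-form 2×2
Bartlett construction; the draw is positive definite by construction and
the kernel aborts with the iteration index if any variance draw goes
non-finite (`NumericalFailureError`).

**Chains.** Retained draws = floor((n_iter − burn_in)/thin). Presets:
`desk` 30,000/3,000/10 (default; used by the tests and acceptance script)
and `full` 300,000/30,000/10, which retains exactly 27,000 draws.
Reported summaries are posterior mean, SD, and the 95% HPD interval
computed as the shortest interval containing 95% of the sorted draws
(cross-checked against `arviz.hdi` in the tests).

**EBV accuracy.** r = √(max(0, 1 − PEV/σ²a)), clamped to [0, 1], with PEV
the variance of the animal's retained breeding-value draws and σ²a the
posterior-mean additive variance. The accuracy expression is sometimes
printed in corrupted forms (e.g. with "1 + PEV/σ²a", which exceeds 1);
the square-root-of-reliability form above is the classical definition and
is what this package computes.

## 4. Geweke diagnostic

z = (m_first − m_last)/√(S_first(0)/n_first + S_last(0)/n_last) over
non-overlapping windows (first 10%, last 50% by default), with the
spectral density at zero estimated as the mean periodogram over the lowest
⌈√n⌉ nonzero frequencies (a batch-means estimator is available behind a
flag). Two-sided normal p-value; converged iff p > α (default 0.05).
Constant (zero-variance) windows report p = 1 with a degenerate flag
rather than NaN. Calibration (null rejection ≈ 5%, near-certain rejection
of a 2-SD drift) is verified in the tests. The pipeline monitors all
variance components and derived parameters of both chains.

## 5. Synthetic-data generator

The generator produces exactly the structure the models assume, with known
truth, so that recovery experiments are well-posed:

* **Pedigree:** two generations — founder sires and dams, recorded
  daughters (deeper pedigrees can be built by composing calls). Sires
  carry the breed profile's Holstein fraction (1.0, 0.625, or 0.0); dam
  fractions sit on a grid so DH varies.
* **Breeding values:** (n, 2) draws from N(0, G₀ ⊗ A) by pedigree
  recursion (parent average + Mendelian sampling scaled by d_i), exact
  including inbreeding.
* **Herds:** each cow belongs to one herd for life. Herd-mean deviations
  are half-normal magnitudes (scale `herd_mean_spread`, truncated at two
  spreads) outside a guard band (`herd_gap`, 300 kg) around the base mean,
  with balanced signs and centered. The guard band ensures the realized
  herd-year SD classes identify the generative strata — without it, herds
  sitting on the class boundary flip class on herd-year noise, each class
  becomes a mixture of both residual-variance strata, and the
  "true" per-stratum parameters a recovery experiment needs are no longer
  well-defined. The truncation keeps even the lowest herd's total yields
  positive (herd means span roughly 2,300–7,700 kg, the realistic range).
* **Records:** 1 to `max_parities` consecutive calvings per cow; age ≈ 30
  months at first calving + 13/parity; calving month uniform (so both
  seasons occur); herd-year-season wiggle N(0, 100 kg); phenotype =
  base + herd deviation + CG wiggle + age effects + β_DH·DH + a(stratum) +
  p + e(stratum). LL ~ U(180, 400) days and MY is back-computed from the
  MY305-scale phenotype via the true slope `b1_ll`, so standardization is
  exercised in both directions. Because the additive standardization
  MY305 = MY + b₁(LL − 305) *re-applies* the estimated trend rather than
  removing it, a true slope c leaks 4c²Var(LL) of noise into the
  standardized trait; the default slope is therefore small (0.1 kg/day,
  configurable) so the residual truth stays interpretable.
* **Default truth:** σ²a 2,100/3,000, σ²p 5,000, σ²e 11,700/21,200 kg²
  (low/high), r_g 0.9, herd spread 1,200 kg — the magnitudes published for
  Bayesian HV analyses of Brazilian dairy herds, giving per-stratum
  h² ≈ 0.10–0.11.

What the generator does **not** emulate: selection or culling, genomic
markers, lactation curves, skewed herd sizes, missing data, or
cross-classified cow movement between herds. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data pathologies.

## 6. Problem sizes and what the experiments show

The standard recovery scenario is 40 sires × 30 daughters (≈ 2,400
records, ≈ 2,440 animals) with desk chains; the test suite runs 20
replicates, the acceptance script 10. At this scale, with h² ≈ 0.1, the
data are *weakly informative* about the genetic (co)variance: exact
restricted-likelihood evaluations on such data show a nearly flat profile
over r_g. Correct behaviour is therefore wide, honestly calibrated
posteriors — HPD coverage of the truth near 95% — rather than sharp point
recovery. The posterior-mean h² consequently fluctuates across replicates
with an SD of a few hundredths, and the cross-class EBV correlation
tracks the (diffuse) posterior of r_g; both are properties of the study
design, visible in the acceptance outputs.

## 7. Known limitations

* Residual and permanent-environment cross-class covariances are fixed at
  zero (not estimable under the class structure), so the model cannot
  represent cows performing in both strata.
* Single-chain inference; no Gelman–Rubin or effective-sample-size suite
  (Geweke only, as the chain-validity criterion).
* No reaction-norm (random-regression on herd mean) alternative; SD
  classes are a hard two-way split.
* Unknown-parent groups, genomic relationship matrices and metafounders
  are out of scope; unknown parents follow classical Henderson rules.
* The heterozygosity model is two-breed only.
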