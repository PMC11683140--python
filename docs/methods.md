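# Statistical methods and implementation notes

## 1. Stage-one multi-environment model

For each trait, plot records from a series of randomized complete block
trials on row/column field grids are analysed with the linear mixed model

```
y = mu + block(env) [fixed] + env + row(env) + col(env) + clone + clone:env + e
```

where environment, row-within-environment, column-within-environment, clone
(genotype) and clone-by-environment (GxE) are independent random effects.
Variance components are estimated by restricted maximum likelihood (REML);
clone effects are predicted as BLUPs from the converged fit and passed to the
genomic prediction stage as the response.

Two heritabilities are reported:

- broad-sense `H² = σ²_g / (σ²_g + σ²_r)` from the phenotypic fit, and
- SNP-based `h² = σ²_A / (σ²_A + σ²_R)` from a second REML fit regressing the
  clone BLUPs on the additive genomic relationship matrix G.

### Environment-variance confounding

With block-within-environment fitted as fixed, each environment indicator
column equals the sum of its block dummy columns, i.e. the environment design
matrix lies in the span of the fixed effects. The restricted likelihood is
therefore *exactly flat* in the environment variance: its reported estimate
is arbitrary (typically near zero or near its starting value) and should not
be interpreted. All other components, the BLUPs, and both heritabilities are
unaffected. This is a structural property of the chosen parameterization, not
an estimation failure; the documentation and tests treat the environment
component as non-identifiable.

## 2. REML engine

`cassgs.reml.MixedModel` fits `y = Xβ + Σ_i Z_i u_i + e`, `u_i ~ N(0, K_i σ²_i)`,
by average-information (AI) REML on Henderson's mixed model equations in
natural units, with:

- EM-REML warm-up iterations for stability far from the optimum;
- an active-set AI step that pins components at the lower bound
  (`1e-8·var(y)`) when their gradient points outward;
- a Nelder–Mead polish fallback on the profiled likelihood if AI stalls;
- an exact single-kernel path: with one random effect, the generalized
  eigendecomposition of `Z K Zᵀ` reduces REML to a one-dimensional profile
  likelihood solved by bounded Brent search plus a `brentq` root of the
  analytic score — this path is deterministic to near machine precision and
  underlies the RR-BLUP/G-BLUP equivalence.

Non-positive-definite covariance matrices are rejected with
`NotPositiveDefiniteError`. Kernels entering multi-component AI fits are
stabilized with a `1e-6` diagonal ridge; the single-kernel path instead clips
negative eigenvalues at zero, preserving exact model equivalences.

## 3. Relationship matrices

- **Additive (VanRaden):** `G = Z Zᵀ / (2 Σ p_j (1 − p_j))` with
  `Z = M − 2p` centered at sample allele frequencies. Sample centering makes
  every row of Z sum-orthogonal to the ones vector, so `ΣG = 0` exactly and
  the mean off-diagonal equals `−trace(G)/(n(n−1))`.
- **Dominance (genotypic coding):** dosages {0, 1, 2} map to
  `{−2p², 2pq, −2q²}`; `D = H Hᵀ / (2 Σ p_j q_j (1 − p_j q_j))` by default,
  with the `Σ(2 p_j q_j)²` denominator available as an option. Fractional
  (imputed) dosages are assigned to the nearest genotype class.
- **Gaussian kernel:** `K = exp(−h · d²_ik / p)` on (optionally centered)
  dosages, unit diagonal by construction.

Marker QC removes markers with minor allele frequency below the threshold
and mean-imputes remaining missing dosages (so QC output may contain
fractional dosages; these are accepted everywhere except VCF export, which
requires integer genotype calls).

## 4. Genomic predictors

All seven methods consume the stage-one BLUPs for the training clones and
return predictions for *every* genotyped clone, which is what allows
cross-validation to mask only validation phenotypes:

| method | model | outputs |
|---|---|---|
| `rrblup` | ridge regression on centered dosages, REML shrinkage | GEBV, marker effects |
| `gblup_a` | additive G-BLUP | GEBV |
| `gblup_ad` | additive + dominance G-BLUP (two kernels) | GEBV, dominance values, GETGV |
| `rkhs` | kernel regression on the Gaussian kernel | GETGV |
| `bayes_a` | Gibbs sampler, marker-specific scaled-inverse-χ² variances | posterior-mean GEBV, effects |
| `bayes_b` | as BayesA plus a point mass at zero (π = 0.5) | GEBV, effects, inclusion probabilities |
| `random_forest` | random forest on dosages (out-of-bag for observed clones) | GETGV |

RR-BLUP and additive G-BLUP are algebraically equivalent given the VanRaden
scaling; both use the exact eigen path, so their GEBVs agree to ~1e-14 and
the acceptance suite asserts < 1e-6. The Gibbs samplers are compiled with
numba and are bit-reproducible for a fixed seed.

A note on BayesA versus BayesB under a null response: BayesB's point mass
lets the model empty itself when n > p, driving the GEBV variance far below
the phenotypic variance; BayesA's prior has no point mass, so its null GEBV
variance plateaus around 10–25% of var(y). When p ≥ n, neither sampler can
shrink below that plateau — null-shrinkage checks are therefore only
meaningful on panels with more clones than markers.

## 5. Cross-validation

`evaluation.make_folds` builds balanced random partitions (fold sizes differ
by at most one) per repeat; `cross_validate` masks the validation clones'
responses, refits the predictor on the training clones, and computes
predictive ability as the Pearson correlation between predictions and the
held-out BLUPs. Folds where either side has zero variance are recorded as
undefined (NaN) with a warning rather than silently dropped.

## 6. Selection

Clones are ranked by a weighted index `InS = Σ_t w_t z_t` over trait values
(z-scored by default; weights default to the breeding-program scheme: 20 for
fresh root yield, 15 for dry matter and root number, 10 for starch/harvest
traits, 5 for architecture traits). The selected set at intensity `i%` has
size `round(i/100 · n)` (half rounded up). Reported per trait are the base
mean X0, selected mean XS and selection differential
`SD% = 100 (XS − X0)/|X0|`; when X0 = 0 the absolute differential is reported
and flagged (predicted genetic values are centered near zero, so percentage
differentials are only meaningful on an entry-mean scale, e.g. trait mean +
GETGV). Agreement between selection strategies is Cohen's kappa on the 2×2
selected/not-selected table; kappa is undefined (NaN, with a warning) when
chance agreement is 1.

## 7. Simulation and ground truth

`simulate.simulate_trials` composes phenotypes from the same effects the
stage-one model estimates. Additive clone values are built from a random QTL
subset in centered-dosage coding and rescaled so the *realized* variance hits
the target exactly; dominance values use the genotypic dominance coding,
orthogonalized against the additive part before rescaling, so component
variances and dominance ratios are exact by construction. This makes recovery
tests calibrated regardless of QTL count. Other effects (environment, block,
row, column, GxE, residual) are i.i.d. normal draws at their target
variances. The returned ground truth holds true additive/dominance/total
values, marker effects and realized heritabilities. `simulate.toy_fixture`
is a fully deterministic 8-clone × 6-marker × 2-environment dataset (one
monomorphic marker, hard-coded noise) for exact regression tests.

## 8. Pipeline reproducibility

`pipeline.run_pipeline` spawns one sub-seed per stage from the master seed
via `numpy.random.SeedSequence`, writes every artifact as plain text
(CSV/VCF/JSON), and records SHA-256 checksums plus all parameters in
`manifest.json`. Reruns with the same configuration reproduce every artifact
bit-for-bit; any stage failure aborts with the stage name.
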