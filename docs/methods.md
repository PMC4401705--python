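# Methods

## The model

`wgreg` assesses whole-genome regression (WGR) for a binary disease trait in
a family sample. The outcome is modeled on a latent *liability* scale with a
probit link:

    P(y_i = 1) = Phi(eta_i),
    eta_i = alpha_0 + alpha_1 s_i + alpha_2 c_i + alpha_3 l_i
            + alpha_4 PC1_i + alpha_5 PC2_i + u_i,

where `s` is a female dummy, `c` a cohort (generation) dummy, `l` age at
last contact, `PC1`/`PC2` marker-derived ancestry principal components, and
`u_i` a genomic value built from genome-wide SNP dosages. Fixed effects get
a flat prior, so their posterior means track the maximum-likelihood probit
fit. The residual variance of the liability is fixed at 1 for
identification, which makes the liability-scale genomic heritability

    h2 = sigma_u^2 / (sigma_u^2 + 1),

computed per posterior sample of `sigma_u^2` (mean of ratios, not ratio of
means).

Binary outcomes are handled by truncated-normal data augmentation
(Albert–Chib): liabilities `z_i ~ N(eta_i, 1)` truncated to `(0, inf)` for
cases and `(-inf, 0]` for controls, making every conditional conjugate.
Tail draws are delegated to SciPy's truncated-normal sampler, which is
stable far beyond |eta| = 6.

## Prior families

The genomic term `u_i = sum_j x_cij beta_j` (dosages centered at `2 q_hat_j`)
is modeled under:

- **Bayesian ridge / G-BLUP (marker form)** — one common `sigma2_beta` for
  all markers; equivalent to a Gaussian random effect with covariance
  proportional to the genomic relationship matrix.
- **G-BLUP (GRM form)** — `u ~ N(0, G sigma_u^2)` sampled in the eigenbasis
  of `G` with a pseudo-inverse over near-null eigenvalues. The two forms are
  the same model; the package cross-checks them (posterior-mean genetic
  values correlate > 0.98 on shared data).
- **Bayes A** — per-marker variances under a scaled-inverse-chi-square
  hyper-prior (marginally scaled-t). Because low degrees of freedom are a
  known source of poor mixing, the runner raises `df_beta` to 4 with a
  warning unless overridden, and Geweke z-scores are always reported.
- **Bayes C-pi** — spike-and-slab: point mass `pi` at zero plus a
  common-variance Gaussian slab. Inclusion is sampled from the marginal odds
  with the effect integrated out; `pi` carries a Beta prior parameterized as
  (prior probability, prior counts) = (0.5, 10). Note the convention: `pi`
  is the *null* mass, so the proportion of markers with signal is `1 - pi`.
- **Bayesian LASSO** — double-exponential prior as a scale mixture of
  normals: `1/tau2_j ~ inverse-Gaussian(sqrt(lambda2/beta_j^2), lambda2)`,
  `lambda2 ~ Gamma(shape 0.55, rate 1e-4)`.

Marker sweeps update effects in fixed column order through numba kernels;
all randomness is pre-generated from a single NumPy `Generator`, so entire
chains are bit-reproducible from one seed.

### Hyperparameter rule

Scaled-inverse-chi-square priors use df = 5 and a scale solved so the prior
*mean* of the genomic variance equals `R2/(1 - R2)` with `R2 = 0.5` of the
unit-residual liability variance; marker-level scales divide by
`2 sum q_j (1 - q_j)` (and by the expected non-null share for the Bayes C-pi
slab). These are the conventional treatment-of-variance defaults when no
problem-specific prior is available.

**Consequence worth knowing:** a scaled-inverse-chi-square prior excludes a
neighborhood of zero (with df = 5 and prior mean 1, the prior probability of
`sigma_u^2 < 0.1` is about 1e-5). On a cohort simulated with *zero*
heritability (n = 1,000 binary observations, p = 2,000 markers), the
marginal likelihood of `sigma_u^2` is only ~9 log units below its optimum at
`sigma_u^2 = 0.2`, so the posterior mean lands near h2 ≈ 0.2 rather than
near zero — and this is the genuine posterior, not a sampler artifact: the
Gibbs chain reproduces an exactly integrated 1-D posterior for the
identity-link GRM model to three decimals. Null-heritability inference at
this sample size is prior-dominated; a user who needs it should supply a
weaker variance prior (`scale_u` / `scale_beta`) explicitly.

Similarly, `pi` in Bayes C-pi is weakly identified: the marginal likelihood
is nearly flat along the ridge `sigma2_beta * (1 - pi) ~ const`, so on a
10%-non-null architecture at n = 1,000 the posterior of `1 - pi` typically
sits in the 0.3–0.6 range instead of concentrating at 0.10. This mirrors the
diffuse non-null fractions reported for complex binary traits in family
samples.

## Genomic relationship matrix

`G = Xc Xc' / (2 sum q_j (1 - q_j))` on frequency-centered dosages
(VanRaden scaling): unit expected diagonal under equilibrium, off-diagonals
estimating twice the kinship (0.5 for parent–offspring and full sibs).
Frequencies are re-estimated from the analysis sample. An `as-printed`
variant additionally divides by n, for fidelity with a published formula
that carries the factor; it is not the default because it would shrink
relationships toward zero as the sample grows.

## Synthetic cohorts

The generator emulates a two-generation family study of a common late-onset
disease: nuclear families (two founders plus full sibs), founder alleles at
frequencies uniform on [0.05, 0.5], offspring genotypes by gene dropping,
sex ~ Bernoulli(0.55 female), cohort = generation, age at last contact
uniform on [34, 104], case prevalence targeted at 939/5245 ≈ 0.179, and
liability-scale covariate effects sex −0.26, cohort −0.40, age +0.016/year —
the magnitudes typical of such cohorts. Age enters the simulated liability
centered; the fitted intercept absorbs the difference.

Design choices:

- Markers are in linkage equilibrium among founders; familial co-segregation
  is the only source of genotype correlation. Chromosome-block LD is outside
  the default generator.
- The liability threshold is fixed at 0 and the intercept solved by
  bisection on Phi (tolerance 1e-6) so expected prevalence matches the
  target.
- Non-null effects are Gaussian, then rescaled so the *realized* sample
  variance of the genetic value equals `h2/(1-h2)` exactly — exact control
  of the simulated heritability at any n (the marginal effect distribution
  is conditioned by this; recovery tests care about the realized variance).

What the generator does **not** emulate: LD with ungenotyped causal
variants, ascertainment, genotyping error, longitudinal exams, shared
family environment. Passing recovery tests therefore show the samplers are
correct for the stated generative model, not that real-data heritability
estimates are unbiased.

## Quality control and imputation

Markers are removed when MAF < 0.05 or missingness > 10% (both strict, MAF
from observed calls, matching the order filter-then-impute). Missing
dosages are then mean-imputed (`2 q_hat_j`), which preserves allele
frequencies; reference-panel imputation is out of scope, so fractional
dosages only arrive via the TSV format. A uniform random marker
down-sampler reproduces the common practice of halving a platform for
compute reasons.

## Cross-validation and evaluation

Because relatives share large genomic segments, subject-level folds leak
signal. Entire families are shuffled with a seed and assigned greedily to
the currently smallest fold (k = 10 by default): folds partition subjects,
no family is split, and sizes are balanced up to the largest family. For
each fold, the held-out linear predictor combines posterior-mean fixed
effects with posterior-mean marker effects applied to held-out dosages
centered at the *training* allele frequencies; GRM-form G-BLUP is refit in
the marker (BRR) parameterization so held-out subjects need no retraining.

AUC is the Mann–Whitney pair statistic (ties 1/2), computed by midranks and
verified against O(n^2) pair enumeration in tests. Fold-level AUCs are
summarized as mean ± SD across folds; the pooled-score AUC is also
reported. Probit coefficients are converted to odds ratios as `exp(beta)`,
labeled an approximation for liability-scale effects.

## Numerical choices

- Gibbs scan order is the fixed marker order (a per-iteration permutation
  exists but is off by default for reproducibility); thinning defaults to 5.
- Partial residuals are updated in place and refreshed against float drift
  every 1,000 iterations.
- GRM eigenvalues are clipped at zero; eigenvalues below 1e-8 are treated
  as null space in the `sigma_u^2` update.
- Convergence is monitored by a Geweke-style z-score per variance parameter
  (first 10% vs last 50%, Bartlett-windowed spectral variances) as an
  automated stand-in for visual trace inspection; traces are exported.
- Production chain defaults are 40,000 iterations with 15,000 burn-in.
  Tests and the acceptance script use desk-scale sizes chosen for a single
  CPU: cohorts of 600–1,000 subjects, 500–2,000 markers, chains of
  1,200–10,000 iterations — large enough that every stationary quantity
  checked is stable at the asserted tolerance.

## Known limitations

- Liability-variance components from binary data at n ~ 1,000 are weakly
  identified; results at that scale are sensitive to the variance prior
  (see above).
- Mean imputation understates genotype uncertainty relative to
  reference-panel imputation.
- The probit-coefficient-to-odds-ratio conversion `exp(beta)` is exact only
  for logit models; it is reported because it reproduces conventional
  tables, with the caveat attached in the report layer.
- No dominance/epistasis, no multi-trait models, no alternative links.
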