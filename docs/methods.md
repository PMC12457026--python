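# Methods

`traitvar` analyses how dietary stress shifts both the mean and the
variance of traits across two generations in a clonal (parthenogenetic)
factorial design, and asks which cross-generational transfer strategy the
joint mean/variance pattern supports. This note records the models, the
defaults and why they are set where they are, the numerical choices, and
what the synthetic-data tests do and do not establish.

## The design

Eight clonal genotypes are split across three diet sequences — AA
(high-quality algae in both generations), CA (low-quality cyanobacteria for
the mothers, algae for the daughters) and CC (cyanobacteria in both) — with
roughly 15 animals per clone x treatment in each of two generations (G2
mothers, G3 daughters), about 120 animals per treatment x generation cell
and ~711 of 720 design slots surviving to measurement. Eye size and body
size (mm) are measured at 132 +/- 12 h of age; reproductive output is the
offspring count over the first three clutches. Each treatment x generation
cell maps to a parental:current environment pair (algae = benign,
cyanobacteria = stressed; G2 animals have parental environment "none"
because their mothers were raised in a common garden).

## Heteroscedastic linear mixed model

For trait value `y_i` in clone `c(i)` and variance group `g(i)`:

    y_i = x_i' b + u_{c(i)} + e_i,   u_c ~ N(0, s2_u),   e_i ~ N(0, s2_{g(i)})

Fixed effects are treatment, generation, their interaction (the six-cell
means model in reference coding, checked for rank, never assumed) and — for
the morphological traits only — age, centred at 132 h so cell means are
interpretable at the design age. The clone intercept is shared across all
of a clone's cells, mirroring the split-clone design.

Four residual-variance structures are entertained: constant (1 parameter),
by generation (2), by treatment (3) and by treatment x generation (6).
Estimation profiles the fixed effects out by GLS and maximises the ML or
REML log-likelihood over log-variances with L-BFGS-B, an analytic score
(gradient), and three deterministic starts (moment-based, pooled, and a
perturbed moment start) to avoid boundary traps. Per-clone covariance
blocks `D_c + s2_u 11'` are handled with the Sherman–Morrison and
matrix-determinant identities, so one likelihood evaluation costs O(n p).
After the optimiser stops, the overall variance scale is polished with its
closed-form optimum (quad/(n−p) under REML), which is what lets the
clone-free constant-variance fit agree with closed-form OLS/REML to 1e−8.

REML is the default (matching the convention of the standard mixed-model
fitters in this area); ML is available by flag. Likelihood-ratio tests
between variance structures are valid under REML here because all
candidates share identical fixed effects. Selection takes the lowest-AIC
structure (AIC = −2 logLik + 2 (p + 1 + k), counting fixed effects, the
clone variance and the k residual variances; ties within 1e−9 go to the
smaller model) and then demotes to the simplest nested structure whose LRT
against the AIC winner is not significant (p > 0.05). The full comparison
trace is recorded on the selection object and in the pipeline run log,
including the estimation method, since AIC conventions (ML vs REML, whether
fixed effects are counted) differ between tools.

Numerical details worth knowing:

* variances are optimised on the log scale with bounds ~[1e−12, e^12] x
  var(y); a clone variance that lands within 10x of the lower bound is
  reported as exactly 0 (boundary estimate; no p-value correction is
  applied for it);
* the convergence flag is a relative gradient criterion
  (1e−6 x max(1, |objective|)): at n ~ 700 the objective is O(10^3) and the
  line search stalls at the objective's machine-precision floor even at the
  true optimum;
* noise-free input (all within-cell residuals exactly zero) short-circuits
  to the OLS solution with zero variances rather than letting log-variances
  diverge; contrasts on such a fit return t = 0 and p = 1 when estimates
  are zero;
* a singular fixed-effect design raises an error naming the aliased
  columns (e.g. a treatment arm entirely absent).

The likelihood code is verified two independent ways: a brute-force dense
n x n covariance evaluation of the same (restricted) likelihood, and
`nlme::lme` with `varIdent` weights through Rscript on a seeded fixture.

## Inference

**Fixed-effect tests** are marginal (Type II) Wald chi-squares: treatment,
generation and age are tested in a refit without the interaction; the
interaction in the full model. Type II is the right default when main
effects are to be reported alongside a significant interaction.

**Cell-mean contrasts**: all 15 pairwise differences of the six model-based
cell means (at 132 h), with SEs from the GLS covariance and df = n −
rank(X). Multiplicity adjustment over the full 15-pair family uses the
studentized-range (Tukey HSD) distribution; because heteroscedastic cells
make the equal-variance assumption of the classical procedure approximate,
a correlation-aware Monte-Carlo max-|t| adjustment (`adjust="mvn"`) is
available and the method used is recorded per table. Adjusted p-values are
clamped to be at least the unadjusted ones. No Satterthwaite or
Kenward–Roger df approximation is applied; df = n − rank(X) is a documented
simplification consistent with the reported df convention.

**Variance CIs** are Wald intervals on log sigma^2 — `[v e^{−zs}, v e^{+zs}]`
with `s` from the observed information (central-difference Hessian of the
REML objective over all log-variance parameters) — hence asymmetric around
the estimate, matching how group variances with ~95% CIs are conventionally
reported. A group at the zero boundary yields a one-sided interval with a
warning.

**Bayesian variance ratio**: for two groups of residuals under Gaussian
models with unknown means and independent Jeffreys priors p(mu, s2) ~ 1/s2,
each variance is a posteriori scaled-inverse-chi-square; the ratio is
summarised from seeded Monte-Carlo draws (default 1e5): posterior mean, 95%
credible interval and P(ratio < 1). The prior is a declared convention
(user-facing output records it); no sampler is needed because the posterior
is exact.

## Heritability

Broad-sense heritability with a genotype-by-environment component comes
from a mixed model with independent random intercepts for clone and
clone x environment plus the trait's fixed effects:

    H2 = (s2_clone + s2_clone_env) / (s2_clone + s2_clone_env + s2_res)

with the clone x environment share reported separately (`H2_GxE`). The
"environment" in the interaction is not uniquely determined by the design:
the dietary treatment (AA/CA/CC, pooled over generations) is the default,
and the full treatment x generation cell is available by flag; both are
legitimate readings and can differ materially, so the choice is always
printed with the result. Estimation uses REML over three log-variances
with dense per-clone covariance blocks; components at the boundary are
reported as 0, and unreplicated clone x environment cells are an error
(the interaction and residual components would be inseparable). H2 is
invariant to affine rescaling of the trait.

## Mechanism framework and classifier

Three cross-generational strategies predict signed shifts of the offspring
generation's mean and variance relative to the parental generation, per
parental:current condition:

| condition          | condition transfer | anticipatory | bet-hedging |
|--------------------|--------------------|--------------|-------------|
| benign : benign    | mean =, var +      | mean =, var +| mean =, var =|
| stressed : benign  | mean +, var −      | mean =, var =| mean =, var +|
| stressed : stressed| mean −, var −      | mean +, var +| mean =, var −|

The adjusted variance for condition i is `E_P(i) E_C(i) + M_i s`, with
`M_i` in {−1, 0, +1} the mechanism's modulation and `s` the additive
within-generation stress shift. The configurable parameter is the additive
shift itself (default 0.2 on a unit baseline); a reading in which the
quoted stress response is the square root of the shift is expressible by
passing its square. `E_P`/`E_C` default to 1 (benign) and `1 − s`
(stressed) — stress is assumed to reduce within-generation variance — and
both maps are user-overridable since their numeric values under stress are
a convention, not an observation. Three null hypotheses of variance
determination are provided: current environment only, parental only, and
their equal-weight product; with `s = 0` every mechanism collapses to the
interaction null.

The classifier turns observed G2→G3 shifts (mean delta and variance delta
with SEs, per treatment) into signs — '=' when the (1 − alpha) CI covers
zero, alpha defaulting to 0.05 — and scores each mechanism by matched cells
out of 6 (3 conditions x 2 moments). A match count rather than a likelihood
is deliberate: the framework's predictions are directional only, and the
per-cell sign table is reported so partial matches can be inspected. Ties
are reported as ties. In the pipeline, shifts come from the
treatment x generation-structured fit: mean deltas from the cell-means GLS,
variance deltas from per-cell variance estimates with log-scale
delta-method SEs.

## Synthetic data

The generator draws each trait as grand mean + cell offset + clone
intercept (+ clone x treatment intercept where configured) + age slope x
(age − 132) + a cell-specific Gaussian residual; age is Normal(132, 6^2)
truncated to [120, 144] (the stated 132 +/- 12 h read as a range).
Generations are independent samples with cell-specific parameters — no
explicit mother-daughter pedigree — because every downstream statistic
conditions only on cell and clone labels; a pedigree would add structure
nothing here can test. Reproduction is Gaussian, rounded and floored at
zero rather than Poisson: the analyses treat counts with the same Gaussian
machinery as morphology, and a Poisson generator would weld variance to
mean, precluding exactly the mean/variance decoupling under study (a
Poisson option exists for robustness experiments). Optional i.i.d. record
dropout (1.25% under `default_config(attrition=True)`) emulates the
attrition from 720 design slots to ~711 animals; nothing suggests
differential mortality, so dropout is treatment-blind.

Default trait parameters are set once from the study's printed summaries:
cell mean offsets from the reported pairwise contrast estimates (eye
contrasts of 0.006–0.021 mm, body 0.02–0.36 mm, reproduction counts ~18–32
per cell); residual sds per cell realising the reported variance patterns
(eye variance higher by treatment with consistent algae ~47% above
consistent cyanobacteria; body variance ~37% higher in G3; reproduction
variances ~106 under algae vs ~46 under cyanobacteria with the
released-from-stress G3 cell the most variable); clone-level variances
backed out of the reported broad-sense heritabilities (0.19 eye, 0.29 body,
0.17 reproduction, of which a G x E share of 0.15 is carried by a
clone x treatment intercept for reproduction only). Mechanism-driven
generation rewrites cell variances via the adjusted-variance model relative
to each trait's baseline and steps G3 means by sign x effect x baseline-sd
following the prediction matrix.

What passing simulation tests show: the estimators recover what the
generator planted, at the design's scale, under Gaussian noise and the
design's balance. What they do not show: robustness to non-Gaussian tails,
informative missingness, measurement error correlated across traits, or
pedigree effects — none of which the generator emulates.

## Problem sizes used in the checked studies

Simulation studies in the test suite use the design scale (8 clones x 15
per clone x treatment x 6 cells = 720) unless stated: LRT type-I
calibration 1000 replicates; structure recovery 200 replicates per
scenario (homoscedastic, and 3x by-treatment variance ratio); heritability
recovery 200 replicates at components (1, 1, 2); classifier recovery 100
replicates per mechanism at ~2000 animals per cell; variance-CI coverage
~1000 intervals at 120 observations per group; posterior checks at 150
observations per group. These sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping the suite quick.

## Known limitations

* Variance-structure LRTs use the chi-square reference without boundary
  corrections; the clone variance may sit at 0 and its uncertainty is not
  propagated into fixed-effect df.
* The Tukey adjustment treats the 6 cell means as exchangeable even under
  heteroscedasticity unless `adjust="mvn"` is chosen.
* The classifier discretises evidence at a single alpha; near-threshold
  shifts flip signs discontinuously.
* Heritability assumes independent, homoscedastic residuals within the
  component model even when the selected mean-model structure was
  heteroscedastic.
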