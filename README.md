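# traitvar

Joint **mean-and-variance** analysis of intergenerational dietary stress in
clonal factorial designs.

Environmental stress shifts not only trait means but also trait variances,
and the two can move independently. In a split-clone *Daphnia* experiment —
eight clonal genotypes, two generations (G2 mothers, G3 daughters), three
diet sequences (AA algae/algae, CA cyanobacteria/algae, CC
cyanobacteria/cyanobacteria), eye size, body size and reproductive output
measured per animal — the question is which cross-generational strategy the
joint pattern of mean and variance shifts supports: **condition transfer**
(maternal provisioning sets offspring phenotype), **anticipatory
plasticity** (mothers prime daughters for the predicted environment), or
**diversified bet-hedging** (variance inflated under unpredictability).

`traitvar` implements the full analysis chain for that question, for
biostatisticians and evolutionary ecologists working with clonal designs:

* **Heteroscedastic linear mixed models**:
  `y = Xb + u_clone + e`, with residual variance constant or varying by
  treatment, generation, or treatment x generation cell; REML/ML with
  profiled GLS fixed effects, selected by AIC with likelihood-ratio-test
  demotion to the simplest adequate structure.
* **Inference**: Type II Wald chi-square tests per fixed-effect term;
  Tukey-adjusted pairwise contrasts of the six cell means; per-group
  variance estimates with log-scale Wald CIs; a Bayesian two-group
  variance-ratio posterior (Jeffreys prior, scaled-inverse-chi-square).
* **Broad-sense heritability** with a genotype-by-environment share:
  `H2 = (s2_clone + s2_clone_env) / (s2_clone + s2_clone_env + s2_res)`.
* **Mechanism framework**: the adjusted-variance model
  `s2_i = E_P(i) E_C(i) + M_i s` per parental:current condition, the three
  mechanisms' sign-prediction matrices, three variance-determination nulls,
  and a classifier scoring observed G2->G3 mean/variance shifts against
  each mechanism (0-6 matched cells).
* **Seeded synthetic data** faithful to the study design (720 design
  slots, age 132 +/- 12 h, clone intercepts, per-cell means and variances,
  optional attrition and mechanism-driven generation).

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```bash
traitvar simulate --seed 1 --out demo.csv
traitvar select --data demo.csv --trait reproduction
```

```
fit constant: logLik=-2625.324930 AIC=5266.649860 params=8 converged=True method=REML
fit by_generation: logLik=-2612.721611 AIC=5243.443223 params=9 converged=True method=REML
fit by_treatment: logLik=-2605.462945 AIC=5230.925890 params=10 converged=True method=REML
fit by_treatment_generation: logLik=-2584.994509 AIC=5195.989019 params=13 converged=True method=REML
lowest AIC: by_treatment_generation (AIC=5195.989019)
LRT constant vs by_treatment_generation: stat=80.6608 df=5 p=6.104e-16
...
chosen: by_treatment_generation
```

Reproduction needs a different residual variance in every treatment x
generation cell (the interaction structure): the homoscedastic model is
rejected at p ~ 1e-16 and AIC drops by ~70. That is the signature of
variance responding to the diet sequence itself, not just to the current
diet.

```bash
traitvar heritability --data demo.csv --trait reproduction
```

```
trait: reproduction (environment = treatment)
sigma2_clone:     8.88645
sigma2_clone_env: 10.8782
sigma2_residual:  79.1489
H2:    0.1998
H2_GxE: 0.1100
```

About 20% of reproductive variance is genotypic, and more than half of
that genotypic share is genotype-by-diet interaction — clones rank
differently under different diets.

```bash
traitvar classify --data demo.csv --trait eye_size
```

```
"scores": {"condition_transfer": 3, "anticipatory": 2, "bet_hedging": 2},
"top": ["condition_transfer"]
```

The observed signs (mean up when released from maternal stress, mean down
under continued stress) match the condition-transfer row of the prediction
table best.

`traitvar report --data demo.csv --out report/ --seed 1` runs everything —
structure selection, fixed-effect tests, contrasts, variance CIs,
heritability, classification, and the variance-ratio posterior for the two
benign-diet G3 cells — writing one CSV per table plus `run_log.json` with
the seed, config and full selection traces. The same pipeline is available
in Python via `traitvar.run_pipeline(PipelineConfig(...))`.

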