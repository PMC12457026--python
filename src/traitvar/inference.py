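"""Fixed-effect tests, cell-mean contrasts, variance intervals and the
Bayesian variance-ratio comparison.

* Wald chi-square tests per fixed-effect term (marginal / Type II: main
  effects are tested in the model without the interaction, the interaction
  in the full model).
* All 15 pairwise contrasts of the six treatment x generation cell means,
  with Tukey HSD (studentized range) multiplicity adjustment over the full
  family, or a correlation-aware multivariate-normal Monte-Carlo adjustment
  for strongly unbalanced standard errors.
* Per-group residual-variance point estimates with 95% Wald intervals on the
  log-variance scale (exponentiated, hence asymmetric around the estimate).
* A two-group variance-ratio posterior under independent Jeffreys priors on
  Gaussian models with unknown means: each variance is scaled-inverse-
  chi-square a posteriori and the ratio is summarised by Monte-Carlo draws.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import TraitDataset, cell_label
from .lmm import FittedLMM, ModelSpec, design_matrix, _group_codes

#: Table-style report order: the 10 within/between-cell pairs of interest
REPORT_PAIRS = (
    ("AA G2", "CA G2"),
    ("AA G2", "CC G2"),
    ("AA G2", "AA G3"),
    ("AA G2", "CA G3"),
    ("CA G2", "CC G2"),
    ("CA G2", "CA G3"),
    ("CC G2", "CC G3"),
    ("AA G3", "CA G3"),
    ("AA G3", "CC G3"),
    ("CA G3", "CC G3"),
)

_TERM_COLUMNS = {
    "treatment": ("T[CA]", "T[CC]"),
    "generation": ("G[G3]",),
    "age": ("age_c",),
    "interaction": ("T[CA]:G[G3]", "T[CC]:G[G3]"),
}


@dataclass(frozen=True)
class FixedEffectTest:
    term: str
    chi2: float
    df: int
    p: float


def _wald_block(fit: FittedLMM, cols: tuple[str, ...]) -> FixedEffectTest | None:
    idx = [fit.x_names.index(c) for c in cols if c in fit.x_names]
    if not idx:
        return None
    b = fit.beta[idx]
    cov = fit.beta_cov[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(cov, b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"rank-deficient covariance block for term columns {cols}"
        ) from exc
    chi2 = max(chi2, 0.0)
    df = len(idx)
    return FixedEffectTest("", chi2, df, float(stats.chi2.sf(chi2, df)))


def wald_tests(fit: FittedLMM, data: TraitDataset) -> list[FixedEffectTest]:
    """Marginal (Type II) Wald chi-square tests of the fixed-effect terms.

    The interaction is tested in the supplied (full) fit; treatment,
    generation and age are tested in a refit without the interaction under
    the same variance structure, per the Type II convention of reporting
    main effects averaged over the interaction.
    """
    if not fit.converged:
        raise ValueError("Wald tests require a converged fit")
    results: list[FixedEffectTest] = []
    additive = _fit_additive(data, fit.spec)
    for term in ("treatment", "generation", "age"):
        res = _wald_block(additive, _TERM_COLUMNS[term])
        if res is not None:
            results.append(FixedEffectTest(term, res.chi2, res.df, res.p))
    res = _wald_block(fit, _TERM_COLUMNS["interaction"])
    if res is not None:
        results.append(FixedEffectTest("interaction", res.chi2, res.df, res.p))
    return results


def _fit_additive(data: TraitDataset, spec: ModelSpec) -> FittedLMM:
    """Refit without the interaction columns (same variance structure)."""
    from . import lmm as _lmm
    import pandas as pd

    X, y, names, sub = design_matrix(data, spec)
    keep = [i for i, nm in enumerate(names) if nm not in _TERM_COLUMNS["interaction"]]
    clone = pd.Categorical(sub["clone_id"]).codes.astype(np.int64)
    group, labels = _group_codes(sub, spec.variance_structure)
    md = _lmm._ModelData(
        X[:, keep], y, clone, group, len(labels), labels, [names[i] for i in keep]
    )
    return _lmm._fit_model_data(md, spec)


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    se: float
    df: int
    t_ratio: float
    p_adjusted: float
    p_unadjusted: float
    in_report: bool  # one of the 10 table-ordered pairs


def cell_contrasts(fit: FittedLMM, adjust: str = "tukey", seed: int = 0) -> list[ContrastResult]:
    """All 15 pairwise differences of the model-based cell means.

    Means are evaluated at the 132 h design age; SEs come from the GLS
    covariance of the fixed effects; ``adjust`` is ``'tukey'`` (studentized
    range over the 6 means), ``'mvn'`` (Monte-Carlo max-|t| under the
    estimated contrast correlation) or ``'none'``.
    """
    if adjust not in ("tukey", "mvn", "none"):
        raise ValueError(f"unknown adjustment method {adjust!r}")
    L, labels = fit.cell_mean_matrix()
    means = L @ fit.beta
    cov = L @ fit.beta_cov @ L.T
    pairs = list(itertools.combinations(range(len(labels)), 2))
    df = fit.df_resid

    ests, ses, tvals = [], [], []
    for i, j in pairs:
        est = float(means[i] - means[j])
        var = float(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        se = float(np.sqrt(max(var, 0.0)))
        t = 0.0 if est == 0.0 else (np.inf * np.sign(est) if se == 0.0 else est / se)
        ests.append(est)
        ses.append(se)
        tvals.append(t)

    abs_t = np.abs(tvals)
    p_unadj = 2.0 * stats.t.sf(abs_t, df)
    if adjust == "none":
        p_adj = p_unadj.copy()
    elif adjust == "tukey":
        p_adj = stats.studentized_range.sf(abs_t * np.sqrt(2.0), len(labels), df)
    else:  # mvn: max-|t| reference from the contrast correlation structure
        C = np.array([_pair_row(i, j, len(labels)) for i, j in pairs])
        S = C @ cov @ C.T
        d = np.sqrt(np.diag(S))
        d[d == 0] = 1.0
        R = S / np.outer(d, d)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(np.zeros(len(pairs)), R, size=20000,
                                        method="eigh")
        chi = np.sqrt(rng.chisquare(df, size=20000) / df)
        maxt = np.max(np.abs(draws), axis=1) / chi
        p_adj = np.array([float(np.mean(maxt >= t)) for t in abs_t])
    p_adj = np.minimum(np.maximum(p_adj, p_unadj), 1.0)

    report_set = {frozenset(p) for p in REPORT_PAIRS}
    out = []
    for (i, j), est, se, t, pa, pu in zip(pairs, ests, ses, tvals, p_adj, p_unadj):
        lab_i, lab_j = labels[i], labels[j]
        out.append(
            ContrastResult(
                label=f"{lab_i} - {lab_j}",
                estimate=est,
                se=se,
                df=df,
                t_ratio=float(t) if np.isfinite(t) else float(t),
                p_adjusted=float(pa),
                p_unadjusted=float(pu),
                in_report=frozenset((lab_i, lab_j)) in report_set,
            )
        )
    return out


def _pair_row(i: int, j: int, k: int) -> np.ndarray:
    row = np.zeros(k)
    row[i], row[j] = 1.0, -1.0
    return row


@dataclass(frozen=True)
class VarianceEstimate:
    group: str
    sigma2: float
    ci_low: float
    ci_high: float
    se_log: float
    one_sided: bool = False


def variance_cis(fit: FittedLMM, level: float = 0.95) -> list[VarianceEstimate]:
    """Per-group residual-variance estimates with Wald intervals on the
    log-variance scale: [v * exp(-z s), v * exp(+z s)] with s the standard
    error of log sigma^2 from the observed information."""
    if not fit.converged:
        raise ValueError("variance CIs require a converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    cov, names = fit.logvar_cov()
    out = []
    for g, v in fit.residual_variances.items():
        i = names.index(g)
        se = float(np.sqrt(max(cov[i, i], 0.0)))
        if v <= 0 or not np.isfinite(se) or se == 0:
            warnings.warn(f"variance group {g!r} at boundary; one-sided interval")
            out.append(VarianceEstimate(g, v, 0.0, v, np.nan, one_sided=True))
            continue
        out.append(
            VarianceEstimate(
                g, v, v * float(np.exp(-z * se)), v * float(np.exp(z * se)), se
            )
        )
    return out


@dataclass(frozen=True)
class VarianceRatioPosterior:
    ratio_mean: float
    cri_low: float
    cri_high: float
    p_less_than_1: float
    n_draws: int
    seed: int
    prior: str = "jeffreys"


def variance_ratio_posterior(
    group_a: np.ndarray,
    group_b: np.ndarray,
    prior: str = "jeffreys",
    n_draws: int = 100_000,
    seed: int = 0,
    level: float = 0.95,
) -> VarianceRatioPosterior:
    """Posterior of var(A)/var(B) for two independent Gaussian samples.

    Under the Jeffreys prior p(mu, sigma^2) ~ 1/sigma^2, each variance is a
    posteriori scaled-inverse-chi-square: (n-1) s^2 / sigma^2 ~ chi2(n-1).
    The ratio is summarised from seeded Monte-Carlo draws.
    """
    if prior != "jeffreys":
        raise ValueError(f"unknown prior {prior!r}; only 'jeffreys' is implemented")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need >= 3 observations")
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10000")
    sa2, sb2 = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if sa2 <= 0 or sb2 <= 0:
        raise ValueError("degenerate group with zero variance")
    rng = np.random.default_rng(seed)
    na, nb = len(a) - 1, len(b) - 1
    va = na * sa2 / rng.chisquare(na, n_draws)
    vb = nb * sb2 / rng.chisquare(nb, n_draws)
    ratio = va / vb
    lo_q, hi_q = (1 - level) / 2.0, 1 - (1 - level) / 2.0
    return VarianceRatioPosterior(
        ratio_mean=float(np.mean(ratio)),
        cri_low=float(np.quantile(ratio, lo_q)),
        cri_high=float(np.quantile(ratio, hi_q)),
        p_less_than_1=float(np.mean(ratio < 1.0)),
        n_draws=n_draws,
        seed=seed,
    )


def observed_shifts(fit: FittedLMM):
    """G2 -> G3 mean and variance shifts per treatment from a fit with the
    full treatment x generation variance structure, for the mechanism
    classifier.  Mean deltas and SEs come from the cell-means GLS; variance
    deltas use the per-cell variance estimates with log-scale delta-method
    SEs."""
    from .mechanisms import MomentShift

    if fit.spec.variance_structure != "by_treatment_generation":
        raise ValueError("observed_shifts needs the by_treatment_generation structure")
    L, labels = fit.cell_mean_matrix()
    means = L @ fit.beta
    cov = L @ fit.beta_cov @ L.T
    vcov, vnames = fit.logvar_cov()
    shifts = {}
    for trt in ("AA", "CA", "CC"):
        i2, i3 = labels.index(cell_label(trt, "G2")), labels.index(cell_label(trt, "G3"))
        mean_delta = float(means[i3] - means[i2])
        mean_se = float(
            np.sqrt(max(cov[i3, i3] + cov[i2, i2] - 2 * cov[i3, i2], 0.0))
        )
        v2 = fit.residual_variances[cell_label(trt, "G2")]
        v3 = fit.residual_variances[cell_label(trt, "G3")]
        j2, j3 = vnames.index(cell_label(trt, "G2")), vnames.index(cell_label(trt, "G3"))
        var_var = (
            v3**2 * max(vcov[j3, j3], 0.0)
            + v2**2 * max(vcov[j2, j2], 0.0)
            - 2 * v2 * v3 * vcov[j2, j3]
        )
        shifts[trt] = MomentShift(
            mean_delta=mean_delta,
            mean_se=mean_se,
            var_delta=float(v3 - v2),
            var_se=float(np.sqrt(max(var_var, 0.0))),
        )
    return shifts
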