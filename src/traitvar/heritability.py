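"""Broad-sense heritability with a genotype-by-environment component.

In a clonal design the total genotypic variance splits into a clone main
effect and a clone-by-environment interaction.  Fitting a Gaussian mixed
model with independent random intercepts for clone and clone x environment
(plus the trait's usual fixed effects) gives the decomposition

    H2      = (s2_clone + s2_clone_env) / (s2_clone + s2_clone_env + s2_res)
    H2_GxE  =  s2_clone_env             / (s2_clone + s2_clone_env + s2_res)

``environment`` may be the dietary treatment (AA/CA/CC, pooled over
generations, the default) or the full treatment x generation cell; the two
definitions can differ materially, so both are reported when they do.

The covariance of a clone's observations is s2_clone + s2_clone_env * [same
environment] + s2_res * [same animal]; estimation maximises the REML (or
ML) likelihood over the three log-variances with dense per-clone blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import TraitDataset
from .lmm import ModelSpec, _check_rank, design_matrix

_LOG2PI = np.log(2.0 * np.pi)

ENVIRONMENT_DEFS = ("treatment", "generation", "cell")


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    environment: str
    sigma2_clone: float
    sigma2_clone_env: float
    sigma2_residual: float
    loglik: float
    converged: bool

    @property
    def H2(self) -> float:
        tot = self.sigma2_clone + self.sigma2_clone_env + self.sigma2_residual
        return (self.sigma2_clone + self.sigma2_clone_env) / tot

    @property
    def H2_GxE(self) -> float:
        tot = self.sigma2_clone + self.sigma2_clone_env + self.sigma2_residual
        return self.sigma2_clone_env / tot


def plugin_h2(sigma2_clone: float, sigma2_clone_env: float, sigma2_residual: float) -> float:
    """The heritability formula applied to known components."""
    tot = sigma2_clone + sigma2_clone_env + sigma2_residual
    if tot <= 0:
        raise ValueError("total variance must be positive")
    return (sigma2_clone + sigma2_clone_env) / tot


def _env_labels(sub: pd.DataFrame, environment: str) -> pd.Series:
    if environment == "treatment":
        return sub["treatment"].astype(str)
    if environment == "generation":
        return sub["generation"].astype(str)
    if environment == "cell":
        return sub["treatment"].astype(str) + " " + sub["generation"].astype(str)
    raise ValueError(
        f"unknown environment definition {environment!r}; expected one of {ENVIRONMENT_DEFS}"
    )


def fit_components(
    data: TraitDataset,
    trait: str,
    environment: str = "treatment",
    method: str = "REML",
) -> HeritabilityResult:
    """Estimate (s2_clone, s2_clone_env, s2_residual) and the derived H2.

    Requires >= 2 clones, >= 2 environment levels, and replication within
    every clone x environment combination (otherwise the interaction and
    residual components are inseparable).
    """
    spec = ModelSpec(trait=trait, variance_structure="constant", method=method)
    X, y, x_names, sub = design_matrix(data, spec)
    _check_rank(X, x_names)
    clone = pd.Categorical(sub["clone_id"]).codes
    env = _env_labels(sub, environment).reset_index(drop=True)
    ce = pd.Categorical(pd.Series(clone).astype(str) + "|" + env)
    if len(np.unique(clone)) < 2:
        raise ValueError("need >= 2 clones")
    if env.nunique() < 2:
        raise ValueError("need >= 2 environment levels")
    counts = pd.Series(ce.codes).value_counts()
    if (counts < 2).any():
        raise ValueError(
            "unreplicated clone x environment cells; components are inseparable"
        )

    n, p = X.shape
    # per-clone dense blocks: indicator products for the two random terms
    order = np.argsort(clone, kind="stable")
    Xs, ys = X[order], y[order]
    clone_s, ce_s = clone[order], ce.codes[order]
    blocks = []
    for c in np.unique(clone_s):
        idx = np.where(clone_s == c)[0]
        same_env = (ce_s[idx][:, None] == ce_s[idx][None, :]).astype(float)
        blocks.append((Xs[idx], ys[idx], same_env))

    var_y = float(np.var(y))
    lo, hi = np.log(var_y * 1e-10), np.log(var_y) + 8.0

    def nll(phi):
        s2c, s2ce, s2r = np.exp(phi)
        logdetV = 0.0
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        for Xb, yb, same_env in blocks:
            nb = len(yb)
            V = s2c + s2ce * same_env + s2r * np.eye(nb)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e300
            logdetV += 2.0 * float(np.sum(np.log(np.diag(L))))
            Xi = np.linalg.solve(L, Xb)
            yi = np.linalg.solve(L, yb)
            XtVX += Xi.T @ Xi
            XtVy += Xi.T @ yi
            ytVy += float(yi @ yi)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return 1e300
        quad = max(ytVy - float(beta @ XtVy), 0.0)
        if method == "ML":
            return 0.5 * (n * _LOG2PI + logdetV + quad)
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e300
        return 0.5 * ((n - p) * _LOG2PI + logdetV + logdet_XtVX + quad)

    # moment-flavoured and pooled deterministic starts
    starts = [
        np.log([0.2 * var_y, 0.2 * var_y, 0.6 * var_y]),
        np.log([0.05 * var_y, 0.05 * var_y, 0.9 * var_y]),
        np.log([0.45 * var_y, 0.1 * var_y, 0.45 * var_y]),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 3,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    s2c, s2ce, s2r = (float(v) for v in np.exp(best.x))
    floor = var_y * 1e-8
    # boundary components are genuine zeros
    s2c = 0.0 if s2c < floor else s2c
    s2ce = 0.0 if s2ce < floor else s2ce
    gtol = 1e-6 * max(1.0, abs(float(best.fun)))
    conv = bool(best.success or (best.jac is not None and np.max(np.abs(best.jac)) < gtol))
    return HeritabilityResult(
        trait=trait,
        environment=environment,
        sigma2_clone=s2c,
        sigma2_clone_env=s2ce,
        sigma2_residual=s2r,
        loglik=-float(best.fun),
        converged=conv,
    )
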