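"""Heteroscedastic linear mixed models with variance-structure selection.

Model: for trait value :math:`y_i` of an animal in clone :math:`c(i)` and
variance group :math:`g(i)`,

.. math::

    y_i = x_i^T \\beta + u_{c(i)} + \\varepsilon_i,\\qquad
    u_c \\sim N(0, \\sigma^2_u),\\qquad
    \\varepsilon_i \\sim N(0, \\sigma^2_{g(i)})

with fixed effects for treatment, generation and their interaction (age as
a covariate for the morphological traits, centred at the 132 h design age),
a random intercept per clone, and residual variances that may differ by
group.  Four variance structures are supported: ``constant`` (one residual
variance), ``by_treatment`` (3), ``by_generation`` (2) and
``by_treatment_generation`` (6, one per design cell).

Estimation profiles the fixed effects out in closed form (GLS given the
variance parameters) and maximises the ML or REML log-likelihood over the
log-variance parameters with a quasi-Newton optimiser from three
deterministic starting points.  The per-clone covariance blocks
:math:`D_c + \\sigma^2_u \\mathbf{1}\\mathbf{1}^T` are handled with the
Sherman-Morrison and matrix-determinant identities, so a likelihood
evaluation is O(n p) regardless of clone size.

Structures are compared with likelihood-ratio tests (valid under REML here
because every candidate shares identical fixed effects) and selected by
lowest AIC with a demotion to the simplest nested structure that is not
significantly worse (LRT p > 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg
from scipy import optimize, stats

from .data import (
    CELLS,
    DESIGN_AGE_H,
    MORPHOLOGICAL_TRAITS,
    TRAIT_COLUMNS,
    TREATMENTS,
    TraitDataset,
    cell_label,
)

VARIANCE_STRUCTURES = (
    "constant",
    "by_generation",
    "by_treatment",
    "by_treatment_generation",
)

#: residual-variance parameter count per structure
N_VARIANCE_PARAMS = {
    "constant": 1,
    "by_generation": 2,
    "by_treatment": 3,
    "by_treatment_generation": 6,
}

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: trait, variance structure and estimation method.

    Reproduction models exclude the age covariate; morphological models
    include it (centred at the design age so cell means are interpretable
    at 132 h).
    """

    trait: str
    variance_structure: str = "constant"
    method: str = "REML"
    include_clone: bool = True

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_COLUMNS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.variance_structure not in VARIANCE_STRUCTURES:
            raise ValueError(f"unknown variance structure {self.variance_structure!r}")
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")

    @property
    def with_age(self) -> bool:
        return self.trait in MORPHOLOGICAL_TRAITS


def variance_groups(structure: str) -> dict[tuple[str, str], str]:
    """Map each design cell to its variance-group label under a structure."""
    out: dict[tuple[str, str], str] = {}
    for trt, gen in CELLS:
        if structure == "constant":
            out[(trt, gen)] = "all"
        elif structure == "by_treatment":
            out[(trt, gen)] = trt
        elif structure == "by_generation":
            out[(trt, gen)] = gen
        elif structure == "by_treatment_generation":
            out[(trt, gen)] = cell_label(trt, gen)
        else:
            raise ValueError(f"unknown variance structure {structure!r}")
    return out


def is_nested(nested_structure: str, general_structure: str) -> bool:
    """True if the nested structure's grouping is a coarsening of the
    general structure's grouping (every general group lies wholly inside
    one nested group)."""
    coarse = variance_groups(nested_structure)
    fine = variance_groups(general_structure)
    mapping: dict[str, str] = {}
    for cell in CELLS:
        g_fine, g_coarse = fine[cell], coarse[cell]
        if mapping.setdefault(g_fine, g_coarse) != g_coarse:
            return False
    return True


def design_matrix(
    data: TraitDataset, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Fixed-effect design matrix for the 6-cell means model in reference
    coding (reference cell AA G2), plus the response and complete-case frame."""
    sub = data.complete_cases(spec.trait).df.reset_index(drop=True)
    y = sub[TRAIT_COLUMNS[spec.trait]].to_numpy(dtype=float)
    ca = (sub["treatment"] == "CA").to_numpy(dtype=float)
    cc = (sub["treatment"] == "CC").to_numpy(dtype=float)
    g3 = (sub["generation"] == "G3").to_numpy(dtype=float)
    cols = {
        "Intercept": np.ones(len(sub)),
        "T[CA]": ca,
        "T[CC]": cc,
        "G[G3]": g3,
        "T[CA]:G[G3]": ca * g3,
        "T[CC]:G[G3]": cc * g3,
    }
    if spec.with_age:
        cols["age_c"] = sub["age_h"].to_numpy(dtype=float) - DESIGN_AGE_H
    X = np.column_stack(list(cols.values()))
    return X, y, list(cols), sub


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, rmat = np.linalg.qr(X)
    diag = np.abs(np.diag(rmat))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if (diag < tol).any():
        aliased = [names[i] for i in np.where(diag < tol)[0]]
        raise np.linalg.LinAlgError(
            f"singular design matrix; aliased columns: {aliased}"
        )


class _ModelData:
    """Pre-sorted arrays and sufficient statistics for fast likelihood
    evaluation (rows ordered by clone so per-clone sums use ``reduceat``)."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        clone: np.ndarray,
        group: np.ndarray,
        n_groups: int,
        group_labels: list[str],
        x_names: list[str],
    ):
        order = np.argsort(clone, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.y = np.ascontiguousarray(y[order])
        self.clone = clone[order]
        self.group = group[order]
        self.n, self.p = X.shape
        self.k = n_groups
        self.group_labels = group_labels
        self.x_names = x_names
        self.n_clones = int(self.clone.max()) + 1 if len(clone) else 0
        # reduceat boundaries of the clone-sorted rows
        self.starts = np.searchsorted(self.clone, np.arange(self.n_clones))
        self.ng = np.bincount(self.group, minlength=self.k).astype(float)


def _gls_pieces(md: _ModelData, sigma_u2: float, sig_g2: np.ndarray):
    """Woodbury/Sherman-Morrison assembly of X'V^-1 X, X'V^-1 y, y'V^-1 y
    and log|V| for block covariance D + sigma_u2 * 11' per clone."""
    inv_d = 1.0 / sig_g2[md.group]
    Xw = md.X * inv_d[:, None]
    yw = md.y * inv_d
    XtDX = md.X.T @ Xw
    XtDy = Xw.T @ md.y
    ytDy = float(md.y @ yw)
    logdetD = float(md.ng @ np.log(sig_g2))
    if sigma_u2 > 0 and md.n_clones > 0:
        a = np.add.reduceat(inv_d, md.starts)  # sum 1/d_i per clone
        T = np.add.reduceat(Xw, md.starts, axis=0)  # sum x_i/d_i per clone
        s = np.add.reduceat(yw, md.starts)  # sum y_i/d_i per clone
        w = sigma_u2 / (1.0 + sigma_u2 * a)
        XtVX = XtDX - (T * w[:, None]).T @ T
        XtVy = XtDy - T.T @ (w * s)
        ytVy = ytDy - float((w * s) @ s)
        logdetV = logdetD + float(np.sum(np.log1p(sigma_u2 * a)))
    else:
        XtVX, XtVy, ytVy, logdetV = XtDX, XtDy, ytDy, logdetD
    return XtVX, XtVy, ytVy, logdetV


def _profiled_loglik(
    md: _ModelData, sigma_u2: float, sig_g2: np.ndarray, method: str
):
    XtVX, XtVy, ytVy, logdetV = _gls_pieces(md, sigma_u2, sig_g2)
    try:
        c = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, np.nan
    beta = np.linalg.solve(XtVX, XtVy)
    quad = max(ytVy - float(beta @ XtVy), 0.0)
    if method == "ML":
        ll = -0.5 * (md.n * _LOG2PI + logdetV + quad)
    else:
        logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(c))))
        ll = -0.5 * ((md.n - md.p) * _LOG2PI + logdetV + logdet_XtVX + quad)
    return ll, beta, XtVX, quad


def _nll_grad(md: _ModelData, sigma_u2: float, sig_g2: np.ndarray, method: str):
    """Negative (RE)ML log-likelihood and its gradient w.r.t. the
    log-variance parameters (clone first, then residual groups).

    Uses the score equations dl/dtheta = -1/2 [tr(A dV/dtheta)
    - r~' (dV/dtheta) r~] with A = V^-1 (ML) or the REML projection P, and
    r~ = V^-1 (y - X beta_GLS); all traces reduce to per-clone sums under
    the Woodbury representation.
    """
    d = sig_g2[md.group]
    inv_d = 1.0 / d
    Xw = md.X * inv_d[:, None]
    yw = md.y * inv_d
    a = np.add.reduceat(inv_d, md.starts)
    T = np.add.reduceat(Xw, md.starts, axis=0)
    s = np.add.reduceat(yw, md.starts)
    denom = 1.0 + sigma_u2 * a
    w = sigma_u2 / denom
    XtVX = (md.X.T @ Xw) - (T * w[:, None]).T @ T
    XtVy = (Xw.T @ md.y) - T.T @ (w * s)
    ytVy = float(md.y @ yw) - float((w * s) @ s)
    try:
        chol = np.linalg.cholesky(XtVX)
        beta = sp_linalg.cho_solve((chol, True), XtVy)
    except (np.linalg.LinAlgError, ValueError):
        return 1e300, np.zeros(1 + md.k)
    if not np.all(np.isfinite(beta)):
        return 1e300, np.zeros(1 + md.k)
    quad = max(ytVy - float(beta @ XtVy), 0.0)
    logdetV = float(md.ng @ np.log(sig_g2)) + float(np.sum(np.log(denom)))
    if method == "ML":
        ll = -0.5 * (md.n * _LOG2PI + logdetV + quad)
    else:
        logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(chol))))
        ll = -0.5 * ((md.n - md.p) * _LOG2PI + logdetV + logdet_XtVX + quad)

    # residuals and V^-1 r
    r = md.y - md.X @ beta
    rw = r * inv_d
    s_r = np.add.reduceat(rw, md.starts)
    rt = rw - (w * s_r)[md.clone] * inv_d  # V^-1 r elementwise
    # diag(V^-1) and per-group traces
    diag_Vinv = inv_d - w[md.clone] * inv_d**2
    tr_diag = np.bincount(md.group, weights=diag_Vinv, minlength=md.k)
    # clone-direction pieces
    tr_Z = float(np.sum(a / denom))  # tr(V^-1 ZZ')
    sum_rt_clone = s_r / denom  # sum of (V^-1 r) within clone
    quad_Z = float(np.sum(sum_rt_clone**2))
    quad_diag = np.bincount(md.group, weights=rt**2, minlength=md.k)

    if method == "REML":
        C = sp_linalg.cho_solve((chol, True), np.eye(md.p))
        # U = V^-1 X rows: x_i/d_i - w_c T_c / d_i
        U = Xw - (w[md.clone, None] * T[md.clone]) * inv_d[:, None]
        B_diag = np.einsum("ij,jk,ik->i", U, C, U)
        tr_diag = tr_diag - np.bincount(md.group, weights=B_diag, minlength=md.k)
        H = T / denom[:, None]  # sum of U rows within clone
        tr_Z = tr_Z - float(np.einsum("cj,jk,ck->", H, C, H))

    g_groups = -0.5 * (tr_diag - quad_diag) * sig_g2  # d(-ll)/d log sig_g2... sign below
    g_clone = -0.5 * (tr_Z - quad_Z) * sigma_u2
    # above is dl/dphi; negative log-likelihood gradient flips sign
    grad = np.concatenate(([-g_clone], -g_groups))
    return -ll, grad


@dataclass
class FittedLMM:
    """One fitted trait / variance-structure combination."""

    spec: ModelSpec
    beta: np.ndarray
    beta_cov: np.ndarray
    x_names: list[str]
    sigma2_clone: float
    residual_variances: dict[str, float]
    loglik: float
    aic: float
    n_params: int
    converged: bool
    df_resid: int
    n_obs: int
    _md: _ModelData = field(repr=False)
    _phi: np.ndarray = field(repr=False)

    @property
    def group_labels(self) -> list[str]:
        return list(self.residual_variances)

    def cell_mean_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Rows mapping beta to the six treatment x generation cell means,
        evaluated at the 132 h design age (centred age = 0)."""
        rows, labels = [], []
        for trt, gen in CELLS:
            row = np.zeros(len(self.x_names))
            row[self.x_names.index("Intercept")] = 1.0
            if trt != "AA":
                row[self.x_names.index(f"T[{trt}]")] = 1.0
            if gen == "G3":
                row[self.x_names.index("G[G3]")] = 1.0
                if trt != "AA":
                    row[self.x_names.index(f"T[{trt}]:G[G3]")] = 1.0
            rows.append(row)
            labels.append(cell_label(trt, gen))
        return np.array(rows), labels

    def logvar_cov(self) -> tuple[np.ndarray, list[str]]:
        """Covariance of the log-variance parameters from a central-difference
        Hessian of the (RE)ML objective; parameter order is clone variance
        (if estimated) then the residual groups."""
        md, spec = self._md, self.spec
        phi = self._phi.copy()
        with_clone = len(phi) > md.k  # clone variance was estimated
        names = (["clone"] if with_clone else []) + self.group_labels

        def nll(p):
            if with_clone:
                su2, sg2 = np.exp(p[0]), np.exp(p[1:])
            else:
                su2, sg2 = self.sigma2_clone, np.exp(p)
            ll, *_ = _profiled_loglik(md, su2, sg2, spec.method)
            return -ll

        h = 1e-4
        m = len(phi)
        H = np.zeros((m, m))
        for i in range(m):
            for j in range(i, m):
                ei, ej = np.zeros(m), np.zeros(m)
                ei[i], ej[j] = h, h
                fpp = nll(phi + ei + ej)
                fpm = nll(phi + ei - ej)
                fmp = nll(phi - ei + ej)
                fmm = nll(phi - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        cov = np.linalg.pinv(H)
        return cov, names


def _group_codes(sub: pd.DataFrame, structure: str) -> tuple[np.ndarray, list[str]]:
    gmap = variance_groups(structure)
    labels = sorted(set(gmap.values()), key=list(gmap.values()).index)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    codes = np.array(
        [lab_idx[gmap[(t, g)]] for t, g in zip(sub["treatment"], sub["generation"])]
    )
    present = np.bincount(codes, minlength=len(labels))
    kept = [lab for lab, c in zip(labels, present) if c > 0]
    if len(kept) < len(labels):
        remap = {lab_idx[lab]: i for i, lab in enumerate(kept)}
        codes = np.array([remap[c] for c in codes])
        labels = kept
    return codes, labels


def _starts(md: _ModelData, include_clone: bool) -> list[np.ndarray]:
    """Three deterministic starting points on the log-variance scale:
    moment-based, pooled, and a perturbation of the moment start."""
    # OLS residuals for moment estimates
    beta0, *_ = np.linalg.lstsq(md.X, md.y, rcond=None)
    r = md.y - md.X @ beta0
    pooled = max(float(r @ r) / max(md.n - md.p, 1), 1e-12)
    gv = np.full(md.k, pooled)
    for j in range(md.k):
        rj = r[md.group == j]
        if len(rj) >= 2:
            gv[j] = max(float(np.var(rj, ddof=1)), 1e-10 * pooled + 1e-300)
    # clone variance moment: variance of clone-mean residuals minus within/n
    su2 = 0.1 * pooled
    if md.n_clones >= 2:
        cm = np.add.reduceat(r, md.starts) / np.diff(
            np.append(md.starts, md.n)
        )
        nbar = md.n / md.n_clones
        su2 = max(float(np.var(cm, ddof=1)) - pooled / nbar, 0.05 * pooled)
    starts = []
    mom = np.log(np.concatenate(([su2], gv))) if include_clone else np.log(gv)
    pool = (
        np.log(np.concatenate(([0.1 * pooled], np.full(md.k, pooled))))
        if include_clone
        else np.log(np.full(md.k, pooled))
    )
    starts.append(mom)
    starts.append(pool)
    starts.append(mom + np.where(np.arange(len(mom)) % 2 == 0, 1.0, -1.0))
    return starts


def fit_lmm(
    data: TraitDataset,
    spec: ModelSpec,
    fix_clone_variance: float | None = None,
) -> FittedLMM:
    """Fit one trait under one variance structure by (RE)ML.

    ``fix_clone_variance`` pins the clone variance (0 collapses the model to
    heteroscedastic GLS / OLS); otherwise it is estimated.
    """
    X, y, x_names, sub = design_matrix(data, spec)
    _check_rank(X, x_names)
    clone_codes = pd.Categorical(sub["clone_id"]).codes.astype(np.int64)
    if spec.include_clone and fix_clone_variance is None and len(np.unique(clone_codes)) < 2:
        raise ValueError("need >= 2 clones to estimate a clone variance")
    group, labels = _group_codes(sub, spec.variance_structure)
    counts = np.bincount(group)
    if (counts < 2).any():
        small = [labels[i] for i in np.where(counts < 2)[0]]
        raise ValueError(f"variance groups with < 2 observations: {small}")
    md = _ModelData(X, y, clone_codes, group, len(labels), labels, x_names)
    return _fit_model_data(md, spec, fix_clone_variance)


def _fit_model_data(
    md: _ModelData,
    spec: ModelSpec,
    fix_clone_variance: float | None = None,
) -> FittedLMM:
    """Optimise the (RE)ML objective on prepared model data."""
    x_names, labels = md.x_names, md.group_labels
    X, y = md.X, md.y
    include_clone = spec.include_clone and fix_clone_variance is None
    fixed_u2 = 0.0 if fix_clone_variance is None else float(fix_clone_variance)

    var_y = float(np.var(y)) if len(y) else 1.0
    # scale guard: var(y) is 0 for constant y, so fall back to its magnitude
    scale = max(var_y, 1e-8 * float(np.mean(y**2)) if len(y) else 0.0, 1e-300)
    floor = scale * _VAR_FLOOR_REL
    # degenerate noise-free data: all within-group OLS residuals ~ 0
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    if float(np.max(np.abs(y - X @ beta0)) if len(y) else 0.0) ** 2 < floor:
        XtX = X.T @ X
        beta_cov = np.linalg.pinv(XtX) * floor
        return FittedLMM(
            spec=spec,
            beta=beta0,
            beta_cov=beta_cov,
            x_names=x_names,
            sigma2_clone=0.0,
            residual_variances={lab: 0.0 for lab in labels},
            loglik=np.inf,
            aic=-np.inf,
            n_params=md.p + int(include_clone) + md.k,
            converged=True,
            df_resid=md.n - md.p,
            n_obs=md.n,
            _md=md,
            _phi=np.log(np.full(md.k + int(include_clone), floor)),
        )

    lo, hi = np.log(floor), np.log(max(var_y, floor)) + 12.0

    def nll(phi):
        if include_clone:
            f, g = _nll_grad(md, float(np.exp(phi[0])), np.exp(phi[1:]), spec.method)
            return f, g
        f, g = _nll_grad(md, fixed_u2, np.exp(phi), spec.method)
        return f, g[1:]

    best = None
    for x0 in _starts(md, include_clone):
        if not include_clone:
            x0 = x0[-md.k:] if len(x0) > md.k else x0
        x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
        res = optimize.minimize(
            nll,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(x0),
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    phi = best.x
    # relative gradient tolerance 1e-6 on the log-variance scale: the line
    # search can stall at machine precision of the objective, so judge the
    # optimum by its score, not the optimizer's status string
    gtol = 1e-6 * max(1.0, abs(float(best.fun)))
    grad_ok = best.jac is not None and bool(np.max(np.abs(best.jac)) < gtol)
    converged = bool(best.success or grad_ok)

    def unpack(phi):
        if include_clone:
            return float(np.exp(phi[0])), np.exp(phi[1:])
        return fixed_u2, np.exp(phi)

    sigma_u2, sig_g2 = unpack(phi)
    ll, beta, XtVX, quad = _profiled_loglik(md, sigma_u2, sig_g2, spec.method)
    # polish: the overall variance scale has a closed-form optimum given the
    # variance ratios (fixed_u2 != 0 breaks the joint scaling, so skip there)
    if quad > 0 and (include_clone or fixed_u2 == 0.0):
        denom = md.n if spec.method == "ML" else md.n - md.p
        c_star = quad / denom
        phi_new = phi + np.log(c_star)
        if np.all(phi_new > lo) and np.all(phi_new < hi):
            su2_n, sg2_n = unpack(phi_new)
            ll_new, beta_n, XtVX_n, quad_n = _profiled_loglik(
                md, su2_n, sg2_n, spec.method
            )
            if ll_new > ll:
                phi, sigma_u2, sig_g2 = phi_new, su2_n, sg2_n
                ll, beta, XtVX, quad = ll_new, beta_n, XtVX_n, quad_n
    beta_cov = np.linalg.inv(XtVX)
    # clone variance at the floor is a boundary estimate; report as 0
    if include_clone and sigma_u2 <= floor * 10:
        sigma_u2 = 0.0
    n_params = md.p + int(include_clone) + md.k
    aic = -2.0 * ll + 2.0 * n_params
    return FittedLMM(
        spec=spec,
        beta=beta,
        beta_cov=beta_cov,
        x_names=x_names,
        sigma2_clone=sigma_u2,
        residual_variances={lab: float(v) for lab, v in zip(labels, sig_g2)},
        loglik=float(ll),
        aic=float(aic),
        n_params=n_params,
        converged=converged,
        df_resid=md.n - md.p,
        n_obs=md.n,
        _md=md,
        _phi=phi,
    )


def dense_loglik(
    data: TraitDataset,
    spec: ModelSpec,
    sigma2_clone: float,
    residual_variances: dict[str, float],
) -> float:
    """Brute-force (restricted) log-likelihood through the full n x n
    covariance matrix; an independent check of the profiled evaluation for
    small n."""
    X, y, x_names, sub = design_matrix(data, spec)
    n, p = X.shape
    clone = pd.Categorical(sub["clone_id"]).codes
    group, labels = _group_codes(sub, spec.variance_structure)
    d = np.array([residual_variances[labels[g]] for g in group])
    V = np.diag(d)
    same_clone = clone[:, None] == clone[None, :]
    V = V + sigma2_clone * same_clone
    Vinv = np.linalg.inv(V)
    _, logdetV = np.linalg.slogdet(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    quad = float(r @ Vinv @ r)
    if spec.method == "ML":
        return -0.5 * (n * _LOG2PI + logdetV + quad)
    _, logdet_XtVX = np.linalg.slogdet(XtVX)
    return -0.5 * ((n - p) * _LOG2PI + logdetV + logdet_XtVX + quad)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


def lrt(nested: FittedLMM, general: FittedLMM) -> LRTResult:
    """Likelihood-ratio test of a coarser variance structure against a finer
    one (same trait, fixed effects and estimation method)."""
    if nested.spec.trait != general.spec.trait:
        raise ValueError("LRT requires the same trait")
    if nested.spec.method != general.spec.method:
        raise ValueError("LRT requires the same estimation method")
    if not is_nested(nested.spec.variance_structure, general.spec.variance_structure):
        raise ValueError(
            f"{nested.spec.variance_structure!r} is not nested in "
            f"{general.spec.variance_structure!r}"
        )
    df = len(general.residual_variances) - len(nested.residual_variances)
    stat = max(2.0 * (general.loglik - nested.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=df, p=p)


@dataclass
class StructureSelection:
    fits: dict[str, FittedLMM]
    lrt_results: dict[tuple[str, str], LRTResult]
    chosen: str
    trace: list[str]

    @property
    def chosen_fit(self) -> FittedLMM:
        return self.fits[self.chosen]


def select_structure(
    data: TraitDataset,
    trait: str,
    method: str = "REML",
) -> StructureSelection:
    """Fit all four variance structures and select one.

    Rule: take the lowest-AIC structure (ties within 1e-9 go to the fewer
    parameters), then demote to the simplest structure nested within it
    whose LRT against it is not significant (p > 0.05).
    """
    fits: dict[str, FittedLMM] = {}
    trace: list[str] = []
    for s in VARIANCE_STRUCTURES:
        fit = fit_lmm(data, ModelSpec(trait=trait, variance_structure=s, method=method))
        fits[s] = fit
        trace.append(
            f"fit {s}: logLik={fit.loglik:.6f} AIC={fit.aic:.6f} "
            f"params={fit.n_params} converged={fit.converged} method={method}"
        )
        if not fit.converged:
            warnings.warn(f"structure {s} did not converge; excluded from selection")
    usable = {s: f for s, f in fits.items() if f.converged}
    if not usable:
        raise RuntimeError("no variance structure converged")
    best_aic = min(f.aic for f in usable.values())
    tied = [s for s, f in usable.items() if f.aic <= best_aic + 1e-9]
    aic_choice = min(tied, key=lambda s: N_VARIANCE_PARAMS[s])
    trace.append(f"lowest AIC: {aic_choice} (AIC={usable[aic_choice].aic:.6f})")

    lrt_results: dict[tuple[str, str], LRTResult] = {}
    chosen = aic_choice
    # demotion: simplest nested structure not significantly worse
    candidates = [
        s
        for s in VARIANCE_STRUCTURES
        if s in usable
        and s != aic_choice
        and is_nested(s, aic_choice)
    ]
    for s in sorted(candidates, key=lambda s: N_VARIANCE_PARAMS[s]):
        res = lrt(usable[s], usable[aic_choice])
        lrt_results[(s, aic_choice)] = res
        trace.append(
            f"LRT {s} vs {aic_choice}: stat={res.statistic:.4f} df={res.df} p={res.p:.4g}"
        )
        if res.p > 0.05:
            chosen = s
            trace.append(f"demoted to simpler structure {s} (p={res.p:.4g} > 0.05)")
            break
    if chosen == aic_choice:
        trace.append(f"kept {chosen}")
    return StructureSelection(fits=fits, lrt_results=lrt_results, chosen=chosen, trace=trace)
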