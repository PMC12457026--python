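"""Wald tests, Tukey-family contrasts, variance intervals and the Bayesian
variance-ratio comparison."""

import numpy as np
import pytest

from traitvar import (
    ModelSpec,
    cell_contrasts,
    fit_lmm,
    generate_dataset,
    observed_shifts,
    variance_cis,
    variance_ratio_posterior,
    wald_tests,
)
from traitvar.inference import _fit_additive, _wald_block

from conftest import single_trait_config


@pytest.fixture(scope="module")
def repro_fit(study_dataset):
    return fit_lmm(study_dataset, ModelSpec("reproduction", "by_treatment_generation"))


@pytest.fixture(scope="module")
def eye_fit(study_dataset):
    return fit_lmm(study_dataset, ModelSpec("eye_size", "by_treatment"))


# --- fixed-effect Wald tests ------------------------------------------------


def test_terms_and_dfs_match_the_design(study_dataset, eye_fit, repro_fit):
    tests = {t.term: t for t in wald_tests(eye_fit, study_dataset)}
    assert set(tests) == {"treatment", "generation", "age", "interaction"}
    assert tests["treatment"].df == 2
    assert tests["generation"].df == 1
    assert tests["age"].df == 1
    assert tests["interaction"].df == 2
    # reproduction: no age term
    tests_r = {t.term: t for t in wald_tests(repro_fit, study_dataset)}
    assert set(tests_r) == {"treatment", "generation", "interaction"}


def test_one_df_chi2_equals_squared_t(study_dataset, eye_fit):
    tests = {t.term: t for t in wald_tests(eye_fit, study_dataset)}
    additive = _fit_additive(study_dataset, eye_fit.spec)
    i = additive.x_names.index("G[G3]")
    z = additive.beta[i] / np.sqrt(additive.beta_cov[i, i])
    assert tests["generation"].chi2 == pytest.approx(z**2, abs=1e-8)


def test_zero_beta_block_gives_zero_chi2(eye_fit):
    import copy

    fit = copy.copy(eye_fit)
    fit.beta = np.zeros_like(eye_fit.beta)
    res = _wald_block(fit, ("T[CA]", "T[CC]"))
    assert res.chi2 == 0.0
    assert res.p == 1.0


def test_strong_planted_interaction_detected(study_dataset, eye_fit):
    tests = {t.term: t for t in wald_tests(eye_fit, study_dataset)}
    assert tests["interaction"].p < 1e-4  # generator plants a crossing pattern
    assert tests["treatment"].p < 1e-4


# --- cell-mean contrasts ----------------------------------------------------


def test_fifteen_contrasts_with_monotone_adjustment(repro_fit):
    cons = cell_contrasts(repro_fit, adjust="tukey")
    assert len(cons) == 15
    assert sum(c.in_report for c in cons) == 10
    for c in cons:
        assert c.p_adjusted >= c.p_unadjusted - 1e-12
        assert 0.0 <= c.p_adjusted <= 1.0
        if c.se > 0:
            assert c.t_ratio == pytest.approx(c.estimate / c.se, abs=1e-8)
        assert c.df == repro_fit.df_resid


def test_contrast_cycle_sums_to_zero(repro_fit):
    cons = {c.label: c.estimate for c in cell_contrasts(repro_fit)}
    # (AA G2 - CA G2) + (CA G2 - CC G2) - (AA G2 - CC G2) = 0
    cyc = (
        cons["AA G2 - CA G2"] + cons["CA G2 - CC G2"] - cons["AA G2 - CC G2"]
    )
    assert cyc == pytest.approx(0.0, abs=1e-10)


def test_noise_free_cells_give_zero_estimates_and_unit_p(noise_free_config):
    ds = generate_dataset(noise_free_config)
    fit = fit_lmm(ds, ModelSpec("body_size", "constant"), fix_clone_variance=0.0)
    cons = cell_contrasts(fit)
    for c in cons:
        assert c.estimate == pytest.approx(0.0, abs=1e-12)
        assert c.p_adjusted == pytest.approx(1.0)


def test_mvn_adjustment_close_to_tukey_when_balanced(repro_fit):
    tk = {c.label: c.p_adjusted for c in cell_contrasts(repro_fit, adjust="tukey")}
    mv = {c.label: c.p_adjusted for c in cell_contrasts(repro_fit, adjust="mvn", seed=1)}
    for lab in tk:
        assert mv[lab] == pytest.approx(tk[lab], abs=0.05)


def test_unknown_adjustment_rejected(repro_fit):
    with pytest.raises(ValueError, match="adjustment"):
        cell_contrasts(repro_fit, adjust="bonferroni-ish")


def test_familywise_error_controlled_under_null():
    """Nominal 5% Tukey family: FWER over the 15-pair family stays near
    nominal on null (equal cell mean) data."""
    hits = 0
    for s in range(100):
        ds = generate_dataset(single_trait_config(seed=9000 + s, n_per=8))
        fit = fit_lmm(ds, ModelSpec("body_size", "constant"))
        cons = cell_contrasts(fit)
        hits += any(c.p_adjusted < 0.05 for c in cons)
    assert hits / 100 <= 0.07 + 2 * np.sqrt(0.05 * 0.95 / 100)


# --- variance CIs -----------------------------------------------------------


def test_log_scale_interval_definition(eye_fit):
    for v in variance_cis(eye_fit):
        z = 1.959963984540054
        assert v.ci_low == pytest.approx(v.sigma2 * np.exp(-z * v.se_log), rel=1e-9)
        assert v.ci_high == pytest.approx(v.sigma2 * np.exp(z * v.se_log), rel=1e-9)
        assert 0 < v.ci_low <= v.sigma2 <= v.ci_high


def test_interval_width_shrinks_with_group_size():
    widths = []
    for n_per in (4, 15, 60):
        ds = generate_dataset(single_trait_config(seed=77, n_per=n_per))
        fit = fit_lmm(ds, ModelSpec("body_size", "constant"))
        (v,) = variance_cis(fit)
        widths.append(np.log(v.ci_high / v.ci_low))
    assert widths[0] > widths[1] > widths[2]


# --- variance-ratio posterior -----------------------------------------------


def test_identical_groups_split_posterior_mass_evenly():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 200)
    post = variance_ratio_posterior(a, a, n_draws=100_000, seed=3)
    assert post.p_less_than_1 == pytest.approx(0.5, abs=0.02)
    assert post.cri_low < 1 < post.cri_high


def test_posterior_scale_invariance():
    rng = np.random.default_rng(6)
    a, b = rng.normal(0, 1, 150), rng.normal(0, 1.2, 150)
    p1 = variance_ratio_posterior(a, b, seed=11)
    p2 = variance_ratio_posterior(2 * a, 2 * b, seed=11)
    assert p1.ratio_mean == pytest.approx(p2.ratio_mean, rel=1e-12)
    assert p1.p_less_than_1 == p2.p_less_than_1


def test_posterior_input_validation():
    rng = np.random.default_rng(7)
    a = rng.normal(0, 1, 50)
    with pytest.raises(ValueError, match=">= 3"):
        variance_ratio_posterior(a, a[:2])
    with pytest.raises(ValueError, match="zero variance"):
        variance_ratio_posterior(a, np.ones(10))
    with pytest.raises(ValueError, match="n_draws"):
        variance_ratio_posterior(a, a, n_draws=100)
    with pytest.raises(ValueError, match="prior"):
        variance_ratio_posterior(a, a, prior="horseshoe")


# --- observed shifts --------------------------------------------------------


def test_observed_shifts_requires_cell_structure(eye_fit, repro_fit):
    with pytest.raises(ValueError, match="by_treatment_generation"):
        observed_shifts(eye_fit)
    shifts = observed_shifts(repro_fit)
    assert set(shifts) == {"AA", "CA", "CC"}
    for s in shifts.values():
        assert s.mean_se > 0 and s.var_se > 0
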