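"""Permutation test and density-covariate regressions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emonet import (EmotionPanel, LambdaPair, PreprocessConfig, impute, apply_pipeline,
                    individual_densities, individual_density_regressions,
                    permutation_density_test)
from emonet.inference import _sparse_group_density
from emonet.metrics import EDGES_EXCL_AR
from emonet.synthetic import SyntheticSpec, generate_panel


def _cohort_panels(seed, n_per_group=2, p=3, n_days=20, beeps=3, **kw):
    spec = SyntheticSpec(n_subjects_per_group=n_per_group, n_items=p, n_days=n_days,
                         beeps_per_day=beeps, missing_rate=0.0,
                         likert_cutpoints=None, seed=seed, **kw)
    panel, _ = generate_panel(spec)
    imps = impute(panel, 1, seed=seed)
    cfg = PreprocessConfig(n_imputations=1)
    detrended = apply_pipeline(imps, dataclasses.replace(cfg, transform=False))
    return detrended, cfg


LAM = LambdaPair(0.2, 0.05)


def test_identical_groups_give_zero_observed_difference(build_panel):
    # group labels split byte-identical data: observed diff must be exactly 0
    rng = np.random.default_rng(0)
    vals = rng.standard_normal((60, 3))
    data = {f"m{i}": vals for i in range(2)} | {f"c{i}": vals for i in range(2)}
    groups = {f"m{i}": "MDD" for i in range(2)} | {f"c{i}": "control" for i in range(2)}
    panel = build_panel(data, groups, 20, 3, ["x", "y", "z"])
    imps = impute(panel, 1, seed=0)
    cfg = PreprocessConfig(n_imputations=1)
    detrended = apply_pipeline(imps, dataclasses.replace(cfg, transform=False))
    res = permutation_density_test(detrended, ("MDD", "control"), "sparse",
                                   EDGES_EXCL_AR, LAM, cfg, n_perm=100, seed=0)
    assert res.observed_diff == 0.0
    assert res.tail_prop_lower + res.tail_prop_upper >= 1.0


def test_single_subject_per_group_matches_enumeration():
    detrended, cfg = _cohort_panels(1, n_per_group=1)
    n_perm = 400
    res = permutation_density_test(detrended, ("MDD", "control"), "sparse",
                                   EDGES_EXCL_AR, LAM, cfg, n_perm=n_perm, seed=3)
    # brute force: only two assignments of the two subjects to the two groups
    panel = detrended[0]
    subjects, groups, X = panel.to_arrays()
    beeps = panel.data[panel.data["subject_id"] == subjects[0]]["beep"].to_numpy()

    def d(i, j):
        da = _sparse_group_density(X[[i]], beeps, LAM, EDGES_EXCL_AR, False, True)
        db = _sparse_group_density(X[[j]], beeps, LAM, EDGES_EXCL_AR, False, True)
        return da - db

    obs = d(0, 1)
    null = np.array([d(0, 1), d(1, 0)])
    assert np.allclose(np.abs(res.null_draws), abs(obs))
    enum_lower = (null <= obs).mean()
    tol = 3 * np.sqrt(0.25 / n_perm)
    assert abs(res.tail_prop_lower - enum_lower) <= tol
    assert res.observed_diff == pytest.approx(obs)


def test_permutation_result_bookkeeping():
    detrended, cfg = _cohort_panels(5, n_per_group=3)
    res = permutation_density_test(detrended, ("MDD", "control"), "sparse",
                                   EDGES_EXCL_AR, LAM, cfg, n_perm=50, seed=9)
    assert len(res.null_draws) == 50
    assert 0.0 <= res.tail_prop_lower <= 1.0
    assert 0.0 <= res.tail_prop_upper <= 1.0
    assert res.n_perm == 50
    assert not res.averaged  # single imputation
    # deterministic given seed
    res2 = permutation_density_test(detrended, ("MDD", "control"), "sparse",
                                    EDGES_EXCL_AR, LAM, cfg, n_perm=50, seed=9)
    assert np.array_equal(res.null_draws, res2.null_draws)
    assert res.tail_prop_lower == res2.tail_prop_lower


def test_tail_swap_under_group_relabeling():
    detrended, cfg = _cohort_panels(11, n_per_group=3)
    r12 = permutation_density_test(detrended, ("MDD", "control"), "sparse",
                                   EDGES_EXCL_AR, LAM, cfg, n_perm=60, seed=4)
    r21 = permutation_density_test(detrended, ("control", "MDD"), "sparse",
                                   EDGES_EXCL_AR, LAM, cfg, n_perm=60, seed=4)
    assert r21.observed_diff == pytest.approx(-r12.observed_diff)


# ------------------------------------------------------------- regressions

def _cov_frame(n=20, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame({
        "group": ["MDD"] * (n // 2) + ["control"] * (n - n // 2),
        "neuroticism": rng.normal(28, 8, n),
        "bdi": np.concatenate([rng.normal(30, 8, n // 2), rng.normal(3, 2, n - n // 2)]),
        "mean_na": rng.normal(2, 0.5, n),
    }, index=pd.Index(ids, name="subject_id"))


def test_equal_densities_give_null_regressions():
    cov = _cov_frame()
    dens = pd.Series(0.25, index=cov.index)
    regs = individual_density_regressions(dens, cov)
    for r in regs:
        assert r.coefficient == 0.0
        if r.predictor_name == "group":
            assert r.p_value == 1.0


def test_exact_linear_relation_recovered():
    cov = _cov_frame(seed=2)
    dens = pd.Series(0.1 + 0.02 * cov["neuroticism"], index=cov.index)
    regs = {r.predictor_name: r for r in individual_density_regressions(dens, cov)}
    assert abs(regs["neuroticism"].coefficient - 0.02) < 1e-10


def test_regression_matches_normal_equations_oracle():
    cov = _cov_frame(seed=3)
    rng = np.random.default_rng(3)
    dens = pd.Series(0.2 + 0.01 * cov["neuroticism"] + rng.normal(0, 0.05, len(cov)),
                     index=cov.index)
    regs = {r.predictor_name: r for r in individual_density_regressions(dens, cov)}
    x = cov["neuroticism"].to_numpy()
    y = dens.to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    pval = 2 * stats.t.sf(abs(t), df=len(y) - 2)
    r = regs["neuroticism"]
    assert abs(r.coefficient - beta[1]) < 1e-8
    assert abs(r.standard_error - se) < 1e-8
    assert abs(r.p_value - pval) < 1e-8
    assert r.ci95[0] < r.coefficient < r.ci95[1]


def test_bdi_regressions_run_per_group():
    cov = _cov_frame(seed=4)
    rng = np.random.default_rng(4)
    dens = pd.Series(rng.uniform(0.1, 0.4, len(cov)), index=cov.index)
    regs = individual_density_regressions(dens, cov)
    subgroups = {r.subgroup for r in regs if r.predictor_name == "bdi"}
    assert subgroups == {"MDD-only", "control-only"}
    for r in regs:
        assert r.n <= len(cov)


def test_constant_predictor_is_skipped_with_warning():
    cov = _cov_frame(seed=5)
    cov["neuroticism"] = 30.0
    dens = pd.Series(np.linspace(0.1, 0.3, len(cov)), index=cov.index)
    with pytest.warns(UserWarning, match="constant"):
        regs = individual_density_regressions(dens, cov)
    assert "neuroticism" not in {r.predictor_name for r in regs}


def test_individual_densities_average_over_imputations():
    detrended, _ = _cohort_panels(13, n_per_group=2, n_days=30)
    dens1 = individual_densities(detrended, LAM)
    dens2 = individual_densities(detrended + detrended, LAM)
    assert np.allclose(dens1.to_numpy(), dens2.to_numpy())
    assert set(dens1.index) == set(detrended[0].subjects)
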