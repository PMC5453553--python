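"""Imputation, spline detrending, quantile transformation, centering."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emonet import (GROUP_WISE, PER_INDIVIDUAL, PreprocessConfig, apply_pipeline,
                    detrend, impute, nqt, person_mean_center)
from emonet.preprocess import _lambda_for_df, _spline_df
from emonet.synthetic import default_mdd_control_spec, generate_panel

# ---------------------------------------------------------------------- nqt

def test_nqt_worked_example():
    out = nqt([3, 1, 2])
    assert np.allclose(np.round(out, 4), [0.6745, -0.6745, 0.0])


def test_nqt_total_tie_maps_to_zeros():
    assert np.allclose(nqt([7, 7, 7]), 0.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60))
def test_nqt_preserves_sort_order(xs):
    out = nqt(xs)
    assert np.isfinite(out).all()
    assert (np.argsort(out, kind="stable") == np.argsort(xs, kind="stable")).all()


def test_nqt_output_close_to_standard_normal():
    rng = np.random.default_rng(4)
    x = rng.exponential(size=200)  # heavily skewed input
    out = nqt(x)
    assert abs(out.mean()) < 0.05
    assert 0.9 < out.std() < 1.1


def test_nqt_rejects_tiny_input():
    with pytest.raises(ValueError):
        nqt([1, 2])


# ------------------------------------------------------------------ detrend

def test_detrend_reproduces_linear_series_exactly():
    t = np.arange(90.0)
    resid, trend = detrend(2.0 * t)
    scale = np.abs(2.0 * t).max()
    assert np.abs(resid).max() < 1e-8 * scale
    assert np.allclose(trend, 2.0 * t, atol=1e-8 * scale)


def test_detrend_constant_series_gives_zero_residual():
    resid, trend = detrend(np.full(30, 5.0))
    assert np.allclose(resid, 0.0, atol=1e-10)
    assert np.allclose(trend, 5.0)


def test_detrend_residual_mean_is_zero():
    rng = np.random.default_rng(0)
    y = rng.standard_normal(90) + 3.0
    resid, _ = detrend(y)
    assert abs(resid.mean()) < 1e-8


def test_detrend_white_noise_keeps_variance():
    # a df=2 smoother absorbs only ~df/T of white-noise variance
    rng = np.random.default_rng(1)
    y = rng.standard_normal(90)
    resid, _ = detrend(y)
    assert abs(resid.var() - y.var()) < 0.1 * y.var()


def test_spline_df_solver_hits_target():
    for n, df in [(90, 2.0), (90, 5.0), (60, 3.0)]:
        lam = _lambda_for_df(n, df)
        assert abs(_spline_df(n, np.log10(lam)) - df) < 2e-3


def test_detrend_rejects_missing_and_short_series():
    with pytest.raises(ValueError):
        detrend(np.array([1.0, np.nan] + [1.0] * 20))
    with pytest.raises(ValueError):
        detrend(np.arange(5.0))


# ---------------------------------------------------------------- imputation

def test_impute_no_missing_returns_identical_copies():
    spec = default_mdd_control_spec(2, n_subjects_per_group=2, n_items=4, missing_rate=0.0)
    panel, _ = generate_panel(spec)
    imps = impute(panel, 4, seed=0)
    assert imps.n_imputations == 4
    for p in imps.completed_panels:
        assert p.data[p.item_names].equals(panel.data[panel.item_names])


def test_impute_preserves_observed_cells_and_varies_missing():
    spec = default_mdd_control_spec(2, n_subjects_per_group=2, n_items=4, missing_rate=0.1)
    panel, _ = generate_panel(spec)
    _, _, X = panel.to_arrays()
    obs = ~np.isnan(X)
    imps = impute(panel, 3, seed=0)
    arrays = [p.to_arrays()[2] for p in imps.completed_panels]
    for Xi in arrays:
        assert not np.isnan(Xi).any()
        assert (Xi[obs] == X[obs]).all()  # bitwise equality on observed cells
    assert not np.array_equal(arrays[0][~obs], arrays[1][~obs])


def test_impute_single_missing_cell():
    spec = default_mdd_control_spec(2, n_subjects_per_group=2, n_items=4, missing_rate=0.0)
    panel, _ = generate_panel(spec)
    df = panel.data.copy()
    df.loc[df.index[10], panel.item_names[0]] = np.nan
    panel2 = type(panel)(df, panel.item_names)
    imps = impute(panel2, 10, seed=1)
    assert imps.n_imputations == 10
    obs_cols = panel.item_names[1:]
    for p in imps.completed_panels:
        assert p.data[obs_cols].equals(panel.data[obs_cols])


def test_impute_beats_unconditional_mean_baseline():
    # chained imputation uses same-time items and lag/lead, so its MI point
    # estimate should beat per-subject mean imputation on recovered values
    spec = default_mdd_control_spec(7, n_subjects_per_group=6, n_items=6)
    panel, _ = generate_panel(spec)
    full, _ = generate_panel(dataclasses.replace(spec, missing_rate=0.0))
    _, _, Xm = panel.to_arrays()
    _, _, Xf = full.to_arrays()
    mask = np.isnan(Xm)
    imps = impute(panel, 10, seed=7)
    mi_mean = np.mean([p.to_arrays()[2] for p in imps.completed_panels], axis=0)
    err_mi = np.abs(mi_mean[mask] - Xf[mask]).mean()
    base = np.broadcast_to(
        np.nanmean(np.where(mask, np.nan, Xm), axis=1, keepdims=True), Xm.shape)
    err_base = np.abs(base[mask] - Xf[mask]).mean()
    assert err_mi < err_base


def test_impute_fails_on_fully_missing_item():
    spec = default_mdd_control_spec(2, n_subjects_per_group=2, n_items=4, missing_rate=0.0)
    panel, _ = generate_panel(spec)
    df = panel.data.copy()
    sid = panel.subjects[0]
    df.loc[df["subject_id"] == sid, panel.item_names[2]] = np.nan
    with pytest.raises(ValueError, match="entirely missing"):
        impute(type(panel)(df, panel.item_names), 2, seed=0)


# ---------------------------------------------------------------- centering

def test_person_mean_center_examples(build_panel):
    vals = {"a": np.column_stack([np.tile([1.0, 2.0, 3.0], 4)]),
            "b": np.column_stack([np.tile([10.0, 11.0, 12.0], 4)])}
    panel = build_panel(vals, {"a": "MDD", "b": "control"}, 4, 3, ["x"])
    out = person_mean_center(panel)
    for sid in ("a", "b"):
        w = out.wide(sid)[:, 0]
        assert abs(w.mean()) < 1e-12
    assert np.allclose(out.wide("a")[:3, 0], [-1, 0, 1])
    # centering an already-centered panel changes nothing
    again = person_mean_center(out)
    assert np.allclose(again.wide("b"), out.wide("b"))


# ----------------------------------------------------------------- pipeline

def _small_imps(seed=3, missing=0.0, n_imp=1):
    spec = default_mdd_control_spec(seed, n_subjects_per_group=3, n_items=4,
                                    missing_rate=missing)
    panel, _ = generate_panel(spec)
    return impute(panel, n_imp, seed=seed)


def test_pipeline_all_off_is_identity():
    imps = _small_imps()
    cfg = PreprocessConfig(n_imputations=1, detrend=False, transform=False, center=False)
    out = apply_pipeline(imps, cfg)
    assert out[0].data.equals(imps.completed_panels[0].data)


def test_groupwise_vs_individual_nqt_on_disjoint_subjects(build_panel):
    rng = np.random.default_rng(0)
    lo = rng.uniform(0, 1, size=(30, 1))
    hi = rng.uniform(10, 11, size=(30, 1))
    panel = build_panel({"lo": lo, "hi": hi}, {"lo": "MDD", "hi": "MDD"}, 10, 3, ["x"])
    imps = impute(panel, 1, seed=0)
    grp = apply_pipeline(imps, PreprocessConfig(n_imputations=1, detrend=False,
                                                level=GROUP_WISE))[0]
    ind = apply_pipeline(imps, PreprocessConfig(n_imputations=1, detrend=False,
                                                level=PER_INDIVIDUAL))[0]
    # pooled marginal: the low subject fills the lower tail, the high one the upper
    assert grp.wide("lo").max() < 0 < grp.wide("hi").min()
    # per-individual: both subjects separately look standard normal
    for sid in ("lo", "hi"):
        w = ind.wide(sid)[:, 0]
        assert abs(w.mean()) < 0.1 and 0.8 < w.std() < 1.2


def test_detrend_then_transform_reduces_time_correlation():
    spec = default_mdd_control_spec(31, n_subjects_per_group=3, n_items=4,
                                    missing_rate=0.0)
    spec = dataclasses.replace(spec, trend_amplitude=2.0)
    panel, _ = generate_panel(spec)
    imps = impute(panel, 1, seed=31)

    def mean_time_corr(processed):
        t = np.arange(processed.data.groupby("subject_id").size().iloc[0])
        cors = []
        for sid in processed.subjects:
            w = processed.wide(sid)
            for j in range(w.shape[1]):
                if w[:, j].std() > 0:
                    cors.append(abs(np.corrcoef(t, w[:, j])[0, 1]))
        return np.mean(cors)

    with_detrend = apply_pipeline(imps, PreprocessConfig(n_imputations=1))[0]
    without = apply_pipeline(imps, PreprocessConfig(n_imputations=1, detrend=False))[0]
    assert mean_time_corr(with_detrend) < mean_time_corr(without)


def test_pipeline_deterministic_given_seed():
    imps1 = _small_imps(seed=5, missing=0.075, n_imp=2)
    imps2 = _small_imps(seed=5, missing=0.075, n_imp=2)
    cfg = PreprocessConfig(n_imputations=2)
    out1 = apply_pipeline(imps1, cfg)
    out2 = apply_pipeline(imps2, cfg)
    for a, b in zip(out1, out2):
        assert a.data.equals(b.data)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(n_imputations=0).validate()
    with pytest.raises(ValueError):
        PreprocessConfig(level="cohort").validate()
    with pytest.raises(ValueError):
        PreprocessConfig(detrend_df=0.5).validate()
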