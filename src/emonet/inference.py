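"""Group comparison and individual-difference inference.

* Monte Carlo permutation test on network density: subjects (not beeps) are
  reshuffled into two pseudo-groups of the original sizes, the group networks
  are refitted with identical penalties, and the observed density difference
  is located in the permutation null.  Faithfully, group-wise preprocessing
  (the pooled normal quantile transformation) is redone inside every
  permutation, because the preprocessing level is part of the pipeline under
  test; a fast variant that freezes preprocessing is available but is not the
  faithful procedure.
* Univariate OLS regressions of per-subject network density on baseline
  covariates (group, neuroticism, mean NA pooled; severity per group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import EDGES_EXCL_AR, DirectedNetwork, density
from .panel import EmotionPanel
from .preprocess import GROUP_WISE, ImputationSet, PreprocessConfig, nqt
from .tscgm import LambdaPair, fit_tscgm

SPARSE = "sparse"
MULTILEVEL = "multilevel"


@dataclass
class PermutationResult:
    observed_diff: float
    null_draws: np.ndarray           # per-permutation diffs, mean over imputations
    tail_prop_lower: float           # P(null <= observed), averaged over imputations
    tail_prop_upper: float
    n_perm: int
    per_imputation: list[tuple[float, float, float]]  # (obs_diff, lower, upper)
    averaged: bool
    group_order: tuple[str, str]
    n_failed: int = 0


# ---------------------------------------------------------------------------
# fast array-level machinery for the sparse estimator
# ---------------------------------------------------------------------------

def _nqt_pooled(X_g: np.ndarray) -> np.ndarray:
    """Group-wise transformation: pool all subjects per item."""
    S, T, p = X_g.shape
    out = np.empty_like(X_g)
    for j in range(p):
        out[:, :, j] = nqt(X_g[:, :, j].ravel()).reshape(S, T)
    return out


def _transitions_from_array(X_g: np.ndarray, beeps: np.ndarray, drop_overnight: bool):
    keep = np.ones(X_g.shape[1] - 1, dtype=bool)
    if drop_overnight:
        keep &= beeps[1:] != 1
    Xp = X_g[:, :-1][:, keep].reshape(-1, X_g.shape[2])
    Xc = X_g[:, 1:][:, keep].reshape(-1, X_g.shape[2])
    return Xp, Xc


def _sparse_group_density(X_g, beeps, lambdas, density_def, drop_overnight,
                          transform_groupwise, fit_kwargs=None):
    if transform_groupwise:
        X_g = _nqt_pooled(X_g)
    Xp, Xc = _transitions_from_array(X_g, beeps, drop_overnight)
    fit = fit_tscgm(Xp, Xc, lambdas, check_scale=False, **(fit_kwargs or {}))
    return density(DirectedNetwork(fit.A), density_def)


def _multilevel_group_density(panel: EmotionPanel, subjects, density_def, drop_overnight):
    from .multilevel import fit_multilevel

    sub = EmotionPanel(
        panel.data[panel.data["subject_id"].isin(list(subjects))].copy(),
        list(panel.item_names),
    )
    fit = fit_multilevel(sub, drop_overnight=drop_overnight)
    return density(DirectedNetwork(fit.adjacency()), density_def)


# ---------------------------------------------------------------------------
# the permutation test
# ---------------------------------------------------------------------------

def permutation_density_test(
    imps: ImputationSet | list[EmotionPanel],
    group_labels: tuple[str, str],
    estimator: str = SPARSE,
    density_def: str = EDGES_EXCL_AR,
    lambdas: LambdaPair | None = None,
    config: PreprocessConfig | None = None,
    n_perm: int = 30_000,
    seed: int = 0,
    refit_preprocessing: bool = True,
    fit_kwargs: dict | None = None,
) -> PermutationResult:
    """Monte Carlo permutation test for a group difference in network density.

    ``imps`` holds detrended (but not yet quantile-transformed) completed
    panels: when ``config.transform`` is on at group-wise level and
    ``refit_preprocessing`` is True, the pooled transformation is recomputed
    inside every permutation with the permuted group memberships.  The
    observed difference is density(group_labels[0]) - density(group_labels[1]);
    the same permutation stream (deterministic given ``seed``) is applied in
    every imputed dataset and tail proportions are averaged across
    imputations.
    """
    panels = imps.completed_panels if isinstance(imps, ImputationSet) else list(imps)
    config = config or PreprocessConfig()
    lambdas = lambdas or LambdaPair()
    g1, g2 = group_labels
    ref = panels[0]
    subjects = ref.subjects
    groups = ref.group_of.loc[subjects].to_numpy()
    idx1 = np.flatnonzero(groups == g1)
    idx2 = np.flatnonzero(groups == g2)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError(f"both groups must be present; got sizes {len(idx1)}, {len(idx2)}")
    n1 = len(idx1)
    pool = np.concatenate([idx1, idx2])

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9E12)))
    perms = [rng.permutation(pool) for _ in range(n_perm)]

    groupwise_nqt = bool(config.transform) and config.level == GROUP_WISE and refit_preprocessing
    beeps = None
    per_imp = []
    null_mat = np.empty((len(panels), n_perm))
    n_failed = 0

    for mi, panel in enumerate(panels):
        if estimator == SPARSE:
            subj_list, _, X = panel.to_arrays()
            assert subj_list == subjects
            beeps = panel.data[panel.data["subject_id"] == subjects[0]]["beep"].to_numpy()
            if config.transform and not groupwise_nqt:
                # group-independent transform: do it once up front
                if config.level == GROUP_WISE:
                    Xw = X.copy()
                    for g, idx in ((g1, idx1), (g2, idx2)):
                        Xw[idx] = _nqt_pooled(X[idx])
                    X = Xw
                else:
                    S, T, p = X.shape
                    for si in range(S):
                        for j in range(p):
                            X[si, :, j] = nqt(X[si, :, j])

            def dens(idx_a, idx_b):
                da = _sparse_group_density(X[idx_a], beeps, lambdas, density_def,
                                           config.drop_overnight, groupwise_nqt,
                                           fit_kwargs)
                db = _sparse_group_density(X[idx_b], beeps, lambdas, density_def,
                                           config.drop_overnight, groupwise_nqt,
                                           fit_kwargs)
                return da - db
        else:
            subj_arr = np.asarray(subjects, dtype=object)

            def dens(idx_a, idx_b):
                da = _multilevel_group_density(panel, subj_arr[idx_a], density_def,
                                               config.drop_overnight)
                db = _multilevel_group_density(panel, subj_arr[idx_b], density_def,
                                               config.drop_overnight)
                return da - db

        obs = dens(idx1, idx2)
        draws = np.empty(n_perm)
        for b, perm in enumerate(perms):
            try:
                draws[b] = dens(perm[:n1], perm[n1:])
            except (ValueError, np.linalg.LinAlgError):
                draws[b] = np.nan
        bad = np.isnan(draws)
        n_failed += int(bad.sum())
        if bad.mean() > 0.01:
            raise RuntimeError(f"{bad.sum()} of {n_perm} permutation fits failed")
        ok = draws[~bad]
        lower = float((ok <= obs).mean())
        upper = float((ok >= obs).mean())
        per_imp.append((float(obs), lower, upper))
        null_mat[mi] = draws

    observed = float(np.mean([t[0] for t in per_imp]))
    return PermutationResult(
        observed_diff=observed,
        null_draws=np.nanmean(null_mat, axis=0),
        tail_prop_lower=float(np.mean([t[1] for t in per_imp])),
        tail_prop_upper=float(np.mean([t[2] for t in per_imp])),
        n_perm=n_perm,
        per_imputation=per_imp,
        averaged=len(panels) > 1,
        group_order=(g1, g2),
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# per-subject densities and their covariate regressions
# ---------------------------------------------------------------------------

def individual_densities(
    processed_panels: list[EmotionPanel],
    lambdas: LambdaPair | None = None,
    density_def: str = EDGES_EXCL_AR,
    drop_overnight: bool = False,
    fit_kwargs: dict | None = None,
) -> pd.Series:
    """Per-subject network density from individual fits, averaged over imputations."""
    from .tscgm import build_transition_set

    lambdas = lambdas or LambdaPair()
    ref = processed_panels[0]
    out = {}
    for sid in ref.subjects:
        vals = []
        for panel in processed_panels:
            Xp, Xc, _ = build_transition_set(panel, drop_overnight, [sid])
            if Xp.shape[0] < 20:
                raise ValueError(f"subject {sid}: fewer than 20 transitions")
            fit = fit_tscgm(Xp, Xc, lambdas, check_scale=False, **(fit_kwargs or {}))
            vals.append(density(DirectedNetwork(fit.A), density_def))
        out[sid] = float(np.mean(vals))
    return pd.Series(out, name="density")


@dataclass
class DensityRegression:
    predictor_name: str
    coefficient: float
    standard_error: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    subgroup: str = "pooled"


def _ols_density(y: np.ndarray, x: np.ndarray, name: str, subgroup: str) -> DensityRegression:
    import statsmodels.api as sm

    if np.ptp(x) == 0:
        raise ValueError(f"predictor '{name}' is constant in subgroup '{subgroup}'")
    if np.ptp(y) == 0:
        # densities identical across subjects: slope exactly 0, no evidence
        return DensityRegression(name, 0.0, 0.0, 1.0, (0.0, 0.0), len(y), subgroup)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int()[1]
    return DensityRegression(
        predictor_name=name,
        coefficient=float(res.params[1]),
        standard_error=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        ci95=(float(ci[0]), float(ci[1])),
        n=int(res.nobs),
        subgroup=subgroup,
    )


def individual_density_regressions(
    densities: pd.Series,
    covariates: pd.DataFrame,
    group_labels: tuple[str, str] = ("MDD", "control"),
) -> list[DensityRegression]:
    """The standard battery: group / neuroticism / mean NA pooled, severity per group.

    Regressions with a constant predictor are skipped (recorded nowhere: the
    caller sees fewer rows); each fit is plain univariate OLS with two-sided
    p-values and a 95% CI.
    """
    cov = covariates.loc[densities.index]
    y = densities.to_numpy(dtype=float)
    out = []
    specs = [
        ("group", (cov["group"] == group_labels[0]).astype(float).to_numpy(), "pooled", y),
        ("neuroticism", cov["neuroticism"].to_numpy(dtype=float), "pooled", y),
        ("mean_na", cov["mean_na"].to_numpy(dtype=float), "pooled", y),
    ]
    for g in group_labels:
        sel = (cov["group"] == g).to_numpy()
        specs.append(("bdi", cov.loc[sel, "bdi"].to_numpy(dtype=float), f"{g}-only", y[sel]))
    for name, x, subgroup, yy in specs:
        try:
            out.append(_ols_density(yy, x, name, subgroup))
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
    return out
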