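"""Preprocessing stack for diary panels.

Four composable steps, each applicable group-wise (pooled over all subjects
of a group) or per individual:

* multiple imputation of missing beeps (chained equations with posterior
  draws, conditioning on the other items at the same beep and on the lag/lead
  of the same item),
* detrending by subtracting a cubic smoothing spline with a fixed effective
  number of degrees of freedom (default 2, i.e. an essentially linear slow
  trend),
* the normal quantile transformation (rank-based Gaussianization),
* person-mean centering.

Order is fixed: impute -> detrend -> transform; centering, when requested,
applies last.  Detrending always operates per subject-item series; the
group-wise vs per-individual switch governs whose ranks the quantile
transformation pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .panel import EmotionPanel

GROUP_WISE = "group"
PER_INDIVIDUAL = "individual"


@dataclass
class PreprocessConfig:
    """Which steps run, and at what level.

    ``level`` controls the pooling of the quantile transformation:
    ``"group"`` pools every subject of a group into one marginal per item;
    ``"individual"`` transforms each subject-item series on its own ranks.
    ``drop_overnight`` does not change values -- it marks the first beep of
    each day as having no usable lagged predictor, which the estimators
    honour when building lagged designs.
    """

    n_imputations: int = 10
    detrend: bool = True
    detrend_df: float = 2.0
    transform: bool = True
    center: bool = False
    level: str = GROUP_WISE
    drop_overnight: bool = False

    def validate(self) -> None:
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.detrend_df < 1:
            raise ValueError("detrend_df must be >= 1")
        if self.level not in (GROUP_WISE, PER_INDIVIDUAL):
            raise ValueError(f"level must be '{GROUP_WISE}' or '{PER_INDIVIDUAL}'")


@dataclass
class ImputationSet:
    """A list of completed panels agreeing on all originally observed cells."""

    completed_panels: list[EmotionPanel]
    method: str
    seed: int

    @property
    def n_imputations(self) -> int:
        return len(self.completed_panels)


# ---------------------------------------------------------------------------
# smoothing spline with fixed effective df (Reinsch form)
# ---------------------------------------------------------------------------

def _second_difference_mats(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Green-Silverman Q (n x n-2) and R (n-2 x n-2) for unit spacing."""
    Q = np.zeros((n, n - 2))
    idx = np.arange(n - 2)
    Q[idx, idx] = 1.0
    Q[idx + 1, idx] = -2.0
    Q[idx + 2, idx] = 1.0
    R = np.zeros((n - 2, n - 2))
    R[idx, idx] = 2.0 / 3.0
    R[idx[:-1], idx[:-1] + 1] = 1.0 / 6.0
    R[idx[:-1] + 1, idx[:-1]] = 1.0 / 6.0
    return Q, R


def _spline_df(n: int, log10_lam: float) -> float:
    """Effective df = trace of the smoother matrix at penalty 10**log10_lam."""
    Q, R = _second_difference_mats(n)
    lam = 10.0**log10_lam
    B = R + lam * (Q.T @ Q)
    # df = n - lam * tr(B^{-1} Q^T Q)
    M = np.linalg.solve(B, Q.T @ Q)
    return n - lam * np.trace(M)


@lru_cache(maxsize=128)
def _lambda_for_df(n: int, df: float, tol: float = 1e-3) -> float:
    """Solve trace(S_lambda) = df by bisection on log10(lambda).

    df is monotone decreasing in lambda, from n (interpolation) down to 2
    (the straight-line limit); a df of exactly 2 is therefore resolved to
    within ``tol`` at a large but finite penalty.
    """
    if not 2.0 <= df < n:
        raise ValueError(f"detrend_df must be in [2, series length={n})")
    lo, hi = -10.0, 14.0
    if _spline_df(n, hi) > df + tol:
        return 10.0**hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        d = _spline_df(n, mid)
        if abs(d - df) <= tol:
            return 10.0**mid
        if d > df:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))


def detrend(series: np.ndarray, df: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Residual and fitted trend of a cubic smoothing spline with given df.

    The series is assumed equally spaced and complete (run after imputation).
    A constant or exactly linear series is reproduced by the spline, so its
    residuals are (numerically) zero.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("detrending needs series length >= 10")
    if np.isnan(y).any():
        raise ValueError("detrending requires a complete series (impute first)")
    lam = _lambda_for_df(n, float(df))
    Q, R = _second_difference_mats(n)
    B = R + lam * (Q.T @ Q)
    gamma = np.linalg.solve(B, Q.T @ y)
    trend = y - lam * (Q @ gamma)
    return y - trend, trend


# ---------------------------------------------------------------------------
# normal quantile transformation
# ---------------------------------------------------------------------------

def nqt(values: np.ndarray) -> np.ndarray:
    """Map values to standard-normal quantiles of their plotting positions.

    Uses the Weibull position p_i = r_i/(n+1) with average ranks for ties,
    so outputs stay finite and an all-tied input maps to all zeros.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("normal quantile transformation needs n >= 3")
    ranks = rankdata(x, method="average")
    return ndtri(ranks / (n + 1.0))


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

def _imputation_design(panel: EmotionPanel) -> np.ndarray:
    """Stacked (S*T) x 3p matrix: items, within-subject lags, within-subject leads."""
    subjects, _, X = panel.to_arrays()
    S, T, p = X.shape
    lag = np.full_like(X, np.nan)
    lead = np.full_like(X, np.nan)
    lag[:, 1:, :] = X[:, :-1, :]
    lead[:, :-1, :] = X[:, 1:, :]
    return np.concatenate([X, lag, lead], axis=2).reshape(S * T, 3 * p)


def impute(panel: EmotionPanel, n_imputations: int = 10, seed: int = 0) -> ImputationSet:
    """Multiple imputation by chained equations with posterior draws.

    Each item is regressed (Bayesian ridge) on the other items at the same
    beep plus the lag and lead of the same item within the subject; one
    posterior draw per missing cell per imputation.  Observed cells are left
    bit-for-bit untouched.
    """
    subjects, _, X = panel.to_arrays()
    S, T, p = X.shape
    items = panel.item_names

    # diagnostics before fitting anything
    problems = []
    for si, sid in enumerate(subjects):
        frac = np.isnan(X[si]).mean()
        if frac >= 0.5:
            problems.append(f"subject {sid}: {frac:.0%} missing overall")
        for j, name in enumerate(items):
            if np.isnan(X[si, :, j]).all():
                problems.append(f"subject {sid}: item '{name}' entirely missing")
    if problems:
        raise ValueError("cannot impute: " + "; ".join(problems))

    if panel.n_missing() == 0:
        return ImputationSet([panel.with_values(X) for _ in range(n_imputations)],
                             method="none (no missing cells)", seed=seed)

    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    design = _imputation_design(panel)
    completed = []
    ss = np.random.SeedSequence((seed, 0x1A1))
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_imputations)]
    for m in range(n_imputations):
        imputer = IterativeImputer(
            sample_posterior=True,
            max_iter=5,
            random_state=child_seeds[m],
            keep_empty_features=True,
        )
        filled = imputer.fit_transform(design)
        Xm = filled[:, :p].reshape(S, T, p)
        # observed cells: restore exactly (imputer keeps them, but be explicit)
        obs = ~np.isnan(X)
        Xm[obs] = X[obs]
        completed.append(panel.with_values(Xm))
    return ImputationSet(completed, method="chained equations (Bayesian ridge, posterior draws)",
                         seed=seed)


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def person_mean_center(panel: EmotionPanel) -> EmotionPanel:
    """Subtract each subject's own item means (requires complete data)."""
    _, _, X = panel.to_arrays()
    if np.isnan(X).any():
        raise ValueError("person-mean centering requires a complete panel")
    return panel.with_values(X - X.mean(axis=1, keepdims=True))


def _transform_panel(panel: EmotionPanel, level: str) -> EmotionPanel:
    subjects, groups, X = panel.to_arrays()
    S, T, p = X.shape
    out = X.copy()
    if level == PER_INDIVIDUAL:
        for si in range(S):
            for j in range(p):
                out[si, :, j] = nqt(X[si, :, j])
    else:
        for g in np.unique(groups):
            sel = np.flatnonzero(groups == g)
            for j in range(p):
                pooled = X[sel, :, j].ravel()
                out[sel, :, j] = nqt(pooled).reshape(len(sel), T)
    return panel.with_values(out)


def _detrend_panel(panel: EmotionPanel, df: float) -> EmotionPanel:
    subjects, _, X = panel.to_arrays()
    S, T, p = X.shape
    out = np.empty_like(X)
    for si in range(S):
        for j in range(p):
            out[si, :, j], _ = detrend(X[si, :, j], df)
    return panel.with_values(out)


def apply_pipeline(imps: ImputationSet, config: PreprocessConfig) -> list[EmotionPanel]:
    """Run detrend -> transform -> (center) on every completed panel."""
    config.validate()
    processed = []
    for panel in imps.completed_panels:
        cur = panel
        if config.detrend:
            cur = _detrend_panel(cur, config.detrend_df)
        if config.transform:
            cur = _transform_panel(cur, config.level)
        if config.center:
            cur = person_mean_center(cur)
        processed.append(cur)
    return processed


def preprocess(panel: EmotionPanel, config: PreprocessConfig, seed: int = 0) -> tuple[ImputationSet, list[EmotionPanel]]:
    """Impute then apply the configured pipeline; convenience wrapper."""
    imps = impute(panel, config.n_imputations, seed)
    return imps, apply_pipeline(imps, config)
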