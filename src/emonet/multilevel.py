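"""Multilevel (mixed-effects) lag-1 comparator.

For each target item, a univariate linear mixed model regresses the item at
time t on the lagged values of all items at t-1, with a subject-level random
intercept and independent random slopes (diagonal random-effect covariance --
an unstructured covariance does not estimate with 14 items).  An edge j -> k
is drawn when the fixed effect of lagged item j on item k is significant at
``alpha`` (two-sided Wald, normal approximation, no multiplicity
correction, matching the convention of the multilevel network literature).

The need for a fixed linear time trend is checked by comparing the average
BIC across the univariate models with and without the trend term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .panel import EmotionPanel


@dataclass
class MultilevelFit:
    """Fixed-effect lag matrix with inference, one column per target item.

    ``B[j, k]`` is the fixed effect of item j at t-1 on item k at t; the
    diagonal holds autoregressive effects.  ``fallback_items`` lists targets
    whose random slopes had to be dropped (random intercept only) to reach
    convergence.
    """

    B: np.ndarray
    SE: np.ndarray
    pvals: np.ndarray
    alpha: float
    item_names: list[str]
    random_structure: str = "random intercept + independent random slopes"
    fallback_items: list[str] = field(default_factory=list)
    trend_bic: pd.DataFrame | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.pvals < self.alpha

    def adjacency(self, include_nonsignificant: bool = False) -> np.ndarray:
        """Significance-thresholded (default) or raw fixed-effect matrix."""
        if include_nonsignificant:
            return self.B.copy()
        return np.where(self.significant, self.B, 0.0)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        p = len(self.item_names)
        for j in range(p):
            for k in range(p):
                rows.append({
                    "source": self.item_names[j],
                    "target": self.item_names[k],
                    "estimate": self.B[j, k],
                    "se": self.SE[j, k],
                    "p": self.pvals[j, k],
                    "significant": bool(self.significant[j, k]),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def lagged_frame(panel: EmotionPanel, drop_overnight: bool = False) -> pd.DataFrame:
    """Long lag-1 design: one row per usable (t-1, t) pair.

    Rows whose lagged predictor is unavailable are dropped: the first beep of
    each subject always, and (with ``drop_overnight``) the first beep of every
    day.  ``time01`` is global time scaled to [0, 1] within each subject.
    """
    items = panel.item_names
    frames = []
    for sid in panel.subjects:
        sub = panel.data[panel.data["subject_id"] == sid].reset_index(drop=True)
        vals = sub[items].to_numpy(dtype=float)
        T = len(sub)
        keep = np.ones(T - 1, dtype=bool)
        if drop_overnight:
            keep &= sub["beep"].to_numpy()[1:] != 1
        d = {"subject": sid,
             "time01": (sub["time"].to_numpy()[1:][keep] - 1) / max(T - 1, 1)}
        for i, name in enumerate(items):
            d[f"y_{name}"] = vals[1:, i][keep]
            d[f"lag_{name}"] = vals[:-1, i][keep]
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


def _mixed_bic(result) -> float:
    """BIC on the ML likelihood: all fixed + variance parameters counted."""
    model = result.model
    k_var = model.k_re * (model.k_re + 1) // 2 + model.k_vc
    k = model.k_fe + k_var + 1  # + residual variance
    return float(-2.0 * result.llf + np.log(model.nobs) * k)


def _fit_one_item(frame: pd.DataFrame, target: str, items: list[str],
                  with_trend: bool, with_slopes: bool):
    import statsmodels.formula.api as smf

    fixed = " + ".join(f"lag_{n}" for n in items)
    formula = f"y_{target} ~ 1 + {fixed}"
    if with_trend:
        formula += " + time01"
    vc = {f"lag_{n}": f"0 + lag_{n}" for n in items} if with_slopes else None

    def _ok(res):
        return (np.isfinite(res.llf) and np.isfinite(res.fe_params).all()
                and np.isfinite(res.bse_fe).all())

    # variance parameters frequently sit on the boundary (zero variances), so
    # cascade optimizers and keep the best finite ML solution
    best = None
    for method in ("lbfgs", "powell", "bfgs"):
        model = smf.mixedlm(formula, frame, groups=frame["subject"],
                            re_formula="1", vc_formula=vc)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=False, method=method, maxiter=300)
                finite = _ok(result)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if finite:
            if best is None or result.llf > best.llf + 1e-8:
                best = result
            if result.converged:
                break
    if best is None:
        raise np.linalg.LinAlgError("mixed model failed with every optimizer")
    return best


def fit_multilevel(
    panel: EmotionPanel,
    drop_overnight: bool = False,
    alpha: float = 0.05,
) -> MultilevelFit:
    """Per-item univariate mixed models; returns the fixed-effect lag matrix.

    Targets whose mixed fit fails or is singular are refitted with the random
    slopes dropped (random intercept only) and flagged.
    """
    items = panel.item_names
    if len(panel.subjects) < 2:
        raise ValueError("multilevel fitting needs at least 2 subjects")
    frame = lagged_frame(panel, drop_overnight)
    p = len(items)
    B = np.zeros((p, p))
    SE = np.zeros((p, p))
    pvals = np.ones((p, p))
    fallback = []
    for k, target in enumerate(items):
        try:
            result = _fit_one_item(frame, target, items, with_trend=False, with_slopes=True)
        except (np.linalg.LinAlgError, ValueError):
            result = _fit_one_item(frame, target, items, with_trend=False, with_slopes=False)
            fallback.append(target)
        for j, source in enumerate(items):
            est = result.fe_params[f"lag_{source}"]
            se = result.bse_fe[f"lag_{source}"]
            z = est / se if se > 0 else 0.0
            B[j, k] = est
            SE[j, k] = se
            pvals[j, k] = 2.0 * (1.0 - ndtr(abs(z)))
    return MultilevelFit(B=B, SE=SE, pvals=pvals, alpha=alpha, item_names=list(items),
                         fallback_items=fallback)


def trend_bic_check(
    panel: EmotionPanel,
    drop_overnight: bool = False,
) -> tuple[str, pd.DataFrame]:
    """Average-BIC comparison of models with vs without a linear time trend.

    Returns ``("no trend" | "trend", table)`` where the table holds per-item
    BICs for both variants; "no trend" wins ties.
    """
    items = panel.item_names
    frame = lagged_frame(panel, drop_overnight)
    rows = []
    for target in items:
        bics = {}
        for with_trend in (False, True):
            try:
                result = _fit_one_item(frame, target, items, with_trend, with_slopes=True)
            except (np.linalg.LinAlgError, ValueError):
                result = _fit_one_item(frame, target, items, with_trend, with_slopes=False)
            bics[with_trend] = _mixed_bic(result)
        rows.append({"item": target, "bic_no_trend": bics[False], "bic_trend": bics[True]})
    table = pd.DataFrame(rows)
    decision = "no trend" if table["bic_no_trend"].mean() <= table["bic_trend"].mean() else "trend"
    return decision, table
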