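"""Sparse lag-1 VAR / time-series chain graphical model.

The model couples a directed temporal network and an undirected
contemporaneous network: observations follow

    x_t = x_{t-1} A + eps_t,      eps_t ~ N(0, Omega^{-1}),

and both the cross-lagged matrix A (entry (j, k): item j at t-1 -> item k at
t) and the innovation precision Omega are estimated under L1 penalties by
minimizing the penalized negative Gaussian log-likelihood

    -log det Omega + tr(S_A Omega)
        + lambda_Omega * sum_{j != k} |omega_jk|
        + 2 * lambda_A * sum_{j,k} |a_jk|,

with S_A = (Y - X A)' (Y - X A) / n, alternating a graphical-lasso step in
Omega with a coordinate-descent lasso step in A (weighted by Omega).  Exact
zeros in A and in the off-diagonal of Omega are the sparse directed and
undirected networks.

Population fits pool within-subject transitions across subjects (a
constant-coefficient model); per-individual fits restrict to one subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import EmotionPanel

DEFAULT_LAMBDA_A = 0.38
DEFAULT_LAMBDA_OMEGA = 0.05


@dataclass
class LambdaPair:
    """L1 penalty weights: ``lambda_A`` on cross-lagged coefficients,
    ``lambda_Omega`` on off-diagonal precision entries."""

    lambda_A: float = DEFAULT_LAMBDA_A
    lambda_Omega: float = DEFAULT_LAMBDA_OMEGA

    def __post_init__(self) -> None:
        if self.lambda_A < 0 or self.lambda_Omega < 0:
            raise ValueError("penalties must be nonnegative")


@dataclass
class TscgmFit:
    """Fitted sparse VAR: temporal matrix, precision, derived quantities."""

    A: np.ndarray
    Omega: np.ndarray
    Sigma: np.ndarray
    partial_corr: np.ndarray
    lambdas: LambdaPair
    n_transitions: int
    iterations: int
    converged: bool
    objective_path: list[float] = field(default_factory=list)
    item_names: list[str] | None = None


# ---------------------------------------------------------------------------
# transition bookkeeping
# ---------------------------------------------------------------------------

def build_transition_set(
    panel: EmotionPanel,
    drop_overnight: bool = False,
    subjects: list | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within-subject consecutive (t-1, t) pairs as paired design matrices.

    Returns ``(X_prev, X_curr, subject_of_row)``.  Pairs never span two
    subjects; with ``drop_overnight`` the pairs whose *current* observation is
    the first beep of a day are excluded (the overnight lag is treated as
    missing).
    """
    use = subjects if subjects is not None else panel.subjects
    prev_rows, curr_rows, owner = [], [], []
    for sid in use:
        sub = panel.data[panel.data["subject_id"] == sid]
        vals = sub[panel.item_names].to_numpy(dtype=float)
        beeps = sub["beep"].to_numpy()
        T = len(sub)
        if T < 3:
            raise ValueError(f"subject {sid}: fewer than 2 transitions available")
        keep = np.ones(T - 1, dtype=bool)
        if drop_overnight:
            keep &= beeps[1:] != 1
        prev_rows.append(vals[:-1][keep])
        curr_rows.append(vals[1:][keep])
        owner.extend([sid] * int(keep.sum()))
    X_prev = np.vstack(prev_rows)
    X_curr = np.vstack(curr_rows)
    return X_prev, X_curr, np.asarray(owner, dtype=object)


# ---------------------------------------------------------------------------
# penalized objective and alternating solver
# ---------------------------------------------------------------------------

def _grams(X_prev: np.ndarray, X_curr: np.ndarray):
    n = X_prev.shape[0]
    return X_prev.T @ X_prev, X_prev.T @ X_curr, X_curr.T @ X_curr, n


def _residual_cov(G, C, Syy, n, A):
    """S_A = (Y - XA)'(Y - XA) / n from Gram matrices."""
    return (Syy - A.T @ C - C.T @ A + A.T @ G @ A) / n


def penalized_objective(X_prev, X_curr, A, Omega, lambdas: LambdaPair) -> float:
    """The exact objective the alternating solver minimizes."""
    G, C, Syy, n = _grams(X_prev, X_curr)
    return _objective_from_grams(G, C, Syy, n, A, Omega, lambdas)


def _objective_from_grams(G, C, Syy, n, A, Omega, lambdas: LambdaPair) -> float:
    S_A = _residual_cov(G, C, Syy, n, A)
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        return np.inf
    pen_O = lambdas.lambda_Omega * (np.abs(Omega).sum() - np.abs(np.diag(Omega)).sum())
    pen_A = 2.0 * lambdas.lambda_A * np.abs(A).sum()
    return float(-logdet + np.sum(S_A * Omega) + pen_O + pen_A)


def _omega_step(S_A: np.ndarray, lam: float, tol: float = 1e-5,
                max_iter: int = 500) -> np.ndarray:
    """Graphical lasso on S_A (off-diagonal penalty only); closed form at 0."""
    p = S_A.shape[0]
    if lam <= 0:
        try:
            return np.linalg.inv(S_A)
        except np.linalg.LinAlgError:
            jitter = 1e-8 * np.trace(S_A) / p
            return np.linalg.inv(S_A + jitter * np.eye(p))
    from sklearn.covariance import graphical_lasso
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            _, prec = graphical_lasso(S_A, alpha=lam, tol=tol, max_iter=max_iter)
        except FloatingPointError:
            jitter = 1e-8 * np.trace(S_A) / p
            _, prec = graphical_lasso(S_A + jitter * np.eye(p), alpha=lam, tol=tol,
                                      max_iter=max_iter)
    return 0.5 * (prec + prec.T)


def _a_step(G, C, n, A, Omega, lam_A: float, inner_tol: float = 1e-6,
            max_sweeps: int = 1000) -> np.ndarray:
    """Cyclic coordinate descent on the Omega-weighted lasso for A.

    Minimizes tr(Omega (Y-XA)'(Y-XA))/n + 2*lam_A*sum|a_jk| using Gram
    matrices only; row-major sweep order, convergence when the largest
    coefficient change in a sweep is below ``inner_tol``.
    """
    p = A.shape[0]
    if lam_A == 0:
        # exact minimizer: weighted LS decouples to plain multivariate OLS
        return np.linalg.solve(G, C)
    A = A.copy()
    CO = C @ Omega
    M = G @ A @ Omega  # maintained incrementally
    Gd = np.diag(G)
    Od = np.diag(Omega)

    def sweep(coords):
        max_delta = 0.0
        for j, k in coords:
            h = Gd[j] * Od[k]
            if h <= 0:
                continue
            z = A[j, k] + (CO[j, k] - M[j, k]) / h
            thr = lam_A * n / h
            new = np.sign(z) * max(abs(z) - thr, 0.0)
            delta = new - A[j, k]
            if delta != 0.0:
                A[j, k] = new
                M[:, :] += delta * np.outer(G[:, j], Omega[k, :])
                max_delta = max(max_delta, abs(delta))
        return max_delta

    all_coords = [(j, k) for j in range(p) for k in range(p)]
    sweeps = 0
    while sweeps < max_sweeps:
        # full pass establishes the active set ...
        full_delta = sweep(all_coords)
        sweeps += 1
        if full_delta < inner_tol:
            break
        # ... then iterate on the nonzero coordinates only until stable
        while sweeps < max_sweeps:
            active = [(j, k) for j, k in all_coords if A[j, k] != 0.0]
            if not active:
                break
            delta = sweep(active)
            sweeps += 1
            if delta < inner_tol:
                break
    return A


def fit_tscgm(
    X_prev: np.ndarray,
    X_curr: np.ndarray,
    lambdas: LambdaPair | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
    item_names: list[str] | None = None,
    check_scale: bool = True,
    omega_tol: float = 1e-5,
) -> TscgmFit:
    """Alternating estimation of (A, Omega) under the L1-penalized likelihood.

    Initializes A = 0, Omega = diag(1/var); alternates the graphical-lasso
    Omega-step and the coordinate-descent A-step until the relative change of
    the penalized objective drops below ``tol``.  If an (inexactly solved)
    subproblem ever fails to lower the objective, the previous iterate is kept
    and iteration stops, so the recorded objective path is non-increasing.
    """
    if lambdas is None:
        lambdas = LambdaPair()
    X_prev = np.asarray(X_prev, dtype=float)
    X_curr = np.asarray(X_curr, dtype=float)
    n, p = X_curr.shape
    if n < 2:
        raise ValueError("need at least 2 transitions")
    if check_scale:
        sds = X_curr.std(axis=0)
        if ((sds < 0.5) | (sds > 2.0)).any():
            warnings.warn(
                "column SDs outside (0.5, 2); penalties are scale-sensitive -- "
                "did preprocessing run?", stacklevel=2)

    G, C, Syy, n = _grams(X_prev, X_curr)
    A = np.zeros((p, p))
    S0 = Syy / n
    d = np.clip(np.diag(S0), 1e-12, None)
    Omega = np.diag(1.0 / d)

    path = [_objective_from_grams(G, C, Syy, n, A, Omega, lambdas)]
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        S_A = _residual_cov(G, C, Syy, n, A)
        Omega_new = _omega_step(S_A, lambdas.lambda_Omega, omega_tol)
        A_new = _a_step(G, C, n, A, Omega_new, lambdas.lambda_A)
        obj = _objective_from_grams(G, C, Syy, n, A_new, Omega_new, lambdas)
        prev = path[-1]
        if obj > prev:  # inexact subproblem no longer improves: keep old iterate
            converged = True
            break
        A, Omega = A_new, Omega_new
        path.append(obj)
        if abs(prev - obj) <= tol * max(1.0, abs(prev)):
            converged = True
            break
    if not converged:
        warnings.warn("tscgm did not converge; returning best iterate", stacklevel=2)

    Sigma = np.linalg.inv(Omega)
    pc = partial_correlation(Omega)
    return TscgmFit(A=A, Omega=Omega, Sigma=Sigma, partial_corr=pc, lambdas=lambdas,
                    n_transitions=n, iterations=iterations, converged=converged,
                    objective_path=path, item_names=item_names)


def partial_correlation(Omega: np.ndarray) -> np.ndarray:
    """rho_jk = -omega_jk / sqrt(omega_jj * omega_kk), unit diagonal."""
    d = np.sqrt(np.clip(np.diag(Omega), 1e-300, None))
    pc = -Omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


# ---------------------------------------------------------------------------
# model selection: BIC on circular block-bootstrap resamples
# ---------------------------------------------------------------------------

def tscgm_bic(X_prev, X_curr, fit: TscgmFit) -> float:
    """BIC = -2 loglik + log(n) * (nnz A + nnz upper-tri Omega + p)."""
    G, C, Syy, n = _grams(X_prev, X_curr)
    S_A = _residual_cov(G, C, Syy, n, fit.A)
    sign, logdet = np.linalg.slogdet(fit.Omega)
    p = fit.A.shape[0]
    loglik = 0.5 * n * (logdet - np.sum(S_A * fit.Omega) - p * np.log(2 * np.pi))
    k = int((fit.A != 0).sum()) + int((np.triu(fit.Omega, 1) != 0).sum()) + p
    return float(-2.0 * loglik + np.log(n) * k)


def _circular_block_indices(m: int, block_len: int, rng: np.random.Generator) -> np.ndarray:
    """Circular block bootstrap of 0..m-1 preserving within-block order."""
    n_blocks = int(np.ceil(m / block_len))
    starts = rng.integers(0, m, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_len)[None, :]) % m
    return idx.ravel()[:m]


def select_lambda_blockboot(
    X_prev: np.ndarray,
    X_curr: np.ndarray,
    subject_of_row: np.ndarray,
    candidate_lambdas_A: list[float],
    lambda_Omega: float = DEFAULT_LAMBDA_OMEGA,
    n_boot: int = 100,
    block_len: int | None = None,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> tuple[LambdaPair, np.ndarray]:
    """Pick lambda_A by BIC over circular-block-bootstrap resamples.

    Blocks are drawn within each subject's own transition sequence (resampling
    never crosses subject boundaries); for each resample the BIC-minimizing
    candidate is recorded, and the median of the ``n_boot`` selections (which
    lies inside their interquartile range) is returned.
    """
    cands = sorted(candidate_lambdas_A)
    if not cands:
        raise ValueError("candidate list must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB10C)))
    n = X_prev.shape[0]
    if block_len is None:
        block_len = int(np.ceil(np.sqrt(n)))
    subj_idx = {}
    for i, sid in enumerate(subject_of_row):
        subj_idx.setdefault(sid, []).append(i)

    choices = np.empty(n_boot)
    for b in range(n_boot):
        rows = []
        for sid, idx in subj_idx.items():
            idx = np.asarray(idx)
            m = len(idx)
            bl = min(block_len, m)
            rows.append(idx[_circular_block_indices(m, bl, rng)])
        rows = np.concatenate(rows)
        Xp, Xc = X_prev[rows], X_curr[rows]
        bics = []
        for lam in cands:
            fit = fit_tscgm(Xp, Xc, LambdaPair(lam, lambda_Omega), check_scale=False,
                            **(fit_kwargs or {}))
            bics.append(tscgm_bic(Xp, Xc, fit))
        choices[b] = cands[int(np.argmin(bics))]
    n_empty = sum(c == cands[-1] for c in choices)
    if n_empty == n_boot or n_empty == 0:
        pass  # informational only; median returned regardless
    med = float(np.quantile(choices, 0.5, method="lower"))
    # quantile(method="lower") guarantees the median is an actual candidate
    return LambdaPair(med, lambda_Omega), choices


# ---------------------------------------------------------------------------
# population fit averaged over imputations
# ---------------------------------------------------------------------------

@dataclass
class PopulationFit:
    """Element-wise mean over per-imputation fits, plus edge stability."""

    A: np.ndarray
    partial_corr: np.ndarray
    per_imputation: list[TscgmFit]
    stable_A: np.ndarray  # True where nonzero in > 50% of imputations
    stable_pc: np.ndarray
    item_names: list[str] | None = None


def fit_population(
    panels: list[EmotionPanel],
    group: str | None,
    lambdas: LambdaPair | None = None,
    drop_overnight: bool = False,
    **fit_kwargs,
) -> PopulationFit:
    """Constant-coefficient pooled fit per completed dataset, then averaged.

    ``group=None`` pools every subject; otherwise only the subjects with that
    group label.  An edge is flagged stable when nonzero in more than half of
    the imputations (display aid only).
    """
    fits = []
    failures = []
    for panel in panels:
        subjects = panel.subjects_in(group) if group is not None else None
        try:
            Xp, Xc, _ = build_transition_set(panel, drop_overnight, subjects)
            fits.append(fit_tscgm(Xp, Xc, lambdas, item_names=panel.item_names, **fit_kwargs))
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            failures.append(exc)
    if len(failures) > len(panels) / 2:
        raise RuntimeError(f"more than half of the imputation fits failed: {failures[0]}")
    A = np.mean([f.A for f in fits], axis=0)
    pc = np.mean([f.partial_corr for f in fits], axis=0)
    stable_A = np.mean([(f.A != 0) for f in fits], axis=0) > 0.5
    off = ~np.eye(A.shape[0], dtype=bool)
    stable_pc = np.mean([(f.partial_corr * off != 0) for f in fits], axis=0) > 0.5
    return PopulationFit(A=A, partial_corr=pc, per_imputation=fits, stable_A=stable_A,
                         stable_pc=stable_pc, item_names=fits[0].item_names)
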