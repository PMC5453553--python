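"""Synthetic diary cohorts with known lag-1 network ground truth.

The generator emulates the design of a thrice-daily, 30-day experience
sampling study of depressed and healthy participants: each subject follows a
stationary lag-1 vector autoregression on a latent continuous scale,

    x_t = x_{t-1} A_s + trend_t + shift_s + eps_t,   eps_t ~ N(0, Omega^{-1}),

with a sparse cross-lagged matrix ``A_s`` (the subject's perturbation of a
shared ``A_true``), a sparse innovation precision ``Omega``, a slow additive
trend, group- and subject-specific latent level offsets, discretization to a
1..7 Likert scale through per-item cutpoints, and missing-completely-at-random
dropout.  Because the ground-truth matrices are returned alongside the panel,
every downstream estimator can be scored for parameter and support recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import CONTROL, DEFAULT_ITEMS, MDD, META_COLS, NA_ITEMS, PA_ITEMS, EmotionPanel

BURN_IN = 100  # discarded leading steps of every latent series
_MAX_PERTURB_TRIES = 100


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic two-group cohort.

    ``A_true[j, k]`` is the effect of item ``j`` at lag t-1 on item ``k`` at
    time t (so the latent recursion multiplies row-vectors on the left).
    ``likert_cutpoints`` holds 6 strictly increasing thresholds per item; set
    it to None to emit the continuous latent series directly (useful to
    separate estimator behaviour from discretization bias).
    ``subject_level_sd`` adds per-subject, per-item baseline offsets drawn
    from N(0, sd^2), a group-specific amount of between-person heterogeneity
    in levels; ``hetero_sd`` perturbs the nonzero entries of ``A_true``
    per subject (heterogeneity in dynamics).
    """

    n_subjects_per_group: int = 27
    n_items: int = 14
    n_days: int = 30
    beeps_per_day: int = 3
    A_true: np.ndarray | None = None
    Omega_true: np.ndarray | None = None
    hetero_sd: float = 0.0
    trend_amplitude: float = 0.0
    likert_cutpoints: np.ndarray | None = None  # (p, 6) or None
    missing_rate: float = 0.075
    seed: int = 0
    group_shift: dict[str, np.ndarray] = field(default_factory=dict)  # group -> (p,)
    subject_level_sd: dict[str, float] = field(default_factory=dict)  # group -> sd
    overnight_A: np.ndarray | None = None  # optional distinct overnight transition
    item_names: list[str] | None = None
    n_pa: int | None = None  # leading items counted as positive affect

    # ------------------------------------------------------------- plumbing
    @property
    def T(self) -> int:
        return self.n_days * self.beeps_per_day

    def __post_init__(self) -> None:
        p = self.n_items
        if self.A_true is None:
            self.A_true = np.zeros((p, p))
        if self.Omega_true is None:
            self.Omega_true = np.eye(p)
        self.A_true = np.asarray(self.A_true, dtype=float)
        self.Omega_true = np.asarray(self.Omega_true, dtype=float)
        if self.likert_cutpoints is not None:
            self.likert_cutpoints = np.asarray(self.likert_cutpoints, dtype=float)
        if self.item_names is None:
            if p == len(DEFAULT_ITEMS):
                self.item_names = list(DEFAULT_ITEMS)
            else:
                self.item_names = [f"item_{i + 1}" for i in range(p)]
        for g in (MDD, CONTROL):
            self.group_shift.setdefault(g, np.zeros(p))
            self.group_shift[g] = np.asarray(self.group_shift[g], dtype=float)
            self.subject_level_sd.setdefault(g, 0.0)
        if self.n_pa is None:
            self.n_pa = len(PA_ITEMS) if p == len(DEFAULT_ITEMS) else p // 2

    def validate(self) -> None:
        p = self.n_items
        if self.A_true.shape != (p, p):
            raise ValueError("A_true must be n_items x n_items")
        if self.Omega_true.shape != (p, p):
            raise ValueError("Omega_true must be n_items x n_items")
        if not np.allclose(self.Omega_true, self.Omega_true.T, atol=1e-10):
            raise ValueError("Omega_true must be symmetric")
        if np.linalg.eigvalsh(self.Omega_true).min() <= 0:
            raise ValueError("Omega_true must be positive definite")
        if spectral_radius(self.A_true) >= 1:
            raise ValueError("A_true must have spectral radius < 1 (stationarity)")
        if self.likert_cutpoints is not None:
            if self.likert_cutpoints.shape != (p, 6):
                raise ValueError("likert_cutpoints must be (n_items, 6)")
            if not (np.diff(self.likert_cutpoints, axis=1) > 0).all():
                raise ValueError("likert_cutpoints must be strictly increasing per item")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.hetero_sd < 0:
            raise ValueError("hetero_sd must be nonnegative")

    # ----------------------------------------------------------------- YAML
    def to_yaml(self, path) -> None:
        d = {
            "n_subjects_per_group": self.n_subjects_per_group,
            "n_items": self.n_items,
            "n_days": self.n_days,
            "beeps_per_day": self.beeps_per_day,
            "A_true": self.A_true.tolist(),
            "Omega_true": self.Omega_true.tolist(),
            "hetero_sd": float(self.hetero_sd),
            "trend_amplitude": float(self.trend_amplitude),
            "likert_cutpoints": None
            if self.likert_cutpoints is None
            else self.likert_cutpoints.tolist(),
            "missing_rate": float(self.missing_rate),
            "seed": int(self.seed),
            "group_shift": {g: v.tolist() for g, v in self.group_shift.items()},
            "subject_level_sd": {g: float(v) for g, v in self.subject_level_sd.items()},
            "overnight_A": None if self.overnight_A is None else np.asarray(self.overnight_A).tolist(),
            "item_names": list(self.item_names),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("A_true", "Omega_true", "likert_cutpoints", "overnight_A"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        if "group_shift" in d:
            d["group_shift"] = {g: np.asarray(v, dtype=float) for g, v in d["group_shift"].items()}
        return cls(**d)


def spectral_radius(A: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(A)).max()) if A.size else 0.0


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _perturbed_A(A: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Subject-specific transition matrix: Gaussian noise on nonzero entries only.

    Retries until the perturbed matrix is stationary; noise on the true
    support keeps the support itself interpretable for recovery scoring.
    """
    if sd == 0:
        return A.copy()
    mask = A != 0
    for _ in range(_MAX_PERTURB_TRIES):
        A_s = A + sd * rng.standard_normal(A.shape) * mask
        if spectral_radius(A_s) < 1:
            return A_s
    raise RuntimeError(
        f"could not draw a stationary per-subject transition matrix in "
        f"{_MAX_PERTURB_TRIES} tries (hetero_sd={sd}, "
        f"spectral radius of A_true={spectral_radius(A):.3f}); lower hetero_sd"
    )


def _simulate_latent(
    A: np.ndarray,
    chol_sigma: np.ndarray,
    T: int,
    rng: np.random.Generator,
    overnight_A: np.ndarray | None = None,
    beeps_per_day: int | None = None,
) -> np.ndarray:
    p = A.shape[0]
    n = BURN_IN + T
    eps = rng.standard_normal((n, p)) @ chol_sigma.T
    x = np.empty((n, p))
    x[0] = eps[0]
    for t in range(1, n):
        At = A
        if overnight_A is not None and beeps_per_day is not None:
            # overnight step = transition into the first beep of a day
            if (t - BURN_IN) % beeps_per_day == 0:
                At = overnight_A
        x[t] = x[t - 1] @ At + eps[t]
    return x[BURN_IN:]


def generate_panel(spec: SyntheticSpec) -> tuple[EmotionPanel, dict]:
    """Simulate a two-group cohort from ``spec``.

    Returns the panel plus a ground-truth dict with the exact per-subject
    transition matrices (``A``: subject_id -> matrix), ``Omega`` and the
    latent (pre-discretization, pre-missingness) values.

    Every subject draws from an independently spawned child stream of
    ``spec.seed``, so panels are reproducible subject-by-subject and
    unchanged by the number of subjects generated before them.
    """
    spec.validate()
    p, T = spec.n_items, spec.T
    sigma = np.linalg.inv(spec.Omega_true)
    chol_sigma = np.linalg.cholesky(sigma)
    # half-period sinusoid over the whole series: a slow mood drift
    trend = spec.trend_amplitude * np.sin(np.pi * np.arange(T) / max(T - 1, 1))

    root = np.random.SeedSequence(spec.seed)
    n_total = 2 * spec.n_subjects_per_group
    streams = root.spawn(n_total + 1)
    cov_rng = np.random.default_rng(streams[-1])

    rows = []
    ground_truth: dict = {"A": {}, "Omega": spec.Omega_true.copy(), "latent": {}}
    day = np.repeat(np.arange(1, spec.n_days + 1), spec.beeps_per_day)
    beep = np.tile(np.arange(1, spec.beeps_per_day + 1), spec.n_days)
    time = np.arange(1, T + 1)

    cov_records = []
    for s_idx in range(n_total):
        group = MDD if s_idx < spec.n_subjects_per_group else CONTROL
        sid = f"{'mdd' if group == MDD else 'ctl'}_{(s_idx % spec.n_subjects_per_group) + 1:02d}"
        rng = np.random.default_rng(streams[s_idx])
        A_s = _perturbed_A(spec.A_true, spec.hetero_sd, rng)
        latent = _simulate_latent(
            A_s, chol_sigma, T, rng, spec.overnight_A, spec.beeps_per_day
        )
        # per-subject baseline: half a trait-affect component shared across
        # items (raising NA, lowering PA) and half item-specific noise
        trait = np.where(np.arange(p) < spec.n_pa, -1.0, 1.0)
        z = rng.standard_normal()
        offsets = (z * trait + rng.standard_normal(p)) / np.sqrt(2.0)
        level = spec.group_shift[group] + spec.subject_level_sd[group] * offsets
        latent = latent + trend[:, None] + level[None, :]
        ground_truth["A"][sid] = A_s
        ground_truth["latent"][sid] = latent.copy()

        if spec.likert_cutpoints is not None:
            values = np.empty_like(latent)
            for i in range(p):
                values[:, i] = np.searchsorted(spec.likert_cutpoints[i], latent[:, i]) + 1
        else:
            values = latent.copy()
        if spec.missing_rate > 0:
            miss = rng.uniform(size=values.shape) < spec.missing_rate
            values = values.astype(float)
            values[miss] = np.nan

        df = {"subject_id": sid, "group": group, "day": day, "beep": beep, "time": time}
        for i, name in enumerate(spec.item_names):
            df[name] = values[:, i]
        rows.append(df)
        cov_records.append((sid, group, latent))

    data = pd.concat([pd.DataFrame(d) for d in rows], ignore_index=True)

    covariates = _baseline_covariates(cov_records, spec, cov_rng)
    panel = EmotionPanel(data, list(spec.item_names), covariates)
    return panel, ground_truth


def _baseline_covariates(cov_records, spec: SyntheticSpec, rng: np.random.Generator):
    """Per-subject questionnaire-style covariates.

    Neuroticism and baseline depression severity are drawn so that the
    MDD-like group scores higher (severity strongly so, mirroring a
    design-based group split on the severity questionnaire); mean NA is the
    subject's observed mean over the latent NA items.
    """
    n_na = min(len(NA_ITEMS), spec.n_items)
    na_idx = list(range(spec.n_items - n_na, spec.n_items)) if spec.n_items >= n_na else []
    recs = []
    for sid, group, latent in cov_records:
        mean_na = float(latent[:, na_idx].mean()) if na_idx else 0.0
        if group == MDD:
            neuro = rng.normal(34.0, 8.0)
            bdi = rng.normal(31.0, 8.0)
        else:
            neuro = rng.normal(22.0, 8.0)
            bdi = abs(rng.normal(2.5, 2.0))
        recs.append({"subject_id": sid, "group": group, "neuroticism": neuro, "bdi": bdi, "mean_na": mean_na})
    return pd.DataFrame(recs).set_index("subject_id")


# ---------------------------------------------------------------------------
# default cohort
# ---------------------------------------------------------------------------

def default_sparse_A(p: int, rng: np.random.Generator, ar: float = 0.3, cross: float = 0.2,
                     n_cross: int | None = None) -> np.ndarray:
    """Stationary sparse transition matrix: AR diagonal plus ~10% cross edges."""
    if n_cross is None:
        n_cross = max(1, round(0.1 * p * (p - 1)))
    for _ in range(200):
        A = np.diag(np.full(p, ar))
        off = [(j, k) for j in range(p) for k in range(p) if j != k]
        pick = rng.choice(len(off), size=n_cross, replace=False)
        for idx in pick:
            j, k = off[idx]
            A[j, k] = cross * rng.choice([-1.0, 1.0])
        if spectral_radius(A) < 0.95:
            return A
    raise RuntimeError("failed to draw a stationary sparse transition matrix")


def default_tridiag_omega(p: int, off: float = 0.3) -> np.ndarray:
    """Sparse SPD precision: unit diagonal, tridiagonal contemporaneous ties."""
    Om = np.eye(p)
    for i in range(p - 1):
        Om[i, i + 1] = Om[i + 1, i] = off
    # guarantee positive definiteness
    ev = np.linalg.eigvalsh(Om).min()
    if ev <= 0.05:
        Om += (0.05 - ev + 0.05) * np.eye(p)
    return Om


def default_mdd_control_spec(
    seed: int,
    n_subjects_per_group: int = 27,
    n_items: int = 14,
    n_days: int = 30,
    beeps_per_day: int = 3,
    missing_rate: float = 0.075,
    continuous: bool = False,
) -> SyntheticSpec:
    """A documented two-group cohort with depressed-like vs healthy-like marginals.

    The NA items of the MDD-like group sit higher on the latent scale (and
    the PA items lower), so on the raw Likert scale the control-like group
    shows the floor effects typical of healthy diary data on negative items.
    The MDD-like group also gets larger between-person baseline spread.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    p = n_items
    A = default_sparse_A(p, rng)
    Om = default_tridiag_omega(p)

    n_pa = min(len(PA_ITEMS), p) if p == len(DEFAULT_ITEMS) else p // 2
    n_na = p - n_pa
    shift_mdd = np.concatenate([np.full(n_pa, 0.0), np.full(n_na, 1.2)])
    shift_ctl = np.concatenate([np.full(n_pa, 0.8), np.full(n_na, 0.0)])

    if continuous:
        cut = None
    else:
        # PA items: balanced cutpoints; NA items: cutpoints sitting high, so a
        # zero-mean (control-like) series piles up in categories 1-2.
        cut = np.empty((p, 6))
        cut[:n_pa] = np.linspace(-2.0, 2.0, 6)
        cut[n_pa:] = np.linspace(0.4, 3.4, 6)

    return SyntheticSpec(
        n_subjects_per_group=n_subjects_per_group,
        n_items=p,
        n_days=n_days,
        beeps_per_day=beeps_per_day,
        A_true=A,
        Omega_true=Om,
        hetero_sd=0.05,
        trend_amplitude=0.3,
        likert_cutpoints=cut,
        missing_rate=missing_rate,
        seed=seed,
        group_shift={MDD: shift_mdd, CONTROL: shift_ctl},
        subject_level_sd={MDD: 1.0, CONTROL: 0.5},
    )


# ---------------------------------------------------------------------------
# ground-truth export
# ---------------------------------------------------------------------------

def write_ground_truth(ground_truth: dict, item_names: list[str], out_dir) -> list:
    """One adjacency CSV per subject plus the shared precision matrix."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, A in ground_truth["A"].items():
        path = out / f"A_true_{sid}.csv"
        pd.DataFrame(A, index=item_names, columns=item_names).to_csv(path)
        written.append(path)
    path = out / "Omega_true.csv"
    pd.DataFrame(ground_truth["Omega"], index=item_names, columns=item_names).to_csv(path)
    written.append(path)
    return written
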