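import numpy as np
import pandas as pd
import pytest

from emonet import EmotionPanel
from emonet.synthetic import SyntheticSpec, generate_panel


def make_var_data(seed: int, n: int, A: np.ndarray, chol_sigma: np.ndarray | None = None,
                  burn: int = 200):
    """Plain stationary VAR(1) draw -> (X_prev, X_curr); independent of the
    package's cohort generator, for estimator-level tests."""
    rng = np.random.default_rng(seed)
    p = A.shape[0]
    if chol_sigma is None:
        chol_sigma = np.eye(p)
    x = np.zeros(p)
    rows = []
    for _ in range(burn + n + 1):
        x = x @ A + rng.standard_normal(p) @ chol_sigma.T
        rows.append(x.copy())
    X = np.asarray(rows[burn:])
    return X[:-1], X[1:]


def panel_from_arrays(values_by_subject: dict, groups: dict, n_days: int, beeps_per_day: int,
                      item_names: list[str]) -> EmotionPanel:
    """Assemble a balanced panel directly from per-subject (T, p) arrays."""
    T = n_days * beeps_per_day
    day = np.repeat(np.arange(1, n_days + 1), beeps_per_day)
    beep = np.tile(np.arange(1, beeps_per_day + 1), n_days)
    frames = []
    for sid, vals in values_by_subject.items():
        assert vals.shape == (T, len(item_names))
        d = {"subject_id": sid, "group": groups[sid], "day": day, "beep": beep,
             "time": np.arange(1, T + 1)}
        for i, name in enumerate(item_names):
            d[name] = vals[:, i]
        frames.append(pd.DataFrame(d))
    return EmotionPanel(pd.concat(frames, ignore_index=True), list(item_names))


@pytest.fixture
def var_data():
    return make_var_data


@pytest.fixture
def build_panel():
    return panel_from_arrays


@pytest.fixture
def small_continuous_cohort():
    """4 + 4 subjects, 3 items, continuous values, no missingness."""
    A = np.array([[0.3, 0.2, 0.0], [0.0, 0.3, 0.0], [0.0, 0.0, 0.3]])
    spec = SyntheticSpec(n_subjects_per_group=4, n_items=3, n_days=20, beeps_per_day=3,
                         A_true=A, missing_rate=0.0, likert_cutpoints=None, seed=99)
    panel, gt = generate_panel(spec)
    return spec, panel, gt
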