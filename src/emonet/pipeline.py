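"""End-to-end orchestration: simulate -> preprocess -> fit -> metrics -> inference.

A single :func:`run` drives the whole analysis grid (estimation method x
preprocessing level x density definition, per group), writes every artifact
as CSV/JSON/YAML under ``output_dir`` with the seed embedded in file names,
and records a manifest listing each artifact with per-stage wall times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import (SPARSE, MULTILEVEL, individual_densities,
                        individual_density_regressions, permutation_density_test)
from .metrics import DENSITY_DEFS, EDGES_EXCL_AR, DirectedNetwork, density, strengths
from .multilevel import fit_multilevel
from .panel import CONTROL, MDD, EmotionPanel
from .preprocess import GROUP_WISE, PER_INDIVIDUAL, ImputationSet, PreprocessConfig, apply_pipeline, impute
from .synthetic import SyntheticSpec, generate_panel, write_ground_truth
from .tscgm import LambdaPair, fit_population


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the package conventions
    (penalties 0.38 on the temporal matrix and 0.05 on the precision)."""

    spec_or_input: SyntheticSpec | str | Path
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    estimators: tuple[str, ...] = (SPARSE, MULTILEVEL)
    levels: tuple[str, ...] = ("population", "individual")
    lambdas: LambdaPair = field(default_factory=LambdaPair)
    n_perm: int = 1000
    density_defs: tuple[str, ...] = DENSITY_DEFS
    seed: int = 0
    output_dir: str | Path = "emonet_out"
    groups: tuple[str, str] = (MDD, CONTROL)

    def validate(self) -> None:
        if not self.estimators or not self.levels:
            raise ValueError("estimators and levels must be nonempty")
        for e in self.estimators:
            if e not in (SPARSE, MULTILEVEL):
                raise ValueError(f"unknown estimator {e!r}")
        self.preprocess.validate()


def _config_hash(config: RunConfig) -> str:
    payload = repr(config).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_fit_exports(fit_A, partial_corr, item_names, lambdas, n_info, stem: Path,
                       stable=None) -> list[Path]:
    written = []
    adj = pd.DataFrame(fit_A, index=item_names, columns=item_names)
    p1 = stem.with_suffix(".A.csv")
    adj.to_csv(p1)
    written.append(p1)
    if partial_corr is not None:
        p2 = stem.with_suffix(".partial_corr.csv")
        pd.DataFrame(partial_corr, index=item_names, columns=item_names).to_csv(p2)
        written.append(p2)
    net = DirectedNetwork(fit_A, item_names)
    p3 = stem.with_suffix(".edges.csv")
    net.edge_list(stable).to_csv(p3, index=False)
    written.append(p3)
    p4 = stem.with_suffix(".meta.json")
    with open(p4, "w") as fh:
        json.dump({"lambda_A": lambdas.lambda_A, "lambda_Omega": lambdas.lambda_Omega,
                   **n_info}, fh, indent=2)
    written.append(p4)
    return written


def run(config: RunConfig) -> dict:
    """Execute the configured grid; returns the manifest (also written to disk).

    Partial-stage failures are recorded under ``manifest['failures']`` and
    downstream dependents are skipped; callers treat a nonempty failure list
    as a nonzero exit.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    tag = f"seed{seed}"
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "artifacts": [],
        "failures": [],
        "wall_time_s": {},
    }

    def note(paths):
        for p in np.atleast_1d(paths):
            manifest["artifacts"].append(str(p))

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, *exc):
                manifest["wall_time_s"][name] = round(time.time() - self.t0, 3)
                return False

        return _T()

    # ------------------------------------------------------------ simulate
    with stage("simulate"):
        if isinstance(config.spec_or_input, SyntheticSpec):
            panel, gt = generate_panel(config.spec_or_input)
            spec_path = out / f"spec_{tag}.yaml"
            config.spec_or_input.to_yaml(spec_path)
            note(spec_path)
            note(write_ground_truth(gt, panel.item_names, out / f"ground_truth_{tag}"))
        else:
            panel = EmotionPanel.from_csv(config.spec_or_input)
            gt = None
        panel_path = out / f"panel_raw_{tag}.csv"
        panel.to_csv(panel_path)
        note(panel_path)
        if panel.covariates is not None:
            cov_path = out / f"covariates_{tag}.csv"
            panel.covariates.to_csv(cov_path)
            note(cov_path)

    # ------------------------------------------------------------ impute
    with stage("impute"):
        imps = impute(panel, config.preprocess.n_imputations, seed)

    # processed panels at both levels (detrend is level-independent)
    import dataclasses

    processed: dict[str, list[EmotionPanel]] = {}
    with stage("preprocess"):
        for level in (GROUP_WISE, PER_INDIVIDUAL):
            cfg = dataclasses.replace(config.preprocess, level=level)
            processed[level] = apply_pipeline(imps, cfg)
        proc_path = out / f"panel_processed_{config.preprocess.level}_{tag}.csv"
        processed[config.preprocess.level][0].to_csv(proc_path)
        note(proc_path)

    g1, g2 = config.groups
    grid_rows = []

    # ------------------------------------------------- population networks
    if "population" in config.levels:
        for level in (GROUP_WISE, PER_INDIVIDUAL):
            panels = processed[level]
            for group in (g1, g2):
                if SPARSE in config.estimators:
                    with stage(f"sparse_{level}_{group}"):
                        fit = fit_population(panels, group, config.lambdas,
                                             config.preprocess.drop_overnight)
                        stem = out / f"sparse_{level}_{group}_{tag}"
                        note(_write_fit_exports(fit.A, fit.partial_corr, fit.item_names,
                                                config.lambdas,
                                                {"n_imputations": len(panels)},
                                                stem, fit.stable_A))
                        net = DirectedNetwork(fit.A, fit.item_names)
                        st = strengths(net)
                        p_st = out / f"sparse_{level}_{group}_{tag}.strengths.csv"
                        st.to_frame().to_csv(p_st, index=False)
                        note(p_st)
                        for ddef in config.density_defs:
                            grid_rows.append({
                                "method": SPARSE,
                                "preprocessing": f"detrend+nqt ({level})",
                                "density_definition": ddef,
                                "group": group,
                                "density": density(net, ddef),
                            })
                if MULTILEVEL in config.estimators:
                    with stage(f"multilevel_{level}_{group}"):
                        try:
                            sub = EmotionPanel(
                                panels[0].data[panels[0].data["group"] == group].copy(),
                                list(panels[0].item_names))
                            mfit = fit_multilevel(sub, config.preprocess.drop_overnight)
                            p_ml = out / f"multilevel_{level}_{group}_{tag}.edges.csv"
                            mfit.edge_table().to_csv(p_ml, index=False)
                            note(p_ml)
                            for ddef in config.density_defs:
                                W = mfit.adjacency(include_nonsignificant=(ddef == "avg_all"))
                                grid_rows.append({
                                    "method": MULTILEVEL,
                                    "preprocessing": f"detrend+nqt ({level})",
                                    "density_definition": ddef,
                                    "group": group,
                                    "density": density(DirectedNetwork(W), ddef),
                                })
                        except Exception as exc:  # noqa: BLE001
                            manifest["failures"].append(
                                {"stage": f"multilevel_{level}_{group}", "error": str(exc)})

        grid_path = out / f"density_grid_{tag}.csv"
        pd.DataFrame(grid_rows).to_csv(grid_path, index=False)
        note(grid_path)

        # permutation test on the headline sparse group-wise pipeline
        if SPARSE in config.estimators and config.n_perm > 0:
            with stage("permutation"):
                try:
                    # the test redoes the pooled transformation itself, so it
                    # consumes the detrended (pre-transform) panels
                    cfg = dataclasses.replace(config.preprocess, level=GROUP_WISE)
                    detrended = apply_pipeline(
                        imps, dataclasses.replace(cfg, transform=False, center=False))
                    res = permutation_density_test(
                        detrended, (g1, g2), SPARSE, EDGES_EXCL_AR, config.lambdas,
                        cfg, config.n_perm, seed)
                    perm_path = out / f"permutation_{tag}.json"
                    with open(perm_path, "w") as fh:
                        json.dump({
                            "observed_diff": res.observed_diff,
                            "tail_prop_lower": res.tail_prop_lower,
                            "tail_prop_upper": res.tail_prop_upper,
                            "n_perm": res.n_perm,
                            "group_order": list(res.group_order),
                            "per_imputation": res.per_imputation,
                        }, fh, indent=2)
                    note(perm_path)
                    null_path = out / f"permutation_null_{tag}.csv"
                    pd.Series(res.null_draws, name="null_diff").to_csv(null_path, index=False)
                    note(null_path)
                except Exception as exc:  # noqa: BLE001
                    manifest["failures"].append({"stage": "permutation", "error": str(exc)})

    # ------------------------------------------------- individual networks
    if "individual" in config.levels and SPARSE in config.estimators:
        with stage("individual"):
            try:
                dens = individual_densities(processed[PER_INDIVIDUAL], config.lambdas,
                                            EDGES_EXCL_AR, config.preprocess.drop_overnight)
                dens_path = out / f"individual_densities_{tag}.csv"
                dens.rename_axis("subject_id").to_csv(dens_path)
                note(dens_path)
                if panel.covariates is not None:
                    regs = individual_density_regressions(dens, panel.covariates,
                                                          (g1, g2))
                    reg_path = out / f"density_regressions_{tag}.csv"
                    pd.DataFrame([{
                        "predictor": r.predictor_name,
                        "subgroup": r.subgroup,
                        "coefficient": r.coefficient,
                        "se": r.standard_error,
                        "p": r.p_value,
                        "ci_lo": r.ci95[0],
                        "ci_hi": r.ci95[1],
                        "n": r.n,
                    } for r in regs]).to_csv(reg_path, index=False)
                    note(reg_path)
            except Exception as exc:  # noqa: BLE001
                manifest["failures"].append({"stage": "individual", "error": str(exc)})

    manifest_path = out / f"manifest_{tag}.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
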