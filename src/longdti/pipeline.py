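"""Orchestration: simulate -> trajectories -> residualize -> PLS in one run.

``run_pipeline`` either generates a synthetic cohort or loads tables from
disk, runs the trajectory analysis on the two-group table, builds the brain
matrix from the patient subset (subjects with enough scans and complete
risk data), runs the PLS correlation against the risk factors, and writes
every stage output plus a ``report.json`` with seeds, counts and file
checksums sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ldio
from .pls import PLSResult, pls_correlation
from .residualize import build_brain_matrix
from .simulate import SimulationConfig, generate_cohort
from .tracts import RISK_FACTORS, measure_label
from .trajectories import run_trajectory_analysis

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of a full pipeline run."""

    out_dir: str | Path = "longdti_run"
    seed: int = 0
    # either simulate ...
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    # ... or load from disk
    long_table_path: str | Path | None = None
    risk_table_path: str | Path | None = None
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 500
    pls_group: str = "deletion"
    pls_min_scans: int = 2  # patients with repeated scans enter the PLS
    residualize_method: str = "per_scan"  # or "mean_age"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm <= 0 or self.n_boot <= 0:
            raise ValueError("n_perm and n_boot must be positive")
        if self.long_table_path is None and self.simulation is None:
            raise ValueError("provide either a simulation config or input tables")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = d["simulation"]
            for k in ("trajectory_spec", "group_offset"):
                sim[k] = {f"{t}:{m}": v for (t, m), v in sim[k].items()}
            for k in ("latent_behavior_weights", "latent_brain_weights"):
                sim[k] = np.asarray(sim[k]).tolist()
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pls_tables(result: PLSResult) -> dict[str, pd.DataFrame]:
    comps = pd.DataFrame(
        {
            "component": [c.index + 1 for c in result.components],
            "singular_value": result.singular_values,
            "explained_correlation": [c.explained_correlation for c in result.components],
            "perm_p": result.perm_p,
            "latent_r": result.scores.r,
        }
    )
    rows = []
    boot = result.bootstrap
    for k, c in enumerate(result.components):
        for j, name in enumerate(result.behavior_labels):
            rows.append(
                ("behavior", name, k + 1, c.behavior_saliences[j],
                 boot.behavior_mean[k, j], boot.behavior_sd[k, j],
                 boot.behavior_score[k, j], bool(boot.behavior_stable[k, j]))
            )
        for j, name in enumerate(result.brain_labels):
            rows.append(
                ("brain", name, k + 1, c.brain_saliences[j],
                 boot.brain_mean[k, j], boot.brain_sd[k, j],
                 boot.brain_score[k, j], bool(boot.brain_stable[k, j]))
            )
    weights = pd.DataFrame(
        rows,
        columns=["block", "variable", "component", "salience",
                 "boot_mean", "boot_sd", "boot_score", "stable"],
    )
    ncomp = len(result.components)
    scores = pd.DataFrame(
        np.hstack([result.scores.L_X, result.scores.L_Y]),
        columns=[f"L_X{k+1}" for k in range(ncomp)] + [f"L_Y{k+1}" for k in range(ncomp)],
    )
    return {"pls_components": comps, "pls_weights": weights, "pls_scores": scores}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "alpha": config.alpha,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "residualize_method": config.residualize_method,
        "stages": {},
        "checksums": {},
    }
    try:
        # --- inputs -----------------------------------------------------
        if config.long_table_path is not None:
            table = ldio.read_long_table(config.long_table_path)
            risk = ldio.read_risk_table(config.risk_table_path)
        else:
            table, risk, truth = generate_cohort(config.simulation, seed=config.seed)
            ldio.write_long_table(table, out / "long_table.tsv")
            ldio.write_risk_table(risk, out / "risk_factors.tsv")
            (out / "ground_truth.json").write_text(truth.to_json())
        report["stages"]["input"] = {
            "n_subjects": int(table["subject_id"].nunique()),
            "n_scans": int(table.drop_duplicates(["subject_id", "visit_index"]).shape[0]),
            "n_rows": int(len(table)),
        }

        # --- trajectories ----------------------------------------------
        traj = run_trajectory_analysis(table, alpha=config.alpha)
        traj.to_csv(out / "trajectories.tsv", sep="\t", index=False)
        ldio.write_json(
            {
                "age_center": traj.attrs["age_center"],
                "fdr_families": traj.attrs["fdr_families"],
                "estimation": "ML random-intercept, BIC on N_obs, "
                              "k = fixed effects + 2 variance components",
                "seed": config.seed,
            },
            out / "trajectories_meta.json",
        )
        report["stages"]["trajectories"] = {
            "n_models": int(len(traj)),
            "n_group_significant": int(traj["significant_group"].sum()),
            "n_interaction_significant": int(traj["significant_interaction"].sum()),
        }

        # --- residualize -------------------------------------------------
        patients = table[table["group"] == config.pls_group]
        n_scans = patients.drop_duplicates(["subject_id", "visit_index"]).groupby(
            "subject_id"
        ).size()
        keep = n_scans.index[n_scans >= config.pls_min_scans]
        subset = patients[patients["subject_id"].isin(keep)]
        X, models = build_brain_matrix(subset, method=config.residualize_method)
        ldio.write_brain_matrix(X, out / "brain_matrix.tsv")
        (out / "age_models.json").write_text(models.to_json())
        report["stages"]["residualize"] = {
            "n_age_models": len(models),
            "n_subjects": int(X.shape[0]),
            "n_measures": int(X.shape[1]),
        }

        # --- PLS ---------------------------------------------------------
        Y = risk.set_index("subject_id").loc[X.index, list(RISK_FACTORS)]
        pls = pls_correlation(
            X, Y, n_perm=config.n_perm, n_boot=config.n_boot, seed=config.seed
        )
        for name, df in _pls_tables(pls).items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        ldio.write_json(
            {
                "n_perm": config.n_perm,
                "n_boot": config.n_boot,
                "seed": config.seed,
                "n_redrawn_bootstrap": pls.bootstrap.n_redrawn,
                "sign_convention": "largest-|behavior salience| positive",
                "permutation_scheme": "Y rows permuted; rank-matched singular values",
            },
            out / "pls_meta.json",
        )
        report["stages"]["pls"] = {
            "n_components": len(pls.components),
            "n_significant": pls.n_significant(config.alpha),
            "perm_p": pls.perm_p.tolist(),
            "latent_r": pls.scores.r.tolist(),
        }

        for f in sorted(out.glob("*.tsv")):
            report["checksums"][f.name] = ldio.file_checksum(f)
        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed:\n%s", traceback.format_exc())
        ldio.write_json(report, out / "report.json")
        raise
    ldio.write_json(report, out / "report.json")
    return report
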