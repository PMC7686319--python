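"""Synthetic longitudinal DTI cohorts with planted ground truth.

The generator emulates a two-group accelerated-longitudinal design: control
and 22q11.2-deletion groups of ~100 subjects each, ages 5-35 at entry, 1-3
visits per subject at variable intervals, and per-scan tract-average
diffusion metrics (FA, AD, RD, MD over 18 tracts). Observations follow a
random-intercept model per (tract, metric) measure,

    value = b0 + b1*age + b2*age^2 + group_offset*[deletion]
            + sex_effect*[F] + scanner_effect*[B] + b_i + eps,

with b_i ~ N(0, sigma_b^2) per subject and measure, eps ~ N(0, sigma_e^2)
per scan. Five Bernoulli clinical risk factors are drawn per subject, and a
rank-1 latent brain-behavior component is planted: each subject's latent
score (risk factors z-coded against their prevalences, projected on the
unit behavior weights) shifts all of that subject's scans by

    latent_effect * sigma_b(metric) * score_i * w_brain[tract, metric],

i.e. a subject-level constant, so residualize-then-average recovers it.
``latent_effect`` is therefore expressed in units of the subject-level
(random-intercept) SD of each metric.

Default directions of group effects mirror the deletion-syndrome phenotype:
FA offset positive, AD/RD/MD offsets negative.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracts import (
    DEFAULT_METRICS,
    DEFAULT_TRACTS,
    RISK_FACTORS,
    measure_columns,
    measure_label,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "default_trajectory_spec",
    "default_group_offsets",
    "default_brain_weights",
    "default_behavior_weights",
]


class ConfigurationError(ValueError):
    """Invalid simulation settings."""


# Per-metric generating templates chosen to resemble tract-average values in
# school-age-to-adult cohorts: FA rises and saturates, diffusivities decline
# with age. Diffusivities are in um^2/ms so all metrics are O(1).
# (order, (b0, b1, b2)) with age in years (uncentered).
_METRIC_TEMPLATES: dict[str, tuple[int, tuple[float, float, float]]] = {
    "FA": (2, (0.300, 0.0090, -0.00012)),
    "AD": (1, (1.250, -0.0040, 0.0)),
    "RD": (1, (0.720, -0.0050, 0.0)),
    "MD": (2, (0.950, -0.0080, 0.00008)),
}

_METRIC_GROUP_OFFSETS = {"FA": 0.012, "AD": -0.020, "RD": -0.020, "MD": -0.020}
_METRIC_SEX_EFFECTS = {"FA": 0.004, "AD": -0.006, "RD": -0.006, "MD": -0.006}
_METRIC_SCANNER_EFFECTS = {"FA": -0.005, "AD": 0.008, "RD": 0.008, "MD": 0.008}
_METRIC_RI_SD = {"FA": 0.020, "AD": 0.030, "RD": 0.030, "MD": 0.028}
_METRIC_RES_SD = {"FA": 0.012, "AD": 0.020, "RD": 0.020, "MD": 0.018}

#: Prevalences of (uhr, preterm, low_baseline_iq, cognitive_decline,
#: baseline_anxiety), matching the reported subgroup sizes in a deletion
#: cohort of ~39 patients.
DEFAULT_RISK_PREVALENCE = (0.26, 0.31, 0.33, 0.41, 0.54)


def default_trajectory_spec(
    tracts: Sequence[str] = DEFAULT_TRACTS,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> dict[tuple[str, str], tuple[int, tuple[float, float, float]]]:
    """Per-(tract, metric) generating polynomial.

    All tracts share the metric template slope/curvature; intercepts are
    spread deterministically by +-5% across tracts so tracts are
    distinguishable.
    """
    spec = {}
    shifts = np.linspace(-0.05, 0.05, len(tracts))
    for m in metrics:
        order, (b0, b1, b2) = _METRIC_TEMPLATES.get(m, (1, (1.0, -0.003, 0.0)))
        for t, sh in zip(tracts, shifts):
            spec[(t, m)] = (order, (b0 * (1.0 + sh), b1, b2))
    return spec


def default_group_offsets(
    tracts: Sequence[str] = DEFAULT_TRACTS,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> dict[tuple[str, str], float]:
    return {(t, m): _METRIC_GROUP_OFFSETS.get(m, 0.0) for m in metrics for t in tracts}


def default_behavior_weights() -> np.ndarray:
    """Unit-norm behavior weights: a strong positive UHR loading, negative
    preterm and low-IQ loadings, near-zero decline/anxiety loadings."""
    w = np.array([0.75, -0.57, -0.32, -0.02, 0.03])
    return w / np.linalg.norm(w)


def default_brain_weights(
    tracts: Sequence[str] = DEFAULT_TRACTS,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> np.ndarray:
    """Unit-norm brain weights, positive on FA and negative on the
    diffusivities, uniform across tracts."""
    signs = np.array(
        [1.0 if m == "FA" else -1.0 for (_, m) in measure_columns(tracts, metrics)]
    )
    return signs / np.linalg.norm(signs)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator (see module docstring)."""

    n_per_group: int = 100
    age_range: tuple[float, float] = (5.0, 35.0)
    visit_probs: tuple[float, float, float] = (0.55, 0.40, 0.05)  # P(1,2,3 visits)
    visit_interval: tuple[float, float] = (3.0, 1.0)  # mean, sd in years
    tracts: tuple[str, ...] = DEFAULT_TRACTS
    metrics: tuple[str, ...] = DEFAULT_METRICS
    trajectory_spec: Mapping[tuple[str, str], tuple[int, tuple[float, float, float]]] | None = None
    group_offset: Mapping[tuple[str, str], float] | None = None
    group_age_slope: Mapping[str, float] = field(default_factory=dict)  # optional per-metric interaction
    sex_effect: Mapping[str, float] = field(default_factory=lambda: dict(_METRIC_SEX_EFFECTS))
    scanner_effect: Mapping[str, float] = field(default_factory=lambda: dict(_METRIC_SCANNER_EFFECTS))
    random_intercept_sd: Mapping[str, float] = field(default_factory=lambda: dict(_METRIC_RI_SD))
    residual_sd: Mapping[str, float] = field(default_factory=lambda: dict(_METRIC_RES_SD))
    scanner_b_prob: float = 0.37
    risk_prevalence: tuple[float, ...] = DEFAULT_RISK_PREVALENCE
    latent_effect: float = 1.0
    latent_behavior_weights: np.ndarray | None = None
    latent_brain_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ConfigurationError("n_per_group must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy min < max")
        p = np.asarray(self.visit_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ConfigurationError("visit_probs must be 3 nonnegative values summing to 1")
        if self.visit_interval[0] <= 0 or self.visit_interval[1] < 0:
            raise ConfigurationError("visit_interval mean must be > 0 and sd >= 0")
        if len(self.risk_prevalence) != len(RISK_FACTORS):
            raise ConfigurationError(f"risk_prevalence needs {len(RISK_FACTORS)} entries")
        if np.any((np.asarray(self.risk_prevalence) <= 0) | (np.asarray(self.risk_prevalence) >= 1)):
            raise ConfigurationError("risk prevalences must lie strictly in (0, 1)")
        for name in ("random_intercept_sd", "residual_sd"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.trajectory_spec is None:
            self.trajectory_spec = default_trajectory_spec(self.tracts, self.metrics)
        if self.group_offset is None:
            self.group_offset = default_group_offsets(self.tracts, self.metrics)
        if self.latent_behavior_weights is None:
            self.latent_behavior_weights = default_behavior_weights()
        if self.latent_brain_weights is None:
            self.latent_brain_weights = default_brain_weights(self.tracts, self.metrics)
        wY = np.asarray(self.latent_behavior_weights, dtype=float)
        wX = np.asarray(self.latent_brain_weights, dtype=float)
        n_meas = len(self.tracts) * len(self.metrics)
        if wY.shape != (len(RISK_FACTORS),) or not np.isclose(np.linalg.norm(wY), 1.0):
            raise ConfigurationError("latent_behavior_weights must be a unit vector of length 5")
        if wX.shape != (n_meas,) or not np.isclose(np.linalg.norm(wX), 1.0):
            raise ConfigurationError(
                f"latent_brain_weights must be a unit vector of length {n_meas}"
            )
        self.latent_behavior_weights = wY
        self.latent_brain_weights = wX

    @property
    def measures(self) -> list[tuple[str, str]]:
        return measure_columns(self.tracts, self.metrics)


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside a generated cohort."""

    config: SimulationConfig
    subjects: pd.DataFrame  # subject_id, group, sex, latent_score + risk columns
    random_intercepts: pd.DataFrame  # subjects x measures, metric units
    latent_deviation: pd.DataFrame  # subjects x measures: planted rank-1 deviation

    def to_json(self) -> str:
        cfg = dataclasses.asdict(self.config)
        for k in ("trajectory_spec", "group_offset"):
            cfg[k] = {f"{t}:{m}": v for (t, m), v in cfg[k].items()}
        for k in ("latent_behavior_weights", "latent_brain_weights"):
            cfg[k] = np.asarray(cfg[k]).tolist()
        return json.dumps(
            {
                "config": cfg,
                "subjects": self.subjects.to_dict(orient="list"),
                "random_intercepts": self.random_intercepts.to_dict(orient="list"),
                "latent_deviation": self.latent_deviation.to_dict(orient="list"),
            },
            default=float,
        )


def _draw_visit_ages(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Ages for one subject: first age uniform over the range, later visits
    spaced by a truncated-normal interval (> 0.5 y); visits running past the
    age ceiling are dropped."""
    lo, hi = cfg.age_range
    n_target = rng.choice((1, 2, 3), p=cfg.visit_probs)
    ages = [rng.uniform(lo, hi)]
    mean, sd = cfg.visit_interval
    while len(ages) < n_target:
        gap = rng.normal(mean, sd)
        for _ in range(100):
            if gap > 0.5:
                break
            gap = rng.normal(mean, sd)
        nxt = ages[-1] + max(gap, 0.5 + 1e-9)
        if nxt > hi:
            break
        ages.append(nxt)
    return np.asarray(ages)


def generate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (long metric table, risk-factor table, ground truth).

    The long table has one row per (subject, visit, tract, metric); the risk
    table one row per subject. Identical config and seed give identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = 2 * cfg.n_per_group
    measures = cfg.measures
    labels = [measure_label(t, m) for t, m in measures]

    ids = [f"S{i:04d}" for i in range(n)]
    group = np.array(["control"] * cfg.n_per_group + ["deletion"] * cfg.n_per_group)
    sex = rng.choice(["M", "F"], size=n)

    prev = np.asarray(cfg.risk_prevalence)
    risks = (rng.random((n, len(RISK_FACTORS))) < prev).astype(int)
    z = (risks - prev) / np.sqrt(prev * (1.0 - prev))
    score = z @ cfg.latent_behavior_weights

    ri_sd = np.array([cfg.random_intercept_sd.get(m, 0.0) for _, m in measures])
    res_sd = np.array([cfg.residual_sd.get(m, 0.0) for _, m in measures])
    b = rng.normal(0.0, 1.0, size=(n, len(measures))) * ri_sd
    latent_dev = cfg.latent_effect * ri_sd * score[:, None] * cfg.latent_brain_weights

    # scan-level frame
    subj_idx: list[int] = []
    visit_idx: list[int] = []
    scan_age: list[float] = []
    scan_scn: list[str] = []
    for i in range(n):
        ages = _draw_visit_ages(rng, cfg)
        scanners = np.where(rng.random(ages.size) < cfg.scanner_b_prob, "B", "A")
        subj_idx.extend([i] * ages.size)
        visit_idx.extend(range(ages.size))
        scan_age.extend(ages.tolist())
        scan_scn.extend(scanners.tolist())
    si = np.asarray(subj_idx)
    age_arr = np.asarray(scan_age)
    scn_arr = np.asarray(scan_scn)
    n_scans = si.size
    K = len(measures)

    # per-measure generating coefficients (zeroed above the configured order)
    order_arr = np.array([cfg.trajectory_spec[tm][0] for tm in measures])
    c0 = np.array([cfg.trajectory_spec[tm][1][0] for tm in measures])
    c1 = np.array([cfg.trajectory_spec[tm][1][1] for tm in measures]) * (order_arr >= 1)
    c2 = np.array([cfg.trajectory_spec[tm][1][2] for tm in measures]) * (order_arr >= 2)
    goff = np.array([cfg.group_offset[tm] for tm in measures])
    gslope = np.array([cfg.group_age_slope.get(m, 0.0) for _, m in measures])
    sexeff = np.array([cfg.sex_effect.get(m, 0.0) for _, m in measures])
    scneff = np.array([cfg.scanner_effect.get(m, 0.0) for _, m in measures])

    is_del = (group[si] == "deletion").astype(float)[:, None]
    is_f = (sex[si] == "F").astype(float)[:, None]
    is_b = (scn_arr == "B").astype(float)[:, None]
    a = age_arr[:, None]
    values = (
        c0 + c1 * a + c2 * a * a
        + is_del * (goff + gslope * a)
        + is_f * sexeff
        + is_b * scneff
        + b[si, :]
        + latent_dev[si, :]
        + rng.normal(0.0, 1.0, size=(n_scans, K)) * res_sd
    )

    id_arr = np.asarray(ids)
    table = pd.DataFrame(
        {
            "subject_id": np.repeat(id_arr[si], K),
            "group": np.repeat(group[si], K),
            "sex": np.repeat(sex[si], K),
            "scanner": np.repeat(scn_arr, K),
            "visit_index": np.repeat(np.asarray(visit_idx), K),
            "age": np.repeat(age_arr, K),
            "tract": np.tile(np.asarray([t for t, _ in measures]), n_scans),
            "metric": np.tile(np.asarray([m for _, m in measures]), n_scans),
            "value": values.ravel(),
        }
    )
    risk_table = pd.DataFrame(risks, columns=list(RISK_FACTORS))
    risk_table.insert(0, "subject_id", ids)

    subjects = pd.DataFrame(
        {"subject_id": ids, "group": group, "sex": sex, "latent_score": score}
    )
    for j, rf in enumerate(RISK_FACTORS):
        subjects[rf] = risks[:, j]
    truth = GroundTruth(
        config=cfg,
        subjects=subjects,
        random_intercepts=pd.DataFrame(b, index=ids, columns=labels),
        latent_deviation=pd.DataFrame(latent_dev, index=ids, columns=labels),
    )
    return table, risk_table, truth
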