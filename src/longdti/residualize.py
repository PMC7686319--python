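"""Age-adjusted subject deviation scores (the PLS brain matrix).

Three steps build a subjects x measures matrix X of age-adjusted deviations
from the patient group's average developmental curves:

1. for each (tract, metric) measure, fit a random-intercept model of the
   value on an age polynomial (order chosen by BIC among 0-2) plus sex and
   scanner covariates, on the analysis subset only (no group terms — the
   subset is a single group);
2. compute each scan's residual against the fixed-effects-only prediction
   at that scan's age/sex/scanner — the estimated random intercept is
   deliberately excluded, because it would absorb exactly the subject-level
   deviation the matrix is meant to capture;
3. average the residuals across each subject's scans.

Averaging per-scan residuals is algebraically identical to residualizing
the per-subject average at the subject's mean age for linear models and
remains well defined for quadratic ones; the mean-age variant is available
via ``method="mean_age"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracts import measure_columns, measure_label
from .trajectories import ModelSpec, fit_mixed, select_order

__all__ = ["AgeModel", "AgeModelSet", "fit_age_models", "subject_deviation_scores", "build_brain_matrix"]

logger = logging.getLogger(__name__)


def _indicator(arr, positive_label: str) -> np.ndarray:
    """Label arrays become 0/1 indicators; numeric arrays pass through."""
    a = np.asarray(arr)
    if a.dtype.kind in "OUS":
        return (a == positive_label).astype(float)
    return a.astype(float)


@dataclass(frozen=True)
class AgeModel:
    """Fixed-effect age curve for one measure (single-group fit)."""

    tract: str
    metric: str
    order: int
    params: dict[str, float]
    age_center: float
    random_intercept_sd: float
    residual_sd: float
    loglik: float
    bic: float
    dropped: tuple[str, ...] = ()

    def predict(self, age, sex, scanner) -> np.ndarray:
        """Fixed-effects-only prediction at given age/sex/scanner.

        ``sex`` and ``scanner`` may be label arrays ('M'/'F', 'A'/'B') or
        numeric indicator values (fraction female / fraction scanner B).
        """
        ac = np.asarray(age, dtype=float) - self.age_center
        out = np.full(ac.shape, self.params["intercept"], dtype=float)
        if "age" in self.params:
            out += self.params["age"] * ac
        if "age2" in self.params:
            out += self.params["age2"] * ac * ac
        if "sex" in self.params:
            out += self.params["sex"] * _indicator(sex, "F")
        if "scanner" in self.params:
            out += self.params["scanner"] * _indicator(scanner, "B")
        return out


@dataclass
class AgeModelSet:
    """One fitted age model per (tract, metric) measure."""

    models: dict[tuple[str, str], AgeModel]
    age_center: float

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, key: tuple[str, str]) -> AgeModel:
        return self.models[key]

    def to_json(self) -> str:
        return json.dumps(
            {
                "age_center": self.age_center,
                "models": {
                    measure_label(t, m): {
                        "order": am.order,
                        "params": am.params,
                        "random_intercept_sd": am.random_intercept_sd,
                        "residual_sd": am.residual_sd,
                        "loglik": am.loglik,
                        "bic": am.bic,
                        "dropped": list(am.dropped),
                    }
                    for (t, m), am in self.models.items()
                },
            }
        )


def fit_age_models(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "scanner"),
    orders: tuple[int, ...] = (0, 1, 2),
) -> AgeModelSet:
    """Step 1: BIC-selected age curves for every measure in a one-group table."""
    groups = table["group"].unique()
    if len(groups) > 1:
        raise ValueError(f"expected a single-group table, got groups {sorted(groups)}")
    if table["subject_id"].nunique() < 2:
        raise ValueError("need >=2 subjects to fit age models")
    age_center = float(
        table.drop_duplicates(["subject_id", "visit_index"])["age"].mean()
    )
    tracts = list(dict.fromkeys(table["tract"]))
    metrics = list(dict.fromkeys(table["metric"]))
    models: dict[tuple[str, str], AgeModel] = {}
    for tract, metric in measure_columns(tracts, metrics):
        fits = [
            fit_mixed(
                table, tract, metric,
                ModelSpec(order, include_group=False, include_interactions=False,
                          covariates=covariates),
                age_center,
            )
            for order in orders
        ]
        best = select_order(fits)
        models[(tract, metric)] = AgeModel(
            tract=tract,
            metric=metric,
            order=best.spec.order,
            params=best.coefficients,
            age_center=age_center,
            random_intercept_sd=best.random_intercept_sd,
            residual_sd=best.residual_sd,
            loglik=best.loglik,
            bic=best.bic,
            dropped=best.dropped,
        )
    return AgeModelSet(models, age_center)


def subject_deviation_scores(
    table: pd.DataFrame,
    models: AgeModelSet,
    method: str = "per_scan",
) -> pd.DataFrame:
    """Steps 2-3: per-subject average age-adjusted residuals.

    Returns a DataFrame (rows: subject_id, columns: 'tract:metric' labels in
    the fixed metric-major order). A subject entirely missing some measure is
    excluded with a warning. ``method`` is ``"per_scan"`` (average of
    per-scan residuals) or ``"mean_age"`` (residual of the subject's average
    value at the subject's mean age and average covariate indicators).
    """
    if method not in ("per_scan", "mean_age"):
        raise ValueError("method must be 'per_scan' or 'mean_age'")
    cols = {}
    for (tract, metric), am in models.models.items():
        sub = table[(table["tract"] == tract) & (table["metric"] == metric)]
        if method == "per_scan":
            resid = sub["value"].to_numpy() - am.predict(
                sub["age"].to_numpy(), sub["sex"].to_numpy(), sub["scanner"].to_numpy()
            )
            cols[measure_label(tract, metric)] = pd.Series(
                resid, index=sub["subject_id"].to_numpy()
            ).groupby(level=0).mean()
        else:
            agg = sub.groupby("subject_id").agg(
                value=("value", "mean"),
                age=("age", "mean"),
                sex=("sex", lambda s: float(np.mean(s == "F"))),
                scanner=("scanner", lambda s: float(np.mean(s == "B"))),
            )
            cols[measure_label(tract, metric)] = agg["value"] - am.predict(
                agg["age"].to_numpy(), agg["sex"].to_numpy(), agg["scanner"].to_numpy()
            )
    X = pd.DataFrame(cols)
    X = X[[measure_label(t, m) for (t, m) in models.models]]
    incomplete = X.index[X.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "excluding %d subject(s) with missing measures: %s",
            len(incomplete), list(incomplete),
        )
        X = X.drop(index=incomplete)
    X.index.name = "subject_id"
    return X.sort_index()


def build_brain_matrix(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "scanner"),
    method: str = "per_scan",
) -> tuple[pd.DataFrame, AgeModelSet]:
    """Convenience wrapper: fit age models and extract deviation scores."""
    models = fit_age_models(table, covariates=covariates)
    return subject_deviation_scores(table, models, method=method), models
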