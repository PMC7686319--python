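"""Developmental-trajectory mixed models per (tract, metric) measure.

For every measure the mean age trend is modeled as a polynomial of order 0
(constant), 1 (linear) or 2 (quadratic), with a per-subject random intercept
to absorb repeated scans, a group indicator (intercept shift), group-by-age
interaction terms (shape difference), and fixed sex and scanner covariates.
The polynomial order is chosen by BIC on the full model; the group and
interaction effects are then tested by likelihood-ratio tests between nested
ML fits at that order, and p-values are FDR-adjusted across measures with
the Benjamini-Hochberg step-up procedure (separately for the group family
and the interaction family).

Conventions, fixed so that ports reproduce the numbers exactly:

* ML estimation throughout (never REML);
* BIC = -2 logLik + k ln(N_obs) with N_obs the number of scans and k the
  number of fixed effects plus the two variance components;
* age is centered at the pooled sample mean before fitting;
* BIC ties break toward the lower order;
* the interaction LRT drops group x age (and group x age^2 at order 2) from
  the full model (df 1 or 2); the group LRT then drops the group main
  effect from the interaction-free model (df 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .mixedlm import RandomInterceptFit, fit_random_intercept
from .tracts import DEFAULT_METRICS, DEFAULT_TRACTS

__all__ = [
    "ModelSpec",
    "TrajectoryFit",
    "EffectTestResult",
    "fit_mixed",
    "select_order",
    "test_effects",
    "fdr_adjust",
    "run_trajectory_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate trajectory model."""

    order: int = 1
    include_group: bool = True
    include_interactions: bool = True
    covariates: tuple[str, ...] = ("sex", "scanner")

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        if self.include_interactions and not self.include_group:
            raise ValueError("interaction terms require the group main effect")
        bad = set(self.covariates) - {"sex", "scanner"}
        if bad:
            raise ValueError(f"unsupported covariates: {sorted(bad)}")

    @property
    def interaction_terms(self) -> tuple[str, ...]:
        """group x age always; group x age^2 only for quadratic trends."""
        if not self.include_interactions:
            return ()
        return ("group_x_age", "group_x_age2") if self.order == 2 else ("group_x_age",)


@dataclass(frozen=True)
class TrajectoryFit:
    """One ML mixed-model fit for a (tract, metric) measure."""

    tract: str
    metric: str
    spec: ModelSpec
    fit: RandomInterceptFit
    age_center: float
    dropped: tuple[str, ...] = ()

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(self.fit.params)

    @property
    def random_intercept_sd(self) -> float:
        return self.fit.sigma_b

    @property
    def residual_sd(self) -> float:
        return self.fit.sigma_e

    @property
    def loglik(self) -> float:
        return self.fit.llf

    @property
    def bic(self) -> float:
        return self.fit.bic

    @property
    def converged(self) -> bool:
        return self.fit.converged


@dataclass
class EffectTestResult:
    tract: str
    metric: str
    selected_order: int
    p_group: float
    p_interaction: float
    group_direction: float
    q_group: float = np.nan
    q_interaction: float = np.nan


def build_design(
    df: pd.DataFrame, spec: ModelSpec, age_center: float
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Design matrix for one measure subset.

    Returns (X, names, dropped). Covariate or group columns that are constant
    in the data (single sex, single scanner, single group) are dropped with a
    logged warning rather than producing a singular design.
    """
    ac = df["age"].to_numpy(dtype=float) - age_center
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    if spec.order >= 1:
        cols["age"] = ac
    if spec.order >= 2:
        cols["age2"] = ac * ac
    g = (df["group"].to_numpy() == "deletion").astype(float)
    if spec.include_group:
        cols["group"] = g
        for term in spec.interaction_terms:
            cols[term] = g * (ac if term == "group_x_age" else ac * ac)
    if "sex" in spec.covariates:
        cols["sex"] = (df["sex"].to_numpy() == "F").astype(float)
    if "scanner" in spec.covariates:
        cols["scanner"] = (df["scanner"].to_numpy() == "B").astype(float)

    dropped = []
    for name in list(cols):
        if name != "intercept" and np.ptp(cols[name]) == 0.0:
            dropped.append(name)
            del cols[name]
            # interactions with a constant group indicator are gone too
            if name == "group":
                for term in list(cols):
                    if term.startswith("group_x_"):
                        dropped.append(term)
                        del cols[term]
    if dropped:
        logger.warning("dropped degenerate design columns: %s", dropped)
    X = np.column_stack(list(cols.values()))
    return X, tuple(cols), tuple(dropped)


def fit_mixed(
    table: pd.DataFrame,
    tract: str,
    metric: str,
    spec: ModelSpec,
    age_center: float | None = None,
) -> TrajectoryFit:
    """ML fit of one candidate model on the rows of one measure."""
    sub = table[(table["tract"] == tract) & (table["metric"] == metric)]
    if sub["subject_id"].nunique() < 2:
        raise ValueError(f"need >=2 subjects for {tract}:{metric}")
    if age_center is None:
        age_center = float(sub["age"].mean())
    X, names, dropped = build_design(sub, spec, age_center)
    fit = fit_random_intercept(
        sub["value"].to_numpy(dtype=float), X, sub["subject_id"].to_numpy(), names
    )
    return TrajectoryFit(tract, metric, spec, fit, age_center, dropped)


def select_order(fits: list[TrajectoryFit]) -> TrajectoryFit:
    """Minimal-BIC fit among converged candidates; ties favor lower order."""
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to select from")
    best = None
    for f in sorted(usable, key=lambda f: f.spec.order):
        if best is None or f.bic < best.bic:
            best = f
    return best


def test_effects(
    table: pd.DataFrame,
    tract: str,
    metric: str,
    selected_order: int,
    age_center: float | None = None,
    covariates: tuple[str, ...] = ("sex", "scanner"),
) -> EffectTestResult:
    """Likelihood-ratio tests of the interaction and group effects.

    Three nested ML fits at the selected order: full (group + interactions),
    without interactions, and additionally without the group main effect.
    The interaction LRT compares the first pair (df = 2 at order 2, else 1);
    the group LRT compares the second pair (df = 1).
    """
    full_spec = ModelSpec(selected_order, True, True, covariates)
    noint_spec = replace(full_spec, include_interactions=False)
    nogrp_spec = replace(noint_spec, include_group=False)

    full = fit_mixed(table, tract, metric, full_spec, age_center)
    noint = fit_mixed(table, tract, metric, noint_spec, age_center)
    nogrp = fit_mixed(table, tract, metric, nogrp_spec, age_center)

    if "group" in full.dropped:
        logger.warning("group indicator degenerate for %s:%s; no tests", tract, metric)
        return EffectTestResult(tract, metric, selected_order, np.nan, np.nan, np.nan)

    df_int = len(full_spec.interaction_terms)
    stat_int = max(0.0, 2.0 * (full.loglik - noint.loglik))
    p_int = float(chi2.sf(stat_int, df_int)) if df_int else np.nan
    stat_grp = max(0.0, 2.0 * (noint.loglik - nogrp.loglik))
    p_grp = float(chi2.sf(stat_grp, 1))
    direction = float(np.sign(noint.coefficients.get("group", np.nan)))
    return EffectTestResult(tract, metric, selected_order, p_grp, p_int, direction)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are passed through and do
    not count toward the family size."""
    p = np.asarray(pvalues, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.sum():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def _vocab_sort_key(values, vocab):
    lookup = {v: i for i, v in enumerate(vocab)}
    return [lookup.get(v, len(vocab)) for v in values]


def run_trajectory_analysis(
    table: pd.DataFrame,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = ("sex", "scanner"),
) -> pd.DataFrame:
    """Full per-measure analysis: BIC order selection, LRTs, FDR.

    Returns one row per (tract, metric) present in the table, sorted by
    metric then tract, with selected order, coefficients of the full model,
    variance components, raw and FDR-adjusted p-values and the sign of the
    group effect. FDR families: all measures jointly, separately for the
    group tests and the interaction tests.
    """
    combos = table[["tract", "metric"]].drop_duplicates()
    combos = combos.sort_values(
        ["metric", "tract"],
        key=lambda s: _vocab_sort_key(
            s, DEFAULT_METRICS if s.name == "metric" else DEFAULT_TRACTS
        ),
    )
    age_center = float(
        table.drop_duplicates(["subject_id", "visit_index"])["age"].mean()
    )

    rows = []
    for tract, metric in combos.itertuples(index=False):
        fits = []
        for order in (0, 1, 2):
            spec = ModelSpec(order, True, True, covariates)
            try:
                fits.append(fit_mixed(table, tract, metric, spec, age_center))
            except ValueError as exc:
                logger.warning("skipping %s:%s order %d: %s", tract, metric, order, exc)
        if not fits:
            logger.warning("no usable fits for %s:%s; skipped", tract, metric)
            continue
        best = select_order(fits)
        res = test_effects(table, tract, metric, best.spec.order, age_center, covariates)
        row = {
            "tract": tract,
            "metric": metric,
            "selected_order": best.spec.order,
            "loglik": best.loglik,
            "bic": best.bic,
            "random_intercept_sd": best.random_intercept_sd,
            "residual_sd": best.residual_sd,
            "p_group": res.p_group,
            "p_interaction": res.p_interaction,
            "group_direction": res.group_direction,
        }
        for name, value in best.coefficients.items():
            row[f"coef_{name}"] = value
        rows.append(row)

    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no (tract, metric) combinations could be analyzed")
    out["q_group"] = fdr_adjust(out["p_group"])
    out["q_interaction"] = fdr_adjust(out["p_interaction"])
    out["significant_group"] = out["q_group"] < alpha
    out["significant_interaction"] = out["q_interaction"] < alpha
    out.attrs["age_center"] = age_center
    out.attrs["fdr_families"] = "group and interaction corrected separately across all measures"
    return out.reset_index(drop=True)
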