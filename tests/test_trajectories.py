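"""Trajectory mixed models: recovery, order selection, LRTs, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longdti import (
    ModelSpec,
    fdr_adjust,
    fit_mixed,
    generate_cohort,
    run_trajectory_analysis,
    select_order,
)
from longdti import test_effects as effect_tests  # avoid pytest collection

from conftest import noise_free_config, small_config


def brute_force_bh(p):
    """Step-up Benjamini-Hochberg evaluated directly from its definition:
    q_i = min over j with p_j >= p_i of m * p_j / rank_j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


# --- fitting ---------------------------------------------------------------

def test_zero_noise_recovers_planted_linear_slope():
    cfg = noise_free_config(
        trajectory_spec={
            (t, m): (1, (0.40, 0.002, 0.0)) for t in
            ("FMAJ", "FMIN", "lh.UNC", "rh.UNC") for m in ("FA", "MD")
        },
        sex_effect={}, scanner_effect={},
    )
    table, _, _ = generate_cohort(cfg)
    fit = fit_mixed(table, "FMAJ", "FA", ModelSpec(order=1))
    assert fit.coefficients["age"] == pytest.approx(0.002, rel=1e-6)


def test_random_intercept_zero_matches_ols():
    """With no subject-level variance the mixed model's fixed effects must
    coincide with ordinary least squares on the same design."""
    lin = {
        (t, m): (1, (0.40, 0.002, 0.0))
        for t in ("FMAJ", "FMIN", "lh.UNC", "rh.UNC") for m in ("FA", "MD")
    }
    cfg = small_config(
        seed=0, n_per_group=80,
        random_intercept_sd={"FA": 0.0, "MD": 0.0},
        trajectory_spec=lin,
    )
    table, _, _ = generate_cohort(cfg)
    fit = fit_mixed(table, "FMAJ", "FA", ModelSpec(order=1))
    sub = table[(table.tract == "FMAJ") & (table.metric == "FA")]
    ac = sub["age"].to_numpy() - sub["age"].mean()
    X = np.column_stack([
        np.ones(len(sub)), ac,
        (sub["group"] == "deletion").astype(float),
        (sub["group"] == "deletion").astype(float) * ac,
        (sub["sex"] == "F").astype(float),
        (sub["scanner"] == "B").astype(float),
    ])
    beta = np.linalg.lstsq(X, sub["value"].to_numpy())[0]
    ours = [fit.coefficients[k] for k in
            ("intercept", "age", "group", "group_x_age", "sex", "scanner")]
    np.testing.assert_allclose(ours, beta, rtol=1e-4, atol=1e-9)


def test_cloning_subjects_leaves_fixed_effects(small_cohort):
    """Duplicating every subject (fresh ids) doubles the likelihood without
    changing its maximizer, so all estimates are exactly invariant. (Exact
    per-scan duplication is NOT invariant under ML: identical scans collapse
    the residual-variance estimate and reweight subjects.)"""
    table, _, _ = small_cohort
    clones = table.assign(subject_id=table.subject_id + "_clone")
    doubled = pd.concat([table, clones], ignore_index=True)
    f1 = fit_mixed(table, "FMAJ", "FA", ModelSpec(order=1))
    f2 = fit_mixed(doubled, "FMAJ", "FA", ModelSpec(order=1), age_center=f1.age_center)
    for k, v in f1.coefficients.items():
        assert f2.coefficients[k] == pytest.approx(v, rel=1e-6, abs=1e-12)
    assert f2.random_intercept_sd == pytest.approx(f1.random_intercept_sd, abs=1e-6)


# --- order selection -------------------------------------------------------

def test_select_order_prefers_min_bic_and_low_order_ties(small_cohort):
    table, _, _ = small_cohort
    fits = [fit_mixed(table, "FMAJ", "FA", ModelSpec(order=o)) for o in (0, 1, 2)]
    best = select_order(fits)
    assert best.bic == min(f.bic for f in fits)
    # artificial exact tie: duplicate winning fit presented at higher order
    tie = [fits[1], fits[1]]
    assert select_order(tie) is fits[1]
    with pytest.raises(ValueError):
        select_order([])


def test_quadratic_trajectory_selected():
    """A strong planted curvature must be picked up by BIC."""
    cfg = small_config(n_per_group=100, seed=23)
    table, _, _ = generate_cohort(cfg)
    fits = [fit_mixed(table, "FMAJ", "FA", ModelSpec(order=o)) for o in (0, 1, 2)]
    assert select_order(fits).spec.order == 2  # default FA template is quadratic


def test_loglik_nesting_inequality(small_cohort):
    """The full model can never have lower ML log-likelihood than a nested
    submodel fitted on the same observations."""
    table, _, _ = small_cohort
    for order in (0, 1, 2):
        full = fit_mixed(table, "lh.UNC", "MD", ModelSpec(order, True, True))
        noint = fit_mixed(table, "lh.UNC", "MD", ModelSpec(order, True, False))
        nogrp = fit_mixed(table, "lh.UNC", "MD", ModelSpec(order, False, False))
        assert full.loglik >= noint.loglik - 1e-6
        assert noint.loglik >= nogrp.loglik - 1e-6


def test_bic_invariant_to_age_centering(small_cohort):
    table, _, _ = small_cohort
    f0 = fit_mixed(table, "FMAJ", "MD", ModelSpec(order=2), age_center=0.0)
    f1 = fit_mixed(table, "FMAJ", "MD", ModelSpec(order=2), age_center=20.0)
    assert f0.bic == pytest.approx(f1.bic, abs=1e-5)


# --- effect tests ----------------------------------------------------------

def test_lrt_on_noise_free_null_gives_p_one():
    """With a truly zero group effect and no noise, the LRT statistic is 0
    and the p-value 1."""
    cfg = noise_free_config(sex_effect={}, scanner_effect={})
    zero_off = {k: 0.0 for k in cfg.group_offset}
    cfg = noise_free_config(sex_effect={}, scanner_effect={}, group_offset=zero_off)
    table, _, _ = generate_cohort(cfg)
    res = effect_tests(table, "FMAJ", "FA", selected_order=2, covariates=())
    assert res.p_group == pytest.approx(1.0)
    assert res.p_interaction == pytest.approx(1.0)


def test_planted_group_offset_detected():
    table, _, _ = generate_cohort(small_config(n_per_group=150, seed=19))
    res = effect_tests(table, "FMAJ", "FA", selected_order=1)
    assert res.p_group < 1e-3
    assert res.group_direction == 1.0  # FA offset planted positive


# --- FDR -------------------------------------------------------------------

def test_fdr_worked_example():
    p = [0.01, 0.02, 0.03, 0.04, 0.05]
    np.testing.assert_allclose(fdr_adjust(p), [0.05] * 5)


def test_fdr_singleton_identity():
    assert fdr_adjust([0.5])[0] == pytest.approx(0.5)


def test_fdr_rejects_invalid_p():
    with pytest.raises(ValueError):
        fdr_adjust([0.2, 1.4])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=72))
def test_fdr_matches_brute_force_oracle(p):
    q = fdr_adjust(p)
    np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)


# --- full analysis ---------------------------------------------------------

def test_run_trajectory_analysis_bookkeeping(small_cohort):
    table, _, _ = small_cohort
    res = run_trajectory_analysis(table)
    assert len(res) == 8  # 4 tracts x 2 metrics
    assert set(res.columns) >= {
        "tract", "metric", "selected_order", "p_group", "q_group",
        "p_interaction", "q_interaction", "group_direction",
    }
    # q dominates p within each family
    ok = res["p_group"].notna()
    assert np.all(res.loc[ok, "q_group"] >= res.loc[ok, "p_group"] - 1e-12)
    # sorted by metric then tract vocab order
    assert res["metric"].tolist() == sorted(
        res["metric"], key=lambda m: {"FA": 0, "MD": 1}[m]
    )


def test_run_trajectory_analysis_row_order_invariance(small_cohort):
    table, _, _ = small_cohort
    shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
    r1 = run_trajectory_analysis(table)
    r2 = run_trajectory_analysis(shuffled)
    pd.testing.assert_frame_equal(
        r1.reset_index(drop=True), r2.reset_index(drop=True),
        check_exact=False, atol=1e-8,
    )
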