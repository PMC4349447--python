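"""Stepwise / best-subset selection tests against constructed cases and oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exwas import screen, select
from exwas.codebook import standardize
from exwas.studies import brute_force_best_subset

METHODS = ("forwards", "backwards", "subset")


def _frame(rng, n=300, m=5, names=None):
    names = names or [f"x{j}" for j in range(m)]
    return pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)


@pytest.mark.parametrize("method", METHODS)
def test_single_strong_candidate_selected_by_every_method(rng, method):
    X = _frame(rng, m=1)
    y = pd.Series(2.0 * X["x0"] + 0.5 * rng.standard_normal(len(X)))
    fit, trace = select.stepwise_fit(X, y, ["x0"], method=method, p_crit=1e-3)
    assert fit.variables == ["x0"]
    assert fit.pvalues["x0"] < 1e-9
    assert trace.replay() == ["x0"] or method == "subset"


@pytest.mark.parametrize("method", METHODS)
def test_duplicate_predictor_selected_exactly_once(rng, method):
    X = _frame(rng, m=1)
    X["x1"] = X["x0"]  # exact copy
    y = pd.Series(1.5 * X["x0"] + rng.standard_normal(len(X)))
    fit, trace = select.stepwise_fit(X, y, ["x0", "x1"], method=method, p_crit=1e-3)
    assert fit.variables == ["x0"]  # first in candidate order wins
    if method == "backwards":
        assert "x1" in fit.aliased


def test_suppressor_pair_found_by_subset_not_forwards(rng):
    """x1, x2 jointly predictive but marginally null: greedy forward stalls."""
    n = 800
    common = rng.standard_normal(n)
    x1 = common + 0.2 * rng.standard_normal(n)
    x2 = common + 0.2 * rng.standard_normal(n)
    y = pd.Series(x1 - x2 + 0.3 * rng.standard_normal(n))
    X = pd.DataFrame({"x1": x1, "x2": x2})
    assert stats.pearsonr(x1, y).pvalue > 1e-4  # marginally weak
    fwd, _ = select.stepwise_fit(X, y, ["x1", "x2"], method="forwards", p_crit=1e-6)
    sub, _ = select.stepwise_fit(X, y, ["x1", "x2"], method="subset", p_crit=1e-6)
    assert sorted(sub.variables) == ["x1", "x2"]
    assert sub.r2 >= fwd.r2


def test_best_subset_matches_brute_force_enumeration(rng):
    for _ in range(5):
        n, m = 60, 9
        X = rng.standard_normal((n, m)) + 0.4 * rng.standard_normal((n, 1))
        beta = np.zeros(m)
        beta[rng.choice(m, 2, replace=False)] = rng.normal(0, 1, 2)
        y = X @ beta + rng.standard_normal(n)
        names = [f"x{j}" for j in range(m)]
        fit = select.best_subset_search(pd.DataFrame(X, columns=names), pd.Series(y), names, p_crit=0.05)
        oracle, oracle_r2 = brute_force_best_subset(X, y, 0.05)
        assert tuple(sorted(names.index(v) for v in fit.variables)) == tuple(sorted(oracle))
        if oracle:
            assert np.isclose(fit.r2, oracle_r2)


def test_best_subset_empty_admissible_returns_flagged_intercept_fit(rng):
    X = _frame(rng, m=4)
    y = pd.Series(rng.standard_normal(len(X)))
    fit = select.best_subset_search(X, y, list(X.columns), p_crit=1e-12)
    assert fit.empty_admissible
    assert fit.variables == []
    assert fit.r2 == 0.0


@pytest.mark.parametrize("method", METHODS)
def test_every_retained_variable_meets_criterion(small_cohort, method):
    ds = small_cohort
    std, _ = standardize(ds.matrix)
    res = screen.univariable_scan(std, ds.outcome)
    res, dec = screen.mark_fdr(res, 0.001)
    survivors = list(res.index[res["passes_fdr"]])
    p_crit = max(dec.threshold, dec.bonferroni_floor)
    fit, _ = select.stepwise_fit(std, ds.outcome, survivors, method=method, p_crit=p_crit)
    member_p = fit.pvalues[[v for v in fit.variables if v not in fit.forced]]
    assert (member_p <= p_crit).all()


def test_forwards_trace_replay_and_monotone_r2(small_cohort):
    ds = small_cohort
    std, _ = standardize(ds.matrix)
    cands = list(ds.truth.planted_effects)
    fit, trace = select.stepwise_fit(std, ds.outcome, cands, method="forwards", p_crit=0.01)
    assert sorted(trace.replay()) == sorted(v for v in fit.variables if v not in fit.forced)
    r2_prev, current = -1.0, []
    for action, var, _ in trace.steps:
        if action != "add":
            continue
        current.append(var)
        sub = select.fit_linear(std, ds.outcome, current)
        assert sub.r2 >= r2_prev - 1e-12
        r2_prev = sub.r2


def test_domain_models_nest_within_combined_fit(small_cohort):
    ds = small_cohort
    std, _ = standardize(ds.matrix)
    res = screen.univariable_scan(std, ds.outcome)
    res, dec = screen.mark_fdr(res, 0.001)
    p_crit = max(dec.threshold, dec.bonferroni_floor)
    fits, table = select.domain_models(std, ds.outcome, res, p_crit=p_crit)
    pool = []
    for f in fits.values():
        pool += [v for v in f.variables if v not in f.forced]
    assert pool, "expected at least one nonempty domain model"
    combined = select.fit_linear(std, ds.outcome, pool)
    for domain, f in fits.items():
        assert f.r2 <= combined.r2 + 1e-12
        assert table.loc[domain, "model_df"] == f.k
    empty_domains = table.index[table["stage1_selected"] == 0]
    for d in empty_domains:
        assert fits[d].variables == []


def test_final_model_tiers_decompose_r2(small_cohort):
    ds = small_cohort
    std, _ = standardize(ds.matrix)
    res = screen.univariable_scan(std, ds.outcome)
    res, dec = screen.mark_fdr(res, 0.001)
    p_crit = max(dec.threshold, dec.bonferroni_floor)
    fits, _ = select.domain_models(std, ds.outcome, res, p_crit=p_crit)
    final, trace, tiers = select.final_model(std, ds.outcome, fits, res, p_crit=p_crit)
    assert final.variables
    if tiers is not None:
        assert np.isclose(tiers["cumulative_r2_pct"].iloc[-1], 100 * final.r2, atol=1e-6)
        assert (tiers["added_r2_pct"] >= -1e-9).all()


def test_partner_status_forced_into_models_with_partner_variables(missing_cohort):
    from exwas.codebook import drop_degenerate, encode_partner_variables

    ds = missing_cohort
    matrix, _ = drop_degenerate(ds.matrix, ds.outcome)
    std, _ = standardize(matrix)
    enc = encode_partner_variables(std)
    pvars = [v for v in enc.codebook.partner_variables][:2]
    assert pvars
    complete_cols = pvars + [c for c in enc.codebook.names if c not in enc.codebook.partner_variables][:2]
    sub = enc.restrict(complete_cols)
    data_complete = sub.copy()
    data_complete.data = sub.data.fillna(0.0)
    fit = select.fit_linear(data_complete, ds.outcome, complete_cols)
    assert fit.forced == ["partner_status"]
    assert "partner_status" in fit.variables
    assert fit.k == len(complete_cols)


# -- partial correlation and attenuation -------------------------------------


def test_partial_correlation_identities(rng):
    X = _frame(rng, n=500, m=3)
    y = pd.Series(0.8 * X["x0"] - 0.5 * X["x1"] + rng.standard_normal(500))
    single = select.fit_linear(X, y, ["x0"])
    assert np.isclose(
        select.partial_correlation(single, "x0"), stats.pearsonr(X["x0"], y).statistic, atol=1e-10
    )
    joint = select.fit_linear(X, y, ["x0", "x1", "x2"])
    # Frisch-Waugh: residual-on-residual correlation
    for var in ["x0", "x1", "x2"]:
        others = [c for c in ["x0", "x1", "x2"] if c != var]
        A = np.column_stack([np.ones(500), X[others]])
        rx = X[var] - A @ np.linalg.lstsq(A, X[var], rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        expect = stats.pearsonr(rx, ry).statistic
        assert np.isclose(select.partial_correlation(joint, var), expect, atol=1e-10)


def test_attenuation_summary_arithmetic():
    unadj = pd.DataFrame({"B": [-1.0, 2.0, 1.0, -0.5]}, index=["a", "b", "c", "d"])
    adj = pd.Series({"a": -0.59, "b": 2.0, "c": 0.0, "d": 0.25})
    table, summary = select.attenuation_summary(unadj, adj)
    assert np.isclose(table.loc["a", "attenuation_pct"], 41.0)
    assert np.isclose(table.loc["b", "attenuation_pct"], 0.0)
    assert np.isclose(table.loc["c", "attenuation_pct"], 100.0)
    assert table.loc["d", "sign_flip"]
    assert summary["sign_flips"] == ["d"]
    assert np.isclose(summary["mean_attenuation_pct"], (41.0 + 0.0 + 100.0) / 3)


def test_attenuation_rejects_zero_unadjusted():
    unadj = pd.DataFrame({"B": [0.0]}, index=["a"])
    with pytest.raises(ValueError):
        select.attenuation_summary(unadj, pd.Series({"a": 0.1}))
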