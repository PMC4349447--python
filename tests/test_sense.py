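"""Sensitivity-analysis tests: ordinal refit, factors, CHAID tree, consistency."""


import numpy as np
import pandas as pd
import pytest

from exwas import select, sense, synth


def _fit_on(data, outcome, names):
    return select.fit_linear(data, outcome, names)


# -- proportional-odds refit -------------------------------------------------


def _gaussian_model(rng, n=1500, m=3, betas=(1.2, -0.8, 0.5)):
    X = pd.DataFrame(rng.standard_normal((n, m)), columns=[f"x{j}" for j in range(m)])
    y = pd.Series(X @ np.array(betas) + rng.standard_normal(n))
    return X, y, _fit_on(X, y, list(X.columns))


def test_ordinal_or_direction_matches_linear_sign(rng):
    X, y, fit = _gaussian_model(rng)
    ordf = sense.ordinal_refit(fit, X, y, n_bins=10)
    for v in X.columns:
        assert np.sign(np.log(ordf.odds_ratios[v])) == np.sign(fit.coef[v])
        assert ordf.pvalues[v] < 0.001
    assert 0 < ordf.pseudo_r2 < 1


def test_ordinal_rank_concordance_with_linear_effects(rng):
    X, y, fit = _gaussian_model(rng, n=2500, m=4, betas=(1.5, -1.0, 0.6, 0.3))
    ordf = sense.ordinal_refit(fit, X, y, n_bins=20)
    assert ordf.rank_concordance >= 0.8
    assert ordf.max_rank_shift <= 3


def test_ordinal_null_pseudo_r2_near_zero(rng):
    n = 1500
    X = pd.DataFrame({"x0": rng.standard_normal(n)})
    y = pd.Series(rng.standard_normal(n))
    fit = _fit_on(X, y, ["x0"])
    ordf = sense.ordinal_refit(fit, X, y, n_bins=10)
    assert ordf.pseudo_r2 < 0.01


# -- factor-space sensitivity ------------------------------------------------


def _block_cohort(seed=21):
    spec = synth.SyntheticSpec(
        n_subjects=1500, n_variables=30, n_domains=3,
        within_domain_corr=0.6, cross_domain_corr=0.0,
        type_mix=(0.0, 0.0, 1.0),
        planted_effects=((0, 1.5), (10, -1.5), (20, 1.5)),
        missing_rate=0.0, partner_var_fraction=0.0, partnerless_rate=0.0,
        outcome_skew=0.0, seed=seed,
    )
    return synth.generate_exposome(spec)


def test_factor_scores_orthogonal_unit_variance():
    ds = _block_cohort()
    model, fit, mapped = sense.factor_sensitivity(ds.matrix.data, ds.outcome, p_crit=1e-3)
    corr = np.corrcoef(model.scores.to_numpy(), rowvar=False)
    assert np.allclose(corr, np.eye(model.n_factors), atol=0.05)
    assert np.allclose(model.scores.std(ddof=1), 1.0, atol=0.05)


def test_factors_recover_block_structure_and_planted_signal():
    ds = _block_cohort()
    model, fit, mapped = sense.factor_sensitivity(ds.matrix.data, ds.outcome, p_crit=1e-3)
    # selected factors map back to the three blocks carrying planted effects
    domains_hit = {mapped.loc[i, "top_variable"][:3] for i in mapped.index}
    assert domains_hit == {"d01", "d02", "d03"}
    assert len(fit.variables) >= 3


def test_factor_selection_silent_on_pure_noise(rng):
    X = pd.DataFrame(rng.standard_normal((800, 20)), columns=[f"x{j}" for j in range(20)])
    y = pd.Series(rng.standard_normal(800))
    model, fit, mapped = sense.factor_sensitivity(X, y, p_crit=1e-3)
    assert len(fit.variables) == 0


# -- CHAID tree --------------------------------------------------------------


def test_tree_single_strong_binary_predictor_gives_two_leaves(rng):
    n = 1000
    x = rng.choice([0.0, 1.0], n)
    X = pd.DataFrame({"x0": x, "x1": rng.standard_normal(n)})
    y = pd.Series(3.0 * x + rng.standard_normal(n))
    tree = sense.chaid_tree(X, y, alpha_split=0.001, min_leaf=50, max_depth=1)
    leaves = tree.leaves
    assert len(leaves) == 2
    assert tree.nodes[tree.root].split_variable == "x0"
    means = sorted(l.mean for l in leaves)
    assert means[1] - means[0] > 2.0


def test_tree_pure_noise_stays_root_only(rng):
    X = pd.DataFrame(rng.standard_normal((800, 4)), columns=[f"x{j}" for j in range(4)])
    y = pd.Series(rng.standard_normal(800))
    tree = sense.chaid_tree(X, y, alpha_split=0.001, min_leaf=50)
    assert len(tree.nodes) == 1


def test_tree_finds_planted_interaction_hierarchy(rng):
    n = 4000
    x1 = rng.choice([0.0, 1.0], n)
    x2 = rng.choice([0.0, 1.0], n)
    y = pd.Series(2.5 * x1 * x2 + rng.standard_normal(n))
    X = pd.DataFrame({"x1": x1, "x2": x2})
    tree = sense.chaid_tree(X, y, alpha_split=0.001, min_leaf=50, max_depth=2)
    used = {n_.split_variable for n_ in tree.nodes.values() if n_.split_variable}
    assert used == {"x1", "x2"}


def test_tree_leaves_partition_sample_and_ss_decomposition(rng):
    n = 1200
    X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.choice([0.0, 1.0, 2.0], n)})
    y = pd.Series(1.5 * X["b"] + 0.8 * X["a"] + rng.standard_normal(n))
    tree = sense.chaid_tree(X, y, alpha_split=0.01, min_leaf=60)
    rows = np.concatenate([l.subjects for l in tree.leaves])
    assert sorted(rows) == list(range(n))  # leaves partition the sample
    yv = y.to_numpy()
    between = sum(l.size * (l.mean - yv.mean()) ** 2 for l in tree.leaves)
    total = float(((yv - yv.mean()) ** 2).sum())
    assert between <= total + 1e-9
    edges = tree.edge_list()
    assert set(edges["child"]) <= set(tree.nodes)
    assert "mean=" in tree.render()


# -- consistency report ------------------------------------------------------


def test_consistency_identical_and_disjoint_fits(rng):
    X = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
    y = pd.Series(X["a"] + X["c"] + rng.standard_normal(200))
    f_ac = _fit_on(X, y, ["a", "c"])
    f_bd = _fit_on(X, y, ["b", "d"])
    overlap, stability = sense.consistency_report({"m1": f_ac, "m2": f_ac, "m3": f_bd})
    assert overlap.loc["m1", "m2"] == 1.0
    assert overlap.loc["m1", "m3"] == 0.0
    assert stability.loc["a", "inclusion_frequency"] == pytest.approx(2 / 3)
    assert stability.loc["b", "unique_to_one_method"]
    with pytest.raises(ValueError):
        sense.consistency_report({"only": f_ac})


def test_consistency_planted_variables_more_stable_than_nulls(small_cohort):
    from exwas import screen
    from exwas.codebook import standardize

    ds = small_cohort
    std, _ = standardize(ds.matrix)
    res = screen.univariable_scan(std, ds.outcome)
    res, dec = screen.mark_fdr(res, 0.001)
    survivors = list(res.index[res["passes_fdr"]])
    p_crit = max(dec.threshold, dec.bonferroni_floor)
    fits = {}
    for method in ("forwards", "backwards", "subset"):
        fits[method], _ = select.stepwise_fit(std, ds.outcome, survivors, method=method, p_crit=p_crit)
    _, stability = sense.consistency_report(fits)
    planted = set(ds.truth.planted_effects)
    freq = stability["inclusion_frequency"]
    in_planted = freq[[v for v in freq.index if v in planted]]
    in_null = freq[[v for v in freq.index if v not in planted]]
    if len(in_null):
        assert in_planted.mean() >= in_null.mean()
    assert in_planted.mean() > 0.8
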