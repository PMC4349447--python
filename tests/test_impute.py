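"""Chained-equation imputation and Rubin pooling tests."""


import numpy as np
import pandas as pd
import pytest

from exwas import impute, select, synth
from exwas.codebook import Codebook, DOMAINS, ExposomeMatrix, ExposureVariable


def _plain_matrix(data: pd.DataFrame, types: dict[str, str]) -> ExposomeMatrix:
    variables = [
        ExposureVariable(name=c, domain=DOMAINS[0], var_type=types.get(c, "continuous"))
        for c in data.columns
    ]
    return ExposomeMatrix(
        data=data, codebook=Codebook.from_variables(variables),
        partner_status=pd.Series(0, index=data.index),
    )


def test_no_missing_cells_returns_input_for_any_m(rng):
    data = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
    m = _plain_matrix(data, {})
    out = impute.mice_impute(m, pd.Series(rng.standard_normal(50)), M=3, n_iter=2, seed=0)
    assert out.M == 3
    for df in out.datasets:
        pd.testing.assert_frame_equal(df, data)


def test_observed_cells_identical_across_imputations_and_seeded(missing_cohort):
    ds = missing_cohort
    sub = ds.matrix.restrict(ds.matrix.codebook.names[:8])
    out1 = impute.mice_impute(sub, ds.outcome, M=2, n_iter=3, seed=42)
    out2 = impute.mice_impute(sub, ds.outcome, M=2, n_iter=3, seed=42)
    mask = sub.data.isna()
    for a, b in zip(out1.datasets, out2.datasets):
        pd.testing.assert_frame_equal(a, b)  # reproducible under a fixed seed
    for df in out1.datasets:
        # originally observed entries are bit-identical to the input
        np.testing.assert_array_equal(df.to_numpy()[~mask.to_numpy()],
                                      sub.data.to_numpy()[~mask.to_numpy()])
        assert not df.isna().any().any()
    # imputed cells differ between imputations (proper draws)
    diff = (out1.datasets[0] != out1.datasets[1]).to_numpy() & mask.to_numpy()
    assert diff.any()


def test_conditional_model_types_follow_codebook(missing_cohort):
    ds = missing_cohort
    sub = ds.matrix.restrict(ds.matrix.codebook.names[:12])
    out = impute.mice_impute(sub, ds.outcome, M=1, n_iter=2, seed=0)
    types = sub.codebook.table["var_type"]
    expected = {"continuous": "bayes_linear", "binary": "logistic", "ordinal": "pmm"}
    for var, model in out.conditional_models.items():
        assert model == expected[types[var]]
    # discrete variables keep their observed support
    for var in types.index[types != "continuous"]:
        observed_levels = set(sub.data[var].dropna().unique())
        assert set(out.datasets[0][var].unique()) <= observed_levels


def test_fully_missing_variable_rejected(rng):
    data = pd.DataFrame({"a": rng.standard_normal(20), "b": np.full(20, np.nan)})
    m = _plain_matrix(data, {})
    with pytest.raises(ValueError, match="100%"):
        impute.mice_impute(m, pd.Series(rng.standard_normal(20)), M=1, n_iter=1, seed=0)


def test_mar_imputations_track_conditional_mean(rng):
    """x2 = 0.8*x1 + e, missing where x1 is high: imputed cells should sit
    near the anchor-conditional mean, not the observed-cell mean."""
    n = 2000
    x1 = rng.standard_normal(n)
    x2 = 0.8 * x1 + 0.6 * rng.standard_normal(n)
    miss = x1 > 0.8
    data = pd.DataFrame({"x1": x1, "x2": np.where(miss, np.nan, x2)})
    m = _plain_matrix(data, {})
    out = impute.mice_impute(m, None, M=3, n_iter=4, seed=5)
    imputed = np.concatenate([df.loc[miss, "x2"].to_numpy() for df in out.datasets])
    target = 0.8 * x1[miss].mean()
    assert abs(imputed.mean() - target) < 0.1
    assert abs(data["x2"].mean()) < abs(target)  # observed mean is biased low


def test_pool_rubin_single_fit_is_identity(rng):
    X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
    y = pd.Series(X["a"] + rng.standard_normal(100))
    fit = select.fit_linear(X, y, ["a", "b"])
    pooled = impute.pool_rubin([fit])
    pd.testing.assert_series_equal(pooled.coef, fit.coef)
    pd.testing.assert_series_equal(pooled.se, fit.se)


def test_pool_rubin_identical_fits_have_zero_between_variance(rng):
    X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
    y = pd.Series(X["a"] + rng.standard_normal(100))
    fit = select.fit_linear(X, y, ["a", "b"])
    pooled = impute.pool_rubin([fit, fit, fit])
    assert np.allclose(pooled.between_var, 0.0)
    assert np.allclose(pooled.se, fit.se)


def test_pool_rubin_two_imputation_hand_calculation():
    """M=2 with known coefficients/SEs: check the pooling arithmetic."""
    idx = pd.Index(["a"])

    def _fake(coef, se):
        s = pd.Series([coef], index=idx)
        e = pd.Series([se], index=idx)
        return select.ModelFit(
            variables=["a"], coef=s, se=e, ci_low=s, ci_high=s, pvalues=s,
            partial_corr=s, r2=0.5, nobs=100, df_resid=98, intercept=0.0,
            method="fixed", p_crit=1.0,
        )

    pooled = impute.pool_rubin([_fake(1.0, 0.2), _fake(1.4, 0.25)])
    qbar = 1.2
    ubar = (0.2**2 + 0.25**2) / 2
    b = ((1.0 - 1.2) ** 2 + (1.4 - 1.2) ** 2) / 1  # ddof=1
    T = ubar + 1.5 * b
    assert np.isclose(pooled.coef["a"], qbar)
    assert np.isclose(pooled.se["a"], np.sqrt(T))
    lam = 1.5 * b / T
    nu_old = 1 / lam**2
    nu_obs = 99 / 101 * 98 * (1 - lam)
    assert np.isclose(pooled.df["a"], 1 / (1 / nu_old + 1 / nu_obs))


def test_pool_rubin_rejects_mismatched_variable_sets(rng):
    X = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
    y = pd.Series(rng.standard_normal(50))
    f1 = select.fit_linear(X, y, ["a"])
    f2 = select.fit_linear(X, y, ["b"])
    with pytest.raises(ValueError, match="mismatched"):
        impute.pool_rubin([f1, f2])


def test_between_imputation_variance_grows_with_missingness():
    rates = (0.05, 0.20, 0.40)
    means = []
    for rate in rates:
        bs = []
        for seed in range(3):
            spec = synth.SyntheticSpec(
                n_subjects=300, n_variables=4, n_domains=2,
                type_mix=(0.0, 0.0, 1.0), planted_effects=((0, 0.6),),
                missing_rate=rate, missing_mechanism="MCAR",
                partner_var_fraction=0.0, partnerless_rate=0.0,
                outcome_skew=0.0, seed=seed,
            )
            ds = synth.generate_exposome(spec)
            out = impute.mice_impute(ds.matrix, ds.outcome, M=4, n_iter=4, seed=seed)
            fits = [select.fit_linear(df, ds.outcome, list(df.columns)) for df in out.datasets]
            pooled = impute.pool_rubin(fits)
            bs.append(float(pooled.between_var.mean()))
        means.append(np.mean(bs))
    assert means[0] < means[1] < means[2]
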