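"""Missing-value imputation by chained equations, with Rubin pooling.

Each variable with missing cells receives a conditional model on all other
variables (plus the outcome and partner status): Bayesian linear regression
for continuous variables, logistic regression with an asymptotic posterior
draw for binary ones, and predictive-mean matching (donor pool 5) for
ordinal ones so imputed values stay on the observed discrete scale.  Cycling
the conditionals ``n_iter`` times per imputation yields ``M`` completed
datasets whose originally observed cells are bit-identical; only imputed
cells differ.  Proper parameter draws make the between-imputation spread an
honest reflection of imputation uncertainty, which Rubin's rules then fold
into pooled coefficients, CIs and p-values.

The outcome participates as a chained predictor (it carries information
about the missing exposures) but the completed outcome is discarded: the
analysis never uses imputed outcome values.  Cells filled by the
partner-encoding convention are not missing and are never re-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from exwas.codebook import ExposomeMatrix
from exwas.select import ModelFit

__all__ = ["ImputationSet", "PooledFit", "mice_impute", "pool_rubin"]

_OUTCOME = "__outcome__"
_STATUS = "__partner_status__"


@dataclass
class ImputationSet:
    """M completed datasets plus provenance.

    All datasets share shape and observed entries; ``conditional_models``
    records the per-variable conditional form used, and ``chain_means`` holds
    the per-iteration mean of each imputed variable (a convergence trace).
    """

    datasets: list[pd.DataFrame]
    conditional_models: dict[str, str]
    n_iter: int
    seed: int
    imputed_counts: pd.Series
    chain_means: list[pd.DataFrame] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.datasets)

    def to_dir(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets, 1):
            df.to_csv(path / f"imputation_{i:02d}.tsv", sep="\t", index_label="subject")
        manifest = pd.DataFrame(
            {"variable": list(self.conditional_models), "model": list(self.conditional_models.values())}
        )
        manifest.to_csv(path / "manifest.tsv", sep="\t", index=False)


def mice_impute(
    matrix: ExposomeMatrix,
    outcome: pd.Series | None,
    M: int = 5,
    n_iter: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Impute ``matrix`` by chained equations; returns ``M`` completed copies.

    The matrix should already be restricted to the stage-1 selected
    variables; imputation uses every subject supplied, even those whose
    outcome is missing (downstream analyses restrict to outcome-observed
    subjects themselves).
    """
    if M < 1 or n_iter < 1:
        raise ValueError("M and n_iter must be positive")
    df = matrix.data
    miss = df.isna()
    fully_missing = list(miss.columns[miss.all(axis=0)])
    if fully_missing:
        raise ValueError(f"variables with 100% missingness cannot be imputed: {fully_missing[:5]}")

    types = matrix.codebook.table["var_type"].to_dict()
    cond: dict[str, str] = {}
    for name in df.columns:
        if not miss[name].any():
            continue
        cond[name] = {"continuous": "bayes_linear", "binary": "logistic", "ordinal": "pmm"}[types[name]]

    work = df.copy()
    work[_STATUS] = matrix.partner_status.astype(float)
    if outcome is not None:
        work[_OUTCOME] = outcome.astype(float)
        if outcome.isna().any():
            cond[_OUTCOME] = "bayes_linear"
    cols = list(work.columns)
    values = work.to_numpy(float)
    is_missing = np.isnan(values)
    # cycle order: least missing first, so early conditionals are well informed
    chain_cols = sorted(cond, key=lambda c: is_missing[:, cols.index(c)].sum())

    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=M)
    datasets, traces = [], []
    for m_i in range(M):
        rng = np.random.default_rng(child_seeds[m_i])
        filled = values.copy()
        for c in chain_cols:
            j = cols.index(c)
            obs_vals = values[~is_missing[:, j], j]
            filled[is_missing[:, j], j] = rng.choice(obs_vals, size=is_missing[:, j].sum(), replace=True)
        trace_rows = []
        for it in range(n_iter):
            for c in chain_cols:
                j = cols.index(c)
                mis = is_missing[:, j]
                pred_idx = [k for k in range(len(cols)) if k != j]
                X = filled[:, pred_idx]
                X = np.column_stack([np.ones(len(X)), X])
                yv = filled[:, j]
                model = cond[c]
                if model == "bayes_linear":
                    filled[mis, j] = _draw_bayes_linear(rng, X[~mis], values[~mis, j], X[mis])
                elif model == "logistic":
                    filled[mis, j] = _draw_logistic(rng, X[~mis], values[~mis, j], X[mis])
                else:
                    filled[mis, j] = _draw_pmm(rng, X[~mis], values[~mis, j], X[mis], donors=5)
            trace_rows.append({c: filled[is_missing[:, cols.index(c)], cols.index(c)].mean() for c in chain_cols})
        out = pd.DataFrame(filled, columns=cols, index=df.index)
        out = out.drop(columns=[_STATUS] + ([_OUTCOME] if _OUTCOME in out.columns else []))
        datasets.append(out)
        traces.append(pd.DataFrame(trace_rows))
    imputed_counts = miss.sum(axis=0)
    return ImputationSet(
        datasets=datasets,
        conditional_models={k: v for k, v in cond.items() if k != _OUTCOME},
        n_iter=n_iter,
        seed=seed,
        imputed_counts=imputed_counts,
        chain_means=traces,
    )


# ---------------------------------------------------------------------------
# conditional draws

_RIDGE = 1e-6


def _linear_posterior(rng, Xo, yo):
    n, p = Xo.shape
    A = Xo.T @ Xo + _RIDGE * np.eye(p)
    L = np.linalg.cholesky(A)
    beta_hat = np.linalg.solve(A, Xo.T @ yo)
    rss = float(np.sum((yo - Xo @ beta_hat) ** 2))
    df = max(n - p, 1)
    sigma2 = rss / stats.chi2.rvs(df, random_state=rng)
    z = rng.standard_normal(p)
    beta_draw = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return beta_hat, beta_draw, np.sqrt(sigma2)


def _draw_bayes_linear(rng, Xo, yo, Xm):
    _, beta_draw, sigma = _linear_posterior(rng, Xo, yo)
    return Xm @ beta_draw + sigma * rng.standard_normal(len(Xm))


def _draw_pmm(rng, Xo, yo, Xm, donors: int = 5):
    """Type-1 predictive-mean matching: match draws to observed predictions."""
    beta_hat, beta_draw, _ = _linear_posterior(rng, Xo, yo)
    pred_obs = Xo @ beta_hat
    pred_mis = Xm @ beta_draw
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    n_obs = len(sorted_pred)
    k = min(donors, n_obs)
    # candidate window around the insertion point, then the k nearest inside it
    lo = np.clip(pos - k, 0, max(n_obs - 2 * k, 0))
    offsets = np.arange(2 * k)
    win = np.clip(lo[:, None] + offsets[None, :], 0, n_obs - 1)
    dist = np.abs(sorted_pred[win] - pred_mis[:, None])
    nearest = np.argsort(dist, axis=1)[:, :k]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    donor_rows = win[np.arange(len(pred_mis)), pick]
    return yo[order][donor_rows]


def _draw_logistic(rng, Xo, yo, Xm, max_iter: int = 30):
    levels = np.unique(yo)
    if levels.size != 2:  # degenerate observed side; fall back to donor sampling
        return rng.choice(yo, size=len(Xm), replace=True)
    y01 = (yo == levels[1]).astype(float)
    p = Xo.shape[1]
    beta = np.zeros(p)
    lam = _RIDGE * len(Xo)
    cov = None
    for _ in range(max_iter):
        eta = np.clip(Xo @ beta, -30, 30)
        mu = special.expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (Xo * w[:, None]).T @ Xo + lam * np.eye(p)
        g = Xo.T @ (y01 - mu) - lam * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(H) @ g
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(Xo @ beta, -30, 30)
    mu = special.expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    H = (Xo * w[:, None]).T @ Xo + lam * np.eye(p)
    cov = np.linalg.pinv(H)
    beta_draw = rng.multivariate_normal(beta, cov, method="eigh", check_valid="ignore")
    pm = special.expit(np.clip(Xm @ beta_draw, -30, 30))
    return np.where(rng.random(len(Xm)) < pm, levels[1], levels[0])


# ---------------------------------------------------------------------------
# Rubin pooling


@dataclass
class PooledFit:
    """Rubin-pooled coefficients across an imputation set."""

    variables: list[str]
    coef: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    df: pd.Series
    between_var: pd.Series
    within_var: pd.Series
    M: int
    r2: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "B": self.coef,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvalues,
                "df": self.df,
            }
        )


def pool_rubin(fits: list[ModelFit]) -> PooledFit:
    """Pool per-imputation fits of one model by Rubin's rules.

    Pooled coefficient = mean; total variance = within + (1 + 1/M)·between;
    degrees of freedom by the Barnard–Rubin small-sample adjustment.  With a
    single fit the pooled result equals that fit.
    """
    if not fits:
        raise ValueError("no fits to pool")
    varset = list(fits[0].coef.index)
    for f in fits[1:]:
        if list(f.coef.index) != varset:
            raise ValueError("imputation fits have mismatched variable sets")
    M = len(fits)
    Q = np.vstack([f.coef.to_numpy() for f in fits])
    U = np.vstack([f.se.to_numpy() ** 2 for f in fits])
    qbar = Q.mean(axis=0)
    ubar = U.mean(axis=0)
    b = Q.var(axis=0, ddof=1) if M > 1 else np.zeros_like(qbar)
    T = ubar + (1 + 1 / M) * b
    nu_com = fits[0].df_resid
    if M > 1:
        lam = np.clip((1 + 1 / M) * b / T, 1e-12, 1 - 1e-12)
        nu_old = (M - 1) / lam**2
        nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
        df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    else:
        df = np.full_like(qbar, float(nu_com))
    se = np.sqrt(T)
    tstat = np.where(se > 0, qbar / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    tcrit = stats.t.ppf(0.975, df)
    idx = pd.Index(varset)
    return PooledFit(
        variables=varset,
        coef=pd.Series(qbar, index=idx),
        se=pd.Series(se, index=idx),
        ci_low=pd.Series(qbar - tcrit * se, index=idx),
        ci_high=pd.Series(qbar + tcrit * se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        df=pd.Series(df, index=idx),
        between_var=pd.Series(b, index=idx),
        within_var=pd.Series(ubar, index=idx),
        M=M,
        r2=float(np.mean([f.r2 for f in fits])),
    )
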