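"""Stages 2–3: stepwise and best-subset multivariable reduction.

Domain-specific models prune each domain's stage-1 survivors; the union of
the domain survivors is then reduced to a single final model.  Three search
methods share one inclusion/removal criterion ``p_crit`` (by default the
stage-1 FDR threshold):

``forwards``
    add the candidate with the smallest partial p-value while it is below
    ``p_crit``, then sweep out any member that has drifted above it;
``backwards``
    start from the full candidate set and repeatedly remove the largest
    p-value above ``p_crit``;
``subset``
    best-subset search: the subset maximizing R² among subsets whose every
    member satisfies ``p <= p_crit`` in the joint fit.  Exhaustive (hence
    exact) up to ``max_exhaustive`` candidates; beyond that a branch-and-bound
    on residual sum of squares seeded with the forwards and backwards
    solutions, so its R² can never fall below either greedy method.

The partner-status indicator is a structural term: it is forced into any
model containing a partner-reported variable, never counts against model
size, and is exempt from the significance filter.

All fits run on complete data (a completed imputation or complete cases)
through precomputed Gram matrices, so model size — not sample size — drives
the cost of a search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from exwas.codebook import ExposomeMatrix

__all__ = [
    "ModelFit",
    "SelectionTrace",
    "attenuation_summary",
    "best_subset_search",
    "domain_models",
    "final_model",
    "fit_linear",
    "partial_correlation",
    "stepwise_fit",
]


class SingularFitError(np.linalg.LinAlgError):
    """The requested subset is numerically collinear."""


# ---------------------------------------------------------------------------
# Gram-matrix OLS engine


class GramOLS:
    """OLS fits for arbitrary subsets of a fixed candidate pool.

    Columns are centered once (the intercept is implicit) and the Gram matrix
    ``X'X``, ``X'y`` and ``y'y`` precomputed; a subset fit is then a k×k
    solve.  ``forced`` columns are included in every fit.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, names: list[str], forced_names: list[str] | None = None):
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("GramOLS requires complete data")
        self.names = list(names)
        self.forced_names = list(forced_names or [])
        self.n = X.shape[0]
        self._xmean = X.mean(axis=0)
        self._ymean = float(y.mean())
        Xc = X - self._xmean
        yc = y - self._ymean
        self.G = Xc.T @ Xc
        self.Xy = Xc.T @ yc
        self.yy = float(yc @ yc)
        self._forced_idx = [self.names.index(f) for f in self.forced_names]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def fit(self, subset: list[int], strict: bool = False) -> "SubsetFit":
        """Fit on ``subset`` plus the forced columns (indices into names).

        With ``strict`` a numerically singular design raises
        :class:`SingularFitError` instead of falling back to a pseudoinverse.
        """
        idx = list(subset) + [f for f in self._forced_idx if f not in subset]
        k = len(idx)
        if k == 0:
            return SubsetFit(idx=[], coef=np.empty(0), se=np.empty(0), t=np.empty(0),
                             p=np.empty(0), rss=self.yy, r2=0.0, df=self.n - 1, gram=self)
        A = self.G[np.ix_(idx, idx)]
        b = self.Xy[idx]
        try:
            L = np.linalg.cholesky(A)
            coef = _cho_solve(L, b)
            Ainv = _cho_solve(L, np.eye(k))
        except np.linalg.LinAlgError:
            if strict:
                raise SingularFitError("collinear design")
            Ainv = np.linalg.pinv(A)
            coef = Ainv @ b
        rss = max(self.yy - float(coef @ b), 0.0)
        df = self.n - k - 1
        if df <= 0:
            raise ValueError("no residual degrees of freedom")
        sigma2 = rss / df
        se = np.sqrt(np.maximum(np.diag(Ainv), 0.0) * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, coef / se, np.sign(coef) * np.inf)
        p = 2 * stats.t.sf(np.abs(t), df)
        r2 = 1.0 - rss / self.yy if self.yy > 0 else 0.0
        return SubsetFit(idx=idx, coef=coef, se=se, t=t, p=p, rss=rss, r2=r2, df=df, gram=self)

    def rss_of(self, subset: list[int]) -> float:
        """RSS of the subset fit (bound computation; no inference)."""
        idx = list(subset) + [f for f in self._forced_idx if f not in subset]
        if not idx:
            return self.yy
        A = self.G[np.ix_(idx, idx)]
        b = self.Xy[idx]
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            coef = np.linalg.pinv(A) @ b
        return max(self.yy - float(coef @ b), 0.0)

    def independent_subset(self, idx: list[int], tol: float = 1e-9) -> tuple[list[int], list[int]]:
        """Greedy pivoted screen: keep columns adding residual variance > tol.

        Returns (kept, aliased) index lists; used so a collinear backwards
        start does not produce a singular full model.
        """
        kept: list[int] = []
        aliased: list[int] = []
        for j in idx:
            trial = kept + [j]
            A = self.G[np.ix_(trial, trial)]
            d = self.G[j, j]
            if d <= 0:
                aliased.append(j)
                continue
            if kept:
                Ak = self.G[np.ix_(kept, kept)]
                cross = self.G[np.ix_(kept, [j])].ravel()
                try:
                    resid = d - float(cross @ np.linalg.solve(Ak, cross))
                except np.linalg.LinAlgError:
                    resid = 0.0
                if resid <= tol * d:
                    aliased.append(j)
                    continue
            kept.append(j)
        return kept, aliased


def _cho_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    z = solve_triangular(L, b, lower=True)
    return solve_triangular(L.T, z, lower=False)


@dataclass
class SubsetFit:
    idx: list[int]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    r2: float
    df: int
    gram: GramOLS

    def admissible(self, p_crit: float) -> bool:
        """All non-forced members significant at p_crit."""
        forced = set(self.gram._forced_idx)
        return all(pv <= p_crit for j, pv in zip(self.idx, self.p) if j not in forced)


# ---------------------------------------------------------------------------
# public containers


@dataclass
class ModelFit:
    """A fitted multivariable linear model on standardized exposures."""

    variables: list[str]
    coef: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    partial_corr: pd.Series
    r2: float
    nobs: int
    df_resid: int
    intercept: float
    method: str
    p_crit: float
    forced: list[str] = field(default_factory=list)
    aliased: list[str] = field(default_factory=list)
    empty_admissible: bool = False

    @property
    def k(self) -> int:
        """Model size excluding structural (forced) terms."""
        return len([v for v in self.variables if v not in self.forced])

    def predict(self, data: pd.DataFrame) -> pd.Series:
        yhat = pd.Series(self.intercept, index=data.index)
        for v in self.variables:
            yhat = yhat + self.coef[v] * data[v]
        return yhat

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "B": self.coef,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvalues,
                "partial_corr": self.partial_corr,
            }
        )
        df["forced"] = [v in self.forced for v in df.index]
        return df.sort_values("partial_corr", key=lambda s: -s.abs())


@dataclass
class SelectionTrace:
    """Ordered add/remove log; replaying it reproduces the final model."""

    steps: list[tuple[str, str, float]] = field(default_factory=list)

    def record(self, action: str, variable: str, p: float) -> None:
        self.steps.append((action, variable, float(p)))

    def replay(self) -> list[str]:
        current: list[str] = []
        for action, var, _ in self.steps:
            if action == "add":
                current.append(var)
            elif action == "remove":
                current.remove(var)
        return current

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["action", "variable", "p"])


def _as_model_fit(fit: SubsetFit, gram: GramOLS, method: str, p_crit: float,
                  aliased: list[str] | None = None, empty: bool = False) -> ModelFit:
    names = [gram.names[j] for j in fit.idx]
    tcrit = stats.t.ppf(0.975, fit.df) if fit.df > 0 else np.nan
    coef = pd.Series(fit.coef, index=names)
    se = pd.Series(fit.se, index=names)
    pc = pd.Series(
        np.sign(fit.coef) * np.sqrt(fit.t**2 / (fit.t**2 + fit.df)),
        index=names,
    )
    intercept = gram._ymean - float(np.dot(fit.coef, gram._xmean[fit.idx]))
    return ModelFit(
        variables=names,
        coef=coef,
        se=se,
        ci_low=coef - tcrit * se,
        ci_high=coef + tcrit * se,
        pvalues=pd.Series(fit.p, index=names),
        partial_corr=pc,
        r2=fit.r2,
        nobs=gram.n,
        df_resid=fit.df,
        intercept=intercept,
        method=method,
        p_crit=p_crit,
        forced=list(gram.forced_names),
        aliased=aliased or [],
        empty_admissible=empty,
    )


def _prepare_gram(
    data: pd.DataFrame,
    outcome: pd.Series,
    candidates: list[str],
    partner_vars: set[str],
    partner_status: pd.Series | None,
) -> tuple[GramOLS, list[int]]:
    """Build the Gram engine over candidates (+ partner_status if needed)."""
    obs = outcome.notna()
    cols = list(candidates)
    forced: list[str] = []
    if partner_status is not None and any(c in partner_vars for c in cols) and partner_status.loc[obs].nunique() > 1:
        forced = ["partner_status"]
    X = data.loc[obs, cols].to_numpy(float)
    if forced:
        X = np.column_stack([X, partner_status.loc[obs].to_numpy(float)])
    gram = GramOLS(X, outcome.loc[obs].to_numpy(float), cols + forced, forced_names=forced)
    return gram, [gram.index_of(c) for c in cols]


def _resolve_inputs(matrix, outcome):
    """Accept an ExposomeMatrix or a plain DataFrame."""
    if isinstance(matrix, ExposomeMatrix):
        return matrix.data, set(matrix.codebook.partner_variables), matrix.partner_status
    return matrix, set(), None


def fit_linear(matrix, outcome: pd.Series, variables: list[str], method: str = "fixed") -> ModelFit:
    """Plain OLS fit of an exact variable set (no selection)."""
    data, partner_vars, status = _resolve_inputs(matrix, outcome)
    gram, idx = _prepare_gram(data, outcome, list(variables), partner_vars, status)
    return _as_model_fit(gram.fit(idx), gram, method, p_crit=1.0)


# ---------------------------------------------------------------------------
# stepwise search


def stepwise_fit(
    matrix,
    outcome: pd.Series,
    candidates: list[str],
    method: str = "forwards",
    p_crit: float = 1e-3,
    max_exhaustive: int = 15,
) -> tuple[ModelFit, SelectionTrace]:
    """Select a multivariable model from ``candidates`` by ``method``.

    ``matrix`` may be an :class:`ExposomeMatrix` (partner handling applied)
    or a plain complete-data DataFrame.  Ties on p-values break by candidate
    order and are visible in the trace.
    """
    if method not in ("forwards", "backwards", "subset"):
        raise ValueError("method must be forwards, backwards or subset")
    if not 0 < p_crit < 1:
        raise ValueError("p_crit must be in (0, 1)")
    data, partner_vars, status = _resolve_inputs(matrix, outcome)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    gram, cand_idx = _prepare_gram(data, outcome, candidates, partner_vars, status)

    if method == "subset":
        fit, trace = _subset_with_trace(gram, cand_idx, p_crit, max_exhaustive)
        return fit, trace

    trace = SelectionTrace()
    if method == "forwards":
        selected = _forwards(gram, cand_idx, p_crit, trace)
        aliased: list[str] = []
    else:
        kept, dropped = gram.independent_subset(cand_idx)
        aliased = [gram.names[j] for j in dropped]
        for name in aliased:
            trace.record("alias", name, float("nan"))
        selected = _backwards(gram, kept, p_crit, trace)
    fit = gram.fit(selected)
    return _as_model_fit(fit, gram, method, p_crit, aliased=aliased, empty=not selected), trace


def _forwards(gram: GramOLS, cand_idx: list[int], p_crit: float, trace: SelectionTrace) -> list[int]:
    selected: list[int] = []
    remaining = list(cand_idx)
    while remaining:
        best_j, best_p = None, None
        for j in remaining:
            try:
                fit = gram.fit(selected + [j], strict=True)
            except SingularFitError:  # aliased with the current model; not addable
                continue
            pj = fit.p[fit.idx.index(j)]
            if best_p is None or pj < best_p:  # strict < keeps first-in-order on ties
                best_j, best_p, best_tied = j, pj, False
            elif pj == best_p:
                best_tied = True
        if best_p is None or best_p > p_crit:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        if best_tied:
            trace.record("tie", gram.names[best_j], best_p)
        trace.record("add", gram.names[best_j], best_p)
        # removal sweep: earlier members may have drifted over the criterion
        while True:
            fit = gram.fit(selected)
            worst_j, worst_p = None, -1.0
            forced = set(gram._forced_idx)
            for j, pv in zip(fit.idx, fit.p):
                if j in forced or j not in selected:
                    continue
                if pv > worst_p:
                    worst_j, worst_p = j, pv
            if worst_j is None or worst_p <= p_crit:
                break
            selected.remove(worst_j)
            remaining.append(worst_j)
            trace.record("remove", gram.names[worst_j], worst_p)
    return selected


def _backwards(gram: GramOLS, cand_idx: list[int], p_crit: float, trace: SelectionTrace) -> list[int]:
    selected = list(cand_idx)
    for j in selected:
        trace.record("add", gram.names[j], float("nan"))
    while selected:
        fit = gram.fit(selected)
        forced = set(gram._forced_idx)
        worst_j, worst_p = None, -1.0
        for j, pv in zip(fit.idx, fit.p):
            if j in forced:
                continue
            if pv > worst_p:
                worst_j, worst_p = j, pv
        if worst_j is None or worst_p <= p_crit:
            break
        selected.remove(worst_j)
        trace.record("remove", gram.names[worst_j], worst_p)
    return selected


# ---------------------------------------------------------------------------
# best-subset search


def best_subset_search(
    matrix,
    outcome: pd.Series,
    candidates: list[str],
    p_crit: float = 1e-3,
    max_exhaustive: int = 15,
    node_cap: int = 200_000,
) -> ModelFit:
    """Best admissible subset: max R² with every member at ``p <= p_crit``.

    For ``len(candidates) <= max_exhaustive`` the search is exact (the
    branch-and-bound provably enumerates every subset that could beat the
    incumbent).  Larger pools use the same bound with a node cap and
    incumbents from the greedy searches, so the result is best-effort but
    never worse than forwards or backwards.  If no admissible subset exists,
    an intercept-only fit is returned with ``empty_admissible`` set.
    """
    data, partner_vars, status = _resolve_inputs(matrix, outcome)
    gram, cand_idx = _prepare_gram(data, outcome, list(candidates), partner_vars, status)
    fit, _ = _subset_with_trace(gram, cand_idx, p_crit, max_exhaustive, node_cap)
    return fit


def _subset_with_trace(
    gram: GramOLS,
    cand_idx: list[int],
    p_crit: float,
    max_exhaustive: int = 15,
    node_cap: int = 200_000,
) -> tuple[ModelFit, SelectionTrace]:
    # incumbents from the greedy methods guarantee subset >= greedy R²
    t0 = SelectionTrace()
    fwd = _forwards(gram, list(cand_idx), p_crit, t0)
    kept, dropped = gram.independent_subset(list(cand_idx))
    bwd = _backwards(gram, kept, p_crit, SelectionTrace())
    aliased = [gram.names[j] for j in dropped]

    best_set: list[int] | None = None
    best_rss = np.inf
    for inc in (fwd, bwd):
        if not inc:
            continue
        fit = gram.fit(inc)
        if fit.admissible(p_crit) and fit.rss < best_rss:
            best_set, best_rss = list(inc), fit.rss

    # order candidates by |t| in the (independent) full fit: good splits first
    full = gram.fit(kept)
    order = sorted(kept, key=lambda j: -abs(full.t[full.idx.index(j)]))

    nodes = 0
    exact = len(cand_idx) <= max_exhaustive

    def dfs(S: list[int], C: list[int]) -> None:
        nonlocal best_set, best_rss, nodes
        nodes += 1
        if nodes > node_cap and not exact:
            return
        if S:
            fit = gram.fit(S)
            if fit.admissible(p_crit) and fit.rss < best_rss - 1e-12:
                best_set, best_rss = list(S), fit.rss
        if not C:
            return
        if gram.rss_of(S + C) >= best_rss:
            return  # no descendant can beat the admissible incumbent
        dfs(S + [C[0]], C[1:])
        dfs(S, C[1:])

    dfs([], order)

    trace = SelectionTrace()
    if best_set is None:
        fit = gram.fit([])
        model = _as_model_fit(fit, gram, "subset", p_crit, aliased=aliased, empty=True)
        return model, trace
    fit = gram.fit(best_set)
    for j, pv in zip(fit.idx, fit.p):
        if j in best_set:
            trace.record("add", gram.names[j], pv)
    return _as_model_fit(fit, gram, "subset", p_crit, aliased=aliased), trace


# ---------------------------------------------------------------------------
# domain and final models


def domain_models(
    matrix: ExposomeMatrix,
    outcome: pd.Series,
    screen_results: pd.DataFrame,
    method: str = "backwards",
    p_crit: float = 1e-3,
) -> tuple[dict[str, ModelFit], pd.DataFrame]:
    """Stage 2: one stepwise model per domain over its stage-1 survivors.

    ``screen_results`` should be the full stage-1 scan table (all variables,
    pass flags filled); ``matrix`` needs columns only for the survivors.
    Returns the per-domain fits and a summary table (total variables,
    stage-1 selected count, model df and R² per domain).
    """
    fits: dict[str, ModelFit] = {}
    rows = []
    for domain in screen_results["domain"].unique():
        in_dom = screen_results.loc[screen_results["domain"] == domain]
        survivors = list(in_dom.index[in_dom["passes_fdr"]])
        if survivors:
            fit, _ = stepwise_fit(matrix, outcome, survivors, method=method, p_crit=p_crit)
        else:
            fit = _empty_fit(method, p_crit)
        fits[domain] = fit
        rows.append(
            {
                "domain": domain,
                "n_variables": len(in_dom),
                "stage1_selected": len(survivors),
                "stage1_pct": 100.0 * len(survivors) / max(len(in_dom), 1),
                "model_df": fit.k,
                "r2_pct": 100.0 * fit.r2,
            }
        )
    return fits, pd.DataFrame(rows).set_index("domain")


def _empty_fit(method: str, p_crit: float) -> ModelFit:
    empty = pd.Series(dtype=float)
    return ModelFit(
        variables=[], coef=empty, se=empty, ci_low=empty, ci_high=empty,
        pvalues=empty, partial_corr=empty, r2=0.0, nobs=0, df_resid=0,
        intercept=float("nan"), method=method, p_crit=p_crit, empty_admissible=True,
    )


def final_model(
    matrix: ExposomeMatrix,
    outcome: pd.Series,
    domain_fits: dict[str, ModelFit],
    screen_results: pd.DataFrame | None = None,
    method: str = "subset",
    p_crit: float = 1e-3,
) -> tuple[ModelFit, SelectionTrace, pd.DataFrame | None]:
    """Stage 3: combine domain survivors and reduce to the final model.

    Also decomposes the final R² by unadjusted-rank tier (top 5 variables by
    stage-1 rank, next 5, remainder) when screen results are supplied.
    """
    pool: list[str] = []
    for fit in domain_fits.values():
        pool.extend(v for v in fit.variables if v not in fit.forced and v not in pool)
    if not pool:
        return _empty_fit(method, p_crit), SelectionTrace(), None
    fit, trace = stepwise_fit(matrix, outcome, pool, method=method, p_crit=p_crit)

    tiers = None
    if screen_results is not None and fit.variables:
        members = [v for v in fit.variables if v not in fit.forced]
        ranked = screen_results.loc[members, "rank"].sort_values()
        groups = [list(ranked.index[:5]), list(ranked.index[5:10]), list(ranked.index[10:])]
        rows, cum = [], []
        for label, grp in zip(("top5_by_rank", "next5", "remainder"), groups):
            if not grp:
                continue
            cum.extend(grp)
            sub = fit_linear(matrix, outcome, cum)
            rows.append(
                {
                    "tier": label,
                    "variables": len(grp),
                    "rank_range": f"{int(ranked[grp].min())}-{int(ranked[grp].max())}",
                    "cumulative_r2_pct": 100.0 * sub.r2,
                }
            )
        tiers = pd.DataFrame(rows).set_index("tier")
        tiers["added_r2_pct"] = tiers["cumulative_r2_pct"].diff().fillna(tiers["cumulative_r2_pct"])
        tiers["share_of_total_pct"] = 100.0 * tiers["added_r2_pct"] / (100.0 * fit.r2)
    return fit, trace, tiers


def partial_correlation(fit: ModelFit, variable: str) -> float:
    """sign(B)·sqrt(t²/(t²+df)) for one variable of a joint fit."""
    if variable not in fit.coef.index:
        raise KeyError(f"{variable} not in model")
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    t = fit.coef[variable] / fit.se[variable]
    return float(np.sign(t) * np.sqrt(t * t / (t * t + fit.df_resid)))


def attenuation_summary(
    unadjusted: pd.DataFrame,
    adjusted: ModelFit | pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Percentage attenuation of effect sizes due to adjustment.

    attenuation = 100·(1 − B_adj/B_unadj).  Variables whose adjusted effect
    changed sign are excluded from the mean/range and reported separately
    (their magnitude change is still tabulated).
    """
    B_adj = adjusted.coef if isinstance(adjusted, ModelFit) else adjusted
    names = [v for v in B_adj.index if v in unadjusted.index]
    if not names:
        raise ValueError("no overlapping variables between unadjusted and adjusted inputs")
    B_un = unadjusted.loc[names, "B"]
    if (B_un == 0).any():
        raise ValueError("unadjusted coefficient of zero; attenuation undefined")
    ratio = B_adj[names] / B_un
    att = 100.0 * (1.0 - ratio)
    flips = list(att.index[ratio < 0])
    table = pd.DataFrame({"B_unadjusted": B_un, "B_adjusted": B_adj[names],
                          "attenuation_pct": att, "sign_flip": ratio < 0})
    clean = att[ratio >= 0]
    summary = {
        "mean_attenuation_pct": float(clean.mean()) if len(clean) else float("nan"),
        "min_attenuation_pct": float(clean.min()) if len(clean) else float("nan"),
        "max_attenuation_pct": float(clean.max()) if len(clean) else float("nan"),
        "sign_flips": flips,
    }
    return table, summary
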