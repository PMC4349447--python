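"""Sensitivity analyses for the final model.

Four robustness probes:

* **ordinal_refit** — refits the final model as a proportional-odds
  (ordinal logistic) regression on a quantile-binned outcome, a check on the
  normality assumption of the linear fit.  Odds ratios are oriented so that
  OR > 1, like B > 0, means a more favourable outcome; explanatory power is
  reported as McFadden's pseudo-R² (1 − LL/LL₀).
* **factor_sensitivity** — replaces the correlated stage-1 survivors with
  orthogonal factor scores (principal-axis extraction, eigenvalue > 1
  retention, varimax rotation), reruns the stepwise selection on the scores
  and maps significant factors back to variables by top loading.
* **chaid_tree** — a CHAID-style regression tree (F-tests for a continuous
  outcome, stepwise merging of adjacent predictor categories, Bonferroni
  adjusted split selection): a non-linear, interaction-aware counterpart of
  the linear model.
* **consistency_report** — Jaccard overlap / inclusion-frequency comparison
  of variable sets selected by different methods or criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from exwas.select import ModelFit, SelectionTrace, stepwise_fit

__all__ = [
    "FactorModel",
    "OrdinalFit",
    "TreeModel",
    "TreeNode",
    "chaid_tree",
    "consistency_report",
    "factor_sensitivity",
    "ordinal_refit",
]


# ---------------------------------------------------------------------------
# proportional-odds refit


@dataclass
class OrdinalFit:
    odds_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    pseudo_r2: float
    n_bins: int
    converged: bool
    rank_concordance: float  # Spearman rho between |B| ranks and |log OR| ranks
    max_rank_shift: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"OR": self.odds_ratios, "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.pvalues}
        )


def ordinal_refit(
    final_fit: ModelFit,
    matrix,
    outcome: pd.Series,
    n_bins: int = 20,
) -> OrdinalFit:
    """Proportional-odds refit of the final model on a binned outcome.

    The near-continuous outcome is discretized into ``n_bins`` equal-
    frequency categories; on non-convergence the binning is coarsened
    (halved) and the fit retried.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    data = matrix.data if hasattr(matrix, "data") else matrix
    variables = list(final_fit.variables)
    if final_fit.forced and hasattr(matrix, "partner_status"):
        data = data.copy()
        data["partner_status"] = matrix.partner_status.astype(float)
    obs = outcome.notna()
    X = data.loc[obs, variables]
    y = outcome.loc[obs]

    bins = n_bins
    while bins >= 3:
        cats = pd.qcut(y, bins, labels=False, duplicates="drop")
        try:
            model = OrderedModel(cats, X, distr="logit")
            res = model.fit(method="lbfgs", maxiter=500, disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            converged = False
        if converged:
            break
        bins //= 2
    if not converged:
        raise RuntimeError("proportional-odds fit did not converge at any binning")

    k = len(variables)
    params = res.params.iloc[:k]
    se = res.bse.iloc[:k]
    or_ = np.exp(params)
    ci_lo = np.exp(params - 1.96 * se)
    ci_hi = np.exp(params + 1.96 * se)
    pvals = res.pvalues.iloc[:k]

    counts = cats.value_counts().to_numpy(float)
    ll_null = float(np.sum(counts * np.log(counts / counts.sum())))
    pseudo = 1.0 - res.llf / ll_null

    # concordance between linear and ordinal effect-size rankings
    b_rank = final_fit.coef[variables].abs().rank(ascending=False)
    or_rank = np.log(or_).abs().rank(ascending=False)
    rho = float(stats.spearmanr(b_rank, or_rank).statistic) if k > 1 else 1.0
    shift = int((b_rank - or_rank).abs().max()) if k > 1 else 0
    return OrdinalFit(
        odds_ratios=pd.Series(or_.to_numpy(), index=variables),
        ci_low=pd.Series(ci_lo.to_numpy(), index=variables),
        ci_high=pd.Series(ci_hi.to_numpy(), index=variables),
        pvalues=pd.Series(pvals.to_numpy(), index=variables),
        pseudo_r2=float(pseudo),
        n_bins=bins,
        converged=converged,
        rank_concordance=rho,
        max_rank_shift=shift,
    )


# ---------------------------------------------------------------------------
# factor-space sensitivity


@dataclass
class FactorModel:
    loadings: pd.DataFrame       # variables × factors (varimax-rotated)
    scores: pd.DataFrame         # subjects × factors, unit variance, ~orthogonal
    n_factors: int
    attribution: dict[str, str]  # factor -> top-|loading| variable
    eigenvalues: np.ndarray


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns rotated loadings and the rotation matrix."""
    p, k = L.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(L.T @ (Lr**3 - Lr * (Lr**2).sum(axis=0) / p))
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ R, R


def factor_sensitivity(
    matrix,
    outcome: pd.Series,
    p_crit: float = 1e-3,
    method: str = "backwards",
) -> tuple[FactorModel, ModelFit, pd.DataFrame]:
    """Selection on orthogonal factor scores instead of raw variables.

    Factors are extracted from the correlation matrix of the (standardized,
    complete) stage-1 survivors, retained by the eigenvalue-greater-than-one
    rule and varimax-rotated; scores keep unit variance and mutual
    orthogonality.  A stepwise fit on the scores gives a factor-level model,
    mapped back to variables via each factor's top-|loading| variable.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    obs = outcome.notna()
    Z = data.loc[obs]
    if Z.isna().any().any():
        raise ValueError("factor extraction needs complete (imputed) data")
    Zc = (Z - Z.mean()) / Z.std(ddof=1)
    n, p = Zc.shape
    if p > n:
        import warnings

        warnings.warn("more variables than subjects: correlation matrix is rank-deficient", stacklevel=2)
    corr = np.corrcoef(Zc.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = max(int((eigval > 1.0).sum()), 1)
    L = eigvec[:, :k] * np.sqrt(eigval[:k])
    L_rot, R = _varimax(L)
    # unit-variance principal scores carried through the orthogonal rotation
    scores = Zc.to_numpy() @ (eigvec[:, :k] / np.sqrt(eigval[:k])) @ R
    names = [f"factor_{i + 1:02d}" for i in range(k)]
    loadings = pd.DataFrame(L_rot, index=Z.columns, columns=names)
    score_df = pd.DataFrame(scores, index=Z.index, columns=names)
    attribution = {f: loadings[f].abs().idxmax() for f in names}
    model = FactorModel(
        loadings=loadings,
        scores=score_df,
        n_factors=k,
        attribution=attribution,
        eigenvalues=eigval,
    )
    fit, _ = stepwise_fit(score_df, outcome.loc[obs], names, method=method, p_crit=p_crit)
    mapped = pd.DataFrame(
        {
            "factor": fit.variables,
            "top_variable": [attribution[f] for f in fit.variables],
            "B": fit.coef[fit.variables].to_numpy(),
            "p": fit.pvalues[fit.variables].to_numpy(),
        }
    )
    return model, fit, mapped


# ---------------------------------------------------------------------------
# CHAID-style regression tree


@dataclass
class TreeNode:
    node_id: int
    depth: int
    subjects: np.ndarray           # row positions in the fitting sample
    mean: float
    size: int
    split_variable: str | None = None
    groups: list[tuple] = field(default_factory=list)  # merged category tuples
    statistic: float = float("nan")
    p_adjusted: float = float("nan")
    children: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class TreeModel:
    nodes: dict[int, TreeNode]
    root: int = 0

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def render(self) -> str:
        lines: list[str] = []

        def _walk(nid: int, prefix: str) -> None:
            node = self.nodes[nid]
            desc = f"n={node.size} mean={node.mean:.2f}"
            if node.split_variable is not None:
                desc += f" | split {node.split_variable} (F={node.statistic:.1f}, adj p={node.p_adjusted:.2e})"
            lines.append(prefix + desc)
            for cid, grp in zip(node.children, node.groups):
                lines.append(prefix + f"  [{node.split_variable} in {sorted(grp)}]")
                _walk(cid, prefix + "    ")

        _walk(self.root, "")
        return "\n".join(lines)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for node in self.nodes.values():
            for cid, grp in zip(node.children, node.groups):
                child = self.nodes[cid]
                rows.append(
                    {
                        "parent": node.node_id,
                        "child": cid,
                        "variable": node.split_variable,
                        "categories": ",".join(str(g) for g in sorted(grp)),
                        "child_n": child.size,
                        "child_mean": child.mean,
                    }
                )
        return pd.DataFrame(rows)


def _bin_predictors(data: pd.DataFrame, max_levels: int = 5) -> pd.DataFrame:
    """Pre-bin continuous predictors into quintiles; CHAID needs categories."""
    out = {}
    for c in data.columns:
        col = data[c]
        if col.nunique(dropna=True) <= max_levels + 1:
            out[c] = col
        else:
            out[c] = pd.Series(pd.qcut(col, max_levels, labels=False, duplicates="drop"), index=col.index, dtype=float)
    return pd.DataFrame(out)


def _merge_categories(x: np.ndarray, y: np.ndarray, min_leaf: int, merge_alpha: float = 0.05):
    """Stepwise merging of adjacent categories while pairwise tests agree."""
    cats = sorted(set(x))
    groups: list[tuple] = [(c,) for c in cats]

    def _group_values(g):
        mask = np.isin(x, g)
        return y[mask]

    while len(groups) > 1:
        best_pair, best_p = None, -1.0
        for i in range(len(groups) - 1):
            a, b = _group_values(groups[i]), _group_values(groups[i + 1])
            if len(a) < 2 or len(b) < 2:
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
                if np.isnan(p):
                    p = 1.0
            if p > best_p:
                best_pair, best_p = i, p
        undersized = any(len(_group_values(g)) < min_leaf for g in groups)
        if best_p > merge_alpha or undersized:
            merged = groups[best_pair] + groups[best_pair + 1]
            groups = groups[:best_pair] + [merged] + groups[best_pair + 2 :]
        else:
            break
    return groups


def chaid_tree(
    matrix,
    outcome: pd.Series,
    alpha_split: float = 0.001,
    min_leaf: int = 50,
    max_depth: int = 5,
) -> TreeModel:
    """CHAID-style recursive partitioning of a continuous outcome.

    At each node, every predictor's categories are merged stepwise while
    adjacent pairs are statistically indistinguishable; the predictor with
    the smallest Bonferroni-adjusted one-way ANOVA p-value splits the node if
    that p is at most ``alpha_split`` and all children have at least
    ``min_leaf`` subjects.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    obs = outcome.notna()
    X = _bin_predictors(data.loc[obs])
    y = outcome.loc[obs].to_numpy(float)
    Xv = X.to_numpy(float)
    columns = list(X.columns)

    nodes: dict[int, TreeNode] = {}
    counter = [0]

    def _grow(rows: np.ndarray, depth: int) -> int:
        nid = counter[0]
        counter[0] += 1
        node = TreeNode(node_id=nid, depth=depth, subjects=rows, mean=float(y[rows].mean()), size=len(rows))
        nodes[nid] = node
        if depth >= max_depth or len(rows) < 2 * min_leaf:
            return nid
        best = None  # (p_adj, F, col, groups)
        n_tested = 0
        for j, col in enumerate(columns):
            xj = Xv[rows, j]
            if len(set(xj)) < 2:
                continue
            groups = _merge_categories(xj, y[rows], min_leaf)
            if len(groups) < 2:
                continue
            samples = [y[rows][np.isin(xj, g)] for g in groups]
            if any(len(s) < min_leaf for s in samples):
                continue
            n_tested += 1
            F, p = stats.f_oneway(*samples)
            if np.isnan(p):
                continue
            if best is None or p < best[0]:
                best = (float(p), float(F), col, groups, j)
        if best is None or n_tested == 0:
            return nid
        p_raw, F, col, groups, j = best
        p_adj = min(1.0, p_raw * n_tested)  # Bonferroni over predictors tested
        if p_adj > alpha_split:
            return nid
        node.split_variable = col
        node.groups = groups
        node.statistic = F
        node.p_adjusted = p_adj
        xj = Xv[rows, j]
        for g in groups:
            child_rows = rows[np.isin(xj, g)]
            node.children.append(_grow(child_rows, depth + 1))
        return nid

    _grow(np.arange(len(y)), 0)
    return TreeModel(nodes=nodes)


# ---------------------------------------------------------------------------
# cross-method consistency


def consistency_report(fits: dict[str, ModelFit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Jaccard overlap and per-variable inclusion frequency.

    Returns (overlap matrix with R² on the diagonal report, stability table
    listing each variable's inclusion frequency and the methods selecting
    it); variables selected by exactly one method are flagged.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    labels = list(fits)
    sets = {lab: set(v for v in f.variables if v not in f.forced) for lab, f in fits.items()}
    overlap = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            u = sets[a] | sets[b]
            overlap.loc[a, b] = 1.0 if not u else len(sets[a] & sets[b]) / len(u)
    all_vars = sorted(set().union(*sets.values()))
    rows = []
    for v in all_vars:
        chosen = [lab for lab in labels if v in sets[lab]]
        rows.append(
            {
                "variable": v,
                "inclusion_frequency": len(chosen) / len(labels),
                "methods": ",".join(chosen),
                "unique_to_one_method": len(chosen) == 1,
            }
        )
    stability = pd.DataFrame(rows).set_index("variable")
    return overlap, stability
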