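"""Post-model probes: interactions, non-linearity, mediation, prevalence.

Once a final model exists, four questions follow naturally.  Do exposure
pairs act synergistically (product terms, tested one at a time against the
full final model, then greedily reduced to a minimal explanatory set)?  Are
any of the assumed-linear associations curved (one-at-a-time quadratic
terms; binary variables are untestable)?  Are the identified effects routed
through a downstream mediator (coefficient attenuation after entering the
mediators)?  And what would shifting the outcome by a few points do to the
prevalence of an impaired group defined by a fixed population cutoff?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from exwas.select import ModelFit, fit_linear

__all__ = [
    "InteractionResult",
    "MediationResult",
    "interaction_scan",
    "mediation_analysis",
    "prevalence_shift",
    "quadratic_tests",
    "reduce_interactions",
]


@dataclass
class InteractionResult:
    """One pairwise product term tested against the final model."""

    pair: tuple[str, str]
    coef: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    cell_means: pd.DataFrame | None = None
    skipped: str | None = None  # reason, when the product was untestable

    @property
    def significant(self) -> bool:
        return self.skipped is None and not np.isnan(self.p)


def _product_name(a: str, b: str) -> str:
    return f"{a}*{b}"


def _with_products(data: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    out = data.copy()
    for a, b in pairs:
        out[_product_name(a, b)] = data[a] * data[b]
    return out


def _cell_mean_grid(data: pd.DataFrame, outcome: pd.Series, a: str, b: str, max_levels: int = 5) -> pd.DataFrame:
    """Outcome means over the (binned) level grid of a variable pair."""

    def _levels(col: pd.Series) -> pd.Series:
        vals = col.dropna().unique()
        if len(vals) <= max_levels + 1:
            return col
        return pd.Series(pd.qcut(col, max_levels, labels=False, duplicates="drop"), index=col.index)

    ga, gb = _levels(data[a]), _levels(data[b])
    grid = outcome.groupby([ga, gb], observed=True).mean().unstack()
    grid.index.name = a
    grid.columns.name = b
    return grid


def interaction_scan(
    final_fit: ModelFit,
    matrix,
    outcome: pd.Series,
    p_crit: float = 0.001,
) -> list[InteractionResult]:
    """Test every pair of final-model variables for interaction.

    Each product term is added, one at a time, to the full final model
    (all main effects retained, partner status included when structural).
    Product terms collinear with the mains — e.g. a binary variable with
    itself, which cannot happen across distinct variables, but near-constant
    products can — are skipped with a note.
    """
    mains = [v for v in final_fit.variables if v not in final_fit.forced]
    if len(mains) < 2:
        raise ValueError("interaction scan needs a final model with at least 2 variables")
    data, base = _probe_frame(matrix, final_fit)
    results: list[InteractionResult] = []
    for a, b in combinations(mains, 2):
        prod = data[a] * data[b]
        name = _product_name(a, b)
        aug = data[base].copy()
        aug[name] = prod
        # collinearity guard: product must have residual variance given mains
        X = aug.dropna()
        if X[name].nunique() < 2 or _residual_variance_ratio(X, base, name) < 1e-8:
            results.append(InteractionResult(pair=(a, b), coef=np.nan, se=np.nan,
                                             ci_low=np.nan, ci_high=np.nan, p=np.nan,
                                             skipped="product collinear with main effects"))
            continue
        fit = fit_linear(aug, outcome, base + [name])
        results.append(
            InteractionResult(
                pair=(a, b),
                coef=float(fit.coef[name]),
                se=float(fit.se[name]),
                ci_low=float(fit.ci_low[name]),
                ci_high=float(fit.ci_high[name]),
                p=float(fit.pvalues[name]),
                cell_means=_cell_mean_grid(data, outcome, a, b) if fit.pvalues[name] <= p_crit else None,
            )
        )
    return results


def _probe_frame(matrix, final_fit: ModelFit) -> tuple[pd.DataFrame, list[str]]:
    """Data frame and base term list for probe fits.

    The base terms are all final-model variables; when the final model
    carries a structural partner-status term, that indicator is appended as
    an ordinary column so every probe stays adjusted for it.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    base = [v for v in final_fit.variables if v not in final_fit.forced]
    if final_fit.forced and hasattr(matrix, "partner_status"):
        data = data.copy()
        data["partner_status"] = matrix.partner_status.astype(float)
        base = base + ["partner_status"]
    return data, base


def _residual_variance_ratio(X: pd.DataFrame, mains: list[str], name: str) -> float:
    A = np.column_stack([np.ones(len(X)), X[mains].to_numpy(float)])
    y = X[name].to_numpy(float)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    denom = np.sum((y - y.mean()) ** 2)
    return float(np.sum(resid**2) / denom) if denom > 0 else 0.0


def significant_interactions(results: list[InteractionResult], p_crit: float = 0.001) -> list[InteractionResult]:
    return [r for r in results if r.skipped is None and r.p <= p_crit]


def reduce_interactions(
    interactions: list[InteractionResult],
    matrix,
    outcome: pd.Series,
    final_fit: ModelFit,
    p_crit: float = 0.001,
) -> tuple[list[InteractionResult], dict[tuple[str, str], tuple[str, str]]]:
    """Greedy reduction of significant interactions to a minimal set.

    Repeatedly add the most significant remaining interaction to the model,
    re-test all others adjusted for the mains plus the chosen products, and
    drop those no longer significant.  Returns the retained set and a map
    recording which retained term absorbed each dropped one.
    """
    remaining = sorted(
        [r for r in interactions if r.skipped is None and r.p <= p_crit], key=lambda r: r.p
    )
    data, base = _probe_frame(matrix, final_fit)
    retained: list[InteractionResult] = []
    absorbed: dict[tuple[str, str], tuple[str, str]] = {}
    while remaining:
        chosen = remaining.pop(0)
        retained.append(chosen)
        kept_pairs = [r.pair for r in retained]
        still: list[InteractionResult] = []
        for r in remaining:
            aug = _with_products(data[base], kept_pairs + [r.pair])
            fit = fit_linear(aug, outcome, list(aug.columns))
            p = float(fit.pvalues[_product_name(*r.pair)])
            if p <= p_crit:
                still.append(r)
            else:
                absorbed[r.pair] = chosen.pair
        remaining = sorted(still, key=lambda r: r.p)
    return retained, absorbed


def quadratic_tests(
    final_fit: ModelFit,
    matrix,
    outcome: pd.Series,
    p_crit: float = 0.001,
) -> pd.DataFrame:
    """One-at-a-time squared terms for each final-model variable.

    Variables with fewer than 3 distinct levels (binary) cannot carry a
    quadratic term and are flagged untestable.
    """
    data, base = _probe_frame(matrix, final_fit)
    mains = [v for v in final_fit.variables if v not in final_fit.forced]
    rows = []
    for v in mains:
        if data[v].nunique(dropna=True) < 3:
            rows.append({"variable": v, "coef_sq": np.nan, "p": np.nan,
                         "testable": False, "nonlinear": False})
            continue
        name = f"{v}^2"
        aug = data[base].copy()
        aug[name] = data[v] ** 2
        fit = fit_linear(aug, outcome, base + [name])
        p = float(fit.pvalues[name])
        rows.append({"variable": v, "coef_sq": float(fit.coef[name]), "p": p,
                     "testable": True, "nonlinear": p <= p_crit})
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class MediationResult:
    """Coefficient attenuation after entering mediators into the final model."""

    mediators: list[str]
    attenuation: pd.DataFrame  # per variable: B_without, B_with, attenuation_pct, sign flip, no-direct-effect flag
    share_total_explained_pct: float
    r2_without: float
    r2_with_mediators: float


def mediation_analysis(
    final_fit: ModelFit,
    matrix,
    outcome: pd.Series,
    mediators: pd.DataFrame,
    alpha: float = 0.05,
) -> MediationResult:
    """Refit the final model with mediators added and quantify attenuation.

    Per-variable attenuation is 100·(1 − B_with/B_without); sign-discordant
    cases are flagged rather than clipped.  The share of the model's total
    explanation that is mediated uses a semi-partial decomposition: the
    exposure-attributable R² after adjustment is R²(full) − R²(mediators
    alone), and the share is its relative drop from the unadjusted R².
    """
    data, base = _probe_frame(matrix, final_fit)
    mains = [v for v in final_fit.variables if v not in final_fit.forced]
    clash = [m for m in mediators.columns if m in mains]
    if clash:
        raise ValueError(f"mediator identical to a model variable: {clash}")
    aug = data[base].join(mediators)
    med_names = list(mediators.columns)
    fit_without = fit_linear(data[base], outcome, base)
    fit_with = fit_linear(aug, outcome, base + med_names)
    fit_med_only = fit_linear(aug, outcome, med_names)

    B0 = fit_without.coef[mains]
    B1 = fit_with.coef[mains]
    ratio = B1 / B0
    att = 100.0 * (1.0 - ratio)
    table = pd.DataFrame(
        {
            "B_without": B0,
            "B_with": B1,
            "attenuation_pct": att,
            "sign_flip": ratio < 0,
            "no_direct_effect": fit_with.pvalues[mains] > alpha,
        }
    )
    exposure_part = max(fit_with.r2 - fit_med_only.r2, 0.0)
    share = 100.0 * (1.0 - exposure_part / fit_without.r2) if fit_without.r2 > 0 else float("nan")
    return MediationResult(
        mediators=med_names,
        attenuation=table,
        share_total_explained_pct=float(share),
        r2_without=fit_without.r2,
        r2_with_mediators=fit_with.r2,
    )


def prevalence_shift(outcome_distribution, delta: float, tail_fraction: float = 0.10) -> float:
    """Prevalence of the impaired tail after shifting the outcome by delta.

    The cutoff is the ``tail_fraction`` quantile of the *population*
    distribution; the returned value is the fraction of the delta-shifted
    distribution that falls below that fixed cutoff.  Accepts either an
    empirical sample (array-like; interpolated ECDF, exact at delta = 0) or a
    frozen scipy distribution (closed form).
    """
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must be in (0, 1)")
    if hasattr(outcome_distribution, "ppf"):  # frozen distribution
        cutoff = outcome_distribution.ppf(tail_fraction)
        return float(outcome_distribution.cdf(cutoff - delta))
    y = np.sort(np.asarray(outcome_distribution, dtype=float))
    y = y[~np.isnan(y)]
    if y.size < 2:
        raise ValueError("need at least two outcome values")
    if abs(delta) > y[-1] - y[0]:
        raise ValueError("delta exceeds the outcome range")
    cutoff = np.quantile(y, tail_fraction)
    probs = np.arange(y.size) / (y.size - 1)  # inverse of np.quantile's linear interpolation
    target = cutoff - delta
    if target <= y[0]:
        return 0.0
    if target >= y[-1]:
        return 1.0
    return float(np.interp(target, y, probs))
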