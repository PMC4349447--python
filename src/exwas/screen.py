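"""Stage-1 univariable screening with a family-wide FDR criterion.

Every exposure is regressed on its own against the outcome (partner-reported
variables co-adjusted for partner status), and the resulting p-values are
subjected to the Benjamini–Hochberg step-up procedure at a stringent
family-wide rate (default q = 0.001).  The criterion is *variable*: it ranges
from the nominal significance level for the largest p-value down to the
Bonferroni critical value q/m for the smallest, and the operative threshold
is the largest observed p-value under the step-up line.  Variables are ranked
by variance explained, and a Q–Q representation of the p-value spectrum is
provided for inspection.  Variables carrying prior evidence from other
studies may be exempted from the family-wide criterion and admitted at a
nominal level instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from exwas.codebook import DegenerateVariableError, ExposomeMatrix

__all__ = [
    "FdrDecision",
    "apply_prior_hypotheses",
    "fdr_threshold",
    "qq_plot_data",
    "univariable_scan",
]

SCAN_COLUMNS = ["name", "domain", "B", "se", "p", "r2", "n", "rank", "passes_fdr", "route"]


def univariable_scan(matrix: ExposomeMatrix, outcome: pd.Series) -> pd.DataFrame:
    """One OLS fit of the outcome on each standardized exposure.

    Fits use the subjects with both the exposure and the outcome observed
    (pairwise complete); partner-reported variables additionally adjust for
    ``partner_status`` so convention-filled values are interpretable.  Returns
    a DataFrame with slope ``B`` (outcome units per exposure SD), its standard
    error, the two-sided p-value from the t reference distribution, variance
    explained ``r2``, and the rank by descending ``r2``.
    """
    y_obs = outcome.notna()
    data = matrix.data.loc[y_obs]
    y = outcome.loc[y_obs].to_numpy(float)
    status = matrix.partner_status.loc[y_obs].to_numpy(float)
    X = data.to_numpy(float)
    n_rows, m = X.shape

    obs = ~np.isnan(X)
    if (obs.sum(axis=0) < 3).any():
        bad = list(data.columns[obs.sum(axis=0) < 3])
        raise DegenerateVariableError(f"variables with <3 observed outcome-sample values: {bad[:5]}")

    Xf = np.where(obs, X, 0.0)
    nj = obs.sum(axis=0).astype(float)
    sx = Xf.sum(axis=0)
    sxx = np.einsum("ij,ij->j", Xf, Xf)
    sy = obs.T @ y
    syy = obs.T @ (y * y)
    sxy = Xf.T @ y
    cxx = sxx - sx * sx / nj
    cyy = syy - sy * sy / nj
    cxy = sxy - sx * sy / nj
    if (cxx <= 0).any():
        bad = list(data.columns[cxx <= 0])
        raise DegenerateVariableError(f"degenerate columns in scan (run drop_degenerate): {bad[:5]}")

    slope = cxy / cxx
    rss = np.maximum(cyy - slope * cxy, 0.0)
    df = nj - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 / cxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2 * stats.t.sf(np.abs(tval), df)
    r2 = np.where(cyy > 0, cxy * cxy / (cxx * cyy), 0.0)

    # partner variables: re-fit with partner_status as a co-adjustment
    partner = set(matrix.codebook.partner_variables)
    if partner and np.ptp(status) > 0:
        cols = list(data.columns)
        for j, name in enumerate(cols):
            if name not in partner:
                continue
            rows = obs[:, j]
            Xj = np.column_stack([np.ones(rows.sum()), X[rows, j], status[rows]])
            yj = y[rows]
            coef, res, rank, _ = np.linalg.lstsq(Xj, yj, rcond=None)
            fit_rss = float(res[0]) if res.size else float(np.sum((yj - Xj @ coef) ** 2))
            dfj = rows.sum() - rank
            sig2 = fit_rss / dfj
            cov = sig2 * np.linalg.pinv(Xj.T @ Xj)
            slope[j] = coef[1]
            se[j] = np.sqrt(cov[1, 1])
            tj = coef[1] / se[j]
            p[j] = 2 * stats.t.sf(abs(tj), dfj)
            # variance explained attributed to the exposure: squared partial r
            tyy = float(np.sum((yj - yj.mean()) ** 2))
            r2[j] = (tj * tj / (tj * tj + dfj)) if tyy > 0 else 0.0

    order = np.lexsort((np.arange(m), -r2))
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    table = matrix.codebook.table
    return pd.DataFrame(
        {
            "name": data.columns,
            "domain": table["domain"].to_numpy(),
            "B": slope,
            "se": se,
            "p": p,
            "r2": r2,
            "n": nj.astype(int),
            "rank": rank,
            "passes_fdr": False,
            "route": "none",
        }
    ).set_index("name", drop=False)


@dataclass
class FdrDecision:
    """Outcome of the Benjamini–Hochberg step-up at family-wide rate q.

    ``threshold`` is p(i*), the largest observed p-value satisfying the
    step-up inequality p(i) <= i*q/m (0 if none does); every p <= threshold
    passes.  ``bonferroni_floor`` = q/m is the lower end of the variable
    criterion; the nominal level q is its upper end.
    """

    m: int
    q: float
    threshold: float
    passes: np.ndarray
    n_discoveries: int

    @property
    def bonferroni_floor(self) -> float:
        return self.q / self.m


def fdr_threshold(pvalues: np.ndarray | pd.Series, q: float = 0.001) -> FdrDecision:
    """Benjamini–Hochberg step-up over ``pvalues`` at family-wide rate ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    ps = np.sort(p)
    crit = q * np.arange(1, m + 1) / m
    under = np.nonzero(ps <= crit)[0]
    threshold = float(ps[under[-1]]) if under.size else 0.0
    passes = p <= threshold if under.size else np.zeros(m, dtype=bool)
    return FdrDecision(m=m, q=q, threshold=threshold, passes=passes, n_discoveries=int(passes.sum()))


def mark_fdr(results: pd.DataFrame, q: float = 0.001) -> tuple[pd.DataFrame, FdrDecision]:
    """Apply :func:`fdr_threshold` to a scan table, filling the pass flags."""
    decision = fdr_threshold(results["p"].to_numpy(), q)
    out = results.copy()
    out["passes_fdr"] = decision.passes
    out["route"] = np.where(decision.passes, "fdr", "none")
    return out, decision


def qq_plot_data(pvalues: np.ndarray | pd.Series) -> pd.DataFrame:
    """Expected vs observed -log10 p for a Q–Q plot of the scan.

    Expected quantiles are i/(m+1); zero p-values are floored at the smallest
    positive normal float so the plot stays finite.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    m = p.size
    tiny = np.finfo(float).tiny
    # i-th smallest p paired with quantile i/(m+1); both columns descend
    observed = -np.log10(np.maximum(np.sort(p), tiny))
    expected = -np.log10(np.arange(1, m + 1) / (m + 1))
    return pd.DataFrame({"expected": expected, "observed": observed})


def plot_qq(qq: pd.DataFrame, decision: FdrDecision | None, path) -> None:
    """Render the Q–Q plot with the variable FDR criterion line overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(qq["expected"], qq["observed"], ".", ms=3, label="observed")
    lim = float(qq["expected"].max())
    ax.plot([0, lim], [0, lim], "-", color="grey", lw=1, label="null")
    if decision is not None:
        m = decision.m
        ranks = np.arange(1, m + 1)
        crit = -np.log10(decision.q * ranks[::-1] / m)
        ax.plot(-np.log10(ranks / (m + 1)), crit, "--", color="firebrick", lw=1, label="FDR criterion")
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def apply_prior_hypotheses(
    results: pd.DataFrame,
    prior_list: list[str],
    nominal_alpha: float = 0.05,
) -> pd.DataFrame:
    """Admit prior-hypothesis variables at a nominal level.

    Variables in ``prior_list`` pass stage 1 whenever their univariable p is
    at most ``nominal_alpha``, regardless of the family-wide criterion; the
    ``route`` column records the exemption ("prior") so reports can show how
    each variable entered.  All other flags are unchanged.
    """
    unknown = [v for v in prior_list if v not in results.index]
    if unknown:
        raise KeyError(f"unknown prior-hypothesis variables: {unknown}")
    out = results.copy()
    for name in prior_list:
        if not out.at[name, "passes_fdr"] and out.at[name, "p"] <= nominal_alpha:
            out.at[name, "passes_fdr"] = True
            out.at[name, "route"] = "prior"
    return out
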