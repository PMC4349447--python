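"""Validation studies: oracle checks and operating-characteristic simulations.

Because the original cohort data are access-restricted, the pipeline is
validated on its *operating characteristics* rather than by reproducing the
substantive findings: exact agreement of the FDR procedure and the subset
search with brute-force oracles, family-wise behaviour under the global
null, recovery of planted effects by the three-stage selection, calibration
of the mediation and interaction probes, invariance to the arbitrary
partner fill value, and the coverage of Rubin-pooled intervals.  Every
function here regenerates its own data from a seed and returns plain
numbers, so the same code backs the acceptance test-suite and the
acceptance script.

The brute-force oracles (`bh_stepup_oracle`, `brute_force_best_subset`) are
deliberately naive, loop-based implementations kept independent of the
production code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from exwas import explore, impute, screen, select, synth
from exwas.codebook import drop_degenerate, encode_partner_variables, standardize

__all__ = [
    "bh_stepup_oracle",
    "brute_force_best_subset",
    "fdr_oracle_agreement",
    "imputation_coverage",
    "interaction_calibration",
    "mediation_calibration",
    "method_dominance",
    "null_screen_family_rate",
    "partner_invariance",
    "prevalence_closed_form",
    "recovery_study",
    "run_three_stage",
    "subset_oracle_agreement",
]


# ---------------------------------------------------------------------------
# oracles (independent, naive implementations)


def bh_stepup_oracle(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Step-up FDR pass set by explicit enumeration over every index."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    srt = sorted(p)
    i_star = 0
    for i in range(1, m + 1):  # check every index, keep the largest satisfying one
        if srt[i - 1] <= i * q / m:
            i_star = i
    if i_star == 0:
        return np.zeros(m, dtype=bool)
    thr = srt[i_star - 1]
    return p <= thr


def brute_force_best_subset(
    X: np.ndarray, y: np.ndarray, p_crit: float
) -> tuple[tuple[int, ...], float]:
    """Exhaustive admissible best subset via per-subset lstsq fits.

    Enumerates every non-empty subset, fits OLS with an explicit intercept
    column, computes each member's t-based p-value, and returns the subset
    with maximal R² among those whose members all satisfy ``p <= p_crit``
    (empty tuple if none).  Exponential in the number of columns.
    """
    n, m = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    best: tuple[tuple[int, ...], float] = ((), -np.inf)
    for k in range(1, m + 1):
        for subset in combinations(range(m), k):
            A = np.column_stack([np.ones(n), X[:, subset]])
            coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            rss = float(resid @ resid)
            df = n - k - 1
            cov = np.linalg.inv(A.T @ A) * (rss / df)
            tvals = coef[1:] / np.sqrt(np.diag(cov)[1:])
            pvals = 2 * stats.t.sf(np.abs(tvals), df)
            if np.all(pvals <= p_crit):
                r2 = 1 - rss / tss
                if r2 > best[1]:
                    best = (subset, r2)
    return best


# ---------------------------------------------------------------------------
# FDR procedure


def fdr_oracle_agreement(n_vectors: int = 1000, max_len: int = 5000, seed: int = 0) -> float:
    """% of random p-vectors on which fdr_threshold matches the step-up oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        # mixture: mostly uniform nulls, sometimes a slab of small p-values
        p = rng.random(m)
        if rng.random() < 0.5 and m > 4:
            k = int(rng.integers(1, max(m // 10, 2)))
            p[:k] = rng.random(k) * 10.0 ** -rng.integers(2, 8)
        q = float(rng.choice([0.001, 0.01, 0.05, 0.1]))
        decision = screen.fdr_threshold(p, q)
        if np.array_equal(decision.passes, bh_stepup_oracle(p, q)):
            agree += 1
    return 100.0 * agree / n_vectors


def _null_spec(n: int, m: int, seed: int) -> synth.SyntheticSpec:
    return synth.SyntheticSpec(
        n_subjects=n,
        n_variables=m,
        within_domain_corr=0.3,
        cross_domain_corr=0.1,
        type_mix=(0.0, 0.0, 1.0),
        missing_rate=0.0,
        partner_var_fraction=0.0,
        partnerless_rate=0.0,
        seed=seed,
    )


def null_screen_family_rate(
    n_reps: int = 2000, m: int = 1000, n: int = 2000, q: float = 0.001, seed: int = 0
) -> float:
    """Proportion of global-null replicates with >= 1 stage-1 discovery."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        ds = synth.generate_exposome(_null_spec(n, m, int(rng.integers(2**31 - 1))))
        std, _ = standardize(ds.matrix)
        results = screen.univariable_scan(std, ds.outcome)
        decision = screen.fdr_threshold(results["p"].to_numpy(), q)
        hits += decision.n_discoveries > 0
    return hits / n_reps


# ---------------------------------------------------------------------------
# best-subset search


def subset_oracle_agreement(n_instances: int = 100, seed: int = 0) -> float:
    """% of random instances where the subset search equals the brute force."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = 60
        m = int(rng.integers(6, 13))
        # correlated design with a sparse signal
        base = rng.standard_normal((n, 1))
        X = 0.5 * base + rng.standard_normal((n, m))
        k_true = int(rng.integers(0, 4))
        beta = np.zeros(m)
        if k_true:
            beta[rng.choice(m, k_true, replace=False)] = rng.normal(0, 1.0, k_true)
        y = X @ beta + rng.standard_normal(n)
        p_crit = float(rng.choice([0.01, 0.05, 0.1]))
        names = [f"x{j}" for j in range(m)]
        fit = select.best_subset_search(pd.DataFrame(X, columns=names), pd.Series(y), names, p_crit=p_crit)
        ours = tuple(sorted(names.index(v) for v in fit.variables))
        oracle, _ = brute_force_best_subset(X, y, p_crit)
        agree += ours == tuple(sorted(oracle))
    return 100.0 * agree / n_instances


# ---------------------------------------------------------------------------
# three-stage pipeline and recovery


def run_three_stage(
    ds: synth.SyntheticExposome,
    q: float = 0.001,
    domain_method: str = "backwards",
    final_method: str = "subset",
    M: int = 1,
    n_iter: int = 10,
    seed: int = 0,
):
    """Screen → impute → domain models → final model on one dataset.

    Returns (final ModelFit, screen results, FdrDecision, domain fits).
    Selection runs on the first completed dataset, mirroring the design of
    the reporting pipeline.
    """
    matrix, outcome = ds.matrix, ds.outcome
    matrix, _ = drop_degenerate(matrix, outcome)
    std, scale = standardize(matrix)
    std = encode_partner_variables(std, fill_value=0.0)
    results = screen.univariable_scan(std, outcome)
    results, decision = screen.mark_fdr(results, q)
    survivors = list(results.index[results["passes_fdr"]])
    if not survivors:
        return None, results, decision, {}
    p_crit = max(decision.threshold, decision.bonferroni_floor)
    sub = std.restrict(survivors)
    if sub.data.isna().any().any():
        imps = impute.mice_impute(sub, outcome, M=M, n_iter=n_iter, seed=seed)
        completed = sub.copy()
        completed.data = imps.datasets[0]
    else:
        completed = sub
    fits, _ = select.domain_models(completed, outcome, results, method=domain_method, p_crit=p_crit)
    final, _, _ = select.final_model(completed, outcome, fits, results.loc[survivors],
                                     method=final_method, p_crit=p_crit)
    return final, results, decision, fits


def recovery_study(n_seeds: int = 50, seed: int = 0, n_planted: int = 20) -> dict:
    """Sensitivity / false-discovery proportion of the three-stage pipeline.

    Generates the default synthetic cohort (600 variables, 10 domains, block
    correlation 0.3/0.1, 20 planted effects of 0.4–0.8 points per SD,
    n = 7600, 16% MAR missingness) once per seed and scores the final model
    against the planted truth.
    """
    rng = np.random.default_rng(seed)
    sens, fdp, r2s, sizes = [], [], [], []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        ds = synth.generate_exposome(synth.default_spec(seed=s, n_planted=n_planted))
        final, *_ = run_three_stage(ds, seed=s)
        planted = set(ds.truth.planted_effects)
        if final is None or not final.variables:
            sens.append(0.0)
            fdp.append(0.0)
            sizes.append(0)
            r2s.append(0.0)
            continue
        chosen = set(v for v in final.variables if v not in final.forced)
        sens.append(len(chosen & planted) / len(planted))
        fdp.append(len(chosen - planted) / max(len(chosen), 1))
        sizes.append(len(chosen))
        r2s.append(final.r2)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "mean_model_size": float(np.mean(sizes)),
        "mean_r2_pct": 100.0 * float(np.mean(r2s)),
        "n_seeds": n_seeds,
    }


def method_dominance(n_seeds: int = 20, seed: int = 0) -> dict:
    """How often the subset final model's R² >= forwards and backwards R²."""
    rng = np.random.default_rng(seed)
    holds = 0
    margins = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        spec = synth.default_spec(
            seed=s, n_planted=8, n_subjects=1500, n_variables=100, missing_rate=0.0
        )
        ds = synth.generate_exposome(spec)
        r2 = {}
        for method in ("subset", "forwards", "backwards"):
            final, *_ = run_three_stage(ds, final_method=method, seed=s)
            r2[method] = 0.0 if final is None else final.r2
        ok = r2["subset"] >= r2["forwards"] - 1e-12 and r2["subset"] >= r2["backwards"] - 1e-12
        holds += ok
        margins.append(r2["subset"] - max(r2["forwards"], r2["backwards"]))
    return {"dominance_rate": holds / n_seeds, "mean_margin": float(np.mean(margins))}


# ---------------------------------------------------------------------------
# mediation calibration


def _mediation_spec(direct: float, loading: float, effect: float, n: int, seed: int) -> synth.SyntheticSpec:
    return synth.SyntheticSpec(
        n_subjects=n,
        n_variables=10,
        n_domains=10,
        within_domain_corr=0.3,
        cross_domain_corr=0.1,
        type_mix=(0.0, 0.0, 1.0),
        planted_effects=((5, direct),),
        mediator_spec=synth.MediatorSpec(loading=loading, effect=effect),
        missing_rate=0.0,
        partner_var_fraction=0.0,
        partnerless_rate=0.0,
        outcome_skew=0.0,
        seed=seed,
    )


def mediation_calibration(n_seeds: int = 50, n: int = 10000, seed: int = 0) -> dict:
    """Mean attenuation under planted full and half mediation structures.

    Full mediation: no direct effect, X→M→Y only (expected attenuation
    100%).  Half mediation: direct effect equal to the indirect path
    loading·effect (expected 50%).
    """
    rng = np.random.default_rng(seed)
    loading, effect = 0.7, 4.0
    indirect = loading * effect
    full, half = [], []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        for direct, sink in ((0.0, full), (indirect, half)):
            ds = synth.generate_exposome(_mediation_spec(direct, loading, effect, n, s))
            name = list(ds.truth.planted_effects)[0]
            fit = select.fit_linear(ds.matrix.data, ds.outcome, [name])
            med = explore.mediation_analysis(
                fit, ds.matrix.data, ds.outcome, ds.mediator.to_frame("mediator")
            )
            sink.append(float(med.attenuation.loc[name, "attenuation_pct"]))
    return {"full_attenuation_pct": float(np.mean(full)), "half_attenuation_pct": float(np.mean(half))}


# ---------------------------------------------------------------------------
# partner-fill invariance


def partner_invariance(seed: int = 0, fills: tuple[float, float] = (0.0, 5.0)) -> float:
    """Max |difference| of non-status coefficients and fitted values across fills.

    Exercises the algebraic identity that the arbitrary partner fill value is
    absorbed by the partner-status indicator.
    """
    spec = synth.SyntheticSpec(
        n_subjects=500,
        n_variables=40,
        n_domains=4,
        missing_rate=0.0,
        partner_var_fraction=0.3,
        partnerless_rate=0.1,
        seed=seed,
    )
    ds = synth.generate_exposome(spec)
    matrix, _ = drop_degenerate(ds.matrix, ds.outcome)
    std, _ = standardize(matrix)
    partner_vars = std.codebook.partner_variables[:3]
    mother_vars = [v for v in std.codebook.names if v not in std.codebook.partner_variables][:3]
    model_vars = mother_vars + partner_vars
    import warnings

    coefs, fitted = [], []
    for fill in fills:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # fill outside range is the point
            enc = encode_partner_variables(std, fill_value=fill)
        fit = select.fit_linear(enc, ds.outcome, model_vars)
        coefs.append(fit.coef[model_vars].to_numpy())
        frame = enc.data[model_vars].copy()
        frame["partner_status"] = enc.partner_status.astype(float)
        fitted.append(fit.predict(frame).to_numpy())
    dc = float(np.max(np.abs(coefs[0] - coefs[1])))
    dfv = float(np.max(np.abs(fitted[0] - fitted[1])))
    return max(dc, dfv)


# ---------------------------------------------------------------------------
# imputation coverage


def imputation_coverage(n_reps: int = 200, n: int = 800, M: int = 5, seed: int = 0) -> dict:
    """Coverage of Rubin-pooled 95% CIs for planted coefficients (MCAR 20%)."""
    betas = ((0, 0.6), (1, -0.5), (2, 0.5), (3, 0.4), (4, -0.4), (5, 0.3))
    rng = np.random.default_rng(seed)
    covered, total = 0, 0
    for _ in range(n_reps):
        s = int(rng.integers(2**31 - 1))
        spec = synth.SyntheticSpec(
            n_subjects=n,
            n_variables=6,
            n_domains=3,
            within_domain_corr=0.3,
            cross_domain_corr=0.1,
            type_mix=(0.0, 0.0, 1.0),
            planted_effects=betas,
            outcome_noise_sd=7.5,
            outcome_skew=0.0,
            missing_rate=0.20,
            missing_mechanism="MCAR",
            partner_var_fraction=0.0,
            partnerless_rate=0.0,
            seed=s,
        )
        ds = synth.generate_exposome(spec)
        imps = impute.mice_impute(ds.matrix, ds.outcome, M=M, n_iter=5, seed=s)
        names = ds.matrix.codebook.names
        fits = [select.fit_linear(df, ds.outcome, names) for df in imps.datasets]
        pooled = impute.pool_rubin(fits)
        for name, beta in zip(names, [b for _, b in betas]):
            total += 1
            covered += pooled.ci_low[name] <= beta <= pooled.ci_high[name]
    return {"coverage_pct": 100.0 * covered / total, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# interaction scan calibration


def interaction_calibration(
    n_null_reps: int = 2000,
    n_power_reps: int = 50,
    p_crit: float = 0.001,
    seed: int = 0,
) -> dict:
    """Size and power of the interaction scan.

    Size: additive generating model (5 planted mains, no interaction) at
    n = 1500; rejection rate over all pairs should sit near the nominal
    level.  Power: one planted interaction of 0.3 outcome SD (0.3 × noise
    SD in outcome points) at n = 7600.
    """
    rng = np.random.default_rng(seed)
    mains = tuple((j, b) for j, b in zip(range(5), (0.6, -0.5, 0.5, -0.4, 0.4)))

    def _spec(n, s, inter=()):
        return synth.SyntheticSpec(
            n_subjects=n,
            n_variables=5,
            n_domains=1,
            within_domain_corr=0.3,
            cross_domain_corr=0.1,
            type_mix=(0.0, 0.0, 1.0),
            planted_effects=mains,
            planted_interactions=inter,
            missing_rate=0.0,
            partner_var_fraction=0.0,
            partnerless_rate=0.0,
            outcome_skew=0.0,
            seed=s,
        )

    rejections, tests = 0, 0
    for _ in range(n_null_reps):
        ds = synth.generate_exposome(_spec(1500, int(rng.integers(2**31 - 1))))
        names = ds.matrix.codebook.names
        fit = select.fit_linear(ds.matrix.data, ds.outcome, names)
        res = explore.interaction_scan(fit, ds.matrix.data, ds.outcome, p_crit=p_crit)
        rejections += sum(r.p <= p_crit for r in res if r.skipped is None)
        tests += sum(r.skipped is None for r in res)
    size = rejections / tests

    beta_int = 0.3 * 7.5  # 0.3 outcome SD in outcome points
    detected = 0
    for _ in range(n_power_reps):
        ds = synth.generate_exposome(
            _spec(7600, int(rng.integers(2**31 - 1)), inter=(((0, 1), beta_int),))
        )
        names = ds.matrix.codebook.names
        fit = select.fit_linear(ds.matrix.data, ds.outcome, names)
        res = explore.interaction_scan(fit, ds.matrix.data, ds.outcome, p_crit=p_crit)
        hit = any(r.skipped is None and set(r.pair) == {names[0], names[1]} and r.p <= p_crit for r in res)
        detected += hit
    return {
        "null_rejection_rate": size,
        "nominal": p_crit,
        "power_pct": 100.0 * detected / n_power_reps,
    }


# ---------------------------------------------------------------------------
# prevalence shift


def prevalence_closed_form(delta_sd: float = 0.5, tail: float = 0.10) -> dict:
    """Prevalence shift on a standard normal outcome vs the Φ closed form."""
    dist = stats.norm(0, 1)
    up = explore.prevalence_shift(dist, +delta_sd, tail)
    down = explore.prevalence_shift(dist, -delta_sd, tail)
    oracle_up = float(stats.norm.cdf(stats.norm.ppf(tail) - delta_sd))
    oracle_down = float(stats.norm.cdf(stats.norm.ppf(tail) + delta_sd))
    return {
        "shift_up_pct": 100.0 * up,
        "shift_down_pct": 100.0 * down,
        "oracle_up_pct": 100.0 * oracle_up,
        "oracle_down_pct": 100.0 * oracle_down,
    }
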