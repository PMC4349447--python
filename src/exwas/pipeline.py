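"""Pipeline orchestration: one reproducible run from raw matrix to report.

``run_pipeline`` executes the full sequence — degenerate-variable removal,
standardization, partner encoding, univariable FDR screen, chained-equation
imputation of the survivors, domain-specific models, the combined final
model with Rubin-pooled coefficients, the interaction/quadratic/mediation
probes, and the sensitivity analyses — writing every table as TSV plus a
JSON manifest of seeds and configuration into a run directory.
``make_report`` assembles a human-readable summary strictly from those
artifacts (no recomputation), so regenerating the report from an archived
run directory is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from exwas import explore, impute, screen, select, sense
from exwas.codebook import ExposomeMatrix, drop_degenerate, encode_partner_variables, standardize

__all__ = ["RunConfig", "make_report", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run."""

    q: float = 0.001
    prior_hypotheses: list[str] = field(default_factory=list)
    prior_alpha: float = 0.05
    partner_fill: float = 0.0
    M: int = 5
    n_iter: int = 10
    domain_method: str = "backwards"
    final_method: str = "subset"
    p_crit: float | None = None  # None -> the stage-1 FDR threshold
    interaction_p: float = 0.001
    quadratic_p: float = 0.001
    run_interactions: bool = True
    run_quadratics: bool = True
    run_sense: bool = True
    compare_methods: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(
    matrix: ExposomeMatrix,
    outcome: pd.Series,
    config: RunConfig,
    out_dir: str | Path,
    mediators: pd.DataFrame | None = None,
) -> Path:
    """Run every stage on ``matrix``/``outcome`` and write artifacts.

    Returns the run directory.  Any stage failure aborts with the stage name;
    artifacts written before the failure remain, listed in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_digest": config.digest(), "seed": config.seed, "stages": []}
    config.to_yaml(out / "config.yaml")

    def _stage(name: str):
        manifest["stages"].append(name)

    try:
        _stage("drop_degenerate")
        matrix, dropped = drop_degenerate(matrix, outcome)
        pd.Series(dropped, name="dropped", dtype=object).to_csv(out / "dropped_variables.tsv", sep="\t", index=False)

        _stage("standardize")
        std, scale = standardize(matrix)
        scale.rename("sd").to_csv(out / "scale_record.tsv", sep="\t", float_format=_FLOAT_FMT)

        _stage("encode_partner")
        std = encode_partner_variables(std, fill_value=config.partner_fill)

        _stage("screen")
        results = screen.univariable_scan(std, outcome)
        results, decision = screen.mark_fdr(results, config.q)
        if config.prior_hypotheses:
            results = screen.apply_prior_hypotheses(results, config.prior_hypotheses, config.prior_alpha)
        _write(results.drop(columns=["name"]), out / "screen.tsv")
        qq = screen.qq_plot_data(results["p"].to_numpy())
        _write(qq, out / "qq.tsv", index=False)
        (out / "fdr.json").write_text(
            json.dumps(
                {
                    "m": decision.m,
                    "q": decision.q,
                    "threshold": decision.threshold,
                    "bonferroni_floor": decision.bonferroni_floor,
                    "n_discoveries": decision.n_discoveries,
                    "n_stage1": int(results["passes_fdr"].sum()),
                },
                indent=1,
            )
        )
        survivors = list(results.index[results["passes_fdr"]])
        p_crit = config.p_crit or max(decision.threshold, decision.bonferroni_floor)

        if not survivors:
            manifest["final_model"] = []
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            return out

        _stage("impute")
        sub = std.restrict(survivors)
        if sub.data.isna().any().any():
            imps = impute.mice_impute(sub, outcome, M=config.M, n_iter=config.n_iter, seed=config.seed)
            imps.to_dir(out / "imputations")
            completed_sets = []
            for df in imps.datasets:
                c = sub.copy()
                c.data = df
                completed_sets.append(c)
        else:
            completed_sets = [sub]
        completed = completed_sets[0]

        _stage("domain_models")
        fits, table1 = select.domain_models(
            completed, outcome, results, method=config.domain_method, p_crit=p_crit
        )
        _write(table1, out / "table1_domains.tsv")
        rows = []
        for domain, fit in fits.items():
            for v in fit.variables:
                if v in fit.forced:
                    continue
                rows.append(
                    {
                        "domain": domain,
                        "variable": v,
                        "B_unadjusted": results.at[v, "B"],
                        "B_adjusted": fit.coef[v],
                        "ci_low": fit.ci_low[v],
                        "ci_high": fit.ci_high[v],
                        "p": fit.pvalues[v],
                        "partial_corr": fit.partial_corr[v],
                    }
                )
        table2 = pd.DataFrame(rows)
        _write(table2, out / "table2_domain_effects.tsv", index=False)
        if len(table2):
            att, att_summary = select.attenuation_summary(
                results, pd.Series(table2["B_adjusted"].to_numpy(), index=table2["variable"])
            )
            _write(att, out / "attenuation.tsv")
            (out / "attenuation_summary.json").write_text(json.dumps(att_summary, indent=1))

        _stage("final_model")
        final, trace, tiers = select.final_model(
            completed, outcome, fits, results.loc[survivors], method=config.final_method, p_crit=p_crit
        )
        _write(trace.to_frame(), out / "final_trace.tsv", index=False)
        if tiers is not None:
            _write(tiers, out / "final_rank_tiers.tsv")
        manifest["final_model"] = [v for v in final.variables if v not in final.forced]

        _stage("pool")
        member_vars = list(final.variables)
        if member_vars:
            per_imp = [select.fit_linear(c, outcome, member_vars) for c in completed_sets]
            pooled = impute.pool_rubin(per_imp)
            table3 = final.summary_frame()
            table3["B_pooled"] = pooled.coef
            table3["se_pooled"] = pooled.se
            table3["p_pooled"] = pooled.pvalues
            table3["r2_pct"] = 100.0 * final.r2
            _write(table3, out / "table3_final_model.tsv")
        else:
            _write(pd.DataFrame(), out / "table3_final_model.tsv")

        if config.run_interactions and final.k >= 2:
            _stage("interactions")
            inter = explore.interaction_scan(final, completed, outcome, p_crit=config.interaction_p)
            idf = pd.DataFrame(
                [
                    {
                        "var_a": r.pair[0],
                        "var_b": r.pair[1],
                        "coef": r.coef,
                        "p": r.p,
                        "significant": r.skipped is None and r.p <= config.interaction_p,
                        "skipped": r.skipped or "",
                    }
                    for r in inter
                ]
            )
            _write(idf, out / "interactions.tsv", index=False)
            sig = explore.significant_interactions(inter, config.interaction_p)
            if sig:
                kept, absorbed = explore.reduce_interactions(sig, completed, outcome, final, config.interaction_p)
                _write(
                    pd.DataFrame(
                        [{"var_a": r.pair[0], "var_b": r.pair[1], "p": r.p} for r in kept]
                    ),
                    out / "interactions_reduced.tsv",
                    index=False,
                )

        if config.run_quadratics and final.k >= 1:
            _stage("quadratics")
            quad = explore.quadratic_tests(final, completed, outcome, p_crit=config.quadratic_p)
            _write(quad, out / "quadratics.tsv")

        if mediators is not None and final.k >= 1:
            _stage("mediation")
            med = explore.mediation_analysis(final, completed, outcome, mediators)
            _write(med.attenuation, out / "mediation.tsv")
            (out / "mediation_summary.json").write_text(
                json.dumps(
                    {
                        "mediators": med.mediators,
                        "share_total_explained_pct": med.share_total_explained_pct,
                        "r2_without": med.r2_without,
                        "r2_with_mediators": med.r2_with_mediators,
                    },
                    indent=1,
                )
            )

        if config.run_sense and final.k >= 1:
            _stage("sense_ordinal")
            try:
                ordf = sense.ordinal_refit(final, completed, outcome)
                t3 = ordf.summary_frame()
                t3["pseudo_r2_pct"] = 100.0 * ordf.pseudo_r2
                _write(t3, out / "sense_ordinal.tsv")
            except RuntimeError:
                (out / "sense_ordinal.tsv").write_text("non-convergent\n")
            _stage("sense_factors")
            fmodel, ffit, mapped = sense.factor_sensitivity(completed, outcome, p_crit=p_crit)
            _write(fmodel.loadings, out / "factor_loadings.tsv")
            _write(mapped, out / "factor_model.tsv", index=False)
            _stage("sense_tree")
            tree = sense.chaid_tree(completed.restrict(manifest["final_model"]), outcome)
            (out / "tree.txt").write_text(tree.render() + "\n")
            edges = tree.edge_list()
            _write(edges, out / "tree_edges.tsv", index=False)

        if config.compare_methods and survivors:
            _stage("consistency")
            alt = {}
            for method in ("forwards", "backwards", "subset"):
                f, _, _ = select.final_model(
                    completed, outcome, fits, results.loc[survivors], method=method, p_crit=p_crit
                )
                alt[method] = f
            overlap, stability = sense.consistency_report(alt)
            _write(overlap, out / "consistency_overlap.tsv")
            _write(stability, out / "consistency_stability.tsv")

    except Exception as err:  # abort with stage context, keep partial manifest
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed in stage {manifest['failed_stage']}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# reporting


def _read_tsv(path: Path, **kw) -> pd.DataFrame | None:
    return pd.read_csv(path, sep="\t", **kw) if path.exists() else None


def make_report(run_dir: str | Path) -> str:
    """Assemble ``report.md`` from a run directory's artifacts.

    Every number in the report is read from a TSV/JSON artifact; nothing is
    recomputed, so the report is a deterministic function of the directory.
    Missing artifacts are listed and the report still produced.
    """
    run = Path(run_dir)
    missing: list[str] = []
    parts: list[str] = ["# Exposome scan report", ""]

    fdr = json.loads((run / "fdr.json").read_text()) if (run / "fdr.json").exists() else None
    if fdr:
        parts += [
            "## Stage 1: univariable screen",
            "",
            f"- variables tested: {fdr['m']}",
            f"- family-wide FDR rate q: {fdr['q']}",
            f"- FDR criterion (p threshold): {fdr['threshold']:.6g} "
            f"(Bonferroni floor {fdr['bonferroni_floor']:.3g})",
            f"- stage-1 survivors: {fdr['n_stage1']}",
            "",
        ]
    else:
        missing.append("fdr.json")

    screen_df = _read_tsv(run / "screen.tsv", index_col=0)
    if screen_df is not None and "route" in screen_df.columns:
        n_prior = int((screen_df["route"] == "prior").sum())
        if n_prior:
            parts += [f"- admitted via prior-hypothesis route: {n_prior}", ""]
    t1 = _read_tsv(run / "table1_domains.tsv", index_col=0)
    if t1 is not None:
        parts += ["## Stage 2: domain-specific models", "", t1.to_string(float_format=lambda v: f"{v:.2f}"), ""]
    else:
        missing.append("table1_domains.tsv")
    att = run / "attenuation_summary.json"
    if att.exists():
        s = json.loads(att.read_text())
        parts += [
            f"Average attenuation of effect sizes due to within-domain adjustment: "
            f"{s['mean_attenuation_pct']:.0f}% (range {s['min_attenuation_pct']:.0f}% to "
            f"{s['max_attenuation_pct']:.0f}%); sign flips: {len(s['sign_flips'])}.",
            "",
        ]
    t3 = _read_tsv(run / "table3_final_model.tsv", index_col=0)
    parts += ["## Stage 3: final model", ""]
    if t3 is None or t3.empty:
        parts += ["No variable met the criterion: intercept-only final model.", ""]
        if t3 is None:
            missing.append("table3_final_model.tsv")
    else:
        parts += [
            f"{len(t3)} variables (ranked by partial correlation), R² = {t3['r2_pct'].iloc[0]:.2f}%:",
            "",
            t3.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
        ]
    tiers = _read_tsv(run / "final_rank_tiers.tsv", index_col=0)
    if tiers is not None:
        parts += ["Contribution by unadjusted-rank tier:", "", tiers.to_string(float_format=lambda v: f"{v:.2f}"), ""]
    inter = _read_tsv(run / "interactions.tsv")
    if inter is not None:
        nsig = int(inter["significant"].sum())
        parts += [
            "## Probes",
            "",
            f"- interaction pairs tested: {len(inter)}; significant: {nsig}",
        ]
        red = _read_tsv(run / "interactions_reduced.tsv")
        if red is not None:
            parts += [f"- minimal explanatory interaction set: {len(red)}"]
        quad = _read_tsv(run / "quadratics.tsv", index_col=0)
        if quad is not None:
            testable = quad["testable"].sum()
            nl = quad["nonlinear"].sum()
            parts += [f"- quadratic terms testable for {int(testable)} variables; non-linear: {int(nl)}"]
        med = run / "mediation_summary.json"
        if med.exists():
            sm = json.loads(med.read_text())
            parts += [
                f"- mediation by {', '.join(sm['mediators'])}: "
                f"{sm['share_total_explained_pct']:.0f}% of the total explanation mediated"
            ]
        parts += [""]
    ordf = _read_tsv(run / "sense_ordinal.tsv", index_col=0)
    parts += ["## Sensitivity analyses", ""]
    if ordf is not None and "OR" in getattr(ordf, "columns", []):
        parts += [
            f"- proportional-odds refit: pseudo-R² {ordf['pseudo_r2_pct'].iloc[0]:.2f}%",
        ]
    fm = _read_tsv(run / "factor_model.tsv")
    if fm is not None:
        parts += [f"- factor-space selection retained {len(fm)} factors"]
    overlap = _read_tsv(run / "consistency_overlap.tsv", index_col=0)
    if overlap is not None:
        parts += ["- method consistency (Jaccard overlap):", "", overlap.to_string(float_format=lambda v: f"{v:.2f}")]
    parts += [""]
    if missing:
        parts += ["## Missing artifacts", ""] + [f"- {m}" for m in missing] + [""]
    text = "\n".join(parts)
    (run / "report.md").write_text(text)
    return text
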