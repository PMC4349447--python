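#!/usr/bin/env python
"""Stage 1: univariable exposome-wide screen with the FDR criterion.

Regenerates the cohort from its truth record, standardizes every exposure to
unit variance, fits one regression of the outcome per exposure (partner
variables co-adjusted for partner status), applies the family-wide FDR
criterion at q = 0.1%, and reports how many variables — and how many of the
planted effects — survive stage 1.  Writes the scan table and Q–Q data to
results/ and a Q–Q plot to scratch/.
"""

import json
from pathlib import Path

from exwas import screen, synth
from exwas.codebook import drop_degenerate, encode_partner_variables, standardize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    truth = synth.TruthRecord.from_json(ROOT / "scratch" / "cohort" / "truth.json")
    ds = synth.regenerate(truth)
    results = ROOT / "results"

    matrix, dropped = drop_degenerate(ds.matrix, ds.outcome)
    std, scale = standardize(matrix)
    std = encode_partner_variables(std, fill_value=0.0)
    scan = screen.univariable_scan(std, ds.outcome)
    scan, decision = screen.mark_fdr(scan, q=0.001)

    scan.drop(columns=["name"]).to_csv(results / "screen.tsv", sep="\t", float_format="%.6g")
    qq = screen.qq_plot_data(scan["p"].to_numpy())
    qq.to_csv(results / "qq.tsv", sep="\t", index=False, float_format="%.6g")
    screen.plot_qq(qq, decision, ROOT / "scratch" / "qq_plot.png")

    survivors = scan.index[scan["passes_fdr"]]
    planted = set(truth.planted_effects)
    fdr_info = {
        "variables_tested": decision.m,
        "q": decision.q,
        "fdr_criterion": decision.threshold,
        "bonferroni_floor": decision.bonferroni_floor,
        "stage1_survivors": int(decision.n_discoveries),
        "planted_surviving": len(set(survivors) & planted),
        "planted_total": len(planted),
        "dropped_degenerate": len(dropped),
    }
    (results / "fdr.json").write_text(json.dumps(fdr_info, indent=1))
    print(json.dumps(fdr_info, indent=1))
    print(f"\nFDR criterion p <= {decision.threshold:.3e} "
          f"(variable criterion spans {decision.bonferroni_floor:.2e} .. {decision.q})")
    print(f"{decision.n_discoveries} of {decision.m} exposures pass stage 1; "
          f"{fdr_info['planted_surviving']}/{len(planted)} planted effects among them.")


if __name__ == "__main__":
    main()
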