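#!/usr/bin/env python
"""Step 4 — condense the run directory into headline tables.

Reads the artifacts written by step 3 and produces:
  results/summary_by_mode.csv      median AUC / Boyce / %nonanalog per
                                   validation mode and factor level
  results/summary_headline.txt     human-readable digest: internal vs
                                   external medians, novelty-performance
                                   correlations, niche-overlap verdict, and
                                   the significant group comparisons

Run from the repository root (after step 3):
    python analysis/04_summarize.py
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import RESULTS, RUN_DIR  # noqa: E402

METRICS = ["auc", "B", "pct_nonanalog"]
FACTORS = ["group", "size", "predictor_set", "algorithm"]


def factor_medians(rec: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for mode, by_mode in rec.groupby("mode"):
        rows.append({"mode": mode, "factor": "(all)", "level": "(all)",
                     "n": len(by_mode),
                     **{m: by_mode[m].median() for m in METRICS}})
        for factor in FACTORS:
            for level, sub in by_mode.groupby(factor):
                rows.append({"mode": mode, "factor": factor, "level": level,
                             "n": len(sub),
                             **{m: sub[m].median() for m in METRICS}})
    return pd.DataFrame(rows)


def main() -> None:
    rec = pd.read_csv(RUN_DIR / "evaluation_records.csv")
    comparisons = pd.read_csv(RUN_DIR / "comparisons.csv")
    novelty = pd.read_csv(RUN_DIR / "novelty_correlation.csv")
    overlap = json.loads((RUN_DIR / "niche_overlap.json").read_text())

    summary = factor_medians(rec)
    summary.to_csv(RESULTS / "summary_by_mode.csv", index=False,
                   float_format="%.4f")

    lines = ["== Validation-mode medians =="]
    overall = summary[summary["factor"] == "(all)"]
    for _, r in overall.iterrows():
        lines.append(f"  {r['mode']:<12} n={int(r['n']):4d}  "
                     f"AUC={r['auc']:.3f}  B={r['B']:.3f}  "
                     f"%nonanalog={r['pct_nonanalog']:.1f}")

    lines.append("\n== Novelty vs transfer performance ==")
    for _, r in novelty.iterrows():
        lines.append(f"  {r['mode']:<12} {r['metric']:<4} "
                     f"r={r['r']:+.3f}  p={r['p']:.4f}  n={int(r['n'])}")

    lines.append("\n== Niche overlap between clusters ==")
    lines.append(f"  Schoener's D = {overlap['D_observed']:.3f} "
                 f"(PCA-env axes explain "
                 f"{overlap['explained_axis1'] + overlap['explained_axis2']:.1%})")
    lines.append(f"  equivalency: p_divergence={overlap['equivalency_p_divergence']:.3f} "
                 f"p_conservatism={overlap['equivalency_p_conservatism']:.3f}")
    for key in sorted(k for k in overlap if k.startswith("similarity")):
        lines.append(f"  {key} = {overlap[key]:.3f}")

    lines.append("\n== Significant group comparisons (adjusted p < 0.05) ==")
    pcol = comparisons["p_adjusted"].fillna(comparisons["p"])
    sig = comparisons[pcol < 0.05]
    if sig.empty:
        lines.append("  (none)")
    for _, r in sig.iterrows():
        lines.append(f"  [{r['mode']}/{r['metric']}] {r['factor']}: "
                     f"{r['groups']}  {r['test']}  p={r['p']:.4f}  "
                     f"diff={r['estimated_difference']:+.3f}")

    text = "\n".join(lines) + "\n"
    (RESULTS / "summary_headline.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
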