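#!/usr/bin/env python
"""Step 2 — derive the 31-layer candidate pool and build both predictor sets.

Applies the two collinearity-filtering schemes to a seeded study-area sample:
``Ecol`` (pairwise Pearson |r| >= 0.7 resolved by the preference ranking) and
``VIF`` (two-stage variance-inflation filtering at threshold 10). Writes the
retained sets and the removal log to ``results/``.

Run from the repository root:
    python analysis/02_filter_predictors.py
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import RESULTS, build_config  # noqa: E402

from hsmtransfer.pipeline import _default_preference_ranking  # noqa: E402
from hsmtransfer.predictors import (build_candidate_stack,  # noqa: E402
                                    pearson_filter, vif_filter_two_stage)
from hsmtransfer.synthio import make_disjunct_scenario  # noqa: E402


def main() -> None:
    cfg = build_config()
    RESULTS.mkdir(parents=True, exist_ok=True)
    scenario = make_disjunct_scenario(cfg.scenario)
    cand = build_candidate_stack(scenario.landscape)
    table = pd.DataFrame(cand.valid_table(), columns=cand.names)
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(len(table), min(cfg.study_sample_size, len(table)),
                     replace=False)
    sample = table.iloc[np.sort(idx)].reset_index(drop=True)

    ecol = pearson_filter(sample, _default_preference_ranking(cand.names),
                          cfg.pearson_threshold)
    occ_vals = {
        lbl: pd.DataFrame(
            cand.values_at(scenario.occ(lbl).x, scenario.occ(lbl).y),
            columns=cand.names)
        for lbl in ("A", "B")
    }
    proxies = [pd.concat([occ_vals["A"], sample], ignore_index=True),
               pd.concat([occ_vals["B"], sample], ignore_index=True)]
    vif = vif_filter_two_stage(sample, proxies, cfg.vif_threshold)

    pd.DataFrame({
        "set": ["Ecol"] * len(ecol.retained) + ["VIF"] * len(vif.retained),
        "variable": ecol.retained + vif.retained,
    }).to_csv(RESULTS / "predictor_sets.csv", index=False)
    with open(RESULTS / "filtering_log.txt", "w") as fh:
        fh.write("\n".join(["[Ecol]"] + ecol.log + ["[VIF]"] + vif.log))
    print(f"candidates={cand.n_layers} Ecol={len(ecol.retained)} "
          f"VIF={len(vif.retained)}")


if __name__ == "__main__":
    main()
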