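#!/usr/bin/env python
"""Step 3 — fit the full model factorial and run every downstream stage.

Executes the complete pipeline (simulate, filter, fit + evaluate the
dataset x replicate x predictor-set x algorithm x fold factorial, build
Boyce-weighted ensembles, niche-overlap battery, statistical comparisons)
into ``results/run/``. Steps 1-2 are subsets of this run and are re-derived
internally from the same seeded configuration.

Takes roughly ten minutes on one CPU. Run from the repository root:
    python analysis/03_run_experiment.py
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import RUN_DIR, build_config  # noqa: E402

from hsmtransfer.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    cfg = build_config()
    t0 = time.time()
    artifacts = run_pipeline(cfg, RUN_DIR)
    result = artifacts["experiment"]
    print(f"finished in {time.time() - t0:.1f}s: "
          f"{len(result.models)} models, {len(result.records)} evaluation "
          f"records, {len(result.failures)} failures -> {RUN_DIR}")


if __name__ == "__main__":
    main()
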