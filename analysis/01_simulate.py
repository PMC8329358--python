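#!/usr/bin/env python
"""Simulate the study cohort (17 controls, 12 non-symptomatic and 15
symptomatic mild-TBI subjects) with the published FAA/eFAA effect sizes and
questionnaire couplings.

EEG goes to scratch/cohort (binary BrainVision triplets); a small JSON
summary of what was generated goes to results/.  The task here uses 4
blocks × 64 trials per subject (one pass over the four response rules),
which keeps per-condition segment counts at 64 — ample for stable alpha
estimates — while keeping the cohort cheap to regenerate.
"""

import json
from pathlib import Path

from efaa.cli_report import PipelineConfig, simulate_to_dir

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

cfg = PipelineConfig(seed=20260101, n_blocks=4, trials_per_block=64)

if __name__ == "__main__":
    simulate_to_dir(cfg, DATA, force=True)
    manifest = json.loads((DATA / "manifest.json").read_text())
    RESULTS.mkdir(exist_ok=True)
    summary = {
        "subjects": len(manifest["subjects"]),
        "groups": manifest["groups"],
        "n_blocks": manifest["n_blocks"],
        "trials_per_block": manifest["trials_per_block"],
        "seed": manifest["seed"],
        "data_dir": str(DATA.relative_to(ROOT)),
    }
    (RESULTS / "01_simulation.json").write_text(json.dumps(summary, indent=2))
    print(f"simulated {summary['subjects']} subjects "
          f"({summary['n_blocks']}×{summary['trials_per_block']} trials each) "
          f"into {DATA}")
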