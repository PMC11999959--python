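#!/usr/bin/env python
"""Step 3 — detect movement onsets and validate each trial's MRCP.

For every cued trial: detect the EMG onset (threshold + morphology on the
envelope), find the peak negativity (PN), extract the slope descriptors on
the PN-aligned view, and apply the four acceptance rules.  Writes
trial-assessments.csv, success-summaries.csv and the per-processing success
tables (subjects x conditions with MEAN/SD rows) plus the PN-aligned
successful epochs under <run-dir>/epochs.
"""

import argparse
from pathlib import Path

import pandas as pd

from mrcpspeller.config import StudyConfig
from mrcpspeller.pipeline import stage_validate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    cfg = StudyConfig.from_yaml(args.run_dir / "config.yaml")
    df = stage_validate(cfg, args.run_dir)
    summaries = pd.read_csv(args.run_dir / "success-summaries.csv")
    print(f"assessed {len(df)} trials "
          f"({df['success'].mean() * 100:.1f}% validated overall)")
    for proc in cfg.processing:
        sub = summaries[summaries["processing"] == proc]
        by_cond = sub.groupby("condition")["success_rate_pct"].mean()
        cells = ", ".join(f"{c}: {v:.1f}%" for c, v in by_cond.items())
        print(f"  mean success rate [{proc}] - {cells}")


if __name__ == "__main__":
    main()
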