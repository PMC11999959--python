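#!/usr/bin/env python
"""Step 1 — simulate the synthetic cohort.

Writes 13 subjects x 3 speller conditions (control, phrase, random) of
ground-truthed EEG + EMG EDF recordings with cue-event tables under
<run-dir>/data.  Later steps consume this directory.
"""

import argparse
from pathlib import Path

from mrcpspeller.config import StudyConfig
from mrcpspeller.pipeline import stage_simulate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--config", type=Path, default=None,
                        help="optional YAML study configuration")
    args = parser.parse_args()

    cfg = StudyConfig.from_yaml(args.config) if args.config else StudyConfig()
    manifest = stage_simulate(cfg, args.run_dir, args.seed)
    cfg.to_yaml(args.run_dir / "config.yaml")
    print(f"simulated {len(manifest)} subject-condition sessions "
          f"({cfg.n_subjects} subjects x {len(cfg.conditions)} conditions, "
          f"{cfg.rate:.0f} Hz) under {args.run_dir / 'data'}")


if __name__ == "__main__":
    main()
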