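#!/usr/bin/env python
"""Step 4 — MRCP descriptors for the validated trials.

Writes per-trial descriptors (PN amplitude, NS1/NS2 slopes, rebound slope,
peak-to-peak) for successful trials to trial-features.csv and their
subject x condition means to subject-condition-means.csv.
"""

import argparse
from pathlib import Path

from mrcpspeller.config import StudyConfig
from mrcpspeller.features import FEATURE_NAMES
from mrcpspeller.pipeline import stage_features


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    cfg = StudyConfig.from_yaml(args.run_dir / "config.yaml")
    means = stage_features(cfg, args.run_dir)
    print(f"descriptor means for {len(means)} subject-condition cells "
          f"({', '.join(FEATURE_NAMES)})")
    for proc in cfg.processing:
        sub = means[means["processing"] == proc]
        pn = sub.groupby("condition")["pn_uv"].mean()
        cells = ", ".join(f"{c}: {v:.2f} uV" for c, v in pn.items())
        print(f"  mean PN amplitude [{proc}] - {cells}")


if __name__ == "__main__":
    main()
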