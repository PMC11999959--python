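#!/usr/bin/env python
"""Step 2 — filter the EEG and derive the analysis channels.

Applies the 48-52 Hz notch and 0.05-3 Hz band-pass (2nd-order Butterworth,
zero-phase) to every recording and derives the two processing paths: raw Cz
and the large Laplacian around Cz.  Filtered EDFs land under
<run-dir>/filtered.
"""

import argparse
from pathlib import Path

from mrcpspeller.config import StudyConfig
from mrcpspeller.pipeline import stage_preprocess


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    cfg = StudyConfig.from_yaml(args.run_dir / "config.yaml")
    stage_preprocess(cfg, args.run_dir)
    print(f"filtered recordings ({' + '.join(cfg.processing)}) written under "
          f"{args.run_dir / 'filtered'}")


if __name__ == "__main__":
    main()
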