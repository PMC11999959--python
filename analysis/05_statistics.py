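#!/usr/bin/env python
"""Step 5 — descriptor statistics, grand averages, and the 1-D SPM.

Runs the Friedman omnibus per descriptor per processing path (Wilcoxon
signed-rank post-hoc with Bonferroni correction when significant), builds
PN-aligned grand averages, and runs the pointwise repeated-measures ANOVA
with cluster-level permutation correction over the subject-condition mean
traces.  Writes stats-report.json, spm-curve-*.csv and grand-average-*.png.
"""

import argparse
from pathlib import Path

from mrcpspeller.config import StudyConfig
from mrcpspeller.pipeline import stage_stats


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    parser.add_argument("--seed", type=int, default=0,
                        help="seed for the permutation null (use the same "
                             "value as step 1 for a fully pinned run)")
    args = parser.parse_args()

    cfg = StudyConfig.from_yaml(args.run_dir / "config.yaml")
    report = stage_stats(cfg, args.run_dir, args.seed)
    for proc in cfg.processing:
        print(f"[{proc}]")
        for feat, res in report["friedman"][proc].items():
            flag = " *" if res["p_value"] < cfg.stats.alpha else ""
            print(f"  Friedman {feat:>18}: chi2 = {res['chi_square']:6.3f}, "
                  f"p = {res['p_value']:.4f}{flag}")
        spm = report["spm"][proc]
        print(f"  SPM: {spm['n_mean_traces']} mean traces, "
              f"F threshold {spm['threshold']:.2f}, "
              f"{len(spm['clusters'])} supra-threshold cluster(s)")
        for c in spm["clusters"]:
            print(f"    cluster [{c['start_s']:+.2f}, {c['end_s']:+.2f}] s, "
                  f"p = {c['p_value']:.3f}")


if __name__ == "__main__":
    main()
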