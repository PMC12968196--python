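#!/usr/bin/env python
"""Run the complete 20-subject synthetic study end to end.

Per hemisphere (40 in total): quadrant parcellation, tractography-based
target selection, frontal and occipital trajectory safety against the 2 mm
margin, GA-optimized sphere infusion into the motor-dominant segment, and
the paired cohort statistics.  All artifacts land in results/study/.
"""

import json
from pathlib import Path

from cedplan import StudyConfig, run_study

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    cfg = StudyConfig(n_subjects=20, seed=7)
    summary = run_study(cfg, OUT)
    print(f"study artifacts in {OUT}")
    print(f"target segment: {summary['target_segment']}")
    t = summary["contingency"]
    print(f"safety contingency (frontal vs occipital): a={t['a']} b={t['b']} "
          f"c={t['c']} d={t['d']} (n={t['n']})")
    print(f"mid-p McNemar p = {summary['midp_mcnemar_p']:.4f}")
    cov = summary["coverage_percent"]
    print(f"coverage frontal  {cov['frontal']['mean']:.2f}% "
          f"(95% CI {cov['frontal']['ci95_lo']:.2f}-{cov['frontal']['ci95_hi']:.2f})")
    print(f"coverage occipital {cov['occipital']['mean']:.2f}% "
          f"(95% CI {cov['occipital']['ci95_lo']:.2f}-{cov['occipital']['ci95_hi']:.2f})")
    print(f"paired t-test p = {cov['paired_t']['p']:.4f}")


if __name__ == "__main__":
    main()
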