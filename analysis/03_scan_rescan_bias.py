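#!/usr/bin/env python
"""Aim 2 — does motion bias features after modern preprocessing?

Within each subject's session, labels the two scans less-/more-motion,
selects the 120 subjects with the largest motion gap, and runs the
paired signed-rank grids (4 micro x 50 bundles, 7 macro x 50 bundles,
5 connectome metrics) with BH FDR at 0.05. Two runs: a null run (any
rejection is a false positive, since less and more scans measure the
same brain) and a positive control with a -5% FA bias injected into
the more-motion scan. Writes the grids under results/.
"""

import json
from pathlib import Path

import numpy as np

from dwimotion.pipelines import (
    assign_scan_rescan,
    paired_bias_test,
    select_top_movers_diff,
)
from dwimotion.simulate import (
    CohortSimConfig,
    FeatureSimConfig,
    TraceSimConfig,
    simulate_cohort,
    simulate_paired_features,
)

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records = simulate_cohort(
        CohortSimConfig(n_subjects=150, age_range=(55.0, 80.0), scan_rescan=True,
                        cohort_id="RESCAN", seed=SEED + 1),
        TraceSimConfig(n_volumes=30),
    )
    by_subject: dict = {}
    for r in records:
        by_subject.setdefault(r.subject, []).append(r)
    sessions = {s: assign_scan_rescan(pair) for s, pair in by_subject.items()}
    selected = select_top_movers_diff(sessions, k=120)
    gap = float(np.mean([
        sessions[s][1].summary.mean_rel_mm_per_vol
        - sessions[s][0].summary.mean_rel_mm_per_vol
        for s in selected
    ]))
    print(f"selected {len(selected)}/{len(sessions)} subjects; "
          f"mean less/more motion gap {gap:.3f} mm/vol")

    report = {"n_selected": len(selected), "motion_gap_mm_per_vol": gap, "runs": {}}
    for run, bias in (("null", {}), ("fa_bias_5pct", {"FA": 0.95})):
        less, more = simulate_paired_features(
            FeatureSimConfig(n_subjects=len(selected), seed=SEED + 2, injected_bias=bias)
        )
        report["runs"][run] = {}
        for domain in ("micro", "macro", "conn"):
            grid = paired_bias_test(less, more, domain)
            grid.table.to_csv(RESULTS / f"pairbias_{run}_{domain}.tsv",
                              sep="\t", index=False)
            report["runs"][run][domain] = {
                "n_tests": grid.n_tests,
                "n_significant": grid.n_significant,
                "mean_abs_pct_change": float(np.abs(grid.table["pct_change"]).mean()),
            }
            print(f"{run:>12s} {domain:>5s}: {grid.n_significant}/{grid.n_tests} "
                  f"significant after FDR")
        if run == "fa_bias_5pct":
            fa = paired_bias_test(less, more, "micro").table.query("measure == 'FA'")
            print(f"             injected FA bias recovered: "
                  f"{fa['pct_change'].mean():+.2f}% (truth -5%)")

    (RESULTS / "pairbias_report.json").write_text(json.dumps(report, indent=2))
    print("wrote results/pairbias_report.json")


if __name__ == "__main__":
    main()
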