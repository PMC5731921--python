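"""Marker evaluation on a simulated pilot cohort.

Simulates a 14-cancer / 6-non-cancer / 7-post-op urine cohort in which
every prostate-derived marker (and PSA) shares a per-sample prostatic
secretion factor. Raw marker L/H ratios are confounded by that factor;
normalizing against the urinary PSA peptide removes it. The report shows
per-peptide rank-test P and AUC before and after normalization, the
within-protein peptide concordance, and the risk stratification of the
cancer group.
"""

import pandas as pd

from srmquant import (
    CohortSimConfig,
    RunConfig,
    default_marker_specs,
    run_report,
    simulate_cohort,
)

cfg = CohortSimConfig(markers=default_marker_specs(effect_d=1.0),
                      secretion_sd=1.5, seed=11)
matrix, manifest, truth = simulate_cohort(cfg)
out = run_report(RunConfig(output_dir="scratch/example_report", panel_max_size=2),
                 matrix, manifest)

pd.set_option("display.width", 120)
perf = out["performance"]
print("per-peptide performance (cancer vs non-cancer):")
print(perf[["p_raw", "auc_raw", "p_norm", "auc_norm",
            "sensitivity", "specificity"]].round(3))
print()
print("PSA normalization removes the shared secretion factor: auc_norm")
print("recovers the programmed effect that auc_raw dilutes.")
print()
print("within-protein concordance (peptides of one protein should track):")
print(out["concordance"][["protein", "peptide_a", "peptide_b", "r_squared"]]
      .round(3).to_string(index=False))
print()
print("stratification of the cancer group (low-grade vs significant, on")
print("PSA-normalized values; the MMP9 peptides carry a programmed")
print("12-fold shift in significant tumors):")
print(out["stratification"].round(4))
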