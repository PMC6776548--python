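"""Classify every cross-panel drug pair and test per-drug over-representation.

Builds two small panels of three synthetic drugs each over a shared
80-line cohort, classifies all 3 x 3 = 9 pairs, and asks — per drug and
response type — whether that drug's pairs are over-represented in the
type (hypergeometric upper tail), the screen-level summary behind a
pair-grid heatmap.
"""
import numpy as np
import pandas as pd

from pharmseg import ResponseTable
from pharmseg.pipeline import grid_frame, overrepresentation_frame, run_grid

rng = np.random.default_rng(0)
ids = [f"CL{i:03d}" for i in range(80)]


def panel(prefix, n_drugs):
    out = {}
    for k in range(n_drugs):
        out[f"{prefix}{k}"] = ResponseTable(
            drug_id=f"{prefix}{k}",
            data=pd.DataFrame(
                {"log_ic50": rng.normal(1.0, 1.5, len(ids)),
                 "auc": np.clip(rng.normal(0.7, 0.15, len(ids)), 0, 1)},
                index=pd.Index(ids, name="cell_line_id"),
            ),
        )
    return out


grid = run_grid(panel("MAPK", 3), panel("PI3K", 3))
print(grid_frame(grid)[["DRUG_A", "DRUG_B", "N_LEAVES", "RESPONSE_TYPE",
                        "WEIGHTED_PEARSON"]].to_string(index=False))
over = overrepresentation_frame(grid)
print("\nmost over-represented (drug, response type) rows:")
print(over.nsmallest(3, "P_HYPERGEOM").to_string(index=False))
# Unstructured cohorts mostly classify as 'none'; with 9 pairs no drug
# reaches hypergeometric significance, as expected under the null.
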