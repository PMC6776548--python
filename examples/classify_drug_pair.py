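"""Classify a drug pair from its subpopulation quadrant layout.

Uses the 'divergent' preset: disjoint subpopulations are sensitive to one
drug or the other but never both — the response pattern that flags a
candidate drug combination.  Each leaf's mean log(IC50) pair is placed in
a quadrant by the cohort-wide 20th-percentile cutoffs, and each quadrant's
leaf count is tested against the fraction of individual cell lines there.
"""
from pharmseg import (
    build_cohort, classify_pair, generate, percentile_cutoffs,
    preset_scenarios, segment, standardize,
)

spec = preset_scenarios(seed=0)["divergent"]
ta, tb, _, _ = generate(spec)
cohort = standardize(build_cohort(ta, tb))
tree = segment(cohort)
cutoffs = percentile_cutoffs(cohort)  # 20th percentile of each drug's log(IC50)
pc = classify_pair(tree, cohort, cutoffs)

print(f"cutoffs: P20_A={cutoffs.cutoff_a:.2f}, P20_B={cutoffs.cutoff_b:.2f} log(IC50)")
print(f"{pc.n_leaves} leaves; quadrant counts: {pc.quadrant_counts}")
print("binomial p per quadrant:",
      {k: f"{v:.3g}" for k, v in pc.binomial_p.items()})
print(f"response type: {pc.response_type}")
print(f"weighted within-leaf Pearson r of the two log(IC50)s: {pc.weighted_pearson:.3f}")
# 'divergent' requires both the A-only and B-only quadrants to hold more
# leaves than the unsegmented cell-line distribution predicts.
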