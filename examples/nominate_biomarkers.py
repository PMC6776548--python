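"""Nominate biomarkers for each discovered subpopulation.

Each planted cluster carries one binary marker present in 80% of its
members and 5% elsewhere, among background features.  After segmentation,
every (leaf, feature) pair is tested with a one-sided Fisher exact test
and BH-adjusted per leaf; the planted marker should top its leaf's list.
"""
from pharmseg import build_cohort, enrich_tree, generate, segment, standardize, three_cluster_spec

ta, tb, bem, truth = generate(three_cluster_spec(seed=0))
cohort = standardize(build_cohort(ta, tb))
tree = segment(cohort)
records = enrich_tree(tree, bem, scope="leaves")

print(f"{len(records)} (leaf, feature) tests across {tree.n_leaves()} leaves")
for nd in tree.leaves():
    ranked = sorted((r for r in records if r.node_id == nd.node_id),
                    key=lambda r: (r.q_value, r.p_value))
    top = ranked[0]
    print(f"leaf {nd.node_id} (n={nd.n}): top feature {top.feature_id}"
          f"  q={top.q_value:.2e}  inside fraction={top.inside_fraction:.2f}")
# A q-value around 1e-40 for MARKER_* features reflects the planted
# 80%-vs-5% contrast; background features stay far from significance.
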