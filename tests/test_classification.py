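import numpy as np
import pytest

from pharmseg import (
    PairClassification,
    QuadrantCutoffs,
    build_cohort,
    categorize_node,
    classify_pair,
    generate,
    percentile_cutoffs,
    preset_scenarios,
    scatter_frame,
    segment,
    standardize,
    target_overrepresentation,
    weighted_pearson,
)
from pharmseg.classification import classification_frame
from pharmseg.segmentation import SegmentationTree, TreeNode
from tests.conftest import make_table, random_cohort


def make_classification(drug_a, drug_b, rtype):
    quads = ("both_sensitive", "a_only", "b_only", "resistant")
    return PairClassification(
        drug_a_id=drug_a, drug_b_id=drug_b,
        quadrant_counts={q: 0 for q in quads},
        expected_proportions={q: 0.25 for q in quads},
        binomial_p={q: 1.0 for q in quads},
        response_type=rtype,
    )


class TestPercentileCutoffs:
    def test_linear_interpolation(self):
        ids = [f"c{i}" for i in range(100)]
        a = make_table("A", ids, np.arange(1, 101), np.full(100, 0.5))
        b = make_table("B", ids, np.arange(1, 101), np.full(100, 0.5))
        cut = percentile_cutoffs(build_cohort(a, b), q=20)
        assert cut.cutoff_a == pytest.approx(20.8)

    def test_constant_and_minimum(self):
        ids = [f"c{i}" for i in range(10)]
        a = make_table("A", ids, np.full(10, 3.0), np.full(10, 0.5))
        b = make_table("B", ids, np.arange(10), np.full(10, 0.5))
        cohort = build_cohort(a, b)
        assert percentile_cutoffs(cohort, q=20).cutoff_a == 3.0
        assert percentile_cutoffs(cohort, q=0).cutoff_b == 0.0

    def test_original_scale_after_standardization(self):
        ids = [f"c{i}" for i in range(20)]
        a = make_table("A", ids, np.arange(20.0), np.full(20, 0.5))
        b = make_table("B", ids, np.arange(20.0), np.full(20, 0.5))
        cohort = build_cohort(a, b)
        assert percentile_cutoffs(standardize(cohort)).cutoff_a == pytest.approx(
            percentile_cutoffs(cohort).cutoff_a
        )

    def test_too_few_lines(self):
        ids = ["c1", "c2"]
        a = make_table("A", ids, [1, 2], [0.5, 0.5])
        b = make_table("B", ids, [1, 2], [0.5, 0.5])
        with pytest.raises(ValueError):
            percentile_cutoffs(build_cohort(a, b))


class TestCategorizeNode:
    CUT = QuadrantCutoffs(cutoff_a=0.0, cutoff_b=0.0)

    @pytest.mark.parametrize(
        "ma, mb, expected",
        [
            (-1.0, -1.0, "both_sensitive"),
            (-1.0, 1.0, "a_only"),
            (1.0, -1.0, "b_only"),
            (1.0, 1.0, "resistant"),
            (0.0, -1.0, "b_only"),  # boundary: >= cutoff is resistant on that axis
            (0.0, 0.0, "resistant"),
        ],
    )
    def test_quadrant_rules(self, ma, mb, expected):
        assert categorize_node(ma, mb, self.CUT) == expected


class TestClassifyPair:
    def test_single_leaf_never_significant(self):
        cohort = random_cohort(50, seed=0)
        tree = SegmentationTree(
            nodes=[TreeNode(node_id=0, members=list(cohort.cell_line_ids))],
            drug_a_id="A", drug_b_id="B",
        )
        pc = classify_pair(tree, cohort)
        assert pc.response_type == "none"
        assert sum(pc.quadrant_counts.values()) == 1
        assert min(pc.binomial_p.values()) >= 0.2

    def test_expected_proportions_are_empirical_fractions(self):
        cohort = random_cohort(200, seed=1)
        tree = SegmentationTree(
            nodes=[TreeNode(node_id=0, members=list(cohort.cell_line_ids))],
            drug_a_id="A", drug_b_id="B",
        )
        cut = percentile_cutoffs(cohort)
        pc = classify_pair(tree, cohort, cut)
        x = cohort.original_drp
        sens_a = x[:, 0] < cut.cutoff_a
        sens_b = x[:, 2] < cut.cutoff_b
        assert pc.expected_proportions["both_sensitive"] == (sens_a & sens_b).mean()
        assert pc.expected_proportions["a_only"] == (sens_a & ~sens_b).mean()
        assert sum(pc.expected_proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_divergent_and_both_sensitive_constructions(self):
        for preset, expected in [("divergent", "divergent"),
                                 ("both_sensitive", "both_sensitive")]:
            ta, tb, _, _ = generate(preset_scenarios(seed=0)[preset])
            cohort = standardize(build_cohort(ta, tb))
            tree = segment(cohort)
            assert classify_pair(tree, cohort).response_type == expected

    def test_drug_swap_maps_preferential_types(self):
        ta, tb, _, _ = generate(preset_scenarios(seed=0)["a_preferential"])
        forward = standardize(build_cohort(ta, tb))
        swapped = standardize(build_cohort(tb, ta))
        pc_f = classify_pair(segment(forward), forward)
        pc_s = classify_pair(segment(swapped), swapped)
        assert pc_f.response_type == "a_preferential"
        assert pc_s.response_type == "b_preferential"
        assert pc_f.quadrant_counts["a_only"] == pc_s.quadrant_counts["b_only"]
        assert pc_f.quadrant_counts["both_sensitive"] == pc_s.quadrant_counts["both_sensitive"]


class TestWeightedPearson:
    def _tree(self, cohort, *leaf_slices):
        nodes = [TreeNode(node_id=0, members=list(cohort.cell_line_ids),
                          is_leaf=not leaf_slices)]
        if leaf_slices:
            nodes[0].is_leaf = False
            for k, sl in enumerate(leaf_slices, start=1):
                nodes.append(TreeNode(node_id=k, members=list(np.array(cohort.cell_line_ids)[sl]),
                                      parent=0))
                nodes[0].children.append(k)
        return SegmentationTree(nodes=nodes, drug_a_id="A", drug_b_id="B")

    def test_collinear_leaf_gives_one(self):
        ids = [f"c{i}" for i in range(6)]
        a = make_table("A", ids, [1, 2, 3, 4, 5, 6], np.full(6, 0.5))
        b = make_table("B", ids, [2, 4, 6, 8, 10, 12], np.full(6, 0.5))
        cohort = build_cohort(a, b)
        assert weighted_pearson(self._tree(cohort), cohort) == pytest.approx(1.0)

    def test_opposite_correlations_average_to_zero(self):
        ids = [f"c{i}" for i in range(8)]
        a = make_table("A", ids, [1, 2, 3, 4, 1, 2, 3, 4], np.full(8, 0.5))
        b = make_table("B", ids, [1, 2, 3, 4, 4, 3, 2, 1], np.full(8, 0.5))
        cohort = build_cohort(a, b)
        tree = self._tree(cohort, slice(0, 4), slice(4, 8))
        assert weighted_pearson(tree, cohort) == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        cohort = random_cohort(30, seed=7)
        tree = self._tree(cohort, slice(0, 12), slice(12, 30))
        x = cohort.original_drp
        expected = 0.0
        for sl, w in [(slice(0, 12), 12), (slice(12, 30), 18)]:
            a, b = x[sl, 0], x[sl, 2]
            cov = ((a - a.mean()) * (b - b.mean())).mean()
            r = cov / (a.std() * b.std())
            expected += w * r
        expected /= 30
        assert weighted_pearson(tree, cohort) == pytest.approx(expected, abs=1e-12)

    def test_small_and_constant_leaves_skipped(self):
        ids = [f"c{i}" for i in range(7)]
        a = make_table("A", ids, [1, 2, 3, 4, 5, 5, 5], np.full(7, 0.5))
        b = make_table("B", ids, [2, 4, 6, 8, 1, 2, 3], np.full(7, 0.5))
        cohort = build_cohort(a, b)
        # leaf 2 has constant drug-A response -> skipped, weights renormalized
        tree = self._tree(cohort, slice(0, 4), slice(4, 7))
        assert weighted_pearson(tree, cohort) == pytest.approx(1.0)
        lonely = self._tree(cohort, slice(0, 2), slice(2, 4), slice(4, 7))
        with pytest.raises(ValueError):
            weighted_pearson(lonely, cohort)  # no leaf has >= 3 usable members


class TestTargetOverrepresentation:
    def _grid(self):
        grid = [make_classification(f"A{i}", "B0", "none") for i in range(7)]
        grid += [make_classification(f"A{7+i}", "B0", "divergent") for i in range(3)]
        return grid

    def test_drawing_everything_gives_one(self):
        grid = self._grid()
        assert target_overrepresentation(grid, range(len(grid)), "divergent") == 1.0

    def test_exact_enrichment_value(self):
        grid = self._grid()
        p = target_overrepresentation(grid, [7, 8, 9], "divergent")
        assert p == pytest.approx(1 / 120, rel=1e-12)  # C(10,3) draws, all hits

    def test_disjoint_group_gives_one(self):
        grid = self._grid()
        assert target_overrepresentation(grid, [0, 1], "divergent") == 1.0

    def test_predicate_group_and_validation(self):
        grid = self._grid()
        p = target_overrepresentation(grid, lambda pc: pc.drug_a_id == "A7", "divergent")
        assert p == pytest.approx(3 / 10)
        with pytest.raises(ValueError):
            target_overrepresentation(grid, [], "divergent")
        with pytest.raises(ValueError):
            target_overrepresentation([], [0], "divergent")


class TestExports:
    def test_scatter_frame_columns_and_quadrants(self):
        ta, tb, _, _ = generate(preset_scenarios(seed=0)["both_sensitive"])
        cohort = standardize(build_cohort(ta, tb))
        tree = segment(cohort)
        cut = percentile_cutoffs(cohort)
        frame = scatter_frame(tree, cohort, cut)
        assert len(frame) == tree.n_leaves()
        assert frame["N"].sum() == cohort.n
        assert set(frame["QUADRANT"]) <= {"both_sensitive", "a_only", "b_only", "resistant"}
        assert (frame["CUTOFF_A"] == cut.cutoff_a).all()

    def test_classification_frame_rows(self):
        frame = classification_frame(
            [make_classification("A1", "B1", "none"),
             make_classification("A1", "B2", "divergent")]
        )
        assert list(frame["RESPONSE_TYPE"]) == ["none", "divergent"]
        assert {"N_BOTH_SENSITIVE", "P_A_ONLY", "WEIGHTED_PEARSON"} <= set(frame.columns)
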