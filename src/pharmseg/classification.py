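"""Drug-pair classification from the quadrant layout of subpopulations.

Each leaf subpopulation is placed in one of four response quadrants by
comparing its mean log(IC50) per drug against the cohort-wide 20th
percentile cutoffs P20_A and P20_B (strict < means sensitive, >= means
resistant).  The quadrant counts of leaves are compared, one quadrant at a
time, against the fraction of individual cell lines falling in that
quadrant — the distribution expected had no segmentation been performed —
with a one-sided (greater) exact binomial test.  Drug pairs are then
assigned one of five response types:

    both_sensitive  the both-sensitive quadrant is over-represented
    divergent       the A-only AND B-only quadrants are over-represented
    a_preferential  only the A-only quadrant is over-represented
    b_preferential  only the B-only quadrant is over-represented
    none            nothing is over-represented

Precedence on multiple significant quadrants: both_sensitive > divergent >
single-preferential (logged as ambiguous).  A divergent pair — disjoint
subpopulations sensitive to one drug or the other but not both — is the
candidate signal for combination-therapy benefit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, hypergeom

from .io_prep import Cohort, LOG_IC50_A, LOG_IC50_B
from .segmentation import SegmentationTree

logger = logging.getLogger(__name__)

QUADRANTS = ("both_sensitive", "a_only", "b_only", "resistant")
RESPONSE_TYPES = ("none", "both_sensitive", "a_preferential", "b_preferential", "divergent")
DEFAULT_PERCENTILE = 20.0
DEFAULT_ALPHA = 0.05


@dataclass
class QuadrantCutoffs:
    """Per-drug log(IC50) sensitivity cutoffs (percentile of pooled values)."""

    cutoff_a: float
    cutoff_b: float
    q: float = DEFAULT_PERCENTILE


@dataclass
class PairClassification:
    drug_a_id: str
    drug_b_id: str
    quadrant_counts: dict[str, int]
    expected_proportions: dict[str, float]
    binomial_p: dict[str, float]
    response_type: str
    weighted_pearson: float | None = None
    n_leaves: int = 0
    ambiguous: bool = False
    leaf_quadrants: dict[int, str] = field(default_factory=dict)


def percentile_cutoffs(cohort: Cohort, q: float = DEFAULT_PERCENTILE) -> QuadrantCutoffs:
    """Linear-interpolation percentile of each drug's log(IC50) column.

    Computed on the original measurement scale regardless of whether the
    cohort has been standardized.
    """
    if cohort.n < 5:
        raise ValueError("need at least 5 cell lines for a stable percentile cutoff")
    x = cohort.original_drp
    return QuadrantCutoffs(
        cutoff_a=float(np.percentile(x[:, LOG_IC50_A], q)),
        cutoff_b=float(np.percentile(x[:, LOG_IC50_B], q)),
        q=q,
    )


def categorize_node(mean_a: float, mean_b: float, cutoffs: QuadrantCutoffs) -> str:
    """Quadrant of a subpopulation: strict < is sensitive, >= resistant."""
    sens_a = mean_a < cutoffs.cutoff_a
    sens_b = mean_b < cutoffs.cutoff_b
    if sens_a and sens_b:
        return "both_sensitive"
    if sens_a:
        return "a_only"
    if sens_b:
        return "b_only"
    return "resistant"


def _quadrant_fractions(cohort: Cohort, cutoffs: QuadrantCutoffs) -> dict[str, float]:
    """Empirical quadrant fractions of individual cell lines (the no-
    segmentation null)."""
    x = cohort.original_drp
    sens_a = x[:, LOG_IC50_A] < cutoffs.cutoff_a
    sens_b = x[:, LOG_IC50_B] < cutoffs.cutoff_b
    n = cohort.n
    return {
        "both_sensitive": float((sens_a & sens_b).sum()) / n,
        "a_only": float((sens_a & ~sens_b).sum()) / n,
        "b_only": float((~sens_a & sens_b).sum()) / n,
        "resistant": float((~sens_a & ~sens_b).sum()) / n,
    }


def classify_pair(
    tree: SegmentationTree,
    cohort: Cohort,
    cutoffs: QuadrantCutoffs | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> PairClassification:
    """Classify a drug pair from its segmented subpopulations."""
    leaves = tree.leaves()
    if not leaves:
        raise ValueError("tree has no leaves")
    cutoffs = cutoffs or percentile_cutoffs(cohort)
    x = cohort.original_drp
    leaf_quadrants: dict[int, str] = {}
    counts = {quad: 0 for quad in QUADRANTS}
    for nd in leaves:
        idx = cohort.index_of(nd.members)
        quad = categorize_node(
            float(x[idx, LOG_IC50_A].mean()), float(x[idx, LOG_IC50_B].mean()), cutoffs
        )
        leaf_quadrants[nd.node_id] = quad
        counts[quad] += 1
    expected = _quadrant_fractions(cohort, cutoffs)
    k_total = len(leaves)
    pvals = {
        quad: float(
            binomtest(counts[quad], k_total, expected[quad], alternative="greater").pvalue
        )
        for quad in QUADRANTS
    }
    sig = {quad: pvals[quad] < alpha for quad in QUADRANTS}
    if sig["both_sensitive"]:
        rtype = "both_sensitive"
    elif sig["a_only"] and sig["b_only"]:
        rtype = "divergent"
    elif sig["a_only"]:
        rtype = "a_preferential"
    elif sig["b_only"]:
        rtype = "b_preferential"
    else:
        rtype = "none"
    ambiguous = sig["both_sensitive"] and (sig["a_only"] or sig["b_only"])
    if ambiguous:
        logger.warning(
            "%s vs %s: multiple over-represented quadrants; precedence gives %s",
            tree.drug_a_id, tree.drug_b_id, rtype,
        )
    try:
        wp = weighted_pearson(tree, cohort)
    except ValueError:
        wp = None
    return PairClassification(
        drug_a_id=tree.drug_a_id,
        drug_b_id=tree.drug_b_id,
        quadrant_counts=counts,
        expected_proportions=expected,
        binomial_p=pvals,
        response_type=rtype,
        weighted_pearson=wp,
        n_leaves=k_total,
        ambiguous=ambiguous,
        leaf_quadrants=leaf_quadrants,
    )


def weighted_pearson(tree: SegmentationTree, cohort: Cohort, min_size: int = 3) -> float:
    """Size-weighted mean within-leaf Pearson r of the two log(IC50)s.

    Leaves with fewer than ``min_size`` members or a constant log(IC50)
    column are skipped and the remaining weights renormalized.  High values
    mean the two drugs still co-vary inside subpopulations.
    """
    x = cohort.original_drp
    corrs, weights = [], []
    for nd in tree.leaves():
        if nd.n < min_size:
            continue
        idx = cohort.index_of(nd.members)
        a = x[idx, LOG_IC50_A]
        b = x[idx, LOG_IC50_B]
        if a.std() == 0.0 or b.std() == 0.0:
            logger.info("leaf %d has a constant log(IC50) column; skipped", nd.node_id)
            continue
        corrs.append(float(np.corrcoef(a, b)[0, 1]))
        weights.append(nd.n)
    if not corrs:
        raise ValueError("no leaf is eligible for a Pearson correlation")
    w = np.asarray(weights, dtype=float)
    return float(np.average(corrs, weights=w / w.sum()))


def target_overrepresentation(
    grid: list[PairClassification], group, category: str
) -> float:
    """Hypergeometric upper-tail p for over-representation of a pair group.

    ``group`` is a predicate over PairClassification or an iterable of
    indices.  Tests whether pairs in the group fall into ``category`` more
    often than drawing |group| pairs from the grid at random would suggest.
    """
    if not grid:
        raise ValueError("empty classification grid")
    if category not in RESPONSE_TYPES:
        raise ValueError(f"unknown category {category!r}")
    if callable(group):
        members = [i for i, pc in enumerate(grid) if group(pc)]
    else:
        members = sorted(set(group))
    if not members:
        raise ValueError("group selects no drug pairs")
    m_total = len(grid)
    k_cat = sum(1 for pc in grid if pc.response_type == category)
    x = sum(1 for i in members if grid[i].response_type == category)
    return float(min(hypergeom.sf(x - 1, m_total, k_cat, len(members)), 1.0))


def classification_frame(grid: list[PairClassification]) -> pd.DataFrame:
    """One row per drug pair: counts, binomial p-values, type, weighted r."""
    rows = []
    for pc in grid:
        row = {"DRUG_A": pc.drug_a_id, "DRUG_B": pc.drug_b_id, "N_LEAVES": pc.n_leaves}
        for quad in QUADRANTS:
            row[f"N_{quad.upper()}"] = pc.quadrant_counts[quad]
        for quad in QUADRANTS:
            row[f"P_{quad.upper()}"] = pc.binomial_p[quad]
        row["RESPONSE_TYPE"] = pc.response_type
        row["WEIGHTED_PEARSON"] = pc.weighted_pearson
        rows.append(row)
    return pd.DataFrame(rows)


def scatter_frame(
    tree: SegmentationTree, cohort: Cohort, cutoffs: QuadrantCutoffs
) -> pd.DataFrame:
    """Per-leaf scatter export: mean log(IC50)s, quadrant and the cutoffs."""
    x = cohort.original_drp
    rows = []
    for nd in tree.leaves():
        idx = cohort.index_of(nd.members)
        ma = float(x[idx, LOG_IC50_A].mean())
        mb = float(x[idx, LOG_IC50_B].mean())
        rows.append(
            {
                "NODE_ID": nd.node_id,
                "N": nd.n,
                "MEAN_LOG_IC50_A": ma,
                "MEAN_LOG_IC50_B": mb,
                "QUADRANT": categorize_node(ma, mb, cutoffs),
                "CUTOFF_A": cutoffs.cutoff_a,
                "CUTOFF_B": cutoffs.cutoff_b,
            }
        )
    return pd.DataFrame(rows)
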