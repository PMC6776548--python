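"""End-to-end drug-pair analysis and cross-panel grids.

``analyze_pair`` chains the full method for one drug pair: cohort
intersection -> standardisation -> similarity network -> recursive
bisection -> (optional) biomarker enrichment -> quadrant classification.
``run_grid`` repeats the classification for every cross-panel drug pair
and tabulates response types, the raw material for a pair-grid heatmap and
for response-type over-representation tests per drug.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classification import (
    PairClassification,
    QuadrantCutoffs,
    RESPONSE_TYPES,
    classification_frame,
    classify_pair,
    percentile_cutoffs,
    target_overrepresentation,
)
from .enrichment import EnrichmentRecord, enrich_tree
from .io_prep import BinaryEventMatrix, Cohort, ResponseTable, build_cohort, standardize
from .segmentation import SegmentationConfig, SegmentationTree, segment

logger = logging.getLogger(__name__)


@dataclass
class PairResult:
    cohort: Cohort
    tree: SegmentationTree
    cutoffs: QuadrantCutoffs
    classification: PairClassification
    enrichment: list[EnrichmentRecord] = field(default_factory=list)


def analyze_pair(
    table_a: ResponseTable,
    table_b: ResponseTable,
    bem: BinaryEventMatrix | None = None,
    config: SegmentationConfig | None = None,
    alpha: float = 0.05,
    percentile_q: float = 20.0,
    scope: str = "leaves",
) -> PairResult:
    """Run the full analysis for one drug pair."""
    cohort = standardize(build_cohort(table_a, table_b))
    tree = segment(cohort, config)
    cutoffs = percentile_cutoffs(cohort, q=percentile_q)
    classification = classify_pair(tree, cohort, cutoffs, alpha=alpha)
    records = enrich_tree(tree, bem, scope=scope) if bem is not None else []
    return PairResult(
        cohort=cohort, tree=tree, cutoffs=cutoffs,
        classification=classification, enrichment=records,
    )


def run_grid(
    panel_a: dict[str, ResponseTable],
    panel_b: dict[str, ResponseTable],
    config: SegmentationConfig | None = None,
    alpha: float = 0.05,
    percentile_q: float = 20.0,
) -> list[PairClassification]:
    """Classify every cross-panel drug pair; failing pairs are skipped."""
    grid: list[PairClassification] = []
    for a_id, ta in panel_a.items():
        for b_id, tb in panel_b.items():
            try:
                cohort = standardize(build_cohort(ta, tb))
                tree = segment(cohort, config)
                cutoffs = percentile_cutoffs(cohort, q=percentile_q)
                grid.append(classify_pair(tree, cohort, cutoffs, alpha=alpha))
            except ValueError as exc:
                logger.warning("skipping pair %s vs %s: %s", a_id, b_id, exc)
    if not grid:
        raise ValueError("no drug pair could be analysed")
    return grid


def grid_frame(grid: list[PairClassification]) -> pd.DataFrame:
    return classification_frame(grid)


def overrepresentation_frame(grid: list[PairClassification]) -> pd.DataFrame:
    """Per-drug, per-response-type hypergeometric over-representation.

    For each drug (on either side of the grid) the group is all pairs
    involving it; the p-value asks whether that group is over-represented
    in the response type relative to the whole grid.
    """
    rows = []
    drugs_a = sorted({pc.drug_a_id for pc in grid})
    drugs_b = sorted({pc.drug_b_id for pc in grid})
    for side, drugs in (("A", drugs_a), ("B", drugs_b)):
        attr = "drug_a_id" if side == "A" else "drug_b_id"
        for drug in drugs:
            group = [i for i, pc in enumerate(grid) if getattr(pc, attr) == drug]
            for rtype in RESPONSE_TYPES:
                p = target_overrepresentation(grid, group, rtype)
                rows.append(
                    {
                        "PANEL": side,
                        "DRUG_ID": drug,
                        "RESPONSE_TYPE": rtype,
                        "N_PAIRS": len(group),
                        "N_IN_TYPE": sum(
                            1 for i in group if grid[i].response_type == rtype
                        ),
                        "P_HYPERGEOM": p,
                    }
                )
    return pd.DataFrame(rows)
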