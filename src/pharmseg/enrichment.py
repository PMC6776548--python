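"""Biomarker nomination: per-subpopulation enrichment of binary events.

Each (subpopulation, feature) pair is summarised by the 2x2 contingency
table of cell lines inside/outside the subpopulation with/without the
event.  Enrichment significance is the one-sided (greater) Fisher exact
test — identically the hypergeometric upper tail P[X >= in_mut] — and
p-values are Benjamini-Hochberg adjusted per subpopulation across the
tested features.  Features with fewer than ``min_positive`` positive cell
lines cohort-wide are untestable and skipped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_prep import BinaryEventMatrix
from .segmentation import SegmentationTree

logger = logging.getLogger(__name__)

DEFAULT_MIN_POSITIVE = 3


@dataclass
class ContingencyTable:
    in_mut: int
    in_wt: int
    out_mut: int
    out_wt: int

    def __post_init__(self) -> None:
        if min(self.in_mut, self.in_wt, self.out_mut, self.out_wt) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.in_mut + self.in_wt + self.out_mut + self.out_wt


@dataclass
class EnrichmentRecord:
    node_id: int
    feature_id: str
    feature_class: str
    table: ContingencyTable
    p_value: float
    q_value: float
    inside_fraction: float


def contingency(
    members: list[str], feature_values: pd.Series, cohort_ids: list[str]
) -> ContingencyTable:
    """Counts of with/without feature, inside/outside the subpopulation.

    Cell lines absent from the feature column (no BEM row) are excluded
    from all four cells.
    """
    covered = [c for c in cohort_ids if c in feature_values.index]
    n_missing = len(cohort_ids) - len(covered)
    if n_missing:
        logger.warning("%d cell line(s) lack BEM rows and are excluded", n_missing)
    member_set = set(members)
    vals = feature_values.loc[covered].to_numpy()
    inside = np.array([c in member_set for c in covered])
    return ContingencyTable(
        in_mut=int(vals[inside].sum()),
        in_wt=int((~vals[inside].astype(bool)).sum()),
        out_mut=int(vals[~inside].sum()),
        out_wt=int((~vals[~inside].astype(bool)).sum()),
    )


def fisher_enrichment(table: ContingencyTable) -> float:
    """One-sided (greater) Fisher exact p-value for enrichment inside.

    Equals the hypergeometric tail P[X >= in_mut] with
    X ~ Hypergeom(total, in_mut + out_mut, in_mut + in_wt).
    """
    n_in = table.in_mut + table.in_wt
    k_mut = table.in_mut + table.out_mut
    if k_mut == 0 or n_in == 0:
        return 1.0
    p = float(hypergeom.sf(table.in_mut - 1, table.total, k_mut, n_in))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_tree(
    tree: SegmentationTree,
    bem: BinaryEventMatrix,
    scope: str = "leaves",
    min_positive: int = DEFAULT_MIN_POSITIVE,
    bh_scope: str = "per_node",
) -> list[EnrichmentRecord]:
    """Enrichment records for every (node in scope, testable feature) pair.

    ``scope`` is ``'leaves'`` or ``'all_nodes'``.  BH correction is applied
    per node across features by default (``bh_scope='pooled'`` adjusts one
    family across all nodes instead).
    """
    if scope not in ("leaves", "all_nodes"):
        raise ValueError(f"unknown scope {scope!r}")
    if bh_scope not in ("per_node", "pooled"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    cohort_ids = tree.root.members
    covered = [c for c in cohort_ids if c in bem.data.index]
    if not covered:
        logger.warning("tree and BEM share no cell lines; nothing to test")
        return []
    n_missing = len(cohort_ids) - len(covered)
    if n_missing:
        logger.warning("%d cohort cell line(s) lack BEM rows and are excluded", n_missing)
    sub = bem.data.loc[covered]
    totals = sub.sum(axis=0)
    testable = [f for f in bem.feature_ids if totals[f] >= min_positive]
    skipped = bem.n_features - len(testable)
    if skipped:
        logger.info("skipping %d feature(s) with < %d positive cell lines", skipped, min_positive)
    if not testable:
        return []

    nodes = tree.leaves() if scope == "leaves" else tree.nodes
    covered_index = pd.Index(covered)
    mat = sub[testable].to_numpy()
    col_tot = mat.sum(axis=0)
    grand = mat.shape[0]
    records: list[EnrichmentRecord] = []
    for nd in nodes:
        inside = covered_index.isin(nd.members)
        n_in = int(inside.sum())
        in_mut = mat[inside].sum(axis=0)
        tables = [
            ContingencyTable(
                in_mut=int(im),
                in_wt=n_in - int(im),
                out_mut=int(ct - im),
                out_wt=grand - n_in - int(ct - im),
            )
            for im, ct in zip(in_mut, col_tot)
        ]
        ps = np.array([fisher_enrichment(t) for t in tables])
        qs = bh_adjust(ps) if bh_scope == "per_node" else ps  # pooled: fill later
        for f, t, p, q in zip(testable, tables, ps, qs):
            frac = t.in_mut / n_in if n_in else 0.0
            records.append(
                EnrichmentRecord(
                    node_id=nd.node_id,
                    feature_id=f,
                    feature_class=bem.classes[f],
                    table=t,
                    p_value=float(p),
                    q_value=float(q),
                    inside_fraction=float(frac),
                )
            )
    if bh_scope == "pooled":
        qs = bh_adjust([r.p_value for r in records])
        for r, q in zip(records, qs):
            r.q_value = float(q)
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "NODE_ID": [r.node_id for r in records],
            "FEATURE_ID": [r.feature_id for r in records],
            "CLASS": [r.feature_class for r in records],
            "IN_MUT": [r.table.in_mut for r in records],
            "IN_WT": [r.table.in_wt for r in records],
            "OUT_MUT": [r.table.out_mut for r in records],
            "OUT_WT": [r.table.out_wt for r in records],
            "P": [r.p_value for r in records],
            "Q": [r.q_value for r in records],
            "INSIDE_FRACTION": [r.inside_fraction for r in records],
        }
    )


def write_enrichment_report(records: list[EnrichmentRecord], path) -> None:
    enrichment_frame(records).to_csv(path, sep="\t", index=False)
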