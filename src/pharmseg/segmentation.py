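"""Recursive spectral bisection of the cell-line similarity network.

The cohort is split recursively along the Fiedler vector (eigenvector of
the second-smallest eigenvalue of the graph Laplacian L = D - W computed on
the node's induced submatrix of the global W).  A proposed split is
accepted only if

  1. the parent has at least ``min_parent_size`` members (default 40),
  2. both children have at least ``min_child_size`` members (default 20),
  3. the two children are sufficiently separated: mean two-cluster
     silhouette in the standardized 4-D response space of at least
     ``silhouette_threshold`` (default 0.25).

Violating any gate makes the node a leaf carrying the reason.  Leaves are
mutually exclusive and jointly cover the cohort; node ids are assigned
breadth-first in creation order, so identical inputs yield identical trees.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .io_prep import Cohort, DRP_COLUMNS
from .network import adjacency, WeightedAdjacency, DEFAULT_BETA

logger = logging.getLogger(__name__)

FIEDLER_ZERO_TOL = 1e-12

#: leaf termination reasons
PARENT_TOO_SMALL = "parent_too_small"
CHILD_TOO_SMALL = "child_too_small"
SILHOUETTE_TOO_LOW = "silhouette_too_low"
NO_REASON = "none"


@dataclass
class SegmentationConfig:
    """Thresholds of the recursive bisection (defaults: 40 / 20 / 0.25)."""

    min_parent_size: int = 40
    min_child_size: int = 20
    silhouette_threshold: float = 0.25
    laplacian_variant: str = "unnormalized"  # or "normalized"
    beta: float = DEFAULT_BETA
    silhouette_space: str = "euclidean"  # or "network" (1 - w distances)
    recompute_network: bool = False  # rebuild Sigma statistics inside each node
    absolute_differences: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.silhouette_threshold <= 1.0:
            raise ValueError("silhouette_threshold must be in [-1, 1]")
        if self.laplacian_variant not in ("unnormalized", "normalized"):
            raise ValueError(f"unknown laplacian_variant {self.laplacian_variant!r}")
        if self.silhouette_space not in ("euclidean", "network"):
            raise ValueError(f"unknown silhouette_space {self.silhouette_space!r}")
        if self.min_parent_size < 2 * self.min_child_size:
            warnings.warn(
                "min_parent_size < 2 * min_child_size: every split of a "
                "minimal parent will fail the child-size gate",
                stacklevel=2,
            )


@dataclass
class TreeNode:
    node_id: int
    members: list[str]
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    is_leaf: bool = True
    split_silhouette: float | None = None
    termination_reason: str | None = None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class SegmentationTree:
    """Binary tree of subpopulations; leaves partition the cohort."""

    nodes: list[TreeNode]
    drug_a_id: str = ""
    drug_b_id: str = ""

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    def leaves(self) -> list[TreeNode]:
        return [nd for nd in self.nodes if nd.is_leaf]

    def n_leaves(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_leaf)

    def assignment(self) -> dict[str, int]:
        """cell_line_id -> leaf node id."""
        out: dict[str, int] = {}
        for nd in self.leaves():
            for c in nd.members:
                out[c] = nd.node_id
        return out

    def leaf_labels(self, cell_line_ids: list[str]) -> np.ndarray:
        a = self.assignment()
        return np.array([a[c] for c in cell_line_ids])


def fiedler_vector(w_sub: np.ndarray, variant: str = "unnormalized") -> np.ndarray:
    """Eigenvector of the second-smallest Laplacian eigenvalue, sign-fixed.

    Orientation: the first entry exceeding ``FIEDLER_ZERO_TOL`` in absolute
    value is made positive, so repeated runs agree bit-for-bit.
    """
    n = w_sub.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices")
    deg = w_sub.sum(axis=1)
    if variant == "unnormalized":
        lap = np.diag(deg) - w_sub
    elif variant == "normalized":
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        lap = np.eye(n) - inv_sqrt[:, None] * w_sub * inv_sqrt[None, :]
    else:
        raise ValueError(f"unknown laplacian variant {variant!r}")
    _, vecs = scipy.linalg.eigh(lap, subset_by_index=[0, 1])
    v = vecs[:, 1].copy()
    nz = np.flatnonzero(np.abs(v) > FIEDLER_ZERO_TOL)
    if nz.size and v[nz[0]] < 0:
        v = -v
    return v


def fiedler_bisect(
    w_sub: np.ndarray, variant: str = "unnormalized"
) -> tuple[np.ndarray, np.ndarray]:
    """Split vertices by the sign of the Fiedler vector.

    Entries within ``FIEDLER_ZERO_TOL`` of zero go to the positive side.
    If the vector is one-signed (degenerate near-disconnected case) the
    vertices are split at the median instead so that progress is always
    possible; the child-size and silhouette gates still vet the result.
    Returns (positive side, negative side) as index arrays.
    """
    v = fiedler_vector(w_sub, variant=variant)
    neg = v < -FIEDLER_ZERO_TOL
    if neg.all() or not neg.any():
        order = np.argsort(v, kind="stable")
        half = len(v) // 2
        return order[half:], order[:half]
    return np.flatnonzero(~neg), np.flatnonzero(neg)


def two_cluster_silhouette(
    x_left: np.ndarray, x_right: np.ndarray, metric_matrix: np.ndarray | None = None
) -> float:
    """Mean silhouette coefficient over both clusters of a 2-way split.

    Points in singleton clusters contribute 0.  If ``metric_matrix`` is
    given it is the full pairwise distance matrix over [left; right] and the
    coordinate inputs are ignored.
    """
    n_l, n_r = len(x_left), len(x_right)
    if n_l == 0 or n_r == 0:
        raise ValueError("both clusters must be nonempty")
    if metric_matrix is not None:
        d = metric_matrix
    else:
        x = np.vstack([x_left, x_right])
        d = cdist(x, x)
    n = n_l + n_r
    labels = np.zeros(n, dtype=bool)
    labels[n_l:] = True
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own_others = own.copy()
        own_others[i] = False
        if not own_others.any():
            continue  # singleton cluster: silhouette 0
        a = d[i, own_others].mean()
        b = d[i, ~own].mean()
        m = max(a, b)
        scores[i] = 0.0 if m == 0.0 else (b - a) / m
    return float(scores.mean())


def segment(cohort: Cohort, config: SegmentationConfig | None = None) -> SegmentationTree:
    """Recursively bisect the cohort into homogeneous subpopulations."""
    config = config or SegmentationConfig()
    if not cohort.standardized:
        raise ValueError("cohort must be standardized before segmentation")
    if cohort.n < 2:
        raise ValueError("need at least 2 cell lines to segment")
    w_full = adjacency(
        cohort, beta=config.beta, absolute=config.absolute_differences
    ).w
    ids = np.array(cohort.cell_line_ids)

    nodes: list[TreeNode] = []
    root = TreeNode(node_id=0, members=list(ids))
    nodes.append(root)
    queue: list[tuple[int, np.ndarray]] = [(0, np.arange(cohort.n))]
    while queue:
        node_id, member_idx = queue.pop(0)
        node = nodes[node_id]
        if len(member_idx) < config.min_parent_size:
            node.termination_reason = PARENT_TOO_SMALL
            continue
        if config.recompute_network:
            from dataclasses import replace

            sub = replace(
                cohort, cell_line_ids=list(ids[member_idx]), drp=cohort.drp[member_idx]
            )
            w_sub = adjacency(
                sub, beta=config.beta, absolute=config.absolute_differences
            ).w
        else:
            w_sub = w_full[np.ix_(member_idx, member_idx)]
        left_loc, right_loc = fiedler_bisect(w_sub, variant=config.laplacian_variant)
        left, right = member_idx[left_loc], member_idx[right_loc]
        if min(len(left), len(right)) < config.min_child_size:
            node.termination_reason = CHILD_TOO_SMALL
            continue
        if config.silhouette_space == "network":
            order = np.concatenate([left_loc, right_loc])
            dist = 1.0 - w_sub[np.ix_(order, order)]
            np.fill_diagonal(dist, 0.0)
            sil = two_cluster_silhouette(
                cohort.drp[left], cohort.drp[right], metric_matrix=dist
            )
        else:
            sil = two_cluster_silhouette(cohort.drp[left], cohort.drp[right])
        if sil < config.silhouette_threshold:
            node.termination_reason = SILHOUETTE_TOO_LOW
            continue
        node.is_leaf = False
        node.split_silhouette = sil
        for child_idx in (left, right):
            child = TreeNode(
                node_id=len(nodes), members=list(ids[child_idx]), parent=node_id
            )
            node.children.append(child.node_id)
            nodes.append(child)
            queue.append((child.node_id, child_idx))
    tree = SegmentationTree(
        nodes=nodes, drug_a_id=cohort.drug_a_id, drug_b_id=cohort.drug_b_id
    )
    logger.info(
        "segmented %d cell lines into %d leaves (%d nodes total)",
        cohort.n, tree.n_leaves(), len(nodes),
    )
    return tree


def node_summary(node: TreeNode, cohort: Cohort) -> dict:
    """Per-node record with mean responses on the original scale."""
    idx = cohort.index_of(node.members)
    means = cohort.original_drp[idx].mean(axis=0)
    rec = {
        "node_id": node.node_id,
        "parent": node.parent,
        "children": list(node.children),
        "is_leaf": node.is_leaf,
        "termination_reason": node.termination_reason,
        "split_silhouette": node.split_silhouette,
        "n": node.n,
        "members": list(node.members),
    }
    rec.update({f"mean_{c}": float(m) for c, m in zip(DRP_COLUMNS, means)})
    return rec


def all_nodes(tree: SegmentationTree, cohort: Cohort) -> list[dict]:
    """Every node (internal and leaf) with original-scale response summaries.

    Inspecting all nodes, not only the final leaves, surfaces intermediate
    subpopulations that may carry cleaner biomarker signal than any leaf.
    """
    return [node_summary(nd, cohort) for nd in tree.nodes]


def tree_to_json(tree: SegmentationTree, cohort: Cohort | None = None) -> str:
    if cohort is not None:
        records = all_nodes(tree, cohort)
    else:
        records = [asdict(nd) for nd in tree.nodes]
    payload = {
        "drug_a_id": tree.drug_a_id,
        "drug_b_id": tree.drug_b_id,
        "n_nodes": len(tree.nodes),
        "n_leaves": tree.n_leaves(),
        "nodes": records,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def tree_from_json(text: str) -> SegmentationTree:
    payload = json.loads(text)
    nodes = []
    for rec in payload["nodes"]:
        nodes.append(
            TreeNode(
                node_id=rec["node_id"],
                members=list(rec["members"]),
                parent=rec["parent"],
                children=list(rec["children"]),
                is_leaf=rec["is_leaf"],
                split_silhouette=rec.get("split_silhouette"),
                termination_reason=rec.get("termination_reason"),
            )
        )
    nodes.sort(key=lambda nd: nd.node_id)
    return SegmentationTree(
        nodes=nodes, drug_a_id=payload["drug_a_id"], drug_b_id=payload["drug_b_id"]
    )


#: fill colours per response quadrant, mirroring the usual scatter styling
QUADRANT_COLORS = {
    "both_sensitive": "orange",
    "a_only": "palegreen",
    "b_only": "lightblue",
    "resistant": "lightgrey",
}


def tree_to_dot(
    tree: SegmentationTree,
    quadrants: dict[int, str] | None = None,
    colors: dict[str, str] | None = None,
) -> str:
    """Graphviz DOT rendering: node label = member count, fill by quadrant."""
    colors = {**QUADRANT_COLORS, **(colors or {})}
    lines = ["digraph segmentation {", '  node [shape=circle, style=filled];']
    for nd in tree.nodes:
        fill = colors.get((quadrants or {}).get(nd.node_id, ""), "white")
        lines.append(f'  n{nd.node_id} [label="{nd.n}", fillcolor="{fill}"];')
    for nd in tree.nodes:
        for ch in nd.children:
            lines.append(f"  n{nd.node_id} -> n{ch};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_assignment(tree: SegmentationTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("CELL_LINE_ID\tLEAF_ID\n")
        for cell, leaf in sorted(tree.assignment().items()):
            fh.write(f"{cell}\t{leaf}\n")
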