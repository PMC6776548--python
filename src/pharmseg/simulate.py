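"""Synthetic GDSC-like cohorts with planted structure.

Generates drug-pair response tables, a sparse binary event matrix and
ground-truth cluster labels so every pipeline stage can be exercised and
validated without external downloads.  Each cluster draws its length-4
response profile (log IC50 and AUC per drug) from an independent Gaussian
with AUC clipped to [0, 1]; planted biomarkers are Bernoulli with an
elevated rate inside their cluster and the sparse background rate (default
0.05, mimicking somatic event frequencies) elsewhere.

``preset_scenarios`` ships five archetype cohorts — no preference,
both-sensitive, A-preferential, B-preferential and divergent — whose
planted cluster geometry produces the corresponding drug-pair response
type by construction, each sensitive cluster carrying one planted
biomarker.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import BinaryEventMatrix, ResponseTable, write_bem, write_response_table

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND_RATE = 0.05


@dataclass
class PlantedFeature:
    feature_id: str
    inside_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.inside_rate <= 1.0:
            raise ValueError(f"inside_rate must be in [0, 1], got {self.inside_rate}")


@dataclass
class ClusterSpec:
    """One planted subpopulation: size, 4-D response mean/sd, biomarkers."""

    n: int
    mean: tuple[float, float, float, float]  # (log_ic50_A, auc_A, log_ic50_B, auc_B)
    sd: tuple[float, float, float, float]
    planted_features: list[PlantedFeature] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cluster size must be >= 1")
        if len(self.mean) != 4 or len(self.sd) != 4:
            raise ValueError("mean and sd must have length 4")
        if min(self.sd) <= 0:
            raise ValueError("cluster sds must be positive")


@dataclass
class CohortSpec:
    clusters: list[ClusterSpec]
    background_features: list[tuple[str, float]] = field(default_factory=list)
    n_features_total: int = 0
    seed: int = 0
    background_rate: float = DEFAULT_BACKGROUND_RATE
    drug_a_id: str = "DRUG_A"
    drug_b_id: str = "DRUG_B"

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("need at least one cluster")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        for _, rate in self.background_features:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("background feature rates must be in [0, 1]")
        for i, cl in enumerate(self.clusters):
            if not cl.label:
                cl.label = f"cluster_{i}"

    @property
    def n_cell_lines(self) -> int:
        return sum(cl.n for cl in self.clusters)


def generate(
    spec: CohortSpec,
) -> tuple[ResponseTable, ResponseTable, BinaryEventMatrix, dict[str, str]]:
    """Draw a cohort from ``spec``; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    ids, labels, rows = [], [], []
    for cl in spec.clusters:
        draw = rng.normal(loc=cl.mean, scale=cl.sd, size=(cl.n, 4))
        rows.append(draw)
        labels.extend([cl.label] * cl.n)
    drp = np.vstack(rows)
    n_clip = int(((drp[:, [1, 3]] < 0) | (drp[:, [1, 3]] > 1)).sum())
    if n_clip:
        logger.info("clipped %d AUC draw(s) to [0, 1]", n_clip)
    drp[:, [1, 3]] = np.clip(drp[:, [1, 3]], 0.0, 1.0)
    n = drp.shape[0]
    width = max(4, len(str(n)))
    ids = [f"CL{i + 1:0{width}d}" for i in range(n)]
    truth = dict(zip(ids, labels))

    table_a = ResponseTable(
        drug_id=spec.drug_a_id,
        data=pd.DataFrame({"log_ic50": drp[:, 0], "auc": drp[:, 1]},
                          index=pd.Index(ids, name="cell_line_id")),
    )
    table_b = ResponseTable(
        drug_id=spec.drug_b_id,
        data=pd.DataFrame({"log_ic50": drp[:, 2], "auc": drp[:, 3]},
                          index=pd.Index(ids, name="cell_line_id")),
    )

    label_arr = np.array(labels)
    features: dict[str, np.ndarray] = {}
    for cl in spec.clusters:
        inside = label_arr == cl.label
        for pf in cl.planted_features:
            rates = np.where(inside, pf.inside_rate, spec.background_rate)
            features[pf.feature_id] = (rng.random(n) < rates).astype(np.int8)
    for fid, rate in spec.background_features:
        features[fid] = (rng.random(n) < rate).astype(np.int8)
    i = 0
    while len(features) < spec.n_features_total:
        fid = f"BG{i + 1:04d}"
        if fid not in features:
            features[fid] = (rng.random(n) < spec.background_rate).astype(np.int8)
        i += 1
    bem = BinaryEventMatrix(
        data=pd.DataFrame(features, index=pd.Index(ids, name="cell_line_id"))
    )
    return table_a, table_b, bem, truth


def write_cohort_files(
    table_a: ResponseTable,
    table_b: ResponseTable,
    bem: BinaryEventMatrix,
    truth: dict[str, str],
    out_dir: str | Path,
) -> list[Path]:
    """Write the cohort in the same delimited formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [
        out / f"response_{table_a.drug_id}.tsv",
        out / f"response_{table_b.drug_id}.tsv",
        out / "bem.tsv",
        out / "truth.tsv",
    ]
    write_response_table(table_a, paths[0])
    write_response_table(table_b, paths[1])
    write_bem(bem, paths[2])
    pd.DataFrame(
        {"CELL_LINE_ID": list(truth), "CLUSTER": [truth[c] for c in truth]}
    ).to_csv(paths[3], sep="\t", index=False)
    return paths


def _marker(label: str) -> list[PlantedFeature]:
    return [PlantedFeature(feature_id=f"MARKER_{label}", inside_rate=0.8)]


_SENS = (0.12, 0.03, 0.12, 0.03)  # sd of a tight sensitive cluster
_RES_SD = (0.3, 0.04, 0.3, 0.04)


def preset_scenarios(seed: int = 0) -> dict[str, CohortSpec]:
    """Five archetype cohorts, one per drug-pair response type.

    Cluster geometry is chosen so the archetype holds by construction under
    the default gates: sensitive clusters are tight (>= 10 within-cluster
    sd between centres), total sensitive mass per drug is exactly 20% of
    the cohort so the percentile cutoff falls in the gap between the
    sensitive and resistant blocks, and enough sensitive leaves exist for
    the per-quadrant binomial test to clear alpha = 0.05.
    """
    base = (int(seed) * 1009 + 7) % (2**31 - 10)

    def spec(clusters: list[ClusterSpec], offset: int, n_features: int = 30) -> CohortSpec:
        return CohortSpec(
            clusters=clusters, n_features_total=n_features, seed=base + offset
        )

    none = [ClusterSpec(n=300, mean=(0.5, 0.6, 0.5, 0.6), sd=(1.0, 0.12, 1.0, 0.12),
                        label="cloud")]

    # staggered, asymmetric positions: no regular grids (degenerate Fiedler
    # eigenvalues) and no cluster equidistant between two groups.
    _BS_POS = [
        (-4.8, 0.10, -4.1, 0.28),
        (-4.4, 0.38, -2.7, 0.10),
        (-3.1, 0.12, -4.7, 0.42),
        (-2.7, 0.40, -2.9, 0.24),
    ]
    both = [
        ClusterSpec(n=30, mean=pos, sd=(0.1, 0.025, 0.1, 0.025),
                    planted_features=_marker(f"BS{k}"), label=f"sens_both_{k}")
        for k, pos in enumerate(_BS_POS)
    ] + [ClusterSpec(n=480, mean=(2.0, 0.9, 2.0, 0.9), sd=_RES_SD, label="resistant")]

    # (logA, aucA) of the eight drug-A-only clusters: staggered radially
    # (depth on logA) and alternating on aucA.  The similarity measure is
    # driven by the projection of one profile onto the other's direction
    # from the cohort centroid, so clusters in the same quadrant direction
    # must differ in depth to be distinguishable; clusters sensitive to
    # opposite drugs point in anti-parallel directions and separate easily.
    _A_POS = [(-5.2, 0.10), (-4.8, 0.50), (-4.4, 0.10), (-4.0, 0.50),
              (-3.6, 0.10), (-3.2, 0.50), (-2.8, 0.10), (-2.4, 0.50)]
    _B_HIGH = [2.0, 2.35, 2.15, 2.5, 2.05, 2.4, 2.2, 2.45]

    def a_only_clusters(tag: str, n_clusters: int = 8, size: int = 25) -> list[ClusterSpec]:
        return [
            ClusterSpec(n=size, mean=(la, au, lb, 0.88), sd=(0.12, 0.03, 0.12, 0.03),
                        planted_features=_marker(f"{tag}{k}"), label=f"sens_a_{k}")
            for k, ((la, au), lb) in enumerate(
                zip(_A_POS[:n_clusters], _B_HIGH[:n_clusters])
            )
        ]

    def b_only_clusters(tag: str, n_clusters: int = 8, size: int = 25) -> list[ClusterSpec]:
        return [
            ClusterSpec(n=size, mean=(la, 0.88, lb, au), sd=(0.12, 0.03, 0.12, 0.03),
                        planted_features=_marker(f"{tag}{k}"), label=f"sens_b_{k}")
            for k, ((lb, au), la) in enumerate(
                zip(_A_POS[:n_clusters], _B_HIGH[:n_clusters])
            )
        ]

    # single-cluster absorbers soak up the other drug's 20% sensitivity
    # quota (so its percentile cutoff falls in a gap between blocks) while
    # contributing only one leaf, far too few for significance.
    b_absorber = ClusterSpec(
        n=200, mean=(2.2, 0.85, -3.8, 0.15), sd=(0.3, 0.04, 0.12, 0.03),
        planted_features=_marker("BONLY"), label="sens_b_absorber",
    )
    a_absorber = ClusterSpec(
        n=200, mean=(-3.8, 0.15, 2.2, 0.85), sd=(0.12, 0.03, 0.3, 0.04),
        planted_features=_marker("AONLY"), label="sens_a_absorber",
    )
    resistant_600 = ClusterSpec(
        n=600, mean=(2.0, 0.9, 2.0, 0.9), sd=_RES_SD, label="resistant"
    )

    a_pref = a_only_clusters("A") + [b_absorber, resistant_600]
    b_pref = b_only_clusters("B") + [a_absorber, resistant_600]

    # divergent: four widely spaced response shells per side (the drug-B
    # side far more potent, keeping the two anti-parallel sensitive blocks
    # asymmetric), one large compact both-sensitive cluster, and a big
    # resistant cloud.  The both-sensitive monolith absorbs most of each
    # drug's 20% sensitivity quota, so the expected fraction of single-drug
    # quadrant cells is ~0.067 and four leaves per side is decisively
    # over-represented; it itself contributes a single insignificant leaf.
    _DIV_A = [(-6.0, 0.10), (-5.1, 0.50), (-4.2, 0.18), (-3.3, 0.55)]
    _DIV_B = [(-8.0, 0.05), (-7.1, 0.30), (-6.2, 0.08), (-5.3, 0.35)]
    _DIV_HIGH = [2.0, 2.35, 2.15, 2.5]
    div_a = [
        ClusterSpec(n=25, mean=(la, au, lb, 0.88), sd=(0.12, 0.03, 0.12, 0.03),
                    planted_features=_marker(f"DA{k}"), label=f"sens_a_{k}")
        for k, ((la, au), lb) in enumerate(zip(_DIV_A, _DIV_HIGH))
    ]
    div_b = [
        ClusterSpec(n=25, mean=(la, 0.88, lb, au), sd=(0.12, 0.03, 0.12, 0.03),
                    planted_features=_marker(f"DB{k}"), label=f"sens_b_{k}")
        for k, ((lb, au), la) in enumerate(zip(_DIV_B, _DIV_HIGH))
    ]
    # the monolith is shallow (well inside the sensitive half-plane but at
    # a much smaller depth than any shell) and broad, so borderline cells
    # drifting off the resistant cloud attach to its terminal leaf instead
    # of freezing a splittable node via the child-size gate.
    bs_monolith = ClusterSpec(
        n=200, mean=(-2.1, 0.50, -2.1, 0.50), sd=(0.25, 0.04, 0.25, 0.04),
        planted_features=_marker("BSM"), label="sens_both_monolith",
    )
    resistant_1100 = ClusterSpec(
        n=1100, mean=(2.0, 0.9, 2.0, 0.9), sd=(0.25, 0.03, 0.25, 0.03),
        label="resistant",
    )
    divergent = div_a + div_b + [bs_monolith, resistant_1100]

    return {
        "none": spec(none, 1),
        "both_sensitive": spec(both, 2),
        "a_preferential": spec(a_pref, 3),
        "b_preferential": spec(b_pref, 4),
        "divergent": spec(divergent, 5),
    }


#: response type each preset is constructed to produce
PRESET_EXPECTED_TYPE = {
    "none": "none",
    "both_sensitive": "both_sensitive",
    "a_preferential": "a_preferential",
    "b_preferential": "b_preferential",
    "divergent": "divergent",
}


def three_cluster_spec(seed: int = 0, n_per_cluster: int = 100) -> CohortSpec:
    """Three well-separated Gaussian clusters (centres >= 10 within-cluster
    sd apart, non-collinear) with one planted 80%-vs-5% biomarker each —
    the standard parameter-recovery scenario."""
    centers = [
        (-3.0, 0.2, -3.0, 0.2),
        (2.5, 0.9, 0.5, 0.65),
        (0.5, 0.65, 2.5, 0.9),
    ]
    sd = (0.4, 0.04, 0.4, 0.04)
    clusters = [
        ClusterSpec(n=n_per_cluster, mean=c, sd=sd,
                    planted_features=_marker(str(k)), label=f"cluster_{k}")
        for k, c in enumerate(centers)
    ]
    return CohortSpec(clusters=clusters, n_features_total=20, seed=seed)
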