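"""Readers, cohort assembly and standardisation for cell-line drug-response data.

A drug-pair analysis starts from two per-drug response tables (cell line ->
log(IC50), AUC) and an optional binary event matrix (BEM) of somatic
alterations and other binary features.  This module reads those delimited
text files, intersects the cell lines with valid values for both drugs, and
z-scores the four response covariates so that downstream distances are not
dominated by the wide log(IC50) scale.

log(IC50) values are taken as already log-transformed (micromolar scale) and
are never exponentiated; AUC values live in [0, 1] and rows violating that
bound are dropped with a warning.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed column order of the dose-response-profile (DRP) matrix.
LOG_IC50_A, AUC_A, LOG_IC50_B, AUC_B = 0, 1, 2, 3
DRP_COLUMNS = ("log_ic50_a", "auc_a", "log_ic50_b", "auc_b")

FEATURE_CLASSES = ("mutation", "fusion", "amplification", "deletion", "tissue", "pathway")
DEFAULT_FEATURE_CLASS = "mutation"

_RESPONSE_HEADER = {"CELL_LINE_ID": "cell_line_id", "LOG_IC50": "log_ic50", "AUC": "auc"}


def _detect_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


@dataclass
class ResponseTable:
    """Per-drug response measurements keyed by cell-line identifier.

    ``data`` is indexed by cell_line_id with float columns ``log_ic50`` and
    ``auc``; every retained row has finite values and auc in [0, 1].
    """

    drug_id: str
    data: pd.DataFrame
    n_dropped: int = 0

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def read_response_table(path: str | Path, drug_id: str) -> ResponseTable:
    """Read a delimited response table (columns CELL_LINE_ID, LOG_IC50, AUC).

    Rows with missing or unparseable numbers, or AUC outside [0, 1], are
    dropped (counted in ``n_dropped`` and logged).  Duplicate cell-line ids
    are a format error.
    """
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.strip().upper(): c for c in raw.columns}
    missing = [k for k in _RESPONSE_HEADER if k not in cols]
    if missing:
        raise ValueError(
            f"{path}: no recognizable columns; expected header with "
            f"{', '.join(_RESPONSE_HEADER)} (missing {', '.join(missing)})"
        )
    df = pd.DataFrame(
        {
            "cell_line_id": raw[cols["CELL_LINE_ID"]].astype(str).str.strip(),
            "log_ic50": pd.to_numeric(raw[cols["LOG_IC50"]], errors="coerce"),
            "auc": pd.to_numeric(raw[cols["AUC"]], errors="coerce"),
        }
    )
    n_in = len(df)
    df = df.dropna(subset=["log_ic50", "auc"])
    bad_auc = (df["auc"] < 0.0) | (df["auc"] > 1.0)
    if bad_auc.any():
        logger.warning(
            "%s: dropping %d row(s) with AUC outside [0, 1]", path, int(bad_auc.sum())
        )
    df = df[~bad_auc]
    dup = df["cell_line_id"].duplicated()
    if dup.any():
        names = sorted(df.loc[dup, "cell_line_id"].unique())
        raise ValueError(f"{path}: duplicate cell-line ids: {', '.join(names[:5])}")
    df = df.set_index("cell_line_id")
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("%s: dropped %d of %d rows with invalid values", path, n_dropped, n_in)
    return ResponseTable(drug_id=drug_id, data=df, n_dropped=n_dropped)


def write_response_table(table: ResponseTable, path: str | Path, sep: str = "\t") -> None:
    out = table.data.reset_index()
    out.columns = ["CELL_LINE_ID", "LOG_IC50", "AUC"]
    out.to_csv(path, sep=sep, index=False)


@dataclass
class BinaryEventMatrix:
    """Cell lines x binary functional-event features (strictly 0/1).

    ``classes`` maps every feature id to one of mutation / fusion /
    amplification / deletion / tissue / pathway.
    """

    data: pd.DataFrame  # index: cell_line_id, columns: feature_id, values int8 0/1
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("binary event matrix contains values other than 0/1")
        if self.data.columns.duplicated().any():
            raise ValueError("binary event matrix has duplicate feature ids")
        for f in self.data.columns:
            self.classes.setdefault(f, DEFAULT_FEATURE_CLASS)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.classes[f] for f in self.data.columns))


def read_bem(path: str | Path, classes_path: str | Path | None = None) -> BinaryEventMatrix:
    """Read a BEM (first column CELL_LINE_ID, remaining columns 0/1 features).

    Non-binary entries are a validation error naming the offending cell line
    and feature; they are never coerced.  An optional sidecar file with
    columns FEATURE_ID, CLASS assigns feature classes.
    """
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw = raw.set_index(raw.columns[0])
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = ~values.isin([0, 1])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-binary entry {raw.iat[r, c]!r} at cell line "
            f"{raw.index[r]!r}, feature {raw.columns[c]!r}"
        )
    classes: dict[str, str] = {}
    if classes_path is not None:
        side = pd.read_csv(classes_path, sep=_detect_sep(classes_path), dtype=str)
        cols = {c.strip().upper(): c for c in side.columns}
        if "FEATURE_ID" not in cols or "CLASS" not in cols:
            raise ValueError(f"{classes_path}: expected columns FEATURE_ID, CLASS")
        for _, row in side.iterrows():
            cls = row[cols["CLASS"]].strip()
            if cls not in FEATURE_CLASSES:
                raise ValueError(f"{classes_path}: unknown feature class {cls!r}")
            classes[row[cols["FEATURE_ID"]].strip()] = cls
    return BinaryEventMatrix(data=values.astype(np.int8), classes=classes)


def write_bem(bem: BinaryEventMatrix, path: str | Path, classes_path: str | Path | None = None,
              sep: str = "\t") -> None:
    out = bem.data.copy()
    out.index.name = "CELL_LINE_ID"
    out.to_csv(path, sep=sep)
    if classes_path is not None:
        pd.DataFrame(
            {"FEATURE_ID": bem.feature_ids, "CLASS": [bem.classes[f] for f in bem.feature_ids]}
        ).to_csv(classes_path, sep=sep, index=False)


@dataclass
class Cohort:
    """The joint cohort for one drug pair.

    ``drp`` is the N x 4 dose-response-profile matrix with fixed column
    order (log_ic50_A, auc_A, log_ic50_B, auc_B).  After ``standardize``,
    columns are z-scored and the original means/sds are retained so that
    subpopulation summaries can be reported on the measurement scale.
    """

    cell_line_ids: list[str]
    drp: np.ndarray
    drug_a_id: str
    drug_b_id: str
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.cell_line_ids)

    @property
    def original_drp(self) -> np.ndarray:
        """The DRP matrix on the original measurement scale."""
        if not self.standardized:
            return self.drp
        return self.drp * self.column_sds + self.column_means

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_line_ids)}
        return np.array([lookup[c] for c in ids], dtype=np.intp)


def build_cohort(table_a: ResponseTable, table_b: ResponseTable) -> Cohort:
    """Intersect two response tables into the cohort for one drug pair.

    Keeps exactly the cell lines with valid values in both tables; lines
    named the literal string 'NA' are removed (a known identifier artefact).
    """
    common = sorted((set(table_a.data.index) & set(table_b.data.index)) - {"NA"})
    if not common:
        raise ValueError(
            f"no cell lines shared between {table_a.drug_id} and {table_b.drug_id}"
        )
    if len(common) < 2:
        raise ValueError(
            f"only {len(common)} shared cell line(s) between {table_a.drug_id} "
            f"and {table_b.drug_id}; need at least 2 to build a network"
        )
    a = table_a.data.loc[common]
    b = table_b.data.loc[common]
    drp = np.column_stack(
        [a["log_ic50"].to_numpy(), a["auc"].to_numpy(),
         b["log_ic50"].to_numpy(), b["auc"].to_numpy()]
    ).astype(float)
    return Cohort(
        cell_line_ids=list(common), drp=drp,
        drug_a_id=table_a.drug_id, drug_b_id=table_b.drug_id,
    )


def standardize(cohort: Cohort) -> Cohort:
    """Z-score each DRP column over the full cohort (sample sd, ddof=1).

    Constant columns are mapped to 0 with their sd recorded as 0 (warned).
    Applying twice is an error.
    """
    if cohort.standardized:
        raise ValueError("cohort is already standardized")
    if cohort.n < 2:
        raise ValueError("need at least 2 cell lines to standardize")
    means = cohort.drp.mean(axis=0)
    sds = cohort.drp.std(axis=0, ddof=1)
    constant = sds == 0.0
    if constant.any():
        names = [DRP_COLUMNS[i] for i in np.flatnonzero(constant)]
        logger.warning("constant DRP column(s) %s left at 0 after standardization", names)
    safe = np.where(constant, 1.0, sds)
    z = (cohort.drp - means) / safe
    z[:, constant] = 0.0
    return replace(
        cohort, drp=z, standardized=True, column_means=means.copy(), column_sds=sds.copy()
    )
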