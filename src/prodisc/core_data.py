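"""Domain containers and delimited-text I/O for the pan-cancer protein analysis.

The analysis operates on four aligned data sources: a case x protein
expression matrix (RPPA-style normalized levels), somatic-mutation records
in a MAF-like dialect, gene-level copy-number amplification calls, and
per-case annotations (histotype, batch).  Everything downstream assumes the
sources have been restricted to a common, consistently ordered case set via
:func:`align_cases`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Variant classifications that do NOT count as nonsilent under the default
#: rule.  The mutation-calling filter of the original study is not public;
#: this set is configurable wherever it is used.
SILENT_CLASSES = frozenset({"Silent", "Intron", "3'UTR", "5'UTR", "IGR", "RNA"})


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ProteinMatrix:
    """Case x protein real-valued expression matrix.

    Rows are cases, columns are proteins/antibodies (opaque identifiers such
    as ``HER2_pY1248``); values are unitless normalized expression or
    phosphorylation levels.  Missing values are rejected, not imputed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "case identifiers")
        _check_unique(self.data.columns, "protein identifiers")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise ValidationError("protein matrix contains non-numeric columns")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValidationError(f"missing expression values in proteins {bad}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str).str.strip()
        self.data.columns = self.data.columns.astype(str).str.strip()
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_cases(self, cases: Sequence[str]) -> "ProteinMatrix":
        return ProteinMatrix(self.data.loc[list(cases)])


@dataclass
class MutationProfile:
    """Somatic mutation records plus the derived binary case x gene indicator.

    ``records`` columns: case_id, gene_symbol, variant_classification,
    protein_change (stored in normalized short form, leading ``p.``
    stripped).  ``case_ids`` is the set of cases assayed for mutations;
    cases without records are legitimate wild-type cases, so the universe
    cannot be inferred from the records alone.
    """

    records: pd.DataFrame
    case_ids: list[str] = field(default_factory=list)

    REQUIRED = ("case_id", "gene_symbol", "variant_classification", "protein_change")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation table lacks columns {missing}")
        rec = self.records.copy()
        for c in self.REQUIRED:
            rec[c] = rec[c].astype(str).str.strip()
        rec["protein_change"] = normalize_protein_change(rec["protein_change"])
        self.records = rec.reset_index(drop=True)
        if not self.case_ids:
            self.case_ids = sorted(rec["case_id"].unique())
        _check_unique(self.case_ids, "mutation-profile case identifiers")

    def indicator(self, silent_classes: frozenset[str] = SILENT_CLASSES) -> pd.DataFrame:
        """Binary case x gene matrix: True iff >=1 nonsilent record."""
        rec = self.records
        nonsilent = rec[~rec["variant_classification"].isin(silent_classes)]
        ind = pd.crosstab(nonsilent["case_id"], nonsilent["gene_symbol"]).astype(bool)
        genes = sorted(rec["gene_symbol"].unique())
        ind = ind.reindex(index=self.case_ids, columns=genes, fill_value=False)
        ind.index.name = None
        ind.columns.name = None
        return ind

    def subset_cases(self, cases: Sequence[str]) -> "MutationProfile":
        keep = set(cases)
        rec = self.records[self.records["case_id"].isin(keep)]
        return MutationProfile(rec, case_ids=[c for c in cases])


def normalize_protein_change(values: pd.Series) -> pd.Series:
    """Strip the leading ``p.`` so ``p.V600E`` and ``V600E`` compare equal."""
    return values.str.replace(r"^p\.", "", regex=True)


@dataclass
class CnaProfile:
    """Binary case x gene amplification indicator."""

    amplified: pd.DataFrame  # bool, index = case_id, columns = gene

    def __post_init__(self) -> None:
        _check_unique(self.amplified.index, "CNA case identifiers")
        _check_unique(self.amplified.columns, "CNA gene symbols")
        self.amplified = self.amplified.astype(bool)
        self.amplified.index = self.amplified.index.astype(str)
        self.amplified.index.name = None
        self.amplified.columns.name = None

    @property
    def case_ids(self) -> list[str]:
        return list(self.amplified.index)

    def subset_cases(self, cases: Sequence[str]) -> "CnaProfile":
        return CnaProfile(self.amplified.loc[list(cases)])


@dataclass
class Annotations:
    """Per-case histotype and (optional) batch labels.

    Index = case_id; columns ``histotype`` and optionally ``batch_id``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "histotype" not in self.table.columns:
            raise ValidationError("annotations lack a 'histotype' column")
        _check_unique(self.table.index, "annotation case identifiers")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        self.table.index.name = None
        self.table["histotype"] = self.table["histotype"].astype(str)

    @property
    def case_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def histotype(self) -> pd.Series:
        return self.table["histotype"]

    @property
    def batch_id(self) -> pd.Series:
        if "batch_id" not in self.table.columns:
            raise ValidationError("batch screening requested but no batch_id column")
        return self.table["batch_id"]

    def cases_of(self, histotype: str) -> list[str]:
        return list(self.table.index[self.table["histotype"] == histotype])

    def subset_cases(self, cases: Sequence[str]) -> "Annotations":
        return Annotations(self.table.loc[list(cases)])


@dataclass
class ClassAssignment:
    """Mapping case_id -> class label for one named classification."""

    name: str
    labels: pd.Series  # index = case_id, values = class label (str)
    binary: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, f"cases of classification {self.name!r}")
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        self.labels.index.name = None
        self.labels.name = None
        if self.binary and self.labels.nunique() > 2:
            raise ValidationError(
                f"binary classification {self.name!r} has "
                f"{self.labels.nunique()} distinct labels"
            )

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def subset_cases(self, cases: Sequence[str]) -> "ClassAssignment":
        keep = [c for c in cases if c in self.labels.index]
        return ClassAssignment(self.name, self.labels.loc[keep], binary=self.binary)


# ---------------------------------------------------------------------------
# Readers / writers (delimited text; CSV when the path ends in .csv, else TSV)
# ---------------------------------------------------------------------------

def read_protein_matrix(path: str | Path, cases_in: str = "rows") -> ProteinMatrix:
    """Read a delimited expression matrix.

    ``cases_in`` selects the orientation: ``"rows"`` (default, TCPA-style
    cases-in-rows) or ``"columns"`` (transposed on read).
    """
    if cases_in not in ("rows", "columns"):
        raise ValueError("cases_in must be 'rows' or 'columns'")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if cases_in == "columns":
        df = df.T
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric cell(s) in column {col!r}, row(s) {bad.index.tolist()}"
            )
    return ProteinMatrix(df)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep=_sep_for(path))


DEFAULT_MAF_DIALECT: Mapping[str, str] = {
    "case_id": "case_id",
    "gene_symbol": "gene_symbol",
    "variant_classification": "variant_classification",
    "protein_change": "protein_change",
}

#: Column names used by Oncotator-style MAFs.
MAF_DIALECT: Mapping[str, str] = {
    "case_id": "Tumor_Sample_Barcode",
    "gene_symbol": "Hugo_Symbol",
    "variant_classification": "Variant_Classification",
    "protein_change": "Protein_Change",
}


def read_mutation_table(
    path: str | Path,
    dialect: Mapping[str, str] = DEFAULT_MAF_DIALECT,
    case_ids: Sequence[str] | None = None,
) -> MutationProfile:
    """Read a MAF-like delimited mutation table.

    ``dialect`` maps the four canonical fields to the file's column names.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    missing = [v for v in dialect.values() if v not in df.columns]
    if missing:
        raise ValidationError(
            f"mutation table {path} lacks column(s) {missing} required by dialect"
        )
    rec = pd.DataFrame({k: df[v] for k, v in dialect.items()})
    return MutationProfile(rec, case_ids=list(case_ids) if case_ids else [])


def write_mutation_table(profile: MutationProfile, path: str | Path) -> None:
    profile.records.to_csv(path, sep=_sep_for(path), index=False)


def read_cna_table(path: str | Path) -> CnaProfile:
    """Read gene-level amplification calls: columns case_id, gene_symbol, amplified."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("case_id", "gene_symbol", "amplified"):
        if col not in df.columns:
            raise ValidationError(f"CNA table lacks column {col!r}")
    df["amplified"] = df["amplified"].isin(("1", "True", "true", "Y", "yes"))
    wide = df.pivot_table(
        index="case_id", columns="gene_symbol", values="amplified",
        aggfunc="max", fill_value=False,
    ).astype(bool)
    return CnaProfile(wide)


def write_cna_table(profile: CnaProfile, path: str | Path) -> None:
    long = profile.amplified.stack().rename("amplified").reset_index()
    long.columns = ["case_id", "gene_symbol", "amplified"]
    long["amplified"] = long["amplified"].astype(int)
    long.to_csv(path, sep=_sep_for(path), index=False)


def read_annotations(path: str | Path) -> Annotations:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    return Annotations(df)


def write_annotations(annotations: Annotations, path: str | Path) -> None:
    annotations.table.to_csv(path, sep=_sep_for(path), index_label="case_id")


def read_class_assignment(path: str | Path) -> ClassAssignment:
    """Read a class table: columns classification_name, case_id, class."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("classification_name", "case_id", "class"):
        if col not in df.columns:
            raise ValidationError(f"class table lacks column {col!r}")
    names = df["classification_name"].unique()
    if len(names) != 1:
        raise ValidationError(f"class table mixes classifications: {list(names)}")
    labels = df.set_index("case_id")["class"]
    return ClassAssignment(str(names[0]), labels)


def write_class_assignment(assignment: ClassAssignment, path: str | Path) -> None:
    out = pd.DataFrame({
        "classification_name": assignment.name,
        "case_id": assignment.labels.index,
        "class": assignment.labels.values,
    })
    out.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Case alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedData:
    """All sources restricted to the common case set, in one shared order."""

    matrix: ProteinMatrix
    annotations: Annotations
    mutations: MutationProfile | None = None
    cna: CnaProfile | None = None
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def case_ids(self) -> list[str]:
        return self.matrix.case_ids


def align_cases(
    matrix: ProteinMatrix,
    annotations: Annotations,
    mutations: MutationProfile | None = None,
    cna: CnaProfile | None = None,
) -> AlignedData:
    """Restrict every source to the case intersection, in matrix order.

    Cases missing from any provided source are dropped; per-source dropped
    counts are logged and recorded on the result.
    """
    sources: dict[str, Iterable[str]] = {
        "matrix": matrix.case_ids,
        "annotations": annotations.case_ids,
    }
    if mutations is not None:
        sources["mutations"] = mutations.case_ids
    if cna is not None:
        sources["cna"] = cna.case_ids

    common = set(matrix.case_ids)
    for ids in sources.values():
        common &= set(ids)
    if not common:
        raise ValidationError("no case is common to all input sources")
    order = [c for c in matrix.case_ids if c in common]

    dropped = {name: len(set(ids) - common) for name, ids in sources.items()}
    for name, n in dropped.items():
        if n:
            logger.info("align_cases: dropped %d case(s) absent from %s", n, name)

    return AlignedData(
        matrix=matrix.subset_cases(order),
        annotations=annotations.subset_cases(order),
        mutations=mutations.subset_cases(order) if mutations is not None else None,
        cna=cna.subset_cases(order) if cna is not None else None,
        dropped=dropped,
    )
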