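"""Expression-matrix and label-table containers with TSV/CSV ingestion.

The central objects are :class:`ExpressionMatrix` (samples x genes,
non-negative expression values) and :class:`LabelTable` (per-sample cancer
class and sampling site).  Histology codes are harmonized into merged cancer
classes — e.g. lung adenocarcinoma and lung squamous carcinoma both become
the lung class — via an explicit, total code map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical cancer-class tokens for the 15-class cohort, in reporting order.
CANONICAL_CLASSES = [
    "LUNG", "STAD", "COADREAD", "LIHC", "BRCA", "THCA", "CESC", "BRAIN",
    "PAAD", "OV", "UCEC", "BLCA", "KIDNEY", "HNSC", "PRAD",
]

#: Composite spellings accepted as synonyms of the canonical merged tokens.
CLASS_SYNONYMS = {
    "LUAD + LUSC": "LUNG",
    "COAD + READ": "COADREAD",
    "KIRC + KIRP": "KIDNEY",
    "GBM + LGG": "BRAIN",
}

#: Default histology-code map: merged classes plus identity for everything
#: else in the 15-class cohort.  Canonical class tokens map to themselves so
#: harmonization is idempotent.
DEFAULT_CODE_MAP = {
    "LUAD": "LUNG", "LUSC": "LUNG",
    "COAD": "COADREAD", "READ": "COADREAD",
    "KIRC": "KIDNEY", "KIRP": "KIDNEY",
    "GBM": "BRAIN", "LGG": "BRAIN",
    **{c: c for c in CANONICAL_CLASSES},
    **CLASS_SYNONYMS,
}

SITES = ("primary", "metastatic")


def canonical_class(label: str) -> str:
    """Map a class spelling (e.g. ``"COAD + READ"``) to its canonical token."""
    label = str(label).strip()
    return CLASS_SYNONYMS.get(label, label)


def class_order(labels: "LabelTable") -> list[str]:
    """Deterministic class ordering: canonical cohort order when applicable,
    otherwise lexicographic."""
    present = set(labels.class_labels)
    if present <= set(CANONICAL_CLASSES):
        return [c for c in CANONICAL_CLASSES if c in present]
    return sorted(present)


@dataclass
class ExpressionMatrix:
    """Samples-in-rows expression grid with unique sample and gene ids.

    Wraps a :class:`pandas.DataFrame` (index = sample ids, columns = gene
    ids).  Values must be finite and, unless ``require_non_negative`` is
    False (log-scale data), non-negative.
    """

    data: pd.DataFrame
    require_non_negative: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise ValueError(f"non-numeric expression value at {bad}")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing or non-finite value at sample "
                f"{self.data.index[i]!r}, gene {self.data.columns[j]!r}"
            )
        if self.require_non_negative and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value {values[i, j]} at sample "
                f"{self.data.index[i]!r}, gene {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(sample_ids)],
                                require_non_negative=self.require_non_negative)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(gene_ids)],
                                require_non_negative=self.require_non_negative)


def _first_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = coerced.isna() & ~raw_na
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return f"sample {df.index[i]!r}, gene {col!r} (value {df[col].iloc[i]!r})"
    return "unknown cell"


def read_expression_matrix(path, orientation: str = "samples_in_rows") -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Parameters
    ----------
    path
        TSV or CSV file.  The first header field is ``sample_id`` for
        samples-in-rows files or ``gene_id`` for genes-in-rows files.
    orientation
        ``"samples_in_rows"`` or ``"genes_in_rows"``.  The orientation is
        explicit because a tall and a wide matrix cannot be told apart
        reliably; the result is always samples-in-rows.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "genes_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path,
                            orientation: str = "samples_in_rows") -> None:
    """Write a matrix as TSV/CSV (delimiter chosen from the file suffix)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = matrix.data
    if orientation == "genes_in_rows":
        df = df.T
        df.to_csv(path, sep=sep, index_label="gene_id")
    elif orientation == "samples_in_rows":
        df.to_csv(path, sep=sep, index_label="sample_id")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


@dataclass
class LabelTable:
    """Per-sample class label and sampling site (primary or metastatic)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "class_label", "site"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in labels: {dups.tolist()}")
        bad_site = ~self.table["site"].isin(SITES)
        if bad_site.any():
            raise ValueError(
                f"invalid sampling site values: "
                f"{self.table.loc[bad_site, 'site'].unique().tolist()}"
            )

    @classmethod
    def from_records(cls, records) -> "LabelTable":
        return cls(pd.DataFrame(records, columns=["sample_id", "class_label", "site"]))

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def class_labels(self) -> list[str]:
        return self.table["class_label"].tolist()

    @property
    def sites(self) -> list[str]:
        return self.table["site"].tolist()

    def classes(self) -> list[str]:
        return class_order(self)

    def for_samples(self, sample_ids) -> "LabelTable":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return LabelTable(sub)

    def labels_for(self, sample_ids) -> np.ndarray:
        mapping = dict(zip(self.table["sample_id"], self.table["class_label"]))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise KeyError(f"samples without labels: {missing}")
        return np.asarray([mapping[s] for s in sample_ids])


def read_label_table(path) -> LabelTable:
    """Read a TSV with columns sample_id, code (or class_label), site."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "class_label" not in df.columns and "code" in df.columns:
        df = df.rename(columns={"code": "class_label"})
    return LabelTable(df[["sample_id", "class_label", "site"]])


def write_label_table(labels: LabelTable, path) -> None:
    labels.table.to_csv(path, sep="\t", index=False)


def harmonize_labels(raw_labels: pd.DataFrame, code_map: dict | None = None) -> LabelTable:
    """Map raw histology codes to merged cancer classes.

    ``raw_labels`` needs columns sample_id, code, site (``class_label`` is
    accepted for ``code``, making the operation idempotent).  Every code must
    be present in ``code_map``; unknown codes are a hard error rather than a
    silent drop.
    """
    code_map = DEFAULT_CODE_MAP if code_map is None else code_map
    df = raw_labels.copy()
    if "code" not in df.columns and "class_label" in df.columns:
        df = df.rename(columns={"class_label": "code"})
    codes = df["code"].astype(str).str.strip()
    unknown = sorted(set(codes) - set(code_map))
    if unknown:
        raise ValueError(f"unknown histology codes: {unknown}")
    out = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "class_label": codes.map(code_map),
        "site": df["site"].astype(str).str.strip(),
    })
    return LabelTable(out)


def split_by_site(matrix: ExpressionMatrix, labels: LabelTable):
    """Partition into (primary, metastatic) halves of (matrix, labels).

    Every matrix sample must be labeled; the two halves are disjoint and
    exhaustive.  An empty metastatic set is allowed.
    """
    site_of = dict(zip(labels.sample_ids, labels.sites))
    unlabeled = [s for s in matrix.sample_ids if s not in site_of]
    if unlabeled:
        raise ValueError(f"samples without labels: {unlabeled}")
    primary_ids = [s for s in matrix.sample_ids if site_of[s] == "primary"]
    metastatic_ids = [s for s in matrix.sample_ids if site_of[s] == "metastatic"]
    train = (matrix.subset_samples(primary_ids), labels.for_samples(primary_ids))
    test = (matrix.subset_samples(metastatic_ids), labels.for_samples(metastatic_ids))
    return train, test
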