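"""One-vs-rest Pearson-correlation gene ranking and merged panel building.

For each cancer class the sample labels are binarized (1 = focal class),
every gene's expression vector is correlated against that indicator, and
genes are ranked by signed correlation in decreasing order — capturing genes
upregulated in the focal class.  The per-class top-N lists are merged and
de-duplicated into a single gene panel whose expression columns feed the
classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, LabelTable, class_order


def binarize(labels: LabelTable, focal_class: str) -> np.ndarray:
    """0/1 indicator over samples (in label-table order) for ``focal_class``."""
    arr = np.asarray(labels.class_labels)
    if focal_class not in arr:
        raise ValueError(f"focal class {focal_class!r} absent from labels")
    return (arr == focal_class).astype(float)


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    If either vector has zero variance the coefficient is undefined; by
    convention 0.0 is returned with a warning, which keeps constant genes
    out of the top ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        warnings.warn("zero-variance input; returning r = 0", stacklevel=2)
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def correlations_with_indicator(values: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Vectorized per-gene Pearson correlation with a 0/1 class indicator.

    ``values`` is samples x genes.  Zero-variance genes get r = 0 (one
    summary warning).  The indicator must contain both classes.
    """
    indicator = np.asarray(indicator, dtype=float)
    if indicator.min() == indicator.max():
        raise ValueError("indicator is constant; one-vs-rest correlation undefined")
    xc = values - values.mean(axis=0, keepdims=True)
    yc = indicator - indicator.mean()
    gene_ss = np.einsum("ij,ij->j", xc, xc)
    denom = np.sqrt(gene_ss * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / denom
    flat = denom == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance genes assigned r = 0",
                      stacklevel=2)
        r = np.where(flat, 0.0, r)
    return np.clip(r, -1.0, 1.0)


@dataclass
class RankedGeneList:
    """Genes of one class ordered by decreasing correlation (ties: gene id)."""

    class_label: str
    entries: list  # [(gene_id, r), ...] sorted

    def top(self, n: int) -> list[str]:
        if n < 1:
            raise ValueError("n must be >= 1")
        if n > len(self.entries):
            raise ValueError(
                f"requested top {n} genes but only {len(self.entries)} ranked"
            )
        return [g for g, _ in self.entries[:n]]


def rank_order(r: np.ndarray, gene_ids) -> np.ndarray:
    """Indices sorting genes by decreasing r, ties broken by ascending id."""
    return np.lexsort((np.asarray(gene_ids, dtype=object), -np.asarray(r)))


def rank_genes(matrix: ExpressionMatrix, indicator: np.ndarray,
               class_label: str = "") -> RankedGeneList:
    """Rank every gene by its correlation with the class indicator."""
    if len(indicator) != matrix.n_samples:
        raise ValueError("indicator length does not match sample count")
    r = correlations_with_indicator(matrix.values, indicator)
    order = rank_order(r, matrix.gene_ids)
    gene_ids = matrix.gene_ids
    entries = [(gene_ids[i], float(r[i])) for i in order]
    return RankedGeneList(class_label=class_label, entries=entries)


def rank_genes_per_class(matrix: ExpressionMatrix, labels: LabelTable,
                         classes: list[str] | None = None) -> list[RankedGeneList]:
    """One ranked list per class, in deterministic class order."""
    if matrix.sample_ids != labels.sample_ids:
        labels = labels.for_samples(matrix.sample_ids)
    classes = class_order(labels) if classes is None else classes
    values = matrix.values
    out = []
    for cls in classes:
        indicator = binarize(labels, cls)
        r = correlations_with_indicator(values, indicator)
        order = rank_order(r, matrix.gene_ids)
        entries = [(matrix.gene_ids[i], float(r[i])) for i in order]
        out.append(RankedGeneList(class_label=cls, entries=entries))
    return out


@dataclass
class GenePanel:
    """Merged, de-duplicated union of per-class top-N gene lists.

    Order is deterministic: classes in the order their ranked lists were
    given, then rank within class; a gene already contributed by an earlier
    class keeps its first position but records every contributing class.
    """

    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)  # gene_id -> set of classes
    n_per_class: int = 0

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("panel contains duplicate gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id) -> bool:
        return gene_id in self.provenance or gene_id in self.gene_ids


def build_panel(ranked_lists: list[RankedGeneList], n: int) -> GenePanel:
    """Union of per-class top-``n`` genes with duplicates removed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gene_ids: list[str] = []
    provenance: dict[str, set] = {}
    for rl in ranked_lists:
        for gene in rl.top(n):
            if gene not in provenance:
                provenance[gene] = set()
                gene_ids.append(gene)
            provenance[gene].add(rl.class_label)
    return GenePanel(gene_ids=gene_ids, provenance=provenance, n_per_class=n)


def subset_to_panel(matrix: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Column-subset the matrix to the panel genes, in panel order.

    Values are passed through untransformed; no re-normalization happens
    after feature selection.
    """
    missing = [g for g in panel.gene_ids if g not in matrix.data.columns]
    if missing:
        raise KeyError(f"panel genes missing from matrix: {missing}")
    return matrix.subset_genes(panel.gene_ids)


def write_panel(panel: GenePanel, ranked_lists: list[RankedGeneList], path) -> None:
    """Write a panel as TSV (class, rank, gene_id, r) — one row per
    per-class top-N slot, before de-duplication."""
    rows = []
    r_of = {rl.class_label: dict(rl.entries) for rl in ranked_lists}
    for rl in ranked_lists:
        for rank, gene in enumerate(rl.top(panel.n_per_class), start=1):
            rows.append((rl.class_label, rank, gene, r_of[rl.class_label][gene]))
    pd.DataFrame(rows, columns=["class", "rank", "gene_id", "r"]).to_csv(
        path, sep="\t", index=False)


def read_panel(path) -> GenePanel:
    """Read a per-class panel table (class, rank, gene_id[, r]) and merge it."""
    df = pd.read_csv(path, sep="\t")
    # preserve the class order of first appearance in the file
    first_seen = {c: i for i, c in enumerate(dict.fromkeys(df["class"]))}
    df = df.assign(_cls=df["class"].map(first_seen))
    df = df.sort_values(["_cls", "rank"], kind="stable")
    gene_ids: list[str] = []
    provenance: dict[str, set] = {}
    for cls, gene in zip(df["class"], df["gene_id"]):
        if gene not in provenance:
            provenance[gene] = set()
            gene_ids.append(gene)
        provenance[gene].add(cls)
    n = int(df.groupby("class")["gene_id"].count().max())
    return GenePanel(gene_ids=gene_ids, provenance=provenance, n_per_class=n)
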