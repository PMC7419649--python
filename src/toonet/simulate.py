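"""Synthetic bulk expression cohorts with planted tissue-of-origin markers.

The generator emulates the statistical structure the pipeline relies on,
without any download:

* C cancer classes with unequal sample counts (defaults follow the relative
  sizes of the 15-class cohort, scaled to a desk-size total of 750);
* a small disjoint set of marker genes per class whose mean expression is
  multiplied by ``marker_effect`` (default 8x) in their own class only;
* many uninformative background genes with log-normal expression;
* per-sample library-size variation (log-normal, CV 0.2 by default);
* a held-out "metastatic" set drawn from a subset of classes with the
  marker effect attenuated (default 0.5x on the log scale factor), emulating
  the weaker, site-shifted signal of metastatic biopsies.

Expression is continuous and log-normal, matching normalized RNA-seq
values consumed downstream; a negative-binomial count mode is available for
count-like data.  Everything is a pure function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CANONICAL_CLASSES, ExpressionMatrix, LabelTable

#: Relative class sizes of the 15-class reference cohort (primary tumors).
_COHORT_COUNTS = {
    "LUNG": 914, "STAD": 415, "COADREAD": 604, "LIHC": 294, "BRCA": 1056,
    "THCA": 500, "CESC": 258, "BRAIN": 529, "PAAD": 142, "OV": 261,
    "UCEC": 516, "BLCA": 301, "KIDNEY": 748, "HNSC": 480, "PRAD": 379,
}

#: Class composition of the reference metastatic test set (20 samples).
_METASTATIC_COUNTS = {"BRCA": 7, "CESC": 2, "COADREAD": 1, "HNSC": 2, "THCA": 8}


def _scaled_counts(counts: list[int], total: int) -> list[int]:
    """Largest-remainder scaling of integer counts to a new total."""
    counts = np.asarray(counts, dtype=float)
    raw = counts / counts.sum() * total
    out = np.floor(raw).astype(int)
    remainder = raw - out
    for i in np.argsort(-remainder)[: total - out.sum()]:
        out[i] += 1
    return out.tolist()


@dataclass
class SimulationConfig:
    """Generator parameters.

    ``samples_per_class=None`` means: for the 15-class default, the
    reference cohort's relative sizes scaled to 750 samples (about 50 per
    class on average, range ~14-107); otherwise 50 per class.
    """

    n_classes: int = 15
    samples_per_class: list[int] | None = None
    n_genes: int = 2000
    markers_per_class: int = 10
    marker_effect: float = 8.0       # fold-change on the marker mean, own class only
    background_log_mean: float = 1.0  # mean of per-gene baseline log-expression
    background_log_sd: float = 1.0    # spread of per-gene baselines
    noise_log_sd: float = 0.7         # within-gene biological noise (log scale)
    library_size_cv: float = 0.2
    metastatic_n: int = 20
    metastatic_attenuation: float = 0.5
    metastatic_composition: dict | None = None
    count_mode: bool = False
    nb_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_genes < 1 or self.markers_per_class < 0:
            raise ValueError("counts must be positive")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError(
                f"{self.markers_per_class} markers x {self.n_classes} classes "
                f"exceed {self.n_genes} genes")
        if self.marker_effect <= 0:
            raise ValueError("marker_effect must be positive")
        if not (0 < self.metastatic_attenuation <= 1):
            raise ValueError("metastatic_attenuation must be in (0, 1]")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be non-negative")

    def class_names(self) -> list[str]:
        if self.n_classes == 15:
            return list(CANONICAL_CLASSES)
        if self.n_classes < 15:
            return list(CANONICAL_CLASSES[: self.n_classes])
        return [f"CLS{i + 1:02d}" for i in range(self.n_classes)]

    def class_sizes(self) -> list[int]:
        if self.samples_per_class is not None:
            if len(self.samples_per_class) != self.n_classes:
                raise ValueError("samples_per_class length != n_classes")
            return list(self.samples_per_class)
        if self.n_classes == 15:
            return _scaled_counts([_COHORT_COUNTS[c] for c in CANONICAL_CLASSES], 750)
        return [50] * self.n_classes


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort: per-class marker genes plus
    the per-gene baselines needed to draw matched metastatic samples."""

    classes: list[str]
    markers: dict                     # class -> list of marker gene_ids
    gene_ids: list[str] = field(repr=False)
    gene_log_means: np.ndarray = field(repr=False, default=None)

    def all_markers(self) -> list[str]:
        return [g for c in self.classes for g in self.markers[c]]


def _library_factors(rng, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def _draw_block(rng, log_means: np.ndarray, cfg: SimulationConfig,
                lib: np.ndarray) -> np.ndarray:
    """len(lib) samples x genes from the log-normal (or NB count) model.

    Library-size factors scale each sample's mean; in count mode they enter
    the negative-binomial mean so the output stays integer."""
    n = lib.size
    log_x = rng.normal(loc=log_means[None, :], scale=cfg.noise_log_sd,
                       size=(n, log_means.size))
    mean = np.exp(log_x) * lib[:, None]
    if not cfg.count_mode:
        return mean
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mean / shape)
    return rng.poisson(lam).astype(float)


def simulate(cfg: SimulationConfig | None = None):
    """Generate (ExpressionMatrix, LabelTable, GroundTruth) for the primary
    cohort.  Fully determined by ``cfg.seed``."""
    cfg = SimulationConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed)
    classes = cfg.class_names()
    sizes = cfg.class_sizes()
    n_samples = sum(sizes)
    width = len(str(cfg.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]

    # per-gene baseline log-expression
    gene_log_means = rng.normal(cfg.background_log_mean, cfg.background_log_sd,
                                size=cfg.n_genes)
    # disjoint marker blocks, placed at random gene positions
    marker_pos = rng.permutation(cfg.n_genes)[: cfg.markers_per_class * cfg.n_classes]
    markers = {
        cls: [gene_ids[j] for j in
              marker_pos[i * cfg.markers_per_class:(i + 1) * cfg.markers_per_class]]
        for i, cls in enumerate(classes)
    }

    log_effect = np.log(cfg.marker_effect)
    lib = _library_factors(rng, n_samples, cfg.library_size_cv)
    blocks, sample_ids, label_rows = [], [], []
    offset = 0
    for i, (cls, size) in enumerate(zip(classes, sizes)):
        shifted = gene_log_means.copy()
        pos = marker_pos[i * cfg.markers_per_class:(i + 1) * cfg.markers_per_class]
        shifted[pos] += log_effect
        blocks.append(_draw_block(rng, shifted, cfg, lib[offset:offset + size]))
        for j in range(size):
            sid = f"S{offset + j + 1:04d}"
            sample_ids.append(sid)
            label_rows.append((sid, cls, "primary"))
        offset += size

    values = np.vstack(blocks)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=sample_ids,
                                           columns=gene_ids))
    labels = LabelTable.from_records(label_rows)
    truth = GroundTruth(classes=classes, markers=markers, gene_ids=gene_ids,
                        gene_log_means=gene_log_means)
    return matrix, labels, truth


def simulate_metastatic(cfg: SimulationConfig, truth: GroundTruth):
    """Generate the attenuated-signal metastatic test set.

    Samples come from ``cfg.metastatic_composition`` (class -> count);
    the default mirrors the reference metastatic set when those classes
    exist, otherwise spreads ``metastatic_n`` over the first five classes.
    Marker means are elevated by ``marker_effect ** metastatic_attenuation``
    rather than the full effect, weakening but not erasing the class signal.
    """
    cfg = cfg if cfg is not None else SimulationConfig()
    if cfg.metastatic_n == 0:
        empty = pd.DataFrame(np.empty((0, len(truth.gene_ids))),
                             columns=truth.gene_ids, index=pd.Index([], dtype=object))
        return (ExpressionMatrix(empty),
                LabelTable(pd.DataFrame(columns=["sample_id", "class_label", "site"])))

    composition = cfg.metastatic_composition
    if composition is None:
        if set(_METASTATIC_COUNTS) <= set(truth.classes):
            composition = dict(_METASTATIC_COUNTS)
            scale = cfg.metastatic_n / sum(composition.values())
            if scale != 1.0:
                counts = _scaled_counts(list(composition.values()), cfg.metastatic_n)
                composition = dict(zip(composition.keys(), counts))
        else:
            subset = truth.classes[: min(5, len(truth.classes))]
            counts = _scaled_counts([1] * len(subset), cfg.metastatic_n)
            composition = dict(zip(subset, counts))
    unknown = sorted(set(composition) - set(truth.classes))
    if unknown:
        raise ValueError(f"metastatic classes not in the cohort: {unknown}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    gene_index = {g: j for j, g in enumerate(truth.gene_ids)}
    log_effect = np.log(cfg.marker_effect) * cfg.metastatic_attenuation

    total = sum(int(composition.get(c, 0)) for c in truth.classes)
    lib = _library_factors(rng, total, cfg.library_size_cv)
    blocks, sample_ids, label_rows = [], [], []
    offset = 0
    for cls in truth.classes:           # deterministic class order
        size = int(composition.get(cls, 0))
        if size == 0:
            continue
        shifted = truth.gene_log_means.copy()
        pos = [gene_index[g] for g in truth.markers[cls]]
        shifted[pos] += log_effect
        blocks.append(_draw_block(rng, shifted, cfg, lib[offset:offset + size]))
        for j in range(size):
            sid = f"M{offset + j + 1:04d}"
            sample_ids.append(sid)
            label_rows.append((sid, cls, "metastatic"))
        offset += size

    values = np.vstack(blocks)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=sample_ids,
                                           columns=truth.gene_ids))
    return matrix, LabelTable.from_records(label_rows)


def write_truth(truth: GroundTruth, path) -> None:
    rows = [(cls, g) for cls in truth.classes for g in truth.markers[cls]]
    pd.DataFrame(rows, columns=["class", "marker_gene"]).to_csv(
        path, sep="\t", index=False)
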