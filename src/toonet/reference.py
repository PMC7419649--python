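"""Published reference results for the 15-class TCGA cohort, bundled as
plain-text tables.

These are the original study's printed numbers — cohort composition,
per-class sensitivity/precision of the 150-gene neural-network classifier,
the 15 x 10 signature-gene grid, and the per-sample predictions on the
20-sample metastatic test set.  They serve as worked examples and as fixed
inputs for validating the package's scoring arithmetic; nothing here is
recomputed from raw TCGA data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .feature_selection import GenePanel, read_panel
from .io import DEFAULT_CODE_MAP, canonical_class


def _path(name: str):
    return resources.files("toonet").joinpath("data", name)


def load_cohort_counts() -> pd.DataFrame:
    """Cohort summary: site, cancer type, histology code(s), sample count,
    printed percentage of the site total."""
    with resources.as_file(_path("cohort_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reported_metrics() -> pd.DataFrame:
    """Per-class sensitivity and precision (percent) of the reference
    150-gene neural-network classifier."""
    with resources.as_file(_path("reported_metrics.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_metastatic_predictions() -> pd.DataFrame:
    """The 20 metastatic samples with both models' predicted classes and the
    true label, exactly as printed (including composite class spellings)."""
    with resources.as_file(_path("metastatic_predictions.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_signature_panel() -> GenePanel:
    """The published 15-class x top-10 signature grid, merged into a panel."""
    with resources.as_file(_path("signature_panel.tsv")) as p:
        return read_panel(p)


def load_signature_table() -> pd.DataFrame:
    """The signature grid in long form: class, rank, gene_id."""
    with resources.as_file(_path("signature_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def cohort_class_share(cancer_type: str, site: str = "primary",
                       total: int | None = None) -> float:
    """Percentage share of one cancer type within a sampling site.

    ``total`` defaults to the site's printed total (7,460 primary /
    20 metastatic), which is what the printed percentages are computed
    against.
    """
    df = load_cohort_counts()
    sub = df[df["site"] == site]
    if total is None:
        total = {"primary": 7460, "metastatic": 20}[site]
    count = sub.loc[sub["cancer_type"] == cancer_type, "sample_size"]
    if count.empty:
        raise KeyError(f"no {cancer_type!r} row for site {site!r}")
    return float(count.iloc[0]) / total * 100.0


def canonical_code_for(composite: str) -> str:
    """Canonical class token for a printed code string like 'GBM + LGG'."""
    token = canonical_class(composite)
    return DEFAULT_CODE_MAP.get(token, token)
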