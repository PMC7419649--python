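import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import toonet as tn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_matrix():
    """3 samples x 4 genes with simple integer values."""
    df = pd.DataFrame(
        [[2.0, 3.0, 5.0, 0.0],
         [1.0, 1.0, 1.0, 1.0],
         [0.0, 4.0, 2.0, 8.0]],
        index=["s1", "s2", "s3"],
        columns=["gA", "gB", "gC", "gD"])
    return tn.ExpressionMatrix(df)


@pytest.fixture()
def tiny_labels():
    return tn.LabelTable.from_records([
        ("s1", "BRCA", "primary"),
        ("s2", "LUNG", "primary"),
        ("s3", "BRCA", "metastatic")])


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 5-class cohort with strong planted markers, normalized."""
    cfg = tn.SimulationConfig(
        n_classes=5, samples_per_class=[24] * 5, n_genes=300,
        markers_per_class=4, marker_effect=8.0, seed=7)
    matrix, labels, truth = tn.simulate(cfg)
    return tn.normalize_by_sample_sum(matrix), labels, truth, cfg
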