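import numpy as np
import pandas as pd
import pytest

import implinet as im


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort (60 genes, 40 samples/condition)."""
    return im.generate_cohort(im.default_spec(seed=1))


@pytest.fixture(scope="session")
def cohort_networks(default_cohort):
    """GAIN/DIS expression implication networks at the toy-scale s = 3."""
    expr = im.log2_tpm(default_cohort.expression)
    gain, dis = im.split_groups(
        expr, default_cohort.sample_info, default_cohort.comparison
    )["GAIN_vs_DIS"]
    return (
        im.infer_network(gain, s_threshold=3.0),
        im.infer_network(dis, s_threshold=3.0),
    )


@pytest.fixture(scope="session")
def toy_fixtures():
    return im.generate_toy_multilayer()


@pytest.fixture
def expr_matrix():
    """4x3 raw expression matrix with known TPM values."""
    values = pd.DataFrame(
        {"g1": [1.0, 0.0, 3.0, 7.0], "g2": [3.0, 3.0, 1.0, 1.0], "g3": [0.0, 1.0, 0.0, 1.0]},
        index=["s1", "s2", "s3", "s4"],
    )
    return im.FeatureMatrix(values=values, modality="expression", scale="raw")


def bimodal_matrix(rng, n_features, n_samples, copies=None):
    """Random bimodal matrix; ``copies`` maps feature index -> source index."""
    states = rng.integers(0, 2, size=(n_samples, n_features))
    if copies:
        for dst, src in copies.items():
            states[:, dst] = states[:, src]
    vals = np.where(states == 1, 8.0, 2.0) + rng.normal(0, 0.25, states.shape)
    return im.FeatureMatrix(
        values=pd.DataFrame(
            vals,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"f{i:02d}" for i in range(n_features)],
        ),
        modality="expression",
        scale="log2tpm",
    )
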