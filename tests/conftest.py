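import warnings

import numpy as np
import pandas as pd
import pytest

import dbupipe.preprocess as prep
import dbupipe.synthetic_data as synth
from dbupipe.iohub import ExpressionTable, PhenotypeTable


@pytest.fixture(scope="session")
def discovery_bundle():
    return synth.generate_discovery_surrogate(1)


@pytest.fixture(scope="session")
def adjusted_discovery(discovery_bundle):
    """ComBat-adjusted gene-level discovery matrix + batch series."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adjusted, batch = prep.preprocess_bundle(
            discovery_bundle.expression,
            discovery_bundle.phenotype,
            discovery_bundle.annotation,
        )
    return adjusted, batch


@pytest.fixture(scope="session")
def small_consensus(adjusted_discovery):
    """A 25-iteration ensemble run on the adjusted discovery surrogate."""
    import dbupipe.ensemble as ens

    adjusted, _ = adjusted_discovery
    return ens.run_ensemble(
        adjusted,
        ens.UmapParams(),
        ens.DbscanParams(eps=None, min_pts=5),
        ens.EnsembleConfig(n_iterations=25, seed=11),
    )


@pytest.fixture
def toy_expression():
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionTable(data)


@pytest.fixture
def toy_phenotype():
    return PhenotypeTable(
        pd.DataFrame(
            {"histology": ["chRCC", "RO"], "batch": ["b1", "b1"]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )


def two_blob_coords(rng: np.random.Generator | None = None):
    """Two blobs of 10 points: intra-distance <= 1, inter-distance >= 10."""
    rng = rng or np.random.default_rng(0)
    a = rng.uniform(-0.3, 0.3, size=(10, 2))
    b = rng.uniform(-0.3, 0.3, size=(10, 2)) + np.array([20.0, 0.0])
    return np.vstack([a, b])
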