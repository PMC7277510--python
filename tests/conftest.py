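import dataclasses

import numpy as np
import pandas as pd
import pytest

import moxnose as mx
from moxnose.simulate import AcquisitionProtocol, GeneratorParams


@pytest.fixture(scope="session")
def small_manifest():
    """Balanced custom design: 9 replicas per leaf cell plus zero-rind rows."""
    recs = []
    for seas in ("M12", "M24"):
        recs.append(dict(seasoning=seas, process="NONE", rind_pct=0, n=9))
        for proc in ("WR", "SR"):
            for pct in (16, 20, 45):
                recs.append(dict(seasoning=seas, process=proc, rind_pct=pct, n=9))
    return mx.build_manifest("custom", counts=pd.DataFrame(recs))


@pytest.fixture(scope="session")
def small_dataset(small_manifest):
    return mx.simulate_dataset(small_manifest, seed=0)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return mx.extract_table(small_dataset)


@pytest.fixture(scope="session")
def published_features():
    """Feature table of a full published-design-sized synthetic campaign."""
    manifest = mx.build_manifest("published_counts")
    dataset = mx.simulate_dataset(manifest, seed=0)
    return mx.extract_table(dataset)


@pytest.fixture(scope="session")
def noise_free_params():
    return dataclasses.replace(
        GeneratorParams.default(), noise_sd=0.0, replica_cv=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
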