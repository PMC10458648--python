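import numpy as np
import pytest

from lodgetex import synth


@pytest.fixture
def gaussian_table():
    """Factory for small class-conditional Gaussian tables."""

    def make(counts=None, m=4, separation=3.0, seed=0):
        counts = counts or {"NL": 40, "ML": 20, "HL": 15, "SL": 10}
        means, covs = synth.gaussian_table_spec(m, separation=separation)
        return synth.generate_feature_table(counts, means, covs, seed=seed)

    return make


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full small-scale pipeline run (images -> reports), shared by the
    end-to-end assertions."""
    from lodgetex import pipeline

    out = tmp_path_factory.mktemp("run") / "e2e"
    cfg = pipeline.RunConfig(seed=7, out_dir=out)
    return pipeline.run_pipeline(cfg)
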