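import pytest

from cpdaa.pipeline import run_pipeline
from cpdaa.simulate import SimConfig, write_fixture_bundle


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default seeded fixture bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle") / "b"
    cfg = SimConfig(seed=11)
    manifest = write_fixture_bundle(cfg, outdir)
    return {"dir": outdir, "config": cfg, "manifest": manifest}


@pytest.fixture(scope="session")
def pipeline_results(default_bundle):
    """Full pipeline results on the default bundle."""
    return run_pipeline(default_bundle["dir"])
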