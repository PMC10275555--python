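import numpy as np
import pytest
from hypothesis import settings

from sleeparousal.pipeline import PipelineConfig, run_pipeline
from sleeparousal.signal_model import SynthConfig, generate_record

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_record():
    """A 60 s synthetic record with two arousal events."""
    cfg = SynthConfig(duration_s=60.0, fs=200.0, n_arousal_events=2, seed=7)
    record, annotation = generate_record(cfg)
    return cfg, record, annotation


@pytest.fixture(scope="session")
def e2e_report():
    """One full default-configuration pipeline run, shared across tests."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
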