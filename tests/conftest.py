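import numpy as np
import pytest

from crestrack.config import AnalysisConfig, ImagingConfig, SimulationConfig
from crestrack.lineage import LineageForest
from crestrack.simulate import build_embryo_model, simulate_populations


def coarse_config(**kw) -> SimulationConfig:
    """Default study conditions on the 300-frame grid (dt = 240 s)."""
    kw.setdefault("dt_s", 240.0)
    kw.setdefault("seed", 0)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def default_truth():
    cfg = coarse_config()
    model = build_embryo_model(cfg)
    return model, simulate_populations(model, cfg)


@pytest.fixture(scope="session")
def default_forest(default_truth):
    model, truth = default_truth
    return model, truth, LineageForest.from_truth(truth)


@pytest.fixture(scope="session")
def imaging_config():
    return ImagingConfig()


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()
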