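import numpy as np
import pytest

from soiln2o import derive as dv
from soiln2o import pipeline
from soiln2o.params import GeneratorConfig, SimParams


@pytest.fixture(scope="session")
def cfg():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def params():
    return SimParams()


@pytest.fixture(scope="session")
def small_world(cfg, params):
    """A 40-point world over 3 years, with derived inputs: the shared
    substrate for fast simulator-level tests."""
    points, stats, weathers = pipeline.generate_world(40, seed=11, cfg=cfg,
                                                      n_years=3)
    kept, removed = dv.filter_by_soc(points, cfg.soc_exclude_threshold)
    derived = pipeline.derive_all(kept, stats, params, seed=11, n_years=3)
    return dict(points=kept, removed=removed, stats=stats,
                weathers=weathers, derived=derived)


@pytest.fixture(scope="session")
def small_results(small_world, params):
    return pipeline.simulate_cohort(small_world["points"],
                                    small_world["derived"],
                                    small_world["weathers"], params)
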