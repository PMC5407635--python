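"""Shared setup for the numbered analysis drivers.

Each driver rebuilds the stages it needs from the same seed, so the
scripts can run independently (and in any order) while describing one
consistent synthetic world: 1000 survey points, 12 regions in 3
countries, 2009-2014 daily weather, defaults everywhere else.
"""

from __future__ import annotations

import argparse
import os

from soiln2o import derive as dv
from soiln2o import pipeline
from soiln2o.params import GeneratorConfig, SimParams

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def parse_args(description: str, **extra):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-points", type=int, default=1000)
    for name, (typ, default, help_) in extra.items():
        ap.add_argument(f"--{name}", type=typ, default=default, help=help_)
    return ap.parse_args()


def out_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def build_world(seed: int, n_points: int, n_years: int = 6):
    cfg = GeneratorConfig()
    params = SimParams()
    points, stats, weathers = pipeline.generate_world(
        n_points, seed, cfg, n_years=n_years)
    kept, removed = dv.filter_by_soc(points, cfg.soc_exclude_threshold)
    return dict(cfg=cfg, params=params, points=kept, removed=removed,
                stats=stats, weathers=weathers, n_years=n_years)


def build_derived(world, seed: int):
    return pipeline.derive_all(world["points"], world["stats"],
                               world["params"], seed,
                               n_years=world["n_years"])
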