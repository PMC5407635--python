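#!/usr/bin/env python
"""Train the random-forest meta-model on the simulated cohort.

Builds the 12-predictor table (clay, sand, SOC stock, PTR, pH, N-org,
N-min, N deposition, NPP, MxAT, MnAT, rain), splits 75/25, fits 500
bagged trees, and reports RMSE, variance explained and %IncMSE
permutation importance.
"""

import sys, os
sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from common import build_derived, build_world, out_path, parse_args
from soiln2o import emulate as em
from soiln2o import pipeline


def main():
    args = parse_args(__doc__)
    world = build_world(args.seed, args.n_points)
    derived = build_derived(world, args.seed)
    results = pipeline.simulate_cohort(world["points"], derived,
                                       world["weathers"], world["params"])
    table = em.build_table(world["points"], derived, results,
                           world["weathers"])
    table.to_csv(out_path("meta_table.csv"), index=False)

    train, test = em.split(table, 0.75, args.seed)
    model = em.fit(train, em.RFHyper(seed=args.seed))
    rmse_tr, _ = em.evaluate(model, train)
    rmse_te, ve = em.evaluate(model, test)
    imp = em.importance(model, test, n_permutations=5, seed=args.seed)
    report = em.EmulatorReport(variance_explained=ve, rmse_train=rmse_tr,
                               rmse_test=rmse_te, importance=imp)
    report.validate()
    report.to_json(out_path("emulator_report.json"))

    print(f"records: {len(table)} ({len(train)} train / {len(test)} test)")
    print(f"variance explained (held out): {ve:.1f}%")
    print(f"RMSE train/test: {rmse_tr:.2f} / {rmse_te:.2f} kg N/ha/yr")
    ranked = sorted(imp.items(), key=lambda kv: -kv[1])
    print("top predictors (%IncMSE): "
          + ", ".join(f"{k} {v:.0f}%" for k, v in ranked[:4]))
    print(f"least important: {ranked[-1][0]} ({ranked[-1][1]:.1f}%)")
    print("wrote results/meta_table.csv, results/emulator_report.json")


if __name__ == "__main__":
    main()
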