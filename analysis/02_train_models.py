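#!/usr/bin/env python
"""Split, impute, and compare the seven candidate learners.

Splits the simulated cohort 60/40 into development and testing sets,
fits the chained-equations imputer on the development set only, then
cross-validates all seven learner kinds (5-fold) on the questionnaire
features and writes the bake-off table. The boosted-tree learner is
expected to lead, and is the one carried forward.
"""

import sys
from pathlib import Path

import pandas as pd

from dmscreen.io import log_event, read_population, write_population
from dmscreen.riskmodels import LEARNER_KINDS, cross_validate, impute
from dmscreen.synthpop import split_dev_test

SEED = 20221128
OUT = Path("results")
SCRATCH = Path("scratch")  # large intermediates, not part of the reported tables
FEATURES = ["age", "rpr", "sbp", "dbp", "weight", "height", "wc", "hc",
            "bmi", "whr", "whtr", "sleep_duration", "cellphone_years",
            "sex", "smoke", "drink", "physical_activity", "work_status",
            "education"]


def main() -> int:
    pop = read_population(SCRATCH / "cohort.csv")
    dev, test = split_dev_test(pop, 0.6, seed=SEED + 2)
    log_event("INFO", "split", f"dev={len(dev)} test={len(test)}")
    dev, test = impute(dev, test, seed=SEED + 3)
    write_population(dev, SCRATCH / "dev.csv")
    write_population(test, SCRATCH / "test.csv")

    rows = []
    for learner in LEARNER_KINDS:
        cv = cross_validate(dev, learner, FEATURES, k=5, seed=SEED + 4, n_boot=200)
        rows.append({"learner": learner,
                     "auc": cv["pooled_auc"], "auc_lo": cv["auc_ci95"][0],
                     "auc_hi": cv["auc_ci95"][1],
                     "aupr": cv["pooled_aupr"], "aupr_lo": cv["aupr_ci95"][0],
                     "aupr_hi": cv["aupr_ci95"][1]})
        log_event("INFO", "bakeoff",
                  f"{learner}: AUC {rows[-1]['auc']:.3f} "
                  f"[{rows[-1]['auc_lo']:.3f}-{rows[-1]['auc_hi']:.3f}] "
                  f"auPR {rows[-1]['aupr']:.3f}")
    table = pd.DataFrame(rows).sort_values("auc", ascending=False)
    table.to_csv(OUT / "model_bakeoff.csv", index=False)
    log_event("INFO", "bakeoff", f"best learner: {table.iloc[0]['learner']}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
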