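#!/usr/bin/env python
"""Concordance between the rapid test and the 9-item reference test.

On the simulated normosmic group: (a) flower mode — reference item #9 vs the
rapid test's first identification attempt; (b) full mode — reference
binarized category vs the rapid test's overall criterion.  Each mode reports
the 2x2 cells, the concordance proportion, and the Yates two-proportion test
on the marginal pass rates.  Also re-runs the published marginals
(143/148 vs 136/148 -> X2 = 2.25).

Writes results/concordance.json.
"""

import json
from pathlib import Path

from scentinel.concordance import (
    compare_pass_proportions,
    concordance_from_cohort,
    mcnemar_test,
)
from scentinel.io import read_cohort
from scentinel.proportions import two_prop_test_yates

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    normosmic = cohort[cohort["group"] == "normosmic"]
    report: dict = {}

    printed = two_prop_test_yates(143, 148, 136, 148)
    report["printed_marginals"] = {
        "chi2": round(printed.statistic, 2), "df": printed.df,
        "p": printed.p_value,
    }
    print(f"published marginals 143/148 vs 136/148: X2={printed.statistic:.2f}")

    for mode in ("flower", "full"):
        table = concordance_from_cohort(normosmic, mode)
        test = compare_pass_proportions(table)
        mc_stat, mc_p = mcnemar_test(table)
        report[mode] = {
            "cells": {"pass_pass": table.pass_pass,
                      "reference_only": table.a_only,
                      "rapid_only": table.b_only,
                      "fail_fail": table.fail_fail},
            "n": table.n,
            "concordance": table.concordance,
            "discordant": table.discordant,
            "marginal_chi2": test.statistic, "marginal_p": test.p_value,
            "mcnemar_p": mc_p,
        }
        print(f"{mode}: concordance {table.concordance:.3f} "
              f"({table.discordant}/{table.n} discordant), "
              f"marginal X2={test.statistic:.2f} p={test.p_value:.2f}")

    (OUT / "concordance.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT / 'concordance.json'}")


if __name__ == "__main__":
    main()
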