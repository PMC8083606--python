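#!/usr/bin/env python
"""Group comparisons of pass proportions: chi-square tests and Bayes factors.

Two parts: (1) the fixed published counts — detection 49/111, 33/42, 142/154
and intensity 15/111, 30/42, 154/154 — which reproduce the reported
chi-square statistics (76.32 and 212.52, df=2), plus the concordance
marginals 143/148 vs 136/148 (Yates X2 = 2.25); (2) the same statistics
recomputed on the simulated cohort from 02_simulate_cohort.py.

Writes results/group_proportions.json.
"""

import json
from pathlib import Path

from scentinel.io import read_cohort
from scentinel.proportions import (
    bf_k_proportions,
    group_pass_summary,
    k_sample_prop_test,
    two_prop_test_yates,
)

OUT = Path(__file__).resolve().parent.parent / "results"

PRINTED_COUNTS = {
    "detection": ((49, 33, 142), (111, 42, 154)),
    "intensity": ((15, 30, 154), (111, 42, 154)),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    report: dict = {"printed_counts": {}, "simulated_cohort": {}}

    for name, (s, n) in PRINTED_COUNTS.items():
        res = k_sample_prop_test(s, n)
        bf = bf_k_proportions(s, n)
        report["printed_counts"][name] = {
            "successes": s, "totals": n,
            "chi2": round(res.statistic, 2), "df": res.df, "p": res.p_value,
            "bf10_independent_binomial": bf.bf10,
        }
        print(f"{name}: X2={res.statistic:.2f} df={res.df} "
              f"BF10={bf.bf10:.3g}")

    yates = two_prop_test_yates(143, 148, 136, 148)
    report["printed_counts"]["identification_concordance"] = {
        "chi2": round(yates.statistic, 2), "df": yates.df, "p": yates.p_value,
    }
    print(f"reference vs rapid identification: X2={yates.statistic:.2f} "
          f"p={yates.p_value:.2f}")

    cohort_path = OUT / "cohort.csv"
    if cohort_path.exists():
        cohort = read_cohort(cohort_path)
        summary = group_pass_summary(cohort)
        groups = ["anosmic", "other", "normosmic"]
        for subtest in summary.index:
            s = [int(summary.loc[subtest, f"{g}_n"]) for g in groups]
            n = [int(summary.loc[subtest, f"{g}_total"]) for g in groups]
            res = k_sample_prop_test(s, n)
            bf = bf_k_proportions(s, n)
            report["simulated_cohort"][subtest] = {
                "successes": s, "totals": n,
                "chi2": round(res.statistic, 2), "p": res.p_value,
                "bf10": bf.bf10,
            }
            print(f"simulated {subtest}: {s}/{n} X2={res.statistic:.2f} "
                  f"BF10={bf.bf10:.3g}")
    else:
        print("no simulated cohort found; run 02_simulate_cohort.py first")

    (OUT / "group_proportions.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT / 'group_proportions.json'}")


if __name__ == "__main__":
    main()
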