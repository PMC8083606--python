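"""Agreement between the rapid test and the 9-item reference test.

Two comparison modes on the same respondents:

* ``flower`` — single-odor identification: the reference test's item #9
  (flower) correct vs the rapid test's first identification attempt correct;
* ``full`` — whole-test outcomes: the reference test's binarized category
  (normosmia = total >= 5) vs the rapid test's overall accuracy criterion.

Concordance is the proportion of respondents with the same pass/fail outcome
on both tests; the marginal pass proportions are compared with the Yates-
corrected two-proportion chi-square test.  McNemar's paired test on the
discordant cells is provided as an additional (non-primary) output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from scentinel.proportions import (
    ProportionTestResult,
    meets_criterion_vector,
    two_prop_test_yates,
)

NIH_ITEM_COLUMNS = [f"nih_item_{i}" for i in range(1, 10)]


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 pass/fail cross-tabulation of two tests on paired respondents."""

    pass_pass: int
    a_only: int  # test A passed, test B failed
    b_only: int
    fail_fail: int
    test_a: str = "reference"
    test_b: str = "rapid"

    @property
    def n(self) -> int:
        return self.pass_pass + self.a_only + self.b_only + self.fail_fail

    @property
    def concordant(self) -> int:
        return self.pass_pass + self.fail_fail

    @property
    def discordant(self) -> int:
        return self.a_only + self.b_only

    @property
    def concordance(self) -> float:
        return self.concordant / self.n

    @property
    def marginal_pass_a(self) -> int:
        return self.pass_pass + self.a_only

    @property
    def marginal_pass_b(self) -> int:
        return self.pass_pass + self.b_only


def cross_tabulate_tests(
    pass_a: Sequence[bool],
    pass_b: Sequence[bool],
    test_a: str = "reference",
    test_b: str = "rapid",
) -> ConcordanceTable:
    """Cross-tabulate paired pass/fail outcomes of two tests."""
    a = np.asarray(pass_a, dtype=bool)
    b = np.asarray(pass_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired outcome vectors must be 1-d and aligned")
    return ConcordanceTable(
        pass_pass=int((a & b).sum()),
        a_only=int((a & ~b).sum()),
        b_only=int((~a & b).sum()),
        fail_fail=int((~a & ~b).sum()),
        test_a=test_a,
        test_b=test_b,
    )


def concordance_from_cohort(cohort: pd.DataFrame, mode: str) -> ConcordanceTable:
    """Build the concordance table for one comparison mode.

    Rows without a completed reference test (any missing item) are dropped.
    ``mode`` must be ``"flower"`` or ``"full"`` (no default: the two modes
    answer different questions).
    """
    items = cohort[NIH_ITEM_COLUMNS]
    complete = items.notna().all(axis=1)
    sub = cohort[complete]
    if not len(sub):
        raise ValueError("no respondent completed the reference test")
    if mode == "flower":
        ref_pass = sub["nih_item_9"] == 1
        rapid_pass = sub["id1_correct"] == 1
    elif mode == "full":
        ref_pass = sub[NIH_ITEM_COLUMNS].sum(axis=1) >= 5  # binarized normosmia
        rapid_pass = meets_criterion_vector(sub)
    else:
        raise ValueError(f"mode must be 'flower' or 'full', got {mode!r}")
    return cross_tabulate_tests(
        ref_pass.to_numpy(), np.asarray(rapid_pass),
        test_a="reference", test_b="rapid",
    )


def compare_pass_proportions(table: ConcordanceTable) -> ProportionTestResult:
    """Yates-corrected two-proportion test on the two marginal pass counts.

    Depends only on the marginals, not on the joint cells.
    """
    return two_prop_test_yates(
        table.marginal_pass_a, table.n, table.marginal_pass_b, table.n
    )


def mcnemar_test(table: ConcordanceTable) -> tuple[float, float]:
    """McNemar's exact paired test on the discordant cells (extra output;
    the primary comparison is the unpaired two-proportion test above)."""
    b, c = table.a_only, table.b_only
    n = b + c
    if n == 0:
        return 0.0, 1.0
    p = min(1.0, 2 * stats.binom.cdf(min(b, c), n, 0.5))
    return float(min(b, c)), float(p)
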