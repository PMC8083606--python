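"""Frequentist and Bayesian comparisons of pass proportions across groups.

The frequentist test is the Pearson chi-square test for equality of k
proportions (Yates continuity correction available for the 2-group case
only).  The Bayesian counterpart is a closed-form Gunel-Dickey-style Bayes
factor contrasting independent Beta-binomial models per group (H1) against a
single shared proportion (H0), computed in log space via Beta functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import betaln

from scentinel.scoring import DEFAULT_INTENSITY_CUTOFF


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    df: int
    p_value: float
    successes: tuple[int, ...]
    totals: tuple[int, ...]
    continuity_corrected: bool
    low_expected_count: bool = False  # any expected cell < 1 (warning flag)


@dataclass(frozen=True)
class ProportionBayesFactor:
    bf10: float
    model: str
    prior_a: float
    prior_b: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _validate_counts(
    successes: Sequence[int], totals: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(successes, dtype=np.int64)
    n = np.asarray(totals, dtype=np.int64)
    if s.shape != n.shape or s.ndim != 1:
        raise ValueError("successes and totals must be 1-d and aligned")
    if (n <= 0).any():
        raise ValueError("all totals must be positive")
    if ((s < 0) | (s > n)).any():
        raise ValueError("successes must lie in [0, totals]")
    return s, n


def k_sample_prop_test(
    successes: Sequence[int],
    totals: Sequence[int],
    correct: bool = False,
) -> ProportionTestResult:
    """Pearson chi-square test of equal success proportions across k groups.

    Yates continuity correction is applied only when ``correct`` is true and
    k == 2 (for k > 2 the flag is ignored, the usual convention).
    """
    s, n = _validate_counts(successes, totals)
    k = len(s)
    if k < 2:
        raise ValueError("need at least 2 groups")
    table = np.column_stack([s, n - s])
    use_correction = bool(correct) and k == 2
    if s.sum() == 0 or s.sum() == n.sum():
        # degenerate pooled margin (all failures or all successes): the
        # Pearson statistic is 0/0; report no evidence of a difference
        return ProportionTestResult(
            statistic=0.0, df=k - 1, p_value=1.0,
            successes=tuple(int(x) for x in s), totals=tuple(int(x) for x in n),
            continuity_corrected=use_correction, low_expected_count=True,
        )
    chi2, p, df, expected = stats.chi2_contingency(table, correction=use_correction)
    return ProportionTestResult(
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        successes=tuple(int(x) for x in s),
        totals=tuple(int(x) for x in n),
        continuity_corrected=use_correction,
        low_expected_count=bool((expected < 1).any()),
    )


def two_prop_test_yates(s1: int, n1: int, s2: int, n2: int) -> ProportionTestResult:
    """2x2 chi-square with Yates continuity correction, df = 1."""
    return k_sample_prop_test([s1, s2], [n1, n2], correct=True)


def bf_k_proportions(
    successes: Sequence[int],
    totals: Sequence[int],
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> ProportionBayesFactor:
    """Independent-binomial Bayes factor for unequal vs equal proportions.

    H1: each group has its own rate theta_i ~ Beta(a, b), independently.
    H0: a single shared rate theta ~ Beta(a, b).
    Both marginal likelihoods are Beta integrals, so

        BF10 = prod_i B(s_i + a, f_i + b) / B(a, b)
               -----------------------------------
               B(sum s + a, sum f + b) / B(a, b)

    evaluated with log-Beta functions for numerical stability.
    """
    s, n = _validate_counts(successes, totals)
    f = n - s
    log_m1 = float(np.sum(betaln(s + prior_a, f + prior_b) - betaln(prior_a, prior_b)))
    log_m0 = float(
        betaln(s.sum() + prior_a, f.sum() + prior_b) - betaln(prior_a, prior_b)
    )
    return ProportionBayesFactor(
        bf10=float(np.exp(log_m1 - log_m0)),
        model="independent-binomial (Gunel-Dickey style)",
        prior_a=prior_a,
        prior_b=prior_b,
    )


def bf_k_proportions_quadrature(
    successes: Sequence[int],
    totals: Sequence[int],
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> float:
    """Numerical-integration cross-check of ``bf_k_proportions`` (slow)."""
    s, n = _validate_counts(successes, totals)
    f = n - s
    prior = stats.beta(prior_a, prior_b)

    def marginal(si: int, fi: int) -> float:
        val, _ = integrate.quad(
            lambda t: t**si * (1 - t) ** fi * prior.pdf(t), 0.0, 1.0
        )
        return val

    m1 = float(np.prod([marginal(si, fi) for si, fi in zip(s, f)]))
    m0 = marginal(int(s.sum()), int(f.sum()))
    return m1 / m0


def meets_criterion_vector(
    cohort: pd.DataFrame, cutoff: int = DEFAULT_INTENSITY_CUTOFF
) -> pd.Series:
    """Vectorized overall accuracy criterion over a cohort table.

    Equivalent to membership in passing patterns {1, 3, 5, 7}: intensity
    above the cutoff and (detection correct or first identification correct).
    """
    return (cohort["intensity"] > cutoff) & (
        (cohort["detect_correct"] == 1) | (cohort["id1_correct"] == 1)
    )


def group_pass_summary(
    cohort: pd.DataFrame, cutoff: int = DEFAULT_INTENSITY_CUTOFF
) -> pd.DataFrame:
    """Per-group pass counts and percentages per subtest and overall.

    Rows: detection, intensity, id_first, id_second, overall.  The id_second
    row counts second-attempt passes over the whole group (only respondents
    who failed the first attempt were offered one).  Percentages are rounded
    to integers, the convention of the published summary table.
    """
    passes = {
        "detection": cohort["detect_correct"] == 1,
        "intensity": cohort["intensity"] > cutoff,
        "id_first": cohort["id1_correct"] == 1,
        "id_second": cohort["id2_correct"] == 1,
        "overall": meets_criterion_vector(cohort, cutoff),
    }
    groups = [g for g in ("anosmic", "other", "normosmic") if (cohort["group"] == g).any()]
    rows = []
    for subtest, ok in passes.items():
        row: dict = {"subtest": subtest}
        for g in groups:
            mask = cohort["group"] == g
            n, tot = int(ok[mask].sum()), int(mask.sum())
            row[f"{g}_n"] = n
            row[f"{g}_total"] = tot
            row[f"{g}_pct"] = round(100 * n / tot) if tot else np.nan
        row["total_n"] = int(ok.sum())
        row["total_pct"] = round(100 * int(ok.sum()) / len(cohort)) if len(cohort) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtest")
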