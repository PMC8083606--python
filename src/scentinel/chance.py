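"""Analytic model of a zero-smell guesser.

A respondent with no smell ability guesses every forced-choice stage
independently and rates intensity uniformly at random on the integer support
of the visual analog scale.  Under the default test design the stage chance
probabilities are 1/3 for detection (triangle task), 1/4 for the 4-AFC first
identification attempt, 1/3 for the 3-AFC second attempt, and 21/101 for an
intensity rating at or below the cutoff of 20 (21 of the 101 integers 0-100).

Probabilities are computed as exact rationals (`fractions.Fraction`) so that
the 12-pattern distribution sums to 1 with no rounding error; a half-up
2-decimal rounded view matches the published chance column.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from scentinel.scoring import PASSING_PATTERNS, PATTERNS, ResponsePattern


@dataclass(frozen=True)
class GuessingModel:
    """Chance structure of the three-subtest design.

    ``intensity_support`` is the inclusive integer range of the rating scale;
    ``cutoff`` dichotomizes it (at-or-below = low).
    """

    p_detection: Fraction = Fraction(1, 3)
    p_id_first: Fraction = Fraction(1, 4)
    p_id_second: Fraction = Fraction(1, 3)
    intensity_support: tuple[int, int] = (0, 100)
    cutoff: int = 20

    def __post_init__(self) -> None:
        for name in ("p_detection", "p_id_first", "p_id_second"):
            p = getattr(self, name)
            if not 0 < p < 1:
                raise ValueError(f"{name}={p} outside (0, 1)")
        lo, hi = self.intensity_support
        if not lo <= self.cutoff <= hi:
            raise ValueError(
                f"cutoff {self.cutoff} outside support [{lo}, {hi}]"
            )

    @property
    def p_intensity_low(self) -> Fraction:
        """Mass of the uniform rating at or below the cutoff."""
        lo, hi = self.intensity_support
        return Fraction(self.cutoff - lo + 1, hi - lo + 1)


def _branch_probability(model: GuessingModel, pattern: ResponsePattern) -> Fraction:
    p = Fraction(1)
    p *= model.p_detection if pattern.detection_correct else 1 - model.p_detection
    p *= model.p_intensity_low if pattern.intensity_low else 1 - model.p_intensity_low
    if pattern.id_first_correct:
        p *= model.p_id_first
    else:
        p *= 1 - model.p_id_first
        p *= model.p_id_second if pattern.id_second_correct else 1 - model.p_id_second
    return p


def pattern_chance_probability(
    model: GuessingModel, pattern_id: int
) -> Fraction:
    """Exact chance probability of one of the 12 response patterns."""
    if not 1 <= pattern_id <= 12:
        raise ValueError(f"pattern_id must be 1-12, got {pattern_id}")
    return _branch_probability(model, PATTERNS[pattern_id - 1])


def round_half_up(p: Fraction, places: int = 2) -> float:
    """Round half-up to ``places`` decimals (the published-table convention)."""
    d = decimal.Decimal(p.numerator) / decimal.Decimal(p.denominator)
    q = d.quantize(decimal.Decimal(1).scaleb(-places), rounding=decimal.ROUND_HALF_UP)
    return float(q)


def pattern_table(model: Optional[GuessingModel] = None) -> list[dict]:
    """All 12 rows with exact and 2-decimal rounded chance probabilities."""
    model = model or GuessingModel()
    rows = []
    for pattern in PATTERNS:
        exact = _branch_probability(model, pattern)
        rows.append(
            {
                "pattern_id": pattern.pattern_id,
                "detection": "correct" if pattern.detection_correct else "incorrect",
                "intensity": "low" if pattern.intensity_low else "high",
                "id_first": "correct" if pattern.id_first_correct else "incorrect",
                "id_second": (
                    "NA"
                    if pattern.id_second_correct is None
                    else ("correct" if pattern.id_second_correct else "incorrect")
                ),
                "meets_criteria": pattern.meets_criteria,
                "p_chance_exact": exact,
                "p_chance": round_half_up(exact),
            }
        )
    return rows


def chance_pass_probability(model: Optional[GuessingModel] = None) -> Fraction:
    """Probability that a pure guesser meets the overall accuracy criterion.

    Sum over the passing patterns; algebraically equal to
    P(intensity high) * (p_detection + (1 - p_detection) * p_id_first).
    """
    model = model or GuessingModel()
    return sum(
        (pattern_chance_probability(model, pid) for pid in sorted(PASSING_PATTERNS)),
        Fraction(0),
    )


@dataclass
class GuesserSimulation:
    """Empirical pattern distribution from simulated zero-smell responders."""

    n: int
    counts: dict[int, int]
    pass_count: int
    seed: int

    @property
    def frequencies(self) -> dict[int, float]:
        return {pid: c / self.n for pid, c in self.counts.items()}

    @property
    def pass_rate(self) -> float:
        return self.pass_count / self.n

    table: dict = field(default_factory=dict)


def monte_carlo_guessers(
    model: Optional[GuessingModel] = None, n: int = 10_000, seed: int = 0
) -> GuesserSimulation:
    """Simulate ``n`` independent guessers; Monte-Carlo oracle for the
    analytic pattern distribution.  Fully reproducible under ``seed``."""
    model = model or GuessingModel()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = model.intensity_support
    detection = rng.random(n) < float(model.p_detection)
    intensity = rng.integers(lo, hi + 1, size=n)
    low = intensity <= model.cutoff
    id1 = rng.random(n) < float(model.p_id_first)
    id2 = rng.random(n) < float(model.p_id_second)  # consulted only when id1 fails

    # vectorized pattern id, mirroring the canonical row order
    branch = np.where(id1, 0, np.where(id2, 1, 2))  # id branch index
    pid = np.where(detection, 0, 6) + 2 * branch + low.astype(int) + 1
    counts = {int(p): int(c) for p, c in zip(*np.unique(pid, return_counts=True))}
    for missing in range(1, 13):
        counts.setdefault(missing, 0)
    pass_count = int(sum(counts[p] for p in PASSING_PATTERNS))
    return GuesserSimulation(n=n, counts=counts, pass_count=pass_count, seed=seed)
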