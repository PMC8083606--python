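"""Sequential Bayes factor design (SBFD) monitor and operating characteristics.

Enrollment continues until the evidence for a group difference in pass rates
(BF10, alternative over null) exceeds a threshold, the evidence for the null
(BF01) exceeds its own threshold, or a cap on per-group sample size — the
stand-in for a calendar deadline — is reached.  No Bayes factor is evaluated
before a minimum of n0 participants per group (default 43); past n0 the BF
is recomputed after every added participant.

The default Bayes factor is the closed-form independent-binomial construction
from :mod:`scentinel.proportions`; any callable with the same
(successes, totals) -> BF10 contract can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional

import numpy as np

from scentinel.proportions import bf_k_proportions

BfFunction = Callable[[list[int], list[int]], float]


def _default_bf(successes: list[int], totals: list[int]) -> float:
    return bf_k_proportions(successes, totals).bf10


@dataclass(frozen=True)
class SbfdConfig:
    """Stopping design: evidence thresholds, minimum n, cap."""

    bf10_threshold: float = 6.0
    bf01_threshold: float = 3.0
    n0_min_per_group: int = 43
    n_max_per_group: int = 200
    bf_function: BfFunction = _default_bf

    def __post_init__(self) -> None:
        if self.bf10_threshold <= 1 or self.bf01_threshold <= 1:
            raise ValueError("evidence thresholds must exceed 1")
        if self.n0_min_per_group < 1:
            raise ValueError("n0 must be >= 1")
        if self.bf_function is None:
            raise ValueError("bf_function is required")


@dataclass
class SbfdTrace:
    """Full monitoring record: (n per group, BF10) after each evaluation."""

    steps: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    decision: str = "cap_reached"  # H1 | H0 | cap_reached
    stopping_n: tuple[int, int] = (0, 0)

    @property
    def bf_path(self) -> list[float]:
        return [bf for _, bf in self.steps]


def sbfd_monitor(
    stream: Iterable[tuple[int, bool]],
    config: Optional[SbfdConfig] = None,
) -> SbfdTrace:
    """Run the sequential monitor over a stream of (group, passed) outcomes.

    ``group`` is 0 or 1.  The BF is evaluated after every participant once
    both groups have reached n0; the stream stops at the first threshold
    crossing (H1 if BF10 > bf10_threshold, H0 if BF10 < 1/bf01_threshold) or
    when the stream is exhausted (decision ``cap_reached``).
    """
    config = config or SbfdConfig()
    successes = [0, 0]
    totals = [0, 0]
    trace = SbfdTrace()
    it: Iterator[tuple[int, bool]] = iter(stream)
    seen_any = False
    for group, passed in it:
        seen_any = True
        if group not in (0, 1):
            raise ValueError(f"group must be 0 or 1, got {group}")
        totals[group] += 1
        successes[group] += int(bool(passed))
        if min(totals) < config.n0_min_per_group:
            continue
        bf10 = float(config.bf_function(list(successes), list(totals)))
        trace.steps.append(((totals[0], totals[1]), bf10))
        if bf10 > config.bf10_threshold:
            trace.decision = "H1"
            trace.stopping_n = (totals[0], totals[1])
            return trace
        if bf10 < 1.0 / config.bf01_threshold:
            trace.decision = "H0"
            trace.stopping_n = (totals[0], totals[1])
            return trace
    if not seen_any:
        raise ValueError("empty outcome stream")
    trace.decision = "cap_reached"
    trace.stopping_n = (totals[0], totals[1])
    return trace


def _alternating_stream(
    p: tuple[float, float], n_max: int, rng: np.random.Generator
) -> Iterator[tuple[int, bool]]:
    """Balanced accrual: always enroll into the currently smaller group."""
    counts = [0, 0]
    while max(counts) < n_max or min(counts) < n_max:
        group = 0 if counts[0] <= counts[1] else 1
        if counts[group] >= n_max:
            group = 1 - group
        counts[group] += 1
        yield group, bool(rng.random() < p[group])


@dataclass(frozen=True)
class SbfdOperatingCharacteristics:
    p_h1: float
    p_h0: float
    p_cap: float
    mean_stopping_n: float  # mean of max per-group n at stop
    stopping_ns: tuple[int, ...]
    n_sims: int


def sbfd_operating_characteristics(
    pass_rates: tuple[float, float],
    config: Optional[SbfdConfig] = None,
    n_sims: int = 500,
    seed: int = 0,
) -> SbfdOperatingCharacteristics:
    """Monte-Carlo decision rates and stopping times for a true effect.

    ``pass_rates`` are the true per-group Bernoulli pass probabilities;
    equal rates simulate the null.  Accrual alternates between groups so
    that sizes stay balanced, capped at ``config.n_max_per_group``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    config = config or SbfdConfig()
    rng = np.random.default_rng(seed)
    decisions = {"H1": 0, "H0": 0, "cap_reached": 0}
    stop_ns = []
    for _ in range(n_sims):
        trace = sbfd_monitor(
            _alternating_stream(pass_rates, config.n_max_per_group, rng), config
        )
        decisions[trace.decision] += 1
        stop_ns.append(max(trace.stopping_n))
    return SbfdOperatingCharacteristics(
        p_h1=decisions["H1"] / n_sims,
        p_h0=decisions["H0"] / n_sims,
        p_cap=decisions["cap_reached"] / n_sims,
        mean_stopping_n=float(np.mean(stop_ns)),
        stopping_ns=tuple(stop_ns),
        n_sims=n_sims,
    )
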