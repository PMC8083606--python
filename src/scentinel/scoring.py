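"""Response scoring: pattern assignment and the overall accuracy criterion.

A completed test yields a joint outcome over three subtests:

* detection — correct/incorrect on a 3-alternative triangle task;
* intensity — a 0-100 visual analog rating, dichotomized at a cutoff
  (default 20: "low" means at or below the cutoff);
* identification — correct/incorrect on a 4-alternative first attempt; a
  3-alternative second attempt is offered only after a first-attempt failure.

The 12 possible joint outcomes ("response patterns") are numbered 1-12 in a
fixed order: detection correct before incorrect, intensity high before low,
identification first-attempt correct (second attempt not applicable), then
second-attempt correct, then both attempts incorrect.  Patterns 1, 3, 5 and 7
meet the overall accuracy criterion, which is equivalent to: intensity above
the cutoff AND (detection correct OR first identification attempt correct).

The module also scores the 9-item odor-identification reference test (the
NIH Toolbox Odor Identification Test): the official three-way category
(anosmia <=3, hyposmia 4-6, normosmia >=7) and a binarized version
(anosmia <=4, normosmia >=5) used for direct comparison with the rapid test's
pass/fail criterion.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

DEFAULT_INTENSITY_CUTOFF = 20

#: Pattern ids that meet the overall accuracy criterion.
PASSING_PATTERNS = frozenset({1, 3, 5, 7})


class Group(str, enum.Enum):
    """Self-reported smell-ability group."""

    ANOSMIC = "anosmic"
    OTHER = "other"
    NORMOSMIC = "normosmic"


class OfficialCategory(str, enum.Enum):
    ANOSMIA = "anosmia"
    HYPOSMIA = "hyposmia"
    NORMOSMIA = "normosmia"


@dataclass(frozen=True)
class ScentinelResponse:
    """One respondent's raw subtest outcomes plus demographics.

    ``id_second_correct`` must be present exactly when the first
    identification attempt failed: the second attempt is only offered after a
    first-attempt failure, so its presence is structural, not missing data.
    """

    subject_id: str
    detection_correct: bool
    intensity: int
    id_first_correct: bool
    id_second_correct: Optional[bool] = None
    group: Optional[Group] = None
    age: Optional[int] = None
    sex: str = "unreported"
    ethnicity_white: Optional[bool] = None

    def __post_init__(self) -> None:
        intensity = self.intensity
        if not isinstance(intensity, (int,)) or isinstance(intensity, bool):
            if isinstance(intensity, float):
                if not math.isfinite(intensity):
                    raise ValueError(f"non-finite intensity {intensity!r}")
                floored = int(math.floor(intensity))
                warnings.warn(
                    f"non-integer intensity {intensity!r} floored to {floored}",
                    stacklevel=3,
                )
                object.__setattr__(self, "intensity", floored)
            else:
                raise TypeError(f"intensity must be numeric, got {intensity!r}")
        if not 0 <= self.intensity <= 100:
            raise ValueError(f"intensity {self.intensity} outside [0, 100]")
        if self.id_first_correct and self.id_second_correct is not None:
            raise ValueError(
                "second identification attempt recorded despite a correct "
                "first attempt (it is only offered after a failure)"
            )
        if not self.id_first_correct and self.id_second_correct is None:
            raise ValueError(
                "second identification attempt missing after a failed first attempt"
            )
        if self.sex not in ("F", "M", "unreported"):
            raise ValueError(f"sex must be F, M or unreported, got {self.sex!r}")


@dataclass(frozen=True)
class ResponsePattern:
    """One of the 12 joint-outcome rows of the accuracy matrix."""

    pattern_id: int
    detection_correct: bool
    intensity_low: bool
    id_first_correct: bool
    id_second_correct: Optional[bool]  # None = not applicable
    meets_criteria: bool


def _pattern_rows() -> list[ResponsePattern]:
    rows = []
    pid = 1
    for detection in (True, False):
        # identification branch order: first correct, second correct, both wrong
        for id1, id2 in ((True, None), (False, True), (False, False)):
            for low in (False, True):  # high intensity precedes low
                rows.append(
                    ResponsePattern(
                        pattern_id=pid,
                        detection_correct=detection,
                        intensity_low=low,
                        id_first_correct=id1,
                        id_second_correct=id2,
                        meets_criteria=pid in PASSING_PATTERNS,
                    )
                )
                pid += 1
    return rows


#: The 12 patterns in canonical (published) order.
PATTERNS: tuple[ResponsePattern, ...] = tuple(_pattern_rows())


def assign_pattern(
    response: ScentinelResponse, cutoff: int = DEFAULT_INTENSITY_CUTOFF
) -> ResponsePattern:
    """Map a response to the unique matching pattern row.

    ``cutoff`` dichotomizes intensity: at or below is "low", above is "high".
    """
    low = response.intensity <= cutoff
    for pattern in PATTERNS:
        if (
            pattern.detection_correct == response.detection_correct
            and pattern.intensity_low == low
            and pattern.id_first_correct == response.id_first_correct
            and pattern.id_second_correct == response.id_second_correct
        ):
            return pattern
    raise AssertionError("unreachable: pattern grid is exhaustive")


def meets_accuracy_criterion(pattern: ResponsePattern) -> bool:
    """Overall pass rule: true exactly for patterns 1, 3, 5 and 7.

    Equivalently, intensity above the cutoff and at least one of detection or
    first-attempt identification correct.
    """
    return pattern.meets_criteria


@dataclass(frozen=True)
class NihToolboxResult:
    """Scored 9-item odor-identification reference test."""

    item_correct: tuple[bool, ...]
    total: int
    official_category: OfficialCategory
    binarized_category: OfficialCategory


def score_nih(items: Sequence[bool]) -> NihToolboxResult:
    """Score 9 item outcomes into total, official and binarized categories.

    Official: anosmia <=3, hyposmia 4-6, normosmia >=7.
    Binarized: anosmia <=4, normosmia >=5.
    """
    items = tuple(bool(x) for x in items)
    if len(items) != 9:
        raise ValueError(f"expected 9 item outcomes, got {len(items)}")
    total = sum(items)
    if total <= 3:
        official = OfficialCategory.ANOSMIA
    elif total <= 6:
        official = OfficialCategory.HYPOSMIA
    else:
        official = OfficialCategory.NORMOSMIA
    binarized = (
        OfficialCategory.ANOSMIA if total <= 4 else OfficialCategory.NORMOSMIA
    )
    return NihToolboxResult(
        item_correct=items,
        total=total,
        official_category=official,
        binarized_category=binarized,
    )
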