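"""Calibrated synthetic respondents for the three smell-ability groups.

The simulator emulates the study population the evaluation pipeline assumes:
self-reported anosmic (n=111), other-smell-disorder (n=42) and normosmic
(n=154) adults.  Per-group marginal subtest success probabilities are
calibrated to the observed pass rates (detection .44/.79/.92, intensity above
cutoff .14/.71/1.00, first identification .34/.76/.92 for the three groups),
and demographics to the observed means (age 47+-13 / 55+-10 / 47+-14, female
71/67/74%, White 90/90/83%).

Subtests are drawn independently within a respondent by default — only the
marginals are known — with an optional shared latent "ability" coupling
(logistic links) for sensitivity analyses.  Second-attempt identification is
drawn only after a first-attempt failure, so its conditional probability is
back-solved from the whole-group marginal: e.g. 26 of 111 anosmic
participants passed the second attempt, giving (26/111)/(1-0.34) ~= 0.355
among those offered it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from scentinel.scoring import Group, NihToolboxResult, ScentinelResponse, score_nih

AGE_BOUNDS = (18, 75)
INTENSITY_CUTOFF = 20

#: Canonical column order of the cohort table (see io module).
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "ethnicity_white",
    "detect_correct",
    "intensity",
    "id1_correct",
    "id2_correct",
] + [f"nih_item_{i}" for i in range(1, 10)]


@dataclass(frozen=True)
class GroupResponseModel:
    """Generative model for one smell-ability group.

    ``p_id_second`` is conditional on a first-attempt failure.  Intensity is
    a two-part mixture: mass ``p_intensity_high`` above the cutoff
    (discretized truncated normal with ``intensity_loc``/``intensity_scale``,
    or uniform when ``above_cutoff_uniform``), remainder uniform on
    [0, cutoff].  ``latent_rho`` couples the binary subtests through a shared
    standard-normal ability with logistic links; 0 = independent (default).
    """

    group: Group
    p_detection: float
    p_id_first: float
    p_id_second: float
    p_intensity_high: float
    intensity_loc: float = 60.0
    intensity_scale: float = 20.0
    above_cutoff_uniform: bool = False
    age_mean: float = 47.0
    age_sd: float = 13.0
    prop_female: float = 0.71
    prop_white: float = 0.90
    nih_item_p: float = 0.5
    latent_rho: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_detection",
            "p_id_first",
            "p_id_second",
            "p_intensity_high",
            "prop_female",
            "prop_white",
            "nih_item_p",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


def default_group_models() -> dict[Group, GroupResponseModel]:
    """Per-group models calibrated to the observed study marginals."""
    return {
        Group.ANOSMIC: GroupResponseModel(
            group=Group.ANOSMIC,
            p_detection=0.44,
            p_id_first=0.34,
            p_id_second=(26 / 111) / (1 - 0.34),
            p_intensity_high=0.14,
            intensity_loc=40.0,
            intensity_scale=15.0,
            age_mean=47.0,
            age_sd=13.0,
            prop_female=0.71,
            prop_white=0.90,
            nih_item_p=0.25,  # 4-AFC chance level
        ),
        Group.OTHER: GroupResponseModel(
            group=Group.OTHER,
            p_detection=0.79,
            p_id_first=0.76,
            p_id_second=(3 / 42) / (1 - 0.76),
            p_intensity_high=0.71,
            intensity_loc=50.0,
            intensity_scale=20.0,
            age_mean=55.0,
            age_sd=10.0,
            prop_female=0.67,
            prop_white=0.90,
            nih_item_p=0.55,
        ),
        Group.NORMOSMIC: GroupResponseModel(
            group=Group.NORMOSMIC,
            p_detection=0.92,
            p_id_first=0.92,
            p_id_second=(3 / 154) / (1 - 0.92),
            p_intensity_high=1.00,
            intensity_loc=60.0,
            intensity_scale=20.0,
            age_mean=47.0,
            age_sd=14.0,
            prop_female=0.74,
            prop_white=0.83,
            nih_item_p=0.90,
        ),
    }


def pure_guesser_model(group: Group = Group.ANOSMIC) -> GroupResponseModel:
    """Zero-smell preset: every stage at its forced-choice chance level and a
    uniform 0-100 intensity rating (cf. the analytic guessing model)."""
    base = default_group_models()[group]
    return replace(
        base,
        p_detection=1 / 3,
        p_id_first=1 / 4,
        p_id_second=1 / 3,
        p_intensity_high=80 / 101,
        above_cutoff_uniform=True,
        nih_item_p=0.25,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: per-group sizes, seed, optional model overrides."""

    n_anosmic: int = 111
    n_other: int = 42
    n_normosmic: int = 154
    seed: int = 0
    models: Optional[Mapping[Group, GroupResponseModel]] = None
    include_nih: bool = False

    def __post_init__(self) -> None:
        if min(self.n_anosmic, self.n_other, self.n_normosmic) < 0:
            raise ValueError("group sizes must be >= 0")

    @property
    def sizes(self) -> dict[Group, int]:
        return {
            Group.ANOSMIC: self.n_anosmic,
            Group.OTHER: self.n_other,
            Group.NORMOSMIC: self.n_normosmic,
        }


def _bernoulli(rng: np.random.Generator, p: np.ndarray | float, n: int) -> np.ndarray:
    return rng.random(n) < p


def _coupled_probs(p: float, rho: float, z: np.ndarray) -> np.ndarray:
    """Per-respondent success probability under the latent-ability coupling.

    With rho=0 this is exactly ``p``; otherwise the marginal shifts slightly
    (logistic-normal mixing is not mean-preserving), which is acceptable for
    a sensitivity knob.
    """
    if rho == 0.0 or p in (0.0, 1.0):
        return np.full_like(z, p, dtype=float)
    return expit(logit(p) + rho * z)


def _draw_intensity(
    model: GroupResponseModel, rng: np.random.Generator, high: np.ndarray
) -> np.ndarray:
    n = high.size
    out = np.empty(n, dtype=int)
    n_low = int((~high).sum())
    out[~high] = rng.integers(0, INTENSITY_CUTOFF + 1, size=n_low)
    n_high = n - n_low
    if n_high:
        if model.above_cutoff_uniform:
            out[high] = rng.integers(INTENSITY_CUTOFF + 1, 101, size=n_high)
        else:
            lo, hi = INTENSITY_CUTOFF + 0.5, 100.5
            a = (lo - model.intensity_loc) / model.intensity_scale
            b = (hi - model.intensity_loc) / model.intensity_scale
            draws = stats.truncnorm.rvs(
                a, b, loc=model.intensity_loc, scale=model.intensity_scale,
                size=n_high, random_state=rng,
            )
            out[high] = np.clip(np.rint(draws), INTENSITY_CUTOFF + 1, 100).astype(int)
    return out


def _simulate_group(
    model: GroupResponseModel,
    n: int,
    rng: np.random.Generator,
    include_nih: bool,
    id_offset: int,
) -> pd.DataFrame:
    z = rng.standard_normal(n)
    rho = model.latent_rho
    detect = _bernoulli(rng, _coupled_probs(model.p_detection, rho, z), n)
    high = _bernoulli(rng, _coupled_probs(model.p_intensity_high, rho, z), n)
    intensity = _draw_intensity(model, rng, high)
    id1 = _bernoulli(rng, _coupled_probs(model.p_id_first, rho, z), n)
    id2_draw = _bernoulli(rng, _coupled_probs(model.p_id_second, rho, z), n)
    id2 = np.where(id1, np.nan, id2_draw.astype(float))  # NaN = not offered

    a = (AGE_BOUNDS[0] - model.age_mean) / model.age_sd
    b = (AGE_BOUNDS[1] - model.age_mean) / model.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=model.age_mean, scale=model.age_sd, size=n, random_state=rng
    ).round().astype(int)
    female = _bernoulli(rng, model.prop_female, n)
    white = _bernoulli(rng, model.prop_white, n)

    data = {
        "subject_id": [f"S{id_offset + i:05d}" for i in range(n)],
        "group": model.group.value,
        "age": age,
        "sex": np.where(female, "F", "M"),
        "ethnicity_white": white.astype(int),
        "detect_correct": detect.astype(int),
        "intensity": intensity,
        "id1_correct": id1.astype(int),
        "id2_correct": id2,
    }
    if include_nih:
        items = rng.random((n, 9)) < model.nih_item_p
        for j in range(9):
            data[f"nih_item_{j + 1}"] = items[:, j].astype(float)
    else:
        for j in range(9):
            data[f"nih_item_{j + 1}"] = np.nan
    return pd.DataFrame(data, columns=COHORT_COLUMNS)


def simulate_respondent(
    model: GroupResponseModel,
    rng: np.random.Generator,
    subject_id: str = "S00000",
    include_nih: bool = False,
) -> tuple[ScentinelResponse, Optional[NihToolboxResult]]:
    """Draw a single respondent (record-level view of the group simulator)."""
    row = _simulate_group(model, 1, rng, include_nih, 0).iloc[0]
    response = ScentinelResponse(
        subject_id=subject_id,
        detection_correct=bool(row.detect_correct),
        intensity=int(row.intensity),
        id_first_correct=bool(row.id1_correct),
        id_second_correct=None if np.isnan(row.id2_correct) else bool(row.id2_correct),
        group=model.group,
        age=int(row.age),
        sex=str(row.sex),
        ethnicity_white=bool(row.ethnicity_white),
    )
    nih = None
    if include_nih:
        nih = score_nih([bool(row[f"nih_item_{j}"]) for j in range(1, 10)])
    return response, nih


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Concatenated per-group respondents; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    models = dict(default_group_models())
    if spec.models:
        models.update(spec.models)
    frames = []
    offset = 0
    for group in (Group.ANOSMIC, Group.OTHER, Group.NORMOSMIC):
        n = spec.sizes[group]
        if n:
            frames.append(
                _simulate_group(models[group], n, rng, spec.include_nih, offset)
            )
            offset += n
    if not frames:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = spec.seed
    return out
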