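"""Resolve questionnaire responses to exposure profiles and score them.

The total score is a plain weighted sum: one level per factor group, weights
added on the half-point scale.  A total maps to a relative risk through
``RR = 10 ** (total / 10)``, the inverse of the odds-ratio-to-points
encoding used by the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .factor_model import FactorRegistry

__all__ = [
    "RawResponses",
    "ExposureProfile",
    "ScoreResult",
    "CohortSummary",
    "MissingItemError",
    "resolve_profile",
    "score_profile",
    "rr_from_score",
    "score_cohort",
    "summarize_scores",
]

MissingPolicy = Literal["strict", "reference", "exclude"]

ETHNICITIES = ("white", "black_caribbean", "other")
DENSITIES = ("low", "medium", "high")
IMMIGRATION = ("none", "first_generation", "second_generation")
ORIGINS = ("north_africa", "other", "not_applicable")
SEXES = ("male", "female", "other")

MIN_AGE = 14.0  # inclusion floor; override via RawResponses(min_age=...)


class MissingItemError(ValueError):
    """A required questionnaire item is unanswered under the strict policy."""


@dataclass
class RawResponses:
    """One respondent's raw questionnaire answers.

    Boolean items are ``True``/``False``; ``None`` marks a missing answer.
    Categorical items use lower-snake-case codes (see module constants).
    """

    respondent_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    paternal_age: Optional[float] = None
    ethnicity: Optional[str] = None
    ethnic_density: Optional[str] = None
    immigration: Optional[str] = None
    origin: Optional[str] = None
    childhood_trauma: Optional[bool] = None
    non_right_handedness: Optional[bool] = None
    pollution: Optional[bool] = None
    urbanicity: Optional[bool] = None
    winter_spring_birth: Optional[bool] = None
    low_paternal_ses: Optional[bool] = None
    parental_smi: Optional[bool] = None
    adult_life_events: Optional[bool] = None
    daily_smoker: Optional[bool] = None
    heavy_cannabis: Optional[bool] = None
    hearing_problems: Optional[bool] = None
    trait_anhedonia: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age < MIN_AGE:
            raise ValueError(
                f"respondent {self.respondent_id!r}: age {self.age} below "
                f"inclusion floor {MIN_AGE}"
            )
        for name, value, allowed in (
            ("ethnicity", self.ethnicity, ETHNICITIES),
            ("ethnic_density", self.ethnic_density, DENSITIES),
            ("immigration", self.immigration, IMMIGRATION),
            ("origin", self.origin, ORIGINS),
            ("sex", self.sex, SEXES),
        ):
            if value is not None and value not in allowed:
                raise ValueError(
                    f"respondent {self.respondent_id!r}: unknown {name} "
                    f"label {value!r} (allowed: {', '.join(allowed)})"
                )


@dataclass
class ExposureProfile:
    """A resolved selection of exactly one level per factor group."""

    selections: dict[str, str]
    warnings: list[str] = field(default_factory=list)


@dataclass
class ScoreResult:
    """Total score with per-group breakdown and implied relative risk."""

    respondent_id: str
    total: float
    contributions: dict[str, float]
    relative_risk: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "respondent_id": self.respondent_id,
            "total": self.total,
            "relative_risk": self.relative_risk,
            "relative_risk_display": round(self.relative_risk, 2),
            "contributions": dict(self.contributions),
            "warnings": list(self.warnings),
        }


@dataclass
class CohortSummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    # per quartile bin: {"range": (min, max) observed or None, "percent": float}
    quartile_ranges: list[dict]
    threshold_proportions: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "mean_display": round(self.mean, 2),
            "sd_display": round(self.sd, 2),
            "quartile_ranges": [
                {
                    "range": list(q["range"]) if q["range"] is not None else None,
                    "percent": q["percent"],
                    "percent_display": round(q["percent"], 1),
                }
                for q in self.quartile_ranges
            ],
            "threshold_proportions": {
                str(k): v for k, v in self.threshold_proportions.items()
            },
        }


# ---------------------------------------------------------------------------
# Response -> profile resolution
# ---------------------------------------------------------------------------

# group name -> RawResponses attribute, for the plain boolean items
_BOOL_ITEMS: dict[str, str] = {
    "Childhood trauma": "childhood_trauma",
    "Non-right-handedness": "non_right_handedness",
    "Pollution": "pollution",
    "Urbanicity": "urbanicity",
    "Winter or spring birth in northern hemisphere": "winter_spring_birth",
    "Low paternal socioeconomic status": "low_paternal_ses",
    "Parental severe mental illness": "parental_smi",
    "Adult life events": "adult_life_events",
    "Daily smoker": "daily_smoker",
    "Heavy cannabis use": "heavy_cannabis",
    "Hearing problems in past 12 months": "hearing_problems",
    "Trait anhedonia": "trait_anhedonia",
}

# human-readable item names for error messages
_ITEM_NAMES: dict[str, str] = {
    "childhood_trauma": "childhood trauma",
    "non_right_handedness": "non-right-handedness",
    "pollution": "pollution",
    "urbanicity": "urbanicity",
    "winter_spring_birth": "winter or spring birth",
    "low_paternal_ses": "low paternal socioeconomic status",
    "parental_smi": "parental severe mental illness",
    "adult_life_events": "adult life events",
    "daily_smoker": "daily smoker",
    "heavy_cannabis": "heavy cannabis use",
    "hearing_problems": "hearing problems",
    "trait_anhedonia": "trait anhedonia",
}

_DENSITY_DISPLAY = {"low": "low", "medium": "medium", "high": "high"}


def _paternal_age_level(paternal_age: float) -> str:
    # bins printed as <35 / >35 / >45 overlap; resolved as
    # <35 | 35-45 inclusive | >45
    if paternal_age < 35:
        return "<35"
    if paternal_age <= 45:
        return "35-45"
    return ">45"


def resolve_profile(
    raw: RawResponses,
    registry: FactorRegistry,
    missing_policy: MissingPolicy = "strict",
) -> ExposureProfile:
    """Map raw answers to exactly one level per registry group.

    Dependency handling: the immigration level combines generation and
    origin; the ethnicity level combines ethnicity and ethnic density
    (density is ignored for white respondents); the male-and-25-35 item is
    derived from sex and age; paternal age is binned.

    ``missing_policy`` controls unanswered items: ``"strict"`` raises
    :class:`MissingItemError` naming the item, ``"reference"`` imputes the
    group's reference level and records a warning, ``"exclude"`` also
    raises (cohort-level callers catch it and drop the respondent).
    """
    selections: dict[str, str] = {}
    warnings: list[str] = []

    def missing(item: str, group_name: str) -> None:
        if missing_policy == "reference":
            ref = registry.group(group_name).reference_level
            selections[group_name] = ref
            warnings.append(
                f"missing item '{item}': imputed reference level {ref!r} "
                f"for group {group_name!r}"
            )
        else:
            raise MissingItemError(
                f"respondent {raw.respondent_id!r}: missing required item "
                f"'{item}'"
            )

    for group_name, attr in _BOOL_ITEMS.items():
        if group_name not in registry.group_names:
            continue
        value = getattr(raw, attr)
        if value is None:
            missing(_ITEM_NAMES[attr], group_name)
        else:
            selections[group_name] = "Yes" if value else "No"

    # ethnicity x ethnic density
    if "Ethnicity" in registry.group_names:
        if raw.ethnicity is None:
            missing("ethnicity", "Ethnicity")
        elif raw.ethnicity == "white":
            selections["Ethnicity"] = "White"
        else:
            if raw.ethnic_density is None:
                missing("ethnic density", "Ethnicity")
            else:
                base = (
                    "Black Caribbean"
                    if raw.ethnicity == "black_caribbean"
                    else "Other"
                )
                density = _DENSITY_DISPLAY[raw.ethnic_density]
                selections["Ethnicity"] = f"{base}, {density} ethnic density"

    # immigration generation x origin
    if "Immigration" in registry.group_names:
        if raw.immigration is None:
            missing("immigration", "Immigration")
        elif raw.immigration == "none":
            selections["Immigration"] = "Not immigrant"
            if raw.origin not in (None, "not_applicable"):
                warnings.append(
                    "origin given for a non-immigrant respondent; ignored"
                )
        else:
            gen = "1st" if raw.immigration == "first_generation" else "2nd"
            if raw.origin is None or raw.origin == "not_applicable":
                missing("immigration origin", "Immigration")
            else:
                region = (
                    "North Africa" if raw.origin == "north_africa" else "other regions"
                )
                selections["Immigration"] = f"{gen} generation, {region}"
                if raw.ethnicity == "black_caribbean" and raw.origin == "north_africa":
                    warnings.append(
                        "implausible combination: Black Caribbean ethnicity "
                        "with North African immigrant origin"
                    )

    if "Paternal age" in registry.group_names:
        if raw.paternal_age is None:
            missing("paternal age", "Paternal age")
        else:
            selections["Paternal age"] = _paternal_age_level(raw.paternal_age)

    if "Male & 25-35 years old" in registry.group_names:
        if raw.sex is None:
            missing("sex", "Male & 25-35 years old")
        elif raw.age is None:
            missing("age", "Male & 25-35 years old")
        else:
            is_hit = raw.sex == "male" and 25 <= raw.age <= 35
            selections["Male & 25-35 years old"] = "Yes" if is_hit else "No"

    return ExposureProfile(selections=selections, warnings=warnings)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_profile(
    profile: ExposureProfile,
    registry: FactorRegistry,
    respondent_id: str = "",
) -> ScoreResult:
    """Compute the weighted total and per-group contributions."""
    contributions: dict[str, float] = {}
    for group in registry:
        try:
            label = profile.selections[group.name]
        except KeyError:
            raise ValueError(
                f"profile does not cover factor group {group.name!r}"
            ) from None
        contributions[group.name] = group.weight(label)
    extra = set(profile.selections) - set(registry.group_names)
    if extra:
        raise ValueError(f"profile selects unknown groups: {sorted(extra)}")
    total = float(sum(contributions.values()))
    return ScoreResult(
        respondent_id=respondent_id,
        total=total,
        contributions=contributions,
        relative_risk=rr_from_score(total),
        warnings=list(profile.warnings),
    )


def rr_from_score(score: float) -> float:
    """Relative risk implied by a total score: ``10 ** (score / 10)``.

    Strictly increasing; a score of 0 maps to RR 1.  Full precision is
    returned; round to 2 decimals for display.
    """
    return float(10.0 ** (float(score) / 10.0))


# ---------------------------------------------------------------------------
# Cohort-level scoring and summaries
# ---------------------------------------------------------------------------


def summarize_scores(
    totals: Sequence[float],
    thresholds: Sequence[float] = (5.0, 15.0),
) -> CohortSummary:
    """Descriptive summary of a vector of totals.

    Quartile bins split the sorted totals at the linear-interpolation
    0.25/0.5/0.75 quantiles; ties at a boundary fall into the lower
    quartile.  Each bin reports the observed (min, max) and its membership
    percentage.  Threshold proportions use strict ``>``.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        raise ValueError("cannot summarize an empty cohort")
    n = int(totals.size)
    mean = float(np.mean(totals))
    sd = float(np.std(totals, ddof=1)) if n > 1 else 0.0
    qs = np.quantile(totals, [0.25, 0.5, 0.75])
    # bin index = number of quantile boundaries strictly below the score
    bins = np.sum(totals[:, None] > qs[None, :], axis=1)
    quartile_ranges: list[dict] = []
    for b in range(4):
        members = totals[bins == b]
        quartile_ranges.append(
            {
                "range": (float(members.min()), float(members.max()))
                if members.size
                else None,
                "percent": 100.0 * members.size / n,
            }
        )
    threshold_proportions = {
        float(t): float(100.0 * np.mean(totals > t)) for t in thresholds
    }
    return CohortSummary(
        n=n,
        mean=mean,
        sd=sd,
        median=float(np.median(totals)),
        min=float(totals.min()),
        max=float(totals.max()),
        quartile_ranges=quartile_ranges,
        threshold_proportions=threshold_proportions,
    )


def score_cohort(
    responses: Iterable[RawResponses],
    registry: FactorRegistry,
    thresholds: Sequence[float] = (5.0, 15.0),
    missing_policy: MissingPolicy = "strict",
) -> tuple[list[ScoreResult], CohortSummary]:
    """Score every respondent and summarize the cohort.

    Under the ``"exclude"`` policy, respondents with missing items are
    dropped from both the results and the summary.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("empty cohort")
    results: list[ScoreResult] = []
    for raw in responses:
        try:
            profile = resolve_profile(raw, registry, missing_policy=missing_policy)
        except MissingItemError:
            if missing_policy == "exclude":
                continue
            raise
        results.append(score_profile(profile, registry, respondent_id=raw.respondent_id))
    if not results:
        raise ValueError("no scoreable respondents after exclusions")
    summary = summarize_scores([r.total for r in results], thresholds=thresholds)
    return results, summary
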