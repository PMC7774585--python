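from __future__ import annotations

import itertools

import pytest

from polyrisk import RawResponses, default_prevalences, default_registry

# Expected instrument weights, enumerated independently of the package's
# internal table: (group, level) -> weight.
EXPECTED_WEIGHTS = {
    ("Childhood trauma", "Yes"): 4.0,
    ("Childhood trauma", "No"): -0.5,
    ("Ethnicity", "White"): -2.0,
    ("Ethnicity", "Black Caribbean, low ethnic density"): 6.0,
    ("Ethnicity", "Black Caribbean, medium ethnic density"): 5.5,
    ("Ethnicity", "Black Caribbean, high ethnic density"): 3.5,
    ("Ethnicity", "Other, low ethnic density"): 3.5,
    ("Ethnicity", "Other, medium ethnic density"): 3.0,
    ("Ethnicity", "Other, high ethnic density"): 1.0,
    ("Immigration", "Not immigrant"): -0.5,
    ("Immigration", "1st generation, North Africa"): 3.0,
    ("Immigration", "1st generation, other regions"): 2.0,
    ("Immigration", "2nd generation, North Africa"): 2.5,
    ("Immigration", "2nd generation, other regions"): 1.5,
    ("Non-right-handedness", "Yes"): 2.0,
    ("Non-right-handedness", "No"): 0.0,
    ("Pollution", "Yes"): 2.0,
    ("Pollution", "No"): -5.5,
    ("Urbanicity", "Yes"): 1.0,
    ("Urbanicity", "No"): -2.5,
    ("Winter or spring birth in northern hemisphere", "Yes"): 0.0,
    ("Winter or spring birth in northern hemisphere", "No"): 0.0,
    ("Paternal age", "<35"): -0.5,
    ("Paternal age", "35-45"): 0.5,
    ("Paternal age", ">45"): 3.5,
    ("Low paternal socioeconomic status", "Yes"): 1.0,
    ("Low paternal socioeconomic status", "No"): 0.0,
    ("Parental severe mental illness", "Yes"): 5.5,
    ("Parental severe mental illness", "No"): -2.0,
    ("Adult life events", "Yes"): 5.5,
    ("Adult life events", "No"): -2.0,
    ("Daily smoker", "Yes"): 3.0,
    ("Daily smoker", "No"): -0.5,
    ("Heavy cannabis use", "Yes"): 7.0,
    ("Heavy cannabis use", "No"): 0.0,
    ("Hearing problems in past 12 months", "Yes"): 2.0,
    ("Hearing problems in past 12 months", "No"): 0.0,
    ("Trait anhedonia", "Yes"): 6.5,
    ("Trait anhedonia", "No"): 0.0,
    ("Male & 25-35 years old", "Yes"): 2.0,
    ("Male & 25-35 years old", "No"): 0.0,
}


def achievable_totals(registry):
    """Enumeration oracle: the exact set of achievable totals over one
    level per group, built by set reduction (equivalent to iterating the
    full cartesian product of levels)."""
    totals = {0.0}
    for group in registry:
        weights = {lv.weight for lv in group.levels}
        totals = {t + w for t, w in itertools.product(totals, weights)}
    return totals


def make_reference_responses(respondent_id="r1", **overrides) -> RawResponses:
    """A fully answered respondent sitting at every reference level."""
    base = dict(
        respondent_id=respondent_id,
        age=40.0,
        sex="female",
        paternal_age=30.0,
        ethnicity="white",
        ethnic_density="medium",
        immigration="none",
        origin="not_applicable",
        childhood_trauma=False,
        non_right_handedness=False,
        pollution=False,
        urbanicity=False,
        winter_spring_birth=False,
        low_paternal_ses=False,
        parental_smi=False,
        adult_life_events=False,
        daily_smoker=False,
        heavy_cannabis=False,
        hearing_problems=False,
        trait_anhedonia=False,
    )
    base.update(overrides)
    return RawResponses(**base)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def prevalences():
    return default_prevalences()
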