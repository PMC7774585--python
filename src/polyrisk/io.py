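"""Readers, writers and synthetic-fixture generation.

Responses travel as CSV with a fixed data dictionary: one row per
respondent, booleans encoded ``yes``/``no`` (case-insensitive), categorical
codes in lower snake case, blank cells meaning missing.  Reports are JSON.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .factor_model import FactorRegistry, default_registry
from .population_sim import PrevalenceConfig
from .scoring import (
    DENSITIES,
    ETHNICITIES,
    IMMIGRATION,
    ORIGINS,
    SEXES,
    RawResponses,
)

__all__ = [
    "RESPONSE_COLUMNS",
    "read_responses",
    "write_responses",
    "generate_fixture_cohort",
]

_BOOL_COLUMNS = (
    "childhood_trauma",
    "non_right_handedness",
    "pollution",
    "urbanicity",
    "winter_spring_birth",
    "low_paternal_ses",
    "parental_smi",
    "adult_life_events",
    "daily_smoker",
    "heavy_cannabis",
    "hearing_problems",
    "trait_anhedonia",
)
_CAT_COLUMNS = {
    "ethnicity": ETHNICITIES,
    "ethnic_density": DENSITIES,
    "immigration": IMMIGRATION,
    "origin": ORIGINS,
    "sex": SEXES,
}
_NUM_COLUMNS = ("age", "paternal_age")

#: canonical column order of a responses CSV
RESPONSE_COLUMNS: tuple[str, ...] = (
    "respondent_id",
    "age",
    "sex",
    "paternal_age",
    "ethnicity",
    "ethnic_density",
    "immigration",
    "origin",
) + _BOOL_COLUMNS


def _parse_bool(cell: str, row: int, column: str) -> Optional[bool]:
    text = cell.strip().lower()
    if text == "":
        return None
    if text in ("yes", "true", "1"):
        return True
    if text in ("no", "false", "0"):
        return False
    raise ValueError(
        f"row {row}, column {column!r}: cannot parse {cell!r} as yes/no"
    )


def _parse_number(cell: str, row: int, column: str) -> Optional[float]:
    text = cell.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"row {row}, column {column!r}: cannot parse {cell!r} as a number"
        ) from None


def _parse_categorical(
    cell: str, row: int, column: str, allowed: Sequence[str]
) -> Optional[str]:
    text = cell.strip().lower()
    if text == "":
        return None
    if text not in allowed:
        raise ValueError(
            f"row {row}, column {column!r}: unknown label {cell!r} "
            f"(allowed: {', '.join(allowed)})"
        )
    return text


def read_responses(path: str | Path) -> list[RawResponses]:
    """Parse a responses CSV into typed records.

    Errors carry the offending row number (1-based, excluding the header)
    and column name.  Unknown columns and empty files are rejected.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        unknown = set(reader.fieldnames) - set(RESPONSE_COLUMNS)
        if unknown:
            raise ValueError(f"{path}: unknown column(s): {sorted(unknown)}")
        records: list[RawResponses] = []
        for i, row in enumerate(reader, start=1):
            kwargs: dict = {"respondent_id": (row.get("respondent_id") or f"r{i}").strip()}
            for col in _NUM_COLUMNS:
                if col in row and row[col] is not None:
                    kwargs[col] = _parse_number(row[col], i, col)
            for col, allowed in _CAT_COLUMNS.items():
                if col in row and row[col] is not None:
                    kwargs[col] = _parse_categorical(row[col], i, col, allowed)
            for col in _BOOL_COLUMNS:
                if col in row and row[col] is not None:
                    kwargs[col] = _parse_bool(row[col], i, col)
            try:
                records.append(RawResponses(**kwargs))
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from None
    return records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_responses(path: str | Path, responses: Iterable[RawResponses]) -> None:
    """Write records as a responses CSV (lossless round-trip with
    :func:`read_responses`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESPONSE_COLUMNS)
        for r in responses:
            writer.writerow([_format_cell(getattr(r, col)) for col in RESPONSE_COLUMNS])


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


def generate_fixture_cohort(
    prevalences: PrevalenceConfig,
    n: int,
    seed: int,
    registry: Optional[FactorRegistry] = None,
) -> list[RawResponses]:
    """Sample ``n`` synthetic respondents whose raw answers resolve to
    levels drawn from the prevalence configuration.

    Raw fields are generated consistently with the sampled levels: a
    respondent sampled into the male-and-25-35 level gets male sex and an
    age in [25, 35]; paternal age is drawn inside the sampled bin; etc.
    Deterministic for a fixed seed.  ``n = 0`` yields an empty cohort.
    """
    if registry is None:
        registry = default_registry()
    prevalences.validate(registry)
    rng = np.random.default_rng(seed)
    cohort: list[RawResponses] = []
    for i in range(n):
        selections = {
            group.name: group.labels[
                rng.choice(
                    len(group.labels),
                    p=[prevalences.probabilities[group.name][lb] for lb in group.labels],
                )
            ]
            for group in registry
        }
        cohort.append(_responses_from_selections(f"sim{i + 1:05d}", selections, rng))
    return cohort


def _responses_from_selections(
    respondent_id: str, selections: dict[str, str], rng: np.random.Generator
) -> RawResponses:
    kwargs: dict = {"respondent_id": respondent_id}

    bool_map = {
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
    for group, attr in bool_map.items():
        if group in selections:
            kwargs[attr] = selections[group] == "Yes"

    eth = selections.get("Ethnicity")
    if eth is not None:
        if eth == "White":
            kwargs["ethnicity"] = "white"
            # density is still asked; it carries no weight for white
            kwargs["ethnic_density"] = DENSITIES[rng.choice(3)]
        else:
            base, density_part = eth.split(", ")
            kwargs["ethnicity"] = (
                "black_caribbean" if base == "Black Caribbean" else "other"
            )
            kwargs["ethnic_density"] = density_part.split(" ")[0]

    imm = selections.get("Immigration")
    if imm is not None:
        if imm == "Not immigrant":
            kwargs["immigration"] = "none"
            kwargs["origin"] = "not_applicable"
        else:
            kwargs["immigration"] = (
                "first_generation" if imm.startswith("1st") else "second_generation"
            )
            kwargs["origin"] = (
                "north_africa" if "North Africa" in imm else "other"
            )

    pat = selections.get("Paternal age")
    if pat is not None:
        if pat == "<35":
            kwargs["paternal_age"] = float(rng.integers(18, 35))
        elif pat == "35-45":
            kwargs["paternal_age"] = float(rng.integers(35, 46))
        else:
            kwargs["paternal_age"] = float(rng.integers(46, 66))

    male_level = selections.get("Male & 25-35 years old")
    if male_level is not None:
        if male_level == "Yes":
            kwargs["sex"] = "male"
            kwargs["age"] = float(rng.integers(25, 36))
        else:
            sex = "male" if rng.random() < 0.5 else "female"
            kwargs["sex"] = sex
            if sex == "male":
                # avoid the scored age window for male non-hits
                low = rng.random() < 0.5
                kwargs["age"] = float(
                    rng.integers(14, 25) if low else rng.integers(36, 71)
                )
            else:
                kwargs["age"] = float(rng.integers(14, 71))
    return RawResponses(**kwargs)
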