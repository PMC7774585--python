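"""Instrument definition: factor groups, exposure levels, and point weights.

The instrument is a collection of *factor groups*.  Each group offers a set
of mutually exclusive exposure levels, exactly one of which applies to any
respondent.  Every level carries a weight in points on a ``10 * log10(OR)``
scale, stored as an exact multiple of 0.5.  Some groups fold several
logically dependent underlying factors (e.g. immigration generation and
region of origin) into a single scored item; the ``components`` field keeps
track of those underlying factors so the instrument-level factor count is
preserved.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "FactorLevel",
    "FactorGroup",
    "FactorRegistry",
    "default_registry",
    "weight_from_or",
    "combine_nested_weights",
    "validate_registry",
    "load_registry",
]

EVIDENCE_CLASSES = ("I", "II", "III", "IV")

#: tolerance used when checking half-point granularity of weights
_HALF_TOL = 1e-9


def _is_half_multiple(weight: float) -> bool:
    return abs(weight * 2 - round(weight * 2)) < _HALF_TOL


@dataclass(frozen=True)
class FactorLevel:
    """One selectable exposure level with its point weight."""

    label: str
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "weight", float(self.weight))


@dataclass(frozen=True)
class FactorGroup:
    """A set of mutually exclusive levels scored as one item.

    Parameters
    ----------
    name:
        Display name of the group, unique within a registry.
    levels:
        Ordered levels; a scored profile selects exactly one.
    evidence_class:
        Evidence stratum of the underlying factor(s), one of I-IV.
    reference_level:
        Label of the unexposed/baseline level.  The reference level may
        carry a negative (protective) weight.
    components:
        Names of the underlying operationalised factors when this group is
        the result of combining logically dependent factors.  An empty
        tuple means the group corresponds to a single factor.
    """

    name: str
    levels: tuple[FactorLevel, ...]
    evidence_class: str
    reference_level: str
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    def level(self, label: str) -> FactorLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"group {self.name!r} has no level {label!r}")

    def weight(self, label: str) -> float:
        return self.level(label).weight

    @property
    def min_weight(self) -> float:
        return min(lv.weight for lv in self.levels)

    @property
    def max_weight(self) -> float:
        return max(lv.weight for lv in self.levels)

    @property
    def factor_count(self) -> int:
        """Number of underlying operationalised factors in this group."""
        return len(self.components) if self.components else 1


@dataclass(frozen=True)
class FactorRegistry:
    """The full instrument: an ordered collection of factor groups."""

    groups: tuple[FactorGroup, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))

    def __iter__(self) -> Iterator[FactorGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def group(self, name: str) -> FactorGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no factor group named {name!r}")

    @property
    def factor_count(self) -> int:
        """Count of underlying operationalised factors (components counted
        individually)."""
        return sum(g.factor_count for g in self.groups)

    def score_bounds(self) -> tuple[float, float]:
        """(minimum, maximum) achievable total over one level per group."""
        return (
            sum(g.min_weight for g in self.groups),
            sum(g.max_weight for g in self.groups),
        )

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "name": g.name,
                    "evidence_class": g.evidence_class,
                    "reference_level": g.reference_level,
                    "components": list(g.components),
                    "levels": [
                        {"label": lv.label, "weight": lv.weight} for lv in g.levels
                    ],
                }
                for g in self.groups
            ]
        }

    def checksum(self) -> str:
        """Stable content hash, embedded in reports for reproducibility."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def weight_from_or(odds_ratio: float) -> float:
    """Convert an odds ratio to instrument points.

    Points are ``10 * log10(OR)`` rounded to the nearest half point, the
    granularity at which every shipped weight is expressed.

    Raises
    ------
    ValueError
        If ``odds_ratio`` is not strictly positive.
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return round(10.0 * math.log10(odds_ratio) * 2) / 2


def combine_nested_weights(base_weight: float, increment_weight: float) -> float:
    """Fold a nested exposure into its parent category.

    Combination is additive on the point (log odds) scale: e.g. the weight
    for a first-generation immigrant from a higher-risk region is the
    generic first-generation weight plus the region increment.
    """
    for w in (base_weight, increment_weight):
        if not _is_half_multiple(w):
            raise ValueError(f"weight {w} is not a multiple of 0.5")
    return base_weight + increment_weight


# ---------------------------------------------------------------------------
# Default instrument
# ---------------------------------------------------------------------------

# group name, evidence class, reference level, components, [(label, weight)...]
_DEFAULT_TABLE: tuple = (
    ("Childhood trauma", "I", "No", (), [("Yes", 4.0), ("No", -0.5)]),
    (
        "Ethnicity",
        "I",
        "White",
        (
            "white_ethnicity",
            "black_caribbean_ethnicity",
            "low_ethnic_density",
            "medium_ethnic_density",
            "high_ethnic_density",
        ),
        [
            ("White", -2.0),
            ("Black Caribbean, low ethnic density", 6.0),
            ("Black Caribbean, medium ethnic density", 5.5),
            ("Black Caribbean, high ethnic density", 3.5),
            ("Other, low ethnic density", 3.5),
            ("Other, medium ethnic density", 3.0),
            ("Other, high ethnic density", 1.0),
        ],
    ),
    (
        "Immigration",
        "II",
        "Not immigrant",
        (
            "first_generation_immigrant",
            "second_generation_immigrant",
            "north_african_origin",
        ),
        [
            ("Not immigrant", -0.5),
            ("1st generation, North Africa", 3.0),
            ("1st generation, other regions", 2.0),
            ("2nd generation, North Africa", 2.5),
            ("2nd generation, other regions", 1.5),
        ],
    ),
    ("Non-right-handedness", "IV", "No", (), [("Yes", 2.0), ("No", 0.0)]),
    ("Pollution", "IV", "No", (), [("Yes", 2.0), ("No", -5.5)]),
    ("Urbanicity", "III", "No", (), [("Yes", 1.0), ("No", -2.5)]),
    (
        "Winter or spring birth in northern hemisphere",
        "IV",
        "No",
        (),
        [("Yes", 0.0), ("No", 0.0)],
    ),
    (
        "Paternal age",
        "III",
        "<35",
        (),
        [("<35", -0.5), ("35-45", 0.5), (">45", 3.5)],
    ),
    ("Low paternal socioeconomic status", "IV", "No", (), [("Yes", 1.0), ("No", 0.0)]),
    ("Parental severe mental illness", "II", "No", (), [("Yes", 5.5), ("No", -2.0)]),
    ("Adult life events", "III", "No", (), [("Yes", 5.5), ("No", -2.0)]),
    ("Daily smoker", "IV", "No", (), [("Yes", 3.0), ("No", -0.5)]),
    ("Heavy cannabis use", "III", "No", (), [("Yes", 7.0), ("No", 0.0)]),
    (
        "Hearing problems in past 12 months",
        "IV",
        "No",
        (),
        [("Yes", 2.0), ("No", 0.0)],
    ),
    ("Trait anhedonia", "IV", "No", (), [("Yes", 6.5), ("No", 0.0)]),
    ("Male & 25-35 years old", "IV", "No", (), [("Yes", 2.0), ("No", 0.0)]),
)


def default_registry() -> FactorRegistry:
    """Build the shipped 16-group / 22-factor instrument.

    Weights are stored constants; they are never recomputed from source
    effect sizes at runtime.
    """
    groups = tuple(
        FactorGroup(
            name=name,
            levels=tuple(FactorLevel(lb, w) for lb, w in levels),
            evidence_class=ec,
            reference_level=ref,
            components=components,
        )
        for name, ec, ref, components, levels in _DEFAULT_TABLE
    )
    return FactorRegistry(groups=groups)


def validate_registry(registry: FactorRegistry) -> list[str]:
    """Structural validation.  Returns a list of violation messages;
    an empty list means the registry is valid."""
    violations: list[str] = []
    seen_names: set[str] = set()
    for g in registry.groups:
        if g.name in seen_names:
            violations.append(f"duplicate group name {g.name!r}")
        seen_names.add(g.name)
        if not g.levels:
            violations.append(f"group {g.name!r} has no levels")
            continue
        seen_labels: set[str] = set()
        for lv in g.levels:
            if lv.label in seen_labels:
                violations.append(
                    f"group {g.name!r} has duplicate level label {lv.label!r}"
                )
            seen_labels.add(lv.label)
            if not _is_half_multiple(lv.weight):
                violations.append(
                    f"group {g.name!r} level {lv.label!r} weight {lv.weight} "
                    "is not a multiple of 0.5"
                )
        if g.reference_level not in seen_labels:
            violations.append(
                f"group {g.name!r} reference level {g.reference_level!r} "
                "does not name an existing level"
            )
        if g.evidence_class not in EVIDENCE_CLASSES:
            violations.append(
                f"group {g.name!r} evidence class {g.evidence_class!r} invalid"
            )
    return violations


def load_registry(path: str | Path) -> FactorRegistry:
    """Load a registry override from a YAML or JSON file.

    The file mirrors :meth:`FactorRegistry.to_dict`.  The loaded registry
    is validated; any violation raises ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "groups" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'groups' key")
    groups = []
    for raw in data["groups"]:
        groups.append(
            FactorGroup(
                name=raw["name"],
                levels=tuple(
                    FactorLevel(lv["label"], float(lv["weight"]))
                    for lv in raw["levels"]
                ),
                evidence_class=raw.get("evidence_class", "IV"),
                reference_level=raw["reference_level"],
                components=tuple(raw.get("components", ())),
            )
        )
    registry = FactorRegistry(groups=tuple(groups))
    violations = validate_registry(registry)
    if violations:
        raise ValueError(f"{path}: invalid registry: " + "; ".join(violations))
    return registry
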