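"""Monte-Carlo simulation of the score distribution in a synthetic population.

Each synthetic individual is generated by sampling one exposure level per
factor group, independently across groups, from a configurable prevalence
distribution; the individual's score is the weighted sum.  No dependence
structure between exposures is modelled.

The shipped default prevalences are round illustrative values; they are NOT
population estimates and summaries computed from them are not comparable to
any published cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import stats

from .factor_model import FactorRegistry, default_registry
from .scoring import CohortSummary, summarize_scores

__all__ = [
    "PrevalenceConfig",
    "SimulationSummary",
    "default_prevalences",
    "load_prevalences",
    "expected_score",
    "simulate_population",
    "adjusted_jarque_bera",
    "score_histogram",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class PrevalenceConfig:
    """Per-group categorical distribution over level labels."""

    probabilities: dict  # group name -> {level label -> probability}

    def validate(self, registry: FactorRegistry) -> None:
        """Raise ``ValueError`` on any mismatch with the registry."""
        missing = set(registry.group_names) - set(self.probabilities)
        if missing:
            raise ValueError(f"prevalence config missing groups: {sorted(missing)}")
        extra = set(self.probabilities) - set(registry.group_names)
        if extra:
            raise ValueError(f"prevalence config has unknown groups: {sorted(extra)}")
        for group in registry:
            dist = self.probabilities[group.name]
            unknown = set(dist) - set(group.labels)
            if unknown:
                raise ValueError(
                    f"group {group.name!r}: unknown levels {sorted(unknown)}"
                )
            absent = set(group.labels) - set(dist)
            if absent:
                raise ValueError(
                    f"group {group.name!r}: no probability for levels "
                    f"{sorted(absent)}"
                )
            probs = list(dist.values())
            if any(p < 0 for p in probs):
                raise ValueError(f"group {group.name!r}: negative probability")
            if abs(sum(probs) - 1.0) > _PROB_TOL:
                raise ValueError(
                    f"group {group.name!r}: probabilities sum to {sum(probs)}, "
                    "expected 1"
                )

    def group_arrays(
        self, registry: FactorRegistry
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per group, (probabilities, weights) aligned to registry level order."""
        out = []
        for group in registry:
            dist = self.probabilities[group.name]
            probs = np.array([dist[lv.label] for lv in group.levels], dtype=float)
            weights = np.array([lv.weight for lv in group.levels], dtype=float)
            out.append((probs, weights))
        return out


@dataclass
class SimulationSummary:
    """Descriptive statistics of one simulated score distribution."""

    n_permutations: int
    seed: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    quartile_ranges: list[dict]
    threshold_proportions: dict[float, float]
    ajb_statistic: float
    ajb_p: float

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
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
            "normality": {"statistic": self.ajb_statistic, "p": self.ajb_p},
        }


# Illustrative round prevalences only — NOT estimates from any population.
_DEFAULT_PREVALENCES: dict = {
    "Childhood trauma": {"Yes": 0.30, "No": 0.70},
    "Ethnicity": {
        "White": 0.80,
        "Black Caribbean, low ethnic density": 0.01,
        "Black Caribbean, medium ethnic density": 0.02,
        "Black Caribbean, high ethnic density": 0.02,
        "Other, low ethnic density": 0.05,
        "Other, medium ethnic density": 0.05,
        "Other, high ethnic density": 0.05,
    },
    "Immigration": {
        "Not immigrant": 0.85,
        "1st generation, North Africa": 0.01,
        "1st generation, other regions": 0.07,
        "2nd generation, North Africa": 0.01,
        "2nd generation, other regions": 0.06,
    },
    "Non-right-handedness": {"Yes": 0.10, "No": 0.90},
    "Pollution": {"Yes": 0.50, "No": 0.50},
    "Urbanicity": {"Yes": 0.70, "No": 0.30},
    "Winter or spring birth in northern hemisphere": {"Yes": 0.50, "No": 0.50},
    "Paternal age": {"<35": 0.60, "35-45": 0.30, ">45": 0.10},
    "Low paternal socioeconomic status": {"Yes": 0.25, "No": 0.75},
    "Parental severe mental illness": {"Yes": 0.05, "No": 0.95},
    "Adult life events": {"Yes": 0.35, "No": 0.65},
    "Daily smoker": {"Yes": 0.20, "No": 0.80},
    "Heavy cannabis use": {"Yes": 0.05, "No": 0.95},
    "Hearing problems in past 12 months": {"Yes": 0.10, "No": 0.90},
    "Trait anhedonia": {"Yes": 0.05, "No": 0.95},
    "Male & 25-35 years old": {"Yes": 0.10, "No": 0.90},
}


def default_prevalences() -> PrevalenceConfig:
    """Illustrative prevalence configuration (round values, clearly not
    population estimates).  Replace via :func:`load_prevalences` for any
    substantive use."""
    return PrevalenceConfig(
        probabilities={g: dict(d) for g, d in _DEFAULT_PREVALENCES.items()}
    )


def load_prevalences(path: str | Path) -> PrevalenceConfig:
    """Load a prevalence config from YAML or JSON keyed by group then level."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of group -> level -> p")
    return PrevalenceConfig(
        probabilities={g: {k: float(v) for k, v in d.items()} for g, d in data.items()}
    )


def expected_score(
    prevalences: PrevalenceConfig, registry: FactorRegistry
) -> tuple[float, float]:
    """Analytic mean and SD of the score under independent sampling.

    mean = sum over groups of E[w]; variance = sum over groups of Var[w].
    """
    prevalences.validate(registry)
    mean = 0.0
    var = 0.0
    for probs, weights in prevalences.group_arrays(registry):
        m = float(np.dot(probs, weights))
        mean += m
        var += float(np.dot(probs, weights**2)) - m * m
    return mean, float(np.sqrt(var))


def simulate_population(
    prevalences: PrevalenceConfig,
    registry: FactorRegistry,
    n: int,
    seed: int,
    thresholds: Sequence[float] = (5.0, 15.0),
    chunk_size: int = 2_000_000,
    return_scores: bool = False,
) -> SimulationSummary | tuple[SimulationSummary, np.ndarray]:
    """Draw ``n`` synthetic individuals and summarize their scores.

    Sampling is chunked so very large ``n`` keeps peak memory at roughly
    one float64 vector of length ``n`` plus one chunk.  Reproducible for a
    fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prevalences.validate(registry)
    arrays = prevalences.group_arrays(registry)
    rng = np.random.default_rng(seed)
    scores = np.empty(n, dtype=float)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        m = stop - start
        chunk = np.zeros(m, dtype=float)
        for probs, weights in arrays:
            cum = np.cumsum(probs)
            cum[-1] = 1.0  # guard against fp undershoot
            idx = np.searchsorted(cum, rng.random(m), side="right")
            chunk += weights[idx]
        scores[start:stop] = chunk

    base = summarize_scores(scores, thresholds=thresholds)
    if np.ptp(scores) > 0:
        ajb_stat, ajb_p = adjusted_jarque_bera(scores)
    else:  # degenerate point-mass distribution
        ajb_stat, ajb_p = float("nan"), float("nan")
    summary = SimulationSummary(
        n_permutations=n,
        seed=seed,
        mean=base.mean,
        sd=base.sd,
        median=base.median,
        min=base.min,
        max=base.max,
        quartile_ranges=base.quartile_ranges,
        threshold_proportions=base.threshold_proportions,
        ajb_statistic=ajb_stat,
        ajb_p=ajb_p,
    )
    if return_scores:
        return summary, scores
    return summary


def adjusted_jarque_bera(sample: Sequence[float]) -> tuple[float, float]:
    """Normality test on skewness and kurtosis with exact small-sample
    moment corrections.

    With S the sample skewness and K the sample kurtosis (non-excess),

        AJB = S^2 / Var(S) + (K - E[K])^2 / Var(K)

    where E[K] = 3(n-1)/(n+1), Var(S) = 6(n-2)/((n+1)(n+3)) and
    Var(K) = 24n(n-2)(n-3)/((n+1)^2 (n+3)(n+5)); the p-value is taken from
    a chi-square distribution with 2 degrees of freedom.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    centered = x - x.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        raise ValueError("constant sample: moments undefined")
    skew = float(np.mean(centered**3)) / m2**1.5
    kurt = float(np.mean(centered**4)) / m2**2
    e_k = 3.0 * (n - 1) / (n + 1)
    var_s = 6.0 * (n - 2) / ((n + 1) * (n + 3))
    var_k = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    statistic = skew**2 / var_s + (kurt - e_k) ** 2 / var_k
    p = float(stats.chi2.sf(statistic, df=2))
    return float(statistic), p


def score_histogram(scores: np.ndarray) -> list[tuple[float, int]]:
    """(score, count) pairs over the distinct half-point scores, ascending.
    Suitable for CSV export and bar plotting."""
    values, counts = np.unique(np.asarray(scores, dtype=float), return_counts=True)
    return [(float(v), int(c)) for v, c in zip(values, counts)]
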