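"""Shared data model for the DDI-severity / synergy analysis.

The unit of observation is one (drug A, drug B, cell line) row carrying up to
seven synergy scores; toxicity severity is an ordinal label per unordered drug
pair, graded Minor (0) < Moderate (1) < Major (2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Optional

SYNERGY_SCORES = ("bliss", "hsa", "loewe", "zip", "s_max", "s_mean", "s_sum")

_PUNCT_RE = re.compile(r"[^a-z0-9]+")


def normalize_name(name: str) -> str:
    """Normalize a drug name: lowercase, strip whitespace and punctuation.

    Idempotent by construction; no fuzzy matching is attempted.
    """
    return _PUNCT_RE.sub("", name.strip().lower())


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Canonical unordered pair key: lexicographically sorted."""
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


class Severity(IntEnum):
    """Ordinal DDI severity; the ordering drives every trend test."""

    MINOR = 0
    MODERATE = 1
    MAJOR = 2

    @property
    def label(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_word(cls, word: str) -> "Severity":
        try:
            return cls[word.strip().upper()]
        except KeyError:
            raise ValueError(f"unrecognized severity token: {word!r}") from None


SEVERITY_LABELS = tuple(s.label for s in Severity)  # ("Minor", "Moderate", "Major")


@dataclass(frozen=True)
class ToxicityLabel:
    level: Severity
    source: str  # "drugbank" | "ddinter" | "synthetic"


@dataclass
class DrugRecord:
    drug_id: str
    name: str  # normalized
    smiles: Optional[str] = None
    targets: frozenset[str] = frozenset()  # UniProt accessions


@dataclass
class ComboObservation:
    """One (drug A, drug B, cell line) row.

    The pair is stored canonically (drug_a <= drug_b); missing scores are
    simply absent from ``synergy``, never encoded as zero.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    synergy: dict[str, float] = field(default_factory=dict)
    toxicity: dict[str, ToxicityLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drug_a, self.drug_b = canonical_pair(self.drug_a, self.drug_b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


@dataclass
class AnalysisDataset:
    drugs: dict[str, DrugRecord]
    observations: list[ComboObservation]
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for obs in self.observations:
            if obs.drug_a not in self.drugs or obs.drug_b not in self.drugs:
                raise ValueError(
                    f"observation references unknown drug: {obs.pair}"
                )

    def pairs(self) -> list[tuple[str, str]]:
        """Distinct canonical pairs, in sorted order (deterministic)."""
        return sorted({obs.pair for obs in self.observations})


@dataclass
class TrendResult:
    """One statistical comparison from the nonparametric battery."""

    test_name: str
    statistic: float
    p_value: float
    effect_size: float
    effect_name: str
    direction: str  # "increasing" | "decreasing" | "two_sided"
    n_per_group: list[int]
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p": self.p_value,
            "effect": self.effect_size,
            "effect_name": self.effect_name,
            "direction": self.direction,
            "n_per_group": list(self.n_per_group),
            "notes": self.notes,
        }
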