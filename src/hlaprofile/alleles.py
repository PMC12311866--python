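"""HLA nomenclature and elementary epidemiological quantities.

The analysis operates at two-field allele resolution (``LOCUS*group:protein``,
e.g. ``A*01:01``) over the six classical loci: class I A, B, C and class II
DPB1, DQB1, DRB1.  Other loci (DQA1, DPA1, ...) are outside the scope of the
profile and are rejected loudly rather than silently classified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum


class Locus(str, Enum):
    """The six classical HLA loci covered by the profile."""

    A = "A"
    B = "B"
    C = "C"
    DPB1 = "DPB1"
    DQB1 = "DQB1"
    DRB1 = "DRB1"


#: canonical locus ordering used for stable profile layout
LOCUS_ORDER: tuple[Locus, ...] = (
    Locus.A,
    Locus.B,
    Locus.C,
    Locus.DPB1,
    Locus.DQB1,
    Locus.DRB1,
)

CLASS_I_LOCI = frozenset({Locus.A, Locus.B, Locus.C})
CLASS_II_LOCI = frozenset({Locus.DPB1, Locus.DQB1, Locus.DRB1})


class AlleleParseError(ValueError):
    """Raised for names that cannot be resolved to a two-field classical allele."""


@dataclass(frozen=True)
class HlaAllele:
    """A two-field HLA allele, e.g. ``DQB1*03:02``.

    ``field1`` is the allele group and ``field2`` the specific protein.
    HLA class is derived from the locus: class I molecules (A, B, C) present
    intracellular peptides to CD8+ T cells; class II molecules (DPB1, DQB1,
    DRB1) present extracellular peptides to CD4+ T cells.
    """

    locus: Locus
    field1: int
    field2: int

    def __post_init__(self) -> None:
        if self.field1 < 0 or self.field2 < 0:
            raise AlleleParseError(
                f"negative allele fields: {self.field1}:{self.field2}"
            )

    @property
    def hla_class(self) -> str:
        return "I" if self.locus in CLASS_I_LOCI else "II"

    @property
    def gene(self) -> str:
        return self.locus.value

    @property
    def name(self) -> str:
        return f"{self.locus.value}*{self.field1:02d}:{self.field2:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    @property
    def sort_key(self) -> tuple[int, int, int]:
        """Canonical ordering: locus (A, B, C, DPB1, DQB1, DRB1), then fields."""
        return (LOCUS_ORDER.index(self.locus), self.field1, self.field2)

    def __lt__(self, other: "HlaAllele") -> bool:
        return self.sort_key < other.sort_key


def parse_allele(name: str) -> HlaAllele:
    """Parse an HLA allele name into a two-field :class:`HlaAllele`.

    Accepts the colon-delimited style (``A*01:01``), the legacy four-digit
    style without a colon (``DRB1*0401``, split 2+2), and higher-resolution
    names (``A*01:01:01``), which are truncated to two fields with a warning.

    Raises
    ------
    AlleleParseError
        If the locus is not one of the six classical loci or the field
        structure is malformed.
    """
    if not name or not name.strip():
        raise AlleleParseError("empty allele name")
    token = name.strip()
    if "*" not in token:
        raise AlleleParseError(f"missing '*' separator in allele name {token!r}")
    locus_str, _, fields = token.partition("*")
    locus_str = locus_str.removeprefix("HLA-").strip().upper()
    try:
        locus = Locus(locus_str)
    except ValueError:
        raise AlleleParseError(
            f"unknown locus {locus_str!r} in allele name {token!r}; "
            f"expected one of {', '.join(l.value for l in LOCUS_ORDER)}"
        ) from None
    fields = fields.strip()
    if ":" in fields:
        parts = fields.split(":")
        if len(parts) > 2:
            warnings.warn(
                f"allele {token!r} has more than two fields; truncating to "
                f"two-field resolution",
                stacklevel=2,
            )
            parts = parts[:2]
        f1_str, f2_str = parts[0], parts[1]
    else:
        # legacy style: a bare digit run such as "0401", split 2+2
        if len(fields) != 4 or not fields.isdigit():
            raise AlleleParseError(
                f"malformed allele fields {fields!r} in {token!r}: expected "
                f"'ff:ss' or a four-digit run"
            )
        f1_str, f2_str = fields[:2], fields[2:]
    if not (f1_str.isdigit() and f2_str.isdigit()):
        raise AlleleParseError(
            f"non-numeric allele fields {fields!r} in {token!r}"
        )
    return HlaAllele(locus=locus, field1=int(f1_str), field2=int(f2_str))


def prevalence_pct(case_count: int, population: int) -> float:
    """Disease prevalence as a percentage: ``100 * case_count / population``."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if case_count < 0:
        raise ValueError(f"case count must be non-negative, got {case_count}")
    if case_count > population:
        raise ValueError(
            f"case count {case_count} exceeds population {population}"
        )
    return 100.0 * case_count / population


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """One (allele, country) population-frequency observation, in [0, 1]."""

    allele: HlaAllele
    country: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(
                f"allele frequency must lie in [0, 1], got {self.frequency} "
                f"for {self.allele.name} in {self.country}"
            )


@dataclass(frozen=True)
class PrevalenceRecord:
    """Per-country disease burden: case count, population, percent and log prevalence."""

    country: str
    case_count: int
    population: int
    prevalence_pct: float
    log_prevalence: float

    @classmethod
    def from_counts(cls, country: str, case_count: int, population: int) -> "PrevalenceRecord":
        pct = prevalence_pct(case_count, population)
        if pct <= 0:
            raise ValueError(
                f"prevalence must be positive to be log-transformed; "
                f"{country} has {case_count} cases"
            )
        return cls(country, case_count, population, pct, math.log(pct))

    @classmethod
    def from_prevalence(
        cls, country: str, pct: float, population: int = 10_000_000
    ) -> "PrevalenceRecord":
        """Build a record from a percent prevalence directly.

        A nominal population (default 1e7) back-converts to an integer case
        count so the record round-trips through count-based readers.
        """
        if not 0 < pct <= 100:
            raise ValueError(f"prevalence_pct must lie in (0, 100], got {pct}")
        cases = round(pct / 100.0 * population)
        return cls(country, cases, population, pct, math.log(pct))


#: abbreviations used in published scatter plots for the 14 Continental
#: Western European countries, mapped to canonical keys
COUNTRY_ALIASES: dict[str, str] = {
    "au": "austria",
    "be": "belgium",
    "de": "denmark",
    "fi": "finland",
    "fr": "france",
    "ge": "germany",
    "gr": "greece",
    "it": "italy",
    "ne": "netherlands",
    "no": "norway",
    "po": "portugal",
    "sp": "spain",
    "swe": "sweden",
    "swi": "switzerland",
}


def normalize_country(name: str) -> str:
    """Canonicalize a country key: case-insensitive, alias-aware."""
    key = name.strip().lower()
    if not key:
        raise ValueError("empty country name")
    return COUNTRY_ALIASES.get(key, key)
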