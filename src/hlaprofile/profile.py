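"""Construction of population-level HLA-disease association profiles.

The central computation: for every allele reported in at least
``min_countries`` countries, correlate its population frequency with the
natural log of percent disease prevalence across the countries where both
are known, and Fisher z-transform the Pearson correlation,

    r' = atanh(r) = 0.5 * ln((1 + r) / (1 - r)).

The signed r' is the profile statistic: negative values mark presumed
protective alleles, positive values presumed susceptibility alleles, and
|r'| measures association strength.  Because allele reporting is sparse,
each allele's correlation uses only the countries reporting that allele
(intersected with the prevalence table), so the per-allele sample size N
varies across the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alleles import HlaAllele
from .io import AlleleFrequencyTable, PrevalenceTable


class DegenerateDataError(ValueError):
    """Raised when a correlation is undefined (too few pairs, zero variance, |r|=1)."""


@dataclass(frozen=True)
class ProfileEntry:
    """Per-allele profile row: sample size N, Pearson r, and r' = atanh(r)."""

    allele: HlaAllele
    n_countries: int
    r: float
    r_prime: float

    @property
    def direction(self) -> str:
        return "protective" if self.r_prime < 0 else "susceptibility"


@dataclass
class Profile:
    """An ordered collection of per-allele association entries.

    Entries are kept in canonical order (locus A, B, C, DPB1, DQB1, DRB1,
    then numeric fields); allele names are unique.  ``metadata`` records the
    coverage threshold, the prevalence transform, and any alleles that were
    dropped as un-analyzable (with the reason) rather than silently.
    """

    entries: list[ProfileEntry]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [e.allele.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate alleles in profile")
        self.entries = sorted(self.entries, key=lambda e: e.allele.sort_key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def entry(self, name: str) -> ProfileEntry:
        for e in self.entries:
            if e.allele.name == name:
                return e
        raise KeyError(name)

    def restrict(self, hla_class: str | None = None, gene: str | None = None) -> "Profile":
        kept = [
            e
            for e in self.entries
            if (hla_class is None or e.allele.hla_class == hla_class)
            and (gene is None or e.allele.gene == gene)
        ]
        return Profile(entries=kept, metadata=dict(self.metadata))

    @property
    def r_prime(self) -> np.ndarray:
        return np.array([e.r_prime for e in self.entries])

    @property
    def n_countries(self) -> np.ndarray:
        return np.array([e.n_countries for e in self.entries], dtype=int)

    @property
    def classes(self) -> list[str]:
        return [e.allele.hla_class for e in self.entries]

    @property
    def genes(self) -> list[str]:
        return [e.allele.gene for e in self.entries]


def filter_by_coverage(
    freq: AlleleFrequencyTable,
    prev: PrevalenceTable,
    min_countries: int = 9,
) -> AlleleFrequencyTable:
    """Keep alleles reported in >= ``min_countries`` countries that also have
    prevalence data.

    Coverage is counted over the intersection of each allele's reporting
    countries with the prevalence table, since only those observations enter
    the correlation.  The filtered table carries ``n_alleles_before`` /
    ``n_alleles_after`` attributes for bookkeeping.
    """
    if min_countries < 3:
        raise ValueError(
            f"min_countries must be >= 3 for a meaningful correlation, "
            f"got {min_countries}"
        )
    common = set(freq.countries) & set(prev.countries)
    if not common:
        raise ValueError(
            "no countries in common between the frequency and prevalence tables"
        )
    usable: dict[HlaAllele, int] = {}
    for rec in freq.records:
        if rec.country in common:
            usable[rec.allele] = usable.get(rec.allele, 0) + 1
    keep = {a for a, n in usable.items() if n >= min_countries}
    out = freq.subset(keep)
    out.n_alleles_before = len(freq.alleles)
    out.n_alleles_after = len(keep)
    return out


def pair_observations(
    allele: HlaAllele,
    freq: AlleleFrequencyTable,
    prev: PrevalenceTable,
) -> list[tuple[float, float]]:
    """(frequency, log prevalence) pairs over countries where both are known."""
    pairs = [
        (rec.frequency, prev.log_prevalence(rec.country))
        for rec in freq.records
        if rec.allele == allele and rec.country in prev
    ]
    if not any(rec.allele == allele for rec in freq.records):
        raise KeyError(f"allele {allele.name} not present in frequency table")
    return pairs


def pearson_r(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson product-moment correlation of (x, y) pairs.

    Requires at least 3 pairs and non-constant coordinates.
    """
    if len(pairs) < 3:
        raise DegenerateDataError(
            f"need >= 3 observation pairs for a correlation, got {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            "correlation undefined: zero variance in one coordinate"
        )
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(xc @ xc) * math.sqrt(yc @ yc)
    if denom == 0.0:  # numerically constant coordinate (e.g. denormal spread)
        raise DegenerateDataError(
            "correlation undefined: zero variance in one coordinate"
        )
    r = float(xc @ yc / denom)
    return max(-1.0, min(1.0, r))


def fisher_z(r: float, clamp: bool = False) -> float:
    """Fisher z-transform r' = atanh(r), a variance-stabilizing map of r.

    |r| = 1 is a domain error (r' would be infinite and would poison
    downstream ANOVAs); pass ``clamp=True`` to clip at 1 - 1e-12 instead,
    which is occasionally useful on tiny synthetic inputs.
    """
    if abs(r) >= 1.0:
        if not clamp:
            raise DegenerateDataError(
                f"fisher_z undefined for |r| >= 1 (got r={r}); "
                f"use clamp=True to clip"
            )
        r = math.copysign(1.0 - 1e-12, r)
    return math.atanh(r)


def build_profile(
    freq: AlleleFrequencyTable,
    prev: PrevalenceTable,
    min_countries: int = 9,
    clamp: bool = False,
) -> Profile:
    """Build the full association profile from frequency and prevalence tables.

    Composes coverage filtering, per-allele pairing, Pearson correlation and
    the Fisher z-transform.  Alleles whose correlation is undefined (constant
    frequency, or |r| = 1 without ``clamp``) are listed under
    ``metadata['unanalyzable']`` with the reason, never silently dropped.
    """
    filtered = filter_by_coverage(freq, prev, min_countries)
    entries: list[ProfileEntry] = []
    unanalyzable: dict[str, str] = {}
    for allele in filtered.alleles:
        pairs = pair_observations(allele, filtered, prev)
        try:
            r = pearson_r(pairs)
            rp = fisher_z(r, clamp=clamp)
        except DegenerateDataError as exc:
            unanalyzable[allele.name] = str(exc)
            continue
        entries.append(
            ProfileEntry(allele=allele, n_countries=len(pairs), r=r, r_prime=rp)
        )
    return Profile(
        entries=entries,
        metadata={
            "min_countries": min_countries,
            "prevalence_transform": "ln(percent)",
            "n_alleles_before_filter": filtered.n_alleles_before,
            "n_alleles_after_filter": filtered.n_alleles_after,
            "unanalyzable": unanalyzable,
        },
    )


def rank_profile(profile: Profile, direction: str, k: int) -> list[ProfileEntry]:
    """Top-k entries by association strength in one direction.

    ``susceptibility``: descending r'; ``protective``: ascending r'.
    Ties are broken by canonical allele order.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if direction not in ("protective", "susceptibility"):
        raise ValueError(f"direction must be protective|susceptibility, got {direction!r}")
    sign = 1.0 if direction == "protective" else -1.0
    ordered = sorted(
        profile.entries, key=lambda e: (sign * e.r_prime, e.allele.sort_key)
    )
    return ordered[:k]
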