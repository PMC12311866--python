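"""Readers and writers for allele-frequency tables, prevalence tables,
profiles, and statistics reports, plus the packaged reference profile.

Two tabular dialects are supported for allele frequencies:

``simple_csv``
    RFC-4180 CSV with columns ``allele,country,frequency``.
``afnd_export``
    The export layout of population allele-frequency databases: columns
    ``Allele``, ``Population`` (or ``Country``), and ``Overall Allele
    Frequency``.  Frequencies are proportions in [0, 1] unless the frequency
    column header carries a ``(%)`` marker.

Profiles are written as UTF-8 TSV with a ``.`` decimal separator and no
locale dependence; statistics reports are JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

from .alleles import (
    AlleleFrequencyRecord,
    HlaAllele,
    PrevalenceRecord,
    normalize_country,
    parse_allele,
)

Source = Union[str, Path, IO[str]]

_FIXTURE_RESOURCE = "t1d_hla_profile.tsv"


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class AlleleFrequencyTable:
    """Sparse allele x country frequency observations.

    Not every allele is reported in every country; the per-allele country
    coverage is exactly what the downstream coverage filter acts on.
    """

    records: list[AlleleFrequencyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[HlaAllele, str], float] = {}
        for rec in self.records:
            key = (rec.allele, rec.country)
            if key in self._index:
                raise TableFormatError(
                    f"duplicate (allele, country) pair: "
                    f"{rec.allele.name} / {rec.country}"
                )
            self._index[key] = rec.frequency

    def __len__(self) -> int:
        return len(self.records)

    @property
    def countries(self) -> list[str]:
        """Country keys in first-seen order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.country, None)
        return list(seen)

    @property
    def alleles(self) -> list[HlaAllele]:
        """Distinct alleles in canonical order."""
        return sorted({rec.allele for rec in self.records})

    def coverage(self) -> dict[HlaAllele, int]:
        """Number of countries reporting each allele."""
        counts: dict[HlaAllele, int] = {}
        for rec in self.records:
            counts[rec.allele] = counts.get(rec.allele, 0) + 1
        return counts

    def countries_for(self, allele: HlaAllele) -> list[str]:
        return [rec.country for rec in self.records if rec.allele == allele]

    def frequency(self, allele: HlaAllele, country: str) -> float:
        return self._index[(allele, country)]

    def subset(self, alleles: Iterable[HlaAllele]) -> "AlleleFrequencyTable":
        keep = set(alleles)
        return AlleleFrequencyTable(
            [rec for rec in self.records if rec.allele in keep]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele": [rec.allele.name for rec in self.records],
                "country": [rec.country for rec in self.records],
                "frequency": [rec.frequency for rec in self.records],
            }
        )


@dataclass
class PrevalenceTable:
    """Per-country prevalence records keyed by canonical country name."""

    records: list[PrevalenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_country: dict[str, PrevalenceRecord] = {}
        for rec in self.records:
            if rec.country in self._by_country:
                raise TableFormatError(f"duplicate country: {rec.country}")
            if not math.isfinite(rec.log_prevalence):
                raise TableFormatError(
                    f"non-finite log prevalence for {rec.country}"
                )
            self._by_country[rec.country] = rec

    def __len__(self) -> int:
        return len(self.records)

    @property
    def countries(self) -> list[str]:
        return list(self._by_country)

    def __contains__(self, country: str) -> bool:
        return country in self._by_country

    def log_prevalence(self, country: str) -> float:
        return self._by_country[country].log_prevalence

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": [r.country for r in self.records],
                "cases": [r.case_count for r in self.records],
                "population": [r.population for r in self.records],
                "prevalence_pct": [r.prevalence_pct for r in self.records],
                "log_prevalence": [r.log_prevalence for r in self.records],
            }
        )


def _require_columns(df: pd.DataFrame, required: dict[str, list[str]], what: str) -> dict[str, str]:
    """Resolve required logical columns to actual column names (case-insensitive)."""
    lower = {c.lower().strip(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for logical, candidates in required.items():
        for cand in candidates:
            if cand.lower() in lower:
                resolved[logical] = lower[cand.lower()]
                break
        else:
            raise TableFormatError(
                f"{what}: missing required column {candidates[0]!r} "
                f"(have: {list(df.columns)})"
            )
    return resolved


def read_allele_frequencies(source: Source, dialect: str = "simple_csv") -> AlleleFrequencyTable:
    """Read an allele-frequency table in the given dialect.

    Every allele name is parsed and validated; frequencies must lie in
    [0, 1] (or [0, 100] for a percent-marked column in ``afnd_export``);
    duplicate (allele, country) rows are an error.
    """
    if dialect == "simple_csv":
        df = pd.read_csv(source)
        cols = _require_columns(
            df,
            {"allele": ["allele"], "country": ["country"], "frequency": ["frequency"]},
            "simple_csv",
        )
        percent = False
    elif dialect == "afnd_export":
        df = pd.read_csv(source)
        cols = _require_columns(
            df,
            {
                "allele": ["Allele"],
                "country": ["Population", "Country"],
                "frequency": ["Overall Allele Frequency", "Overall Allele Frequency (%)"],
            },
            "afnd_export",
        )
        percent = "(%)" in cols["frequency"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    records = []
    for name, ctry, raw_freq in zip(
        df[cols["allele"]], df[cols["country"]], df[cols["frequency"]]
    ):
        allele = parse_allele(str(name))
        country = normalize_country(str(ctry))
        freq = float(raw_freq)
        if percent:
            freq /= 100.0
        if not 0.0 <= freq <= 1.0:
            raise TableFormatError(
                f"frequency {freq} out of range [0, 1] for "
                f"{allele.name} in {country}"
            )
        records.append(AlleleFrequencyRecord(allele, country, freq))
    return AlleleFrequencyTable(records)


def read_prevalence(source: Source) -> PrevalenceTable:
    """Read per-country prevalence as ``country,cases,population`` or
    ``country,prevalence_pct``."""
    df = pd.read_csv(source)
    lower = {c.lower().strip() for c in df.columns}
    records = []
    if {"cases", "population"} <= lower:
        cols = _require_columns(
            df,
            {"country": ["country"], "cases": ["cases"], "population": ["population"]},
            "prevalence",
        )
        for ctry, cases, pop in zip(
            df[cols["country"]], df[cols["cases"]], df[cols["population"]]
        ):
            records.append(
                PrevalenceRecord.from_counts(
                    normalize_country(str(ctry)), int(cases), int(pop)
                )
            )
    elif "prevalence_pct" in lower:
        cols = _require_columns(
            df, {"country": ["country"], "pct": ["prevalence_pct"]}, "prevalence"
        )
        for ctry, pct in zip(df[cols["country"]], df[cols["pct"]]):
            records.append(
                PrevalenceRecord.from_prevalence(
                    normalize_country(str(ctry)), float(pct)
                )
            )
    else:
        raise TableFormatError(
            "prevalence table needs columns country,cases,population or "
            "country,prevalence_pct"
        )
    return PrevalenceTable(records)


def load_profile_fixture():
    """Load the packaged 127-allele T1D reference profile.

    The table holds, per allele: class, the number of Continental Western
    European countries N it was observed in, and the published Fisher
    z-transformed correlation r' between allele population frequency and
    ln(percent T1D prevalence).  r is recovered as tanh(r').  Integrity is
    enforced on load: exactly 127 entries, N in [9, 14], and the printed
    class column must equal the class implied by each locus.
    """
    from .profile import Profile, ProfileEntry  # deferred: avoids module cycle

    path = resources.files("hlaprofile.data").joinpath(_FIXTURE_RESOURCE)
    with path.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    entries = []
    for name, printed_class, raw_n, raw_rp in zip(
        df["allele"], df["hla_class"], df["n_countries"], df["r_prime"]
    ):
        allele = parse_allele(name)
        if allele.hla_class != printed_class:
            raise TableFormatError(
                f"fixture integrity failure: {allele.name} printed class "
                f"{printed_class} != derived {allele.hla_class}"
            )
        n = int(raw_n)
        if not 9 <= n <= 14:
            raise TableFormatError(
                f"fixture integrity failure: N={n} out of [9, 14] for {allele.name}"
            )
        r_prime = float(raw_rp)
        entries.append(
            ProfileEntry(
                allele=allele,
                n_countries=n,
                r=math.tanh(r_prime),
                r_prime=r_prime,
            )
        )
    if len(entries) != 127:
        raise TableFormatError(
            f"fixture integrity failure: expected 127 entries, got {len(entries)}"
        )
    return Profile(
        entries=entries,
        metadata={
            "source": "packaged reference profile (T1D, 14 CWE countries)",
            "min_countries": 9,
            "prevalence_transform": "ln(percent)",
        },
    )


_PROFILE_COLUMNS = ["index", "allele", "class", "gene", "N", "r", "r_prime"]


def write_profile(profile, dest: Source) -> None:
    """Write a profile as TSV with deterministic column order."""
    rows = []
    for i, e in enumerate(profile.entries, start=1):
        rows.append(
            {
                "index": i,
                "allele": e.allele.name,
                "class": e.allele.hla_class,
                "gene": e.allele.gene,
                "N": e.n_countries,
                "r": repr(e.r),
                "r_prime": repr(e.r_prime),
            }
        )
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    df.to_csv(dest, sep="\t", index=False)


def read_profile(source: Source):
    """Read a profile TSV written by :func:`write_profile`."""
    from .profile import Profile, ProfileEntry

    df = pd.read_csv(source, sep="\t", float_precision="round_trip")
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"profile TSV missing columns: {sorted(missing)}")
    entries = [
        ProfileEntry(
            allele=parse_allele(name),
            n_countries=int(n),
            r=float(r),
            r_prime=float(rp),
        )
        for name, n, r, rp in zip(df["allele"], df["N"], df["r"], df["r_prime"])
    ]
    return Profile(entries=entries, metadata={})


def write_stats_report(report, dest: Source) -> None:
    """Serialize a statistics report to JSON.

    Each test entry carries ``{test, statistic, df, p_value, groups}``;
    the report header carries input provenance.
    """
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        json.dump(payload, dest, indent=2, sort_keys=False)


def read_stats_report(source: Source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return json.load(fh)
    return json.load(source)
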