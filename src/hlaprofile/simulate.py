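"""Synthetic allele-frequency and prevalence data with the statistical
structure the profile analysis assumes.

The generator emulates the study design end to end:

* per country and locus, an allele-frequency composition drawn around a
  shared mean composition (Dirichlet, with a ``concentration`` parameter
  controlling between-country heterogeneity);
* a hidden "rare tail" share of each locus that is never reported, so the
  observed per-locus frequencies sum to less than one, as in real exports
  where only commonly typed alleles appear;
* allele-level missingness (each (allele, country) record independently
  unobserved with probability ``missing_rate``), reproducing the varying
  per-allele country coverage;
* prevalence generated from the log-linear model

      ln(prevalence_pct_c) = alpha + sum_a beta_a * f_{a,c} + eps_c,
      eps_c ~ Normal(0, noise_sd^2),

  i.e. log disease prevalence is linear in allele frequency, with additive
  per-allele effects and no interactions.

All randomness flows from a single integer seed through named substreams,
so every stage is reproducible independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alleles import AlleleFrequencyRecord, HlaAllele, Locus, PrevalenceRecord
from .io import AlleleFrequencyTable, PrevalenceTable
from .profile import build_profile
from .stats import one_sample_proportion_z, sign_counts

#: alleles per locus matching the coverage-filtered profile of the study
#: (class I: A 20, B 36, C 13; class II: DPB1 15, DQB1 14, DRB1 29)
DEFAULT_LOCI: dict[str, int] = {
    "A": 20,
    "B": 36,
    "C": 13,
    "DPB1": 15,
    "DQB1": 14,
    "DRB1": 29,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: 14 countries, 127 alleles
    distributed over the six classical loci as in the reference profile,
    20% missingness (mean per-allele coverage 11.2 countries, spanning the
    observed 9-14 range), and a baseline percent prevalence of 0.3
    (``alpha = ln(0.3)``), typical of type 1 diabetes in Western Europe.
    """

    n_countries: int = 14
    loci: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LOCI))
    concentration: float = 50.0
    effect_map: dict[str, float] = field(default_factory=dict)
    alpha: float = math.log(0.3)
    noise_sd: float = 0.15
    missing_rate: float = 0.2
    hidden_mass: float = 0.15
    population: int = 10_000_000
    min_countries: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ValueError("need at least 3 countries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.hidden_mass < 1.0:
            raise ValueError("hidden_mass must lie in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        unknown = set(self.loci) - {l.value for l in Locus}
        if unknown:
            raise ValueError(f"unknown loci in config: {sorted(unknown)}")

    @property
    def countries(self) -> list[str]:
        return [f"c{i + 1:02d}" for i in range(self.n_countries)]

    def allele_names(self) -> list[str]:
        names = []
        for locus, count in self.loci.items():
            names.extend(f"{locus}*{i + 1:02d}:01" for i in range(count))
        return names


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_frequencies(config: SyntheticConfig) -> AlleleFrequencyTable:
    """Draw per-country, per-locus allele-frequency compositions.

    For each locus a mean composition over its alleles plus a hidden rare
    tail (share ``hidden_mass``) is drawn once; each country's composition
    is then Dirichlet-distributed around that mean with total concentration
    ``concentration`` (larger = more homogeneous countries).  Observed
    frequencies per locus and country are non-negative and sum to
    ``1 - hidden share`` < 1.
    """
    rng = _rng(config, 1)
    records: list[AlleleFrequencyRecord] = []
    for locus, count in config.loci.items():
        mean = rng.dirichlet(np.ones(count))
        full_mean = np.concatenate([(1.0 - config.hidden_mass) * mean, [config.hidden_mass]]) \
            if config.hidden_mass > 0 else mean
        comps = rng.dirichlet(config.concentration * full_mean, size=config.n_countries)
        for c_idx, country in enumerate(config.countries):
            for a_idx in range(count):
                allele = HlaAllele(Locus(locus), a_idx + 1, 1)
                records.append(
                    AlleleFrequencyRecord(
                        allele, country, float(comps[c_idx, a_idx])
                    )
                )
    return AlleleFrequencyTable(records)


def generate_prevalence(
    config: SyntheticConfig, freqs: AlleleFrequencyTable
) -> PrevalenceTable:
    """Generate per-country prevalence from the log-linear model.

    Percent prevalence is back-converted to an integer case count against
    ``config.population`` so records round-trip through the count-based
    reader; with the default population of 1e7 the integer rounding
    perturbs ln prevalence by well under 1e-5.
    """
    rng = _rng(config, 2)
    effects = {name: float(b) for name, b in config.effect_map.items()}
    present = {rec.allele.name for rec in freqs.records}
    unknown = set(effects) - present
    if unknown:
        raise ValueError(
            f"effect_map names not in the frequency table: {sorted(unknown)}; "
            f"generated names look like 'A*01:01' .. 'A*{config.loci.get('A', 0):02d}:01'"
        )
    lookup = {(rec.allele.name, rec.country): rec.frequency for rec in freqs.records}
    records = []
    noise = rng.normal(0.0, config.noise_sd, size=config.n_countries)
    for c_idx, country in enumerate(config.countries):
        ln_prev = config.alpha + sum(
            beta * lookup.get((name, country), 0.0) for name, beta in effects.items()
        )
        if config.noise_sd > 0:
            ln_prev += noise[c_idx]
        pct = math.exp(ln_prev)
        if pct > 100.0:
            raise ValueError(
                f"generated prevalence {pct:.2f}% exceeds 100% for {country}; "
                f"alpha/beta are mis-specified"
            )
        # floor at one case: a country with literally zero cases has no
        # finite log prevalence and cannot enter the correlation
        cases = max(1, round(pct / 100.0 * config.population))
        records.append(
            PrevalenceRecord.from_counts(country, cases, config.population)
        )
    return PrevalenceTable(records)


def apply_missingness(
    freqs: AlleleFrequencyTable, missing_rate: float, seed: int
) -> AlleleFrequencyTable:
    """Drop each (allele, country) record independently with the given rate."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if missing_rate == 0.0:
        return AlleleFrequencyTable(list(freqs.records))
    rng = np.random.default_rng([seed, 3])
    keep = rng.random(len(freqs.records)) >= missing_rate
    return AlleleFrequencyTable(
        [rec for rec, k in zip(freqs.records, keep) if k]
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[AlleleFrequencyTable, PrevalenceTable]:
    """Full synthetic dataset: frequencies (with missingness) and prevalence.

    Prevalence is generated from the complete frequency table before
    missingness is applied, as the disease burden of a country does not
    depend on which alleles happen to be reported there.
    """
    freqs = generate_frequencies(config)
    prev = generate_prevalence(config, freqs)
    observed = apply_missingness(freqs, config.missing_rate, config.seed)
    return observed, prev


def recovery_experiment(config: SyntheticConfig, n_reps: int = 100) -> pd.DataFrame:
    """Repeatedly simulate and re-estimate the profile; summarize recovery.

    Per repetition the full pipeline runs (generate, filter at
    ``config.min_countries``, correlate, Fisher-transform) and three
    quantities are recorded:

    * ``sign_recovery_rate`` — fraction of effect alleles (those with a
      nonzero slope in ``effect_map``) whose estimated r' sign matches the
      generating slope's sign;
    * ``null_mean_r_prime`` — mean r' over null alleles (bias check);
    * ``sign_split_p`` — two-sided proportion-test p for the profile's
      negative/positive split, whose rejection rate at alpha = 0.05 under
      an all-null configuration estimates the test's empirical size.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    effects = {k: v for k, v in config.effect_map.items() if v != 0.0}
    rows = []
    for rep in range(n_reps):
        cfg = replace(config, seed=config.seed + rep)
        freqs, prev = generate_dataset(cfg)
        profile = build_profile(freqs, prev, cfg.min_countries, clamp=True)
        by_name = {e.allele.name: e for e in profile.entries}
        n_effect = n_recovered = 0
        for name, beta in effects.items():
            entry = by_name.get(name)
            if entry is None:  # dropped by the coverage filter this rep
                continue
            n_effect += 1
            n_recovered += int(math.copysign(1, entry.r_prime) == math.copysign(1, beta))
        null_rp = [
            e.r_prime for e in profile.entries if e.allele.name not in effects
        ]
        s = sign_counts(profile)
        _, p_split = one_sample_proportion_z(s.n_positive, s.n_total)
        rows.append(
            {
                "rep": rep,
                "n_alleles": len(profile),
                "n_effect_alleles": n_effect,
                "sign_recovery_rate": (n_recovered / n_effect) if n_effect else np.nan,
                "null_mean_r_prime": float(np.mean(null_rp)) if null_rp else np.nan,
                "sign_split_p": p_split,
            }
        )
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Aggregate a recovery-experiment table into headline numbers."""
    return {
        "n_reps": int(len(results)),
        "sign_recovery_rate": float(results["sign_recovery_rate"].mean()),
        "null_mean_r_prime": float(results["null_mean_r_prime"].mean()),
        "sign_split_rejection_rate": float(
            (results["sign_split_p"] < alpha).mean()
        ),
    }
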