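"""Profile-level inference: sign splits, proportion tests, ANOVAs and
strength comparisons.

All tests operate on a :class:`~hlaprofile.profile.Profile` (or on raw
counts/vectors) and report plain dictionaries with ``test``, ``statistic``,
``df``, ``p_value`` and group bookkeeping, collected into a
:class:`StatsReport` for serialization.

A note on the proportion test: the sign-split inference is the normal
approximation to the one-sample binomial test,

    z = (k - n p0) / sqrt(n p0 (1 - p0)),

with no continuity correction, reported as |z| with a two-sided normal
p-value.  An exact two-sided binomial p (summing outcomes no more probable
than the observed one) is provided separately as a cross-check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profile import Profile

__all__ = [
    "SignSummary",
    "StatsReport",
    "sign_counts",
    "one_sample_proportion_z",
    "exact_binomial_two_sided",
    "wald_two_proportion",
    "anova_oneway",
    "pairwise_group_means",
    "anova_class_gene",
    "strength_ttest",
    "full_report",
]


@dataclass(frozen=True)
class SignSummary:
    """Counts of negative (protective) and positive (susceptibility) r' values."""

    n_total: int
    n_negative: int
    n_positive: int
    n_zero: int = 0
    z: float | None = None
    p_two_sided: float | None = None

    def __post_init__(self) -> None:
        if self.n_negative + self.n_positive + self.n_zero != self.n_total:
            raise ValueError("sign counts do not add up to the total")


@dataclass
class StatsReport:
    """An ordered collection of test results with input provenance."""

    tests: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, **result) -> None:
        if not 0.0 <= result.get("p_value", 0.0) <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {result}")
        self.tests.append(result)

    def find(self, name: str) -> list[dict]:
        return [t for t in self.tests if t["test"] == name]

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "tests": self.tests,
            "warnings": self.warnings,
        }


def sign_counts(profile: Profile) -> SignSummary:
    """Count negative, positive and exactly-zero r' values in a profile."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    rp = profile.r_prime
    neg = int((rp < 0).sum())
    pos = int((rp > 0).sum())
    zero = int((rp == 0).sum())
    return SignSummary(n_total=len(profile), n_negative=neg, n_positive=pos, n_zero=zero)


def one_sample_proportion_z(k: int, n: int, p0: float = 0.5) -> tuple[float, float]:
    """One-sample proportion test, normal approximation, no continuity correction.

    Returns (|z|, two-sided p).  This is the approximation whose z values
    are conventionally reported alongside "binomial test" p-values by the
    major statistics packages.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    z = abs(k - n * p0) / math.sqrt(n * p0 * (1.0 - p0))
    p = 2.0 * sps.norm.sf(z)
    return z, min(1.0, float(p))


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p: total probability of outcomes no more
    likely than the observed count under Binomial(n, p0)."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    return float(sps.binomtest(k, n, p0).pvalue)


def wald_two_proportion(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Unpooled (Wald) z test comparing two independent proportions.

    z = (p1 - p2) / sqrt(p1 q1 / n1 + p2 q2 / n2), two-sided normal p.
    Note the caveat for complementary splits of one sample: the two
    proportions then share a denominator and are not independent.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie within group sizes")
    p1, p2 = k1 / n1, k2 / n2
    se2 = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if se2 == 0:
        raise ValueError(
            "Wald statistic undefined: both sample proportions are degenerate (0 or 1)"
        )
    z = (p1 - p2) / math.sqrt(se2)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), min(1.0, float(p))


def _group_arrays(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    return {g: values[groups == g] for g in pd.unique(groups)}


def anova_oneway(values, groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p).

    For a single factor the F statistic is the same whether the factor is
    treated as fixed or random, so this serves both framings.
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(len(v) for v in by_group.values())
    if n_total <= len(by_group):
        raise ValueError("need more observations than groups")
    if np.ptp(np.asarray(values, dtype=float)) == 0:
        raise ValueError("F undefined: all values identical")
    F, p = sps.f_oneway(*by_group.values())
    return float(F), len(by_group) - 1, n_total - len(by_group), float(p)


def pairwise_group_means(values, groups, method: str = "bonferroni") -> list[dict]:
    """All pairwise group-mean comparisons by pooled-variance t-tests.

    ``method`` is the multiplicity adjustment: ``bonferroni`` (default) or
    ``none``.  Each row reports the raw and adjusted two-sided p.
    """
    from statsmodels.stats.multitest import multipletests

    if method not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment method {method!r}")
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g1, g2 in itertools.combinations(by_group, 2):
        a, b = by_group[g1], by_group[g2]
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "groups": [str(g1), str(g2)],
                "group_sizes": [int(len(a)), int(len(b))],
                "mean_difference": float(a.mean() - b.mean()),
                "t": float(t),
                "df": int(len(a) + len(b) - 2),
                "p_value": float(p),
            }
        )
    if method == "bonferroni" and rows:
        adj = multipletests([r["p_value"] for r in rows], method="bonferroni")[1]
        for r, pa in zip(rows, adj):
            r["p_adjusted"] = float(pa)
    else:
        for r in rows:
            r["p_adjusted"] = r["p_value"]
    return rows


def anova_class_gene(profile: Profile, class_error_term: str = "residual") -> list[dict]:
    """Nested ANOVA of r' on HLA class and gene within class.

    Because gene fully determines class, the sums of squares partition
    sequentially: SS(class) from the class-only fit, SS(gene within class)
    as the increment explained by the gene fit, and the gene fit's residual.
    With the six classical loci this gives df = 1, 4 and n - 6.  The F for
    the class effect uses the residual mean square by default; pass
    ``class_error_term='gene'`` to test it against the gene-within-class
    mean square instead (the conventional choice when genes are viewed as a
    random sample of loci).
    """
    import statsmodels.formula.api as smf

    if class_error_term not in ("residual", "gene"):
        raise ValueError(f"class_error_term must be residual|gene, got {class_error_term!r}")
    df = pd.DataFrame(
        {
            "r_prime": profile.r_prime,
            "cls": profile.classes,
            "gene": profile.genes,
        }
    )
    small = df.groupby("gene").size()
    for gene, n in small.items():
        if n < 2:
            warnings.warn(
                f"gene {gene} has {n} entry; nested ANOVA degrades to pooled "
                f"handling for it",
                stacklevel=2,
            )
    if np.ptp(df["r_prime"].to_numpy()) == 0:
        raise ValueError("F undefined: all r' values identical")
    m_class = smf.ols("r_prime ~ C(cls)", data=df).fit()
    m_gene = smf.ols("r_prime ~ C(gene)", data=df).fit()
    n_classes = df["cls"].nunique()
    n_genes = df["gene"].nunique()
    ss_class = float(m_class.ess)
    df_class = n_classes - 1
    ss_gene = float(m_gene.ess - m_class.ess)
    df_gene = n_genes - n_classes
    ss_res = float(m_gene.ssr)
    df_res = len(df) - n_genes
    ms_gene = ss_gene / df_gene
    ms_res = ss_res / df_res
    if class_error_term == "residual":
        F_class = (ss_class / df_class) / ms_res
        p_class = float(sps.f.sf(F_class, df_class, df_res))
        df_class_err = df_res
    else:
        F_class = (ss_class / df_class) / ms_gene
        p_class = float(sps.f.sf(F_class, df_class, df_gene))
        df_class_err = df_gene
    F_gene = ms_gene / ms_res
    p_gene = float(sps.f.sf(F_gene, df_gene, df_res))
    return [
        {
            "test": "anova_class",
            "statistic": float(F_class),
            "df": [df_class, df_class_err],
            "p_value": p_class,
            "error_term": class_error_term,
            "sum_sq": ss_class,
        },
        {
            "test": "anova_gene_within_class",
            "statistic": float(F_gene),
            "df": [df_gene, df_res],
            "p_value": p_gene,
            "sum_sq": ss_gene,
        },
    ]


def strength_ttest(profile: Profile, split_by: str = "class") -> list[dict]:
    """Compare association strength |r'| between protective and
    susceptibility alleles within each class (or gene).

    Pooled-variance two-sided t-tests; cells with fewer than two entries of
    either sign are skipped with a warning.
    """
    if split_by not in ("class", "gene"):
        raise ValueError(f"split_by must be class|gene, got {split_by!r}")
    labels = profile.classes if split_by == "class" else profile.genes
    rp = profile.r_prime
    rows = []
    for label in dict.fromkeys(labels):
        mask = np.array([l == label for l in labels])
        neg = np.abs(rp[mask & (rp < 0)])
        pos = np.abs(rp[mask & (rp > 0)])
        if len(neg) < 2 or len(pos) < 2:
            warnings.warn(
                f"{split_by} {label}: fewer than two alleles of one sign; "
                f"strength comparison skipped",
                stacklevel=2,
            )
            continue
        t, p = sps.ttest_ind(neg, pos, equal_var=True)
        rows.append(
            {
                "test": f"strength_ttest_{split_by}",
                "group": str(label),
                "groups": ["negative |r'|", "positive |r'|"],
                "group_sizes": [int(len(neg)), int(len(pos))],
                "statistic": float(t),
                "df": int(len(neg) + len(pos) - 2),
                "p_value": float(p),
            }
        )
    return rows


def full_report(profile: Profile) -> StatsReport:
    """Run the complete profile-level inference battery.

    Sign splits (overall, per class, and the class-membership split) with
    proportion z-tests, one-way ANOVA of r' by sample size N with pairwise
    group-mean comparisons, the nested class/gene ANOVA, and the |r'|
    strength t-tests by class and gene.  Individual test failures are
    isolated and recorded as warnings rather than aborting the report.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    report = StatsReport(
        provenance={
            "n_alleles": len(profile),
            "metadata": profile.metadata,
        }
    )

    def _guard(fn, label):
        try:
            fn()
        except Exception as exc:  # test-level isolation
            report.warnings.append(f"{label}: {exc}")

    def _sign_block(label: str, sub: Profile):
        s = sign_counts(sub)
        z, p = one_sample_proportion_z(s.n_positive, s.n_total)
        report.add(
            test=f"sign_split_{label}",
            statistic=z,
            df=None,
            p_value=p,
            groups=["negative", "positive", "zero"],
            group_sizes=[s.n_negative, s.n_positive, s.n_zero],
            n=s.n_total,
        )

    _guard(lambda: _sign_block("overall", profile), "sign_split_overall")
    classes = sorted(set(profile.classes))
    if len(classes) > 1:
        # class membership split: is either class over-represented?
        n_class_first = sum(1 for c in profile.classes if c == classes[0])
        z, p = one_sample_proportion_z(n_class_first, len(profile))
        report.add(
            test="class_membership_split",
            statistic=z,
            df=None,
            p_value=p,
            groups=classes,
            group_sizes=[
                n_class_first,
                len(profile) - n_class_first,
            ],
            n=len(profile),
        )
    for cls in classes:
        _guard(
            lambda cls=cls: _sign_block(f"class_{cls}", profile.restrict(hla_class=cls)),
            f"sign_split_class_{cls}",
        )

    def _anova_by_n():
        F, dfb, dfw, p = anova_oneway(profile.r_prime, profile.n_countries)
        report.add(
            test="anova_by_sample_size",
            statistic=F,
            df=[dfb, dfw],
            p_value=p,
            groups=sorted(int(n) for n in set(profile.n_countries)),
        )
        pairs = pairwise_group_means(profile.r_prime, profile.n_countries)
        report.add(
            test="pairwise_means_by_sample_size",
            statistic=float(max(abs(r["t"]) for r in pairs)),
            df=None,
            p_value=float(min(r["p_adjusted"] for r in pairs)),
            groups="min adjusted p over all pairs",
            comparisons=pairs,
        )

    _guard(_anova_by_n, "anova_by_sample_size")

    def _nested():
        for row in anova_class_gene(profile):
            report.add(**row)

    if len(classes) > 1:
        _guard(_nested, "anova_class_gene")

    for split in ("class", "gene"):
        _guard(
            lambda split=split: [report.add(**row) for row in strength_ttest(profile, split)],
            f"strength_ttest_{split}",
        )
    return report
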