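"""Genotype and allele association statistics.

Small-sample exact and chi-square statistics used around the transmission
analysis: Hardy-Weinberg equilibrium, genotype-frequency comparisons
against a reference population, offspring sex-ratio distortion, the
prostate-ovary 2x2 Fisher test, and the allele-frequency vs ovarian-cancer
incidence correlation across populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "SexRatioResult",
    "allele_frequency",
    "hwe_chi_square",
    "genotype_freq_test",
    "sex_ratio_test",
    "fisher_exact_2x2",
    "freq_incidence_correlation",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Biallelic genotype counts (AA homozygous reference, AB heterozygous,
    BB homozygous alternate)."""

    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.total == 0:
            raise ValueError("need at least one genotype")

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb


@dataclass(frozen=True)
class SexRatioResult:
    daughters: int
    sons: int
    ratio: float  # daughters / sons; inf when sons == 0
    p_value: float


def allele_frequency(counts: GenotypeCounts) -> tuple[float, int, int]:
    """Minor allele frequency: (maf, minor allele count, total alleles)."""
    n_a = 2 * counts.n_aa + counts.n_ab
    n_b = counts.n_ab + 2 * counts.n_bb
    total = n_a + n_b
    minor = min(n_a, n_b)
    return minor / total, minor, total


def hwe_chi_square(counts: GenotypeCounts, df: int = 2) -> tuple[float, int, float]:
    """Hardy-Weinberg chi-square over the three genotype classes.

    Expected counts are n*(p^2, 2pq, q^2) at the estimated allele
    frequency.  With the frequency estimated from the same sample the
    asymptotically correct reference has one degree of freedom; ``df``
    defaults to 2, the unadjusted three-class test.
    """
    n = counts.total
    q = (counts.n_ab + 2 * counts.n_bb) / (2 * n)
    p = 1 - q
    if q in (0.0, 1.0):
        raise ValueError("monomorphic sample: HWE test undefined")
    expected = np.array([n * p * p, n * 2 * p * q, n * q * q])
    observed = np.array([counts.n_aa, counts.n_ab, counts.n_bb])
    x2 = float(((observed - expected) ** 2 / expected).sum())
    return x2, df, float(stats.chi2.sf(x2, df))


def genotype_freq_test(
    carriers: int, n: int, reference: float
) -> tuple[float, float]:
    """Observed genotype-class proportion vs a reference population value.

    Two-sided exact binomial test of ``carriers`` successes in ``n``
    against the null proportion ``reference``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < reference < 1:
        raise ValueError("reference proportion must be in (0, 1)")
    res = stats.binomtest(carriers, n, reference, alternative="two-sided")
    return carriers / n, float(res.pvalue)


def sex_ratio_test(daughters: int, sons: int, null_p: float = 0.5) -> SexRatioResult:
    """Offspring sex-ratio distortion test.

    Exact two-sided binomial test of the daughter count against a null
    daughter probability (0.5 by default; the demographic male excess can
    be supplied instead).
    """
    total = daughters + sons
    if total == 0:
        raise ValueError("need at least one offspring")
    ratio = daughters / sons if sons else np.inf
    p = float(stats.binomtest(daughters, total, null_p).pvalue)
    return SexRatioResult(daughters, sons, ratio, p)


def fisher_exact_2x2(
    table: tuple[int, int, int, int]
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table, (a, b, c, d) row-wise.

    Two-sided p by the probability-mass rule (sum of hypergeometric
    probabilities no larger than the observed table's).  Returns the sample
    odds ratio (nan on a zero margin, with p = 1).
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    arr = np.array([[a, b], [c, d]])
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    orr = (a * d) / (b * c) if b * c else np.inf
    return float(orr), float(p)


def freq_incidence_correlation(
    table: pd.DataFrame, exclusions: set[str] | None = None
) -> tuple[float, float, float]:
    """Pearson correlation and least-squares line of incidence on allele
    frequency across populations.

    ``table`` needs columns ``population``, ``freq``, ``incidence``;
    populations in ``exclusions`` are dropped first.  Returns
    (r, slope, intercept); r is 0 when either variable is constant.
    """
    df = table
    if exclusions:
        df = df[~df["population"].isin(exclusions)]
    if len(df) < 3:
        raise ValueError("need at least three populations")
    x = df["freq"].to_numpy(dtype=float)
    y = df["incidence"].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        slope, intercept = 0.0, float(np.mean(y))
        return 0.0, slope, intercept
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)
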