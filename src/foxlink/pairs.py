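"""Grandmother-granddaughter pair extraction and transmission-model testing.

Under an autosomal dominant model an affected grandmother transmits the
risk allele to a granddaughter with probability 1/4 on either side of the
family.  Under an X-linked dominant model the maternal-grandmother route is
still 1/4, but a paternal grandmother's allele reaches every granddaughter
through the obligate-carrier father, doubling the paternal-lineage rate.
Comparing granddaughter cancer rates between maternal- and paternal-lineage
pairs with exactly one affected grandmother therefore discriminates the two
models: equal rates favour autosomal, a 2:1 paternal excess favours
X-linkage.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .pedigree import (
    BrcaStatus,
    CancerSite,
    DiseasePattern,
    Pedigree,
    Sex,
)

__all__ = [
    "Lineage",
    "TransmissionModel",
    "EligibilityRule",
    "GGPair",
    "PairCountTable",
    "TransmissionFit",
    "RiskRatio",
    "eligible_women",
    "extract_gg_pairs",
    "pair_counts",
    "transmission_expected",
    "xlinked_mle",
    "gof_chi_square",
    "relative_risk",
    "odds_ratio",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # normal quantile for the default 95% level


class Lineage(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"


class TransmissionModel(str, enum.Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    XLINKED_DOMINANT = "xlinked_dominant"


@dataclass(frozen=True)
class EligibilityRule:
    """Who counts as having a determinable ovarian-cancer status.

    A woman is informative if she has ovarian cancer (confirmed, when
    ``require_confirmed_case``), or is unaffected and either reached
    ``min_unaffected_age`` at last contact or died without disease.
    """

    min_unaffected_age: float = 45.0
    require_confirmed_case: bool = False

    def __post_init__(self) -> None:
        if self.min_unaffected_age <= 0:
            raise ValueError("min_unaffected_age must be positive")


@dataclass(frozen=True)
class GGPair:
    """One grandmother-granddaughter observation."""

    family_id: str
    granddaughter_id: str
    grandmother_id: str
    lineage: Lineage
    intermediate_parent_id: str
    grandmother_affected: bool
    granddaughter_affected: bool
    granddaughter_is_proband: bool
    n_affected_grandmothers: int  # 0, 1 or 2 for this granddaughter
    granddaughter_age: float | None = None  # age at last contact/death


@dataclass(frozen=True)
class PairCountTable:
    """2 x 2 summary of informative pairs by lineage."""

    n_mat: int
    w_mat: int
    n_pat: int
    w_pat: int

    def __post_init__(self) -> None:
        for n, w in ((self.n_mat, self.w_mat), (self.n_pat, self.w_pat)):
            if not 0 <= w <= n:
                raise ValueError(f"need 0 <= W <= N, got W={w}, N={n}")

    @property
    def n_total(self) -> int:
        return self.n_mat + self.n_pat

    @property
    def w_total(self) -> int:
        return self.w_mat + self.w_pat

    def swapped(self) -> "PairCountTable":
        return PairCountTable(self.n_pat, self.w_pat, self.n_mat, self.w_mat)


@dataclass(frozen=True)
class TransmissionFit:
    model: TransmissionModel
    rate_estimate: float
    expected_mat: float
    expected_pat: float
    chi_square: float | None = None
    df: int | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class RiskRatio:
    estimate: float
    lcl: float
    ucl: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.lcl <= self.estimate <= self.ucl):
            raise ValueError("confidence bounds must bracket the estimate")


# ---------------------------------------------------------------------------
# Eligibility and pair extraction
# ---------------------------------------------------------------------------

def _is_eligible(ind, rule: EligibilityRule) -> bool | None:
    """True = eligible, False = not, None = status not determinable."""
    if ind.sex is not Sex.FEMALE:
        return False
    if ind.has_cancer(CancerSite.OVARY, confirmed_only=rule.require_confirmed_case):
        return True
    if ind.has_cancer(CancerSite.OVARY):
        # has an unconfirmed cancer while confirmation is required: ambiguous
        return None
    from .pedigree import VitalStatus  # local import avoids cycle at module load

    if ind.vital_status is VitalStatus.DEAD:
        return True  # died without disease
    if (
        ind.age_last_contact is not None
        and ind.age_last_contact >= rule.min_unaffected_age
    ):
        return True
    return None


def eligible_women(
    pedigrees: list[Pedigree], rule: EligibilityRule | None = None
) -> set[tuple[str, str]]:
    """Women with determinable ovarian-cancer status under ``rule``.

    Returns ``(family_id, individual_id)`` keys.  Women with missing ages
    and no qualifying condition are excluded; their count is logged.
    """
    rule = rule or EligibilityRule()
    out: set[tuple[str, str]] = set()
    n_indeterminate = 0
    for ped in pedigrees:
        for ind in ped:
            status = _is_eligible(ind, rule)
            if status:
                out.add((ped.family_id, ind.id))
            elif status is None:
                n_indeterminate += 1
    if n_indeterminate:
        logger.info(
            "eligible_women: %d women with indeterminate status excluded",
            n_indeterminate,
        )
    return out


def extract_gg_pairs(
    pedigrees: list[Pedigree], rule: EligibilityRule | None = None
) -> list[GGPair]:
    """All grandmother-granddaughter pairs with determinable statuses.

    A granddaughter is informative only when BOTH grandmothers are present
    in the pedigree with determinable ovarian-cancer status and she is
    herself eligible; each informative granddaughter yields two pairs, one
    per lineage, annotated with her total number of affected grandmothers.
    """
    rule = rule or EligibilityRule()
    pairs: list[GGPair] = []
    for ped in pedigrees:
        for ind in ped:
            if _is_eligible(ind, rule) is not True:
                continue
            father, mother = ped.father(ind), ped.mother(ind)
            pgm = ped.mother(father) if father else None
            mgm = ped.mother(mother) if mother else None
            if pgm is None or mgm is None:
                continue
            gm_status = {
                Lineage.PATERNAL: _grandmother_affected(pgm, rule),
                Lineage.MATERNAL: _grandmother_affected(mgm, rule),
            }
            if any(s is None for s in gm_status.values()):
                continue
            n_aff = sum(gm_status.values())
            last_age = max(
                (a for a in (ind.age_last_contact, ind.age_at_death) if a is not None),
                default=None,
            )
            for lineage, gm, parent in (
                (Lineage.PATERNAL, pgm, father),
                (Lineage.MATERNAL, mgm, mother),
            ):
                pairs.append(
                    GGPair(
                        family_id=ped.family_id,
                        granddaughter_id=ind.id,
                        grandmother_id=gm.id,
                        lineage=lineage,
                        intermediate_parent_id=parent.id,
                        grandmother_affected=gm_status[lineage],
                        granddaughter_affected=ind.has_cancer(CancerSite.OVARY),
                        granddaughter_is_proband=ind.proband,
                        n_affected_grandmothers=n_aff,
                        granddaughter_age=last_age,
                    )
                )
    return pairs


def _grandmother_affected(gm, rule: EligibilityRule) -> bool | None:
    status = _is_eligible(gm, rule)
    if status is not True:
        return None
    return gm.has_cancer(
        CancerSite.OVARY, confirmed_only=rule.require_confirmed_case
    )


def pair_counts(
    pairs: list[GGPair],
    exclude_probands: bool = False,
    min_granddaughter_age: float | None = None,
    pattern: DiseasePattern | None = None,
    brca: BrcaStatus | None = None,
    family_pattern: dict[str, DiseasePattern] | None = None,
    family_brca: dict[str, BrcaStatus] | None = None,
) -> PairCountTable:
    """Lineage-classified counts over granddaughters with exactly one
    affected grandmother, keeping the pair whose grandmother is affected.

    ``min_granddaughter_age`` drops unaffected granddaughters younger than
    the cutoff (affected granddaughters are always kept).  Stratum filters
    need the per-family classification maps.
    """
    kept = [
        p for p in pairs
        if p.n_affected_grandmothers == 1 and p.grandmother_affected
    ]
    if exclude_probands:
        kept = [p for p in kept if not p.granddaughter_is_proband]
    if min_granddaughter_age is not None:
        kept = [
            p for p in kept
            if p.granddaughter_affected
            or (p.granddaughter_age is not None
                and p.granddaughter_age >= min_granddaughter_age)
        ]
    if pattern is not None:
        if family_pattern is None:
            raise ValueError("pattern filter requires family_pattern map")
        kept = [p for p in kept if family_pattern.get(p.family_id) == pattern]
    if brca is not None:
        if family_brca is None:
            raise ValueError("brca filter requires family_brca map")
        kept = [p for p in kept if family_brca.get(p.family_id) == brca]

    mat = [p for p in kept if p.lineage is Lineage.MATERNAL]
    pat = [p for p in kept if p.lineage is Lineage.PATERNAL]
    return PairCountTable(
        n_mat=len(mat),
        w_mat=sum(p.granddaughter_affected for p in mat),
        n_pat=len(pat),
        w_pat=sum(p.granddaughter_affected for p in pat),
    )


# ---------------------------------------------------------------------------
# Transmission models
# ---------------------------------------------------------------------------

def transmission_expected(
    counts: PairCountTable, model: TransmissionModel
) -> TransmissionFit:
    """Expected affected counts per lineage under a transmission model.

    Autosomal: both lineages share the pooled rate
    ``p = (W_mat + W_pat) / (N_mat + N_pat)``.  X-linked: the paternal rate
    is constrained to twice the maternal rate; the maternal rate is the
    moment estimator ``m = (W_mat + W_pat/2) / (N_mat + N_pat)`` (the exact
    binomial MLE is available as :func:`xlinked_mle`).
    """
    if counts.n_total == 0:
        raise ValueError("no pairs: rate undefined")
    if model is TransmissionModel.AUTOSOMAL_DOMINANT:
        p = counts.w_total / counts.n_total
        return TransmissionFit(model, p, p * counts.n_mat, p * counts.n_pat)
    m = (counts.w_mat + counts.w_pat / 2) / counts.n_total
    return TransmissionFit(model, m, m * counts.n_mat, 2 * m * counts.n_pat)


def xlinked_mle(counts: PairCountTable, tol: float = 1e-10) -> float:
    """Exact MLE of the maternal-lineage cancer rate m under the X-linked
    model (paternal rate 2m), maximizing

    ``l(m) = W_mat log m + (N_mat-W_mat) log(1-m)
           + W_pat log 2m + (N_pat-W_pat) log(1-2m)``

    over m in (0, 1/2), to within 1e-8.
    """
    if counts.w_total == 0:
        logger.warning("xlinked_mle: no affected granddaughters; returning 0")
        return 0.0

    w_m, n_m, w_p, n_p = counts.w_mat, counts.n_mat, counts.w_pat, counts.n_pat

    def neg_ll(m: float) -> float:
        if m <= 0 or m >= 0.5:
            return np.inf
        ll = 0.0
        if w_m:
            ll += w_m * np.log(m)
        if n_m - w_m:
            ll += (n_m - w_m) * np.log1p(-m)
        if w_p:
            ll += w_p * np.log(2 * m)
        if n_p - w_p:
            ll += (n_p - w_p) * np.log1p(-2 * m)
        return -ll

    res = optimize.minimize_scalar(
        neg_ll, bounds=(1e-12, 0.5 - 1e-12), method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def gof_chi_square(
    counts: PairCountTable, fit: TransmissionFit
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square over the two affected-count cells.

    ``X^2 = (W_mat - E_mat)^2/E_mat + (W_pat - E_pat)^2/E_pat`` with one
    degree of freedom (one rate parameter estimated from two cells).
    """
    if fit.expected_mat <= 0 or fit.expected_pat <= 0:
        raise ValueError("expected cell count is zero; chi-square undefined")
    x2 = (
        (counts.w_mat - fit.expected_mat) ** 2 / fit.expected_mat
        + (counts.w_pat - fit.expected_pat) ** 2 / fit.expected_pat
    )
    df = 1
    p = float(stats.chi2.sf(x2, df))
    return float(x2), df, p


# ---------------------------------------------------------------------------
# Risk statistics
# ---------------------------------------------------------------------------

def relative_risk(
    exposed: tuple[int, int],
    unexposed: tuple[int, int],
    level: float = 0.95,
) -> RiskRatio:
    """Risk ratio with the log-transform (Katz) Wald interval.

    ``exposed``/``unexposed`` are (events, n) pairs.  The CI is
    ``exp(log RR +/- z * sqrt(1/e1 - 1/n1 + 1/e0 - 1/n0))``.
    """
    e1, n1 = exposed
    e0, n0 = unexposed
    if n1 <= 0 or n0 <= 0:
        raise ValueError("group sizes must be positive")
    if e1 > n1 or e0 > n0:
        raise ValueError("events cannot exceed group size")
    if e1 == 0 or e0 == 0:
        raise ZeroDivisionError(
            "zero events in one arm: RR degenerate, CI undefined"
        )
    rr = (e1 / n1) / (e0 / n0)
    se = np.sqrt(1 / e1 - 1 / n1 + 1 / e0 - 1 / n0)
    z = float(stats.norm.ppf(0.5 + level / 2)) if level != 0.95 else Z_95
    return RiskRatio(
        estimate=float(rr),
        lcl=float(rr * np.exp(-z * se)),
        ucl=float(rr * np.exp(z * se)),
        level=level,
    )


def odds_ratio(
    table: tuple[int, int, int, int], level: float = 0.95
) -> RiskRatio:
    """Sample odds ratio ad/bc with the Woolf log-scale Wald interval.

    ``table`` is (a, b, c, d) row-wise.  Zero cells raise; callers wanting a
    continuity correction add 0.5 themselves.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    if min(a, b, c, d) == 0:
        raise ZeroDivisionError("zero cell: OR/CI undefined without correction")
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(0.5 + level / 2)) if level != 0.95 else Z_95
    return RiskRatio(
        estimate=float(orr),
        lcl=float(orr * np.exp(-z * se)),
        ucl=float(orr * np.exp(z * se)),
        level=level,
    )
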