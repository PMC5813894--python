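"""Within-sibship segregation likelihoods for dominant inheritance models.

A sistership of N daughters contains N_c carriers and N_n = N - N_c
non-carriers of a dominant risk allele; W = W_c + W_n of them are affected,
with W_c ~ Binomial(N_c, p_c) and W_n ~ Binomial(N_n, p_n) given the split.
Under an autosomal dominant model each daughter is an independent carrier
with probability 1/2, so N_c ~ Binomial(N, 1/2).  Under an X-linked
dominant model transmitted through the father, the sistership segregates as
a block: a carrier father makes every daughter a carrier (N_c = N) while a
non-carrier father makes none (N_c = 0).

The likelihood ratio L_xlinked / L_autosomal summarizes how strongly the
observed clustering of disease within a sistership favours X-linkage.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass

import networkx as nx
from scipy.stats import binom

from .pairs import EligibilityRule, _is_eligible
from .pedigree import CancerSite, Individual, Pedigree, Sex

__all__ = [
    "Model",
    "CarrierPriorMode",
    "SibshipObservation",
    "SibshipLikelihoodResult",
    "ModelClass",
    "PedigreeModelClass",
    "sibship_likelihood_enum",
    "sibship_likelihood_closed",
    "likelihood_ratio",
    "xlinked_compatible",
    "classify_pedigrees",
]

logger = logging.getLogger(__name__)

DEFAULT_P_CARRIER = 0.65      # carrier penetrance
DEFAULT_P_NONCARRIER = 0.15   # familial background rate in non-carriers


class CarrierPriorMode(str, enum.Enum):
    """How the two X-linked segregation states (all daughters carriers vs
    none) are combined.

    ``unweighted_sum`` adds the two state probabilities without prior
    weights (the likelihood then sums to 2 over W, not 1); ``half_half``
    is the proper equal-prior mixture; ``father_carrier`` conditions on a
    carrier father.
    """

    UNWEIGHTED_SUM = "unweighted_sum"
    HALF_HALF = "half_half"
    FATHER_CARRIER = "father_carrier"


class Model(str, enum.Enum):
    AUTOSOMAL = "autosomal"
    XLINKED = "xlinked"


@dataclass(frozen=True)
class SibshipObservation:
    """W affected among N daughters, with carrier / non-carrier penetrances."""

    n: int
    w: int
    p_c: float = DEFAULT_P_CARRIER
    p_n: float = DEFAULT_P_NONCARRIER

    def __post_init__(self) -> None:
        if not 0 <= self.w <= self.n:
            raise ValueError(f"need 0 <= W <= N, got W={self.w}, N={self.n}")
        if not 0 <= self.p_n <= self.p_c <= 1:
            raise ValueError(
                f"need 0 <= p_n <= p_c <= 1, got p_n={self.p_n}, p_c={self.p_c}"
            )


@dataclass(frozen=True)
class SibshipLikelihoodResult:
    l_autosomal: float
    l_xlinked: float
    lr: float
    mode: CarrierPriorMode


class ModelClass(str, enum.Enum):
    XLINKED_EXCLUDED = "xlinked_excluded"
    EQUAL = "equal"
    WEAK_XLINKED = "weak_xlinked"      # 1 < LR <= 1.5
    STRONG_XLINKED = "strong_xlinked"  # LR > 1.5


@dataclass(frozen=True)
class PedigreeModelClass:
    family_id: str
    model_class: ModelClass
    lr: float


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def sibship_likelihood_enum(
    obs: SibshipObservation,
    model: Model,
    mode: CarrierPriorMode = CarrierPriorMode.UNWEIGHTED_SUM,
) -> float:
    """Sibship likelihood by enumerating admissible (W_c, W_n, N_c, N_n).

    Autosomal: sum over N_c = 0..N of Binom(N_c; N, 1/2) times the
    convolution of carrier/non-carrier affection counts summing to W.
    X-linked: the two segregation states N_c = N and N_c = 0 combined
    according to ``mode``.
    """
    n, w = obs.n, obs.w

    def given_split(n_c: int) -> float:
        n_n = n - n_c
        total = 0.0
        for w_c in range(max(0, w - n_n), min(w, n_c) + 1):
            total += binom.pmf(w_c, n_c, obs.p_c) * binom.pmf(w - w_c, n_n, obs.p_n)
        return total

    if model is Model.AUTOSOMAL:
        return float(
            sum(binom.pmf(n_c, n, 0.5) * given_split(n_c) for n_c in range(n + 1))
        )
    all_c, none_c = given_split(n), given_split(0)
    if mode is CarrierPriorMode.UNWEIGHTED_SUM:
        return float(all_c + none_c)
    if mode is CarrierPriorMode.HALF_HALF:
        return float(0.5 * (all_c + none_c))
    return float(all_c)


def sibship_likelihood_closed(
    obs: SibshipObservation,
    model: Model,
    mode: CarrierPriorMode = CarrierPriorMode.UNWEIGHTED_SUM,
) -> float:
    """Closed-form sibship likelihood (analytic twin of the enumeration).

    Autosomal: marginally each daughter is affected independently with
    probability (p_c + p_n)/2, so W ~ Binomial(N, (p_c + p_n)/2).
    X-linked: Binom(W; N, p_c) and Binom(W; N, p_n) combined per ``mode``.
    """
    n, w = obs.n, obs.w
    if model is Model.AUTOSOMAL:
        return float(binom.pmf(w, n, 0.5 * (obs.p_c + obs.p_n)))
    all_c = binom.pmf(w, n, obs.p_c)
    none_c = binom.pmf(w, n, obs.p_n)
    if mode is CarrierPriorMode.UNWEIGHTED_SUM:
        return float(all_c + none_c)
    if mode is CarrierPriorMode.HALF_HALF:
        return float(0.5 * (all_c + none_c))
    return float(all_c)


def likelihood_ratio(
    obs: SibshipObservation,
    mode: CarrierPriorMode = CarrierPriorMode.UNWEIGHTED_SUM,
) -> SibshipLikelihoodResult:
    """L_xlinked / L_autosomal for one sistership observation."""
    l_a = sibship_likelihood_closed(obs, Model.AUTOSOMAL)
    l_x = sibship_likelihood_closed(obs, Model.XLINKED, mode)
    if l_a == 0:
        raise ZeroDivisionError("autosomal likelihood is zero; LR undefined")
    return SibshipLikelihoodResult(l_a, l_x, l_x / l_a, mode)


# ---------------------------------------------------------------------------
# X-linkage compatibility
# ---------------------------------------------------------------------------

def _descent_graph(ped: Pedigree) -> nx.DiGraph:
    """Parent -> child edges along which an X allele can travel: a mother
    transmits to any child, a father only to daughters."""
    g = nx.DiGraph()
    g.add_nodes_from(ped.members)
    for ind in ped:
        if ind.mother_id and ind.mother_id in ped.members:
            g.add_edge(ind.mother_id, ind.id)
        if ind.father_id and ind.father_id in ped.members:
            if ind.sex is Sex.FEMALE:
                g.add_edge(ind.father_id, ind.id)
    return g


def _source_candidates(ped: Pedigree) -> list[str]:
    """Members at whom a single X-linked allele can enter the family: anyone
    with an absent parent of the sex able to transmit to them (an absent
    mother for anyone, an absent father for a female)."""
    out = []
    for ind in ped:
        mother_absent = not (ind.mother_id and ind.mother_id in ped.members)
        father_absent = not (ind.father_id and ind.father_id in ped.members)
        if mother_absent or (ind.sex is Sex.FEMALE and father_absent):
            out.append(ind.id)
    return out


def xlinked_compatible(
    ped: Pedigree, affected_ids: set[str] | None = None
) -> tuple[bool, tuple[str, str] | None]:
    """Whether a single segregating X-linked allele can explain all affected
    females.

    Compatible iff some allele entry point reaches every affected female
    through valid transmission steps (mother to any child, father to
    daughter) — i.e. no chain of descent is forced through a father-to-son
    step.  On incompatibility, returns one father-son parent-child edge on
    a genealogical path connecting covered and uncovered affected females,
    as the witness of the forced violation.
    """
    if affected_ids is None:
        affected_ids = {
            m.id for m in ped
            if m.sex is Sex.FEMALE and m.has_cancer(CancerSite.OVARY)
        }
    if not affected_ids:
        raise ValueError("compatibility needs at least one affected female")
    g = _descent_graph(ped)
    best_cover: set[str] = set()
    for src in _source_candidates(ped):
        reach = nx.descendants(g, src) | {src}
        cover = affected_ids & reach
        if cover == affected_ids:
            return True, None
        if len(cover) > len(best_cover):
            best_cover = cover
    witness = _father_son_witness(ped, best_cover, affected_ids - best_cover)
    return False, witness


def _father_son_witness(
    ped: Pedigree, covered: set[str], uncovered: set[str]
) -> tuple[str, str] | None:
    """Find a father->son edge on an undirected genealogical path between a
    covered and an uncovered affected female."""
    ug = nx.Graph()
    ug.add_nodes_from(ped.members)
    father_son = set()
    for ind in ped:
        for pid in (ind.father_id, ind.mother_id):
            if pid and pid in ped.members:
                ug.add_edge(pid, ind.id)
        if (
            ind.sex is Sex.MALE
            and ind.father_id
            and ind.father_id in ped.members
        ):
            father_son.add((ind.father_id, ind.id))
    for a in sorted(uncovered):
        for b in sorted(covered) or sorted(ped.members):
            if a == b or not nx.has_path(ug, a, b):
                continue
            path = nx.shortest_path(ug, a, b)
            for u, v in zip(path, path[1:]):
                if (u, v) in father_son:
                    return (u, v)
                if (v, u) in father_son:
                    return (v, u)
    # fall back: any father->son edge in the family
    return next(iter(sorted(father_son)), None)


# ---------------------------------------------------------------------------
# Registry-wide classification
# ---------------------------------------------------------------------------

def _sisterships(
    ped: Pedigree, rule: EligibilityRule
) -> list[tuple[int, int]]:
    """(N, W) per nuclear-family sistership with >= 1 eligible daughter.

    N counts daughters with determinable disease status under ``rule``;
    W counts those with ovarian cancer.
    """
    groups: dict[tuple[str, str], list[Individual]] = {}
    for ind in ped:
        if ind.sex is Sex.FEMALE and ind.father_id and ind.mother_id:
            groups.setdefault((ind.father_id, ind.mother_id), []).append(ind)
    out = []
    for sisters in groups.values():
        eligible = [s for s in sisters if _is_eligible(s, rule) is True]
        if not eligible:
            continue
        w = sum(s.has_cancer(CancerSite.OVARY) for s in eligible)
        out.append((len(eligible), w))
    return out


def classify_pedigrees(
    pedigrees: list[Pedigree],
    p_c: float = DEFAULT_P_CARRIER,
    p_n: float = DEFAULT_P_NONCARRIER,
    mode: CarrierPriorMode = CarrierPriorMode.UNWEIGHTED_SUM,
    rule: EligibilityRule | None = None,
    min_affected: int = 2,
) -> list[PedigreeModelClass]:
    """Classify families by their X-linked vs autosomal likelihood ratio.

    The family LR is the product of per-sistership likelihood ratios over
    nuclear-family sisterships with at least one eligible daughter
    (sisterships segregate independently given the founders).  Families
    whose affection pattern cannot be produced by a single X-linked allele
    are ``xlinked_excluded``; otherwise LR <= 1 is ``equal``, 1 < LR <= 1.5
    ``weak_xlinked`` and LR > 1.5 ``strong_xlinked``.

    Families with fewer than ``min_affected`` affected females are skipped.
    """
    rule = rule or EligibilityRule()
    out: list[PedigreeModelClass] = []
    for ped in pedigrees:
        n_affected = sum(
            m.sex is Sex.FEMALE and m.has_cancer(CancerSite.OVARY) for m in ped
        )
        if n_affected < min_affected:
            continue
        compatible, _ = xlinked_compatible(ped)
        if not compatible:
            out.append(PedigreeModelClass(ped.family_id, ModelClass.XLINKED_EXCLUDED, 0.0))
            continue
        sibs = _sisterships(ped, rule)
        if not sibs:
            logger.warning(
                "family %s: no qualifying sistership; LR set to 1", ped.family_id
            )
            out.append(PedigreeModelClass(ped.family_id, ModelClass.EQUAL, 1.0))
            continue
        lr = 1.0
        for n, w in sibs:
            lr *= likelihood_ratio(SibshipObservation(n, w, p_c, p_n), mode).lr
        if lr <= 1.0:
            cls = ModelClass.EQUAL
        elif lr <= 1.5:
            cls = ModelClass.WEAK_XLINKED
        else:
            cls = ModelClass.STRONG_XLINKED
        out.append(PedigreeModelClass(ped.family_id, cls, lr))
    return out


# ---------------------------------------------------------------------------
# Brute-force oracle helper (used by tests; exact for small pedigrees)
# ---------------------------------------------------------------------------

def xlinked_compatible_bruteforce(
    ped: Pedigree, affected_ids: set[str] | None = None, max_members: int = 20
) -> bool:
    """Exhaustive search over carrier assignments with a single allele
    origin; exponential, intended as an independent oracle on tiny families.
    """
    if affected_ids is None:
        affected_ids = {
            m.id for m in ped
            if m.sex is Sex.FEMALE and m.has_cancer(CancerSite.OVARY)
        }
    ids = sorted(ped.members)
    if len(ids) > max_members:
        raise ValueError("brute force limited to small pedigrees")
    sources = set(_source_candidates(ped))
    for r in range(len(ids) + 1):
        for subset in itertools.combinations(ids, r):
            s = set(subset)
            if not affected_ids <= s:
                continue
            roots = []
            ok = True
            for x in s:
                ind = ped.members[x]
                mother_in = ind.mother_id in s if ind.mother_id else False
                father_in = (
                    ind.father_id in s
                    if (ind.father_id and ind.sex is Sex.FEMALE)
                    else False
                )
                if mother_in or father_in:
                    continue
                if x in sources:
                    roots.append(x)
                else:
                    ok = False
                    break
            if ok and len(roots) == 1:
                return True
    return False
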