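"""Synthetic familial ovarian cancer registry generator.

Families are built around the grandmother-granddaughter design: two founder
couples, their children (one son on the paternal side marrying one daughter
of the maternal side), and the granddaughter generation, optionally
extended to deeper generations through external founder spouses.  A single
dominant risk allele segregates either autosomally or X-linked; female
carriers develop ovarian cancer with penetrance ``p_c`` and non-carriers
with ``p_n``, with Weibull onset ages accelerated in carriers by a
configurable hazard ratio.  Registry ascertainment keeps only families
meeting the enrollment criteria (two or more ovarian cancers; one ovarian
cancer plus two other cancers; or an early-onset ovarian cancer plus
another cancer), via rejection sampling.

Everything is driven by one seeded generator: the same config yields
byte-identical output.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import (
    BrcaTest,
    CancerSite,
    Diagnosis,
    Individual,
    Pedigree,
    Sex,
    VitalStatus,
)

__all__ = ["TruthMode", "SimConfig", "SimOutput", "simulate_registry",
           "simulate_genotype_matrix"]

logger = logging.getLogger(__name__)


class TruthMode(str, enum.Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    XLINKED_DOMINANT = "xlinked_dominant"
    NULL = "null"


# Onset model: Weibull with shape 7.3 and scale 52.6 years puts the
# non-carrier median at ~50 y; under proportional hazards with HR 2.85 the
# carrier median advances by ~6.7 y (scale shrinks by HR^(-1/shape)).
DEFAULT_ONSET_SHAPE = 7.3
DEFAULT_ONSET_SCALE = 52.6

# Last-contact age means by generation depth (founders, middle, youngest),
# and the probability the individual has died by last contact.
_CONTACT_MEAN = (85.0, 62.0, 50.0)
_CONTACT_SD = 10.0
_DEATH_PROB = (0.6, 0.2, 0.05)


@dataclass(frozen=True)
class SimConfig:
    """Generative specification of the synthetic registry."""

    mode: TruthMode = TruthMode.XLINKED_DOMINANT
    founder_allele_freq: float = 0.05
    p_c: float = 0.65           # carrier penetrance (lifetime)
    p_n: float = 0.15           # non-carrier penetrance (familial background)
    onset_shape: float = DEFAULT_ONSET_SHAPE
    onset_scale: float = DEFAULT_ONSET_SCALE
    carrier_hr: float = 2.85    # onset hazard ratio in carriers
    sex_ratio_distortion: float = 0.5  # P(daughter) for a carrier father's child
    generations: int = 3
    sibship_mean: float = 2.5   # truncated-Poisson (>=1) mean
    other_cancer_rate: float = 0.05     # lifetime background, any site, either sex
    prostate_penetrance_carrier: float = 0.0  # optional carrier-male phenotype
    oophorectomy_rate: float = 0.02
    ascertainment: str = "registry"     # "registry" or "none"
    early_onset_age: float = 45.0
    n_families: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("founder_allele_freq", "p_c", "p_n",
                     "sex_ratio_distortion", "other_cancer_rate",
                     "oophorectomy_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 2:
            raise ValueError("generations must be >= 2")
        if self.ascertainment not in ("registry", "none"):
            raise ValueError(f"unknown ascertainment {self.ascertainment!r}")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")
        return self.seed


@dataclass
class SimOutput:
    pedigrees: list[Pedigree]
    carriers: dict[tuple[str, str], bool]  # (family_id, individual_id) -> truth
    config: SimConfig
    n_simulated: int   # families drawn before ascertainment
    acceptance_rate: float = 1.0


# ---------------------------------------------------------------------------
# Per-individual machinery
# ---------------------------------------------------------------------------

def _founder_carrier(sex: Sex, cfg: SimConfig, rng: np.random.Generator) -> bool:
    """Founders carry the dominant allele at the population frequency; under
    X-linkage males are hemizygous (one draw) while females have two
    chances, as does anyone under the autosomal model."""
    f = cfg.founder_allele_freq
    if cfg.mode is TruthMode.NULL:
        return False
    if cfg.mode is TruthMode.XLINKED_DOMINANT and sex is Sex.MALE:
        return bool(rng.random() < f)
    return bool(rng.random() < 1 - (1 - f) ** 2)


def _child_sex(father_carrier: bool, cfg: SimConfig, rng: np.random.Generator) -> Sex:
    p_daughter = 0.5
    if cfg.mode is TruthMode.XLINKED_DOMINANT and father_carrier:
        p_daughter = cfg.sex_ratio_distortion
    return Sex.FEMALE if rng.random() < p_daughter else Sex.MALE


def _child_carrier(
    father_carrier: bool,
    mother_carrier: bool,
    child_sex: Sex,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> bool:
    """Mendelian transmission of a single (heterozygous) dominant allele."""
    if cfg.mode is TruthMode.NULL:
        return False
    if cfg.mode is TruthMode.AUTOSOMAL_DOMINANT:
        got = False
        if father_carrier and rng.random() < 0.5:
            got = True
        if mother_carrier and rng.random() < 0.5:
            got = True
        return got
    # X-linked: a carrier father gives his X to every daughter, never a son;
    # a carrier mother transmits either X with probability 1/2 to any child.
    got = father_carrier and child_sex is Sex.FEMALE
    if mother_carrier and rng.random() < 0.5:
        got = True
    return got


def _onset_age(carrier: bool, cfg: SimConfig, rng: np.random.Generator) -> float:
    scale = cfg.onset_scale
    if carrier and cfg.carrier_hr != 1.0:
        scale *= cfg.carrier_hr ** (-1.0 / cfg.onset_shape)
    return float(scale * rng.weibull(cfg.onset_shape))


def _sibship_size(cfg: SimConfig, rng: np.random.Generator) -> int:
    # Poisson truncated to >= 1 with the configured mean before truncation.
    while True:
        k = int(rng.poisson(cfg.sibship_mean))
        if k >= 1:
            return k


class _Builder:
    """Accumulates one family's members and truth labels."""

    def __init__(self, family_id: str, cfg: SimConfig, rng: np.random.Generator):
        self.fid = family_id
        self.cfg = cfg
        self.rng = rng
        self.members: dict[str, Individual] = {}
        self.carrier: dict[str, bool] = {}
        self._n = 0

    def new_id(self) -> str:
        self._n += 1
        return f"I{self._n}"

    def add(
        self,
        sex: Sex,
        carrier: bool,
        depth: int,
        father_id: str | None = None,
        mother_id: str | None = None,
    ) -> str:
        cfg, rng = self.cfg, self.rng
        iid = self.new_id()
        tier = min(depth, len(_CONTACT_MEAN) - 1)
        contact = float(
            np.clip(rng.normal(_CONTACT_MEAN[tier], _CONTACT_SD), 18.0, 105.0)
        )
        dead = rng.random() < _DEATH_PROB[tier]
        diagnoses: list[Diagnosis] = []
        ooph_age: float | None = None

        if sex is Sex.FEMALE:
            ooph = rng.random() < cfg.oophorectomy_rate
            if ooph:
                ooph_age = float(min(rng.uniform(35.0, 50.0), contact))
            destined = rng.random() < (cfg.p_c if carrier else cfg.p_n)
            if destined:
                onset = _onset_age(carrier, cfg, rng)
                blocked = ooph_age is not None and ooph_age < onset
                if onset <= contact and not blocked:
                    diagnoses.append(
                        Diagnosis(CancerSite.OVARY, round(onset, 1), True)
                    )
                    ooph_age = None  # prophylaxis only recorded when it precedes
        elif carrier and cfg.prostate_penetrance_carrier > 0:
            if self.rng.random() < cfg.prostate_penetrance_carrier:
                age = float(min(rng.uniform(50.0, 80.0), contact))
                diagnoses.append(Diagnosis(CancerSite.PROSTATE, round(age, 1), True))

        if rng.random() < cfg.other_cancer_rate:
            age = float(min(rng.uniform(30.0, 75.0), contact))
            diagnoses.append(Diagnosis(CancerSite.OTHER, round(age, 1), True))

        contact = round(contact, 1)
        self.members[iid] = Individual(
            id=iid,
            family_id=self.fid,
            sex=sex,
            father_id=father_id,
            mother_id=mother_id,
            proband=False,
            diagnoses=diagnoses,
            oophorectomy_age=ooph_age if ooph_age is None else round(ooph_age, 1),
            vital_status=VitalStatus.DEAD if dead else VitalStatus.ALIVE,
            age_last_contact=None if dead else contact,
            age_at_death=contact if dead else None,
            brca_test=BrcaTest.UNTESTED,
        )
        self.carrier[iid] = carrier
        return iid


def _simulate_family(
    family_id: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[Pedigree, dict[str, bool]]:
    b = _Builder(family_id, cfg, rng)

    # Founder couples: paternal grandparents and maternal grandparents.
    pgf = b.add(Sex.MALE, _founder_carrier(Sex.MALE, cfg, rng), 0)
    pgm = b.add(Sex.FEMALE, _founder_carrier(Sex.FEMALE, cfg, rng), 0)
    mgf = b.add(Sex.MALE, _founder_carrier(Sex.MALE, cfg, rng), 0)
    mgm = b.add(Sex.FEMALE, _founder_carrier(Sex.FEMALE, cfg, rng), 0)

    def make_children(
        father: str, mother: str, depth: int, force_sex: Sex | None = None
    ) -> list[str]:
        """One sibship; optionally force the first child's sex (the lineal
        connector) so the three-generation chain always exists."""
        n = _sibship_size(cfg, rng)
        kids = []
        fc, mc = b.carrier[father], b.carrier[mother]
        for i in range(n):
            sex = force_sex if (i == 0 and force_sex) else _child_sex(fc, cfg, rng)
            carrier = _child_carrier(fc, mc, sex, cfg, rng)
            kids.append(b.add(sex, carrier, depth, father, mother))
        return kids

    paternal_sibs = make_children(pgf, pgm, 1, force_sex=Sex.MALE)
    maternal_sibs = make_children(mgf, mgm, 1, force_sex=Sex.FEMALE)
    father, mother = paternal_sibs[0], maternal_sibs[0]

    couples = [(father, mother)]
    depth = 2
    while couples and depth <= cfg.generations - 1:
        next_couples = []
        for f_id, m_id in couples:
            kids = make_children(f_id, m_id, depth)
            if depth + 1 <= cfg.generations - 1:
                for kid in kids:
                    spouse_sex = (
                        Sex.FEMALE if b.members[kid].sex is Sex.MALE else Sex.MALE
                    )
                    spouse = b.add(
                        spouse_sex, _founder_carrier(spouse_sex, cfg, rng), depth
                    )
                    pair = (
                        (kid, spouse)
                        if b.members[kid].sex is Sex.MALE
                        else (spouse, kid)
                    )
                    next_couples.append(pair)
        couples = next_couples
        depth += 1

    ped = Pedigree(family_id=family_id, members=b.members)
    return ped, b.carrier


def _meets_registry_criteria(ped: Pedigree, cfg: SimConfig) -> bool:
    ovary, other = [], 0
    for m in ped:
        for d in m.diagnoses:
            if d.site is CancerSite.OVARY:
                ovary.append(d)
            else:
                other += 1
    if len(ovary) >= 2:
        return True
    if len(ovary) == 1:
        if other >= 2:
            return True
        early = any(
            d.age_at_dx is not None and d.age_at_dx <= cfg.early_onset_age
            for d in ovary
        )
        if early and other >= 1:
            return True
    return False


def _flag_proband(ped: Pedigree) -> None:
    """The proband is the earliest-onset confirmed ovarian cancer case."""
    best: tuple[float, str] | None = None
    for m in ped:
        for d in m.diagnoses:
            if d.site is CancerSite.OVARY and d.confirmed and d.age_at_dx is not None:
                key = (d.age_at_dx, m.id)
                if best is None or key < best:
                    best = key
    if best is not None:
        ped[best[1]].proband = True


def simulate_registry(config: SimConfig) -> SimOutput:
    """Generate ``n_families`` families under the configured truth.

    With registry ascertainment, families are rejection-sampled against the
    enrollment criteria and the earliest-onset case in each accepted family
    is flagged as the proband.  Aborts with a diagnostic if the acceptance
    rate falls below 1e-4.
    """
    seed = config.require_seed()
    rng = np.random.default_rng(seed)
    accepted: list[Pedigree] = []
    carriers: dict[tuple[str, str], bool] = {}
    n_drawn = 0
    while len(accepted) < config.n_families:
        n_drawn += 1
        ped, truth = _simulate_family(f"F{n_drawn}", config, rng)
        if config.ascertainment == "registry":
            if not _meets_registry_criteria(ped, config):
                if n_drawn >= 20_000 and len(accepted) < n_drawn * 1e-4:
                    raise RuntimeError(
                        f"ascertainment acceptance rate "
                        f"{len(accepted) / n_drawn:.2e} below 1e-4 after "
                        f"{n_drawn} draws; check penetrance configuration"
                    )
                continue
            _flag_proband(ped)
        accepted.append(ped)
        for iid, c in truth.items():
            carriers[(ped.family_id, iid)] = c
    rate = len(accepted) / n_drawn
    logger.info(
        "simulate_registry: %d families accepted of %d drawn (%.1f%%)",
        len(accepted), n_drawn, 100 * rate,
    )
    return SimOutput(accepted, carriers, config, n_drawn, rate)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

def simulate_genotype_matrix(
    config: SimConfig,
    subjects: list[tuple[str, bool]],
    n_variants: int = 2161,
    causal_id: str = "causal",
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
) -> pd.DataFrame:
    """Variant x subject alt-allele-count matrix with one causal variant.

    ``subjects`` pairs subject ids with their true carrier status; the
    causal variant's genotype is the carrier status (heterozygous).  The
    remaining ``n_variants - 1`` null variants have MAFs drawn uniformly
    from ``maf_range`` and genotypes in Hardy-Weinberg proportions,
    independent of phenotype.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = [s for s, _ in subjects]
    carrier = np.array([c for _, c in subjects], dtype=int)
    n = len(ids)
    m_null = n_variants - 1
    mafs = rng.uniform(*maf_range, size=m_null)
    null = rng.binomial(2, np.repeat(mafs, n)).reshape(m_null, n)
    data = np.vstack([carrier[None, :], null])
    index = [causal_id] + [f"null_{i + 1}" for i in range(m_null)]
    return pd.DataFrame(data, index=pd.Index(index, name="variant_id"), columns=ids)
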