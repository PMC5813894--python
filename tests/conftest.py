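"""Shared fixtures: hand-built pedigrees and small simulated registries."""

from __future__ import annotations

import pytest

from foxlink.pedigree import (
    BrcaTest,
    CancerSite,
    Diagnosis,
    Individual,
    Pedigree,
    Sex,
    VitalStatus,
)
from foxlink.simulate import SimConfig, TruthMode, simulate_registry


def make_person(
    iid: str,
    fam: str = "F1",
    sex: Sex = Sex.FEMALE,
    father: str | None = None,
    mother: str | None = None,
    ovary_dx: float | None = None,
    breast_dx: float | None = None,
    contact: float | None = 70.0,
    dead: bool = False,
    proband: bool = False,
    brca: BrcaTest = BrcaTest.UNTESTED,
    ooph: float | None = None,
) -> Individual:
    dxs = []
    if ovary_dx is not None:
        dxs.append(Diagnosis(CancerSite.OVARY, ovary_dx, True))
    if breast_dx is not None:
        dxs.append(Diagnosis(CancerSite.BREAST, breast_dx, True))
    return Individual(
        id=iid,
        family_id=fam,
        sex=sex,
        father_id=father,
        mother_id=mother,
        proband=proband,
        diagnoses=dxs,
        oophorectomy_age=ooph,
        vital_status=VitalStatus.DEAD if dead else VitalStatus.ALIVE,
        age_last_contact=None if dead else contact,
        age_at_death=contact if dead else None,
        brca_test=brca,
    )


@pytest.fixture
def trio() -> Pedigree:
    """Father, mother, affected daughter."""
    ped = Pedigree(
        "F1",
        [
            make_person("dad", sex=Sex.MALE),
            make_person("mom"),
            make_person("kid", father="dad", mother="mom", ovary_dx=45.0),
        ],
    )
    ped.validate()
    return ped


@pytest.fixture
def three_gen() -> Pedigree:
    """Three generations: both grandmother lineages present; the paternal
    grandmother is the only affected grandmother."""
    ped = Pedigree(
        "F2",
        [
            make_person("pgf", sex=Sex.MALE, dead=True, contact=80.0),
            make_person("pgm", ovary_dx=55.0, dead=True, contact=78.0),
            make_person("mgf", sex=Sex.MALE, dead=True, contact=82.0),
            make_person("mgm", contact=84.0),
            make_person("dad", sex=Sex.MALE, father="pgf", mother="pgm"),
            make_person("aunt_p", father="pgf", mother="pgm", contact=66.0),
            make_person("mom", father="mgf", mother="mgm"),
            make_person("gd", father="dad", mother="mom", ovary_dx=44.0,
                        contact=50.0, proband=True),
            make_person("gd2", father="dad", mother="mom", contact=52.0),
        ],
    )
    ped.validate()
    return ped


@pytest.fixture(scope="session")
def xlinked_registry():
    """Small ascertained registry under X-linked truth (frozen seed)."""
    cfg = SimConfig(
        mode=TruthMode.XLINKED_DOMINANT, n_families=150, seed=7,
    )
    return simulate_registry(cfg)
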