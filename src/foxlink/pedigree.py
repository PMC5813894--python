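"""Pedigree data model, validation, and extended-PED file I/O.

The registry pedigrees are multi-generation families with per-individual
cancer diagnoses, censoring ages, BRCA test results and optional genotypes.
Files use a LINKAGE-compatible tab-separated dialect: the first five columns
are the classic ``family_id individual_id father_id mother_id sex`` fields,
followed by registry phenotype columns (see :class:`PedDialect`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CancerSite",
    "Sex",
    "VitalStatus",
    "BrcaTest",
    "BrcaStatus",
    "DiseasePattern",
    "Diagnosis",
    "Individual",
    "Pedigree",
    "PedDialect",
    "PedigreeError",
    "read_ped",
    "write_ped",
    "read_genotype_table",
    "write_genotype_table",
    "attach_genotypes",
    "classify_brca",
    "classify_pattern",
    "relations",
    "Relations",
]

MAX_AGE = 120.0


class CancerSite(str, enum.Enum):
    OVARY = "ovary"
    BREAST = "breast"
    PROSTATE = "prostate"
    OTHER = "other"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class VitalStatus(str, enum.Enum):
    ALIVE = "alive"
    DEAD = "dead"


class BrcaTest(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNTESTED = "untested"


class BrcaStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class DiseasePattern(str, enum.Enum):
    SITE_SPECIFIC_OVARY = "site_specific_ovary"
    BREAST_AND_OVARY = "breast_and_ovary"
    OTHER = "other"


class PedigreeError(ValueError):
    """Raised on malformed pedigree files or invariant violations."""


@dataclass(frozen=True)
class Diagnosis:
    """A single cancer diagnosis: site, age at diagnosis (years, may be
    unknown) and whether it was confirmed by medical record or death
    certificate."""

    site: CancerSite
    age_at_dx: float | None = None
    confirmed: bool = True

    def __post_init__(self) -> None:
        if self.age_at_dx is not None and not (0 <= self.age_at_dx <= MAX_AGE):
            raise PedigreeError(
                f"diagnosis age {self.age_at_dx} outside [0, {MAX_AGE}]"
            )


@dataclass
class Individual:
    id: str
    family_id: str
    sex: Sex = Sex.UNKNOWN
    father_id: str | None = None
    mother_id: str | None = None
    proband: bool = False
    diagnoses: list[Diagnosis] = field(default_factory=list)
    oophorectomy_age: float | None = None
    vital_status: VitalStatus = VitalStatus.ALIVE
    age_last_contact: float | None = None
    age_at_death: float | None = None
    brca_test: BrcaTest = BrcaTest.UNTESTED
    genotypes: dict[str, int | None] = field(default_factory=dict)

    # -- phenotype helpers ------------------------------------------------

    def diagnoses_of(self, site: CancerSite) -> list[Diagnosis]:
        return [d for d in self.diagnoses if d.site is site]

    def has_cancer(self, site: CancerSite, confirmed_only: bool = False) -> bool:
        return any(
            not confirmed_only or d.confirmed for d in self.diagnoses_of(site)
        )

    def ovarian_dx_age(self) -> float | None:
        """Earliest known ovarian-cancer diagnosis age, or None."""
        ages = [
            d.age_at_dx for d in self.diagnoses_of(CancerSite.OVARY)
            if d.age_at_dx is not None
        ]
        return min(ages) if ages else None

    @property
    def is_female(self) -> bool:
        return self.sex is Sex.FEMALE


@dataclass
class Pedigree:
    """One family: a collection of individuals keyed by id.

    Parent references form a directed acyclic graph; fathers are male and
    mothers female.  BRCA status and disease pattern are derivable from the
    members via :func:`classify_brca` / :func:`classify_pattern`.
    """

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.members, (list, tuple)):
            self.members = {m.id: m for m in self.members}

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, id: str) -> Individual:
        try:
            return self.members[id]
        except KeyError:
            raise PedigreeError(
                f"individual {id!r} not in family {self.family_id!r}"
            ) from None

    def father(self, ind: Individual) -> Individual | None:
        return self.members.get(ind.father_id) if ind.father_id else None

    def mother(self, ind: Individual) -> Individual | None:
        return self.members.get(ind.mother_id) if ind.mother_id else None

    @property
    def brca_status(self) -> BrcaStatus:
        return classify_brca(self)

    @property
    def disease_pattern(self) -> DiseasePattern:
        return classify_pattern(self)

    def validate(self) -> None:
        validate_pedigree(self)


def validate_pedigree(ped: Pedigree) -> None:
    """Check structural invariants; raise :class:`PedigreeError` listing
    every offending individual."""
    if not ped.members:
        raise PedigreeError(f"family {ped.family_id!r} has no members")
    problems: list[str] = []
    for ind in ped:
        for pid, want in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
            if pid is None:
                continue
            parent = ped.members.get(pid)
            if parent is not None and parent.sex is not want:
                role = "father" if want is Sex.MALE else "mother"
                problems.append(
                    f"{ind.id}: {role} {pid} has sex {parent.sex.value}"
                )
        cap = max(
            (a for a in (ind.age_last_contact, ind.age_at_death) if a is not None),
            default=None,
        )
        for label, age in [("oophorectomy", ind.oophorectomy_age)] + [
            (f"{d.site.value} dx", d.age_at_dx) for d in ind.diagnoses
        ]:
            if age is None:
                continue
            if not (0 <= age <= MAX_AGE):
                problems.append(f"{ind.id}: {label} age {age} outside [0,{MAX_AGE}]")
            elif cap is not None and age > cap:
                problems.append(
                    f"{ind.id}: {label} age {age} exceeds last known age {cap}"
                )
        for a in (ind.age_last_contact, ind.age_at_death):
            if a is not None and not (0 <= a <= MAX_AGE):
                problems.append(f"{ind.id}: age {a} outside [0,{MAX_AGE}]")
    cycle = _find_cycle(ped)
    if cycle:
        problems.append("ancestry cycle: " + " -> ".join(cycle))
    if problems:
        raise PedigreeError(
            f"family {ped.family_id!r}: " + "; ".join(problems)
        )


def _find_cycle(ped: Pedigree) -> list[str] | None:
    """Iterative three-colour DFS over child->parent edges."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {i: WHITE for i in ped.members}
    for start in ped.members:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(_parent_ids(ped, start)))]
        colour[start] = GREY
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in colour:
                    continue
                if colour[nxt] == GREY:
                    return path[path.index(nxt):] + [nxt]
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(_parent_ids(ped, nxt))))
                    path.append(nxt)
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
                path.pop()
    return None


def _parent_ids(ped: Pedigree, id: str) -> list[str]:
    ind = ped.members[id]
    return [p for p in (ind.father_id, ind.mother_id) if p]


# ---------------------------------------------------------------------------
# Extended-PED dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedDialect:
    """Column conventions for the extended PED format.

    The first five columns match LINKAGE (sex coded 1=male, 2=female,
    0=unknown; parent ids use ``missing_id`` when absent).  Ages use
    ``missing_age``; the diagnosis column is semicolon-delimited
    ``site:age:confirmed`` triples or ``missing_age`` when there are none.
    """

    missing_id: str = "0"
    missing_age: str = "NA"
    sep: str = "\t"

    COLUMNS = (
        "family_id",
        "individual_id",
        "father_id",
        "mother_id",
        "sex",
        "proband",
        "diagnoses",
        "oophorectomy_age",
        "vital_status",
        "age_last_contact",
        "age_at_death",
        "brca_test",
    )


_SEX_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_SEX_DECODE = {v: k for k, v in _SEX_CODE.items()}


def _fmt_age(age: float | None, dialect: PedDialect) -> str:
    if age is None:
        return dialect.missing_age
    return f"{age:g}"


def _parse_age(tok: str, dialect: PedDialect, line_no: int) -> float | None:
    if tok == dialect.missing_age:
        return None
    try:
        return float(tok)
    except ValueError:
        raise PedigreeError(f"line {line_no}: bad age token {tok!r}") from None


def _fmt_diagnoses(dxs: list[Diagnosis], dialect: PedDialect) -> str:
    if not dxs:
        return dialect.missing_age
    return ";".join(
        f"{d.site.value}:{_fmt_age(d.age_at_dx, dialect)}:{int(d.confirmed)}"
        for d in dxs
    )


def _parse_diagnoses(tok: str, dialect: PedDialect, line_no: int) -> list[Diagnosis]:
    if tok == dialect.missing_age or tok == "":
        return []
    out = []
    for part in tok.split(";"):
        try:
            site_s, age_s, conf_s = part.split(":")
            out.append(
                Diagnosis(
                    site=CancerSite(site_s),
                    age_at_dx=_parse_age(age_s, dialect, line_no),
                    confirmed=bool(int(conf_s)),
                )
            )
        except (ValueError, PedigreeError) as exc:
            raise PedigreeError(
                f"line {line_no}: bad diagnosis field {part!r} ({exc})"
            ) from None
    return out


def read_ped(path: str | Path, dialect: PedDialect | None = None) -> list[Pedigree]:
    """Read an extended-PED file into validated pedigrees.

    One row per individual, '#' comment lines ignored, row order preserved
    within each family.  Raises :class:`PedigreeError` naming the line
    number on a malformed row, and a validation error listing offending ids
    on parent-sex conflicts or ancestry cycles.
    """
    dialect = dialect or PedDialect()
    families: dict[str, Pedigree] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            toks = line.split(dialect.sep) if dialect.sep in line else line.split()
            if len(toks) != len(PedDialect.COLUMNS):
                raise PedigreeError(
                    f"line {line_no}: expected {len(PedDialect.COLUMNS)} "
                    f"columns, got {len(toks)}"
                )
            (fam, iid, fid, mid, sex_s, proband_s, dx_s, ooph_s,
             vital_s, alc_s, aad_s, brca_s) = toks
            try:
                ind = Individual(
                    id=iid,
                    family_id=fam,
                    sex=_SEX_DECODE.get(sex_s, Sex.UNKNOWN),
                    father_id=None if fid == dialect.missing_id else fid,
                    mother_id=None if mid == dialect.missing_id else mid,
                    proband=bool(int(proband_s)),
                    diagnoses=_parse_diagnoses(dx_s, dialect, line_no),
                    oophorectomy_age=_parse_age(ooph_s, dialect, line_no),
                    vital_status=VitalStatus(vital_s),
                    age_last_contact=_parse_age(alc_s, dialect, line_no),
                    age_at_death=_parse_age(aad_s, dialect, line_no),
                    brca_test=BrcaTest(brca_s),
                )
            except ValueError as exc:
                raise PedigreeError(f"line {line_no}: {exc}") from None
            fam_ped = families.setdefault(fam, Pedigree(family_id=fam))
            if iid in fam_ped.members:
                raise PedigreeError(
                    f"line {line_no}: duplicate individual {iid!r} in family {fam!r}"
                )
            fam_ped.members[iid] = ind
    peds = list(families.values())
    for ped in peds:
        validate_pedigree(ped)
    return peds


def write_ped(
    pedigrees: Iterable[Pedigree],
    path: str | Path,
    dialect: PedDialect | None = None,
) -> None:
    """Write pedigrees in the extended-PED dialect; re-reading yields
    field-identical pedigrees (round-trip property)."""
    dialect = dialect or PedDialect()
    with open(path, "w") as fh:
        fh.write("#" + dialect.sep.join(PedDialect.COLUMNS) + "\n")
        for ped in pedigrees:
            for ind in ped:
                row = [
                    ped.family_id,
                    ind.id,
                    ind.father_id or dialect.missing_id,
                    ind.mother_id or dialect.missing_id,
                    _SEX_CODE[ind.sex],
                    str(int(ind.proband)),
                    _fmt_diagnoses(ind.diagnoses, dialect),
                    _fmt_age(ind.oophorectomy_age, dialect),
                    ind.vital_status.value,
                    _fmt_age(ind.age_last_contact, dialect),
                    _fmt_age(ind.age_at_death, dialect),
                    ind.brca_test.value,
                ]
                fh.write(dialect.sep.join(row) + "\n")


# ---------------------------------------------------------------------------
# Genotype table I/O
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a variant x individual alt-allele-count matrix.

    Tab-separated; first column variant id, header row of individual ids,
    entries 0/1/2 or NA.  Returns a DataFrame indexed by variant id with
    nullable-integer entries.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df = df.astype("Int64")
    bad = df.stack().dropna()
    if ((bad < 0) | (bad > 2)).any():
        raise PedigreeError("genotype entries must be 0, 1, 2 or NA")
    return df


def write_genotype_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", index_label="variant_id")


def attach_genotypes(pedigrees: Iterable[Pedigree], table: pd.DataFrame) -> int:
    """Copy genotype calls from a variant x individual table onto members.

    Individual ids are matched as ``family_id:individual_id`` if the column
    contains a colon, bare individual id otherwise.  Returns the number of
    individuals that received genotypes.
    """
    n = 0
    for ped in pedigrees:
        for ind in ped:
            for key in (f"{ped.family_id}:{ind.id}", ind.id):
                if key in table.columns:
                    col = table[key]
                    ind.genotypes = {
                        v: (None if pd.isna(g) else int(g))
                        for v, g in col.items()
                    }
                    n += 1
                    break
    return n


# ---------------------------------------------------------------------------
# Family-level classification
# ---------------------------------------------------------------------------

def classify_brca(ped: Pedigree) -> BrcaStatus:
    """Family BRCA status: positive if any member tested positive; negative
    if at least one member was tested and none positive; unknown when no
    member was tested."""
    tested = [m for m in ped if m.brca_test is not BrcaTest.UNTESTED]
    if any(m.brca_test is BrcaTest.POSITIVE for m in tested):
        return BrcaStatus.POSITIVE
    if tested:
        return BrcaStatus.NEGATIVE
    return BrcaStatus.UNKNOWN


def classify_pattern(ped: Pedigree, min_breast: int = 1) -> DiseasePattern:
    """Disease pattern of the family.

    Families with ovarian cancers and at least ``min_breast`` breast cancers
    are breast-and-ovary; families with ovarian cancers and fewer breast
    cancers are site-specific ovary; anything else is other.
    """
    n_ovary = sum(len(m.diagnoses_of(CancerSite.OVARY)) for m in ped)
    n_breast = sum(len(m.diagnoses_of(CancerSite.BREAST)) for m in ped)
    if n_ovary >= 1 and n_breast >= min_breast:
        return DiseasePattern.BREAST_AND_OVARY
    if n_ovary >= 1:
        return DiseasePattern.SITE_SPECIFIC_OVARY
    return DiseasePattern.OTHER


# ---------------------------------------------------------------------------
# Relations
# ---------------------------------------------------------------------------

@dataclass
class Relations:
    """Relatives of one individual, classified by lineage where relevant."""

    parents: list[str]
    siblings: list[str]           # full siblings: share both parents
    paternal_grandmother: str | None
    maternal_grandmother: str | None
    paternal_aunts: list[str]     # father's full sisters
    maternal_aunts: list[str]     # mother's full sisters
    offspring: list[str]


def relations(ped: Pedigree, id: str) -> Relations:
    """Relatives of ``id`` within the family.

    Paternal grandmother is the mother of the father; maternal grandmother
    the mother of the mother.  Full siblings share both (known) parents;
    aunts are the parents' full sisters, classified by side.
    """
    ind = ped[id]

    def full_sibs(of: Individual) -> list[str]:
        if not (of.father_id and of.mother_id):
            return []
        return [
            m.id for m in ped
            if m.id != of.id
            and m.father_id == of.father_id
            and m.mother_id == of.mother_id
        ]

    father = ped.father(ind)
    mother = ped.mother(ind)

    def grandmother(parent: Individual | None) -> str | None:
        if parent is None:
            return None
        gm = ped.mother(parent)
        return gm.id if gm else None

    def aunts(parent: Individual | None) -> list[str]:
        if parent is None:
            return []
        return [s for s in full_sibs(parent) if ped[s].sex is Sex.FEMALE]

    return Relations(
        parents=[p.id for p in (father, mother) if p is not None],
        siblings=full_sibs(ind),
        paternal_grandmother=grandmother(father),
        maternal_grandmother=grandmother(mother),
        paternal_aunts=aunts(father),
        maternal_aunts=aunts(mother),
        offspring=[
            m.id for m in ped if id in (m.father_id, m.mother_id)
        ],
    )
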