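"""Age-of-onset endpoints, Kaplan-Meier / log-rank / Cox estimation, and the
X-chromosome variant scan with a Bonferroni LOD threshold.

The endpoint is age at ovarian-cancer diagnosis; death, prophylactic
oophorectomy and last contact censor the observation at their age.  The
variant scan tests each retained variant for an age-of-onset association
with a two-group log-rank test and reports LOD = -log10(p) against the
chromosome-wide Bonferroni threshold -log10(alpha / m_retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .pedigree import CancerSite, Pedigree, Sex

__all__ = [
    "SurvivalRecord",
    "KMFit",
    "ScanResult",
    "onset_records",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "CoxResult",
    "variant_scan",
    "bonferroni_lod_threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float
    event: bool
    group: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")


@dataclass(frozen=True)
class KMFit:
    """Product-limit estimate: step function with Greenwood-based bands and
    the median with its log-log confidence interval (upper bound may be
    infinite when the band never crosses one half)."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    median_lcl: float
    median_ucl: float  # np.inf when not estimable
    fitter: KaplanMeierFitter

    def survival_at(self, t: float) -> float:
        return float(self.fitter.predict(t))


@dataclass(frozen=True)
class ScanResult:
    variant_id: str
    nonref_rate: float
    logrank_stat: float
    p_value: float
    lod: float


@dataclass(frozen=True)
class CoxResult:
    coefs: pd.Series
    ses: pd.Series
    hr: pd.Series
    hr_lcl: pd.Series
    hr_ucl: pd.Series
    fitter: CoxPHFitter


# ---------------------------------------------------------------------------
# Endpoint construction
# ---------------------------------------------------------------------------

def onset_records(
    pedigrees: Sequence[Pedigree],
    grouping: Callable[[Pedigree, object], str | None] | None = None,
    oophorectomy_as_event: bool = False,
) -> list[SurvivalRecord]:
    """Age-of-onset records for all women with a usable age.

    Time is the earliest of ovarian-cancer diagnosis, death, prophylactic
    oophorectomy and last contact; the event indicator is true only when
    that earliest age is the diagnosis age (``oophorectomy_as_event``
    additionally counts oophorectomy as an event).  Women with no usable
    age are dropped and counted in a log message.
    """
    records: list[SurvivalRecord] = []
    n_dropped = 0
    n_women = 0
    for ped in pedigrees:
        for ind in ped:
            if ind.sex is not Sex.FEMALE:
                continue
            n_women += 1
            dx_age = ind.ovarian_dx_age()
            candidates = {
                "dx": dx_age,
                "death": ind.age_at_death,
                "ooph": ind.oophorectomy_age,
                "contact": ind.age_last_contact,
            }
            known = {k: v for k, v in candidates.items() if v is not None and v > 0}
            if not known:
                n_dropped += 1
                continue
            which = min(known, key=known.get)
            time = known[which]
            event = which == "dx" or (oophorectomy_as_event and which == "ooph")
            group = grouping(ped, ind) if grouping else None
            if grouping and group is None:
                continue
            records.append(
                SurvivalRecord(
                    subject_id=f"{ped.family_id}:{ind.id}",
                    time=time,
                    event=event,
                    group=group,
                )
            )
    if n_women:
        logger.info(
            "onset_records: %d/%d women usable (%.1f%%), %d dropped for "
            "missing ages",
            n_women - n_dropped, n_women,
            100 * (n_women - n_dropped) / n_women, n_dropped,
        )
    return records


def _frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def km_fit(records: Sequence[SurvivalRecord], alpha: float = 0.05) -> KMFit:
    """Kaplan-Meier product-limit fit with Greenwood/log-log intervals."""
    if not records:
        raise ValueError("km_fit needs at least one record")
    df = _frame(records)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(df["time"], df["event"])
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lcl, ucl = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMFit(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
        at_risk=kmf.event_table["at_risk"].to_numpy(),
        median=median,
        median_lcl=lcl,
        median_ucl=ucl,
        fitter=kmf,
    )


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, int, float]:
    """Mantel-Haenszel log-rank chi-square across the record groups."""
    df = _frame(records)
    groups = df["group"].dropna().unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariate_names: Sequence[str] | None = None,
    level: float = 0.95,
) -> CoxResult:
    """Cox proportional-hazards fit by maximum partial likelihood.

    Covariates come from each record's ``covariates`` map (all names when
    ``covariate_names`` is None); a binary ``group`` label is used as a
    single indicator covariate when no covariates are present.  Hazard-ratio
    intervals are Wald intervals on the log scale.
    """
    if not any(r.event for r in records):
        raise ValueError("cox_fit needs at least one event")
    rows = []
    for r in records:
        row = {"time": r.time, "event": int(r.event)}
        if r.covariates:
            row.update(r.covariates)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.shape[1] == 2:  # no covariates supplied: encode the group label
        labels = sorted({r.group for r in records})
        if len(labels) != 2:
            raise ValueError("need covariates or exactly two group labels")
        df["group"] = [float(r.group == labels[1]) for r in records]
    if covariate_names:
        df = df[["time", "event", *covariate_names]]
    for col in df.columns.drop(["time", "event"]):
        if df[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant (collinear)")
    cph = CoxPHFitter(alpha=1 - level)
    cph.fit(df, duration_col="time", event_col="event")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    coefs = cph.params_
    ses = cph.standard_errors_
    return CoxResult(
        coefs=coefs,
        ses=ses,
        hr=np.exp(coefs),
        hr_lcl=np.exp(coefs - z * ses),
        hr_ucl=np.exp(coefs + z * ses),
        fitter=cph,
    )


# ---------------------------------------------------------------------------
# Variant scan
# ---------------------------------------------------------------------------

def bonferroni_lod_threshold(m: int, alpha: float = 0.05) -> float:
    """Chromosome-wide LOD significance threshold -log10(alpha / m)."""
    if m < 1:
        raise ValueError("need at least one retained variant")
    return float(-np.log10(alpha / m))


def variant_scan(
    genotypes: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    min_nonref_rate: float = 0.10,
    alpha: float = 0.05,
    coding: str = "dominant",
) -> tuple[list[ScanResult], float]:
    """Per-variant log-rank scan of age-of-onset against genotype.

    ``genotypes`` is a variant x subject alt-allele-count table.  Variants
    with a non-reference genotype rate below ``min_nonref_rate`` (among
    subjects with records and non-missing calls) are discarded before the
    Bonferroni threshold is set from the retained count.  Dominant coding
    contrasts any-alt against no-alt; ``coding="additive"`` uses the allele
    count as a three-level group label.  Returns results sorted by
    descending LOD plus the threshold.
    """
    ids = [r.subject_id for r in records]
    missing = [i for i in ids if i not in genotypes.columns]
    if missing:
        raise KeyError(f"records without genotype column: {missing[:5]}")
    sub = genotypes[ids]
    times = np.array([r.time for r in records])
    events = np.array([int(r.event) for r in records])

    calls = sub.to_numpy(dtype=float)  # NaN for missing
    with np.errstate(invalid="ignore"):
        nonref = (calls > 0).sum(axis=1)
    typed = (~np.isnan(calls)).sum(axis=1)
    rate = np.divide(nonref, typed, out=np.zeros(len(sub)), where=typed > 0)
    keep = rate >= min_nonref_rate
    m = int(keep.sum())
    if m == 0:
        raise ValueError("no variants pass the non-reference rate filter")
    threshold = bonferroni_lod_threshold(m, alpha)

    results: list[ScanResult] = []
    for i in np.flatnonzero(keep):
        row = calls[i]
        ok = ~np.isnan(row)
        if coding == "dominant":
            grp = (row[ok] > 0).astype(int)
        elif coding == "additive":
            grp = row[ok].astype(int)
        else:
            raise ValueError(f"unknown coding {coding!r}")
        if len(np.unique(grp)) < 2:
            continue
        res = multivariate_logrank_test(times[ok], grp, events[ok])
        p = float(res.p_value)
        results.append(
            ScanResult(
                variant_id=str(sub.index[i]),
                nonref_rate=float(rate[i]),
                logrank_stat=float(res.test_statistic),
                p_value=p,
                lod=float(-np.log10(p)) if p > 0 else np.inf,
            )
        )
    results.sort(key=lambda r: r.lod, reverse=True)
    return results, threshold
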