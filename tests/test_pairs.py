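"""Pair extraction, transmission-model fitting and risk statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foxlink.pairs import (
    EligibilityRule,
    GGPair,
    Lineage,
    PairCountTable,
    TransmissionModel,
    eligible_women,
    extract_gg_pairs,
    gof_chi_square,
    odds_ratio,
    pair_counts,
    relative_risk,
    transmission_expected,
    xlinked_mle,
)
from foxlink.pedigree import Pedigree, Sex

from conftest import make_person

# Observed informative-pair table from the grandmother-granddaughter study:
# 663 maternal pairs with 92 affected granddaughters, 229 paternal with 65.
REGISTRY = PairCountTable(n_mat=663, w_mat=92, n_pat=229, w_pat=65)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def test_eligibility_rules():
    people = [
        make_person("young", contact=40.0),            # alive, 40, unaffected
        make_person("dead38", contact=38.0, dead=True),  # died without disease
        make_person("case", ovary_dx=52.0, contact=60.0),
        make_person("old", contact=47.0),
        make_person("man", sex=Sex.MALE, contact=70.0),
    ]
    ped = Pedigree("F1", people)
    got = eligible_women([ped])
    assert got == {("F1", "dead38"), ("F1", "case"), ("F1", "old")}


# ---------------------------------------------------------------------------
# Pair extraction
# ---------------------------------------------------------------------------

def test_extract_pairs_three_gen(three_gen):
    pairs = extract_gg_pairs([three_gen])
    by_gd = {}
    for p in pairs:
        by_gd.setdefault(p.granddaughter_id, []).append(p)
    # both granddaughters informative, two pairs each
    assert set(by_gd) == {"gd", "gd2"}
    for gid, ps in by_gd.items():
        assert len(ps) == 2
        assert {p.lineage for p in ps} == {Lineage.MATERNAL, Lineage.PATERNAL}
        affected = [p for p in ps if p.grandmother_affected]
        assert len(affected) == 1
        assert affected[0].lineage is Lineage.PATERNAL
        assert affected[0].grandmother_id == "pgm"
        assert all(p.n_affected_grandmothers == 1 for p in ps)


def test_missing_grandmother_excludes_granddaughter(trio):
    # the trio daughter has no grandmothers in the pedigree
    assert extract_gg_pairs([trio]) == []


def test_pairs_match_bruteforce_rescan(xlinked_registry):
    """Pair counts equal an independent brute-force scan over all
    (granddaughter, father, mother, grandmother) combinations."""
    peds = xlinked_registry.pedigrees
    rule = EligibilityRule()
    pairs = extract_gg_pairs(peds, rule)
    got = {(p.family_id, p.granddaughter_id, p.grandmother_id, p.lineage)
           for p in pairs}

    from foxlink.pairs import _grandmother_affected, _is_eligible

    expected = set()
    for ped in peds:
        for gd in ped:
            if _is_eligible(gd, rule) is not True:
                continue
            f = ped.father(gd)
            m = ped.mother(gd)
            pgm = ped.mother(f) if f else None
            mgm = ped.mother(m) if m else None
            if pgm is None or mgm is None:
                continue
            sp = _grandmother_affected(pgm, rule)
            sm = _grandmother_affected(mgm, rule)
            if sp is None or sm is None:
                continue
            expected.add((ped.family_id, gd.id, pgm.id, Lineage.PATERNAL))
            expected.add((ped.family_id, gd.id, mgm.id, Lineage.MATERNAL))
    assert got == expected


def _pair(lineage, gm_aff=True, gd_aff=False, proband=False, n_aff=1,
          age=60.0, fam="F1"):
    return GGPair(
        family_id=fam,
        granddaughter_id="gd",
        grandmother_id="gm",
        lineage=lineage,
        intermediate_parent_id="p",
        grandmother_affected=gm_aff,
        granddaughter_affected=gd_aff,
        granddaughter_is_proband=proband,
        n_affected_grandmothers=n_aff,
        granddaughter_age=age,
    )


def test_pair_counts_filters():
    pairs = [
        _pair(Lineage.MATERNAL, gd_aff=True),
        _pair(Lineage.MATERNAL, gd_aff=False),
        _pair(Lineage.PATERNAL, gd_aff=True, proband=True),
        _pair(Lineage.PATERNAL, gm_aff=False),       # unaffected gm: dropped
        _pair(Lineage.PATERNAL, n_aff=2),            # two affected gms: dropped
        _pair(Lineage.PATERNAL, gd_aff=False, age=40.0),
    ]
    c = pair_counts(pairs)
    assert (c.n_mat, c.w_mat, c.n_pat, c.w_pat) == (2, 1, 2, 1)
    c = pair_counts(pairs, exclude_probands=True)
    assert (c.n_mat, c.w_mat, c.n_pat, c.w_pat) == (2, 1, 1, 0)
    # young unaffected granddaughters omitted; affected ones always kept
    c = pair_counts(pairs, min_granddaughter_age=45.0)
    assert (c.n_mat, c.w_mat, c.n_pat, c.w_pat) == (2, 1, 1, 1)


def test_pair_counts_empty():
    c = pair_counts([])
    assert (c.n_mat, c.w_mat, c.n_pat, c.w_pat) == (0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Transmission models
# ---------------------------------------------------------------------------

def test_autosomal_expected_counts():
    fit = transmission_expected(REGISTRY, TransmissionModel.AUTOSOMAL_DOMINANT)
    assert fit.rate_estimate == pytest.approx(157 / 892)
    assert round(fit.expected_mat, 1) == 116.7
    assert round(fit.expected_pat, 1) == 40.3
    # expected affected under the pooled-rate model reproduces the total
    assert fit.expected_mat + fit.expected_pat == pytest.approx(157)


def test_xlinked_expected_counts():
    fit = transmission_expected(REGISTRY, TransmissionModel.XLINKED_DOMINANT)
    assert round(fit.expected_mat, 1) == 92.5
    assert round(fit.expected_pat, 1) == 63.9
    assert round(100 * fit.rate_estimate, 1) == 14.0


def test_expected_counts_zero_affected():
    counts = PairCountTable(100, 0, 50, 0)
    for model in TransmissionModel:
        fit = transmission_expected(counts, model)
        assert fit.expected_mat == 0 and fit.expected_pat == 0


def test_xlinked_mle_matches_grid_oracle():
    grid = np.arange(1e-6, 0.5, 1e-6)

    def loglik(m, c):
        return (
            c.w_mat * np.log(m)
            + (c.n_mat - c.w_mat) * np.log1p(-m)
            + c.w_pat * np.log(2 * m)
            + (c.n_pat - c.w_pat) * np.log1p(-2 * m)
        )

    m_hat = xlinked_mle(REGISTRY)
    oracle = grid[np.argmax(loglik(grid, REGISTRY))]
    assert m_hat == pytest.approx(oracle, abs=1e-6)
    assert round(m_hat, 4) == 0.1402
    assert round(100 * m_hat, 1) == 14.0

    rng = np.random.default_rng(42)
    for _ in range(10):
        n_m, n_p = rng.integers(20, 400, size=2)
        w_m = rng.integers(1, n_m // 3)
        w_p = rng.integers(1, n_p // 3)
        c = PairCountTable(int(n_m), int(w_m), int(n_p), int(w_p))
        assert xlinked_mle(c) == pytest.approx(
            grid[np.argmax(loglik(grid, c))], abs=1e-6
        )


def test_xlinked_mle_boundary():
    assert xlinked_mle(PairCountTable(100, 0, 100, 0)) == 0.0


def test_gof_autosomal_rejected_xlinked_accepted():
    auto = transmission_expected(REGISTRY, TransmissionModel.AUTOSOMAL_DOMINANT)
    x2, df, p = gof_chi_square(REGISTRY, auto)
    assert round(x2, 1) == 20.4
    assert df == 1 and p < 0.001

    xl = transmission_expected(REGISTRY, TransmissionModel.XLINKED_DOMINANT)
    x2, df, p = gof_chi_square(REGISTRY, xl)
    assert round(x2, 2) == 0.02
    assert p == pytest.approx(0.89, abs=0.01)


def test_gof_observed_equal_expected():
    counts = PairCountTable(100, 20, 100, 20)
    fit = transmission_expected(counts, TransmissionModel.AUTOSOMAL_DOMINANT)
    x2, _, p = gof_chi_square(counts, fit)
    assert x2 == pytest.approx(0.0) and p == pytest.approx(1.0)


@given(
    n_m=st.integers(10, 500), n_p=st.integers(10, 500),
    w_m=st.integers(1, 9), w_p=st.integers(1, 9),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_gof_invariant_under_lineage_swap(n_m, n_p, w_m, w_p):
    """Swapping lineage labels together with their counts leaves the
    autosomal goodness-of-fit unchanged."""
    c = PairCountTable(n_m, w_m, n_p, w_p)
    fit = transmission_expected(c, TransmissionModel.AUTOSOMAL_DOMINANT)
    x2, _, _ = gof_chi_square(c, fit)
    cs = c.swapped()
    fits = transmission_expected(cs, TransmissionModel.AUTOSOMAL_DOMINANT)
    x2s, _, _ = gof_chi_square(cs, fits)
    assert x2 == pytest.approx(x2s, rel=1e-12)


# ---------------------------------------------------------------------------
# Risk statistics
# ---------------------------------------------------------------------------

def test_relative_risk_registry_values():
    rr = relative_risk((65, 229), (92, 663))
    assert rr.estimate == pytest.approx(2.04, abs=0.01)
    assert round(rr.lcl, 2) == 1.55
    assert round(rr.ucl, 2) == 2.71

    rr = relative_risk((26, 133), (36, 374))
    assert rr.estimate == pytest.approx(2.03, abs=0.01)
    assert round(rr.lcl, 2) == 1.28
    assert round(rr.ucl, 2) == 3.23


def test_relative_risk_equal_rates_is_one():
    rr = relative_risk((10, 100), (10, 100))
    assert rr.estimate == pytest.approx(1.0)
    assert rr.lcl < 1.0 < rr.ucl


@given(
    e1=st.integers(1, 50), n1x=st.integers(0, 100),
    e0=st.integers(1, 50), n0x=st.integers(0, 100),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_relative_risk_reciprocal(e1, n1x, e0, n0x):
    n1, n0 = e1 + n1x, e0 + n0x
    a = relative_risk((e1, n1), (e0, n0))
    b = relative_risk((e0, n0), (e1, n1))
    assert a.estimate * b.estimate == pytest.approx(1.0, rel=1e-12)
    # intervals invert too
    assert a.lcl == pytest.approx(1 / b.ucl, rel=1e-9)


def test_relative_risk_zero_events_raises():
    with pytest.raises(ZeroDivisionError):
        relative_risk((0, 10), (5, 10))


def test_odds_ratio_values():
    assert odds_ratio((10, 10, 10, 10)).estimate == pytest.approx(1.0)
    assert odds_ratio((20, 10, 10, 20)).estimate == pytest.approx(4.0)
    with pytest.raises(ZeroDivisionError):
        odds_ratio((0, 10, 10, 10))


@given(st.tuples(*[st.integers(1, 60)] * 4))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_odds_ratio_matches_woolf(table):
    """OR and CI agree with the direct Woolf log-scale computation."""
    a, b, c, d = table
    res = odds_ratio(table)
    assert res.estimate == pytest.approx(a * d / (b * c), rel=1e-12)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert np.log(res.ucl) - np.log(res.lcl) == pytest.approx(
        2 * 1.959964 * se, rel=1e-9
    )
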