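"""X-APL family statistic: EM fixed points, Mendelian expectations,
TDT equivalence, stratum additivity and variance estimators."""

import numpy as np
import pytest

from xwas.core import MISSING, MarkerInfo, ModelError, Region, Sex, UnitKind
from xwas.family import (
    ClusterUnits,
    MatingTypeModel,
    Stratum,
    _hwe_mu,
    cluster_score,
    em_mating_types,
    family_contribution,
    family_contributions,
    transmission_or,
    xapl_test,
)

from conftest import make_table


def trio(gm, gf, child_sex, x, aff=2, fam="f1"):
    return [
        (fam, "mo", "", "", 2, 1, [gm]),
        (fam, "fa", "", "", 1, 1, [gf]),
        (fam, "ch", "fa", "mo", child_sex, aff, [x]),
    ]


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def test_em_observed_parents_free_mode_gives_empirical_proportions():
    recs = trio(1, 0, 1, 1, fam="a") + trio(2, 1, 2, 2, fam="b") + trio(1, 1, 1, 0, fam="c")
    t = make_table(recs)
    m = em_mating_types(t, 0, "c1", constraint="free")
    # observed mating types: a=(1,0), b=(2,1), c=(1,1), one each
    want = np.zeros(6)
    want[1 * 2 + 0] = 1 / 3
    want[1 * 2 + 1] = 1 / 3
    want[2 * 2 + 1] = 1 / 3
    assert np.allclose(m.mu, want, atol=1e-9)
    assert m.n_iter <= 2


def test_em_unrelated_females_recovers_allele_counting():
    recs = []
    k = 0
    for g, cnt in [(2, 9), (1, 42), (0, 49)]:
        for _ in range(cnt):
            k += 1
            recs.append((f"u{k}", f"i{k}", "", "", 2, 1, [g], UnitKind.UNRELATED_CONTROL))
    t = make_table(recs)
    m = em_mating_types(t, 0, "c1")
    assert m.p == pytest.approx(0.30, abs=1e-6)
    # init independence (HWE parameterization)
    m2 = em_mating_types(t, 0, "c1", init=0.9)
    assert m2.p == pytest.approx(m.p, abs=1e-6)


def test_em_loglik_nondecreasing(small_cohort):
    _, table, _ = small_cohort
    m = em_mating_types(table, table.n_markers - 1, "fam")
    tr = np.array(m.loglik_trace)
    assert np.all(np.diff(tr) >= -1e-9)
    assert m.converged


def test_em_no_informative_units_raises():
    t = make_table([("f", "i", "", "", 2, 1, [MISSING])])
    t.individuals[0].unit_kind = UnitKind.UNRELATED_CONTROL
    with pytest.raises(ModelError):
        em_mating_types(t, 0, "c1")


# ---------------------------------------------------------------------------
# contributions
# ---------------------------------------------------------------------------


def test_trio_contribution_het_mother():
    t = make_table(trio(1, 0, 1, 1))
    m = em_mating_types(t, 0, "c1")
    D, n, cu = family_contributions(t, 0, m)
    assert D[0] == pytest.approx(0.5)  # observed 1 - expected 0.5
    assert n[0] == 1


def test_trio_contribution_uninformative_daughter():
    t = make_table(trio(2, 1, 2, 2))
    m = em_mating_types(t, 0, "c1")
    D, _, _ = family_contributions(t, 0, m)
    assert D[0] == pytest.approx(0.0)  # 2 - (1 + 1)


def test_unrelated_case_expectation_is_population_frequency():
    """A male case's expectation collapses to p under HWE mating types."""
    p = 0.3
    t = make_table([("u", "case", "", "", 1, 2, [1], UnitKind.UNRELATED_CASE)])
    model = MatingTypeModel("c1", "X_NONPAR", _hwe_mu(p, "X_NONPAR"), p, 1, [], True, 1)
    D, n, _ = family_contributions(t, 0, model)
    assert D[0] == pytest.approx(1 - p)
    # female case dose 2: expectation 2p
    t2 = make_table([("u", "case", "", "", 2, 2, [2], UnitKind.UNRELATED_CASE)])
    D2, _, _ = family_contributions(t2, 0, model)
    assert D2[0] == pytest.approx(2 - 2 * p)


def test_control_contributes_zero():
    t = make_table([("u", "ctl", "", "", 1, 1, [1], UnitKind.UNRELATED_CONTROL)])
    model = MatingTypeModel("c1", "X_NONPAR", _hwe_mu(0.3, "X_NONPAR"), 0.3, 1, [], True, 1)
    D, n, _ = family_contributions(t, 0, model)
    assert D[0] == 0.0 and n[0] == 0


def test_missing_child_genotype_skipped():
    t = make_table(trio(1, 0, 1, MISSING))
    m = MatingTypeModel("c1", "X_NONPAR", _hwe_mu(0.3, "X_NONPAR"), 0.3, 1, [], True, 1)
    D, n, _ = family_contributions(t, 0, m)
    assert D[0] == 0.0 and n[0] == 0


def test_complete_data_reduction_with_unaffected_sib():
    """With observed parents the posterior is a point mass, so adding an
    unaffected sibling leaves D unchanged."""
    base = trio(1, 1, 2, 1)
    with_sib = base + [("f1", "sib", "fa", "mo", 1, 1, [0])]
    m = MatingTypeModel("c1", "X_NONPAR", _hwe_mu(0.4, "X_NONPAR"), 0.4, 1, [], True, 1)
    D1, _, _ = family_contributions(make_table(base), 0, m)
    D2, _, _ = family_contributions(make_table(with_sib), 0, m)
    assert D1[0] == pytest.approx(D2[0])
    # daughter x=1 from het mother, het father... non-PAR father is 0/1;
    # expected = 0.5 + 1 with father 1 -> D = 1 - 1.5 = -0.5
    assert D1[0] == pytest.approx(-0.5)


def test_family_contribution_records(small_cohort):
    _, table, _ = small_cohort
    m = em_mating_types(table, 2, "fam")
    recs = family_contribution(table, 2, m, Stratum.OVERALL)
    D, n, cu = family_contributions(table, 2, m, Stratum.OVERALL)
    assert [r.D for r in recs] == pytest.approx(list(D))
    assert all(abs(r.D) <= 2 * r.n_contributing + 1e-9 for r in recs)


# ---------------------------------------------------------------------------
# the test statistic
# ---------------------------------------------------------------------------


def tdt_table(b, c):
    recs = []
    for i in range(b + c):
        x = 1 if i < b else 0
        recs += [
            (f"f{i}", "mo", "", "", 2, 1, [1]),
            (f"f{i}", "fa", "", "", 1, 1, [0]),
            (f"f{i}", "ch", "fa", "mo", 1, 2, [x]),
        ]
    return make_table(recs)


def test_tdt_equivalence():
    """On complete affected-son trios the statistic equals McNemar's TDT."""
    t = tdt_table(30, 20)
    r = xapl_test(t, 0, "c1")
    assert r.S == pytest.approx(5.0)
    assert r.V == pytest.approx(12.5)
    assert r.Z == pytest.approx((30 - 20) / np.sqrt(30 + 20))
    assert r.P == pytest.approx(0.1573, abs=2e-4)
    assert r.odds_ratio == pytest.approx(1.5)
    assert (r.ci_low, r.ci_high) == (pytest.approx(0.8519, abs=2e-4),
                                     pytest.approx(2.6413, abs=2e-4))


def test_all_zero_contributions_flagged():
    # polymorphic but uninformative: daughter's allele fully determined
    t = make_table(trio(0, 1, 2, 1))
    r = xapl_test(t, 0, "c1")
    assert "non-informative" in r.note
    assert r.P == 1.0


def test_monomorphic_marker_skipped():
    recs = [(f"f{i}", "i", "", "", 2, 1, [2], UnitKind.UNRELATED_CONTROL) for i in range(5)]
    r = xapl_test(make_table(recs), 0, "c1")
    assert "monomorphic" in r.note


def test_stratum_additivity(small_cohort):
    _, table, _ = small_cohort
    cu = ClusterUnits.from_table(table, "fam")
    for j in (0, 5, table.n_markers - 1):
        parts = {}
        for s in Stratum:
            m = em_mating_types(table, j, "fam", cu=cu)
            D, _, _ = family_contributions(table, j, m, s, cu)
            parts[s] = D.sum()
        assert parts[Stratum.OVERALL] == pytest.approx(
            parts[Stratum.MALE] + parts[Stratum.FEMALE]
        )


def test_bootstrap_close_to_empirical_variance():
    from xwas.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(n_singleton_families=150, n_multiplex_families=50, n_cases=0,
                    n_controls=0, n_markers=3, ld_block_size=1,
                    parent_missing_rate=0.2, seed=42)
    t, _ = simulate_cohort(cfg)
    _, Ve, _, _, _ = cluster_score(t, 1, "fam", variance_method="empirical")
    _, Vb, _, _, _ = cluster_score(t, 1, "fam", variance_method="bootstrap",
                                   n_boot=2000, seed=3)
    assert abs(Ve - Vb) / Vb < 0.10


def test_empirical_reduces_to_sum_d2_on_complete_trios():
    t = tdt_table(12, 8)
    Se, Ve, D, _, _ = cluster_score(t, 0, "c1", variance_method="empirical")
    _, Vp, _, _, _ = cluster_score(t, 0, "c1", variance_method="plain")
    assert Ve == pytest.approx(Vp) == pytest.approx((D**2).sum())


# ---------------------------------------------------------------------------
# transmission odds ratio
# ---------------------------------------------------------------------------


def test_transmission_or_closed_form():
    t = tdt_table(30, 20)
    orr, lo, hi, b, c = transmission_or(t, 0)
    assert (b, c) == (30, 20)
    assert orr == pytest.approx(1.5)
    assert lo == pytest.approx(np.exp(np.log(1.5) - 1.96 * np.sqrt(1 / 30 + 1 / 20)))


def test_transmission_or_symmetry_and_flip():
    t = tdt_table(15, 15)
    orr, *_ = transmission_or(t, 0)
    assert orr == pytest.approx(1.0)
    t2 = tdt_table(30, 20)
    fwd, *_ = transmission_or(t2, 0)
    rev, *_ = transmission_or(t2, 0, flip_reference=True)
    assert rev == pytest.approx(1 / fwd)


def test_transmission_or_zero_cell():
    t = tdt_table(5, 0)
    orr, lo, hi, b, c = transmission_or(t, 0)
    assert orr == np.inf and np.isnan(lo)
    orr_h, lo_h, hi_h, *_ = transmission_or(t, 0, haldane=True)
    assert np.isfinite(orr_h) and np.isfinite(lo_h)


# ---------------------------------------------------------------------------
# PAR mode
# ---------------------------------------------------------------------------


def test_par_expectations_diploid():
    mks = [MarkerInfo("p1", 100_000, "A", "G", region=Region.PAR1)]
    recs = [
        ("f1", "mo", "", "", 2, 1, [1]),
        ("f1", "fa", "", "", 1, 1, [2]),
        ("f1", "ch", "fa", "mo", 1, 2, [2]),
    ]
    t = make_table(recs, mks)
    m = em_mating_types(t, 0, "c1")
    assert m.mode == "PAR"
    D, _, _ = family_contributions(t, 0, m)
    assert D[0] == pytest.approx(2 - (0.5 + 1.0))
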