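"""QC battery: sex inference, Mendel rules, HWE exact test, missingness
tests, filter ordering and fixture-manifest recovery."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xwas.core import HET_FLAG, MISSING, MarkerInfo, Region, Sex
from xwas.pedio import read_ped_map
from xwas.qc import (
    QCThresholds,
    apply_snp_filters,
    compute_sample_qc,
    compute_snp_qc,
    hwe_chisq_p,
    hwe_exact_p,
    mendel_error_scan,
    missingness_sex_test,
    resolve_male_hets,
    run_qc,
)

from conftest import make_table


def hwe_enumeration_oracle(nAA, nAa, naa):
    """Exact-test P by full enumeration with rational arithmetic."""
    n = nAA + nAa + naa
    na = 2 * nAA + nAa
    na = min(na, 2 * n - na)

    def prob(h):
        hr = (na - h) // 2
        hc = n - h - hr
        if hc < 0:
            return Fraction(0)
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hr) * math.factorial(h) * math.factorial(hc),
        )

    tot = sum(prob(h) for h in range(na % 2, na + 1, 2))
    po = prob(nAa)
    return float(sum(p for h in range(na % 2, na + 1, 2) if (p := prob(h)) <= po) / tot)


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------


def test_sex_inference_and_mismatch_removal():
    mks = [MarkerInfo(f"m{i}", 3_000_000 + i * 1000, "A", "G") for i in range(8)]
    # reported male but heterozygous at 2 of 8 markers (het frac 0.25)
    recs = [
        ("f1", "badmale", "", "", 1, 1, [0, HET_FLAG, 1, HET_FLAG, 0, 0, 1, 0]),
        ("f2", "goodfem", "", "", 2, 1, [0, 1, 1, 2, 0, 1, 2, 0]),
        ("f3", "goodmale", "", "", 1, 1, [0, 1, 1, 0, 0, 0, 1, 0]),
    ]
    rep = compute_sample_qc(make_table(recs, mks))
    assert rep.removed("sample") == ["f1/badmale"]
    assert rep.removals[0].rule == "sex_mismatch"


def test_call_rate_boundary_is_inclusive():
    mks = [MarkerInfo(f"m{i}", 3_000_000 + i * 1000, "A", "G") for i in range(20)]
    het = [1, 0] * 10  # heterozygous enough to read as female
    kept = het[:19] + [MISSING]  # call rate 0.95 -> retained
    dropped = het[:18] + [MISSING, MISSING]  # 0.90 -> removed
    rep = compute_sample_qc(
        make_table([("a", "keep", "", "", 2, 1, kept), ("b", "drop", "", "", 2, 1, dropped)], mks)
    )
    assert rep.removed("sample") == ["b/drop"]
    assert rep.removals[0].rule == "sample_call_rate"


def test_uninferrable_sex_flagged_not_removed():
    # all informative (non-PAR) calls missing but PAR call rate is fine
    mks = [MarkerInfo(f"p{i}", 100_000 + i, "A", "G", region=Region.PAR1) for i in range(20)]
    mks.append(MarkerInfo("x1", 3_000_000, "A", "G"))
    t = make_table([("f", "i", "", "", 0, 1, [1] * 20 + [MISSING])], mks)
    rep = compute_sample_qc(t)
    assert rep.sample_metrics["sex_uninferrable"].iloc[0]
    assert rep.removed("sample") == []


# ---------------------------------------------------------------------------
# Mendel rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sex,child,mother,father,is_error",
    [
        (1, 1, 0, 0, True),   # son carries allele mother lacks
        (1, 0, 2, 1, True),   # son lacks allele mother must transmit
        (1, 1, 1, 0, False),
        (2, 2, 2, 0, True),   # daughter hom needs paternal allele
        (2, 2, 0, 1, True),
        (2, 0, 2, 0, True),
        (2, 0, 1, 1, True),   # father transmits his only allele
        (2, 1, 0, 0, True),
        (2, 1, 2, 1, True),
        (2, 1, 2, 0, False),
        (2, 1, 0, 1, False),
    ],
)
def test_mendel_rule_table_nonpar(sex, child, mother, father, is_error):
    recs = [
        ("f", "mo", "", "", 2, 1, [mother]),
        ("f", "fa", "", "", 1, 1, [father]),
        ("f", "ch", "fa", "mo", sex, 2, [child]),
    ]
    rep = mendel_error_scan(make_table(recs))
    assert rep.snp_metrics["mendel_errors"].iloc[0] == int(is_error)
    assert rep.snp_metrics["mendel_opportunities"].iloc[0] == 1


def test_mendel_par_autosomal_rules():
    mks = [MarkerInfo("p1", 100_000, "A", "G", region=Region.PAR1)]
    recs = [
        ("f", "mo", "", "", 2, 1, [0]),
        ("f", "fa", "", "", 1, 1, [2]),
        ("f", "ch", "fa", "mo", 1, 2, [0]),  # child 0 but father must transmit
    ]
    rep = mendel_error_scan(make_table(recs, mks))
    assert rep.snp_metrics["mendel_errors"].iloc[0] == 1


def test_mendel_missing_parent_is_no_opportunity():
    recs = [
        ("f", "mo", "", "", 2, 1, [MISSING]),
        ("f", "fa", "", "", 1, 1, [0]),
        ("f", "ch", "fa", "mo", 1, 2, [1]),
    ]
    rep = mendel_error_scan(make_table(recs))
    assert rep.snp_metrics["mendel_opportunities"].iloc[0] == 0


def test_mendel_het_flag_not_an_error():
    recs = [
        ("f", "mo", "", "", 2, 1, [0]),
        ("f", "fa", "", "", 1, 1, [0]),
        ("f", "ch", "fa", "mo", 1, 2, [HET_FLAG]),
    ]
    rep = mendel_error_scan(make_table(recs))
    assert rep.snp_metrics["mendel_errors"].iloc[0] == 0


def test_planted_family_rate_triggers_removal():
    # one family, 100 markers, 5 planted errors -> rate 0.05 > 0.02
    mks = [MarkerInfo(f"m{i}", 3_000_000 + i * 1000, "A", "G") for i in range(100)]
    mo = [1] * 100
    fa = [0] * 100
    ch = [0] * 100
    for j in range(5):
        mo[j] = 0
        ch[j] = 1
    rep = mendel_error_scan(
        make_table(
            [("f", "mo", "", "", 2, 1, mo), ("f", "fa", "", "", 1, 1, fa),
             ("f", "ch", "fa", "mo", 1, 2, ch)],
            mks,
        )
    )
    assert rep.family_metrics["rate"].iloc[0] == pytest.approx(0.05)
    assert rep.removed("family") == ["f"]


# ---------------------------------------------------------------------------
# HWE
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts", [(16, 48, 36), (9, 42, 49), (3, 2, 45), (0, 5, 20), (10, 0, 10), (1, 1, 1)]
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), abs=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    nAA=st.integers(0, 16), nAa=st.integers(0, 17), naa=st.integers(0, 17)
)
def test_hwe_exact_enumeration_property(nAA, nAa, naa):
    if nAA + nAa + naa == 0:
        return
    assert hwe_exact_p(nAA, nAa, naa) == pytest.approx(
        hwe_enumeration_oracle(nAA, nAa, naa), abs=1e-10
    )


def test_hwe_at_exact_proportions_is_one_and_ge_chisq():
    # females at exact HWE proportions: exact P ~ 1 and >= chi-square P
    assert hwe_exact_p(16, 48, 36) == pytest.approx(1.0)
    assert hwe_exact_p(16, 48, 36) >= hwe_chisq_p(16, 48, 36)


# ---------------------------------------------------------------------------
# SNP metrics and missingness test
# ---------------------------------------------------------------------------


def test_maf_counts_founders_with_hemizygous_males():
    # 10 males (3 carrying candidate) + 10 females (7 candidate alleles)
    recs = []
    for i in range(10):
        recs.append((f"m{i}", "i", "", "", 1, 1, [1 if i < 3 else 0]))
    fem = [2, 2, 2, 1, 0, 0, 0, 0, 0, 0]  # 7 alleles
    for i, g in enumerate(fem):
        recs.append((f"f{i}", "i", "", "", 2, 1, [g]))
    m = compute_snp_qc(make_table(recs))
    assert m["maf"].iloc[0] == pytest.approx(10 / 30)


def test_male_het_fraction():
    recs = [(f"m{i}", "i", "", "", 1, 1, [HET_FLAG if i < 2 else 0]) for i in range(100)]
    m = compute_snp_qc(make_table(recs))
    assert m["male_het_fraction"].iloc[0] == pytest.approx(0.02)


def test_missingness_chi2_oracle():
    # 30/1000 male missing vs 5/1000 female missing; frozen from the
    # textbook Pearson 2x2 chi-square (no continuity correction)
    recs = []
    for i in range(1000):
        recs.append((f"m{i}", "i", "", "", 1, 1, [MISSING if i < 30 else 0]))
    for i in range(1000):
        recs.append((f"f{i}", "i", "", "", 2, 1, [MISSING if i < 5 else 0]))
    r = missingness_sex_test(make_table(recs))
    assert r["missing_chi2"].iloc[0] == pytest.approx(18.1748, abs=1e-3)
    assert r["missing_p"].iloc[0] == pytest.approx(2.0148e-5, rel=1e-3)


def test_missingness_identical_rates_and_zero_margin():
    recs = [("a", "i", "", "", 1, 1, [0, MISSING]), ("b", "i", "", "", 2, 1, [0, MISSING])]
    mks = [MarkerInfo("m1", 3_000_000, "A", "G"), MarkerInfo("m2", 3_001_000, "A", "G")]
    r = missingness_sex_test(make_table(recs, mks))
    assert r["missing_chi2"].iloc[0] == 0 and r["missing_p"].iloc[0] == 1.0
    assert r["uninformative"].iloc[1]  # all-missing marker has a zero margin


# ---------------------------------------------------------------------------
# filters and resolution
# ---------------------------------------------------------------------------


def test_filter_rules_and_first_hit_ledger():
    import pandas as pd

    metrics = pd.DataFrame(
        {
            "marker_id": ["xy", "lowcall", "badhwe", "rare", "sexmiss", "malehet", "ok"],
            "region": [Region.XY_HOMOLOGOUS] + [Region.X_NONPAR] * 6,
            "call_rate": [0.99, 0.90, 0.99, 0.99, 0.99, 0.99, 0.99],
            "hwe_p": [1e-6, 1e-6, 1e-6, 0.5, 0.5, 0.5, 0.5],
            "maf": [0.2, 0.2, 0.2, 0.005, 0.2, 0.2, 0.2],
            "male_missing": [0.0, 0.0, 0.0, 0.0, 0.03, 0.0, 0.0],
            "female_missing": [0.0] * 7,
            "male_het_fraction": [0.0, 0.0, 0.0, 0.0, 0.0, 0.02, 0.0],
        }
    )
    survivors, removals = apply_snp_filters(metrics)
    assert survivors == ["ok"]
    rules = {r.entity_id: r.rule for r in removals}
    assert rules == {
        "xy": "xy_homologous_region",
        "lowcall": "snp_call_rate",
        "badhwe": "hwe",
        "rare": "maf",
        "sexmiss": "per_sex_missingness",
        "malehet": "male_het_fraction",
    }


def test_resolve_male_hets():
    t = make_table([("a", "i", "", "", 1, 1, [HET_FLAG]), ("b", "i", "", "", 1, 1, [1])])
    out, n = resolve_male_hets(t)
    assert n == 1
    assert out.calls[0, 0] == MISSING and out.calls[1, 0] == 1
    out2, n2 = resolve_male_hets(out)
    assert n2 == 0 and np.array_equal(out2.calls, out.calls)


def test_snp_metrics_order_independent(small_cohort):
    _, table, _ = small_cohort
    m1 = compute_snp_qc(table)
    perm = np.random.default_rng(0).permutation(table.n_markers)
    m2 = compute_snp_qc(table.subset_markers(perm)).set_index("marker_id")
    m1 = m1.set_index("marker_id")
    for col in ("call_rate", "maf", "hwe_p", "male_het_fraction"):
        a = m1[col].sort_index()
        b = m2[col].sort_index()
        assert np.allclose(a.fillna(-1), b.fillna(-1))


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------


def test_fixture_suite_ledgers_match_manifests(fixture_suite):
    out, manifests = fixture_suite
    for name, man in manifests.items():
        t = read_ped_map(out / name / "fix.ped", out / name / "fix.map", cluster_label=name)
        filtered, rep = run_qc(t)
        got = sorted((r.entity, r.entity_id, r.rule) for r in rep.removals)
        want = sorted((e["entity"], e["id"], e["rule"]) for e in man["expected_removals"])
        assert got == want, f"fixture {name}"
        if "resolved_het_snp" in man:
            ids = [m.marker_id for m in filtered.markers]
            assert man["resolved_het_snp"] in ids
            assert not (filtered.calls == HET_FLAG).any()


def test_qc_idempotence(fixture_suite):
    out, _ = fixture_suite
    t = read_ped_map(out / "mendel" / "fix.ped", out / "mendel" / "fix.map", cluster_label="x")
    once, rep1 = run_qc(t)
    twice, rep2 = run_qc(once)
    assert np.array_equal(once.calls, twice.calls)
    assert rep2.removals == []
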