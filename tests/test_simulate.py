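"""Synthetic cohort generator: haplotype pools, transmission, ascertainment,
disease model and artifact injection."""

import dataclasses

import numpy as np
import pytest

from xwas.core import HET_FLAG, MISSING, ConfigError, Region, Sex, SimulationError, UnitKind
from xwas.multiplicity import ld_r2
from xwas.qc import mendel_error_scan
from xwas.simulate import (
    SimConfig,
    build_haplotype_pool,
    inject_artifacts,
    simulate_cohort,
)


def cc_only(n_cases, n_controls, **kw):
    return SimConfig(
        n_singleton_families=0, n_multiplex_families=0,
        n_cases=n_cases, n_controls=n_controls, extra_sib_rate=0.0, **kw
    )


# ---------------------------------------------------------------------------
# haplotype pool
# ---------------------------------------------------------------------------


def test_pool_frequencies_normalized_and_in_range():
    cfg = SimConfig(n_markers=30, ld_block_size=5, seed=3)
    pool = build_haplotype_pool(cfg)
    lo, hi = cfg.allele_freq_range
    for b in pool.blocks:
        assert np.isclose(b.freqs.sum(), 1.0)
        assert np.isclose(b.freqs2.sum(), 1.0)
        af = b.allele_freqs()
        assert ((af >= lo) & (af <= hi)).all()


def test_pool_block_size_validation():
    with pytest.raises(ConfigError):
        build_haplotype_pool(SimConfig(n_markers=3, ld_block_size=5))


def test_no_ld_limit_and_two_haplotype_blocks():
    # block size 1: independent markers, pairwise r2 near zero
    t, _ = simulate_cohort(cc_only(0, 500, n_markers=10, ld_block_size=1, seed=4))
    r2 = ld_r2(t)
    off = r2[np.triu_indices(10, 1)]
    assert np.nanmax(off) < 0.02
    # two haplotypes per block: within-block r2 exactly 1
    t2, _ = simulate_cohort(
        cc_only(0, 400, n_markers=6, ld_block_size=3, n_haplotypes_per_block=2, seed=5)
    )
    r2 = ld_r2(t2)
    assert np.isclose(r2[0, 1], 1.0) and np.isclose(r2[1, 2], 1.0)
    assert r2[0, 3] < 0.05


# ---------------------------------------------------------------------------
# cohort structure and disease model
# ---------------------------------------------------------------------------


def test_determinism():
    cfg = SimConfig(n_singleton_families=20, n_multiplex_families=10, n_cases=15,
                    n_controls=30, n_markers=12, ld_block_size=3, seed=77)
    a, _ = simulate_cohort(cfg)
    b, _ = simulate_cohort(cfg)
    assert np.array_equal(a.calls, b.calls)
    assert [i.individual_id for i in a.individuals] == [i.individual_id for i in b.individuals]


def test_ascertainment_postcondition(small_cohort):
    _, table, _ = small_cohort
    fams = {}
    for ind in table.individuals:
        if ind.unit_kind == UnitKind.FAMILY_MEMBER and not ind.is_founder:
            fams.setdefault(ind.family_id, []).append(ind)
    assert fams
    for fam, kids in fams.items():
        n_aff = sum(k.affection == 2 for k in kids)
        want = 2 if fam.endswith("_m") else 1
        assert n_aff >= want, f"{fam} has {n_aff} affected children"


def test_affected_sex_ratio_matches_penetrance_ratio():
    # at RR=1 the affected male:female ratio equals the penetrance ratio 4.6
    cfg = SimConfig(n_singleton_families=4000, n_multiplex_families=0, n_cases=0,
                    n_controls=0, n_markers=4, ld_block_size=1, extra_sib_rate=0.0, seed=7)
    t, _ = simulate_cohort(cfg)
    aff = (t.affection == 2) & ~t.is_founder
    ratio = (t.sex[aff] == Sex.MALE).sum() / (t.sex[aff] == Sex.FEMALE).sum()
    # ratio of 4.6 with ~700 affected females: 3 SE band
    assert 3.9 < ratio < 5.4


def test_null_case_control_frequency_equal():
    cfg = cc_only(1000, 1000, n_markers=3, ld_block_size=1, causal_marker_index=1,
                  causal_allele_freq=0.3, rr_per_allele=1.0, seed=8)
    t, _ = simulate_cohort(cfg)
    male = t.sex == Sex.MALE
    freqs = {}
    for kind in (UnitKind.UNRELATED_CASE, UnitKind.UNRELATED_CONTROL):
        sel = t.unit_kind == kind
        chroms = np.where(male[sel], 1, 2)
        freqs[kind] = t.calls[sel, 1].sum() / chroms.sum()
    # |delta| within 3 binomial SEs at ~2000 alleles total
    se = np.sqrt(2 * 0.3 * 0.7 / 1500)
    assert abs(freqs[UnitKind.UNRELATED_CASE] - freqs[UnitKind.UNRELATED_CONTROL]) < 3 * se


def test_transmission_validity_no_mendel_errors(small_cohort):
    _, table, _ = small_cohort
    rep = mendel_error_scan(table)
    assert rep.snp_metrics["mendel_errors"].sum() == 0


def test_founder_allele_frequency_recovery(small_cohort):
    cfg, table, truth = small_cohort
    fmask = table.is_founder & (table.cluster == "fam")
    sex = table.sex[fmask]
    ok_any = False
    for j in range(table.n_markers):
        g = table.calls[fmask, j]
        ok = (g >= 0) & (g != HET_FLAG)
        chroms = np.where((sex == Sex.MALE) & (int(table.region[j]) == Region.X_NONPAR), 1, 2)[ok]
        n = chroms.sum()
        if n < 50:
            continue
        est = g[ok].sum() / n
        p = truth.allele_freqs_cluster1[j]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(est - p) < 4 * se, f"marker {j}: {est} vs {p}"
        ok_any = True
    assert ok_any


def test_conditional_equals_rejection_sampling():
    """The exact ascertainment sampler matches literal resampling."""
    base = dict(n_singleton_families=2500, n_multiplex_families=800, n_cases=0,
                n_controls=0, n_markers=2, ld_block_size=1, causal_marker_index=0,
                causal_allele_freq=0.3, rr_per_allele=1.8,
                baseline_prevalence_male=0.3, baseline_prevalence_female=0.12,
                extra_sib_rate=0.0)
    tc, _ = simulate_cohort(SimConfig(**base, seed=21, ascertainment="conditional"))
    tr, _ = simulate_cohort(SimConfig(**base, seed=22, ascertainment="rejection"))

    def stats(t):
        ch = ~t.is_founder
        mo = t.is_founder & (t.sex == Sex.FEMALE)
        male_ch = ch & (t.sex == Sex.MALE)
        return np.array([
            t.calls[mo, 0].mean() / 2,            # ascertained maternal freq
            t.calls[male_ch, 0].mean(),           # affected-son dose
            (t.sex[ch] == Sex.MALE).mean(),       # affected sex skew
        ])

    a, b = stats(tc), stats(tr)
    assert np.all(np.abs(a - b) < 0.025), (a, b)


def test_unattainable_ascertainment_raises():
    with pytest.raises(SimulationError):
        simulate_cohort(SimConfig(n_singleton_families=5, n_markers=4, ld_block_size=1,
                                  baseline_prevalence_male=0.0,
                                  baseline_prevalence_female=0.0, seed=1))


def test_parent_missing_rate():
    cfg = SimConfig(n_singleton_families=400, n_multiplex_families=0, n_cases=0,
                    n_controls=0, n_markers=4, ld_block_size=1,
                    parent_missing_rate=0.2, extra_sib_rate=0.0, seed=9)
    t, _ = simulate_cohort(cfg)
    founders = t.is_founder & (t.unit_kind == UnitKind.FAMILY_MEMBER)
    all_missing = (t.calls == MISSING).all(axis=1)
    rate = all_missing[founders].mean()
    assert 0.14 < rate < 0.26  # 3 SE around 0.2 at n=800


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def test_artifacts_identity_at_zero_rates(small_cohort):
    cfg, table, _ = small_cohort
    out = inject_artifacts(table, cfg, seed=5)
    assert np.array_equal(out.calls, table.calls)


def test_male_het_error_binomial_mean():
    cfg = cc_only(0, 200, n_markers=10, ld_block_size=1,
                  male_het_error_rate=0.02, control_male_fraction=0.5, seed=10)
    t, _ = simulate_cohort(dataclasses.replace(cfg, male_het_error_rate=0.0))
    out = inject_artifacts(t, cfg, seed=11)
    male = out.sex == Sex.MALE
    nonpar = out.region == Region.X_NONPAR
    flags = (out.calls[male][:, nonpar] == HET_FLAG).sum()
    n_targets = male.sum() * nonpar.sum()
    expect = 0.02 * n_targets
    assert abs(flags - expect) < 4 * np.sqrt(expect)


def test_sex_differential_targets_only_designated_markers():
    cfg = cc_only(0, 800, n_markers=10, ld_block_size=1,
                  sex_differential_rate=0.08, seed=12)
    t, _ = simulate_cohort(dataclasses.replace(cfg, sex_differential_rate=0.0))
    out = inject_artifacts(t, cfg, seed=13, sex_missing_markers=[2, 5])
    male = out.sex == Sex.MALE
    female = out.sex == Sex.FEMALE
    gap = (out.calls[male] == MISSING).mean(axis=0) - (out.calls[female] == MISSING).mean(axis=0)
    assert gap[2] > 0.04 and gap[5] > 0.04
    others = np.delete(gap, [2, 5])
    assert np.abs(others).max() < 0.03


def test_artifact_rate_validation(small_cohort):
    cfg, table, _ = small_cohort
    bad = dataclasses.replace(cfg, missing_base_rate=1.5)
    with pytest.raises(ValueError):
        inject_artifacts(table, bad, seed=1)


def test_truth_record_manifest(small_cohort):
    cfg, table, truth = small_cohort
    man = truth.to_manifest()
    assert man["config"]["seed"] == cfg.seed
    assert len(man["allele_freqs_cluster1"]) == cfg.n_markers
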