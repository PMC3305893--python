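import numpy as np
import pytest

from xwas.core import (
    Affection,
    GenotypeTable,
    MarkerInfo,
    PedigreeIndividual,
    RegionConfig,
    Sex,
    UnitKind,
)


def make_table(records, markers=None, cluster="c1"):
    """Build a GenotypeTable from (fam, iid, father, mother, sex, aff, calls)
    tuples; unrelateds are marked by kind= in a trailing element."""
    markers = markers if markers is not None else [MarkerInfo("m1", 5_000_000, "A", "G")]
    inds, calls = [], []
    for rec in records:
        fam, iid, fid, mid, sex, aff, cs = rec[:7]
        ind = PedigreeIndividual(
            iid, fam, fid, mid, Sex(sex), Affection(aff), cluster=cluster
        )
        if len(rec) > 7:
            ind.unit_kind = UnitKind(rec[7])
        inds.append(ind)
        calls.append(cs)
    return GenotypeTable(markers, inds, np.array(calls, dtype=np.int8))


@pytest.fixture(scope="session")
def region_config():
    return RegionConfig.default()


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The deterministic QC fixture suite, generated once per session."""
    from xwas.simulate import make_fixture_suite

    out = tmp_path_factory.mktemp("fixtures")
    manifests = make_fixture_suite(out)
    return out, manifests


@pytest.fixture(scope="session")
def small_cohort():
    """A mixed family + case-control cohort reused by several tests."""
    from xwas.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_singleton_families=60,
        n_multiplex_families=25,
        n_cases=60,
        n_controls=120,
        n_markers=24,
        ld_block_size=3,
        par_fraction=0.12,
        parent_missing_rate=0.15,
        seed=1234,
    )
    table, truth = simulate_cohort(cfg)
    return cfg, table, truth
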