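"""Sample- and SNP-level quality control for X-chromosome data.

The battery covers sample call rate and X-heterozygosity sex inference,
Mendelian-error scans with X-specific rules, SNP call rate, minor allele
frequency, an exact Hardy-Weinberg test in females, male-heterozygote
screening, per-sex missingness and the male-vs-female missingness test.
SNP filters apply in a fixed order so removal ledgers are reproducible;
each removed entity records the first rule it tripped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    HET_FLAG,
    MISSING,
    GenotypeTable,
    Region,
    Sex,
    UnitKind,
)

SNP_FILTER_ORDER = (
    "xy_homologous_region",
    "snp_call_rate",
    "mendel_snp_rate",
    "hwe",
    "maf",
    "per_sex_missingness",
    "male_het_fraction",
)


@dataclass
class QCThresholds:
    """Exclusion thresholds; defaults follow the emulated study's QC."""

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    family_mendel_rate_max: float = 0.02
    snp_mendel_rate_max: float = 0.04
    hwe_p_min: float = 1e-4
    maf_min: float = 0.01
    per_sex_missing_max: float = 0.025
    male_het_fraction_max: float = 0.01
    male_het_rate_sex_check: float = 0.05  # sex-inference het cutoff

    def validate(self) -> None:
        import dataclasses

        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f_.name} = {v} outside [0, 1]")


@dataclass
class Removal:
    entity: str  # "sample" | "family" | "snp"
    entity_id: str
    rule: str
    value: float
    threshold: float


@dataclass
class QCReport:
    sample_metrics: pd.DataFrame | None = None
    snp_metrics: pd.DataFrame | None = None
    family_metrics: pd.DataFrame | None = None
    removals: list[Removal] = field(default_factory=list)

    def removed(self, entity: str) -> list[str]:
        return [r.entity_id for r in self.removals if r.entity == entity]

    def removals_frame(self) -> pd.DataFrame:
        import dataclasses

        return pd.DataFrame([dataclasses.asdict(r) for r in self.removals])


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------


def sample_het_fraction(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample non-PAR X heterozygosity fraction and called-count.

    A heterozygote is call == 1 under diploid coding or HET_FLAG under
    hemizygous coding, so the metric is meaningful whichever sex the
    sample was read as.
    """
    nonpar = table.region == Region.X_NONPAR
    sub = table.calls[:, nonpar]
    called = sub != MISSING
    male_coded = (table.sex == Sex.MALE)[:, None]
    het = np.where(male_coded, sub == HET_FLAG, sub == 1)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_called > 0, het.sum(axis=1) / np.maximum(n_called, 1), np.nan)
    return frac, n_called


def compute_sample_qc(
    table: GenotypeTable, thresholds: QCThresholds | None = None
) -> QCReport:
    """Call-rate screen and X-heterozygosity sex inference.

    Sex is inferred MALE when the non-PAR X heterozygosity fraction is at
    or below ``male_het_rate_sex_check``, FEMALE otherwise; samples whose
    reported sex disagrees are removed, samples with no informative calls
    are flagged UNINFERRABLE (and excluded from non-PAR statistics
    downstream, not removed here).
    """
    th = thresholds or QCThresholds()
    th.validate()
    call_rate = (table.calls != MISSING).mean(axis=1) if table.n_markers else np.ones(
        table.n_individuals
    )
    het_frac, n_called = sample_het_fraction(table)
    inferred = np.where(het_frac <= th.male_het_rate_sex_check, Sex.MALE, Sex.FEMALE)
    inferred = np.where(n_called == 0, Sex.UNKNOWN, inferred).astype(np.int8)

    removals: list[Removal] = []
    labels = []
    for r, ind in enumerate(table.individuals):
        label = f"{ind.family_id}/{ind.individual_id}"
        labels.append(label)
        if call_rate[r] < th.sample_call_rate_min:
            removals.append(
                Removal("sample", label, "sample_call_rate", float(call_rate[r]),
                        th.sample_call_rate_min)
            )
        elif (
            ind.sex != Sex.UNKNOWN
            and inferred[r] != Sex.UNKNOWN
            and int(ind.sex) != int(inferred[r])
        ):
            removals.append(
                Removal("sample", label, "sex_mismatch", float(het_frac[r]),
                        th.male_het_rate_sex_check)
            )

    df = pd.DataFrame(
        {
            "sample": labels,
            "call_rate": call_rate,
            "x_het_fraction": het_frac,
            "reported_sex": table.sex,
            "inferred_sex": inferred,
            "sex_uninferrable": n_called == 0,
        }
    )
    return QCReport(sample_metrics=df, removals=removals)


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------


def _trio_rows(table: GenotypeTable):
    rows = table.row_index()
    out = []
    for r, ind in enumerate(table.individuals):
        if ind.unit_kind != UnitKind.FAMILY_MEMBER or ind.is_founder:
            continue
        mo = rows.get((ind.family_id, ind.mother_id), -1) if ind.mother_id else -1
        fa = rows.get((ind.family_id, ind.father_id), -1) if ind.father_id else -1
        out.append((r, mo, fa, ind.family_id, int(ind.sex)))
    return out


def mendel_error_scan(
    table: GenotypeTable, thresholds: QCThresholds | None = None
) -> QCReport:
    """Scan parent-child transmissions for impossible genotypes.

    Non-PAR X rules: a son's hemizygous call must be transmissible by his
    mother (son 1 with mother 0, or son 0 with mother 2, is an error; the
    father is irrelevant); a daughter's genotype must decompose into one
    maternal draw plus the father's allele.  PAR markers use the standard
    autosomal trio table.  Male HET_FLAG calls are never Mendel errors --
    they are handled by the male-heterozygote screen.  An opportunity is a
    (child, SNP) pair where the needed parental genotypes are present.
    """
    th = thresholds or QCThresholds()
    trios = _trio_rows(table)
    M = table.n_markers
    nonpar = table.region == Region.X_NONPAR

    fam_err: dict[str, int] = {}
    fam_opp: dict[str, int] = {}
    snp_err = np.zeros(M, dtype=int)
    snp_opp = np.zeros(M, dtype=int)

    for r, mo, fa, fam, sex in trios:
        x = table.calls[r].astype(int)
        gm = table.calls[mo].astype(int) if mo >= 0 else np.full(M, MISSING)
        gf = table.calls[fa].astype(int) if fa >= 0 else np.full(M, MISSING)
        x_ok = (x >= 0) & (x <= 2)
        gm_ok = (gm >= 0) & (gm <= 2)
        gf_ok = (gf >= 0) & (gf <= 2)

        err = np.zeros(M, dtype=bool)
        opp = np.zeros(M, dtype=bool)
        if sex == Sex.MALE:
            o = nonpar & x_ok & gm_ok
            err |= o & (((x == 1) & (gm == 0)) | ((x == 0) & (gm == 2)))
            opp |= o
        elif sex == Sex.FEMALE:
            o = nonpar & x_ok & gm_ok & gf_ok
            err |= o & (x == 2) & ((gm == 0) | (gf == 0))
            err |= o & (x == 0) & ((gm == 2) | (gf == 1))
            err |= o & (x == 1) & (((gm == 0) & (gf == 0)) | ((gm == 2) & (gf == 1)))
            opp |= o
        o = ~nonpar & x_ok & gm_ok & gf_ok
        err |= o & (x == 2) & ((gm == 0) | (gf == 0))
        err |= o & (x == 0) & ((gm == 2) | (gf == 2))
        err |= o & (x == 1) & (((gm == 0) & (gf == 0)) | ((gm == 2) & (gf == 2)))
        opp |= o

        fam_err[fam] = fam_err.get(fam, 0) + int(err.sum())
        fam_opp[fam] = fam_opp.get(fam, 0) + int(opp.sum())
        snp_err += err
        snp_opp += opp

    removals: list[Removal] = []
    fam_rows = []
    for fam in sorted(fam_opp):
        rate = fam_err[fam] / fam_opp[fam] if fam_opp[fam] else 0.0
        fam_rows.append({"family": fam, "mendel_errors": fam_err[fam],
                         "opportunities": fam_opp[fam], "rate": rate})
        if rate > th.family_mendel_rate_max:
            removals.append(
                Removal("family", fam, "mendel_family_rate", rate, th.family_mendel_rate_max)
            )
    with np.errstate(invalid="ignore"):
        snp_rate = np.where(snp_opp > 0, snp_err / np.maximum(snp_opp, 1), 0.0)
    for j in range(M):
        if snp_opp[j] and snp_rate[j] > th.snp_mendel_rate_max:
            removals.append(
                Removal("snp", table.markers[j].marker_id, "mendel_snp_rate",
                        float(snp_rate[j]), th.snp_mendel_rate_max)
            )
    snp_df = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in table.markers],
            "mendel_errors": snp_err,
            "mendel_opportunities": snp_opp,
            "mendel_rate": snp_rate,
        }
    )
    return QCReport(
        family_metrics=pd.DataFrame(fam_rows), snp_metrics=snp_df, removals=removals
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_hom_cand: int, n_het: int, n_hom_other: int) -> float:
    """Exact Hardy-Weinberg P: total probability of heterozygote counts no
    more likely than the observed one, conditional on the allele counts.

    The conditional distribution of the heterozygote count n_het given n
    genotypes and n_a copies of the rarer allele is

        P(n_het) = C(n, (n_a-n_het)/2, n_het, ...) 2^n_het / C(2n, n_a)

    computed here in log space over all n_het with the parity of n_a.
    """
    n = n_hom_cand + n_het + n_hom_other
    if n == 0:
        return float("nan")
    na = 2 * n_hom_cand + n_het
    na = min(na, 2 * n - na)  # rarer allele count
    obs_het = n_het

    hets = range(na % 2, na + 1, 2)
    logs = []
    for h in hets:
        hom_rare = (na - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            logs.append(-math.inf)
            continue
        lg = (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
            + h * math.log(2.0)
        )
        logs.append(lg)
    mx = max(logs)
    probs = np.exp(np.array(logs) - mx)
    probs /= probs.sum()
    p_obs = probs[list(hets).index(obs_het)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_chisq_p(n_hom_cand: int, n_het: int, n_hom_other: int) -> float:
    """1-df chi-square alternative to the exact test."""
    n = n_hom_cand + n_het + n_hom_other
    if n == 0:
        return float("nan")
    p = (2 * n_hom_cand + n_het) / (2 * n)
    exp = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    obs = np.array([n_hom_cand, n_het, n_hom_other], dtype=float)
    if (exp == 0).any():
        return 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# SNP metrics
# ---------------------------------------------------------------------------


def compute_snp_qc(table: GenotypeTable, hwe_method: str = "exact") -> pd.DataFrame:
    """Per-SNP metric block: call rate, MAF, female HWE P, male het
    fraction, per-sex missing rates.

    MAF counts founders and unrelateds only (one chromosome per male at
    non-PAR markers); HWE uses founder females plus female unrelated
    controls; HET_FLAG counts as a call for call-rate purposes but never
    as a genotype.
    """
    M = table.n_markers
    calls = table.calls
    male = table.sex == Sex.MALE
    female = table.sex == Sex.FEMALE
    nonpar = table.region == Region.X_NONPAR

    called = calls != MISSING
    call_rate = called.mean(axis=0) if table.n_individuals else np.ones(M)

    founders = table.is_founder | (table.unit_kind != UnitKind.FAMILY_MEMBER)
    genod = (calls >= 0) & (calls <= 2)
    hemi = np.outer(male, nonpar)
    chroms = np.where(hemi, 1, 2)
    fsel = founders[:, None] & genod
    with np.errstate(invalid="ignore"):
        freq = (calls * fsel).sum(axis=0) / np.maximum((chroms * fsel).sum(axis=0), 1)
    freq = np.where((chroms * fsel).sum(axis=0) > 0, freq, np.nan)
    maf = np.minimum(freq, 1 - freq)

    hwe_females = female & (
        table.is_founder & (table.unit_kind == UnitKind.FAMILY_MEMBER)
        | (table.unit_kind == UnitKind.UNRELATED_CONTROL)
    )
    hwe_fn = hwe_exact_p if hwe_method == "exact" else hwe_chisq_p
    hwe_p = np.full(M, np.nan)
    sub = calls[hwe_females]
    for j in range(M):
        g = sub[:, j]
        counts = [(g == 2).sum(), (g == 1).sum(), (g == 0).sum()]
        if sum(counts) > 0:
            hwe_p[j] = hwe_fn(*map(int, counts))

    male_called = (calls != MISSING) & male[:, None] & nonpar[None, :]
    het_flags = (calls == HET_FLAG) & male[:, None] & nonpar[None, :]
    n_male_called = male_called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        male_het_fraction = np.where(
            n_male_called > 0, het_flags.sum(axis=0) / np.maximum(n_male_called, 1), np.nan
        )
    male_het_fraction = np.where(nonpar, male_het_fraction, np.nan)

    miss = calls == MISSING
    n_m, n_f = male.sum(), female.sum()
    male_missing = miss[male].mean(axis=0) if n_m else np.full(M, np.nan)
    female_missing = miss[female].mean(axis=0) if n_f else np.full(M, np.nan)

    return pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in table.markers],
            "region": table.region,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "male_het_count": het_flags.sum(axis=0),
            "male_het_fraction": male_het_fraction,
            "male_missing": male_missing,
            "female_missing": female_missing,
        }
    )


def missingness_sex_test(table: GenotypeTable) -> pd.DataFrame:
    """Per-SNP 1-df chi-square of missingness x sex (no continuity
    correction).  Zero-margin tables get P = 1 and an `uninformative` flag.
    """
    male = table.sex == Sex.MALE
    female = table.sex == Sex.FEMALE
    miss = table.calls == MISSING
    a = miss[male].sum(axis=0).astype(float)  # male missing
    b = (~miss[male]).sum(axis=0).astype(float)
    c = miss[female].sum(axis=0).astype(float)  # female missing
    d = (~miss[female]).sum(axis=0).astype(float)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1), 0.0)
    p = stats.chi2.sf(chi2, 1)
    p = np.where(denom > 0, p, 1.0)
    return pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in table.markers],
            "missing_chi2": np.where(denom > 0, chi2, 0.0),
            "missing_p": p,
            "uninformative": denom <= 0,
        }
    )


def apply_snp_filters(
    metrics: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    mendel_metrics: pd.DataFrame | None = None,
) -> tuple[list[str], list[Removal]]:
    """Apply SNP filters in the fixed order; returns (survivors, removals).

    Order: XY-homologous region, call rate, Mendel SNP rate, HWE, MAF,
    per-sex missingness (either sex), male-heterozygote fraction.  Only the
    first rule a SNP trips is recorded.
    """
    th = thresholds or QCThresholds()
    th.validate()
    m = metrics.set_index("marker_id")
    mendel = (
        mendel_metrics.set_index("marker_id")["mendel_rate"]
        if mendel_metrics is not None
        else None
    )
    survivors: list[str] = []
    removals: list[Removal] = []
    for mid, row in m.iterrows():
        rule = None
        value = np.nan
        thr = np.nan
        if int(row.get("region", Region.X_NONPAR)) == Region.XY_HOMOLOGOUS:
            rule, value, thr = "xy_homologous_region", float(row["region"]), np.nan
        elif row["call_rate"] < th.snp_call_rate_min:
            rule, value, thr = "snp_call_rate", float(row["call_rate"]), th.snp_call_rate_min
        elif mendel is not None and mid in mendel.index and mendel[mid] > th.snp_mendel_rate_max:
            rule, value, thr = "mendel_snp_rate", float(mendel[mid]), th.snp_mendel_rate_max
        elif not np.isnan(row["hwe_p"]) and row["hwe_p"] < th.hwe_p_min:
            rule, value, thr = "hwe", float(row["hwe_p"]), th.hwe_p_min
        elif not np.isnan(row["maf"]) and row["maf"] < th.maf_min:
            rule, value, thr = "maf", float(row["maf"]), th.maf_min
        elif (
            not np.isnan(row["male_missing"]) and row["male_missing"] > th.per_sex_missing_max
        ) or (
            not np.isnan(row["female_missing"])
            and row["female_missing"] > th.per_sex_missing_max
        ):
            worst = np.nanmax([row["male_missing"], row["female_missing"]])
            rule, value, thr = "per_sex_missingness", float(worst), th.per_sex_missing_max
        elif (
            not np.isnan(row["male_het_fraction"])
            and row["male_het_fraction"] > th.male_het_fraction_max
        ):
            rule, value, thr = "male_het_fraction", float(row["male_het_fraction"]), th.male_het_fraction_max
        if rule is None:
            survivors.append(mid)
        else:
            removals.append(Removal("snp", mid, rule, value, thr))
    return survivors, removals


def resolve_male_hets(table: GenotypeTable) -> tuple[GenotypeTable, int]:
    """Set surviving male-heterozygote flags to missing (call-error rule)."""
    out = table.copy()
    mask = out.calls == HET_FLAG
    n = int(mask.sum())
    out.calls[mask] = MISSING
    return out, n


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------


def run_qc(
    table: GenotypeTable,
    thresholds: QCThresholds | None = None,
    hwe_method: str = "exact",
) -> tuple[GenotypeTable, QCReport]:
    """Full QC battery; returns the filtered table and a combined report.

    Steps: sample QC (call rate, sex check; unknown-sex samples get their
    inferred sex assigned and hemizygous recoding applied), family and SNP
    Mendel screens, SNP metric filters in fixed order, then resolution of
    surviving male-heterozygote calls to missing.  Applying the battery to
    its own output removes nothing further.
    """
    th = thresholds or QCThresholds()

    srep = compute_sample_qc(table, th)
    removed_samples = set(srep.removed("sample"))
    keep_rows = []
    t1 = table.copy()
    inferred = srep.sample_metrics["inferred_sex"].to_numpy()
    for r, ind in enumerate(t1.individuals):
        label = f"{ind.family_id}/{ind.individual_id}"
        if label in removed_samples:
            continue
        if ind.sex == Sex.UNKNOWN and inferred[r] != Sex.UNKNOWN:
            ind.sex = Sex(int(inferred[r]))
            if ind.sex == Sex.MALE:  # recode diploid-read calls hemizygously
                nonpar = t1.region == Region.X_NONPAR
                row = t1.calls[r]
                row[nonpar & (row == 2)] = 1
                row[nonpar & (row == 1)] = HET_FLAG
        keep_rows.append(r)
    t1 = t1.subset_individuals(keep_rows)

    mrep = mendel_error_scan(t1, th)
    removed_fams = set(mrep.removed("family"))
    if removed_fams:
        keep = [
            r
            for r, ind in enumerate(t1.individuals)
            if ind.family_id not in removed_fams
        ]
        t1 = t1.subset_individuals(keep)

    snp_metrics = compute_snp_qc(t1, hwe_method=hwe_method)
    miss_test = missingness_sex_test(t1)
    snp_metrics = snp_metrics.merge(miss_test, on="marker_id")
    survivors, snp_removals = apply_snp_filters(snp_metrics, th, mrep.snp_metrics)
    surv_idx = [j for j, m in enumerate(t1.markers) if m.marker_id in set(survivors)]
    t2 = t1.subset_markers(surv_idx)
    t3, n_het_resolved = resolve_male_hets(t2)

    # mendel SNP removals re-derive through apply_snp_filters (first-rule
    # semantics), so only family-level mendel removals are added here
    fam_removals = [r for r in mrep.removals if r.entity == "family"]
    report = QCReport(
        sample_metrics=srep.sample_metrics,
        snp_metrics=snp_metrics,
        family_metrics=mrep.family_metrics,
        removals=srep.removals + fam_removals + snp_removals,
    )
    report.n_male_hets_resolved = n_het_resolved  # type: ignore[attr-defined]
    return t3, report
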