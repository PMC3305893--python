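"""Case-control association tests with X-aware allele counting.

Allele-based 1-df chi-square tests with sex strata (males contribute one
chromosome at non-PAR X markers, two in the PARs; females always two),
genomic-control correction of the resulting chi-squares, a female
recessive-model genotype test, and a male multi-marker haplotype test
(phase is observed directly in hemizygous males).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenotypeTable, HET_FLAG, Region, Sex, UnitKind
from .family import AssocResult, Stratum

#: median of the 1-df chi-square distribution
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


@dataclass
class AlleleCountTable:
    """2x2 candidate/other x case/control chromosome counts."""

    case_candidate: float
    case_other: float
    control_candidate: float
    control_other: float
    male_chromosomes: int = 0
    female_chromosomes: int = 0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.case_candidate, self.case_other],
                [self.control_candidate, self.control_other],
            ]
        )


@dataclass
class GCResult:
    lambda_gc: float
    corrected_chi2: np.ndarray
    corrected_p: np.ndarray
    applied: bool


def _chi2_2x2(t: np.ndarray) -> float:
    """Pearson chi-square without continuity correction."""
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return float(n * (a * d - b * c) ** 2 / denom)


def _woolf_or(t: np.ndarray) -> tuple[float, float, float]:
    a, b = t[0]
    c, d = t[1]
    if min(a, b, c, d) == 0:
        if b == 0 or c == 0:
            return (np.inf, np.nan, np.nan)
        return (0.0, np.nan, np.nan)
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(orr),
        float(np.exp(np.log(orr) - 1.96 * se)),
        float(np.exp(np.log(orr) + 1.96 * se)),
    )


def _stratum_rows(table: GenotypeTable, stratum: Stratum) -> np.ndarray:
    sel = np.ones(table.n_individuals, dtype=bool)
    if stratum == Stratum.MALE:
        sel &= table.sex == Sex.MALE
    elif stratum == Stratum.FEMALE:
        sel &= table.sex == Sex.FEMALE
    return sel


def allele_count_table(
    table: GenotypeTable, marker: int | str, stratum: Stratum = Stratum.OVERALL
) -> AlleleCountTable:
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    sel = _stratum_rows(table, stratum)
    case = sel & (table.unit_kind == UnitKind.UNRELATED_CASE)
    ctrl = sel & (table.unit_kind == UnitKind.UNRELATED_CONTROL)
    g = table.calls[:, j].astype(float)
    ok = (g >= 0) & (g != HET_FLAG)
    hemi = (table.sex == Sex.MALE) & (int(table.region[j]) == Region.X_NONPAR)
    chroms = np.where(hemi, 1.0, 2.0)

    def counts(mask):
        m = mask & ok
        cand = g[m].sum()
        total = chroms[m].sum()
        return cand, total - cand, m

    cc, co, mcase = counts(case)
    tc, to, mctrl = counts(ctrl)
    both = mcase | mctrl
    return AlleleCountTable(
        cc, co, tc, to,
        male_chromosomes=int(chroms[both & (table.sex == Sex.MALE)].sum()),
        female_chromosomes=int(chroms[both & (table.sex == Sex.FEMALE)].sum()),
    )


def allelic_test(
    table: GenotypeTable, marker: int | str, stratum: Stratum = Stratum.OVERALL
) -> AssocResult:
    """Allele-based case-control chi-square with Woolf-CI odds ratio."""
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    mid = table.markers[j].marker_id
    act = allele_count_table(table, j, stratum)
    t = act.as_array()
    n_case = t[0].sum()
    n_ctrl = t[1].sum()
    if n_case == 0 or n_ctrl == 0:
        return AssocResult(mid, "cc_allelic", stratum.value, 0, 0, 0.0, 1.0,
                           note="skipped: empty stratum")
    chi2 = _chi2_2x2(t)
    if t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
        return AssocResult(mid, "cc_allelic", stratum.value, 0, 0, 0.0, 1.0,
                           note="non-informative: zero allele margin")
    p = float(stats.chi2.sf(chi2, 1))
    orr, lo, hi = _woolf_or(t)
    z = float(np.sign(np.log(orr)) * np.sqrt(chi2)) if orr not in (0.0, np.inf) else (
        float(np.sqrt(chi2)) if orr == np.inf else float(-np.sqrt(chi2))
    )
    return AssocResult(
        mid, "cc_allelic", stratum.value,
        S=float(t[0, 0]), V=chi2, Z=z, P=p,
        odds_ratio=orr, ci_low=lo, ci_high=hi,
        n_units=int(n_case + n_ctrl),
    )


def genomic_control(chi_squares) -> GCResult:
    """Divide 1-df chi-squares by lambda = median(chi2)/chi2_median when the
    inflation factor exceeds 1; never deflates."""
    x = np.asarray(chi_squares, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("no finite chi-square values for genomic control")
    lam = float(np.median(x[finite]) / CHI2_MEDIAN_1DF)
    if lam > 1.0:
        corrected = x / lam
        applied = True
    else:
        corrected = x.copy()
        applied = False
    p = stats.chi2.sf(corrected, 1)
    return GCResult(lam, corrected, p, applied)


def female_recessive_test(table: GenotypeTable, marker: int | str) -> AssocResult:
    """Candidate-homozygote vs other genotypes among female cases/controls."""
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    mid = table.markers[j].marker_id
    female = table.sex == Sex.FEMALE
    g = table.calls[:, j]
    ok = (g >= 0) & (g != HET_FLAG)
    case = female & ok & (table.unit_kind == UnitKind.UNRELATED_CASE)
    ctrl = female & ok & (table.unit_kind == UnitKind.UNRELATED_CONTROL)
    t = np.array(
        [
            [(g[case] == 2).sum(), (g[case] != 2).sum()],
            [(g[ctrl] == 2).sum(), (g[ctrl] != 2).sum()],
        ],
        dtype=float,
    )
    if t.sum() == 0 or t[0].sum() == 0 or t[1].sum() == 0:
        return AssocResult(mid, "cc_female_recessive", "female", 0, 0, 0.0, 1.0,
                           note="skipped: empty stratum")
    if t[:, 0].sum() == 0:
        return AssocResult(mid, "cc_female_recessive", "female", 0, 0, 0.0, 1.0,
                           note="non-informative: no candidate homozygotes")
    chi2 = _chi2_2x2(t)
    orr, lo, hi = _woolf_or(t)
    return AssocResult(
        mid, "cc_female_recessive", "female",
        S=float(t[0, 0]), V=chi2,
        Z=float(np.sign(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) * np.sqrt(chi2)),
        P=float(stats.chi2.sf(chi2, 1)),
        odds_ratio=orr, ci_low=lo, ci_high=hi,
        n_units=int(t.sum()),
    )


@dataclass
class HaplotypeTestResult:
    marker_ids: list[str]
    chi2: float
    df: int
    P: float
    haplotype_counts: dict = field(default_factory=dict)
    note: str = ""


def male_haplotype_test(
    table: GenotypeTable, marker_set, min_expected: float = 5.0
) -> HaplotypeTestResult:
    """Global haplotype x case/control chi-square among males.

    Hemizygous males carry one non-PAR X haplotype, so phase is observed;
    individuals with any missing call in the set are dropped, and
    haplotypes with expected count < ``min_expected`` pool into one class.
    """
    js = [m if isinstance(m, int) else table.marker_index(m) for m in marker_set]
    ids = [table.markers[j].marker_id for j in js]
    for j in js:
        if table.markers[j].region != Region.X_NONPAR:
            raise ValueError(f"marker {table.markers[j].marker_id} is not non-PAR X")
    male = table.sex == Sex.MALE
    case = male & (table.unit_kind == UnitKind.UNRELATED_CASE)
    ctrl = male & (table.unit_kind == UnitKind.UNRELATED_CONTROL)
    g = table.calls[:, js]
    complete = ((g >= 0) & (g <= 1)).all(axis=1)

    def haps(mask):
        rows = g[mask & complete]
        return ["".join(map(str, r)) for r in rows]

    hc, ht = haps(case), haps(ctrl)
    labels = sorted(set(hc) | set(ht))
    if len(labels) < 2:
        return HaplotypeTestResult(ids, 0.0, 0, 1.0,
                                   note="non-informative: <2 distinct haplotypes")
    counts = np.array(
        [[hc.count(h) for h in labels], [ht.count(h) for h in labels]], dtype=float
    )
    # pool rare haplotypes (small expected counts destabilize the chi-square)
    n = counts.sum()
    exp = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    rare = exp.min(axis=0) < min_expected
    if rare.any() and (~rare).sum() >= 1:
        pooled = counts[:, ~rare]
        pooled = np.hstack([pooled, counts[:, rare].sum(axis=1, keepdims=True)])
        labels = [l for l, r in zip(labels, rare) if not r] + ["pooled_rare"]
        counts = pooled
    if counts.shape[1] < 2:
        return HaplotypeTestResult(ids, 0.0, 0, 1.0,
                                   note="non-informative: <2 haplotype classes")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return HaplotypeTestResult(
        ids, float(chi2), int(df), float(p),
        haplotype_counts={h: (int(counts[0, k]), int(counts[1, k])) for k, h in enumerate(labels)},
    )
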