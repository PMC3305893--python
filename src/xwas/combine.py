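"""Joint cluster-stratified statistic, weighted-Z meta-analysis,
replication assessment and the candidate-gene screen.

The joint statistic fits allele frequencies separately in each cluster
(family cohorts; case-control cohort with cases as proband-only triads and
controls anchoring the EM), sums the per-cluster score numerators and
estimates the variance jointly:

    Z_joint = (sum_k S_k) / sqrt(sum_k V_k)

Frequencies are never pooled across clusters, which is what protects the
statistic from between-cluster stratification.  The meta-analysis combines
signed study Z scores with weights w_i (default sqrt of the effective
sample size): Z_meta = sum(w_i Z_i) / sqrt(sum(w_i^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenotypeTable, ModelError
from .family import (
    ClusterUnits,
    Stratum,
    _is_monomorphic,
    cluster_score,
    em_mating_types,
    zp_from_sv,
)


@dataclass
class CombinedResult:
    marker_id: str
    stratum: str
    cluster_S: dict = field(default_factory=dict)
    cluster_V: dict = field(default_factory=dict)
    Z: float = 0.0
    P: float = 1.0
    note: str = ""

    @property
    def S(self) -> float:
        return float(sum(self.cluster_S.values()))

    @property
    def V(self) -> float:
        return float(sum(self.cluster_V.values()))


def joint_test(
    table: GenotypeTable,
    marker: int | str,
    clusters: list[str] | None = None,
    stratum: Stratum = Stratum.OVERALL,
    variance_method: str = "empirical",
    pool_frequencies: bool = False,
    cus: dict[str, ClusterUnits] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> CombinedResult:
    """Cluster-stratified joint test at one marker.

    ``pool_frequencies=True`` fits a single EM across all units (the naive
    analysis the stratified statistic exists to avoid); it is provided for
    calibration comparisons only.
    """
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    mid = table.markers[j].marker_id
    clusters = clusters if clusters is not None else table.clusters()
    if not clusters:
        raise ModelError("no clusters to combine")
    cus = cus or {}

    pooled_model = None
    if pool_frequencies:
        pooled = table.copy()
        for ind in pooled.individuals:
            ind.cluster = "__pooled__"
        pooled_cu = ClusterUnits.from_table(pooled, "__pooled__")
        pooled_model = em_mating_types(pooled, j, "__pooled__", cu=pooled_cu)

    out = CombinedResult(mid, stratum.value)
    dropped = []
    for cl in clusters:
        if _is_monomorphic(table, j, cl):
            dropped.append(cl)
            continue
        cu = cus.get(cl)
        if cu is None:
            cu = cus[cl] = ClusterUnits.from_table(table, cl)
        model = None
        if pooled_model is not None:
            model = type(pooled_model)(**{**pooled_model.__dict__, "cluster": cl})
        try:
            S, V, _, _, _ = cluster_score(
                table, j, cl, stratum, variance_method, cu, model, n_boot, seed
            )
        except ModelError:
            dropped.append(cl)
            continue
        out.cluster_S[cl] = S
        out.cluster_V[cl] = V
    if not out.cluster_S:
        raise ModelError(f"all clusters dropped for marker {mid}")
    if dropped:
        out.note = f"clusters dropped: {','.join(dropped)}"
    out.Z, out.P = zp_from_sv(out.S, out.V)
    if out.V <= 0:
        out.note = (out.note + "; " if out.note else "") + "non-informative: zero variance"
    return out


def meta_combine(z_scores, weights=None) -> tuple[float, float]:
    """Weighted-Z combination: Z = sum(w_i Z_i)/sqrt(sum w_i^2).

    Z scores must already be sign-aligned to the same candidate allele
    (use :func:`align_candidate_alleles` when combining across tables).
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("no studies to combine")
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != z.shape or (w <= 0).any():
        raise ValueError("weights must be positive and match the study count")
    zm = float((w * z).sum() / np.sqrt((w**2).sum()))
    return zm, float(2.0 * stats.norm.sf(abs(zm)))


def align_candidate_alleles(tables: list[GenotypeTable], marker_id: str) -> list[int]:
    """Per-table sign (+1/-1) aligning each table's candidate allele to the
    first table's; raises on incompatible allele labels."""
    ref = tables[0].markers[tables[0].marker_index(marker_id)]
    signs = []
    for t in tables:
        m = t.markers[t.marker_index(marker_id)]
        if m.allele_candidate == ref.allele_candidate:
            signs.append(1)
        elif (
            m.allele_candidate == ref.allele_other
            and m.allele_other == ref.allele_candidate
        ):
            signs.append(-1)
        else:
            raise ValueError(
                f"marker {marker_id}: allele labels "
                f"{m.allele_candidate}/{m.allele_other} incompatible with "
                f"{ref.allele_candidate}/{ref.allele_other}"
            )
    return signs


def cc_signed_z(chi2: float, odds_ratio: float) -> float:
    """Case-control Z as sign(OR - 1) * sqrt(chi2) (GC-corrected chi2)."""
    if not np.isfinite(odds_ratio) or odds_ratio <= 0:
        s = 1.0 if odds_ratio == np.inf else -1.0
    else:
        s = np.sign(np.log(odds_ratio)) or 1.0
    return float(s * np.sqrt(max(chi2, 0.0)))


REPLICATED = "REPLICATED"
NOT_REPLICATED = "NOT_REPLICATED"


@dataclass
class ReplicationVerdict:
    verdict: str
    near_miss: bool
    p_discovery: float
    p_validation: float
    threshold: float


def replication_assess(
    p_discovery: float, p_validation: float, threshold: float = 0.0025
) -> ReplicationVerdict:
    """Strict rule: replicated iff both P values fall below the threshold.

    A near-miss annotation (reporting only, never part of the verdict)
    marks results where one side passes and the other is within 10x.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    rep = p_discovery < threshold and p_validation < threshold
    near = not rep and (
        (p_discovery < threshold and p_validation < 10 * threshold)
        or (p_validation < threshold and p_discovery < 10 * threshold)
    )
    return ReplicationVerdict(
        REPLICATED if rep else NOT_REPLICATED, near, p_discovery, p_validation, threshold
    )


@dataclass
class CandidateGeneHit:
    marker_id: str
    gene_ids: list[str]
    p_discovery: float
    p_validation: float
    p_joint: float


def candidate_gene_screen(
    results,
    candidate_genes,
    alpha: float = 0.05,
) -> tuple[list[CandidateGeneHit], float]:
    """Flag markers with discovery, validation and joint P all below alpha
    that sit in a candidate gene.

    ``results`` is an iterable of records with ``marker_id``, ``gene_ids``,
    ``p_discovery``, ``p_validation``, ``p_joint`` attributes or keys.
    Returns the hits plus the expected-by-chance count n_candidate * alpha^3
    (an upper-bound style approximation; the three analyses share data, so
    the true chance rate is larger).
    """
    cand = set(candidate_genes)
    hits: list[CandidateGeneHit] = []
    n_candidate_snps = 0

    def get(rec, name):
        return rec[name] if isinstance(rec, dict) else getattr(rec, name)

    for rec in results:
        genes = list(get(rec, "gene_ids"))
        in_candidate = bool(cand.intersection(genes))
        if in_candidate:
            n_candidate_snps += 1
        ps = [get(rec, k) for k in ("p_discovery", "p_validation", "p_joint")]
        if in_candidate and all(np.isfinite(p) and p < alpha for p in ps):
            hits.append(
                CandidateGeneHit(get(rec, "marker_id"), genes, *map(float, ps))
            )
    expected = n_candidate_snps * alpha**3
    return hits, expected
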