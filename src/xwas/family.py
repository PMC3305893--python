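"""Family-based X-linked transmission test (X-APL form) with EM handling
of missing parental genotypes.

The statistic compares, per independent unit (nuclear family or unrelated
proband), the observed candidate-allele count among affected offspring with
its Mendelian expectation given the parental *mating type* -- the ordered
pair of parental genotypes.  On the non-PAR X there are six mating types
(mother 0/1/2 copies x father 0/1); in the PARs markers behave autosomally
and there are nine.

When parents are ungenotyped, mating-type frequencies ``mu`` are estimated
by EM over all units of a cluster; unrelated cases and controls enter the
EM as single offspring of an unobserved mating, which is how case-control
individuals are folded into the family framework.  A unit's contribution

    D = sum over affected offspring of (observed - E[count | mating type])

averages the expectation over the unit's posterior mating-type weights.
That posterior conditions on the observed parents and genotyped
*unaffected* siblings only, never on the affected offspring being scored:
this keeps E[D] = 0 exactly under the null hypothesis.  With both parents
genotyped the posterior is a point mass and D reduces to the direct
Mendelian deviation.

Per cluster the test is Z = S / sqrt(V) with S = sum(D) and, by default,
the empirical variance V = sum(D^2) (valid because the D are independent,
mean-zero under H0); a unit-level nonparametric bootstrap variance is
available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .core import (
    HET_FLAG,
    MISSING,
    Affection,
    GenotypeTable,
    ModelError,
    Region,
    Sex,
    UnitKind,
)

EM_TOL = 1e-8
EM_MAX_ITER = 500


class Stratum(str, Enum):
    OVERALL = "overall"
    MALE = "male"
    FEMALE = "female"


@dataclass
class MatingTypeModel:
    """EM-estimated mating-type frequencies for one cluster at one marker."""

    cluster: str
    mode: str  # "X_NONPAR" or "PAR"
    mu: np.ndarray
    p: float  # implied candidate-allele frequency
    n_iter: int
    loglik_trace: list[float]
    converged: bool
    n_units: int


@dataclass
class FamilyContribution:
    unit_id: str
    stratum: Stratum
    D: float
    n_contributing: int


@dataclass
class AssocResult:
    """One marker x one analysis x one stratum."""

    marker_id: str
    analysis: str
    stratum: str
    S: float
    V: float
    Z: float
    P: float
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_units: int = 0
    note: str = ""

    @property
    def informative(self) -> bool:
        return "non-informative" not in self.note and "skipped" not in self.note


# ---------------------------------------------------------------------------
# transmission and expectation tables
# ---------------------------------------------------------------------------

# non-PAR X: mating type index = 2*g_M + g_F with g_M in 0..2, g_F in 0..1
_MT_X = [(gm, gf) for gm in range(3) for gf in range(2)]
# PAR: index = 3*g_M + g_F, both parents 0..2
_MT_PAR = [(gm, gf) for gm in range(3) for gf in range(3)]


def _maternal(a: int, gm: int) -> float:
    """P(mother transmits `a` candidate alleles | mother genotype gm)."""
    return {0: (1.0, 0.0), 1: (0.5, 0.5), 2: (0.0, 1.0)}[gm][a]


def _tables_x():
    nmt = len(_MT_X)
    # T[sex01, x, mt]; sex01: 0 = male child, 1 = female child
    T = np.zeros((2, 3, nmt))
    E = np.zeros((2, nmt))
    for m, (gm, gf) in enumerate(_MT_X):
        for a in (0, 1):
            T[0, a, m] = _maternal(a, gm)  # son: maternal draw only
            xd = a + gf  # daughter: maternal draw + paternal allele
            T[1, xd, m] += _maternal(a, gm)
        E[0, m] = gm / 2.0
        E[1, m] = gm / 2.0 + gf
    return T, E


def _tables_par():
    nmt = len(_MT_PAR)
    T = np.zeros((2, 3, nmt))
    E = np.zeros((2, nmt))
    for m, (gm, gf) in enumerate(_MT_PAR):
        for am in (0, 1):
            for af in (0, 1):
                T[:, am + af, m] += _maternal(am, gm) * _maternal(af, gf)
        E[:, m] = gm / 2.0 + gf / 2.0
    return T, E


_T_X, _E_X = _tables_x()
_T_PAR, _E_PAR = _tables_par()

with np.errstate(divide="ignore"):
    _LOGT_X = np.log(_T_X)
    _LOGT_PAR = np.log(_T_PAR)

# parent-genotype consistency indicators, log scale; last row = unknown parent
def _consistency(values, nmt, which, mts):
    C = np.full((4, nmt), -np.inf)
    C[3] = 0.0
    for g in values:
        for m, mt in enumerate(mts):
            if mt[which] == g:
                C[g, m] = 0.0
    return C


_CM_X = _consistency((0, 1, 2), 6, 0, _MT_X)
_CF_X = _consistency((0, 1), 6, 1, _MT_X)
_CM_PAR = _consistency((0, 1, 2), 9, 0, _MT_PAR)
_CF_PAR = _consistency((0, 1, 2), 9, 1, _MT_PAR)


# ---------------------------------------------------------------------------
# unit structure
# ---------------------------------------------------------------------------


@dataclass
class ClusterUnits:
    """Marker-independent unit structure of one cluster.

    Each unit is a nuclear family (possibly with ungenotyped parents) or an
    unrelated case/control standing as a proband-only triad.  Children are
    stored flat, sorted by unit, so per-marker likelihoods aggregate with
    ``np.add.reduceat``.
    """

    unit_ids: list[str]
    mother_row: np.ndarray  # (U,) row index or -1
    father_row: np.ndarray
    child_row: np.ndarray  # (C,) sorted by unit
    child_unit: np.ndarray
    child_sex: np.ndarray  # Sex codes
    child_aff: np.ndarray  # bool: affected
    seg_starts: np.ndarray  # (U,) reduceat segment starts
    is_unrelated: np.ndarray  # (U,) bool

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @classmethod
    def from_table(cls, table: GenotypeTable, cluster: str) -> "ClusterUnits":
        rows = table.row_index()
        in_cluster = [
            (r, ind) for r, ind in enumerate(table.individuals) if ind.cluster == cluster
        ]
        # nuclear families keyed by (family, mother, father)
        fam_children: dict[tuple[str, str, str], list[int]] = {}
        unrelated: list[int] = []
        for r, ind in in_cluster:
            if ind.unit_kind != UnitKind.FAMILY_MEMBER:
                unrelated.append(r)
            elif ind.mother_id or ind.father_id:
                key = (ind.family_id, ind.mother_id, ind.father_id)
                fam_children.setdefault(key, []).append(r)

        unit_ids: list[str] = []
        mother_row: list[int] = []
        father_row: list[int] = []
        child_row: list[int] = []
        child_unit: list[int] = []
        child_sex: list[int] = []
        child_aff: list[bool] = []
        is_unrel: list[bool] = []

        for (fam, mid, fid), kids in fam_children.items():
            u = len(unit_ids)
            unit_ids.append(fam if mid == "" and fid == "" else f"{fam}:{mid}x{fid}")
            mother_row.append(rows.get((fam, mid), -1) if mid else -1)
            father_row.append(rows.get((fam, fid), -1) if fid else -1)
            is_unrel.append(False)
            for r in kids:
                child_row.append(r)
                child_unit.append(u)
                child_sex.append(int(table.individuals[r].sex))
                child_aff.append(table.individuals[r].affection == Affection.AFFECTED)

        for r in unrelated:
            ind = table.individuals[r]
            u = len(unit_ids)
            unit_ids.append(f"{ind.family_id}/{ind.individual_id}")
            mother_row.append(-1)
            father_row.append(-1)
            is_unrel.append(True)
            child_row.append(r)
            child_unit.append(u)
            child_sex.append(int(ind.sex))
            child_aff.append(ind.unit_kind == UnitKind.UNRELATED_CASE)

        order = np.argsort(np.asarray(child_unit, dtype=int), kind="stable")
        child_unit_arr = np.asarray(child_unit, dtype=int)[order]
        counts = np.bincount(child_unit_arr, minlength=len(unit_ids))
        if (counts == 0).any():
            raise ModelError("unit without children; cannot happen by construction")
        seg_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        return cls(
            unit_ids=unit_ids,
            mother_row=np.asarray(mother_row, dtype=int),
            father_row=np.asarray(father_row, dtype=int),
            child_row=np.asarray(child_row, dtype=int)[order],
            child_unit=child_unit_arr,
            child_sex=np.asarray(child_sex, dtype=np.int8)[order],
            child_aff=np.asarray(child_aff, dtype=bool)[order],
            seg_starts=seg_starts,
            is_unrelated=np.asarray(is_unrel, dtype=bool),
        )


def _mode_for(table: GenotypeTable, j: int) -> str:
    return "PAR" if table.markers[j].region in (Region.PAR1, Region.PAR2) else "X_NONPAR"


def _parent_logc(cu: ClusterUnits, col: np.ndarray, mode: str) -> np.ndarray:
    CM, CF = (_CM_X, _CF_X) if mode == "X_NONPAR" else (_CM_PAR, _CF_PAR)

    def codes(rowidx, valid_max):
        g = np.where(rowidx >= 0, col[np.clip(rowidx, 0, None)], MISSING)
        g = np.where((g >= 0) & (g <= valid_max), g, 3)  # 3 = unknown row
        return g.astype(int)

    gm = codes(cu.mother_row, 2)
    gf = codes(cu.father_row, 2 if mode == "PAR" else 1)
    return CM[gm] + CF[gf]


def _child_logl(cu, col, mode, include_mask):
    """(C, nmt) per-child log transmission likelihoods; excluded or
    ungenotyped children contribute log 1 = 0."""
    LT = _LOGT_X if mode == "X_NONPAR" else _LOGT_PAR
    nmt = LT.shape[2]
    x = col[cu.child_row].astype(int)
    sex01 = np.where(cu.child_sex == Sex.FEMALE, 1, 0)
    valid = (x >= 0) & (x <= 2) & (x != HET_FLAG)
    if mode == "X_NONPAR":
        valid &= cu.child_sex != Sex.UNKNOWN  # transmission law needs sex
        valid &= ~((cu.child_sex == Sex.MALE) & (x == 2))
    use = valid & include_mask
    out = np.zeros((len(x), nmt))
    out[use] = LT[sex01[use], x[use]]
    return out, valid


def _seg_sum(cu: ClusterUnits, child_vals: np.ndarray) -> np.ndarray:
    return np.add.reduceat(child_vals, cu.seg_starts, axis=0)


def _hwe_mu(p: float, mode: str) -> np.ndarray:
    """Mating-type frequencies implied by allele frequency p under HWE and
    random mating (mother genotype independent of father genotype)."""
    q = 1.0 - p
    mother = np.array([q * q, 2 * p * q, p * p])
    father = np.array([q, p]) if mode == "X_NONPAR" else np.array([q * q, 2 * p * q, p * p])
    return np.outer(mother, father).ravel()


def em_mating_types(
    table: GenotypeTable,
    marker: int | str,
    cluster: str,
    cu: ClusterUnits | None = None,
    constraint: str = "hwe",
    init: np.ndarray | float | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> MatingTypeModel:
    """Fit mating-type frequencies ``mu`` for one cluster at one marker.

    E-step weights are proportional to mu(mt) x consistency with observed
    parents x product of offspring transmission probabilities.

    ``constraint="hwe"`` (default) parameterizes mu by the candidate-allele
    frequency p under Hardy-Weinberg proportions and random mating, the
    identifiable model the APL family of tests uses: the M-step sets p to
    the posterior-expected parental allele count divided by the number of
    parental allele copies (3 per non-PAR X mating, 4 per PAR mating).
    ``constraint="free"`` updates all mating-type cells independently
    (the M-step averages the posterior weights); with fully genotyped
    parents the free fit equals the empirical mating-type proportions after
    one iteration, but with much missing data the cell frequencies are not
    identifiable and only the likelihood, not mu itself, is stable.
    """
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    cu = cu or ClusterUnits.from_table(table, cluster)
    mode = _mode_for(table, j)
    col = table.calls[:, j]

    logc = _parent_logc(cu, col, mode)
    logl, _ = _child_logl(cu, col, mode, np.ones(len(cu.child_row), dtype=bool))
    logA = logc + _seg_sum(cu, logl)
    A = np.exp(logA)

    # units with a constant likelihood row (e.g. all genotypes missing)
    # carry no information and would only dilute the M-step
    keep = (A.max(axis=1) > 0) & (A.min(axis=1) < A.max(axis=1))
    if not keep.any():
        raise ModelError(f"no informative units for marker {j} in cluster '{cluster}'")
    Ak = A[keep]

    mts = _MT_X if mode == "X_NONPAR" else _MT_PAR
    denom = 3.0 if mode == "X_NONPAR" else 4.0
    copies = np.array([gm + gf for gm, gf in mts], dtype=float)
    nmt = A.shape[1]

    if constraint == "hwe":
        p = 0.5 if init is None else float(init)
        mu = _hwe_mu(p, mode)
    elif constraint == "free":
        mu = np.full(nmt, 1.0 / nmt) if init is None else np.asarray(init, float)
    else:
        raise ValueError(f"unknown constraint '{constraint}'")

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = Ak * mu
        s = W.sum(axis=1)
        trace.append(float(np.log(s).sum()))
        W /= s[:, None]
        if constraint == "hwe":
            p = float(W.mean(axis=0) @ copies / denom)
            p = min(max(p, 1e-12), 1 - 1e-12)
            mu_new = _hwe_mu(p, mode)
        else:
            mu_new = W.mean(axis=0)
        if np.max(np.abs(mu_new - mu)) < tol:
            mu = mu_new
            converged = True
            break
        mu = mu_new

    p_out = float(mu @ copies / denom)
    return MatingTypeModel(
        cluster=cluster,
        mode=mode,
        mu=mu,
        p=p_out,
        n_iter=it,
        loglik_trace=trace,
        converged=converged,
        n_units=int(keep.sum()),
    )


def _stratum_mask(cu: ClusterUnits, stratum: Stratum) -> np.ndarray:
    if stratum == Stratum.MALE:
        return cu.child_sex == Sex.MALE
    if stratum == Stratum.FEMALE:
        return cu.child_sex == Sex.FEMALE
    return np.ones(len(cu.child_row), dtype=bool)


def family_contributions(
    table: GenotypeTable,
    marker: int | str,
    model: MatingTypeModel,
    stratum: Stratum = Stratum.OVERALL,
    cu: ClusterUnits | None = None,
) -> tuple[np.ndarray, np.ndarray, ClusterUnits]:
    """Per-unit deviations D and contributing-affected counts.

    Controls and units with no scoreable affected offspring get D = 0.
    """
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    cu = cu or ClusterUnits.from_table(table, model.cluster)
    mode = _mode_for(table, j)
    col = table.calls[:, j]
    B, obs, Esum, n_contrib = _contribution_arrays(cu, col, mode, stratum)
    D = _D_from_mu(B, obs, Esum, n_contrib, model.mu)
    return D, n_contrib, cu


def _contribution_arrays(cu: ClusterUnits, col: np.ndarray, mode: str, stratum: Stratum):
    """Marker-level arrays from which D follows for any mu:
    B (posterior kernel over parents + unaffected sibs), observed affected
    counts, per-mating-type expectation sums, and contributing counts."""
    ET = _E_X if mode == "X_NONPAR" else _E_PAR
    logc = _parent_logc(cu, col, mode)
    logl_unaff, _ = _child_logl(cu, col, mode, ~cu.child_aff)
    B = np.exp(logc + _seg_sum(cu, logl_unaff))

    _, valid = _child_logl(cu, col, mode, np.ones(len(cu.child_row), dtype=bool))
    score = cu.child_aff & valid & _stratum_mask(cu, stratum)
    x = col[cu.child_row].astype(float)
    obs = _seg_sum(cu, np.where(score, x, 0.0))
    sex01 = np.where(cu.child_sex == Sex.FEMALE, 1, 0)
    Erows = np.where(score[:, None], ET[sex01], 0.0)
    Esum = _seg_sum(cu, Erows)
    n_contrib = _seg_sum(cu, score.astype(float)).astype(int)
    return B, obs, Esum, n_contrib


def _D_from_mu(B, obs, Esum, n_contrib, mu) -> np.ndarray:
    WB = B * mu
    sB = WB.sum(axis=1)
    good = sB > 0
    WB[good] /= sB[good, None]
    WB[~good] = 0.0
    D = obs - np.einsum("um,um->u", WB, Esum)
    D[n_contrib == 0] = 0.0
    D[~good] = 0.0  # Mendel-inconsistent unit: excluded
    return D


def family_contribution(
    table: GenotypeTable,
    marker: int | str,
    model: MatingTypeModel,
    stratum: Stratum = Stratum.OVERALL,
    cu: ClusterUnits | None = None,
) -> list[FamilyContribution]:
    """Per-unit contributions as records (thin wrapper over the array form)."""
    D, n, cu = family_contributions(table, marker, model, stratum, cu)
    return [
        FamilyContribution(uid, stratum, float(d), int(k))
        for uid, d, k in zip(cu.unit_ids, D, n)
    ]


def _is_monomorphic(table: GenotypeTable, j: int, cluster: str) -> bool:
    """True when only one allele is observed in the cluster at marker j."""
    mask = table.cluster == cluster
    g = table.calls[mask, j].astype(int)
    sex = table.sex[mask]
    ok = (g >= 0) & (g != HET_FLAG)
    if not ok.any():
        return True
    hemi = (sex == Sex.MALE) & (int(table.region[j]) == Region.X_NONPAR)
    chroms = np.where(hemi, 1, 2)[ok]
    count = int(g[ok].sum())
    return count == 0 or count == int(chroms.sum())


def zp_from_sv(S: float, V: float) -> tuple[float, float]:
    if V <= 0:
        return 0.0, 1.0
    z = S / np.sqrt(V)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def cluster_score(
    table: GenotypeTable,
    marker: int | str,
    cluster: str,
    stratum: Stratum = Stratum.OVERALL,
    variance_method: str = "empirical",
    cu: ClusterUnits | None = None,
    model: MatingTypeModel | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray, np.ndarray, MatingTypeModel]:
    """Score numerator S, variance V and per-unit D for one cluster.

    Variance methods:

    * ``"empirical"`` (default): sum of squared influence contributions
      psi_u = D_u + S'(p) s_u / I, which augments the naive sum(D^2) with
      the first-order effect of the EM-estimated allele frequency.  When
      no expectation depends on the estimate (all parents genotyped) it
      reduces to sum(D^2) exactly.  Without the augmentation, units whose
      expectations are centered at the within-cluster estimate (unrelated
      cases anchored by controls, missing-parent families) make the test
      conservative.
    * ``"plain"``: naive sum(D^2).
    * ``"bootstrap"``: unit-level nonparametric bootstrap with the EM
      refitted in every resample.
    """
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    cu = cu or ClusterUnits.from_table(table, cluster)
    mode = _mode_for(table, j)
    col = table.calls[:, j]
    model = model or em_mating_types(table, j, cluster, cu=cu)
    B, obs, Esum, n_contrib = _contribution_arrays(cu, col, mode, stratum)
    D = _D_from_mu(B, obs, Esum, n_contrib, model.mu)
    S = float(D.sum())

    if variance_method == "plain":
        return S, float((D**2).sum()), D, n_contrib, model

    logc = _parent_logc(cu, col, mode)
    logl, _ = _child_logl(cu, col, mode, np.ones(len(cu.child_row), dtype=bool))
    A = np.exp(logc + _seg_sum(cu, logl))
    keep = A.max(axis=1) > 0

    mts = _MT_X if mode == "X_NONPAR" else _MT_PAR
    denom = 3.0 if mode == "X_NONPAR" else 4.0
    copies = np.array([gm + gf for gm, gf in mts], dtype=float)

    if variance_method == "bootstrap":
        rng = np.random.default_rng(seed)
        U = len(D)
        Ss = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, U, size=U)
            Ab = A[idx]
            keepb = Ab.max(axis=1) > 0
            Akb = Ab[keepb]
            mu = model.mu
            if len(Akb):
                for _ in range(200):
                    W = Akb * mu
                    W /= W.sum(axis=1)[:, None]
                    mu_new = _hwe_mu(
                        min(max(float(W.mean(axis=0) @ copies / denom), 1e-12), 1 - 1e-12),
                        mode,
                    )
                    if np.max(np.abs(mu_new - mu)) < 1e-7:
                        mu = mu_new
                        break
                    mu = mu_new
            Db = _D_from_mu(B[idx].copy(), obs[idx], Esum[idx], n_contrib[idx], mu)
            Ss[b] = Db.sum()
        return S, float(Ss.var(ddof=1)), D, n_contrib, model

    if variance_method != "empirical":
        raise ValueError(f"unknown variance_method '{variance_method}'")

    # influence-function augmentation for the EM-estimated frequency;
    # requires the HWE parameterization (model.mu == hwe(p))
    p = float(min(max(model.p, 1e-6), 1 - 1e-6))
    if not np.allclose(model.mu, _hwe_mu(p, mode), atol=1e-6):
        return S, float((D**2).sum()), D, n_contrib, model
    delta = max(1e-5, 1e-3 * p * (1 - p))
    if p - 2 * delta <= 0 or p + 2 * delta >= 1:
        return S, float((D**2).sum()), D, n_contrib, model

    def ell(pv):
        out = np.full(len(D), 0.0)
        vals = A[keep] @ _hwe_mu(pv, mode)
        out[keep] = np.log(np.maximum(vals, 1e-300))
        return out

    def S_of(pv):
        return float(_D_from_mu(B.copy(), obs, Esum, n_contrib, _hwe_mu(pv, mode)).sum())

    l0, lp, lm = ell(p), ell(p + delta), ell(p - delta)
    s_u = (lp - lm) / (2 * delta)
    info = float(-((lp - 2 * l0 + lm) / delta**2).sum())
    if info <= 0:
        return S, float((D**2).sum()), D, n_contrib, model
    Sp = (S_of(p + delta) - S_of(p - delta)) / (2 * delta)
    psi = D.copy()
    psi[keep] += Sp * s_u[keep] / info
    return S, float((psi**2).sum()), D, n_contrib, model


def xapl_test(
    table: GenotypeTable,
    marker: int | str,
    cluster: str,
    stratum: Stratum = Stratum.OVERALL,
    variance_method: str = "empirical",
    n_boot: int = 2000,
    seed: int = 0,
    cu: ClusterUnits | None = None,
    model: MatingTypeModel | None = None,
) -> AssocResult:
    """Single-cluster X-APL test at one marker."""
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    mid = table.markers[j].marker_id
    if _is_monomorphic(table, j, cluster):
        return AssocResult(mid, "xapl", stratum.value, 0.0, 0.0, 0.0, 1.0,
                           note="skipped: monomorphic in cluster")
    cu = cu or ClusterUnits.from_table(table, cluster)
    S, V, D, n_contrib, model = cluster_score(
        table, j, cluster, stratum, variance_method, cu, model, n_boot, seed
    )
    Z, P = zp_from_sv(S, V)
    res = AssocResult(
        mid, "xapl", stratum.value, S, V, Z, P, n_units=int((n_contrib > 0).sum())
    )
    if V <= 0:
        res.note = "non-informative: zero variance"
        return res
    orr = transmission_or(table, j, stratum, cu=cu)
    if orr is not None:
        res.odds_ratio, res.ci_low, res.ci_high = orr[:3]
    return res


def transmission_or(
    table: GenotypeTable,
    marker: int | str,
    stratum: Stratum = Stratum.OVERALL,
    cu: ClusterUnits | None = None,
    cluster: str | None = None,
    flip_reference: bool = False,
    haldane: bool = False,
) -> tuple[float, float, float, int, int] | None:
    """Transmission odds ratio b/c from heterozygous parents with both
    parental genotypes observed, plus a 95% Woolf-type CI.

    On the non-PAR X only maternal transmissions are countable; in the PARs
    heterozygous fathers also transmit informatively.  Double-heterozygote
    PAR matings with a heterozygous child are phase-ambiguous and skipped.
    Returns None when no fully observed transmissions exist; with b or c
    zero the CI is undefined (NaN) unless ``haldane`` adds 0.5 to both.
    """
    j = marker if isinstance(marker, int) else table.marker_index(marker)
    if cu is None:
        cluster = cluster if cluster is not None else table.individuals[0].cluster
        cu = ClusterUnits.from_table(table, cluster)
    mode = _mode_for(table, j)
    col = table.calls[:, j]

    gm = np.where(cu.mother_row >= 0, col[np.clip(cu.mother_row, 0, None)], MISSING)
    gf = np.where(cu.father_row >= 0, col[np.clip(cu.father_row, 0, None)], MISSING)
    gm_c, gf_c = gm[cu.child_unit], gf[cu.child_unit]
    x = col[cu.child_row].astype(int)
    _, valid = _child_logl(cu, col, mode, np.ones(len(cu.child_row), dtype=bool))
    score = cu.child_aff & valid & _stratum_mask(cu, stratum)

    b = c = 0
    if mode == "X_NONPAR":
        dau = cu.child_sex == Sex.FEMALE
        # father's genotype is needed only to subtract a daughter's paternal allele
        sel = score & (gm_c == 1) & (~dau | ((gf_c >= 0) & (gf_c <= 1)))
        a_mat = x[sel] - np.where(dau[sel], gf_c[sel], 0)
        ok = (a_mat >= 0) & (a_mat <= 1)
        b = int((a_mat[ok] == 1).sum())
        c = int((a_mat[ok] == 0).sum())
    else:
        both = score & (gm_c >= 0) & (gf_c >= 0)
        # unambiguous decompositions of child genotype into parental draws
        for het_parent, other_g in ((gm_c, gf_c), (gf_c, gm_c)):
            sel = both & (het_parent == 1) & (other_g != 1)
            transmitted = x[sel] - other_g[sel] // 2
            ok = (transmitted >= 0) & (transmitted <= 1)
            b += int((transmitted[ok] == 1).sum())
            c += int((transmitted[ok] == 0).sum())
        sel = both & (gm_c == 1) & (gf_c == 1) & (x != 1)
        b += 2 * int((x[sel] == 2).sum())
        c += 2 * int((x[sel] == 0).sum())
    if b + c == 0:
        return None
    if flip_reference:
        b, c = c, b
    if haldane and (b == 0 or c == 0):
        bf, cf = b + 0.5, c + 0.5
    else:
        bf, cf = float(b), float(c)
    if bf == 0 or cf == 0:
        return (np.inf if cf == 0 else 0.0, np.nan, np.nan, b, c)
    orr = bf / cf
    se = np.sqrt(1.0 / bf + 1.0 / cf)
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return (float(orr), float(lo), float(hi), b, c)
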