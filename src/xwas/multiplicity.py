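"""Effective number of independent tests (simpleM) and significance
thresholds.

simpleM estimates the effective test count M_eff from the eigenvalues of
the genotype-dosage correlation matrix: within map-ordered blocks of at
most ``block_size`` markers, M_eff is the smallest number of principal
components whose eigenvalues explain at least a fraction C (default 0.995)
of the total variance; block counts sum.  Thresholds follow:

    alpha_snp         = alpha_chromosome / M_eff
    alpha_replication = sqrt(alpha_snp)

so that requiring two independent data sets to each pass
``alpha_replication`` controls the chromosome-wide error at
``alpha_chromosome``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeTable, Region, Sex, UnitKind, HET_FLAG, MISSING

DEFAULT_C = 0.995
DEFAULT_BLOCK = 1000


@dataclass
class ThresholdSet:
    m_eff: int
    alpha_chromosome: float = 0.05
    alpha_snp: float = 0.0
    alpha_replication: float = 0.0
    variance_explained: float = DEFAULT_C
    block_size: int = DEFAULT_BLOCK


def derive_thresholds(
    m_eff: int,
    alpha_chromosome: float = 0.05,
    variance_explained: float = DEFAULT_C,
    block_size: int = DEFAULT_BLOCK,
) -> ThresholdSet:
    if m_eff < 1:
        raise ValueError("M_eff must be >= 1")
    alpha_snp = alpha_chromosome / m_eff
    return ThresholdSet(
        m_eff=int(m_eff),
        alpha_chromosome=alpha_chromosome,
        alpha_snp=alpha_snp,
        alpha_replication=float(np.sqrt(alpha_snp)),
        variance_explained=variance_explained,
        block_size=block_size,
    )


def dosage_matrix(table: GenotypeTable, rows: np.ndarray | None = None) -> np.ndarray:
    """Founder/unrelated dosage matrix with males coded 0/2 at non-PAR X
    markers (dosage doubling keeps male-female mixing from attenuating
    correlations); missing and HET_FLAG entries are NaN."""
    if rows is None:
        rows = np.where(table.is_founder | (table.unit_kind != UnitKind.FAMILY_MEMBER))[0]
    d = table.calls[rows].astype(float)
    d[(d == MISSING) | (d == HET_FLAG)] = np.nan
    male = (table.sex[rows] == Sex.MALE)[:, None]
    nonpar = (table.region == Region.X_NONPAR)[None, :]
    d = np.where(male & nonpar, d * 2.0, d)
    return d


def ld_r2(
    table: GenotypeTable,
    marker_pairs=None,
    rows: np.ndarray | None = None,
) -> np.ndarray | dict:
    """Squared Pearson correlation of candidate-allele dosages.

    With ``marker_pairs=None`` returns the full (M, M) matrix
    (pairwise-complete); otherwise a dict {(i, j): r2}.  Monomorphic
    markers give NaN.
    """
    d = dosage_matrix(table, rows)
    M = d.shape[1]

    def pair_r2(i, j):
        ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
        if ok.sum() < 2:
            return np.nan
        xi, xj = d[ok, i], d[ok, j]
        si, sj = xi.std(), xj.std()
        if si == 0 or sj == 0:
            return np.nan
        r = np.corrcoef(xi, xj)[0, 1]
        return float(r * r)

    if marker_pairs is not None:
        idx = [
            (
                a if isinstance(a, int) else table.marker_index(a),
                b if isinstance(b, int) else table.marker_index(b),
            )
            for a, b in marker_pairs
        ]
        return {pair: pair_r2(*pair) for pair in idx}
    out = np.full((M, M), np.nan)
    for i in range(M):
        out[i, i] = 1.0
        for j in range(i + 1, M):
            out[i, j] = out[j, i] = pair_r2(i, j)
    return out


def simple_m_eff(
    table: GenotypeTable,
    C: float = DEFAULT_C,
    block_size: int = DEFAULT_BLOCK,
    rows: np.ndarray | None = None,
) -> int:
    """simpleM effective number of tests on founder/unrelated dosages.

    Markers split by map order into blocks of <= block_size; per block the
    missing entries are imputed to the marker mean (eigen step only), the
    correlation matrix eigendecomposed, and the block M_eff is the smallest
    k whose top-k eigenvalue sum reaches C of the total.  Zero-variance
    markers drop from the eigen step and count one test each.
    """
    if table.n_markers < 1:
        return 0
    d = dosage_matrix(table, rows)
    order = np.argsort(table.bp, kind="stable")
    total = 0
    for start in range(0, len(order), block_size):
        cols = order[start : start + block_size]
        sub = d[:, cols]
        means = np.nanmean(sub, axis=0)
        dead = ~np.isfinite(means)
        sub = np.where(np.isnan(sub), means, sub)
        sds = sub.std(axis=0)
        keep = (sds > 0) & ~dead
        total += int(dead.sum() + (~keep & ~dead).sum())  # constant markers: 1 test each
        sub = sub[:, keep]
        if sub.shape[1] == 0:
            continue
        if sub.shape[1] == 1:
            total += 1
            continue
        corr = np.corrcoef(sub, rowvar=False)
        ev = np.linalg.eigvalsh(corr)[::-1]
        ev = np.clip(ev, 0, None)
        cum = np.cumsum(ev) / ev.sum()
        total += int(np.searchsorted(cum, C - 1e-12) + 1)
    return total


def min_p_permutation_threshold(
    table: GenotypeTable,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    rows: np.ndarray | None = None,
) -> float:
    """Permutation min-P significance threshold (validation oracle).

    Random binary labels are permuted across founder/unrelated individuals;
    per permutation the minimum two-sided trend-test P over markers is
    taken, and the alpha-quantile of that min-P distribution is the
    per-marker threshold that controls the family-wise rate at alpha.
    """
    from scipy import stats as st

    rng = np.random.default_rng(seed)
    d = dosage_matrix(table, rows)
    means = np.nanmean(d, axis=0)
    keep = np.isfinite(means)
    d = np.where(np.isnan(d), means, d)[:, keep]
    sds = d.std(axis=0)
    d = d[:, sds > 0]
    n, M = d.shape
    dz = (d - d.mean(axis=0)) / d.std(axis=0)
    labels = (np.arange(n) < n // 2).astype(float)
    minp = np.empty(n_perm)
    for b in range(n_perm):
        lab = rng.permutation(labels)
        lz = (lab - lab.mean()) / lab.std()
        r = (lz @ dz) / n
        chi2 = (n - 1) * r**2  # Armitage-style trend statistic
        minp[b] = st.chi2.sf(chi2, 1).min()
    return float(np.quantile(minp, alpha))
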