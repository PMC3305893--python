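"""Synthetic X-linked cohort generator.

Emulates the data the analysis modules expect but cannot obtain from the
non-public study cohorts: nuclear families ascertained through affected
children, unrelated cases and controls with a male-skewed case sex ratio,
biallelic X SNPs in LD blocks, a sex-aware multiplicative disease model,
two-cluster allele-frequency structure, and genotyping artifacts
(missingness patterns, male-heterozygote calls, Mendel errors, batch
perturbation of controls).

Haplotypes live in non-recombining blocks: each block of ``ld_block_size``
consecutive markers holds ``n_haplotypes_per_block`` haplotypes with
Dirichlet frequencies, and every transmitted chromosome is an independent
block-wise mosaic (free recombination between blocks, none within).

Disease model: P(affected | dose, sex) = prevalence_sex * RR^dose, with
dose the candidate-allele count at the causal marker -- 0/1/2 for females
(RR = ``rr_per_allele``) and 0/1 for hemizygous males
(RR = ``male_hemizygote_rr``).

Ascertainment: affection depends on genotype only through the causal
marker, so ascertained families can be drawn exactly -- parental causal
genotypes from the analytically tilted mating-type distribution and
proband children i.i.d. from the affected-child conditional
(``ascertainment="conditional"``, the default, equivalent in distribution
to resampling families until the criterion holds).  A literal rejection
sampler (``ascertainment="rejection"``) is provided as a cross-check.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    HET_FLAG,
    MISSING,
    Affection,
    ConfigError,
    GenotypeTable,
    MarkerInfo,
    PedigreeIndividual,
    Region,
    RegionConfig,
    Sex,
    SimulationError,
    UnitKind,
)

_REJECTION_CAP = 1_000_000  # families drawn before giving up


@dataclass
class SimConfig:
    """Study-design parameters of a simulated two-cluster cohort.

    Defaults mirror the realized composition of the emulated study: 758
    singleton + 698 multiplex ASD families, 1,204 cases / 6,472 controls,
    affected male fraction 0.82 (4.6:1) and control male fraction 0.52
    (1.1:1), with a male:female penetrance ratio of 4.6.
    """

    n_singleton_families: int = 758
    n_multiplex_families: int = 698
    n_cases: int = 1204
    n_controls: int = 6472
    case_male_fraction: float = 0.82
    control_male_fraction: float = 0.52
    n_markers: int = 200
    ld_block_size: int = 5
    n_haplotypes_per_block: int = 4
    allele_freq_range: tuple[float, float] = (0.1, 0.5)
    causal_marker_index: int | None = None
    rr_per_allele: float = 1.0
    male_hemizygote_rr: float | None = None  # defaults to rr_per_allele
    baseline_prevalence_male: float = 0.015
    baseline_prevalence_female: float = 0.0032609  # 4.6:1 male:female
    cluster_freq_shift: float = 0.0
    batch_freq_perturbation: float = 0.0
    missing_base_rate: float = 0.0
    sex_differential_rate: float = 0.0
    genotype_dependent_missing_rate: float = 0.0
    male_het_error_rate: float = 0.0
    mendel_error_rate: float = 0.0
    par_fraction: float = 0.015
    seed: int = 0
    # extensions beyond the core study-design fields
    causal_allele_freq: float | None = None
    parent_missing_rate: float = 0.0
    extra_sib_rate: float = 0.3
    cluster_labels: tuple[str, str] = ("fam", "cc")
    ascertainment: str = "conditional"

    @property
    def rr_male(self) -> float:
        return self.rr_per_allele if self.male_hemizygote_rr is None else self.male_hemizygote_rr

    def validate(self) -> None:
        props = dict(
            case_male_fraction=self.case_male_fraction,
            control_male_fraction=self.control_male_fraction,
            cluster_freq_shift=self.cluster_freq_shift,
            batch_freq_perturbation=self.batch_freq_perturbation,
            missing_base_rate=self.missing_base_rate,
            sex_differential_rate=self.sex_differential_rate,
            genotype_dependent_missing_rate=self.genotype_dependent_missing_rate,
            male_het_error_rate=self.male_het_error_rate,
            mendel_error_rate=self.mendel_error_rate,
            par_fraction=self.par_fraction,
            parent_missing_rate=self.parent_missing_rate,
            extra_sib_rate=self.extra_sib_rate,
            baseline_prevalence_male=self.baseline_prevalence_male,
            baseline_prevalence_female=self.baseline_prevalence_female,
        )
        for k, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{k} = {v} outside [0, 1]")
        if self.rr_per_allele <= 0 or self.rr_male <= 0:
            raise ConfigError("relative risks must be positive")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if self.ld_block_size > self.n_markers:
            raise ConfigError("ld_block_size larger than marker count")
        if self.n_haplotypes_per_block < 2:
            raise ConfigError("need at least 2 haplotypes per block")
        lo, hi = self.allele_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ConfigError(f"allele_freq_range {self.allele_freq_range} invalid")
        if self.baseline_prevalence_female * self.rr_per_allele**2 > 1.0:
            raise ConfigError("female penetrance exceeds 1 at dose 2")
        if self.baseline_prevalence_male * self.rr_male > 1.0:
            raise ConfigError("male penetrance exceeds 1 at dose 1")
        if self.causal_marker_index is not None and not (
            0 <= self.causal_marker_index < self.n_markers
        ):
            raise ConfigError("causal_marker_index out of range")
        if self.ascertainment not in ("conditional", "rejection"):
            raise ConfigError(f"unknown ascertainment '{self.ascertainment}'")


@dataclass
class Block:
    """One LD block: haplotype alleles and frequencies per cluster."""

    start: int  # marker index range [start, stop)
    stop: int
    region: Region
    haps: np.ndarray  # (H, L) candidate-allele indicators
    freqs: np.ndarray  # cluster-1 haplotype frequencies
    freqs2: np.ndarray  # cluster-2 frequencies

    def allele_freqs(self, cluster2: bool = False) -> np.ndarray:
        f = self.freqs2 if cluster2 else self.freqs
        return f @ self.haps


@dataclass
class HaplotypePool:
    blocks: list[Block]
    n_markers: int

    def allele_freqs(self, cluster2: bool = False) -> np.ndarray:
        out = np.empty(self.n_markers)
        for b in self.blocks:
            out[b.start : b.stop] = b.allele_freqs(cluster2)
        return out

    def block_of(self, marker: int) -> Block:
        for b in self.blocks:
            if b.start <= marker < b.stop:
                return b
        raise KeyError(marker)


@dataclass
class TruthRecord:
    """Generating truth serialized alongside every simulated cohort."""

    causal_marker_id: str | None
    config: SimConfig
    true_calls: np.ndarray  # pre-artifact call matrix
    allele_freqs_cluster1: np.ndarray
    allele_freqs_cluster2: np.ndarray
    artifacts: dict = field(default_factory=dict)

    def to_manifest(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["allele_freq_range"] = list(cfg["allele_freq_range"])
        cfg["cluster_labels"] = list(cfg["cluster_labels"])
        return {
            "causal_marker_id": self.causal_marker_id,
            "config": cfg,
            "allele_freqs_cluster1": [round(float(x), 6) for x in self.allele_freqs_cluster1],
            "allele_freqs_cluster2": [round(float(x), 6) for x in self.allele_freqs_cluster2],
            "artifacts": self.artifacts,
        }


# ---------------------------------------------------------------------------
# haplotype pool
# ---------------------------------------------------------------------------


def _block_column(rng, freqs, p_target, lo, hi) -> np.ndarray | None:
    """Allele column over haplotypes whose implied frequency lies in range,
    or None when the frequency vector cannot realize one."""
    H = len(freqs)
    best, best_d = None, np.inf
    for _ in range(100):
        col = (rng.random(H) < p_target).astype(np.int8)
        implied = float(freqs @ col)
        d = abs(implied - p_target)
        if lo <= implied <= hi and d < best_d:
            best, best_d = col, d
            if d < 0.02:
                break
    return best


def _block_alleles(rng, config, length, lo, hi):
    """Haplotype frequencies plus an allele matrix for one block; redraws
    the Dirichlet frequencies when they cannot realize in-range columns."""
    H = config.n_haplotypes_per_block
    for _ in range(100):
        freqs = rng.dirichlet(np.ones(H))
        haps = np.empty((H, length), dtype=np.int8)
        ok = True
        for k in range(length):
            col = _block_column(rng, freqs, float(rng.uniform(lo, hi)), lo, hi)
            if col is None:
                ok = False
                break
            haps[:, k] = col
        if ok:
            return freqs, haps
    raise SimulationError("could not construct haplotype block within allele_freq_range")


def _tilted_freqs(rng, freqs, shift) -> np.ndarray:
    if shift == 0:
        return freqs.copy()
    w = freqs * np.exp(rng.normal(0.0, 4.0 * shift, size=len(freqs)))
    return w / w.sum()


def build_haplotype_pool(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePool:
    """Per-block haplotypes and frequencies for both clusters.

    Blocks are laid out in map order, PAR1 blocks first.  If
    ``causal_allele_freq`` is set the causal marker becomes its own
    two-haplotype block so its frequency is exact.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    M, L = config.n_markers, config.ld_block_size
    n_par = int(round(config.par_fraction * M))
    # PAR markers occupy whole leading blocks so blocks never straddle regions
    n_par = (n_par // L) * L if n_par >= L else (L if 0 < n_par and M >= 2 * L else 0)

    ci = config.causal_marker_index
    if ci is not None and ci < n_par:
        raise ConfigError("causal marker must be X_NONPAR, not in a PAR block")

    # the causal marker always gets its own two-haplotype block, so causal
    # genotypes can be sampled (and conditioned on) exactly
    edges = []
    pos = 0
    while pos < M:
        stop = min(pos + L, M)
        if ci is not None and pos <= ci < stop:
            if pos < ci:
                edges.append((pos, ci))
            edges.append((ci, ci + 1))
            if ci + 1 < stop:
                edges.append((ci + 1, stop))
        else:
            edges.append((pos, stop))
        pos = stop

    lo, hi = config.allele_freq_range
    blocks: list[Block] = []
    for start, stop in edges:
        length = stop - start
        region = Region.PAR1 if stop <= n_par else Region.X_NONPAR
        if ci is not None and start == ci and length == 1:
            p = (
                config.causal_allele_freq
                if config.causal_allele_freq is not None
                else float(rng.uniform(lo, hi))
            )
            haps = np.array([[1], [0]], dtype=np.int8)
            freqs = np.array([p, 1.0 - p])
        else:
            freqs, haps = _block_alleles(rng, config, length, lo, hi)
        freqs2 = _tilted_freqs(rng, freqs, config.cluster_freq_shift)
        blocks.append(Block(start, stop, region, haps, freqs, freqs2))
    return HaplotypePool(blocks, M)


def _marker_infos(config: SimConfig, pool: HaplotypePool) -> list[MarkerInfo]:
    regions = RegionConfig.default()
    n_par = sum(b.stop - b.start for b in pool.blocks if b.region != Region.X_NONPAR)
    par_lo, par_hi = regions.par1
    infos = []
    par_step = max((par_hi - par_lo - 2) // max(n_par, 1), 1)
    np_lo, np_hi = 3_000_000, 88_000_000
    np_step = max((np_hi - np_lo) // max(config.n_markers - n_par, 1), 1)
    for j in range(config.n_markers):
        if j < n_par:
            bp = par_lo + 1 + j * par_step
        else:
            bp = np_lo + (j - n_par) * np_step
        infos.append(
            MarkerInfo(
                marker_id=f"snp{j:05d}",
                bp=int(bp),
                allele_candidate="A",
                allele_other="G",
                region=regions.classify(int(bp)),
            )
        )
    return infos


# ---------------------------------------------------------------------------
# disease model helpers
# ---------------------------------------------------------------------------


def _penetrances(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    fm = config.baseline_prevalence_male * config.rr_male ** np.arange(2)
    ff = config.baseline_prevalence_female * config.rr_per_allele ** np.arange(3)
    return fm, ff


_T_MAT = np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 1.0]])  # P(a | g_M), a x g_M


def _mating_grid(p: float) -> np.ndarray:
    """(6,) prior over (g_M 0..2) x (father allele y 0..1) under HWE."""
    q = 1.0 - p
    hwem = np.array([q * q, 2 * p * q, p * p])
    return np.outer(hwem, [q, p]).ravel()  # index 2*g_M + y


def _child_state_table(config: SimConfig) -> np.ndarray:
    """P(sex, a | mt) unnormalized by affection: (6, 4) over states
    (son a=0, son a=1, dau a=0, dau a=1) with affection probabilities
    applied by the caller."""
    out = np.zeros((6, 4))
    for gm in range(3):
        for y in range(2):
            m = 2 * gm + y
            for a in range(2):
                out[m, a] = 0.5 * _T_MAT[a, gm]
                out[m, 2 + a] = 0.5 * _T_MAT[a, gm]
    return out


def _affected_child_dist(config: SimConfig) -> np.ndarray:
    """(6, 4) joint P(sex, maternal allele, affected | mt), pre-normalization.

    State order: son/a=0, son/a=1, daughter/a=0, daughter/a=1; the
    daughter's paternal allele is the mating type's y.
    """
    fm, ff = _penetrances(config)
    base = _child_state_table(config)
    out = base.copy()
    for gm in range(3):
        for y in range(2):
            m = 2 * gm + y
            out[m, 0] *= fm[0]
            out[m, 1] *= fm[1]
            out[m, 2] *= ff[y]
            out[m, 3] *= ff[1 + y]
    return out


def _sample_rows(rng, prob_rows: np.ndarray) -> np.ndarray:
    """Categorical draw per row of a (n, k) probability matrix."""
    c = np.cumsum(prob_rows, axis=1)
    c /= c[:, -1][:, None]
    u = rng.random((len(prob_rows), 1))
    return (u > c).sum(axis=1)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


class _HapBuilder:
    """Accumulates two haplotype vectors per individual, block-wise."""

    def __init__(self, n: int, pool: HaplotypePool) -> None:
        self.hapA = np.zeros((n, pool.n_markers), dtype=np.int8)
        self.hapB = np.zeros((n, pool.n_markers), dtype=np.int8)
        self.pool = pool

    def draw(self, rng, rows, which, cluster2=False, block=None):
        """Free pool draws for `rows` into hapA/hapB over all (or one) block."""
        target = self.hapA if which == "A" else self.hapB
        blocks = [block] if block is not None else self.pool.blocks
        for b in blocks:
            f = b.freqs2 if cluster2 else b.freqs
            idx = rng.choice(len(f), size=len(rows), p=f)
            target[np.ix_(rows, range(b.start, b.stop))] = b.haps[idx]

    def draw_conditional(self, rng, rows, which, block, allele, cluster2=False):
        """Draws from one block conditional on the causal-site allele."""
        f = block.freqs2 if cluster2 else block.freqs
        site = block.haps[:, 0] if block.stop - block.start == 1 else None
        if site is None:
            raise SimulationError("conditional draws require a singleton causal block")
        target = self.hapA if which == "A" else self.hapB
        for a in (0, 1):
            sel = np.asarray(allele) == a
            if not sel.any():
                continue
            mask = site == a
            if f[mask].sum() <= 0:
                raise SimulationError(f"no haplotype carries causal allele {a}")
            fc = f * mask
            fc = fc / fc.sum()
            idx = rng.choice(len(f), size=int(sel.sum()), p=fc)
            target[np.ix_(np.asarray(rows)[sel], range(block.start, block.stop))] = block.haps[idx]


def simulate_cohort(config: SimConfig) -> tuple[GenotypeTable, TruthRecord]:
    """Simulate families plus unrelated cases/controls; deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool = build_haplotype_pool(config, rng)
    markers = _marker_infos(config, pool)

    ci = config.causal_marker_index
    causal_block = pool.block_of(ci) if ci is not None else None
    if causal_block is not None and markers[ci].region != Region.X_NONPAR:
        raise ConfigError("causal marker must lie in the non-PAR X")

    if config.ascertainment == "rejection":
        fam = _simulate_families_rejection(config, rng, pool, causal_block)
    else:
        fam = _simulate_families_conditional(config, rng, pool, causal_block)
    unrel = _simulate_unrelateds(config, rng, pool, causal_block)

    individuals, hapA, hapB = _concat_people(fam, unrel)
    calls = _calls_from_haps(individuals, markers, hapA, hapB)

    # structurally missing parents (ungenotyped founders)
    if config.parent_missing_rate > 0:
        for r, ind in enumerate(individuals):
            if (
                ind.unit_kind == UnitKind.FAMILY_MEMBER
                and ind.is_founder
                and rng.random() < config.parent_missing_rate
            ):
                calls[r, :] = MISSING

    table = GenotypeTable(markers, individuals, calls)
    truth = TruthRecord(
        causal_marker_id=markers[ci].marker_id if ci is not None else None,
        config=config,
        true_calls=calls.copy(),
        allele_freqs_cluster1=pool.allele_freqs(False),
        allele_freqs_cluster2=pool.allele_freqs(True),
    )
    return table, truth


def _concat_people(*parts):
    individuals, hapAs, hapBs = [], [], []
    for inds, hA, hB in parts:
        individuals.extend(inds)
        hapAs.append(hA)
        hapBs.append(hB)
    return individuals, np.concatenate(hapAs), np.concatenate(hapBs)


def _calls_from_haps(individuals, markers, hapA, hapB) -> np.ndarray:
    sex = np.array([int(i.sex) for i in individuals], dtype=np.int8)
    region = np.array([int(m.region) for m in markers], dtype=np.int8)
    calls = (hapA + hapB).astype(np.int8)
    male = sex == Sex.MALE
    nonpar = region == Region.X_NONPAR
    # hemizygous males: the maternal/X haplotype is the genotype
    calls[np.ix_(male, nonpar)] = hapA[np.ix_(male, nonpar)]
    return calls


def _family_members(config, rng, pool, causal_block, gm, y, packed):
    """Assemble haplotypes and pedigree records for pre-sampled families.

    gm, y: maternal causal genotype and paternal causal allele per family.
    packed: flat (child_fam, sex, maternal causal allele, affected) arrays.
    """
    (child_fam, sexes, alleles, affected) = packed
    n_fam = len(gm)
    n_children = len(child_fam)
    label = config.cluster_labels[0]

    individuals: list[PedigreeIndividual] = []
    n_total = 2 * n_fam + n_children
    hb = _HapBuilder(n_total, pool)
    mo_rows = np.arange(n_fam) * 2
    fa_rows = mo_rows + 1
    ch_rows = 2 * n_fam + np.arange(n_children)

    # free draws everywhere, then overwrite the causal block conditionally
    hb.draw(rng, mo_rows, "A")
    hb.draw(rng, mo_rows, "B")
    hb.draw(rng, fa_rows, "A")
    hb.draw(rng, fa_rows, "B")

    if causal_block is not None:
        # mother: two draws with allele pair implied by her genotype (order
        # randomized so transmissions are exchangeable)
        first = np.where(gm == 1, rng.integers(0, 2, n_fam), (gm == 2).astype(int))
        second = gm - first
        hb.draw_conditional(rng, mo_rows, "A", causal_block, first)
        hb.draw_conditional(rng, mo_rows, "B", causal_block, second)
        hb.draw_conditional(rng, fa_rows, "A", causal_block, y)

    # transmissions, block by block
    mo_of = mo_rows[child_fam]
    fa_of = fa_rows[child_fam]
    is_dau = sexes == Sex.FEMALE
    for b in pool.blocks:
        cols = range(b.start, b.stop)
        if causal_block is not None and b is causal_block:
            # transmit the maternal haplotype carrying the child's sampled
            # causal allele; a coin flip when both carry the same allele
            mA = hb.hapA[np.ix_(mo_of, cols)][:, 0]
            mB = hb.hapB[np.ix_(mo_of, cols)][:, 0]
            a = np.asarray(alleles)
            pick_B = np.where(mA != mB, mB == a, rng.random(n_children) < 0.5)
        else:
            pick_B = rng.random(n_children) < 0.5
        src = np.where(pick_B[:, None], hb.hapB[np.ix_(mo_of, cols)], hb.hapA[np.ix_(mo_of, cols)])
        hb.hapA[np.ix_(ch_rows, cols)] = src
        if b.region == Region.X_NONPAR:
            pat = hb.hapA[np.ix_(fa_of, cols)]
            pat = np.where(is_dau[:, None], pat, 0)
        else:
            pickf = rng.random(n_children) < 0.5
            pat = np.where(
                pickf[:, None], hb.hapB[np.ix_(fa_of, cols)], hb.hapA[np.ix_(fa_of, cols)]
            )
        hb.hapB[np.ix_(ch_rows, cols)] = pat

    child_counter = np.zeros(n_fam, dtype=int)
    rows_order = np.empty(n_total, dtype=int)
    k = 0
    for i in range(n_fam):
        fid = f"{label}_F{i:05d}"
        individuals.append(PedigreeIndividual("mo", fid, sex=Sex.FEMALE, cluster=label))
        individuals.append(PedigreeIndividual("fa", fid, sex=Sex.MALE, cluster=label))
        rows_order[k] = mo_rows[i]
        rows_order[k + 1] = fa_rows[i]
        k += 2
    for c in range(n_children):
        i = child_fam[c]
        fid = f"{label}_F{i:05d}"
        child_counter[i] += 1
        individuals.append(
            PedigreeIndividual(
                f"c{child_counter[i]}",
                fid,
                father_id="fa",
                mother_id="mo",
                sex=Sex(int(sexes[c])),
                affection=Affection.AFFECTED if affected[c] else Affection.UNAFFECTED,
                cluster=label,
            )
        )
        rows_order[k] = ch_rows[c]
        k += 1
    return individuals, hb.hapA[rows_order], hb.hapB[rows_order]


def _causal_freq(config, pool, causal_block, cluster2=False):
    if causal_block is None:
        return 0.0
    f = causal_block.freqs2 if cluster2 else causal_block.freqs
    return float(f @ causal_block.haps[:, 0])


def _simulate_families_conditional(config, rng, pool, causal_block):
    """Exact sampler for ascertained families (see module docstring)."""
    fm, ff = _penetrances(config)
    p = _causal_freq(config, pool, causal_block)
    prior = _mating_grid(p)
    aff_tab = _affected_child_dist(config)  # (6,4)
    alpha = aff_tab.sum(axis=1)  # P(child affected | mt)
    if np.all(alpha <= 0):
        raise SimulationError("zero penetrance: ascertainment unattainable")

    def draw_families(n, k):
        tilt = prior * alpha**k
        if tilt.sum() <= 0:
            raise SimulationError("ascertainment unattainable for this config")
        mt = rng.choice(6, size=n, p=tilt / tilt.sum())
        gm, y = mt // 2, mt % 2
        fams, sexes, alleles, affected = [], [], [], []
        for child in range(k):
            st = _sample_rows(rng, aff_tab[mt])
            fams.append(np.arange(n))
            sexes.append(np.where(st < 2, Sex.MALE, Sex.FEMALE))
            alleles.append(st % 2)
            affected.append(np.ones(n, dtype=bool))
        # unascertained extra siblings
        has_sib = rng.random(n) < config.extra_sib_rate
        if has_sib.any():
            idx = np.where(has_sib)[0]
            base = _child_state_table(config)[mt[idx]]
            st = _sample_rows(rng, base)
            sexes_s = np.where(st < 2, Sex.MALE, Sex.FEMALE)
            alleles_s = st % 2
            dose = np.where(
                sexes_s == Sex.MALE, alleles_s, alleles_s + y[idx]
            )
            pen = np.where(sexes_s == Sex.MALE, fm[np.minimum(dose, 1)], ff[dose])
            aff_s = rng.random(len(idx)) < pen
            fams.append(idx)
            sexes.append(sexes_s)
            alleles.append(alleles_s)
            affected.append(aff_s)
        child_fam = np.concatenate(fams)
        order = np.argsort(child_fam, kind="stable")
        packed = (
            child_fam[order],
            np.concatenate(sexes)[order],
            np.concatenate(alleles)[order],
            np.concatenate(affected)[order],
        )
        return gm, y, packed

    parts = []
    offset = 0
    for n, k in ((config.n_singleton_families, 1), (config.n_multiplex_families, 2)):
        if n == 0:
            continue
        gm, y, packed = draw_families(n, k)
        inds, hA, hB = _family_members(config, rng, pool, causal_block, gm, y, packed)
        # family ids must not collide between the two family kinds
        for ind in inds:
            ind.family_id = f"{ind.family_id}_{'s' if k == 1 else 'm'}"
        parts.append((inds, hA, hB))
        offset += n
    if not parts:
        return [], np.zeros((0, pool.n_markers), np.int8), np.zeros((0, pool.n_markers), np.int8)
    return _concat_people(*parts)


def _simulate_families_rejection(config, rng, pool, causal_block):
    """Literal resample-until-ascertained reference sampler (slow)."""
    fm, ff = _penetrances(config)
    p = _causal_freq(config, pool, causal_block)
    prior = _mating_grid(p)
    base_tab = _child_state_table(config)

    def attempt(n, k):
        mt = rng.choice(6, size=n, p=prior / prior.sum())
        gm, y = mt // 2, mt % 2
        sexes = np.empty((k, n), dtype=np.int8)
        alleles = np.empty((k, n), dtype=np.int8)
        affected = np.empty((k, n), dtype=bool)
        for child in range(k):
            st = _sample_rows(rng, base_tab[mt])
            sexes[child] = np.where(st < 2, Sex.MALE, Sex.FEMALE)
            alleles[child] = st % 2
            dose = np.where(sexes[child] == Sex.MALE, alleles[child], alleles[child] + y)
            pen = np.where(sexes[child] == Sex.MALE, fm[np.minimum(dose, 1)], ff[dose])
            affected[child] = rng.random(n) < pen
        ok = affected.sum(axis=0) >= k
        return gm, y, sexes, alleles, affected, ok

    def collect(n_needed, k):
        got_gm, got_y = [], []
        got_children = []
        drawn = 0
        while sum(len(g) for g in got_gm) < n_needed:
            batch = max(2048, n_needed)
            drawn += batch
            if drawn > _REJECTION_CAP:
                raise SimulationError(
                    "ascertainment not met within the retry cap; "
                    "check prevalence and relative risk"
                )
            gm, y, sexes, alleles, affected, ok = attempt(batch, k)
            got_gm.append(gm[ok])
            got_y.append(y[ok])
            got_children.append((sexes[:, ok], alleles[:, ok], affected[:, ok]))
        gm = np.concatenate(got_gm)[:n_needed]
        y = np.concatenate(got_y)[:n_needed]
        sexes = np.concatenate([c[0] for c in got_children], axis=1)[:, :n_needed]
        alleles = np.concatenate([c[1] for c in got_children], axis=1)[:, :n_needed]
        affected = np.concatenate([c[2] for c in got_children], axis=1)[:, :n_needed]
        n = n_needed
        child_fam = np.repeat(np.arange(n)[None, :], k, axis=0).ravel()
        order = np.argsort(child_fam, kind="stable")
        packed = (
            child_fam[order],
            sexes.ravel()[order],
            alleles.ravel()[order],
            affected.ravel()[order],
        )
        return gm, y, packed

    parts = []
    for n, k in ((config.n_singleton_families, 1), (config.n_multiplex_families, 2)):
        if n == 0:
            continue
        gm, y, packed = collect(n, k)
        inds, hA, hB = _family_members(config, rng, pool, causal_block, gm, y, packed)
        for ind in inds:
            ind.family_id = f"{ind.family_id}_{'s' if k == 1 else 'm'}"
        parts.append((inds, hA, hB))
    if not parts:
        return [], np.zeros((0, pool.n_markers), np.int8), np.zeros((0, pool.n_markers), np.int8)
    return _concat_people(*parts)


def _simulate_unrelateds(config, rng, pool, causal_block):
    """Cases conditional on affection, controls on its complement."""
    fm, ff = _penetrances(config)
    p2 = _causal_freq(config, pool, causal_block, cluster2=True)
    q2 = 1.0 - p2
    hwe2 = np.array([q2 * q2, 2 * p2 * q2, p2 * p2])
    hwe1 = np.array([q2, p2])
    label = config.cluster_labels[1]

    groups = []
    for kind, n_total, male_frac in (
        (UnitKind.UNRELATED_CASE, config.n_cases, config.case_male_fraction),
        (UnitKind.UNRELATED_CONTROL, config.n_controls, config.control_male_fraction),
    ):
        n_male = int(round(n_total * male_frac))
        for sex, n in ((Sex.MALE, n_male), (Sex.FEMALE, n_total - n_male)):
            if n == 0:
                continue
            pen = fm if sex == Sex.MALE else ff
            base = hwe1 if sex == Sex.MALE else hwe2
            w = base * (pen if kind == UnitKind.UNRELATED_CASE else (1.0 - pen))
            if causal_block is None:
                w = base.copy()
            if w.sum() <= 0:
                raise SimulationError("unattainable case/control sampling")
            dose = rng.choice(len(w), size=n, p=w / w.sum())
            groups.append((kind, sex, dose))

    n_total = sum(len(d) for _, _, d in groups)
    hb = _HapBuilder(n_total, pool)
    individuals: list[PedigreeIndividual] = []
    row = 0
    counters = {UnitKind.UNRELATED_CASE: 0, UnitKind.UNRELATED_CONTROL: 0}
    for kind, sex, dose in groups:
        rows = np.arange(row, row + len(dose))
        hb.draw(rng, rows, "A", cluster2=True)
        hb.draw(rng, rows, "B", cluster2=True)
        if causal_block is not None:
            if sex == Sex.MALE:
                hb.draw_conditional(rng, rows, "A", causal_block, dose, cluster2=True)
            else:
                first = np.where(dose == 1, rng.integers(0, 2, len(dose)), (dose == 2).astype(int))
                hb.draw_conditional(rng, rows, "A", causal_block, first, cluster2=True)
                hb.draw_conditional(rng, rows, "B", causal_block, dose - first, cluster2=True)
        tag = "CASE" if kind == UnitKind.UNRELATED_CASE else "CTRL"
        for _ in rows:
            counters[kind] += 1
            iid = f"{tag}{counters[kind]:05d}"
            ind = PedigreeIndividual(
                iid,
                iid,
                sex=sex,
                affection=Affection.AFFECTED
                if kind == UnitKind.UNRELATED_CASE
                else Affection.UNAFFECTED,
                cluster=label,
            )
            ind.unit_kind = kind
            individuals.append(ind)
        row += len(dose)
    return individuals, hb.hapA, hb.hapB


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------


def inject_artifacts(
    table: GenotypeTable,
    config: SimConfig,
    seed: int,
    truth: TruthRecord | None = None,
    sex_missing_markers: list[int] | None = None,
    genotype_missing_markers: list[int] | None = None,
) -> GenotypeTable:
    """Apply genotyping artifacts in a fixed order; returns a new table.

    Order: uniform missingness, sex-differential missingness (extra male
    missingness on a designated subset), genotype-dependent missingness
    (non-reference calls preferentially masked), male heterozygote call
    errors, child-genotype Mendel corruption, and batch perturbation of
    control allele labels in the case-control cluster.
    """
    for rate in (
        config.missing_base_rate,
        config.sex_differential_rate,
        config.genotype_dependent_missing_rate,
        config.male_het_error_rate,
        config.mendel_error_rate,
        config.batch_freq_perturbation,
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"artifact rate {rate} outside [0, 1]")

    rng = np.random.default_rng(seed)
    out = table.copy()
    calls = out.calls
    n, M = calls.shape
    male = out.sex == Sex.MALE
    nonpar = out.region == Region.X_NONPAR
    called = calls != MISSING

    def pick_markers(fraction=0.1):
        k = max(1, int(round(fraction * M)))
        return sorted(rng.choice(M, size=min(k, M), replace=False).tolist())

    if config.missing_base_rate > 0:
        mask = called & (rng.random((n, M)) < config.missing_base_rate)
        calls[mask] = MISSING

    sd_markers = []
    if config.sex_differential_rate > 0:
        sd_markers = (
            sex_missing_markers if sex_missing_markers is not None else pick_markers()
        )
        mask = np.zeros((n, M), dtype=bool)
        mask[np.ix_(male, sd_markers)] = True
        mask &= (calls != MISSING) & (rng.random((n, M)) < config.sex_differential_rate)
        calls[mask] = MISSING

    gd_markers = []
    if config.genotype_dependent_missing_rate > 0:
        gd_markers = (
            genotype_missing_markers
            if genotype_missing_markers is not None
            else pick_markers()
        )
        carrier = np.zeros((n, M), dtype=bool)
        carrier[:, gd_markers] = np.isin(calls[:, gd_markers], (1, 2))
        mask = carrier & (rng.random((n, M)) < config.genotype_dependent_missing_rate)
        calls[mask] = MISSING

    if config.male_het_error_rate > 0:
        target = np.zeros((n, M), dtype=bool)
        target[np.ix_(male, nonpar)] = True
        target &= calls != MISSING
        mask = target & (rng.random((n, M)) < config.male_het_error_rate)
        calls[mask] = HET_FLAG

    if config.mendel_error_rate > 0:
        child = np.array([not i.is_founder for i in out.individuals])
        target = np.zeros((n, M), dtype=bool)
        target[child, :] = True
        target &= (calls != MISSING) & (calls != HET_FLAG)
        mask = target & (rng.random((n, M)) < config.mendel_error_rate)
        hemi = np.zeros((n, M), dtype=bool)
        hemi[np.ix_(male, nonpar)] = True
        flip_hemi = mask & hemi
        calls[flip_hemi] = 1 - calls[flip_hemi]
        dip = mask & ~hemi
        shift = rng.integers(1, 3, size=int(dip.sum()))
        calls[dip] = ((calls[dip] + shift) % 3).astype(np.int8)

    if config.batch_freq_perturbation > 0:
        ctrl = out.unit_kind == UnitKind.UNRELATED_CONTROL
        direction = rng.random(M) < 0.5  # per-marker: True = toward candidate
        rows = np.where(ctrl)[0]
        sub = calls[np.ix_(rows, range(M))]
        hemi = np.zeros((len(rows), M), dtype=bool)
        hemi[male[rows], :] = nonpar
        chroms = np.where(hemi, 1, 2)
        for c in range(2):
            has_chrom = chroms > c
            # allele on this chromosome: candidate iff copies remain
            cand_here = (sub - c) > 0
            flip = has_chrom & (rng.random(sub.shape) < config.batch_freq_perturbation)
            inc = flip & ~cand_here & direction[None, :] & (sub >= 0)
            dec = flip & cand_here & ~direction[None, :] & (sub >= 0)
            sub = np.where(inc, sub + 1, sub)
            sub = np.where(dec, sub - 1, sub)
        sub = np.clip(sub, -1, 3).astype(np.int8)
        sub[calls[np.ix_(rows, range(M))] == MISSING] = MISSING
        sub[calls[np.ix_(rows, range(M))] == HET_FLAG] = HET_FLAG
        calls[rows, :] = sub

    out._cache.clear()
    if truth is not None:
        truth.artifacts = {
            "sex_differential_markers": [int(i) for i in sd_markers],
            "genotype_dependent_markers": [int(i) for i in gd_markers],
            "seed": int(seed),
        }
    return out


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------


def make_fixture_suite(out_dir) -> dict[str, dict]:
    """Write small deterministic PED/MAP fixtures with QC-outcome manifests.

    Each fixture directory holds ``fix.ped``, ``fix.map`` and
    ``manifest.json`` listing the planted defects QC is expected to find.
    Regeneration is byte-identical (fixed seeds, fixed ordering).
    """
    from . import pedio

    out_dir = Path(out_dir)
    manifests: dict[str, dict] = {}

    base = SimConfig(
        n_singleton_families=20,
        n_multiplex_families=0,
        n_cases=0,
        n_controls=0,
        n_markers=40,
        ld_block_size=4,
        allele_freq_range=(0.2, 0.5),
        par_fraction=0.1,
        extra_sib_rate=0.0,
        seed=11,
    )

    def emit(name, table, manifest):
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        pedio.write_ped_map(table, d / "fix.ped", d / "fix.map")
        manifest["fixture"] = name
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        manifests[name] = manifest

    clean, _ = simulate_cohort(base)
    emit("clean", clean, {"expected_removals": []})

    multi, _ = simulate_cohort(
        dataclasses.replace(base, n_singleton_families=0, n_multiplex_families=6, seed=12)
    )
    emit("multiplex", multi, {"expected_removals": []})

    # planted Mendel errors: one family with 5 errors across 5 SNPs
    # (5/60 > 2%; the other planted families stay at 1/60 < 2%), and one
    # SNP with errors in 3 of 30 families (10% > 4%; the single-error SNPs
    # stay at 1/30 < 4%)
    mend, _ = simulate_cohort(
        dataclasses.replace(base, n_singleton_families=30, n_markers=60, seed=13)
    )
    rows = mend.row_index()
    nonpar_js = [j for j in range(mend.n_markers) if mend.markers[j].region == Region.X_NONPAR]
    bad_snp = nonpar_js[-1]
    fam_ids = sorted({i.family_id for i in mend.individuals})
    bad_fam = fam_ids[0]
    for j in nonpar_js[:5]:
        mend.calls[rows[(bad_fam, "mo")], j] = 0
        mend.calls[rows[(bad_fam, "c1")], j] = (
            1 if mend.individuals[rows[(bad_fam, "c1")]].sex == Sex.MALE else 2
        )
    for fam in fam_ids[1:4]:
        mend.calls[rows[(fam, "mo")], bad_snp] = 0
        mend.calls[rows[(fam, "c1")], bad_snp] = (
            1 if mend.individuals[rows[(fam, "c1")]].sex == Sex.MALE else 2
        )
    emit(
        "mendel",
        mend,
        {
            "expected_removals": [
                {"entity": "family", "id": bad_fam, "rule": "mendel_family_rate"},
                {"entity": "snp", "id": mend.markers[bad_snp].marker_id, "rule": "mendel_snp_rate"},
            ]
        },
    )

    # planted male-heterozygote SNP: >1% of males HET at one SNP; a second
    # SNP with a single flagged male (of >100) survives with that call set
    # to missing
    mh, _ = simulate_cohort(dataclasses.replace(base, n_singleton_families=120, seed=14))
    male_rows = [r for r, i in enumerate(mh.individuals) if i.sex == Sex.MALE]
    nonpar_js = [j for j in range(mh.n_markers) if mh.markers[j].region == Region.X_NONPAR]
    removed_j, kept_j = nonpar_js[2], nonpar_js[3]
    for r in male_rows[:4]:
        mh.calls[r, removed_j] = HET_FLAG
    mh.calls[male_rows[5], kept_j] = HET_FLAG
    emit(
        "male_het",
        mh,
        {
            "expected_removals": [
                {"entity": "snp", "id": mh.markers[removed_j].marker_id, "rule": "male_het_fraction"}
            ],
            "resolved_het_snp": mh.markers[kept_j].marker_id,
        },
    )

    # planted sex-differential missingness: 6% of males missing at one SNP
    # (above the 2.5% per-sex limit while overall call rate stays >= 95%)
    sm, _ = simulate_cohort(dataclasses.replace(base, n_singleton_families=60, seed=15))
    male_rows = [r for r, i in enumerate(sm.individuals) if i.sex == Sex.MALE]
    nonpar_js = [j for j in range(sm.n_markers) if sm.markers[j].region == Region.X_NONPAR]
    sd_j = nonpar_js[4]
    k = max(1, int(round(0.06 * len(male_rows))))
    for r in male_rows[:k]:
        sm.calls[r, sd_j] = MISSING
    emit(
        "sex_missing",
        sm,
        {
            "expected_removals": [
                {"entity": "snp", "id": sm.markers[sd_j].marker_id, "rule": "per_sex_missingness"}
            ]
        },
    )

    joint, _ = simulate_cohort(
        dataclasses.replace(
            base, n_singleton_families=15, n_cases=30, n_controls=60, seed=16
        )
    )
    emit("two_cluster", joint, {"expected_removals": []})

    with open(out_dir / "suite_manifest.json", "w") as fh:
        json.dump(manifests, fh, indent=1, sort_keys=True)
    return manifests
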