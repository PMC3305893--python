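"""Monte-Carlo power and type-I error engine.

Per replicate a cohort is simulated under a :class:`SimConfig`, the
requested test (family X-APL, case-control allelic, or cluster-stratified
joint) is run at the causal marker, and the rejection fraction at the
requested alpha is reported with its binomial standard error.

For null calibration at scale, :func:`null_panel_rejection` exploits the
block structure of the generator: markers in distinct blocks are
independent, so a cohort simulated with ``ld_block_size=1`` yields one
independent replicate of the test statistic per marker (conditional on the
pedigree design), at a fraction of the cost of re-simulating cohorts.

The replication procedure's family-wise error has its own simulation mode:
two sets of M independent uniform P values per replicate, declaring
replication when both fall below the threshold at the same index
(closed form: 1 - (1 - t^2)^M).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .cc import allelic_test, genomic_control
from .combine import joint_test
from .family import ClusterUnits, Stratum, xapl_test
from .simulate import SimConfig, simulate_cohort


@dataclass
class PowerResult:
    """Rejection-rate estimate for one scenario."""

    config: SimConfig
    alpha: float
    test: str
    stratum: str
    replicates: int
    rejections: int
    power: float
    se: float
    seed: int
    n_noninformative: int = 0
    warning: str = ""


def _run_test(table, config, test, stratum, marker):
    fam_label, cc_label = config.cluster_labels
    if test == "family":
        return xapl_test(table, marker, fam_label, stratum)
    if test == "cc":
        return allelic_test(table, marker, stratum)
    if test == "joint":
        clusters = [c for c in (fam_label, cc_label) if (table.cluster == c).any()]
        return joint_test(table, marker, clusters, stratum)
    raise ValueError(f"unknown test '{test}'")


def _power_loop(config, alpha, test, stratum, R, seed) -> PowerResult:
    if R < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=R)
    marker = config.causal_marker_index if config.causal_marker_index is not None else 0
    rejections = 0
    noninf = 0
    for b in range(R):
        cfg = dataclasses.replace(config, seed=int(rep_seeds[b]))
        table, _ = simulate_cohort(cfg)
        res = _run_test(table, cfg, test, stratum, marker)
        if not getattr(res, "informative", True) or "non-informative" in getattr(res, "note", ""):
            noninf += 1
            continue
        if res.P < alpha:
            rejections += 1
    power = rejections / R
    se = float(np.sqrt(power * (1 - power) / R))
    out = PowerResult(config, alpha, test, stratum.value, R, rejections, power, se, seed,
                      n_noninformative=noninf)
    if noninf > 0.1 * R:
        out.warning = f"{noninf}/{R} replicates non-informative"
    return out


def estimate_power(
    config: SimConfig,
    alpha: float,
    test: str = "joint",
    stratum: Stratum = Stratum.OVERALL,
    R: int = 500,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power for a causal-marker scenario."""
    if R < 50:
        raise ValueError("R >= 50 required for a meaningful power estimate")
    if config.causal_marker_index is None:
        raise ValueError("power scenarios need a causal marker")
    return _power_loop(config, alpha, test, stratum, R, seed)


def estimate_type1(
    config_null: SimConfig,
    alpha: float,
    test: str = "joint",
    stratum: Stratum = Stratum.OVERALL,
    R: int = 2000,
    seed: int = 0,
) -> PowerResult:
    """Type-I error under a null (RR = 1) configuration."""
    if config_null.rr_per_allele != 1.0 or config_null.rr_male != 1.0:
        raise ValueError("type-I scenarios require RR = 1")
    return _power_loop(config_null, alpha, test, stratum, R, seed)


def null_panel_rejection(
    config: SimConfig,
    test: str = "family",
    stratum: Stratum = Stratum.OVERALL,
    alpha: float = 0.05,
    n_cohorts: int = 4,
    seed: int = 0,
    apply_gc: bool = False,
    pool_frequencies: bool = False,
) -> tuple[int, int, np.ndarray, np.ndarray]:
    """Null rejection count over many independent markers (see module doc).

    Returns (rejections, n_tests, P values, Z values).  ``apply_gc``
    genomic-controls the case-control chi-squares panel-wide first;
    ``pool_frequencies`` runs the joint test in its naive pooled mode.
    """
    if config.rr_per_allele != 1.0 or config.rr_male != 1.0:
        raise ValueError("null panels require RR = 1")
    rng = np.random.default_rng(seed)
    ps, zs = [], []
    fam_label, cc_label = config.cluster_labels
    for c in range(n_cohorts):
        cfg = dataclasses.replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        table, _ = simulate_cohort(cfg)
        cus = {}
        for label in (fam_label, cc_label):
            if (table.cluster == label).any():
                cus[label] = ClusterUnits.from_table(table, label)
        chi2s, ors = [], []
        for j in range(table.n_markers):
            if test == "family":
                r = xapl_test(table, j, fam_label, stratum, cu=cus.get(fam_label))
                if r.informative:
                    ps.append(r.P)
                    zs.append(r.Z)
            elif test == "cc":
                r = allelic_test(table, j, stratum)
                if r.informative:
                    chi2s.append(r.V)
                    ors.append(r.odds_ratio)
                    ps.append(r.P)
                    zs.append(r.Z)
            elif test == "joint":
                clusters = [c_ for c_ in (fam_label, cc_label) if c_ in cus]
                try:
                    r = joint_test(table, j, clusters, stratum, cus=cus,
                                   pool_frequencies=pool_frequencies)
                except Exception:
                    continue
                if "non-informative" not in r.note:
                    ps.append(r.P)
                    zs.append(r.Z)
            else:
                raise ValueError(f"unknown test '{test}'")
        if test == "cc" and apply_gc and chi2s:
            gc = genomic_control(np.asarray(chi2s))
            # replace this cohort's P values with GC-corrected ones
            ps[-len(chi2s):] = list(gc.corrected_p)
            zs[-len(chi2s):] = [
                float(np.sign(np.log(o)) * np.sqrt(x)) if np.isfinite(o) and o > 0 else 0.0
                for o, x in zip(ors, gc.corrected_chi2)
            ]
    ps_arr = np.asarray(ps)
    zs_arr = np.asarray(zs)
    return int((ps_arr < alpha).sum()), len(ps_arr), ps_arr, zs_arr


def replication_fwer(
    M: int = 8000,
    threshold: float = 0.0025,
    R: int = 2000,
    seed: int = 0,
    chunk: int = 200,
) -> PowerResult:
    """Family-wise error of the two-data-set replication rule by simulation.

    Each replicate draws M independent null P values for discovery and
    validation; a marker replicates when both are below the threshold.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < R:
        b = min(chunk, R - done)
        disc = rng.random((b, M)) < threshold
        val = rng.random((b, M)) < threshold
        hits += int((disc & val).any(axis=1).sum())
        done += b
    fwer = hits / R
    cfg = SimConfig(n_singleton_families=0, n_multiplex_families=0, n_cases=0,
                    n_controls=0, n_markers=M, ld_block_size=1, extra_sib_rate=0.0)
    return PowerResult(cfg, threshold, "replication", "overall", R, hits, fwer,
                       float(np.sqrt(fwer * (1 - fwer) / R)), seed)


def replication_fwer_closed_form(M: int = 8000, threshold: float = 0.0025) -> float:
    """1 - (1 - t^2)^M."""
    return float(1.0 - (1.0 - threshold**2) ** M)
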