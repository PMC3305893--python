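"""End-to-end discovery -> validation -> meta/joint -> candidate-gene
workflow.

The pipeline mirrors a multi-cohort X-chromosome study design: per-data-set
QC, family-based X-APL association in each family cohort, GC-corrected
allelic tests in the case-control cohort, a discovery statistic combining
the family cohorts (cluster-summed), validation from the case-control
cohort, meta- and joint analysis restricted to markers surviving QC in
every data set, simpleM-derived significance thresholds, replication
verdicts and the candidate-gene screen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cc import allelic_test, genomic_control
from .combine import (
    cc_signed_z,
    candidate_gene_screen,
    joint_test,
    meta_combine,
    replication_assess,
)
from .core import (
    Affection,
    GenotypeTable,
    Region,
    RegionConfig,
    Sex,
    UnitKind,
    XwasError,
)
from .family import ClusterUnits, Stratum, xapl_test
from .multiplicity import ThresholdSet, derive_thresholds, simple_m_eff
from .pedio import read_gene_intervals, read_ped_map, annotate_genes
from .qc import QCThresholds, run_qc

log = logging.getLogger("xwas.pipeline")

STRATA = (Stratum.OVERALL, Stratum.MALE, Stratum.FEMALE)


@dataclass
class RunManifest:
    """Reproducibility record referenced by every pipeline output."""

    config_hash: str
    seed: int
    version: str
    input_digests: dict = field(default_factory=dict)
    steps: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @property
    def manifest_id(self) -> str:
        return self.config_hash[:12]

    def record(self, step: str, rows_in: int, rows_out: int) -> None:
        self.steps.append({"step": step, "rows_in": rows_in, "rows_out": rows_out})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _flip_candidate(table: GenotypeTable, j: int) -> None:
    """Swap candidate/other allele of marker j, recoding calls in place."""
    m = table.markers[j]
    m.allele_candidate, m.allele_other = m.allele_other, m.allele_candidate
    col = table.calls[:, j]
    male = table.sex == Sex.MALE
    hemi = male & (int(table.region[j]) == Region.X_NONPAR)
    g = col.copy()
    sw2 = {0: 2, 1: 1, 2: 0}
    for a, b in sw2.items():
        col[(~hemi) & (g == a)] = b
    col[hemi & (g == 0)] = 1
    col[hemi & (g == 1)] = 0
    table._cache.clear()


def merge_tables(tables: list[GenotypeTable], marker_ids: list[str]) -> GenotypeTable:
    """Stack data sets over a shared marker list, aligning candidate
    alleles to the first table's choice."""
    ref = tables[0]
    ref_idx = {m.marker_id: k for k, m in enumerate(ref.markers)}
    merged_markers = [
        dataclasses.replace(ref.markers[ref_idx[mid]], gene_ids=list(ref.markers[ref_idx[mid]].gene_ids))
        for mid in marker_ids
    ]
    parts = []
    individuals = []
    for t in tables:
        sub = t.subset_markers([t.marker_index(mid) for mid in marker_ids])
        for k, mid in enumerate(marker_ids):
            mm = sub.markers[k]
            refm = merged_markers[k]
            if mm.allele_candidate == refm.allele_candidate:
                continue
            if (
                mm.allele_candidate == refm.allele_other
                and mm.allele_other == refm.allele_candidate
            ):
                _flip_candidate(sub, k)
            elif refm.allele_other == "N" or mm.allele_other == "N":
                # monomorphic in one set: counts are comparable only if the
                # observed allele matches either label; be strict
                raise XwasError(
                    f"marker {mid}: monomorphic allele labels cannot be aligned"
                )
            else:
                raise XwasError(f"marker {mid}: allele labels incompatible")
        parts.append(sub.calls)
        individuals.extend(sub.individuals)
    return GenotypeTable(merged_markers, individuals, np.vstack(parts))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the full workflow; returns a bundle of data frames.

    Config keys: ``datasets`` (list of {name, ped, map, kind}), optional
    ``regions`` (YAML path), ``qc_thresholds`` (mapping), ``candidate_genes``
    (BED path), ``candidate_gene_ids`` (list), ``flank_bp``, ``simplem``
    ({C, block_size}), ``alpha_chromosome``, ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seed=int(config.get("seed", 0)),
        version=__version__,
    )

    region_cfg = (
        RegionConfig.from_yaml(config["regions"]) if config.get("regions") else RegionConfig.default()
    )
    qc_th = QCThresholds(**config.get("qc_thresholds", {}))

    datasets = config["datasets"]
    if not any(d.get("kind", "family") == "family" for d in datasets):
        raise XwasError("pipeline needs at least one family data set")

    tables: dict[str, GenotypeTable] = {}
    qc_reports = {}
    kinds: dict[str, str] = {}
    for ds in datasets:
        name = ds["name"]
        kinds[name] = ds.get("kind", "family")
        t = read_ped_map(ds["ped"], ds["map"], region_cfg, cluster_label=name)
        manifest.input_digests[name] = {
            "ped": _digest(ds["ped"]), "map": _digest(ds["map"])
        }
        n0 = t.n_individuals * t.n_markers
        t_qc, rep = run_qc(t, qc_th)
        qc_reports[name] = rep
        manifest.record(f"qc:{name}", n0, t_qc.n_individuals * t_qc.n_markers)
        log.info(
            "%s: QC kept %d/%d individuals, %d/%d markers",
            name, t_qc.n_individuals, t.n_individuals, t_qc.n_markers, t.n_markers,
        )
        for r in rep.removals:
            log.info("%s removal: %s %s by %s", name, r.entity, r.entity_id, r.rule)
        tables[name] = t_qc

    # overlap restriction: only markers surviving QC in every data set
    common = None
    for t in tables.values():
        ids = {m.marker_id for m in t.markers}
        common = ids if common is None else (common & ids)
    if not common:
        raise XwasError("no overlapping markers after QC")
    ref = tables[datasets[0]["name"]]
    marker_ids = [m.marker_id for m in ref.markers if m.marker_id in common]
    manifest.record("overlap", sum(t.n_markers for t in tables.values()), len(marker_ids))

    if config.get("candidate_genes"):
        genes = read_gene_intervals(config["candidate_genes"])
        flank = int(config.get("flank_bp", 0))
    else:
        genes, flank = [], 0

    fam_names = [d["name"] for d in datasets if kinds[d["name"]] == "family"]
    cc_names = [d["name"] for d in datasets if kinds[d["name"]] != "family"]
    merged = merge_tables([tables[n] for n in fam_names + cc_names], marker_ids)
    annotate_genes(merged.markers, genes, flank)
    cus = {n: ClusterUnits.from_table(merged, n) for n in fam_names + cc_names}

    n_eff = {}
    for n in fam_names:
        aff = (merged.cluster == n) & (merged.affection == Affection.AFFECTED)
        n_eff[n] = int(aff.sum())
    for n in cc_names:
        n_eff[n] = int(((merged.cluster == n) & (merged.unit_kind == UnitKind.UNRELATED_CASE)).sum())

    rows = []
    cc_chi2 = {s: {} for s in STRATA}
    cc_or = {s: {} for s in STRATA}
    for s in STRATA:
        for mid in marker_ids:
            rec = {"marker_id": mid, "stratum": s.value}
            # discovery: family clusters combined by the summed-cluster statistic
            try:
                disc = joint_test(merged, mid, fam_names, s, cus=cus)
                rec["z_discovery"], rec["p_discovery"] = disc.Z, disc.P
            except XwasError:
                rec["z_discovery"], rec["p_discovery"] = np.nan, np.nan
            # per family cohort (for meta weights/Z)
            for n in fam_names:
                r = xapl_test(merged, mid, n, s, cu=cus[n])
                rec[f"z_{n}"], rec[f"p_{n}"] = r.Z, r.P
            # validation: case-control allelic (GC applied panel-wide below)
            if cc_names:
                r = allelic_test(merged, mid, s)
                cc_chi2[s][mid] = r.V if r.informative else np.nan
                cc_or[s][mid] = r.odds_ratio
            rows.append(rec)

    res = pd.DataFrame(rows)

    # genomic control per stratum on the case-control panel
    for s in STRATA:
        if not cc_names:
            break
        mids = [m for m in marker_ids if np.isfinite(cc_chi2[s].get(m, np.nan))]
        if not mids:
            continue
        gc = genomic_control([cc_chi2[s][m] for m in mids])
        log.info("GC lambda (%s stratum): %.3f", s.value, gc.lambda_gc)
        manifest.thresholds[f"lambda_{s.value}"] = gc.lambda_gc
        zmap = {
            m: cc_signed_z(c, cc_or[s][m]) for m, c in zip(mids, gc.corrected_chi2)
        }
        pmap = dict(zip(mids, gc.corrected_p))
        sel = res["stratum"] == s.value
        res.loc[sel, "z_validation"] = res.loc[sel, "marker_id"].map(zmap)
        res.loc[sel, "p_validation"] = res.loc[sel, "marker_id"].map(pmap)
    if "p_validation" not in res.columns:
        res["z_validation"] = np.nan
        res["p_validation"] = np.nan
        log.info("no case-control data set: family-only discovery analysis")

    # joint and meta across all clusters
    zj, pj, zm, pm = [], [], [], []
    for _, rec in res.iterrows():
        s = Stratum(rec["stratum"])
        try:
            jt = joint_test(merged, rec["marker_id"], fam_names + cc_names, s, cus=cus)
            zj.append(jt.Z)
            pj.append(jt.P)
        except XwasError:
            zj.append(np.nan)
            pj.append(np.nan)
        zs, ws = [], []
        for n in fam_names:
            if np.isfinite(rec[f"z_{n}"]):
                zs.append(rec[f"z_{n}"])
                ws.append(np.sqrt(max(n_eff[n], 1)))
        if cc_names and np.isfinite(rec.get("z_validation", np.nan)):
            zs.append(rec["z_validation"])
            ws.append(np.sqrt(max(sum(n_eff[n] for n in cc_names), 1)))
        if zs:
            z, p = meta_combine(zs, ws)
            zm.append(z)
            pm.append(p)
        else:
            zm.append(np.nan)
            pm.append(np.nan)
    res["z_joint"], res["p_joint"] = zj, pj
    res["z_meta"], res["p_meta"] = zm, pm

    # multiplicity thresholds from the merged panel
    sm_cfg = config.get("simplem", {})
    m_eff = simple_m_eff(
        merged, C=float(sm_cfg.get("C", 0.995)), block_size=int(sm_cfg.get("block_size", 1000))
    )
    thresholds = derive_thresholds(m_eff, float(config.get("alpha_chromosome", 0.05)))
    manifest.thresholds.update(
        m_eff=thresholds.m_eff,
        alpha_chromosome=thresholds.alpha_chromosome,
        alpha_snp=thresholds.alpha_snp,
        alpha_replication=thresholds.alpha_replication,
    )

    verdicts, nears = [], []
    for _, rec in res.iterrows():
        if np.isfinite(rec["p_discovery"]) and np.isfinite(rec["p_validation"]):
            v = replication_assess(
                rec["p_discovery"], rec["p_validation"], thresholds.alpha_replication
            )
            verdicts.append(v.verdict)
            nears.append(v.near_miss)
        else:
            verdicts.append("NA")
            nears.append(False)
    res["replication"] = verdicts
    res["replication_near_miss"] = nears

    gene_map = {m.marker_id: m.gene_ids for m in merged.markers}
    res["gene_ids"] = res["marker_id"].map(lambda m: ",".join(gene_map[m]))
    cand_ids = list(config.get("candidate_gene_ids", [g[0] for g in genes]))
    recs = [
        {
            "marker_id": rec["marker_id"],
            "gene_ids": gene_map[rec["marker_id"]],
            "p_discovery": rec["p_discovery"] if np.isfinite(rec["p_discovery"]) else np.nan,
            "p_validation": rec["p_validation"] if np.isfinite(rec["p_validation"]) else np.nan,
            "p_joint": rec["p_joint"] if np.isfinite(rec["p_joint"]) else np.nan,
        }
        for _, rec in res.iterrows()
    ]
    hits, expected = candidate_gene_screen(recs, cand_ids)
    hit_keys = {(h.marker_id) for h in hits}
    res["candidate_gene_hit"] = [
        rec["marker_id"] in hit_keys
        and np.isfinite(rec["p_discovery"])
        and rec["p_discovery"] < 0.05
        for _, rec in res.iterrows()
    ]
    log.info("candidate-gene hits expected by chance: %.3f", expected)

    bp_map = {m.marker_id: m.bp for m in merged.markers}
    maf = _panel_maf(merged)
    res.insert(1, "bp", res["marker_id"].map(bp_map))
    res.insert(2, "maf", res["marker_id"].map(maf))
    res.insert(
        3, "alleles",
        res["marker_id"].map(
            {m.marker_id: f"{m.allele_candidate}/{m.allele_other}" for m in merged.markers}
        ),
    )
    res["manifest_id"] = manifest.manifest_id

    return {
        "results": res,
        "thresholds": thresholds,
        "manifest": manifest,
        "qc_reports": qc_reports,
        "merged_table": merged,
        "expected_candidate_hits": expected,
    }


def _panel_maf(table: GenotypeTable) -> dict[str, float]:
    calls = table.calls
    male = table.sex == Sex.MALE
    nonpar = table.region == Region.X_NONPAR
    founders = table.is_founder | (table.unit_kind != UnitKind.FAMILY_MEMBER)
    genod = (calls >= 0) & (calls <= 2)
    hemi = np.outer(male, nonpar)
    chroms = np.where(hemi, 1, 2)
    fsel = founders[:, None] & genod
    with np.errstate(invalid="ignore"):
        freq = (calls * fsel).sum(axis=0) / np.maximum((chroms * fsel).sum(axis=0), 1)
    maf = np.minimum(freq, 1 - freq)
    return {m.marker_id: float(maf[j]) for j, m in enumerate(table.markers)}


def render_report(bundle: dict) -> str:
    """Human-readable summary: thresholds, QC counts, per-marker table."""
    th: ThresholdSet = bundle["thresholds"]
    res: pd.DataFrame = bundle["results"]
    man: RunManifest = bundle["manifest"]
    lines = [
        f"xwas pipeline report (manifest {man.manifest_id}, version {man.version})",
        "",
        "Significance thresholds",
        f"  effective number of tests (simpleM): {th.m_eff}",
        f"  chromosome-wide alpha:               {th.alpha_chromosome}",
        f"  SNP-wise alpha:                      {th.alpha_snp:.3g}",
        f"  replication threshold (per set):     {th.alpha_replication:.4g}",
        "",
        "QC removals",
    ]
    for name, rep in bundle["qc_reports"].items():
        lines.append(f"  {name}: {len(rep.removals)} removals")
    lines += ["", "Per-marker results (sorted by joint P)"]
    cols = [
        "marker_id", "bp", "alleles", "maf", "stratum",
        "p_discovery", "p_validation", "p_meta", "p_joint",
        "replication", "candidate_gene_hit", "gene_ids",
    ]
    body = res.sort_values("p_joint")[cols]
    lines.append(body.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    return "\n".join(lines)


def write_bundle(bundle: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["results"].to_csv(out / "results.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        fh.write(bundle["manifest"].to_json())
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(bundle))
    for name, rep in bundle["qc_reports"].items():
        rep.removals_frame().to_csv(out / f"qc_removals_{name}.tsv", sep="\t", index=False)
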