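"""PLINK-style text PED/MAP input and output, region classification and
gene annotation.

PED conventions: six leading columns (family, individual, father, mother,
sex, phenotype) then two allele columns per marker; sex 1=male, 2=female,
0=unknown; phenotype 2=affected, 1=unaffected, 0/-9=unknown; missing allele
"0".  MAP columns: chromosome, marker id, genetic position, bp (1-based).

The counted ("candidate") allele of each marker is the minor allele among
founders and unrelated individuals pooled, with males contributing a single
allele at non-PAR X markers; ties break to the lexicographically smaller
allele.  A male record with two unequal alleles at a non-PAR X marker
becomes ``HET_FLAG`` for QC to resolve.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    HET_FLAG,
    MISSING,
    UNSEEN_ALLELE,
    Affection,
    GenotypeTable,
    MarkerInfo,
    ParseError,
    PedigreeIndividual,
    Region,
    RegionConfig,
    Sex,
    StructuralError,
    UnitKind,
)

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENO_CODES = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}


def read_map(map_path) -> list[tuple[str, int]]:
    """Return [(marker_id, bp), ...] from a MAP file."""
    out: list[tuple[str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP columns")
            try:
                bp = int(tokens[3])
            except ValueError as exc:
                raise ParseError(f"{map_path}:{lineno}: bad bp '{tokens[3]}'") from exc
            out.append((tokens[1], bp))
    return out


def read_ped_map(
    ped_path,
    map_path,
    region_config: RegionConfig | None = None,
    cluster_label: str = "",
) -> GenotypeTable:
    """Read a PED/MAP pair into a :class:`GenotypeTable`.

    Individuals in single-member families with no parent links are typed as
    unrelated cases/controls by affection status; everyone else is a family
    member.
    """
    region_config = region_config or RegionConfig.default()
    marker_defs = read_map(map_path)
    n_markers = len(marker_defs)
    expected = 6 + 2 * n_markers

    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != expected:
                raise StructuralError(
                    f"{ped_path}:{lineno}: expected {expected} fields "
                    f"(6 + 2x{n_markers} markers), found {len(tokens)}"
                )
            if tokens[4] not in _SEX_CODES:
                raise ParseError(
                    f"{ped_path}:{lineno}: sex code '{tokens[4]}' not in {{1,2,0}}"
                )
            if tokens[5] not in _PHENO_CODES:
                raise ParseError(
                    f"{ped_path}:{lineno}: phenotype code '{tokens[5]}' "
                    "not in {2,1,0,-9}"
                )
            rows.append(tokens)

    fam_sizes: dict[str, int] = {}
    for tokens in rows:
        fam_sizes[tokens[0]] = fam_sizes.get(tokens[0], 0) + 1

    individuals: list[PedigreeIndividual] = []
    for tokens in rows:
        fam, iid, fid, mid, sx, ph = tokens[:6]
        fid = "" if fid == "0" else fid
        mid = "" if mid == "0" else mid
        aff = _PHENO_CODES[ph]
        individuals.append(
            PedigreeIndividual(
                individual_id=iid,
                family_id=fam,
                father_id=fid,
                mother_id=mid,
                sex=_SEX_CODES[sx],
                affection=aff,
                cluster=cluster_label,
            )
        )
    # unrelated typing: singleton family, no parent links
    for ind in individuals:
        if fam_sizes[ind.family_id] == 1 and ind.is_founder:
            ind.unit_kind = (
                UnitKind.UNRELATED_CASE
                if ind.affection == Affection.AFFECTED
                else UnitKind.UNRELATED_CONTROL
            )

    regions = np.array(
        [int(region_config.classify(bp)) for _, bp in marker_defs], dtype=np.int8
    )
    sexes = np.array([int(i.sex) for i in individuals], dtype=np.int8)
    founders = np.array(
        [i.is_founder or i.unit_kind != UnitKind.FAMILY_MEMBER for i in individuals]
    )

    tok = np.array(rows, dtype=object) if rows else np.empty((0, expected), object)
    a1 = tok[:, 6::2].astype(str) if len(rows) else np.empty((0, n_markers), "<U1")
    a2 = tok[:, 7::2].astype(str) if len(rows) else np.empty((0, n_markers), "<U1")

    markers: list[MarkerInfo] = []
    calls = np.full((len(rows), n_markers), MISSING, dtype=np.int8)
    male = sexes == Sex.MALE
    for j, (mid_, bp) in enumerate(marker_defs):
        c1, c2 = a1[:, j], a2[:, j]
        called = (c1 != "0") & (c2 != "0")
        nonpar_male = male & (regions[j] == Region.X_NONPAR)
        het = c1 != c2
        cand, other = _candidate_allele(
            c1, c2, called, founders, nonpar_male, het, ped_path, mid_
        )
        markers.append(
            MarkerInfo(
                marker_id=mid_,
                bp=bp,
                allele_candidate=cand,
                allele_other=other,
                region=Region(int(regions[j])),
            )
        )
        col = calls[:, j]
        dose = (c1 == cand).astype(np.int8) + (c2 == cand).astype(np.int8)
        col[called] = dose[called]
        # male hemizygous coding: homozygote -> single-copy count, het -> flag
        hm = called & nonpar_male
        col[hm & ~het] = (c1[hm & ~het] == cand).astype(np.int8)
        col[hm & het] = HET_FLAG
        calls[:, j] = col

    table = GenotypeTable(markers, individuals, calls)
    table.validate()
    return table


def _candidate_allele(c1, c2, called, founders, nonpar_male, het, path, marker_id):
    """Minor allele among founders+unrelateds; males one allele on non-PAR X.

    HET_FLAG males (impossible genotypes) are excluded from the count so the
    choice is stable under write/read round trips.
    """
    use = called & founders
    single = use & nonpar_male
    diplo = use & ~nonpar_male
    pool = np.concatenate(
        [c1[diplo], c2[diplo], c1[single & ~het]]  # het males contribute nothing
    )
    alleles = sorted(set(np.concatenate([c1[called], c2[called]])))
    if len(alleles) > 2:
        raise ParseError(
            f"{path}: marker {marker_id} has {len(alleles)} alleles {alleles}; "
            "only biallelic markers are supported"
        )
    if len(alleles) == 0:
        return "A", UNSEEN_ALLELE  # fully missing column
    if len(alleles) == 1:
        return alleles[0], UNSEEN_ALLELE
    n0 = int(np.sum(pool == alleles[0]))
    n1 = int(np.sum(pool == alleles[1]))
    if n0 == n1:
        return alleles[0], alleles[1]  # lexicographic tie-break
    return (alleles[0], alleles[1]) if n0 < n1 else (alleles[1], alleles[0])


def write_ped_map(table: GenotypeTable, ped_path, map_path) -> None:
    """Write a table back to PED/MAP; inverse of :func:`read_ped_map`."""
    with open(map_path, "w") as fh:
        for m in table.markers:
            fh.write(f"X\t{m.marker_id}\t0\t{m.bp}\n")

    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}
    male = table.sex == Sex.MALE
    nonpar = table.region == Region.X_NONPAR
    with open(ped_path, "w") as fh:
        for r, ind in enumerate(table.individuals):
            fields = [
                ind.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                sex_out[ind.sex],
                aff_out[ind.affection],
            ]
            for j, m in enumerate(table.markers):
                c = int(table.calls[r, j])
                cand, other = m.allele_candidate, m.allele_other
                if c == MISSING:
                    pair = ("0", "0")
                elif c == HET_FLAG:
                    pair = (cand, other)
                elif male[r] and nonpar[j]:
                    pair = (cand, cand) if c == 1 else (other, other)
                else:
                    pair = {0: (other, other), 1: (cand, other), 2: (cand, cand)}[c]
                fields.extend(pair)
            fh.write("\t".join(fields) + "\n")


def classify_marker_regions(
    markers: Sequence[MarkerInfo], region_config: RegionConfig
) -> list[MarkerInfo]:
    """Assign each marker its region from the bp-interval config (in place)."""
    for m in markers:
        m.region = region_config.classify(m.bp)
    return list(markers)


def read_gene_intervals(path) -> list[tuple[str, int, int]]:
    """BED-like gene list: chrom, start, end, gene_id (0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 BED columns")
            out.append((tokens[3], int(tokens[1]), int(tokens[2])))
    return out


def annotate_genes(
    markers: Sequence[MarkerInfo],
    gene_intervals: Sequence[tuple[str, int, int]],
    flank_bp: int = 0,
) -> list[MarkerInfo]:
    """Attach gene ids to markers whose 0-based position falls inside
    [start - flank, end + flank) of a gene interval.

    A marker inside several (possibly overlapping) genes gets all of them.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    for m in markers:
        pos0 = m.bp - 1
        m.gene_ids = [
            gid
            for gid, start, end in gene_intervals
            if start - flank_bp <= pos0 < end + flank_bp
        ]
    return list(markers)


def results_to_frame(results) -> pd.DataFrame:
    """Flatten a list of AssocResult-like dataclasses into a DataFrame."""
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def write_results(results, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
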