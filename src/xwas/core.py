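"""Shared domain model for X-chromosome association analysis.

Genotypes are stored as counts of a per-marker *candidate* allele (by
convention the minor allele among founders and unrelated individuals).
Females, and everyone in the pseudoautosomal regions, carry 0/1/2 copies;
males are hemizygous outside the PARs and carry 0/1.  Two sentinels extend
the count scale:

* ``MISSING`` (-1): no genotype call.
* ``HET_FLAG`` (3): a male called heterozygous at a non-PAR X marker.  This
  is biologically impossible and is carried through to QC, which either
  removes the marker (too many flagged males) or sets the call to missing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import yaml

MISSING: int = -1
HET_FLAG: int = 3

#: sentinel for the second allele of a marker seen monomorphic in the input
UNSEEN_ALLELE: str = "N"


class Sex(IntEnum):
    """PED sex codes."""

    UNKNOWN = 0
    MALE = 1
    FEMALE = 2


class Affection(IntEnum):
    """PED phenotype codes (0 / -9 both map to UNKNOWN on input)."""

    UNKNOWN = 0
    UNAFFECTED = 1
    AFFECTED = 2


class Region(IntEnum):
    """Marker region on the X chromosome."""

    X_NONPAR = 0
    PAR1 = 1
    PAR2 = 2
    XY_HOMOLOGOUS = 3


class UnitKind(IntEnum):
    FAMILY_MEMBER = 0
    UNRELATED_CASE = 1
    UNRELATED_CONTROL = 2


class XwasError(Exception):
    """Base class for package errors."""


class ParseError(XwasError):
    """Malformed input file."""


class StructuralError(XwasError):
    """Inconsistent input structure (e.g. PED/MAP marker count mismatch)."""


class ConfigError(XwasError):
    """Invalid configuration."""


class ModelError(XwasError):
    """A statistical model could not be fitted."""


class SimulationError(XwasError):
    """Simulation could not satisfy its constraints."""


@dataclass
class MarkerInfo:
    """A biallelic X-chromosome SNP.

    ``allele_candidate`` is the counted allele; ``bp`` is 1-based.
    """

    marker_id: str
    bp: int
    allele_candidate: str
    allele_other: str
    region: Region = Region.X_NONPAR
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"marker {self.marker_id}: bp must be >= 1")
        if self.allele_candidate == self.allele_other:
            raise ValueError(
                f"marker {self.marker_id}: candidate and other allele identical"
            )


@dataclass
class PedigreeIndividual:
    """One row of a pedigree: identity, links, sex, affection, cohort."""

    individual_id: str
    family_id: str
    father_id: str = ""
    mother_id: str = ""
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    cluster: str = ""
    unit_kind: UnitKind = UnitKind.FAMILY_MEMBER

    def __post_init__(self) -> None:
        if self.unit_kind != UnitKind.FAMILY_MEMBER and (
            self.father_id or self.mother_id
        ):
            raise ValueError(
                f"{self.individual_id}: unrelated individuals cannot have parents"
            )

    @property
    def is_founder(self) -> bool:
        return not self.father_id and not self.mother_id


@dataclass
class RegionConfig:
    """Half-open [start, end) bp intervals for PAR1, PAR2 and XY homology."""

    par1: tuple[int, int]
    par2: tuple[int, int]
    xy_homologous: list[tuple[int, int]] = field(default_factory=list)
    build: str = "unspecified"

    def __post_init__(self) -> None:
        ivals = [tuple(self.par1), tuple(self.par2)] + [
            tuple(iv) for iv in self.xy_homologous
        ]
        for s, e in ivals:
            if not s < e:
                raise ConfigError(f"region interval ({s}, {e}) must have start < end")
        for i, (s1, e1) in enumerate(ivals):
            for s2, e2 in ivals[i + 1 :]:
                if s1 < e2 and s2 < e1:
                    raise ConfigError(
                        f"region intervals ({s1},{e1}) and ({s2},{e2}) overlap"
                    )
        self.par1 = tuple(self.par1)
        self.par2 = tuple(self.par2)
        self.xy_homologous = [tuple(iv) for iv in self.xy_homologous]

    def classify(self, bp: int) -> Region:
        if self.par1[0] <= bp < self.par1[1]:
            return Region.PAR1
        if self.par2[0] <= bp < self.par2[1]:
            return Region.PAR2
        for s, e in self.xy_homologous:
            if s <= bp < e:
                return Region.XY_HOMOLOGOUS
        return Region.X_NONPAR

    @classmethod
    def from_yaml(cls, path) -> "RegionConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            par1=tuple(doc["par1"]),
            par2=tuple(doc["par2"]),
            xy_homologous=[tuple(iv) for iv in doc.get("xy_homologous", [])],
            build=str(doc.get("build", "unspecified")),
        )

    @classmethod
    def default(cls) -> "RegionConfig":
        """Packaged default (GRCh37 coordinates; always overridable)."""
        ref = importlib.resources.files("xwas.data") / "regions_grch37.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)


class GenotypeTable:
    """Individuals x markers candidate-allele count matrix plus metadata.

    ``calls`` is int8 with values {0,1,2}, ``MISSING`` and ``HET_FLAG``.
    Cached per-individual arrays (sex, affection, founder status, ...) are
    derived lazily and invalidated on subsetting (subsets build new tables).
    """

    def __init__(
        self,
        markers: Sequence[MarkerInfo],
        individuals: Sequence[PedigreeIndividual],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(individuals), len(markers)):
            raise StructuralError(
                f"calls shape {calls.shape} does not match "
                f"{len(individuals)} individuals x {len(markers)} markers"
            )
        self.markers = list(markers)
        self.individuals = list(individuals)
        self.calls = calls
        self._cache: dict[str, np.ndarray] = {}

    # -- basic shape ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.marker_id == marker_id:
                return i
        raise KeyError(marker_id)

    # -- cached metadata arrays -----------------------------------------
    def _arr(self, key: str, fn) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def sex(self) -> np.ndarray:
        return self._arr(
            "sex", lambda: np.array([int(i.sex) for i in self.individuals], dtype=np.int8)
        )

    @property
    def affection(self) -> np.ndarray:
        return self._arr(
            "aff",
            lambda: np.array([int(i.affection) for i in self.individuals], dtype=np.int8),
        )

    @property
    def is_founder(self) -> np.ndarray:
        return self._arr(
            "founder", lambda: np.array([i.is_founder for i in self.individuals])
        )

    @property
    def unit_kind(self) -> np.ndarray:
        return self._arr(
            "kind",
            lambda: np.array([int(i.unit_kind) for i in self.individuals], dtype=np.int8),
        )

    @property
    def cluster(self) -> np.ndarray:
        return self._arr(
            "cluster", lambda: np.array([i.cluster for i in self.individuals])
        )

    @property
    def region(self) -> np.ndarray:
        """Per-marker region codes."""
        return self._arr(
            "region", lambda: np.array([int(m.region) for m in self.markers], dtype=np.int8)
        )

    @property
    def bp(self) -> np.ndarray:
        return self._arr("bp", lambda: np.array([m.bp for m in self.markers]))

    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.cluster, None)
        return list(seen)

    def row_index(self) -> dict[tuple[str, str], int]:
        """(family_id, individual_id) -> row."""
        return {
            (ind.family_id, ind.individual_id): r
            for r, ind in enumerate(self.individuals)
        }

    # -- subsetting ------------------------------------------------------
    def subset_markers(self, idx: Iterable[int]) -> "GenotypeTable":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeTable(
            [self.markers[i] for i in idx], self.individuals, self.calls[:, idx]
        )

    def subset_individuals(self, idx: Iterable[int]) -> "GenotypeTable":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeTable(
            self.markers, [self.individuals[i] for i in idx], self.calls[idx, :]
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            [replace(m, gene_ids=list(m.gene_ids)) for m in self.markers],
            [replace(i) for i in self.individuals],
            self.calls.copy(),
        )

    # -- validity --------------------------------------------------------
    def validate(self, allow_het_flag: bool = True) -> None:
        """Raise if the call matrix violates the sex-aware coding rules."""
        ok = {MISSING, 0, 1, 2} | ({HET_FLAG} if allow_het_flag else set())
        bad = ~np.isin(self.calls, list(ok))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise StructuralError(
                f"invalid call {self.calls[r, c]} at individual {r}, marker {c}"
            )
        male = self.sex == Sex.MALE
        nonpar = self.region == Region.X_NONPAR
        if male.any() and nonpar.any():
            block = self.calls[np.ix_(male, nonpar)]
            if (block == 2).any():
                raise StructuralError("male non-PAR X call equal to 2")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeTable({self.n_individuals} individuals x "
            f"{self.n_markers} markers)"
        )
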