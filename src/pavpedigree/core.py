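"""Core data model: SV calls, PAV records, and the presence matrix.

Coordinates are 1-based inclusive throughout (VCF POS/END convention);
conversions to 0-based half-open happen only at I/O boundaries (BED export).
A presence-matrix entry of 1 means the sample carries the *reference*
(backbone-like) segment; 0 means it carries the alternative allele (the
structural variation); NaN means the genotype is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

# allele states
REF = "REF"
ALT = "ALT"
MISSING = "MISSING"

# segment source categories (inferred from the two parents' allele states)
P1_INHERITED = "P1_INHERITED"
P2_INHERITED = "P2_INHERITED"
REF_SPECIFIC = "REF_SPECIFIC"
BIPARENTAL = "BIPARENTAL"
UNCLASSIFIED = "UNCLASSIFIED"
CATEGORIES = (P1_INHERITED, P2_INHERITED, REF_SPECIFIC, BIPARENTAL)

# per-trait effect labels
FAVORABLE = "FAVORABLE"
DELETERIOUS = "DELETERIOUS"
NONE = "NONE"

# genomic contexts, in priority order
CONTEXT_EXON = "exon"
CONTEXT_INTRON = "intron"
CONTEXT_PROMOTER = "promoter"
CONTEXT_INTERVAL = "interval"

# sample roles
ROLE_REFERENCE = "reference"
ROLE_PARENT1 = "parent1"
ROLE_PARENT2 = "parent2"
ROLE_PROGENY = "progeny"
ROLE_POPULATION = "population"

DEL = "DEL"
INS = "INS"

MIN_SV_LENGTH = 20  # calls below this are rejected at parse time


@dataclass(frozen=True)
class SvCall:
    """A single structural-variant call from one caller in one sample.

    ``end`` is the 1-based inclusive end for deletions (``pos + length - 1``)
    and equals ``pos`` for insertions, whose length lives off-reference.
    """

    sample: str
    caller: str
    chrom: str
    pos: int
    end: int
    svtype: str
    length: int

    def __post_init__(self) -> None:
        if self.svtype not in (DEL, INS):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.end < self.pos:
            raise ValueError(f"end {self.end} < pos {self.pos}")
        if self.length < MIN_SV_LENGTH:
            raise ValueError(
                f"call length {self.length} below the {MIN_SV_LENGTH} bp floor"
            )
        if self.svtype == DEL and self.length != self.end - self.pos + 1:
            raise ValueError("deletion length must equal end - pos + 1")


@dataclass
class PavRecord:
    """One non-redundant segment on the reference with per-member alleles.

    ``alleles`` maps sample id to REF (the sample carries the reference
    segment), ALT (it carries the variation) or MISSING.
    """

    id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    length: int
    alleles: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.pos, self.end)


class PresenceMatrix:
    """Binary segments x samples matrix with sample roles and region labels.

    Parameters
    ----------
    data
        DataFrame indexed by segment id with one column per sample; values
        1.0 (carries the reference segment), 0.0 (carries the variation)
        or NaN (missing genotype).
    roles
        Mapping from sample id to one of the role constants.
    regions
        Optional mapping from (population) sample id to a region label.
    foreign
        Optional set of sample ids flagged as foreign-introduced; these can
        be trimmed before sub-group analyses.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        roles: Mapping[str, str],
        regions: Optional[Mapping[str, str]] = None,
        foreign: Optional[Iterable[str]] = None,
    ) -> None:
        roles = pd.Series(dict(roles), dtype=object)
        missing_roles = set(data.columns) - set(roles.index)
        if missing_roles:
            raise ValueError(f"samples without a role: {sorted(missing_roles)[:5]}")
        self.data = data.astype(float)
        self.roles = roles.loc[list(data.columns)]
        self.regions = pd.Series(dict(regions), dtype=object) if regions else None
        self.foreign = frozenset(foreign) if foreign else frozenset()
        ref = self.samples_with_role(ROLE_REFERENCE)
        for s in ref:
            col = self.data[s]
            if not (col.dropna() == 1.0).all():
                raise ValueError("reference sample column must be all 1")

    # -- sample accessors -------------------------------------------------
    def samples_with_role(self, *wanted: str) -> list:
        return [s for s in self.data.columns if self.roles[s] in wanted]

    @property
    def parent_samples(self) -> list:
        return self.samples_with_role(ROLE_PARENT1, ROLE_PARENT2)

    @property
    def progeny_samples(self) -> list:
        return self.samples_with_role(ROLE_PROGENY)

    @property
    def pedigree_samples(self) -> list:
        """Parents plus progenies (the reference itself excluded)."""
        return self.samples_with_role(ROLE_PARENT1, ROLE_PARENT2, ROLE_PROGENY)

    @property
    def population_samples(self) -> list:
        return self.samples_with_role(ROLE_POPULATION)

    @property
    def segment_ids(self) -> pd.Index:
        return self.data.index

    def subset_samples(self, samples: Iterable[str]) -> "PresenceMatrix":
        samples = list(samples)
        regions = (
            {s: self.regions[s] for s in samples if s in self.regions.index}
            if self.regions is not None
            else None
        )
        return PresenceMatrix(
            self.data[samples],
            self.roles.loc[samples].to_dict(),
            regions=regions,
            foreign=self.foreign & set(samples),
        )

    def subset_segments(self, segment_ids: Iterable[str]) -> "PresenceMatrix":
        sub = PresenceMatrix.__new__(PresenceMatrix)
        sub.data = self.data.loc[list(segment_ids)]
        sub.roles = self.roles
        sub.regions = self.regions
        sub.foreign = self.foreign
        return sub

    def allele(self, segment_id: str, sample: str) -> str:
        v = self.data.at[segment_id, sample]
        if np.isnan(v):
            return MISSING
        return REF if v == 1.0 else ALT

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PresenceMatrix({self.data.shape[0]} segments x "
            f"{self.data.shape[1]} samples)"
        )


def matrix_from_records(
    records: Iterable[PavRecord],
    roles: Mapping[str, str],
    regions: Optional[Mapping[str, str]] = None,
    foreign: Optional[Iterable[str]] = None,
) -> PresenceMatrix:
    """Build a PresenceMatrix from PavRecords (entry 1 <=> allele REF)."""
    records = list(records)
    samples = list(roles)
    code = {REF: 1.0, ALT: 0.0, MISSING: np.nan}
    arr = np.empty((len(records), len(samples)))
    for i, rec in enumerate(records):
        for j, s in enumerate(samples):
            arr[i, j] = code[rec.alleles.get(s, REF)]
    data = pd.DataFrame(arr, index=[r.id for r in records], columns=samples)
    return PresenceMatrix(data, roles, regions=regions, foreign=foreign)


@dataclass
class GeneModels:
    """Gene structures used for context annotation and cis windows.

    ``genes``: DataFrame with columns gene_id, chrom, start, end, strand.
    ``exons``: DataFrame with columns gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "start", "end", "strand"}
        if not need <= set(self.genes.columns):
            raise ValueError(f"gene table missing columns {need - set(self.genes.columns)}")
        if (self.genes["end"] < self.genes["start"]).any():
            raise ValueError("malformed gene model: end < start")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise ValueError("malformed gene model: strand must be + or -")
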