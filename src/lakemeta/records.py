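"""Domain record types shared across the pipeline.

All fractions (breadth, relative coverage) are stored in ``[0, 1]``;
percentages appear only at reporting boundaries.  Completeness and
redundancy are percentages in ``[0, 100]`` because that is how upstream
quality tools report them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class LineageClass(str, Enum):
    """Broad lineage bucket used for marker-set selection upstream."""

    CPR = "CPR"
    DPANN = "DPANN"
    OTHER = "other"


class Compartment(str, Enum):
    """The four depth compartments of a meromictic lake, shallow to deep."""

    OXYGEN_MAX = "oxygen_max"
    INTERFACE = "interface"
    ANOXIC = "anoxic"
    SEDIMENT = "sediment"


COMPARTMENT_ORDER = [
    Compartment.OXYGEN_MAX,
    Compartment.INTERFACE,
    Compartment.ANOXIC,
    Compartment.SEDIMENT,
]


@dataclass(frozen=True)
class MarkerHit:
    """One hmmsearch hit of a protein against an HMM.

    ``bitscore`` is the full-sequence bit score; ``evalue`` the
    full-sequence E-value.  (protein, model) pairs may repeat across raw
    files; they are unique only after best-hit reduction.
    """

    protein_id: str
    model_id: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.bitscore):
            raise ValueError(f"non-finite bitscore for {self.protein_id}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.protein_id}")


@dataclass(frozen=True)
class PathwayDefinition:
    """A marker-gene pathway: HMM set, per-model score cutoffs, and the
    minimum number of distinct markers required to call presence.

    Most pathways use ``min_markers=1``; false-positive-prone pathways
    (formate oxidation, CO oxidation, Wood-Ljungdahl) use 2/3/2.
    """

    pathway_id: str
    per_model_threshold: dict[str, float]
    min_markers: int = 1

    @property
    def marker_models(self) -> frozenset[str]:
        return frozenset(self.per_model_threshold)

    def __post_init__(self) -> None:
        if self.min_markers < 1:
            raise ValueError(f"{self.pathway_id}: min_markers must be >= 1")
        if self.min_markers > len(self.per_model_threshold):
            raise ValueError(
                f"{self.pathway_id}: min_markers={self.min_markers} exceeds "
                f"marker count {len(self.per_model_threshold)}"
            )


@dataclass(frozen=True)
class GenomeRecord:
    """One draft genome (bin) with taxonomy and quality metrics."""

    genome_id: str
    phylum: str = ""  # empty string == unassigned
    lineage_class: LineageClass = LineageClass.OTHER
    completeness: float = 0.0
    redundancy: float = 0.0
    methanogenic_lineage: bool = False

    def __post_init__(self) -> None:
        for name in ("completeness", "redundancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.genome_id}: {name}={v} outside [0, 100]")


@dataclass(frozen=True)
class CoverageRecord:
    """Mean read depth and breadth for one entity in one sample.

    The entity may be a genome, a scaffold, or a species-group
    representative; the same record type serves all granularities.
    """

    entity_id: str
    sample_id: str
    mean_coverage: float
    breadth: float

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError(f"negative coverage for {self.entity_id}/{self.sample_id}")
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError(
                f"breadth {self.breadth} outside [0, 1] for "
                f"{self.entity_id}/{self.sample_id}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One metagenomic sample: depth (with unit label) and compartment."""

    sample_id: str
    depth: float
    depth_unit: str  # "m" for water column, "cm" for sediment cores
    compartment: Compartment


@dataclass(frozen=True)
class PhageQCRecord:
    """Per-scaffold viral QC summary (viral/host gene counts, provirus and
    completeness flags) as produced by an upstream viral QC tool."""

    scaffold_id: str
    length: int
    viral_genes: int
    host_genes: int
    provirus_call: bool
    complete_100: bool

    def __post_init__(self) -> None:
        if self.viral_genes < 0 or self.host_genes < 0:
            raise ValueError(f"{self.scaffold_id}: negative gene counts")
        if self.length < 0:
            raise ValueError(f"{self.scaffold_id}: negative length")


@dataclass(frozen=True)
class FamilyMembership:
    """Membership of one protein (from one genome) in one protein family."""

    family_id: str
    protein_id: str
    genome_id: str


@dataclass
class TaxonomyEvidence:
    """The three phylum-level evidence lines for a species group: bin
    taxonomy, best reference hit, and scaffold protein consensus.
    ``None`` marks an absent line."""

    bin_taxonomy: str | None = None
    best_hit_taxonomy: str | None = None
    scaffold_consensus_taxonomy: str | None = None

    def lines(self) -> list[str | None]:
        return [
            self.bin_taxonomy,
            self.best_hit_taxonomy,
            self.scaffold_consensus_taxonomy,
        ]


@dataclass
class SpeciesGroup:
    """A cluster of marker-protein sequences at species-level identity."""

    group_id: str
    member_ids: list[str] = field(default_factory=list)
    representative_protein_id: str = ""
    representative_scaffold_id: str = ""
    taxonomy: str | None = None  # None == unresolved
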