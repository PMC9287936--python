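"""Domain types shared across the meta-QTL pipeline.

Genetic positions are centimorgans (cM, non-negative reals); physical
positions are base pairs, 1-based and inclusive inside the package.  BED
export converts to 0-based half-open coordinates at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Trait(str, Enum):
    GDR = "GDR"  # grain drying (dehydration) rate
    GWC = "GWC"  # grain water content


class PopulationType(str, Enum):
    """Mapping-population types; the type selects the CI-imputation formula."""

    F2 = "F2"
    F2_3 = "F2_3"
    F3_4 = "F3_4"
    BC = "BC"
    TC = "TC"
    RIL = "RIL"
    DH = "DH"
    OTHER = "other"


class MappingMethod(str, Enum):
    IM = "IM"    # interval mapping
    CIM = "CIM"  # composite interval mapping
    SPA = "SPA"  # single-point analysis


class CoordSystem(str, Enum):
    GENETIC = "genetic"
    PHYSICAL = "physical"


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass
class MarkerLocus:
    """A marker on a linkage group: genetic position, optional physical anchor."""

    name: str
    linkage_group: str
    genetic_pos: float
    physical_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genetic_pos < 0:
            raise ValidationError(
                f"marker {self.name!r}: genetic position must be >= 0 cM, "
                f"got {self.genetic_pos}"
            )
        if self.physical_pos is not None and self.physical_pos < 1:
            raise ValidationError(
                f"marker {self.name!r}: physical position must be >= 1 bp, "
                f"got {self.physical_pos}"
            )

    @property
    def is_anchor(self) -> bool:
        return self.physical_pos is not None


@dataclass
class GeneticMap:
    """An ordered set of linkage groups, each a list of markers sorted by cM.

    Marker names are unique within a map.  ``groups`` preserves insertion
    order of linkage groups; each group's marker list is kept sorted by
    ``genetic_pos`` (ties keep input order).
    """

    map_id: str
    groups: dict[str, list[MarkerLocus]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group, loci in self.groups.items():
            loci.sort(key=lambda m: m.genetic_pos)
            for locus in loci:
                if locus.name in seen:
                    raise ValidationError(
                        f"map {self.map_id!r}: duplicate marker name {locus.name!r}"
                    )
                seen.add(locus.name)

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def marker_names(self, group: Optional[str] = None) -> list[str]:
        if group is not None:
            return [m.name for m in self.groups.get(group, [])]
        return [m.name for loci in self.groups.values() for m in loci]

    def positions(self, group: str) -> dict[str, float]:
        return {m.name: m.genetic_pos for m in self.groups.get(group, [])}

    def group_length(self, group: str) -> float:
        loci = self.groups[group]
        return loci[-1].genetic_pos - loci[0].genetic_pos if loci else 0.0


@dataclass
class ExperimentMeta:
    """One QTL-mapping experiment (one population, trait, set of environments)."""

    experiment_id: str
    parents: str
    population_type: PopulationType
    population_size: int
    n_environments: int = 1
    mapping_method: MappingMethod = MappingMethod.CIM

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValidationError(
                f"experiment {self.experiment_id!r}: population size must be >= 2"
            )
        if isinstance(self.population_type, str):
            self.population_type = PopulationType(self.population_type)
        if isinstance(self.mapping_method, str):
            self.mapping_method = MappingMethod(self.mapping_method)


@dataclass
class QTLRecord:
    """A published QTL as collected from the literature.

    A usable record carries at least one of: an explicit CI pair, a pair of
    flanking markers, or R-squared (so that the CI can be imputed from the
    linked experiment's population size and type).
    """

    qtl_id: str
    trait: Trait
    experiment_id: str
    linkage_group: str
    peak_pos: Optional[float] = None
    ci_start: Optional[float] = None
    ci_end: Optional[float] = None
    flank_left: Optional[str] = None
    flank_right: Optional[str] = None
    lod: Optional[float] = None
    r_squared: Optional[float] = None
    coord_system: CoordSystem = CoordSystem.GENETIC

    def __post_init__(self) -> None:
        if isinstance(self.trait, str):
            self.trait = Trait(self.trait)
        if isinstance(self.coord_system, str):
            self.coord_system = CoordSystem(self.coord_system)
        if (
            self.ci_start is not None
            and self.ci_end is not None
            and self.ci_start > self.ci_end
        ):
            raise ValidationError(
                f"QTL {self.qtl_id!r}: ci_start ({self.ci_start}) > ci_end "
                f"({self.ci_end})"
            )
        if self.r_squared is not None and not 0 < self.r_squared <= 1:
            raise ValidationError(
                f"QTL {self.qtl_id!r}: r_squared must be in (0, 1], got "
                f"{self.r_squared}"
            )

    @property
    def has_ci(self) -> bool:
        return self.ci_start is not None and self.ci_end is not None

    @property
    def has_flanks(self) -> bool:
        return self.flank_left is not None and self.flank_right is not None

    def is_informative(self) -> bool:
        """Whether the record carries enough to place it on a consensus map."""
        return self.has_ci or self.has_flanks or self.r_squared is not None


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive physical interval on a chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chromosome, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene model: identifier, genomic interval, strand."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid strand {self.strand!r}"
            )
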