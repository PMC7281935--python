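"""Core domain types: genome/gene models and somatic variant calls."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from . import intervals
from .intervals import Interval


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is infeasible."""


@dataclass
class GeneModel:
    """A protein-coding gene: genomic span plus exon/CDS/UTR structure.

    Coordinates are 0-based half-open. ``utr5`` is the UTR at the
    transcription start (5') side in the gene's own orientation, so for a
    minus-strand gene it sits at the numerically larger end of the span.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    is_key: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty span")
        self.exons = intervals.merge(self.exons)
        for name, ivs in (("cds", self.cds), ("utr5", self.utr5), ("utr3", self.utr3)):
            for s, e in ivs:
                if not any(es <= s and e <= ee for es, ee in self.exons):
                    raise ValueError(f"{self.gene_id}: {name} interval ({s},{e}) not inside an exon")
        if intervals.intersect(self.cds, self.utr5) or intervals.intersect(self.cds, self.utr3):
            raise ValueError(f"{self.gene_id}: UTRs overlap CDS")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def atg_pos(self) -> int:
        """0-based position of the first base of the start codon."""
        if not self.cds:
            raise ValueError(f"{self.gene_id}: no annotated CDS")
        if self.strand == "+":
            return min(s for s, _ in self.cds)
        return max(e for _, e in self.cds) - 1

    @property
    def introns(self) -> list[Interval]:
        return intervals.subtract([self.span], self.exons)


@dataclass
class GenomeModel:
    """Chromosome sizes plus gene models and lincRNA intervals."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    lincrnas: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lens = self.chrom_lengths
        for g in self.genes:
            if g.chrom not in lens:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > lens[g.chrom]:
                raise ValueError(f"{g.gene_id}: span outside chromosome bounds")
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene_id")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in genome") from None

    @property
    def key_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_key]

    @lru_cache(maxsize=None)
    def cds_union(self, chrom: str) -> tuple[Interval, ...]:
        """Merged union of all genes' CDS intervals on one chromosome."""
        ivs = [iv for g in self.genes if g.chrom == chrom for iv in g.cds]
        return tuple(intervals.merge(ivs))

    def __hash__(self) -> int:  # for lru_cache on methods
        return id(self)

    def __eq__(self, other) -> bool:
        return self is other


@dataclass
class VariantCall:
    """A single somatic call from one sample with read support and provenance."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    ref_reads: int = 0
    alt_reads: int = 0
    provenance: set[str] = field(default_factory=set)
    filter_trail: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("negative read counts")

    @property
    def vtype(self) -> str:
        """SPM for single-base substitutions, SIM for indels."""
        return "SPM" if len(self.ref) == 1 and len(self.alt) == 1 else "SIM"

    @property
    def pos0(self) -> int:
        """0-based anchor (leftmost) base."""
        return self.pos - 1

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)
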