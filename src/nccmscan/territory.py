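"""Per-gene queried territories and the key-gene set.

A gene's territory is the non-coding neighborhood over which its mutation
rate is normalized: 5'/3' UTRs, introns, and +/-100 kbp (default)
intergenic flanks anchored at the gene span and clipped to chromosome
bounds. Territories of different genes are built independently, so one
position may belong to several genes' territories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import intervals
from .constraint import ConstraintTrack
from .intervals import Interval
from .models import GeneModel, GenomeModel

LABELS = ("utr5", "utr3", "intron", "flank")


@dataclass
class GeneTerritory:
    gene_id: str
    chrom: str
    regions: dict[str, list[Interval]]
    is_key: bool = False
    constrained_bases: int | None = None

    @property
    def total_length(self) -> int:
        return sum(intervals.total_length(ivs) for ivs in self.regions.values())

    def label_at(self, pos0: int) -> str | None:
        """Territory label covering a 0-based position, or None."""
        for label in LABELS:  # UTR labels take precedence over intron
            if intervals.contains(self.regions.get(label, []), pos0):
                return label
        return None

    def all_intervals(self) -> list[tuple[int, int, str]]:
        return [(s, e, lab) for lab in LABELS for s, e in self.regions.get(lab, [])]


def build_territory(gene: GeneModel, genome: GenomeModel, flank_bp: int = 100_000,
                    exclude_neighbor_cds: bool = False) -> GeneTerritory:
    """Assemble one gene's labeled territory.

    Introns are the gene span minus its exons; UTRs come from annotation and
    take precedence over intron labels; flanks extend ``flank_bp`` from each
    end of the span, clipped to the chromosome. Flank bases overlapping a
    neighboring gene's coding exons are retained by default
    (``exclude_neighbor_cds=True`` removes them from the territory).
    """
    genome.gene(gene.gene_id)  # KeyError if the gene is not in this genome
    chrom_len = genome.chrom_lengths[gene.chrom]
    introns = intervals.subtract([gene.span], gene.exons)
    introns = intervals.subtract(introns, gene.utr5 + gene.utr3)
    flanks = intervals.clip(
        [(gene.start - flank_bp, gene.start), (gene.end, gene.end + flank_bp)],
        0, chrom_len,
    )
    if exclude_neighbor_cds:
        flanks = intervals.subtract(flanks, list(genome.cds_union(gene.chrom)))
    regions = {
        "utr5": intervals.merge(gene.utr5),
        "utr3": intervals.merge(gene.utr3),
        "intron": introns,
        "flank": flanks,
    }
    return GeneTerritory(gene_id=gene.gene_id, chrom=gene.chrom, regions=regions, is_key=gene.is_key)


def build_all_territories(genome: GenomeModel, flank_bp: int = 100_000,
                          exclude_neighbor_cds: bool = False) -> dict[str, GeneTerritory]:
    return {
        g.gene_id: build_territory(g, genome, flank_bp, exclude_neighbor_cds)
        for g in genome.genes
    }


@dataclass
class KeyGeneSet:
    gene_ids: set[str]
    sources: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)


def assemble_key_gene_set(list_a, list_b, label_a: str = "external_smg",
                          label_b: str = "cohort_smg_fmg") -> KeyGeneSet:
    """Pool two gene lists into one key set with per-gene provenance."""
    sources: dict[str, list[str]] = {}
    for label, ids in ((label_a, list_a), (label_b, list_b)):
        for gid in ids:
            sources.setdefault(gid, []).append(label)
    return KeyGeneSet(gene_ids=set(sources), sources=sources)


def constrained_fraction(territory: GeneTerritory, track: ConstraintTrack,
                         threshold: float = 2.0) -> float:
    """Fraction of territory bases with constraint score >= threshold.

    Bases missing from the track score as unconstrained.
    """
    total = territory.total_length
    if total == 0:
        raise ValueError(f"{territory.gene_id}: zero-length territory")
    ivs = [(s, e) for s, e, _ in territory.all_intervals()]
    hit = track.constrained_bases(territory.chrom, ivs, threshold)
    territory.constrained_bases = hit
    return hit / total


def territories_to_bed(territories: dict[str, GeneTerritory]):
    """BED6 rows (name = gene_id|label) for export."""
    for t in territories.values():
        for s, e, lab in t.all_intervals():
            yield (t.chrom, s, e, f"{t.gene_id}|{lab}")
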