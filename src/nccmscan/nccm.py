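"""Non-coding constraint mutation (NCCM) calling.

A filtered somatic variant becomes an NCCM record for every gene whose
territory contains its anchor base, provided the position is non-coding
(outside every gene's CDS) and its constraint score meets the threshold
(RS >= 2 by default). VAFs are binned to the conventions used for
browser-track coloring: low (0-10%], mid (10-45%], high (>45%].
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from . import intervals
from .constraint import ConstraintTrack
from .filtration import compute_vaf
from .models import GenomeModel, VariantCall
from .territory import GeneTerritory

CATEGORY_FROM_LABEL = {
    "flank": "intergenic",
    "intron": "intronic",
    "utr5": "utr5",
    "utr3": "utr3",
}


@dataclass
class NCCMRecord:
    variant: VariantCall
    gene_id: str
    category: str
    gerp_rs: float
    vaf: float
    vaf_bin: str
    in_lincrna: bool = False
    annotations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sample_id(self) -> str:
        return self.variant.sample_id

    @property
    def site(self):
        return self.variant.site


def vaf_bin(vaf: float) -> str:
    """low for [0, 0.10], mid for (0.10, 0.45], high for (0.45, 1]."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF {vaf} outside [0, 1]")
    if vaf <= 0.10:
        return "low"
    if vaf <= 0.45:
        return "mid"
    return "high"


class TerritoryIndex:
    """Interval index over all genes' labeled territories plus the CDS union."""

    def __init__(self, territories: dict[str, GeneTerritory], genome: GenomeModel):
        self.genome = genome
        self.trees: dict[str, IntervalTree] = {}
        for t in territories.values():
            tree = self.trees.setdefault(t.chrom, IntervalTree())
            for s, e, lab in t.all_intervals():
                tree.addi(s, e, (t.gene_id, lab))
        self.cds: dict[str, list] = {
            chrom: list(genome.cds_union(chrom)) for chrom, _ in genome.chromosomes
        }
        self.linc: dict[str, list] = {}
        for chrom, s, e, _name in genome.lincrnas:
            self.linc.setdefault(chrom, []).append((s, e))
        self.linc = {c: intervals.merge(v) for c, v in self.linc.items()}

    def coding(self, chrom: str, pos0: int) -> bool:
        return intervals.contains(self.cds.get(chrom, []), pos0)

    def in_lincrna(self, chrom: str, pos0: int) -> bool:
        return intervals.contains(self.linc.get(chrom, []), pos0)

    def assignments(self, chrom: str, pos0: int) -> list[tuple[str, str]]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = sorted((iv.data for iv in tree.at(pos0)))
        return hits


def classify_variant(variant: VariantCall, index: TerritoryIndex) -> list[tuple[str, str]]:
    """(gene_id, category) for every territory containing the anchor base.

    Positions inside any coding exon are excluded from all assignments.
    UTR labels shadow intron labels for the same gene.
    """
    pos0 = variant.pos0
    if index.coding(variant.chrom, pos0):
        return []
    priority = {"utr5": 0, "utr3": 0, "intron": 1, "flank": 2}
    best: dict[str, tuple[int, str]] = {}
    for gene_id, label in index.assignments(variant.chrom, pos0):
        pr = priority[label]
        if gene_id not in best or pr < best[gene_id][0]:
            best[gene_id] = (pr, CATEGORY_FROM_LABEL[label])
    return sorted((g, cat) for g, (_, cat) in best.items())


def call_nccms(variants, territories: dict[str, GeneTerritory], track: ConstraintTrack,
               genome: GenomeModel, gerp_min: float = 2.0,
               dedupe_sites: bool = False) -> list[NCCMRecord]:
    """NCCM records for each (variant, gene-territory) assignment passing the
    constraint threshold; indel scores are taken at the anchor base.

    ``dedupe_sites`` keeps one record per (site, gene) across samples.
    """
    index = TerritoryIndex(territories, genome)
    records = []
    seen = set()
    for v in variants:
        score = track.score(v.chrom, v.pos0)
        if score < gerp_min:
            continue
        assigns = classify_variant(v, index)
        if not assigns:
            continue
        vaf = compute_vaf(v) if (v.ref_reads + v.alt_reads) > 0 else 0.0
        linc = index.in_lincrna(v.chrom, v.pos0)
        for gene_id, category in assigns:
            if dedupe_sites:
                key = (v.site, gene_id)
                if key in seen:
                    continue
                seen.add(key)
            records.append(
                NCCMRecord(variant=v, gene_id=gene_id, category=category,
                           gerp_rs=score, vaf=vaf, vaf_bin=vaf_bin(vaf),
                           in_lincrna=linc)
            )
    return records


def nccm_counts(records: list[NCCMRecord]) -> dict[str, int]:
    """Variant-occurrence NCCM count per gene."""
    out: dict[str, int] = {}
    for r in records:
        out[r.gene_id] = out.get(r.gene_id, 0) + 1
    return out


def patient_support(records: list[NCCMRecord]) -> dict[str, int]:
    """Number of distinct samples carrying >= 1 NCCM, per gene."""
    samples: dict[str, set] = {}
    for r in records:
        samples.setdefault(r.gene_id, set()).add(r.sample_id)
    return {g: len(s) for g, s in samples.items()}


def records_frame(records: list[NCCMRecord]):
    import pandas as pd

    rows = [
        {
            "sample_id": r.sample_id, "gene_id": r.gene_id, "chrom": r.variant.chrom,
            "pos": r.variant.pos, "ref": r.variant.ref, "alt": r.variant.alt,
            "category": r.category, "gerp_rs": round(r.gerp_rs, 3),
            "vaf": round(r.vaf, 4), "vaf_bin": r.vaf_bin,
            "in_lincrna": r.in_lincrna,
            "n_annotations": len(r.annotations),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene_id", "chrom", "pos", "ref", "alt", "category",
                 "gerp_rs", "vaf", "vaf_bin", "in_lincrna", "n_annotations"],
    )
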