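"""Recurrent-site (hotspot) detection, promoter offsets, mutual exclusivity.

The canonical use is a TERT-promoter-style analysis: find sites recurrently
mutated across samples, express their positions relative to a reference
gene's start codon (negative = upstream in the gene's orientation), and
check whether pairs of hotspots are mutually exclusive across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .models import GeneModel, VariantCall


@dataclass
class HotspotSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    n_samples: int
    sample_ids: list[str] = field(default_factory=list)
    offset_bp: int | None = None

    @property
    def site(self):
        return (self.chrom, self.pos, self.ref, self.alt)


def find_recurrent(variants: list[VariantCall], min_samples: int = 2) -> list[HotspotSite]:
    """Sites carried by >= min_samples distinct samples, most recurrent first.

    Recurrence counts samples: one sample contributes once per site. The same
    position with different alternate alleles forms distinct sites.
    """
    carriers: dict[tuple, set[str]] = {}
    for v in variants:
        carriers.setdefault(v.site, set()).add(v.sample_id)
    sites = [
        HotspotSite(chrom=c, pos=p, ref=r, alt=a,
                    n_samples=len(samps), sample_ids=sorted(samps))
        for (c, p, r, a), samps in carriers.items()
        if len(samps) >= min_samples
    ]
    sites.sort(key=lambda h: (-h.n_samples, h.chrom, h.pos, h.alt))
    return sites


def promoter_offset(pos: int, gene: GeneModel) -> int:
    """Signed offset (bp) of a 1-based position from the gene's ATG.

    Offset 0 is the first base of the start codon; upstream bases are
    negative in the gene's own orientation: for a plus-strand gene
    ``pos - atg``; for a minus-strand gene ``atg - pos`` (numerically
    larger positions lie upstream).
    """
    atg1 = gene.atg_pos + 1  # 1-based
    if gene.strand == "+":
        return pos - atg1
    return atg1 - pos


def annotate_offsets(sites: list[HotspotSite], gene: GeneModel) -> list[HotspotSite]:
    for h in sites:
        if h.chrom != gene.chrom:
            raise ValueError(f"hotspot on {h.chrom} but gene {gene.gene_id} is on {gene.chrom}")
        h.offset_bp = promoter_offset(h.pos, gene)
    return sites


@dataclass
class ExclusivityResult:
    site_a: tuple
    site_b: tuple
    n_a: int
    n_b: int
    n_both: int
    exclusive: bool


def mutual_exclusivity(sites: list[HotspotSite]) -> list[ExclusivityResult]:
    """Pairwise co-occurrence across samples; a pair is exclusive iff no
    sample carries both sites. A single site is vacuously exclusive."""
    results = []
    for a, b in combinations(sites, 2):
        both = set(a.sample_ids) & set(b.sample_ids)
        results.append(
            ExclusivityResult(site_a=a.site, site_b=b.site,
                              n_a=a.n_samples, n_b=b.n_samples,
                              n_both=len(both), exclusive=not both)
        )
    return results
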