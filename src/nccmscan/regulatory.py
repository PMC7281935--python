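"""Regulatory annotation of NCCMs against interval tracks.

Each track (TFBS ChIP, histone marks, DNase clusters, methylation, curated
elements) is an interval set; an NCCM is annotated by every element whose
interval contains the variant's anchor base. Because tracks are curated
independently, the number of distinct tracks supporting a position is a
simple evidence count for regulatory function.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .nccm import NCCMRecord

KINDS = ("tfbs", "histone", "dnase", "methylation", "curated", "other")


@dataclass
class AnnotationTrack:
    name: str
    kind: str = "other"
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name, elements, kind: str = "other") -> "AnnotationTrack":
        """Build from (chrom, start, end, label) tuples (0-based half-open)."""
        if kind not in KINDS:
            raise ValueError(f"unknown track kind {kind!r}")
        track = cls(name=name, kind=kind)
        for chrom, start, end, label in elements:
            if end > start:
                track.trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
        return track

    def hits(self, chrom: str, pos0: int, proximity: int = 0) -> list[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        if proximity:
            ivs = tree.overlap(pos0 - proximity, pos0 + proximity + 1)
        else:
            ivs = tree.at(pos0)
        return sorted(iv.data for iv in ivs)


def annotate_nccms(nccms: list[NCCMRecord], tracks: list[AnnotationTrack],
                   proximity: int = 0) -> list[NCCMRecord]:
    """Fill each NCCM's annotations with (track name, element label) overlaps.

    Overlap is point-in-interval at the variant anchor base; ``proximity``
    widens the query window by that many bp on each side (used for
    near-miss TFBS reporting). Returns the same records, annotated.
    """
    for rec in nccms:
        ann = []
        for track in tracks:
            for label in track.hits(rec.variant.chrom, rec.variant.pos0, proximity):
                ann.append((track.name, label))
        rec.annotations = ann
    return nccms


def support_count(rec: NCCMRecord) -> int:
    """Number of distinct tracks with >= 1 overlapping element."""
    return len({name for name, _ in rec.annotations})


def regulatory_summary(nccms: list[NCCMRecord], tracks: list[AnnotationTrack] | None = None) -> dict:
    """Fraction annotated, support-count histogram, and per-kind breakdown."""
    if not nccms:
        raise ValueError("no NCCMs to summarize")
    kind_of = {t.name: t.kind for t in tracks} if tracks else {}
    hist: Counter = Counter()
    per_kind: Counter = Counter()
    annotated = 0
    for rec in nccms:
        s = support_count(rec)
        hist[s] += 1
        if s > 0:
            annotated += 1
        for kind in {kind_of.get(name, "other") for name, _ in rec.annotations}:
            per_kind[kind] += 1
    return {
        "n_nccms": len(nccms),
        "fraction_annotated": annotated / len(nccms),
        "support_histogram": dict(sorted(hist.items())),
        "per_kind_counts": dict(sorted(per_kind.items())),
    }
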