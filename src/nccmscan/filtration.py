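"""Somatic-call filtration cascade.

Order of operations mirrors a conservative tumor-only cleanup: caller
concordance (keep only calls both callers agree on), a panel-of-normals
filter (drop sites germline in >= 2 normal samples), and a germline
database filter with a somatic whitelist (database hits survive when
whitelisted). Every step appends to each call's ``filter_trail`` and is a
subset operation on its input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .models import VariantCall

Site = tuple[str, int, str, str]


@dataclass
class PanelOfNormals:
    """Per-site count of normal samples carrying the (allele-specific) site."""

    counts: Counter = field(default_factory=Counter)

    def count(self, site: Site, allele_specific: bool = True) -> int:
        if allele_specific:
            return self.counts[site]
        chrom, pos, _, _ = site
        return sum(n for s, n in self.counts.items() if s[0] == chrom and s[1] == pos)


def build_pon(normal_site_sets) -> PanelOfNormals:
    """Tally germline sites across normal samples.

    ``normal_site_sets`` is an iterable of per-normal site collections;
    multiple alleles at one position count as distinct sites.
    """
    pon = PanelOfNormals()
    for sites in normal_site_sets:
        for site in set(sites):
            pon.counts[tuple(site)] += 1
    return pon


def intersect_callers(calls_a: list[VariantCall], calls_b: list[VariantCall],
                      read_source: str = "a") -> list[VariantCall]:
    """Concordant calls: exact (chrom, pos, ref, alt) match between callers.

    Read counts are taken from the designated caller; provenance records
    both callers. Both call sets must come from the same sample.
    """
    samples_a = {c.sample_id for c in calls_a}
    samples_b = {c.sample_id for c in calls_b}
    if samples_a and samples_b and samples_a != samples_b:
        raise ValueError(f"caller call sets are from different samples: {samples_a} vs {samples_b}")
    if read_source not in ("a", "b"):
        raise ValueError("read_source must be 'a' or 'b'")
    by_site_b = {c.site: c for c in calls_b}
    out = []
    for ca in calls_a:
        cb = by_site_b.get(ca.site)
        if cb is None:
            ca.filter_trail.append(("concordance", "fail"))
            continue
        keep, other = (ca, cb) if read_source == "a" else (cb, ca)
        keep.provenance = ca.provenance | cb.provenance
        keep.filter_trail.append(("concordance", "pass"))
        out.append(keep)
        other.filter_trail.append(("concordance", "pass"))
    for cb in calls_b:
        if cb.site not in {c.site for c in calls_a}:
            cb.filter_trail.append(("concordance", "fail"))
    return out


def filter_pon(calls: list[VariantCall], pon: PanelOfNormals, min_normals: int = 2,
               allele_specific: bool = True) -> list[VariantCall]:
    """Drop calls whose site is germline in >= ``min_normals`` normals."""
    out = []
    for c in calls:
        if pon.count(c.site, allele_specific=allele_specific) >= min_normals:
            c.filter_trail.append(("panel_of_normals", "fail"))
        else:
            c.filter_trail.append(("panel_of_normals", "pass"))
            out.append(c)
    return out


def filter_germline(calls: list[VariantCall], germline_dbs, whitelist_db=None) -> list[VariantCall]:
    """Drop calls present in any germline DB unless whitelisted as somatic."""
    dbs = [set(map(tuple, db)) for db in germline_dbs]
    wl = set(map(tuple, whitelist_db)) if whitelist_db else set()
    out = []
    for c in calls:
        in_db = any(c.site in db for db in dbs)
        if in_db and c.site not in wl:
            c.filter_trail.append(("germline_db", "fail"))
        else:
            outcome = "whitelisted" if in_db else "pass"
            c.filter_trail.append(("germline_db", outcome))
            out.append(c)
    return out


def compute_vaf(call: VariantCall) -> float:
    """Variant allele fraction: alt reads over total reads at the site."""
    depth = call.ref_reads + call.alt_reads
    if depth <= 0:
        raise ValueError(f"zero depth at {call.chrom}:{call.pos}")
    return call.alt_reads / depth


def run_cascade(calls_a, calls_b, pon, germline_dbs, whitelist_db=None,
                min_normals: int = 2, read_source: str = "a") -> dict[str, list[VariantCall]]:
    """Full cascade; returns the surviving call list after each stage."""
    concordant = intersect_callers(calls_a, calls_b, read_source=read_source)
    after_pon = filter_pon(list(concordant), pon, min_normals=min_normals)
    final = filter_germline(list(after_pon), germline_dbs, whitelist_db)
    return {"concordant": concordant, "after_pon": after_pon, "final": final}
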