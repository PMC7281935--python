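"""Per-gene NCCM rates and key-vs-OPCG enrichment statistics.

Rates are NCCMs per 100 kbp of queried territory. The two-group comparison
is a Welch (unequal-variance) two-sided t test on per-gene rates; the same
test applied to per-gene constrained-base fractions serves as the control
that enrichment is not driven by constraint-site availability. Genes are
also ranked at inclusive rate thresholds, and frequently mutated genes
(FMGs) are tallied from a gene x sample incidence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constraint import ConstraintTrack
from .territory import GeneTerritory, constrained_fraction

RATE_UNIT_BP = 100_000


@dataclass
class GeneRate:
    gene_id: str
    nccm_count: int
    territory_length: int
    rate: float  # NCCMs per 100 kbp
    group: str  # 'key' or 'opcg'


@dataclass
class EnrichmentResult:
    mean_key: float
    mean_opcg: float
    t_stat: float
    p_value: float
    control_t: float | None = None
    control_p: float | None = None
    n_key: int = 0
    n_opcg: int = 0


def nccm_rate(nccm_counts: dict[str, int], territories: dict[str, GeneTerritory],
              key_genes: set[str] | None = None) -> list[GeneRate]:
    """Length-normalized NCCM rate per gene; zero-NCCM genes included."""
    key_genes = key_genes if key_genes is not None else {
        g for g, t in territories.items() if t.is_key
    }
    rates = []
    for gene_id, t in territories.items():
        length = t.total_length
        if length == 0:
            raise ValueError(f"{gene_id}: zero-length territory")
        n = nccm_counts.get(gene_id, 0)
        rates.append(
            GeneRate(
                gene_id=gene_id,
                nccm_count=n,
                territory_length=length,
                rate=n / length * RATE_UNIT_BP,
                group="key" if gene_id in key_genes else "opcg",
            )
        )
    return rates


def compare_groups(key_rates, opcg_rates, key_control=None, opcg_control=None) -> EnrichmentResult:
    """Welch two-sided t test of key vs OPCG per-gene rates.

    ``key_control``/``opcg_control`` (per-gene constrained fractions) run
    the same test as the constraint-site-availability control.
    """
    key = np.asarray([r.rate if isinstance(r, GeneRate) else r for r in key_rates], dtype=float)
    opcg = np.asarray([r.rate if isinstance(r, GeneRate) else r for r in opcg_rates], dtype=float)
    if key.size < 2 or opcg.size < 2:
        raise ValueError("each group needs >= 2 genes")
    t, p = stats.ttest_ind(key, opcg, equal_var=False)
    if np.isnan(t):  # zero variance in both groups (e.g. identical values)
        t, p = 0.0, 1.0
    res = EnrichmentResult(
        mean_key=float(key.mean()), mean_opcg=float(opcg.mean()),
        t_stat=float(t), p_value=float(p), n_key=key.size, n_opcg=opcg.size,
    )
    if key_control is not None and opcg_control is not None:
        ct, cp = stats.ttest_ind(np.asarray(key_control, float),
                                 np.asarray(opcg_control, float), equal_var=False)
        if np.isnan(ct):
            ct, cp = 0.0, 1.0
        res.control_t, res.control_p = float(ct), float(cp)
    return res


def enrichment_analysis(rates: list[GeneRate], territories: dict[str, GeneTerritory],
                        track: ConstraintTrack | None = None,
                        threshold: float = 2.0) -> EnrichmentResult:
    """Group rates by key/OPCG and run the comparison plus the control."""
    key = [r for r in rates if r.group == "key"]
    opcg = [r for r in rates if r.group == "opcg"]
    kc = oc = None
    if track is not None:
        kc = [constrained_fraction(territories[r.gene_id], track, threshold) for r in key]
        oc = [constrained_fraction(territories[r.gene_id], track, threshold) for r in opcg]
    return compare_groups(key, opcg, kc, oc)


def rank_genes(rates: list[GeneRate], thresholds=(1.0, 2.0, 3.0, 4.0)) -> dict[float, list[str]]:
    """Genes at rate >= threshold, sorted by descending rate then gene_id."""
    ordered = sorted(rates, key=lambda r: (-r.rate, r.gene_id))
    return {
        float(t): [r.gene_id for r in ordered if r.rate >= t]
        for t in thresholds
    }


def fmg_frequency(incidence: pd.DataFrame, min_samples: int = 4) -> pd.DataFrame:
    """Frequently mutated genes from a gene x sample binary incidence matrix.

    Returns genes mutated in >= ``min_samples`` samples with counts and the
    cohort percentage, sorted by count descending.
    """
    counts = incidence.astype(bool).sum(axis=1)
    n_samples = incidence.shape[1]
    hits = counts[counts >= min_samples].sort_values(ascending=False)
    return pd.DataFrame({
        "gene_id": hits.index,
        "n_samples": hits.values,
        "pct_cohort": (100.0 * hits.values / n_samples).round(1),
    }).reset_index(drop=True)


def rates_frame(rates: list[GeneRate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": r.gene_id, "group": r.group, "nccm_count": r.nccm_count,
             "territory_length": r.territory_length, "rate_per_100kbp": round(r.rate, 4)}
            for r in sorted(rates, key=lambda r: (-r.rate, r.gene_id))
        ]
    )
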