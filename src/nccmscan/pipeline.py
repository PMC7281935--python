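"""End-to-end orchestration: simulate -> filter -> territories -> NCCM ->
enrichment -> regulatory annotation -> TRAP -> hotspots -> signatures.

Runs entirely on the synthetic study, writes per-stage tables under an
output directory, and collects a consolidated JSON summary. Deterministic
given (config, seed).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as nio
from .cohort import cohort_summary, load_metadata
from .enrichment import enrichment_analysis, fmg_frequency, nccm_rate, rank_genes, rates_frame
from .filtration import build_pon, run_cascade
from .hotspot import find_recurrent, mutual_exclusivity
from .models import VariantCall
from .nccm import call_nccms, nccm_counts, patient_support, records_frame
from .regulatory import AnnotationTrack, annotate_nccms, regulatory_summary
from .signatures import count_contexts, make_default_catalog, refit
from .simulate import SimConfig, TRACK_KINDS, generate_study
from .territory import build_all_territories, territories_to_bed
from .trap import affinity_delta, variant_windows

log = logging.getLogger("nccmscan")


@dataclass
class PipelineConfig:
    """Numeric thresholds of the scan plus the simulation block."""

    seed: int = 0
    gerp_min: float = 2.0
    flank: int = 100_000
    pon_min: int = 2
    fmg_min: int = 4
    rate_thresholds: tuple = (1.0, 2.0, 3.0, 4.0)
    window: int = 41
    hotspot_min_samples: int = 2
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if min(self.gerp_min, self.flank, self.pon_min, self.fmg_min, self.window) <= 0:
            raise ValueError("thresholds must be positive")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed
        self.sim.flank = self.flank

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _coding_incidence(genome, calls_by_sample) -> pd.DataFrame:
    """Binary gene x sample matrix of coding (CDS-overlapping) mutations."""
    from . import intervals

    samples = sorted(calls_by_sample)
    genes = [g.gene_id for g in genome.genes]
    mat = pd.DataFrame(False, index=genes, columns=samples)
    for sample, calls in calls_by_sample.items():
        for c in calls:
            for g in genome.genes:
                if g.chrom == c.chrom and intervals.contains(g.cds, c.pos0):
                    mat.loc[g.gene_id, sample] = True
    return mat


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    os.makedirs(outdir, exist_ok=True)
    summary: dict = {"seed": config.seed}

    log.info("stage: simulate")
    genome, sequences, track, cohort, reg_tracks, pfms = generate_study(
        config.sim, outdir=os.path.join(outdir, "sim")
    )

    log.info("stage: cohort metadata")
    metas = load_metadata()
    summary["cohort"] = {
        k: v for k, v in cohort_summary(metas).items() if k != "per_sample_totals"
    }

    log.info("stage: filtration")
    pon = build_pon(cohort.normals.values())
    filtered: dict[str, list[VariantCall]] = {}
    counts_stage = {"raw_a": 0, "concordant": 0, "after_pon": 0, "final": 0}
    for sample in cohort.samples:
        stages = run_cascade(
            cohort.calls_a[sample], cohort.calls_b[sample], pon,
            [cohort.germline_db], cohort.whitelist, min_normals=config.pon_min,
        )
        filtered[sample] = stages["final"]
        counts_stage["raw_a"] += len(cohort.calls_a[sample])
        for k in ("concordant", "after_pon", "final"):
            counts_stage[k] += len(stages[k])
    summary["filtration"] = counts_stage
    all_filtered = [c for calls in filtered.values() for c in calls]

    log.info("stage: territories")
    territories = build_all_territories(genome, flank_bp=config.flank)
    nio.write_bed(os.path.join(outdir, "territories.bed"), territories_to_bed(territories))

    log.info("stage: NCCM calling")
    records = call_nccms(all_filtered, territories, track, genome, gerp_min=config.gerp_min)
    records_frame(records).to_csv(os.path.join(outdir, "nccm.tsv"), sep="\t", index=False)
    summary["nccm"] = {
        "n_records": len(records),
        "n_variants": len({r.site + (r.sample_id,) for r in records}),
        "patient_support": patient_support(records),
    }

    log.info("stage: enrichment")
    rates = nccm_rate(nccm_counts(records), territories)
    rates_frame(rates).to_csv(os.path.join(outdir, "rates.tsv"), sep="\t", index=False)
    enr = enrichment_analysis(rates, territories, track, threshold=config.gerp_min)
    summary["enrichment"] = {
        "mean_key": enr.mean_key, "mean_opcg": enr.mean_opcg,
        "t_stat": enr.t_stat, "p_value": enr.p_value,
        "control_p": enr.control_p, "n_key": enr.n_key, "n_opcg": enr.n_opcg,
    }
    summary["gene_rankings"] = {
        str(t): genes for t, genes in rank_genes(rates, config.rate_thresholds).items()
    }
    incidence = _coding_incidence(genome, filtered)
    fmg = fmg_frequency(incidence, min_samples=config.fmg_min)
    summary["fmg"] = fmg.to_dict(orient="records")

    log.info("stage: regulatory annotation")
    tracks = [
        AnnotationTrack.from_intervals(name, elems, TRACK_KINDS.get(name, "other"))
        for name, elems in reg_tracks.items()
    ]
    annotate_nccms(records, tracks)
    if records:
        summary["regulatory"] = regulatory_summary(records, tracks)

    log.info("stage: TRAP deltas")
    trap_rows = []
    for rec in records[:25]:  # top-of-table report; full scan via the trap CLI
        wt, mut = variant_windows(sequences, rec.variant, window=config.window)
        for d in affinity_delta(wt, mut, pfms, top=5):
            trap_rows.append({
                "sample_id": rec.sample_id, "gene_id": rec.gene_id,
                "chrom": rec.variant.chrom, "pos": rec.variant.pos,
                "tf_name": d.tf_name, "delta": d.delta, "rank": d.rank,
            })
    pd.DataFrame(trap_rows).to_csv(os.path.join(outdir, "trap_deltas.tsv"), sep="\t", index=False)

    log.info("stage: hotspots")
    hotspots = find_recurrent(all_filtered, min_samples=config.hotspot_min_samples)
    summary["hotspots"] = {
        "n_sites": len(hotspots),
        "top": [
            {"chrom": h.chrom, "pos": h.pos, "ref": h.ref, "alt": h.alt, "n": h.n_samples}
            for h in hotspots[:5]
        ],
        "n_exclusive_pairs": sum(r.exclusive for r in mutual_exclusivity(hotspots[:10])),
    }

    log.info("stage: signatures")
    catalog = make_default_catalog()
    spectrum = count_contexts(all_filtered, sequences)
    if spectrum.total > 0:
        fit = refit(spectrum, catalog)
        summary["signatures"] = {
            "n_spms": int(spectrum.total),
            "exposures": {k: round(v, 4) for k, v in fit.exposures.items()},
            "reconstruction_cosine": round(fit.reconstruction_cosine, 4),
        }

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log.info("pipeline complete: %s", outdir)
    return summary
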