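"""Synthetic toy study generator.

Produces a self-contained miniature of a tumor-cohort WGS analysis: a toy
genome with gene models, a block-structured per-base constraint track, a
cohort of paired-caller somatic VCFs with read counts and germline
contamination, germline databases with a somatic whitelist, regulatory
annotation tracks, and JASPAR-format PFMs. A planted elevation of the
constrained non-coding mutation rate inside designated key-gene
territories gives downstream enrichment analysis a known ground truth,
recorded per variant in a truth table.

All outputs are deterministic functions of (config, seed): every stage
draws from its own `numpy` Generator spawned from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import intervals
from .constraint import ConstraintTrack
from .models import ConfigurationError, GeneModel, GenomeModel, VariantCall

BASES = "ACGT"

# fixed nuisance constants of the toy model (documented in docs/methods.md)
_GERMLINE_POOL_DENSITY = 2e-5  # germline sites per bp in the cohort pool
_MEAN_BLOCK_LEN = 100.0  # mean constrained-element length, bp
_TUMOR_DEPTH = 75  # mean tumor coverage, matching a ~75x regime
_MIN_DEPTH = 10


@dataclass
class SimConfig:
    """Generative knobs of the toy study.

    Defaults mirror the real-study regime where one exists: a 100 kbp
    intergenic flank, ~15% of bases constrained (RS >= 2), a 38-sample
    cohort at ~75x depth, and an indel share of ~4% of somatic calls.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 8
    n_key_genes: int = 2
    flank: int = 100_000
    constrained_block_rate: float = 0.15
    base_mut_rate: float = 2.5e-6
    enrichment_factor: float = 4.0
    n_samples: int = 38
    germline_contamination_rate: float = 0.10
    discordance_rate: float = 0.05
    indel_fraction: float = 0.04
    track_coverage: float = 0.10
    germline_db_sensitivity: float = 0.90
    whitelist_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "constrained_block_rate",
            "base_mut_rate",
            "germline_contamination_rate",
            "discordance_rate",
            "indel_fraction",
            "track_coverage",
            "germline_db_sensitivity",
            "whitelist_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.enrichment_factor < 1.0:
            raise ConfigurationError("enrichment_factor must be >= 1")
        if self.flank <= 0:
            raise ConfigurationError("flank must be positive")
        if self.chrom_length <= 2 * self.flank:
            raise ConfigurationError("chrom_length must exceed 2*flank")
        if self.n_key_genes > self.n_genes:
            raise ConfigurationError("n_key_genes exceeds n_genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ------------------------------------------------------------- genome


def _gene_structure(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_exons = int(rng.integers(2, 7))
    exon_lens = rng.integers(150, 401, n_exons)
    intron_lens = rng.integers(500, 3001, n_exons - 1)
    return exon_lens, intron_lens


def _build_gene(gene_id, chrom, start, exon_lens, intron_lens, strand, rng) -> GeneModel:
    exons = []
    cur = start
    for i, el in enumerate(exon_lens):
        exons.append((cur, cur + int(el)))
        cur += int(el)
        if i < len(intron_lens):
            cur += int(intron_lens[i])
    end = exons[-1][1]
    u5 = int(rng.integers(40, min(150, exon_lens[0 if strand == "+" else -1] - 60) + 1))
    u3 = int(rng.integers(40, min(150, exon_lens[-1 if strand == "+" else 0] - 60) + 1))
    left, right = exons[0], exons[-1]
    if strand == "+":
        utr5 = [(left[0], left[0] + u5)]
        utr3 = [(right[1] - u3, right[1])]
    else:
        utr5 = [(right[1] - u5, right[1])]
        utr3 = [(left[0], left[0] + u3)]
    cds = intervals.subtract(exons, utr5 + utr3)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
        exons=exons, cds=cds, utr5=utr5, utr3=utr3,
    )


def generate_genome(config: SimConfig) -> tuple[GenomeModel, dict[str, str]]:
    """Toy genome: uniform-random FASTA plus non-overlapping gene models.

    Raises ConfigurationError when the requested genes cannot be placed on
    the chromosomes with minimal spacing.
    """
    rng = config.rng(0)
    chroms = [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)]
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    margin, min_gap = 1_000, 200
    genes: list[GeneModel] = []
    gi = 0
    for (chrom, length), k in zip(chroms, per_chrom):
        if k == 0:
            continue
        structures = [_gene_structure(rng) for _ in range(k)]
        span_lens = [int(el.sum() + il.sum()) for el, il in structures]
        free = length - 2 * margin - sum(span_lens) - (k + 1) * min_gap
        if free < 0:
            raise ConfigurationError(
                f"{chrom}: cannot place {k} genes on {length} bp"
            )
        gaps = min_gap + np.floor(rng.dirichlet(np.ones(k + 1)) * free).astype(int)
        cur = margin
        for j, (el, il) in enumerate(structures):
            cur += int(gaps[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_build_gene(f"G{gi:04d}", chrom, cur, el, il, strand, rng))
            cur += span_lens[j]
            gi += 1

    if config.n_key_genes and genes:
        for idx in rng.choice(len(genes), size=config.n_key_genes, replace=False):
            genes[int(idx)].is_key = True

    # lincRNAs dropped into intergenic gaps
    lincrnas = []
    li = 0
    for chrom, length in chroms:
        spans = intervals.merge([(g.start, g.end) for g in genes if g.chrom == chrom])
        for gs, ge in intervals.subtract([(0, length)], spans):
            if ge - gs >= 4_000 and rng.random() < 0.5:
                ll = int(rng.integers(1_000, 3_001))
                s = int(rng.integers(gs, ge - ll))
                lincrnas.append((chrom, s, s + ll, f"LINC{li:03d}"))
                li += 1

    genome = GenomeModel(chromosomes=chroms, genes=genes, lincrnas=lincrnas)

    alphabet = np.frombuffer(BASES.encode(), dtype=np.uint8)
    sequences = {
        chrom: bytes(alphabet[rng.integers(0, 4, length, dtype=np.uint8)]).decode()
        for chrom, length in chroms
    }
    return genome, sequences


# ---------------------------------------------------------- constraint


def generate_constraint_track(genome: GenomeModel, config: SimConfig) -> ConstraintTrack:
    """Two-component RS-like score track.

    Background bases score < 2; contiguous constrained blocks score >= 2.
    Block/gap lengths are geometric-like so the realized constrained
    fraction converges to ``constrained_block_rate`` on Mbp scales.
    """
    rng = config.rng(1)
    r = config.constrained_block_rate
    arrays = {}
    for chrom, length in genome.chromosomes:
        a = np.empty(length, dtype=np.float32)
        if r <= 0.0:
            pos = 0
            while pos < length:
                run = int(rng.exponential(_MEAN_BLOCK_LEN)) + 1
                a[pos:pos + run] = rng.uniform(-8.0, 1.9)
                pos += run
            arrays[chrom] = a
            continue
        mean_gap = _MEAN_BLOCK_LEN * (1.0 - r) / r
        pos = 0
        in_block = rng.random() < r
        while pos < length:
            if in_block:
                run = int(rng.exponential(_MEAN_BLOCK_LEN)) + 1
                score = rng.uniform(2.0, 6.0)
            else:
                run = int(rng.exponential(mean_gap)) + 1 if mean_gap > 0 else 0
                score = rng.uniform(-8.0, 1.9)
            if run:
                a[pos:pos + run] = score
                pos += run
            in_block = not in_block
        arrays[chrom] = a
    return ConstraintTrack(arrays)


# ---------------------------------------------------- regulatory tracks

TRACK_KINDS = {
    "TxnFactorChIP": "tfbs",
    "H3K4Me3": "histone",
    "DNaseClusters": "dnase",
    "BrainMethylation": "methylation",
    "ORegAnno": "curated",
}


def generate_regulatory_tracks(
    genome: GenomeModel, config: SimConfig
) -> dict[str, list[tuple[str, int, int, str]]]:
    """Synthetic annotation tracks, each covering ~``track_coverage`` of the genome.

    Elements are short intervals scattered independently per track so that
    multi-track support counts behave like independent evidence.
    """
    rng = config.rng(4)
    tracks: dict[str, list[tuple[str, int, int, str]]] = {}
    for name in TRACK_KINDS:
        elems = []
        ei = 0
        for chrom, length in genome.chromosomes:
            mean_elem = 300.0
            n_elems = int(config.track_coverage * length / mean_elem)
            if n_elems == 0:
                continue
            starts = np.sort(rng.integers(0, length, n_elems))
            for s in starts:
                e = min(length, int(s) + int(rng.exponential(mean_elem)) + 50)
                elems.append((chrom, int(s), e, f"{name}_{ei:05d}"))
                ei += 1
        tracks[name] = elems
    return tracks


# -------------------------------------------------------------- cohort


@dataclass
class CohortData:
    """In-memory synthetic cohort: caller outputs, databases, and truth."""

    samples: list[str]
    calls_a: dict[str, list[VariantCall]]
    calls_b: dict[str, list[VariantCall]]
    normals: dict[str, list[tuple[str, int, str, str]]]
    germline_db: set[tuple[str, int, str, str]]
    whitelist: set[tuple[str, int, str, str]]
    truth: pd.DataFrame


def _territory_cds_masks(genome, track, config):
    """Per-chromosome boolean masks of the enhanced stratum components."""
    masks = {}
    for chrom, length in genome.chromosomes:
        cds = np.zeros(length, dtype=bool)
        for s, e in genome.cds_union(chrom):
            cds[s:e] = True
        key = np.zeros(length, dtype=bool)
        for g in genome.key_genes:
            if g.chrom == chrom:
                key[max(0, g.start - config.flank):min(length, g.end + config.flank)] = True
        constrained = track.constrained_mask(chrom)
        masks[chrom] = (cds, key, constrained)
    return masks


def _draw_variant(rng, chrom, pos0, seq, config, length):
    ref = seq[pos0]
    if rng.random() < config.indel_fraction:
        ilen = int(rng.integers(1, 6))
        if rng.random() < 0.5 and pos0 + 1 + ilen <= length:  # deletion
            ref = seq[pos0:pos0 + 1 + ilen]
            alt = seq[pos0]
        else:  # insertion
            alt = ref + "".join(BASES[i] for i in rng.integers(0, 4, ilen))
    else:
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
    return ref, alt


def _read_counts(rng, vaf):
    depth = max(_MIN_DEPTH, int(rng.poisson(_TUMOR_DEPTH)))
    alt_reads = int(rng.binomial(depth, vaf))
    alt_reads = max(1, alt_reads)
    return depth - alt_reads, alt_reads


def generate_cohort(
    genome: GenomeModel,
    sequences: dict[str, str],
    track: ConstraintTrack,
    config: SimConfig,
) -> CohortData:
    """Plant somatic mutations, germline leakage, and caller discordance.

    Somatic positions mutate at ``base_mut_rate`` per bp per sample, except
    constrained non-coding positions inside key-gene territories which
    mutate at ``base_mut_rate * enrichment_factor``. Every planted call is
    recorded in the truth table with its stratum labels.
    """
    rng = config.rng(2)
    masks = _territory_cds_masks(genome, track, config)
    strata = {}
    for chrom, length in genome.chromosomes:
        cds, key, constrained = masks[chrom]
        enhanced = key & constrained & ~cds
        strata[chrom] = (
            np.flatnonzero(enhanced),
            np.flatnonzero(~enhanced),
            enhanced,
            key,
            constrained,
        )

    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    calls_a: dict[str, list[VariantCall]] = {s: [] for s in samples}
    calls_b: dict[str, list[VariantCall]] = {s: [] for s in samples}
    truth_rows = []

    # cohort-level germline pool shared by tumors, normals, and databases
    genome_size = sum(length for _, length in genome.chromosomes)
    n_pool = max(20, int(genome_size * _GERMLINE_POOL_DENSITY))
    pool = []
    seen = set()
    while len(pool) < n_pool:
        ci = int(rng.integers(0, len(genome.chromosomes)))
        chrom, length = genome.chromosomes[ci]
        p0 = int(rng.integers(0, length))
        ref = sequences[chrom][p0]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        site = (chrom, p0 + 1, ref, alt)
        if site not in seen:
            seen.add(site)
            pool.append(site)
    # carrier frequencies skewed toward rare: rare sites evade the PoN and
    # must be caught by the (more sensitive) germline databases
    pool_freq = rng.beta(0.5, 1.5, size=len(pool))

    def emit(sample, chrom, pos1, ref, alt, vaf, origin, pos0):
        _, _, enhanced, key, constrained = strata[chrom]
        ref_reads, alt_reads = _read_counts(rng, vaf)
        concordant = rng.random() >= config.discordance_rate
        call_kw = dict(sample_id=sample, chrom=chrom, pos=pos1, ref=ref, alt=alt,
                       ref_reads=ref_reads, alt_reads=alt_reads)
        if concordant:
            calls_a[sample].append(VariantCall(provenance={"callerA"}, **call_kw))
            calls_b[sample].append(VariantCall(provenance={"callerB"}, **call_kw))
            n_callers = 2
        elif rng.random() < 0.5:
            calls_a[sample].append(VariantCall(provenance={"callerA"}, **call_kw))
            n_callers = 1
        else:
            calls_b[sample].append(VariantCall(provenance={"callerB"}, **call_kw))
            n_callers = 1
        truth_rows.append({
            "sample_id": sample, "chrom": chrom, "pos": pos1, "ref": ref, "alt": alt,
            "vtype": "SPM" if len(ref) == 1 and len(alt) == 1 else "SIM",
            "origin": origin,
            "constrained": bool(constrained[pos0]),
            "in_key_territory": bool(key[pos0]),
            "enhanced": bool(enhanced[pos0]),
            "n_callers": n_callers,
            "vaf_true": round(float(vaf), 4),
        })

    enhanced_rate = min(1.0, config.base_mut_rate * config.enrichment_factor)
    for sample in samples:
        used: set[tuple[str, int]] = set()
        for chrom, length in genome.chromosomes:
            enh_pos, bg_pos, *_ = strata[chrom]
            seq = sequences[chrom]
            for positions, rate in ((enh_pos, enhanced_rate), (bg_pos, config.base_mut_rate)):
                if positions.size == 0 or rate == 0.0:
                    continue
                k = int(rng.binomial(positions.size, rate))
                if k == 0:
                    continue
                chosen = rng.choice(positions, size=k, replace=False)
                for p0 in sorted(int(p) for p in chosen):
                    ref, alt = _draw_variant(rng, chrom, p0, seq, config, length)
                    vaf = float(np.clip(rng.beta(2.0, 4.0), 0.02, 0.98))
                    used.add((chrom, p0))
                    emit(sample, chrom, p0 + 1, ref, alt, vaf, "somatic", p0)
        # germline leakage into the tumor call set
        if config.germline_contamination_rate > 0:
            for site in pool:
                chrom, pos1, ref, alt = site
                if rng.random() < config.germline_contamination_rate and (chrom, pos1 - 1) not in used:
                    vaf = float(np.clip(rng.beta(20.0, 20.0), 0.05, 0.95))
                    emit(sample, chrom, pos1, ref, alt, vaf, "germline", pos1 - 1)

    normals = {}
    for i in range(config.n_samples):
        nid = f"N{i:03d}"
        normals[nid] = [site for site, q in zip(pool, pool_freq) if rng.random() < q]

    germline_db = {site for site in pool if rng.random() < config.germline_db_sensitivity}
    somatic_sites = sorted(
        {(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in truth_rows if r["origin"] == "somatic"}
    )
    whitelist = {site for site in somatic_sites if rng.random() < config.whitelist_fraction}
    germline_db |= whitelist  # COSMIC-like sites wrongly present in germline DBs

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "vtype", "origin",
                 "constrained", "in_key_territory", "enhanced", "n_callers", "vaf_true"],
    )
    return CohortData(samples, calls_a, calls_b, normals, germline_db, whitelist, truth)


# ----------------------------------------------------------------- PFMs


def generate_pfms(config: SimConfig, depth: int = 100):
    """JASPAR-style PFM set: >= 5 matrices plus one high-information matrix.

    The designated matrix ('FOXA1LIKE') carries a near-invariant T column,
    mimicking a factor whose binding collapses when that base mutates.
    """
    from .trap import PFMModel  # local import to avoid a cycle

    rng = config.rng(3)
    pfms = []

    consensus = "TGGTTTGC"  # invariant column: index 3 (T)
    counts = np.full((4, len(consensus)), 10, dtype=int)
    for j, base in enumerate(consensus):
        counts[:, j] = 10
        counts[BASES.index(base), j] = depth - 30
    counts[:, 3] = 1
    counts[BASES.index("T"), 3] = depth - 3
    pfms.append(PFMModel("FOXA1LIKE", counts))

    for i in range(5):
        w = int(rng.integers(6, 16))
        cols = []
        for _ in range(w):
            probs = rng.dirichlet(np.full(4, 0.5))
            cols.append(rng.multinomial(depth, probs))
        pfms.append(PFMModel(f"TF{i + 1:02d}", np.array(cols).T))
    return pfms


# ------------------------------------------------------------ writing


def write_study(outdir, genome, sequences, track, cohort, tracks=None, pfms=None, config=None):
    """Write every artifact of the toy study to ``outdir``."""
    import os

    import yaml

    from . import io as nio
    from .trap import write_jaspar

    os.makedirs(outdir, exist_ok=True)
    contigs = genome.chrom_lengths
    nio.write_fasta(os.path.join(outdir, "genome.fa"), sequences)
    nio.write_gtf(os.path.join(outdir, "genes.gtf"), genome)
    nio.write_bed(os.path.join(outdir, "lincrna.bed"), genome.lincrnas)
    track.to_bedgraph(os.path.join(outdir, "constraint.bedGraph"))

    for sub in ("caller_a", "caller_b", "normals"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    for sample in cohort.samples:
        nio.write_vcf(os.path.join(outdir, "caller_a", f"{sample}.vcf"),
                      cohort.calls_a[sample], contigs, sample=sample)
        nio.write_vcf(os.path.join(outdir, "caller_b", f"{sample}.vcf"),
                      cohort.calls_b[sample], contigs, sample=sample)
    for nid, sites in cohort.normals.items():
        nio.write_vcf(os.path.join(outdir, "normals", f"{nid}.vcf"), sites, contigs)
    nio.write_vcf(os.path.join(outdir, "germline_db.vcf"), sorted(cohort.germline_db), contigs)
    nio.write_vcf(os.path.join(outdir, "whitelist.vcf"), sorted(cohort.whitelist), contigs)
    cohort.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    if tracks is not None:
        os.makedirs(os.path.join(outdir, "tracks"), exist_ok=True)
        manifest = {}
        for name, elems in tracks.items():
            rel = os.path.join("tracks", f"{name}.bed")
            nio.write_bed(os.path.join(outdir, rel), elems)
            manifest[name] = {"path": rel, "kind": TRACK_KINDS.get(name, "other")}
        with open(os.path.join(outdir, "tracks", "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh)
    if pfms is not None:
        write_jaspar(pfms, os.path.join(outdir, "pfms.jaspar"))
    if config is not None:
        with open(os.path.join(outdir, "sim_config.yaml"), "w") as fh:
            yaml.safe_dump(asdict(config), fh)


def generate_study(config: SimConfig, outdir=None):
    """Run every generator stage; optionally write all artifacts to disk."""
    genome, sequences = generate_genome(config)
    track = generate_constraint_track(genome, config)
    cohort = generate_cohort(genome, sequences, track, config)
    tracks = generate_regulatory_tracks(genome, config)
    pfms = generate_pfms(config)
    if outdir is not None:
        write_study(outdir, genome, sequences, track, cohort, tracks, pfms, config)
    return genome, sequences, track, cohort, tracks, pfms
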