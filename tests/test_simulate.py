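"""Synthetic-study generator: determinism, planted structure, file dialects."""

import numpy as np
import pandas as pd
import pytest

from nccmscan.models import ConfigurationError
from nccmscan.simulate import (
    SimConfig,
    generate_cohort,
    generate_constraint_track,
    generate_genome,
    generate_pfms,
    generate_study,
)
from nccmscan.trap import matrix_position_conservation, read_jaspar, write_jaspar


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(constrained_block_rate=1.5)
    with pytest.raises(ConfigurationError):
        SimConfig(enrichment_factor=0.5)
    with pytest.raises(ConfigurationError):
        SimConfig(chrom_length=150_000, flank=100_000)


def test_genome_determinism_and_file_identity(tmp_path):
    cfg = SimConfig(seed=5, chrom_length=300_000, flank=20_000, n_genes=6, n_samples=3)
    for sub in ("a", "b"):
        generate_study(cfg, outdir=tmp_path / sub)
    for rel in ("genome.fa", "genes.gtf", "constraint.bedGraph", "truth.tsv",
                "pfms.jaspar", "caller_a/S000.vcf", "normals/N001.vcf"):
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_zero_genes_yields_empty_gtf(tmp_path):
    cfg = SimConfig(seed=0, n_genes=0, n_key_genes=0, chrom_length=250_000, flank=20_000)
    genome, seqs = generate_genome(cfg)
    assert genome.genes == []
    from nccmscan.io import write_gtf

    path = tmp_path / "empty.gtf"
    write_gtf(path, genome)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert lines == []


def test_gene_spans_disjoint_brute_force():
    cfg = SimConfig(seed=3, n_chromosomes=1, chrom_length=2_000_000, n_genes=20,
                    n_key_genes=4, flank=50_000)
    genome, _ = generate_genome(cfg)
    assert len(genome.genes) == 20
    spans = [(g.chrom, g.start, g.end) for g in genome.genes]
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            ci, si, ei = spans[i]
            cj, sj, ej = spans[j]
            assert ci != cj or ei <= sj or ej <= si, f"genes {i},{j} overlap"


def test_too_many_genes_is_configuration_error():
    cfg = SimConfig(seed=0, n_chromosomes=1, chrom_length=201_000, n_genes=50,
                    n_key_genes=1, flank=100_000)
    with pytest.raises(ConfigurationError):
        generate_genome(cfg)


def test_gene_structure_invariants():
    cfg = SimConfig(seed=9, chrom_length=500_000, n_genes=10, n_key_genes=2, flank=20_000)
    genome, _ = generate_genome(cfg)
    from nccmscan import intervals

    for g in genome.genes:
        exonic = intervals.merge(g.exons)
        covered = intervals.merge(g.cds + g.utr5 + g.utr3)
        assert covered == exonic  # exon union = CDS u UTR5 u UTR3
        assert not intervals.intersect(g.cds, g.utr5 + g.utr3)
        assert g.strand in "+-"


@pytest.mark.parametrize("rate", [0.0, 0.15])
def test_constraint_track_realized_fraction(rate):
    cfg = SimConfig(seed=2, n_chromosomes=1, chrom_length=1_000_000,
                    n_genes=4, n_key_genes=1, constrained_block_rate=rate)
    genome, _ = generate_genome(cfg)
    track = generate_constraint_track(genome, cfg)
    frac = track.constrained_fraction_genome()
    if rate == 0.0:
        assert frac == 0.0
    else:
        assert rate - 0.02 <= frac <= rate + 0.02


def test_constraint_blocks_half_open_non_overlapping():
    cfg = SimConfig(seed=4, n_chromosomes=1, chrom_length=200_000, n_genes=2,
                    n_key_genes=1, flank=30_000)
    genome, _ = generate_genome(cfg)
    track = generate_constraint_track(genome, cfg)
    mask = track.constrained_mask("chr1")
    # sweep oracle: reconstruct blocks from the per-base mask
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    blocks = []
    start = 0 if mask[0] else None
    for e in edges:
        if start is None:
            start = e + 1
        else:
            blocks.append((start, e + 1))
            start = None
    if start is not None:
        blocks.append((start, mask.size))
    assert all(s < e for s, e in blocks)
    assert all(blocks[i][1] <= blocks[i + 1][0] for i in range(len(blocks) - 1))
    assert sum(e - s for s, e in blocks) == int(mask.sum())


def test_zero_mutation_rate_empty_vcfs():
    cfg = SimConfig(seed=1, chrom_length=250_000, flank=20_000, n_genes=4,
                    n_key_genes=1, base_mut_rate=0.0,
                    germline_contamination_rate=0.0, n_samples=3)
    genome, seqs = generate_genome(cfg)
    track = generate_constraint_track(genome, cfg)
    cohort = generate_cohort(genome, seqs, track, cfg)
    assert all(not v for v in cohort.calls_a.values())
    assert all(not v for v in cohort.calls_b.values())
    assert cohort.truth.empty


def test_zero_discordance_makes_callers_identical(small_study):
    cfg = SimConfig(seed=8, chrom_length=400_000, flank=20_000, n_genes=6,
                    n_key_genes=2, base_mut_rate=2e-5, discordance_rate=0.0, n_samples=5)
    genome, seqs = generate_genome(cfg)
    track = generate_constraint_track(genome, cfg)
    cohort = generate_cohort(genome, seqs, track, cfg)
    for s in cohort.samples:
        sites_a = {c.site for c in cohort.calls_a[s]}
        sites_b = {c.site for c in cohort.calls_b[s]}
        assert sites_a == sites_b


def test_truth_table_conservation(small_study):
    """Union of caller records equals the truth table, per sample."""
    cohort = small_study["cohort"]
    truth_sites = {
        (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
        for r in cohort.truth.itertuples()
    }
    vcf_sites = set()
    for s in cohort.samples:
        for c in cohort.calls_a[s] + cohort.calls_b[s]:
            vcf_sites.add((s, c.chrom, c.pos, c.ref, c.alt))
    assert vcf_sites == truth_sites


def test_planted_enrichment_ratio_from_truth():
    """Truth-table mutation rate ratio recovers enrichment_factor=4 within [3, 5]."""
    cfg = SimConfig(seed=21, n_chromosomes=4, chrom_length=1_000_000, n_genes=120,
                    n_key_genes=50, flank=10_000, base_mut_rate=5e-6,
                    enrichment_factor=4.0, n_samples=38,
                    germline_contamination_rate=0.0, discordance_rate=0.0)
    genome, seqs = generate_genome(cfg)
    track = generate_constraint_track(genome, cfg)
    cohort = generate_cohort(genome, seqs, track, cfg)
    som = cohort.truth[cohort.truth.origin == "somatic"]
    assert len(som) >= 500
    from nccmscan.simulate import _territory_cds_masks

    n_enh = n_bg = 0
    for chrom, _ in genome.chromosomes:
        cds, key, constrained = _territory_cds_masks(genome, track, cfg)[chrom]
        enhanced = key & constrained & ~cds
        n_enh += int(enhanced.sum())
        n_bg += int((~enhanced).sum())
    rate_enh = som.enhanced.sum() / (n_enh * cfg.n_samples)
    rate_bg = (~som.enhanced).sum() / (n_bg * cfg.n_samples)
    assert 3.0 <= rate_enh / rate_bg <= 5.0


def test_planted_rates_within_binomial_error(small_study):
    """Empirical background mutation rate agrees with the configured rate (3 sigma)."""
    cfg, cohort = small_study["config"], small_study["cohort"]
    som = small_study["cohort"].truth
    som = som[(som.origin == "somatic") & (~som.enhanced)]
    genome_size = sum(l for _, l in small_study["genome"].chromosomes)
    from nccmscan.simulate import _territory_cds_masks

    masks = _territory_cds_masks(small_study["genome"], small_study["track"], cfg)
    n_enh = sum(int((key & con & ~cds).sum()) for cds, key, con in masks.values())
    n_trials = (genome_size - n_enh) * cfg.n_samples
    expected = n_trials * cfg.base_mut_rate
    assert abs(len(som) - expected) <= 3 * np.sqrt(expected)


def test_pfm_depths_and_roundtrip(tmp_path, small_study):
    pfms = small_study["pfms"]
    assert len(pfms) >= 5
    for p in pfms:
        depths = p.counts.sum(axis=0)
        assert (depths == depths[0]).all()
        assert 6 <= p.width <= 15
        assert (p.counts >= 0).all() and (p.counts == p.counts.astype(int)).all()
    path = tmp_path / "pfms.jaspar"
    write_jaspar(pfms, path)
    back = read_jaspar(path)
    for p, q in zip(pfms, back):
        assert p.tf_name == q.tf_name
        np.testing.assert_array_equal(p.counts, q.counts)
    # write-parse-write is a fixed point
    path2 = tmp_path / "pfms2.jaspar"
    write_jaspar(back, path2)
    assert path.read_text() == path2.read_text()


def test_designated_pfm_has_conserved_column(small_study):
    pfm = next(p for p in small_study["pfms"] if p.tf_name == "FOXA1LIKE")
    ics = [matrix_position_conservation(pfm, j) for j in range(pfm.width)]
    assert max(ics) >= 1.5
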