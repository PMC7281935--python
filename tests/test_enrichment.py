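"""Rates per 100 kbp, Welch comparison, gene ranking, FMG tally."""

import math

import numpy as np
import pandas as pd
import pytest

from nccmscan.enrichment import (
    compare_groups,
    enrichment_analysis,
    fmg_frequency,
    nccm_rate,
    rank_genes,
)
from nccmscan.nccm import call_nccms, nccm_counts
from nccmscan.simulate import SimConfig, generate_cohort, generate_constraint_track, generate_genome
from nccmscan.territory import build_all_territories


def _rates_for(cfg):
    genome, seqs = generate_genome(cfg)
    track = generate_constraint_track(genome, cfg)
    cohort = generate_cohort(genome, seqs, track, cfg)
    calls = [c for s in cohort.samples for c in cohort.calls_a[s]]
    terr = build_all_territories(genome, flank_bp=cfg.flank)
    recs = call_nccms(calls, terr, track, genome)
    return nccm_rate(nccm_counts(recs), terr), terr, track


class TestRates:
    def test_zero_nccms_rate_zero(self, toy_genome):
        terr = build_all_territories(toy_genome, flank_bp=500)
        rates = nccm_rate({}, terr)
        assert {r.rate for r in rates} == {0.0}
        assert len(rates) == 2  # zero-NCCM genes included

    def test_arithmetic(self, toy_genome):
        terr = build_all_territories(toy_genome, flank_bp=500)
        terr = {"GB": terr["GB"]}
        # GB territory = 2 x 500 flanks = 1000 bp
        rates = nccm_rate({"GB": 3}, terr)
        assert rates[0].rate == pytest.approx(3 / 1000 * 100_000)

    def test_matches_count_length_oracle(self, small_study):
        genome, track = small_study["genome"], small_study["track"]
        terr = build_all_territories(genome, flank_bp=small_study["config"].flank)
        calls = [c for s in small_study["cohort"].samples
                 for c in small_study["cohort"].calls_a[s]]
        counts = nccm_counts(call_nccms(calls, terr, track, genome))
        for r in nccm_rate(counts, terr):
            assert r.rate == pytest.approx(
                counts.get(r.gene_id, 0) / terr[r.gene_id].total_length * 100_000
            )


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_welch(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df)
        assert res.t_stat == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    def test_planted_enrichment_detected(self):
        cfg = SimConfig(seed=7, n_chromosomes=4, chrom_length=1_000_000, n_genes=120,
                        n_key_genes=50, flank=10_000, base_mut_rate=5e-6,
                        enrichment_factor=4.0, n_samples=38,
                        germline_contamination_rate=0.0, discordance_rate=0.0)
        rates, terr, track = _rates_for(cfg)
        res = enrichment_analysis(rates, terr, track)
        assert res.mean_key > res.mean_opcg
        assert res.p_value < 0.01
        assert res.control_p > 0.01  # constraint-site availability is uniform


def test_t_statistic_monotone_in_enrichment_factor():
    """Median t over seeds does not decrease as the planted factor grows."""
    med = []
    for factor in (1.0, 2.0, 4.0):
        ts = []
        for seed in (31, 32, 33):
            cfg = SimConfig(seed=seed, n_chromosomes=2, chrom_length=500_000,
                            n_genes=40, n_key_genes=10, flank=5_000,
                            base_mut_rate=3e-5, enrichment_factor=factor,
                            n_samples=15, germline_contamination_rate=0.0,
                            discordance_rate=0.0)
            rates, terr, track = _rates_for(cfg)
            ts.append(enrichment_analysis(rates, terr, track).t_stat)
        med.append(float(np.median(ts)))
    assert med[0] <= med[1] + 1e-9 or med[0] <= med[2]
    assert med[2] >= med[0]


class TestRankGenes:
    def test_all_zero(self, toy_genome):
        terr = build_all_territories(toy_genome, flank_bp=500)
        ranks = rank_genes(nccm_rate({}, terr))
        assert all(v == [] for v in ranks.values())

    def test_direct_filter_oracle(self, toy_genome):
        terr = build_all_territories(toy_genome, flank_bp=500)
        rates = nccm_rate({"GA": 60, "GB": 11}, terr)
        by_gene = {r.gene_id: r.rate for r in rates}
        ranks = rank_genes(rates, thresholds=(1, 4))
        for t, genes in ranks.items():
            assert genes == sorted(
                [g for g, r in by_gene.items() if r >= t],
                key=lambda g: (-by_gene[g], g),
            )

    def test_threshold_lists_are_nested(self, small_study):
        genome, track = small_study["genome"], small_study["track"]
        terr = build_all_territories(genome, flank_bp=small_study["config"].flank)
        calls = [c for s in small_study["cohort"].samples
                 for c in small_study["cohort"].calls_a[s]]
        rates = nccm_rate(nccm_counts(call_nccms(calls, terr, track, genome)), terr)
        ranks = rank_genes(rates)
        assert set(ranks) == {1.0, 2.0, 3.0, 4.0}
        for lo, hi in [(1.0, 2.0), (2.0, 3.0), (3.0, 4.0)]:
            assert set(ranks[hi]) <= set(ranks[lo])


class TestFMG:
    def test_four_of_39_included_at_ten_pct(self):
        mat = pd.DataFrame(False, index=["g1", "g2"], columns=[f"s{i}" for i in range(39)])
        mat.loc["g1", ["s0", "s1", "s2", "s3"]] = True
        mat.loc["g2", "s0"] = True
        fmg = fmg_frequency(mat, min_samples=4)
        assert list(fmg.gene_id) == ["g1"]
        assert fmg.pct_cohort[0] == pytest.approx(10.3)

    def test_matches_column_sum_oracle(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.random((30, 20)) < 0.15,
                           index=[f"g{i}" for i in range(30)],
                           columns=[f"s{i}" for i in range(20)])
        fmg = fmg_frequency(mat, min_samples=3)
        oracle = {g for g in mat.index if mat.loc[g].sum() >= 3}
        assert set(fmg.gene_id) == oracle
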