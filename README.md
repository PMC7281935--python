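# nccmscan

Non-coding constraint mutation (NCCM) analysis for tumor WGS cohorts.

Most somatic mutations in cancer genomes land in non-coding DNA, and almost
all of them are neutral passengers. One practical way to find the needles
with regulatory potential is to keep only somatic variants that hit
*evolutionarily constrained* positions (rejected-substitutions score
RS ≥ 2) inside a gene's regulatory neighborhood — its 5′/3′ UTRs, introns,
and ±100 kbp intergenic flanks. These are NCCMs. `nccmscan` implements the
full desk side of that analysis:

- **Filtration** — caller-concordance intersection of paired somatic call
  sets, a panel-of-normals filter (site germline in ≥ 2 normals → removed),
  and a germline-database filter with a somatic whitelist.
- **Territories** — per-gene labeled interval sets (UTR/intron/flank) with
  interval arithmetic, lengths, and constrained-base fractions.
- **NCCM calling** — classify each filtered variant into every territory
  containing it, apply the RS ≥ 2 threshold, compute and bin VAFs.
- **Enrichment** — per-gene rates `r_g = n_g / L_g × 10^5` (NCCMs per
  100 kbp), Welch *t* test of a key-gene set against all other
  protein-coding genes (OPCG), a constraint-site-availability control, gene
  ranking at rate thresholds {1,2,3,4}, and a frequently-mutated-gene tally
  (non-silent mutations in ≥ 4 samples).
- **Regulatory annotation** — intersection with TFBS/histone/DNase/
  methylation/curated tracks; multi-track support counts.
- **TRAP affinity** — biophysical TF-binding model: mismatch energies
  `E(b,j) = λ⁻¹ ln(p_max,j / p_b,j)` from a PFM, expected occupancy
  `Σᵢ R₀e^(−Eᵢ)/(1+R₀e^(−Eᵢ))` over both strands, and wt-vs-mutant affinity
  deltas for 41-bp variant-centered windows, ranked per TF.
- **Hotspots** — recurrent (position, allele) sites across samples,
  strand-aware offsets from a gene's start codon (the −124/−146
  TERT-promoter geometry), and mutual-exclusivity checks.
- **Signatures** — 96-channel trinucleotide spectra (pyrimidine frame) and
  signature refitting by non-negative least squares with exposures on the
  simplex, including coding/non-coding and constraint/non-constraint splits.

Because the cohorts this kind of analysis targets are controlled-access,
the package ships a first-class **synthetic study generator**: a toy genome
with gene models, a block-structured constraint track, paired-caller VCFs
with read counts, germline contamination, regulatory tracks, JASPAR PFMs,
and — crucially — a *planted* elevation of the constrained non-coding
mutation rate inside key-gene territories, recorded in a per-variant truth
table. Every downstream stage is therefore testable against known ground
truth.

## Worked example

Summarize the packaged 39-patient cohort table:

```bash
$ nccm-scan cohort-summary
{
  "age_max": 83,
  "age_median": 65,
  "age_min": 38,
  "excluded_hypermutated": ["3151"],
  "n": 39,
  "n_excl": 38,
  "recurrent_count": 4,
  "sex_counts": {"F": 8, "M": 31},
  "sim_total_excl": 10927,
  "spm_total_excl": 263454,
  "subtype_counts": {"CL": 15, "MS": 15, "PN": 7, "n/a": 2}
}
```

39 patients (31 M / 8 F), ages 38–83 (median 65), subtypes 15 classical /
15 mesenchymal / 7 proneural / 2 unclassified; mutation totals are reported
with the hyper-mutated recurrent sample 3151 excluded.

Recover a planted 4× enrichment from a synthetic cohort:

```python
from nccmscan.simulate import (SimConfig, generate_genome,
                               generate_constraint_track, generate_cohort)
from nccmscan.territory import build_all_territories
from nccmscan.nccm import call_nccms, nccm_counts
from nccmscan.enrichment import nccm_rate, enrichment_analysis

cfg = SimConfig(seed=7, n_chromosomes=4, chrom_length=1_000_000, n_genes=120,
                n_key_genes=50, flank=10_000, base_mut_rate=5e-6,
                n_samples=38, germline_contamination_rate=0.0,
                discordance_rate=0.0)
genome, seqs = generate_genome(cfg)
track = generate_constraint_track(genome, cfg)
cohort = generate_cohort(genome, seqs, track, cfg)
calls = [c for s in cohort.samples for c in cohort.calls_a[s]]
territories = build_all_territories(genome, flank_bp=cfg.flank)
records = call_nccms(calls, territories, track, genome)
rates = nccm_rate(nccm_counts(records), territories)
res = enrichment_analysis(rates, territories, track)
```

which prints, via the obvious f-strings:

```
NCCM records: 227
key mean rate:  11.93 NCCMs/100 kbp (n=50)
OPCG mean rate: 4.21 NCCMs/100 kbp (n=70)
Welch t = 7.17, p = 3.33e-10
constraint-site control p = 0.38
```

The 50 key genes carry a significantly higher NCCM rate than the 70 other
genes (p ≪ 0.01), while the control test confirms constrained *sites* are
equally available in both groups (p = 0.38) — the enrichment is in the
mutations, not the sequence.

The whole pipeline (simulate → filter → territories → NCCM → enrichment →
annotation → TRAP → hotspots → signatures) runs from one command:

```bash
nccm-scan all --out out/ --seed 1      # writes out/summary.json + tables
```

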