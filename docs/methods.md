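# Methods

This note documents the models, conventions, and numerical choices behind
`nccmscan`, and what the synthetic study does and does not emulate.

## Coordinates and formats

All internal intervals are 0-based half-open. VCF positions are 1-based and
converted at the I/O boundary; BED/bedGraph are 0-based half-open. VCFs are
v4.2 with `GT:AD:DP` genotypes (AD carries ref,alt depths); GTF uses
explicit `gene/transcript/exon/CDS/five_prime_utr/three_prime_utr`
features. An indel is represented by its leftmost (anchor) base; its
constraint score, territory membership, and annotation overlaps are all
evaluated at the anchor. No indel left-normalization is performed — the
synthetic generator emits normalized alleles, and exact
(chrom, pos, ref, alt) matching is a documented dialect limitation for
external data.

## The NCCM model

A somatic variant is an NCCM for gene *g* when (i) its anchor base lies in
*g*'s territory — 5′UTR, 3′UTR, intron, or the ±`flank` (default 100 kbp)
intergenic flank anchored at the gene span — (ii) the position is outside
every gene's CDS, and (iii) its constraint score RS ≥ 2 (inclusive).
Territories are built independently per gene, so one variant can be an
NCCM for several genes (intron of one, flank of its neighbor); this
mirrors how overlapping gene neighborhoods are counted separately in
cluster regions. UTR labels take precedence over intron labels; flank maps
to the category `intergenic`. Flank bases overlapping a neighboring gene's
coding exons stay in the territory length by default
(`exclude_neighbor_cds=True` reverses this); the variant classifier
excludes coding positions regardless, so only the normalizing length is
affected. NCCMs are counted at variant-occurrence level (one record per
sample carrying the variant, per gene); per-gene patient support is
reported separately, and a `dedupe_sites` flag collapses recurrent
identical sites.

VAF bins are (0–10%] low, (10–45%] mid, (>45%] high — a contiguous
partition chosen because the browser-legend conventions they mimic are
themselves inconsistent at the 45/46% boundary; a VAF of exactly 0 falls
in `low`.

## Enrichment statistics

Per-gene rate: NCCMs per 100 kbp of territory, zero-NCCM genes included
(their exclusion is available behind a flag but shifts the OPCG mean).
The key-vs-OPCG comparison is a Welch two-sided t test on per-gene rates —
Welch because the two groups are wildly unequal in size and variance, and
the underlying method description says only "t test". The control applies
the identical test to per-gene constrained-base *fractions*: a significant
control would mean the key genes simply sit in more-constrained sequence.
Rate thresholds use ≥ (inclusive). FMGs are genes with non-silent
mutations in ≥ 4 samples of the cohort incidence matrix.

## TRAP affinity

Energies from a PFM with pseudocount 1:
`p(b,j) = (n(b,j)+1)/(N+4)`, `E(b,j) = λ⁻¹ ln(p_max,j/p(b,j))`, so the
per-column consensus base has energy exactly 0 and all energies are ≥ 0.
Site energy is the sum over columns; occupancy per offset is
`R₀e^(−E)/(1+R₀e^(−E))`; affinity is the sum over all offsets on both
strands, making it invariant under reverse complement. Defaults λ = 0.7
and ln R₀ = 0.584·W − 5.66 are the published TRAP constants. An `N` base
contributes its column-mean energy. Variant impact is the raw affinity
difference between mutant and wild-type windows (41 bp, variant-centered;
configurable), ranked by |Δ| with ties broken by TF name. The original
tool's p-value machinery needs a background promoter model that is not
specified in our sources, so it is deliberately not reproduced; a log-ratio
is available for users who want a scale-free statistic.

## Hotspots

Recurrence counts distinct samples per (chrom, pos, ref, alt). Promoter
offsets: the first base of the start codon is offset 0; bases upstream in
the gene's orientation are negative (`pos − atg` on +, `atg − pos` on −),
matching the −124/−146 convention for a minus-strand telomerase-like gene.
A hotspot pair is mutually exclusive iff no sample carries both. No
recurrence significance model is attached.

## Signatures

Spectra use the canonical 96 channels (six pyrimidine substitutions × 16
flanking contexts); purine-reference substitutions are reverse-complemented
into frame; indels are excluded; contig-edge variants are skipped with a
warning. Refitting solves NNLS on the normalized frequency vector against
a column-stochastic catalog and renormalizes exposures to the simplex —
this is our concrete reading of a "maximum likelihood with linear
regression" refit; a true multinomial-MLE mode (`method="mle"`) and a
greedy forward-selection subset search (off by default) are provided.
The packaged catalog is synthetic: five spiky, well-separated signatures
generated programmatically (block-concentrated Dirichlet draws, pairwise
cosine < 0.6). Any 96 × K TSV can be loaded instead. Coding/non-coding and
constraint/non-constraint splits are exact partitions of the total
spectrum by construction.

## The synthetic study

What it emulates, with defaults chosen to mirror the real-data regime:
±100 kbp flanks; ~15% of bases constrained (RS ≥ 2) in geometric-length
blocks (mean 100 bp) with background scores in [−8, 1.9) and block scores
in [2, 6); a 38-sample cohort; tumor depth ~ Poisson(75) with
alt reads ~ Binomial(depth, VAF) and VAF ~ Beta(2,4) clipped to
[0.02, 0.98] (germline leaks use Beta(20,20), centered at 0.5); an indel
share of 4% of calls with 1–5 bp alleles; caller discordance 5% (a
discordant call is private to one caller, chosen at random); germline
contamination at rate 0.10 per pool site per sample, from a cohort-level
pool of density 2 × 10⁻⁵ sites/bp whose carrier frequencies are
Beta(0.5, 1.5) — deliberately skewed rare so that some sites evade the
panel of normals and the germline-database filter has real work; database
sensitivity 0.9; 2% of somatic sites are planted into the germline DB and
whitelist to exercise whitelisting. The planted effect multiplies the
per-base mutation rate by `enrichment_factor` exactly on bases that are
(in a key-gene territory) ∧ (constrained) ∧ (non-coding). The base
mutation rate default, 2.5 × 10⁻⁶/bp/sample, is the order observed in
whole-genome tumor cohorts; tests and the acceptance script raise it
(2 × 10⁻⁵–5 × 10⁻⁵) on their megabase-scale toy genomes so that per-gene
counts are informative at desk scale — a deliberate density trade-off, not
a change of model.

It does **not** emulate: sequencing error or caller-specific artifact
models, copy-number alteration, mappability, replication timing or other
covariates of regional mutation rate, linkage between germline sites, or
human-genome scale. Passing tests therefore demonstrate correctness of the
*computations* (interval logic, filters, statistics, planted-effect
recovery), not robustness to real-data confounders.

## Problem sizes and calibration checks

The planted-enrichment check uses 4 × 1 Mbp chromosomes, 120 genes (50
key), 10 kbp flanks, rate 5 × 10⁻⁶, 38 samples: ~900 somatic events, and
the 4× plant is recovered as a truth-table rate ratio in [3, 5] and a
Welch p < 0.01. The null calibration regenerates 200 cohorts
(enrichment_factor = 1) over a fixed 2 × 400 kbp genome and observes the
rejection rate at α = 0.05 inside the binomial 3σ band. Signature
recovery draws 10,000 multinomial mutations from a 0.7/0.3 mixture and
recovers exposures within ±0.03. All suites run on one CPU in well under
a minute each.

## Design choices where the design was open

- Panel-of-normals membership is allele-specific (germline *SNPs*, not
  positions); a position-specific mode exists behind a flag.
- Concordant calls take read counts from one designated caller (default A)
  since paired callers report incompatible count fields.
- Flanks anchor at the gene span (TSS-to-TES), not the TSS alone.
- Hyper-mutated samples are excluded from cohort totals by explicit flag
  in the metadata; the fallback rule (total > 10× cohort median) exists
  for unflagged tables.
- Multi-allelic VCF records are split into biallelic calls at load time.
- The pipeline orchestrator does not cache stages by content hash: at toy
  scale every stage re-runs in seconds and a cache only adds staleness
  failure modes.

## Known limitations

Exact-match allele keys (no indel normalization) across databases;
point-anchor semantics for indels spanning territory boundaries; the
regulatory "fraction annotated" depends directly on the synthetic track
coverage parameter and is not comparable to fractions computed on real
curated tracks; TRAP deltas are raw affinities, not background-calibrated
p-values.
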