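"""Readers/writers for the standard formats the pipeline exchanges.

Reading goes through established parsers (pysam for VCF, gffutils for GTF,
pyfaidx for FASTA); writing emits the plain-text dialects the synthetic
study uses (VCF 4.2 with AD genotypes, GTF with explicit UTR features,
BED6, wrapped FASTA).
"""

from __future__ import annotations

import os
import textwrap

import gffutils
import pysam

from .models import GeneModel, GenomeModel, VariantCall

# ---------------------------------------------------------------- VCF

VCF_FORMAT_HEADER = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)


def write_vcf(path, records, contigs: dict[str, int], sample: str | None = None) -> None:
    """Write a VCF 4.2 file.

    ``records`` are VariantCall objects (genotyped, when ``sample`` given) or
    bare (chrom, pos, ref, alt) tuples for sites-only files.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample is not None:
            fh.write(VCF_FORMAT_HEADER)
            cols += ["FORMAT", sample]
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            if isinstance(rec, VariantCall):
                chrom, pos, ref, alt = rec.chrom, rec.pos, rec.ref, rec.alt
                filt = "PASS"
                if rec.filter_trail and rec.filter_trail[-1][1] != "pass":
                    filt = rec.filter_trail[-1][0]
                fields = [chrom, str(pos), ".", ref, alt, ".", filt, "."]
                if sample is not None:
                    dp = rec.ref_reads + rec.alt_reads
                    fields += ["GT:AD:DP", f"0/1:{rec.ref_reads},{rec.alt_reads}:{dp}"]
            else:
                chrom, pos, ref, alt = rec
                fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", "."]
                if sample is not None:
                    fields += ["GT", "0/1"]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, sample_id: str, caller: str | None = None) -> list[VariantCall]:
    """Load a VCF into VariantCalls; multi-allelic records are split."""
    calls = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        has_sample = len(vf.header.samples) > 0
        for rec in vf:
            alts = rec.alts or ()
            ad = None
            if has_sample:
                sdata = rec.samples[0]
                if "AD" in sdata and sdata["AD"] is not None:
                    ad = sdata["AD"]
            for i, alt in enumerate(alts):
                ref_reads = alt_reads = 0
                if ad is not None and ad[0] is not None:
                    ref_reads = int(ad[0])
                    if len(ad) > i + 1 and ad[i + 1] is not None:
                        alt_reads = int(ad[i + 1])
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        ref_reads=ref_reads,
                        alt_reads=alt_reads,
                        provenance={caller} if caller else set(),
                    )
                )
    return calls


def read_vcf_sites(path) -> set[tuple[str, int, str, str]]:
    """Load just the (chrom, pos, ref, alt) site keys of a VCF."""
    sites = set()
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                sites.add((rec.chrom, rec.pos, rec.ref, alt))
    return sites


# ---------------------------------------------------------------- FASTA


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for line in textwrap.wrap(seq, width, break_on_hyphens=False):
                fh.write(line + "\n")


# ---------------------------------------------------------------- GTF

_UTR_FEATURE = {"utr5": "five_prime_utr", "utr3": "three_prime_utr"}


def write_gtf(path, genome: GenomeModel) -> None:
    """GTF (1-based inclusive) with gene/transcript/exon/CDS/UTR features."""

    def line(g: GeneModel, feature: str, s: int, e: int) -> str:
        attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; key_gene "{int(g.is_key)}";'
        return f"{g.chrom}\ttoysim\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##format: gtf\n##generated-by: nccmscan synthetic_data\n")
        for g in sorted(genome.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(line(g, "gene", g.start, g.end))
            fh.write(line(g, "transcript", g.start, g.end))
            for s, e in g.exons:
                fh.write(line(g, "exon", s, e))
            for s, e in g.cds:
                fh.write(line(g, "CDS", s, e))
            for label in ("utr5", "utr3"):
                for s, e in getattr(g, label):
                    fh.write(line(g, _UTR_FEATURE[label], s, e))


def read_gtf(path, chrom_lengths: dict[str, int]) -> GenomeModel:
    """Parse a GTF written by :func:`write_gtf` back into a GenomeModel."""
    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for grec in db.features_of_type("gene"):
        parts: dict[str, list] = {"exon": [], "CDS": [], "five_prime_utr": [], "three_prime_utr": []}
        for child in db.region(seqid=grec.seqid, start=grec.start, end=grec.end):
            if child.featuretype in parts and child.attributes.get("gene_id") == grec.attributes.get("gene_id"):
                parts[child.featuretype].append((child.start - 1, child.end))
        genes.append(
            GeneModel(
                gene_id=grec.attributes["gene_id"][0],
                chrom=grec.seqid,
                strand=grec.strand,
                start=grec.start - 1,
                end=grec.end,
                exons=parts["exon"],
                cds=parts["CDS"],
                utr5=parts["five_prime_utr"],
                utr3=parts["three_prime_utr"],
                is_key=grec.attributes.get("key_gene", ["0"])[0] == "1",
            )
        )
    return GenomeModel(chromosomes=sorted(chrom_lengths.items()), genes=genes)


# ---------------------------------------------------------------- BED


def write_bed(path, records) -> None:
    """BED6 from (chrom, start, end, name) or (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 4:
                rec = (*rec, 0, ".")
            chrom, start, end, name, score, strand = rec
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else "."
            out.append((f[0], int(f[1]), int(f[2]), name))
    return out
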