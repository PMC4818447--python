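"""Readers and writers for the plain-text interchange formats.

Array data travel as TSV (haplotype matrix + marker map + phenotypes),
sequence variants as VCF v4.2, gene models as GFF3, sequence as FASTA,
intervals as BED.  Everything round-trips losslessly so every pipeline
stage can be invoked on files produced by the previous one.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (MISSING, GeneModel, GenomeSequence, GenotypeMatrix,
                   MarkerMap, PhenotypeTable, Variant, VariantCallSet)

# ---------------------------------------------------------------- array TSVs


def write_marker_map(mmap: MarkerMap, path) -> None:
    mmap.table.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_haplotypes(gm: GenotypeMatrix, path) -> None:
    """One row per haplotype: individual, hap index, then 0/1/. alleles."""
    with open(path, "w") as fh:
        fh.write("individual\thap\talleles\n")
        for i, ind in enumerate(gm.individuals):
            for h in (0, 1):
                row = gm.haplotypes[2 * i + h]
                alleles = "".join("." if a == MISSING else str(a) for a in row)
                fh.write(f"{ind}\t{h + 1}\t{alleles}\n")


def read_haplotypes(path, phased: bool = True) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"alleles": str})
    individuals = list(dict.fromkeys(df["individual"]))
    n_markers = len(df["alleles"].iloc[0])
    haps = np.full((2 * len(individuals), n_markers), MISSING, dtype=np.int8)
    index = {ind: i for i, ind in enumerate(individuals)}
    for _, row in df.iterrows():
        r = 2 * index[row["individual"]] + int(row["hap"]) - 1
        haps[r] = [MISSING if c == "." else int(c) for c in row["alleles"]]
    return GenotypeMatrix(individuals, haps, phased=phased)


def write_phenotypes(phenos: PhenotypeTable, path) -> None:
    phenos.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


# --------------------------------------------------------------------- VCF


def _format_gt(gt: np.ndarray, phased: bool) -> str:
    sep = "|" if phased else "/"
    return sep.join("." if a == MISSING else str(int(a)) for a in gt)


def write_vcf(calls: VariantCallSet, path, contig_lengths: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = contig_lengths or {
            c: 500_000_000 for c in dict.fromkeys(v.chrom for v in calls.variants)}
        for c, length in contigs.items():
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(calls.samples) + "\n")
        for v in calls.variants:
            gts = "\t".join(_format_gt(g, v.phased) for g in v.gts)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> VariantCallSet:
    """Read an (uncompressed) VCF via cyvcf2, decomposing multi-allelic sites.

    In decomposed records, genotype alleles equal to a different alternate
    allele are encoded as reference for the record at hand.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    for rec in vcf:
        raw = rec.genotype.array()[:, :2] if len(samples) else np.empty((0, 2), int)
        phased = bool(rec.genotype.array()[:, 2].all()) if len(samples) else False
        for ai, alt in enumerate(rec.ALT, start=1):
            gts = np.zeros_like(raw, dtype=np.int8)
            gts[raw == ai] = 1
            gts[raw < 0] = MISSING
            variants.append(Variant(str(rec.CHROM), int(rec.POS), rec.REF, alt,
                                    rec.ID or ".", gts, phased))
    vcf.close()
    return VariantCallSet(samples, variants)


# ------------------------------------------------------------- GFF3 / FASTA


def write_gff3(gene: GeneModel, path) -> None:
    gs, ge = gene.span
    lines = ["##gff-version 3",
             f"##sequence-region {gene.contig} 1 {ge + 10_000}"]
    attrs_gene = f"ID={gene.gene_id};Name={gene.gene_id}"
    lines.append("\t".join([gene.contig, "recessmap", "gene", str(gs), str(ge),
                            ".", gene.strand, ".", attrs_gene]))
    attrs_tx = f"ID={gene.transcript_id};Parent={gene.gene_id}"
    lines.append("\t".join([gene.contig, "recessmap", "mRNA", str(gs), str(ge),
                            ".", gene.strand, ".", attrs_tx]))
    for i, (s, e) in enumerate(gene.exons, start=1):
        attrs = f"ID={gene.transcript_id}.exon{i};Parent={gene.transcript_id}"
        lines.append("\t".join([gene.contig, "recessmap", "exon", str(s), str(e),
                                ".", gene.strand, ".", attrs]))
    # CDS phase bookkeeping: transcript here is fully coding between
    # cds_start/cds_end; emit CDS rows clipped to that interval.
    tx_len = 0
    ordered = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    phase = 0
    for s, e in ordered:
        exon_len = e - s + 1
        lo = max(gene.cds_start, tx_len + 1)
        hi = min(gene.cds_end, tx_len + exon_len)
        if lo <= hi:
            if gene.strand == "+":
                cs, ce = s + (lo - tx_len - 1), s + (hi - tx_len - 1)
            else:
                cs, ce = e - (hi - tx_len - 1), e - (lo - tx_len - 1)
            attrs = f"ID={gene.transcript_id}.cds;Parent={gene.transcript_id}"
            lines.append("\t".join([gene.contig, "recessmap", "CDS", str(cs),
                                    str(ce), ".", gene.strand, str(phase), attrs]))
            phase = (3 - ((hi - gene.cds_start + 1) % 3)) % 3
        tx_len += exon_len
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> GeneModel:
    """Load the first gene/mRNA with exons from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="merge")
    mrna = next(db.features_of_type("mRNA"))
    gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
    exons = sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
    cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
    gene = GeneModel(gene_id, mrna.id, str(mrna.seqid), mrna.strand, exons)
    if cds:
        tpos = sorted(filter(None, (gene.genomic_to_transcript(p)
                                    for s, e in cds for p in (s, e))))
        gene.cds_start, gene.cds_end = tpos[0], tpos[-1]
    return gene


def write_fasta(genome: GenomeSequence, path) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.name,
                    description=f"offset={genome.offset}")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> GenomeSequence:
    rec = next(SeqIO.parse(str(path), "fasta"))
    offset = 0
    for token in rec.description.split():
        if token.startswith("offset="):
            offset = int(token.split("=", 1)[1])
    return GenomeSequence(rec.id, str(rec.seq), offset)


# ----------------------------------------------------------------- BED/JSON


def write_bed(intervals, path) -> None:
    """Intervals as (chrom, start_1based, end_1based, name); emitted 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
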