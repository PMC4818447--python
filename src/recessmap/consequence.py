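"""Coding-consequence prediction on a gene model.

Builds mutant coding sequences by splicing exons (optionally retaining
an intron), applying a normalized small variant in transcript space and
translating with the standard genetic code; names frameshifts in HGVS
protein notation and runs exact-match in-silico RT-PCR on transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .core import GeneModel, GenomeSequence, Variant, normalize_variant, revcomp


@dataclass
class ConsequenceRecord:
    transcript_id: str
    cdna_description: str
    protein_description: str | None
    first_altered_residue: int | None
    stop_residue: int | None          # mutant stop position counting from residue 1
    mutant_length: int
    wild_length: int
    runoff: bool = False
    mutant_protein: str = ""

    @property
    def residues_removed(self) -> int | None:
        if self.runoff:
            return None
        return self.wild_length - self.mutant_length

    @property
    def truncation_fraction(self) -> float | None:
        removed = self.residues_removed
        if removed is None:
            return None
        return removed / self.wild_length


def translate_cds(cds: str) -> tuple[str, bool]:
    """Protein up to (not including) the first stop; flag whether a stop exists."""
    usable = len(cds) - len(cds) % 3
    prot = str(Seq(cds[:usable]).translate())
    if "*" in prot:
        return prot[:prot.index("*")], True
    return prot, False


def _aa3(aa: str) -> str:
    return "Ter" if aa in ("*", "X") else seq3(aa)


def name_frameshift(wild_protein: str, mutant_protein: str) -> str:
    """HGVS protein name for a frameshift (or plain nonsense) change.

    Frameshifts are written ``p.<Ref><Pos><Alt>fsTer<N>`` with the stop
    counted from the first changed residue as position 1.  A mutant that
    is a pure prefix of the wild type (stop gained, no new residues) is
    named ``p.<Ref><Pos>Ter``.
    """
    if wild_protein == mutant_protein:
        raise ValueError("not a frameshift: proteins are identical")
    i = 0
    limit = min(len(wild_protein), len(mutant_protein))
    while i < limit and wild_protein[i] == mutant_protein[i]:
        i += 1
    pos = i + 1
    if i == len(mutant_protein):
        # nonsense: translation stops where wild type continues
        return f"p.{_aa3(wild_protein[i])}{pos}Ter"
    stop_offset = len(mutant_protein) - i + 1
    return (f"p.{_aa3(wild_protein[i])}{pos}{_aa3(mutant_protein[i])}"
            f"fsTer{stop_offset}")


def _apply_variant_to_transcript(gene: GeneModel, transcript: str,
                                 variant: Variant,
                                 retained_intron: int | None = None) -> tuple[str, str]:
    """Apply a normalized variant inside the (possibly intron-retained)
    transcript; returns (mutant transcript, cDNA-level description)."""
    pos, ref, alt = normalize_variant(variant.pos, variant.ref, variant.alt)

    def to_tpos(gpos: int) -> int | None:
        if retained_intron is None:
            return gene.genomic_to_transcript(gpos)
        # coordinates within the retained transcript: exons plus one intron
        introns = gene.introns()
        if gene.strand == "-":
            introns = list(reversed(introns))
        gi_s, gi_e = introns[retained_intron - 1]
        t = gene.genomic_to_transcript(gpos)
        intron_len = gi_e - gi_s + 1
        # transcript offset of the retained intron start
        up_exons = gene._ordered_exons()[:retained_intron]
        boundary = sum(e - s + 1 for s, e in up_exons)
        if t is not None:
            return t if t <= boundary else t + intron_len
        if gi_s <= gpos <= gi_e:
            off = (gpos - gi_s) if gene.strand == "+" else (gi_e - gpos)
            return boundary + off + 1
        return None

    tpos = to_tpos(pos)
    if tpos is None:
        raise ValueError(f"variant at {variant.chrom}:{pos} does not overlap "
                         "the transcript")
    if gene.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
        tpos = tpos - len(ref) + 1
    if transcript[tpos - 1:tpos - 1 + len(ref)] != ref:
        raise ValueError(
            f"reference allele mismatch at transcript position {tpos}: "
            f"expected {ref!r}, found "
            f"{transcript[tpos - 1:tpos - 1 + len(ref)]!r}")
    mutant = transcript[:tpos - 1] + alt + transcript[tpos - 1 + len(ref):]
    cpos = tpos - (gene.cds_start - 1)
    if len(ref) > len(alt):
        removed = ref[len(alt):]
        start = cpos + len(alt)
        end = start + len(removed) - 1
        cdna = (f"c.{start}del{removed}" if start == end
                else f"c.{start}_{end}del{removed}")
    elif len(alt) > len(ref):
        inserted = alt[len(ref):]
        cdna = f"c.{cpos + len(ref) - 1}_{cpos + len(ref)}ins{inserted}"
    else:
        cdna = f"c.{cpos}{ref}>{alt}"
    return mutant, cdna


def _build_record(gene: GeneModel, wild_protein: str, mutant_cds: str,
                  cdna: str) -> ConsequenceRecord:
    mut_prot, stopped = translate_cds(mutant_cds)
    rec = ConsequenceRecord(
        transcript_id=gene.transcript_id, cdna_description=cdna,
        protein_description=None, first_altered_residue=None,
        stop_residue=None, mutant_length=len(mut_prot),
        wild_length=len(wild_protein), runoff=not stopped,
        mutant_protein=mut_prot)
    if stopped:
        rec.stop_residue = len(mut_prot) + 1
    if mut_prot == wild_protein:
        rec.protein_description = "p.(=)"
        return rec
    i = 0
    limit = min(len(wild_protein), len(mut_prot))
    while i < limit and wild_protein[i] == mut_prot[i]:
        i += 1
    rec.first_altered_residue = i + 1
    if stopped:
        rec.protein_description = name_frameshift(wild_protein, mut_prot)
    return rec


def apply_variant_and_translate(gene: GeneModel, genome: GenomeSequence,
                                variant: Variant) -> ConsequenceRecord:
    """Consequence of one small variant on the spliced coding sequence.

    Handles frameshifting and in-frame indels as well as SNVs.  After a
    frameshift the reading continues past the wild-type stop into the
    remaining transcript; absence of any stop is flagged as runoff.
    """
    transcript = gene.splice(genome)
    wild_protein, _ = translate_cds(transcript[gene.cds_start - 1:gene.cds_end])
    mutant_tx, cdna = _apply_variant_to_transcript(gene, transcript, variant)
    mutant_cds = mutant_tx[gene.cds_start - 1:]
    return _build_record(gene, wild_protein, mutant_cds, cdna)


def retained_intron_translate(gene: GeneModel, genome: GenomeSequence,
                              intron_index: int,
                              upstream_variant: Variant | None = None
                              ) -> tuple[ConsequenceRecord, str]:
    """Consequence of retaining one intron, optionally on top of a variant.

    Returns the record plus the mutant (intron-retained) transcript.
    """
    if not 1 <= intron_index <= gene.n_exons - 1:
        raise ValueError(f"intron index {intron_index} out of range "
                         f"(gene has {gene.n_exons - 1} introns)")
    transcript = gene.splice(genome)
    wild_protein, _ = translate_cds(transcript[gene.cds_start - 1:gene.cds_end])
    retained = gene.splice(genome, retain_intron=intron_index)
    cdna = f"r.retained_intron_{intron_index}"
    if upstream_variant is not None:
        retained, var_cdna = _apply_variant_to_transcript(
            gene, retained, upstream_variant, retained_intron=intron_index)
        cdna = f"{var_cdna};{cdna}"
    mutant_cds = retained[gene.cds_start - 1:]
    rec = _build_record(gene, wild_protein, mutant_cds, cdna)
    return rec, retained


def insilico_rtpcr(transcripts: list[str], forward_primer: str,
                   reverse_primer: str) -> list[list[int]]:
    """Exact-match in-silico PCR: amplicon lengths per transcript.

    The forward primer is searched on the sense strand and the reverse
    primer as its reverse complement downstream of each forward site;
    every (forward, reverse) pairing yields a product whose length is
    the inclusive span.  Transcripts without both sites get an empty list.
    """
    if len(forward_primer) < 15 or len(reverse_primer) < 15:
        raise ValueError("primers must be at least 15 nt")
    fwd = forward_primer.upper()
    rev_rc = revcomp(reverse_primer.upper())

    def occurrences(seq: str, sub: str) -> list[int]:
        out, start = [], 0
        while True:
            i = seq.find(sub, start)
            if i < 0:
                return out
            out.append(i)
            start = i + 1

    products = []
    for tx in transcripts:
        tx = tx.upper()
        f_sites = occurrences(tx, fwd)
        r_sites = occurrences(tx, rev_rc)
        lengths = sorted(r + len(rev_rc) - f
                         for f in f_sites for r in r_sites
                         if r + len(rev_rc) > f + len(fwd) and r >= f)
        products.append(lengths)
    return products
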