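"""Core data structures shared by all pipeline stages.

Allele encoding on arrays: ``0`` = reference allele, ``1`` = alternate
allele, ``-1`` = missing.  A phased genotype matrix stores two haplotype
rows per individual (rows ``2*i`` and ``2*i + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

PHENO_COLUMNS = ["individual", "status", "role", "breed", "sex", "birth_year"]

STATUS_AFFECTED = "affected"
STATUS_UNAFFECTED = "unaffected"
STATUS_UNKNOWN = "unknown"

ROLE_CASE = "case"
ROLE_CARRIER = "obligate_carrier"
ROLE_CONTROL = "control"
ROLE_PANEL = "panel"


class GenotypeMatrix:
    """Diploid genotypes for a marker panel, optionally phased.

    Parameters
    ----------
    individuals:
        Ordered individual identifiers (length ``n``).
    haplotypes:
        ``(2n, m)`` int8 array; rows ``2i`` and ``2i+1`` are the two
        haplotypes of individual ``i``.  When ``phased`` is False the
        assignment of alleles to rows is arbitrary but the allele sum
        per individual is still meaningful.
    """

    def __init__(self, individuals: Sequence[str], haplotypes: np.ndarray,
                 phased: bool = True):
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.ndim != 2 or haplotypes.shape[0] != 2 * len(individuals):
            raise ValueError(
                f"haplotype array shape {haplotypes.shape} does not match "
                f"{len(individuals)} individuals (need 2 rows each)")
        if not np.isin(haplotypes, (0, 1, MISSING)).all():
            raise ValueError("alleles must be 0, 1 or -1 (missing)")
        self.individuals = list(individuals)
        self.haplotypes = haplotypes
        self.phased = bool(phased)
        self._index = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def individual_index(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"individual {individual!r} not in matrix") from None

    def genotypes(self) -> np.ndarray:
        """``(n, m)`` dosage matrix: 0/1/2 alt-allele count, -1 missing."""
        a = self.haplotypes[0::2]
        b = self.haplotypes[1::2]
        g = (a + b).astype(np.int8)
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g

    def individual_haplotypes(self, individual: str) -> np.ndarray:
        i = self.individual_index(individual)
        return self.haplotypes[2 * i:2 * i + 2]

    def subset_individuals(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep = list(keep)
        rows = np.concatenate(
            [(2 * self.individual_index(k), 2 * self.individual_index(k) + 1)
             for k in keep]) if keep else np.empty(0, dtype=int)
        return GenotypeMatrix(keep, self.haplotypes[rows], phased=self.phased)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals, self.haplotypes[:, mask],
                              phased=self.phased)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals, self.haplotypes.copy(),
                              phased=self.phased)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.individuals == other.individuals
                and self.phased == other.phased
                and np.array_equal(self.haplotypes, other.haplotypes))


class MarkerMap:
    """Ordered marker coordinates: marker id, chromosome, bp position, alleles."""

    COLUMNS = ["marker", "chrom", "pos", "ref", "alt"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"marker map lacks columns: {sorted(missing)}")
        table = table.loc[:, self.COLUMNS].reset_index(drop=True)
        table["chrom"] = table["chrom"].astype(str)
        table["pos"] = table["pos"].astype(np.int64)
        for chrom, grp in table.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"markers on chromosome {chrom} not sorted by pos")
        self.table = table

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == str(chrom)).to_numpy())

    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def marker_index(self, marker: str) -> int:
        hits = np.flatnonzero((self.table["marker"] == marker).to_numpy())
        if hits.size == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(hits[0])

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(mask)].reset_index(drop=True))


class PhenotypeTable:
    """Individual-level metadata: status, role, breed, sex, birth year."""

    def __init__(self, table: pd.DataFrame):
        missing = {"individual", "status", "role"} - set(table.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
        table = table.copy()
        for col in PHENO_COLUMNS:
            if col not in table.columns:
                table[col] = pd.NA
        bad = set(table["status"]) - {STATUS_AFFECTED, STATUS_UNAFFECTED,
                                      STATUS_UNKNOWN}
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        self.table = table.loc[:, PHENO_COLUMNS].reset_index(drop=True)

    def _ids_where(self, mask) -> list[str]:
        return list(self.table.loc[mask, "individual"])

    @property
    def case_ids(self) -> list[str]:
        return self._ids_where(self.table["status"] == STATUS_AFFECTED)

    @property
    def control_ids(self) -> list[str]:
        return self._ids_where((self.table["status"] == STATUS_UNAFFECTED)
                               & (self.table["role"] != ROLE_PANEL))

    @property
    def unknown_ids(self) -> list[str]:
        return self._ids_where(self.table["status"] == STATUS_UNKNOWN)

    def role_ids(self, role: str) -> list[str]:
        return self._ids_where(self.table["role"] == role)

    def status_of(self, individual: str) -> str:
        row = self.table.loc[self.table["individual"] == individual]
        if row.empty:
            return STATUS_UNKNOWN
        return str(row["status"].iloc[0])

    def subset(self, ids: Iterable[str]) -> "PhenotypeTable":
        ids = set(ids)
        return PhenotypeTable(
            self.table.loc[self.table["individual"].isin(ids)])


@dataclass
class Variant:
    """A bi-allelic sequence variant with per-sample diploid genotypes.

    ``gts`` is an ``(n_samples, 2)`` int8 array over {0, 1, -1}.
    """

    chrom: str
    pos: int           # 1-based, VCF convention (anchor base for indels)
    ref: str
    alt: str
    vid: str = "."
    gts: np.ndarray | None = None
    phased: bool = False

    @property
    def variant_class(self) -> str:
        if len(self.ref) >= 50 or len(self.alt) >= 50 or self.alt.startswith("<"):
            return "SV"
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "indel"

    @property
    def is_indel(self) -> bool:
        return self.variant_class == "indel"

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping at least one base of each allele.

    Collapses redundant representations such as ``CCC -> CC`` to the
    canonical single-base deletion with one anchor base.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class VariantCallSet:
    """A set of variants sharing one ordered sample list."""

    def __init__(self, samples: Sequence[str], variants: list[Variant]):
        self.samples = list(samples)
        for v in variants:
            if v.gts is None:
                raise ValueError(f"variant {v.key()} lacks genotypes")
            if v.gts.shape != (len(self.samples), 2):
                raise ValueError(
                    f"variant {v.key()} genotype shape {v.gts.shape} does not "
                    f"match {len(self.samples)} samples")
        self.variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def __len__(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in call set") from None

    def genotypes_for(self, variant: Variant, samples: Sequence[str]) -> np.ndarray:
        idx = [self.sample_index(s) for s in samples]
        return variant.gts[idx]

    def subset_samples(self, keep: Sequence[str]) -> "VariantCallSet":
        idx = [self.sample_index(s) for s in keep]
        new = [Variant(v.chrom, v.pos, v.ref, v.alt, v.vid, v.gts[idx], v.phased)
               for v in self.variants]
        return VariantCallSet(list(keep), new)

    def find(self, chrom: str, pos: int, ref: str, alt: str) -> Variant | None:
        key = (str(chrom),) + normalize_variant(pos, ref, alt)
        for v in self.variants:
            if (v.chrom,) + normalize_variant(v.pos, v.ref, v.alt) == key:
                return v
        return None


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A contig (or contig slice) of genomic sequence.

    ``offset`` lets a slice represent genomic interval
    ``[offset + 1, offset + len(seq)]`` of the full contig without
    storing flanking sequence.
    """

    name: str
    seq: str
    offset: int = 0

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def start(self) -> int:
        return self.offset + 1

    @property
    def end(self) -> int:
        return self.offset + len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """1-based inclusive slice in genomic coordinates."""
        if start < self.start or end > self.end or start > end:
            raise ValueError(
                f"interval {start}-{end} outside contig slice "
                f"{self.start}-{self.end}")
        return self.seq[start - 1 - self.offset:end - self.offset]

    def base_at(self, pos: int) -> str:
        return self.fetch(pos, pos)


@dataclass
class GeneModel:
    """Exon/intron structure of one transcript, 1-based inclusive coordinates."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int = 1         # transcript coordinate of first coding base
    cds_end: int | None = None  # transcript coordinate of last coding base

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        self.validate()
        if self.cds_end is None:
            self.cds_end = self.transcript_length

    def validate(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon {s}-{e} has start > end")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
                for i in range(len(self.exons) - 1)]

    def _ordered_exons(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'→3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def splice(self, genome: GenomeSequence,
               retain_intron: int | None = None) -> str:
        """Spliced transcript sequence, optionally retaining one intron.

        ``retain_intron`` is the 1-based intron index in transcript order
        (intron i follows exon i).
        """
        introns = self.introns()
        if self.strand == "-":
            introns = list(reversed(introns))
        parts = []
        ordered = self._ordered_exons()
        for i, (s, e) in enumerate(ordered, start=1):
            block = genome.fetch(s, e)
            parts.append(block if self.strand == "+" else revcomp(block))
            if retain_intron is not None and i == retain_intron and i <= len(introns):
                gs, ge = introns[i - 1]
                iseq = genome.fetch(gs, ge)
                parts.append(iseq if self.strand == "+" else revcomp(iseq))
        return "".join(parts)

    def cds(self, genome: GenomeSequence) -> str:
        return self.splice(genome)[self.cds_start - 1:self.cds_end]

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to 1-based transcript coordinate; None if intronic/outside."""
        offset = 0
        for s, e in self._ordered_exons():
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s) + 1
                return offset + (e - pos) + 1
            offset += e - s + 1
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        offset = 0
        for s, e in self._ordered_exons():
            length = e - s + 1
            if tpos <= offset + length:
                within = tpos - offset - 1
                return s + within if self.strand == "+" else e - within
            offset += length
        raise ValueError(f"transcript position {tpos} beyond transcript end")

    def exon_of(self, pos: int) -> int | None:
        """1-based exon index (genomic order) containing ``pos``, else None."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None
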