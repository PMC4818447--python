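"""Recessive-compatibility filtering, cross-population exclusion and
genic region classification of candidate variants.

A variant is compatible with recessive inheritance of the defect when
every case sample is homozygous for the alternate allele, every obligate
carrier is heterozygous and every control is homozygous reference.
Compatible candidates segregating in a multi-breed panel are excluded;
the survivors are classified against a gene model (exonic / intronic /
intergenic, with intronic variants far from any splice site
deprioritized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (MISSING, GeneModel, Variant, VariantCallSet,
                   normalize_variant)

SPLICE_DISTANCE_THRESHOLD = 4000   # bp; intronic variants farther away are deprioritized


@dataclass
class CandidateVariant:
    variant: Variant
    case_hom_alt: bool
    carrier_het: bool
    controls_hom_ref: bool
    panel_polymorphic: bool | None = None   # None = untested
    region: str | None = None               # exonic / intronic / intergenic
    gene_id: str | None = None
    splice_distance: int | None = None
    priority: str | None = None

    @property
    def compatible(self) -> bool:
        return self.case_hom_alt and self.carrier_het and self.controls_hom_ref

    @property
    def key(self):
        return self.variant.key()


def _group_flag(gts: np.ndarray, want, strict_missing: bool) -> bool:
    """True iff every sample genotype matches ``want`` (a set of sorted
    allele pairs); missing fails in strict mode, is skipped otherwise."""
    has_missing = (gts == MISSING).any(axis=1)
    if strict_missing and has_missing.any():
        return False
    tested = gts[~has_missing]
    if tested.shape[0] == 0:
        return False                       # nothing testable in this group
    pairs = np.sort(tested, axis=1)
    return all(tuple(p) in want for p in pairs)


_HOM_ALT = {(1, 1)}
_HET = {(0, 1)}
_HOM_REF = {(0, 0)}


def recessive_compatibility_filter(calls: VariantCallSet,
                                   case_ids: list[str],
                                   carrier_ids: list[str],
                                   control_ids: list[str],
                                   strict_missing: bool = True
                                   ) -> list[CandidateVariant]:
    """Variants passing all three compatibility conditions.

    ``strict_missing=True`` (default) fails a variant with any missing
    genotype in a decisive sample; the lenient mode ignores missing
    samples as long as at least one sample per group remains testable.
    """
    for name, group in (("case", case_ids), ("carrier", carrier_ids),
                        ("control", control_ids)):
        if not group:
            raise ValueError(f"empty {name} sample group: condition untestable")
    candidates = []
    for v in calls.variants:
        npos, nref, nalt = normalize_variant(v.pos, v.ref, v.alt)
        nv = Variant(v.chrom, npos, nref, nalt, v.vid, v.gts, v.phased)
        flags = (
            _group_flag(calls.genotypes_for(v, case_ids), _HOM_ALT, strict_missing),
            _group_flag(calls.genotypes_for(v, carrier_ids), _HET, strict_missing),
            _group_flag(calls.genotypes_for(v, control_ids), _HOM_REF,
                        strict_missing),
        )
        cand = CandidateVariant(nv, *flags)
        if cand.compatible:
            candidates.append(cand)
    return candidates


def cross_population_exclusion(candidates: list[CandidateVariant],
                               panel: VariantCallSet | None
                               ) -> tuple[list[CandidateVariant],
                                          list[CandidateVariant]]:
    """Exclude candidates whose alternate allele is seen in any panel genotype.

    Candidates absent from the panel data are retained with
    ``panel_polymorphic = None`` (untested).
    """
    retained, excluded = [], []
    for cand in candidates:
        v = cand.variant
        hit = panel.find(v.chrom, v.pos, v.ref, v.alt) if panel is not None \
            else None
        if hit is None:
            cand.panel_polymorphic = None
            retained.append(cand)
            continue
        cand.panel_polymorphic = bool((hit.gts == 1).any())
        (excluded if cand.panel_polymorphic else retained).append(cand)
    return retained, excluded


def _affected_positions(variant: Variant) -> tuple[int, int]:
    """Genomic footprint of the allele change after normalization."""
    pos, ref, alt = normalize_variant(variant.pos, variant.ref, variant.alt)
    if len(ref) == 1 and len(alt) == 1:
        return pos, pos
    # indel: the changed bases sit after the anchor base
    return pos + 1, pos + max(len(ref) - 1, 1)


def classify_variant_region(variant: Variant, gene: GeneModel,
                            splice_distance_threshold: int = SPLICE_DISTANCE_THRESHOLD
                            ) -> CandidateVariant:
    """Classify a variant as exonic / intronic / intergenic for one gene model.

    Intronic variants get the distance to the nearest flanking exon
    boundary and are labelled ``deprioritized`` beyond the configured
    splice-distance threshold.
    """
    gene.validate()
    start, _ = _affected_positions(variant)
    pos = start
    cand = CandidateVariant(variant, False, False, False)
    gs, ge = gene.span
    if pos < gs or pos > ge:
        cand.region, cand.priority = "intergenic", "candidate"
        return cand
    exon = gene.exon_of(pos)
    if exon is not None:
        cand.region, cand.gene_id = "exonic", gene.gene_id
        cand.priority = "candidate"
        return cand
    for intron_start, intron_end in gene.introns():
        if intron_start <= pos <= intron_end:
            dist = min(pos - intron_start + 1, intron_end - pos + 1)
            cand.region, cand.gene_id = "intronic", gene.gene_id
            cand.splice_distance = int(dist)
            cand.priority = ("deprioritized" if dist > splice_distance_threshold
                             else "candidate")
            return cand
    raise AssertionError("position inside gene span but neither exonic nor intronic")


def candidates_to_frame(candidates: list[CandidateVariant]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        v = c.variant
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "id": v.vid,
            "type": v.variant_class, "ref": v.ref, "alt": v.alt,
            "gene": c.gene_id or "", "region": c.region or "",
            "splice_distance": c.splice_distance,
            "panel_polymorphic": c.panel_polymorphic,
            "priority": c.priority or "",
            "compatible": c.compatible})
    return pd.DataFrame(rows)
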