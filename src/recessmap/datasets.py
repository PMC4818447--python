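"""Published reference tables from the bovine dwarfism (DW) locus mapping.

Bundled as plain data so the filtering and concordance operations can be
exercised on the real published counts without any external download:

* ``DW_CANDIDATE_VARIANTS``: the ten sequence variants on chromosome 3
  compatible with recessive inheritance of DW, with the flag marking the
  eight that segregate in a 1005-animal multi-breed panel.
* ``DW_VALIDATION_GENOTYPES``: validation-assay genotype counts at the
  causal 1-bp deletion (rs723240647) and the linked intronic SNV
  (rs715250609), stratified by array-derived haplotype status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Variant, VariantCallSet
from .recfilter import CandidateVariant

# chrom, pos, id, type, ref, alt, gene, effect, polymorphic in multi-breed panel
DW_CANDIDATE_VARIANTS = pd.DataFrame(
    [
        ("3", 15_079_217, "rs723240647", "indel", "C", "-", "GON4L",
         "p.E1430Kfs66", False),
        ("3", 15_713_943, "rs524337907", "SNV", "G", "C", "", "", True),
        ("3", 15_713_959, "rs719431247", "SNV", "G", "A", "", "", True),
        ("3", 15_737_755, "rs723848297", "SNV", "C", "T", "", "", True),
        ("3", 15_737_992, "ss1457237026", "indel", "T", "-", "", "", True),
        ("3", 15_738_245, "rs720131431", "indel", "C", "-", "", "", True),
        ("3", 15_815_016, "rs723370534", "SNV", "G", "A", "KCNN3",
         "intronic", True),
        ("3", 15_924_914, "rs717718209", "SNV", "G", "A", "KCNN3",
         "intronic", True),
        ("3", 16_046_490, "rs720952332", "SNV", "T", "C", "ADAR",
         "intronic", True),
        ("3", 16_131_785, "rs715250609", "SNV", "T", "C", "TDRD10",
         "intronic", False),
    ],
    columns=["chrom", "pos", "id", "type", "ref", "alt", "gene", "effect",
             "panel_polymorphic"],
)

# haplotype status → genotype class → count, per assayed variant
DW_VALIDATION_GENOTYPES = {
    "rs723240647": {
        "non-carrier": {"hom_ref": 3581, "het": 0, "hom_alt": 0},
        "carrier": {"hom_ref": 1, "het": 82, "hom_alt": 0},
        "homozygous": {"hom_ref": 0, "het": 0, "hom_alt": 27},
        "unknown": {"hom_ref": 180, "het": 11, "hom_alt": 0},
    },
    "rs715250609": {
        "non-carrier": {"hom_ref": 1737, "het": 3, "hom_alt": 0},
        "carrier": {"hom_ref": 0, "het": 53, "hom_alt": 0},
        "homozygous": {"hom_ref": 0, "het": 0, "hom_alt": 27},
        "unknown": {"hom_ref": 31, "het": 0, "hom_alt": 0},
    },
}


def _vcf_alleles(row) -> tuple[int, str, str]:
    """Printed '-' deletions become anchored VCF-style alleles."""
    if row["alt"] == "-":
        return int(row["pos"]) - 1, "N" + row["ref"], "N"
    return int(row["pos"]), row["ref"], row["alt"]


def candidate_variants() -> list[CandidateVariant]:
    """The published candidates as already-compatible ``CandidateVariant``s."""
    out = []
    for _, row in DW_CANDIDATE_VARIANTS.iterrows():
        pos, ref, alt = _vcf_alleles(row)
        v = Variant(row["chrom"], pos, ref, alt, row["id"],
                    np.zeros((0, 2), dtype=np.int8))
        out.append(CandidateVariant(v, True, True, True,
                                    gene_id=row["gene"] or None))
    return out


def panel_callset(n_panel: int = 1005) -> VariantCallSet:
    """A panel call set realizing the published polymorphic-in-panel flags.

    Variants flagged polymorphic get one heterozygous panel genotype;
    the others are monomorphic reference across the panel.
    """
    samples = [f"PANEL_{i + 1:04d}" for i in range(n_panel)]
    variants = []
    for _, row in DW_CANDIDATE_VARIANTS.iterrows():
        pos, ref, alt = _vcf_alleles(row)
        gts = np.zeros((n_panel, 2), dtype=np.int8)
        if row["panel_polymorphic"]:
            gts[0] = (0, 1)
        variants.append(Variant(row["chrom"], pos, ref, alt, row["id"], gts))
    return VariantCallSet(samples, variants)


def validation_crosstab_series(variant_id: str) -> tuple[pd.Series, pd.Series]:
    """Expand the published counts into per-individual genotype/status series."""
    try:
        counts = DW_VALIDATION_GENOTYPES[variant_id]
    except KeyError:
        raise KeyError(f"no validation genotypes for {variant_id!r}") from None
    genotypes, statuses, index = [], [], []
    i = 0
    for status, row in counts.items():
        for cls, n in row.items():
            for _ in range(n):
                index.append(f"A{i:05d}")
                genotypes.append(cls)
                statuses.append(status)
                i += 1
    idx = pd.Index(index)
    return pd.Series(genotypes, index=idx), pd.Series(statuses, index=idx)
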