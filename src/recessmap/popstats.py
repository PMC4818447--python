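"""Population-genetic summaries: LD, genotype–haplotype concordance,
carrier-frequency trends and Hardy–Weinberg expectations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING

HAP_STATUSES = ("non-carrier", "carrier", "homozygous", "unknown")
GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")
# expected concordant genotype per known haplotype status
EXPECTED_GENOTYPE = {"non-carrier": "hom_ref", "carrier": "het",
                     "homozygous": "hom_alt"}


def ld_r2(alleles_a: np.ndarray, alleles_b: np.ndarray) -> float:
    """Squared allelic correlation between two loci from phased haplotypes.

    Inputs are parallel 0/1 allele vectors (one entry per haplotype copy;
    -1 = missing, dropped pairwise).  Monomorphic loci give NaN
    (undefined), never 0.
    """
    a = np.asarray(alleles_a, dtype=float)
    b = np.asarray(alleles_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("allele vectors differ in length")
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least 2 complete haplotypes")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


@dataclass
class CrossTab:
    table: pd.DataFrame                   # statuses × genotype classes
    discordant: int
    discordant_cells: list[tuple[str, str, int]]

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def genotype_haplotype_crosstab(genotype_class: pd.Series,
                                hap_status: pd.Series) -> CrossTab:
    """Cross-tabulate variant genotype classes against haplotype status.

    Both inputs are indexed by individual; the intersection of indices is
    tabulated.  Discordance counts individuals with a KNOWN status whose
    genotype differs from the expected class (non-carrier → hom_ref,
    carrier → het, homozygous → hom_alt).
    """
    common = genotype_class.index.intersection(hap_status.index)
    g = genotype_class.loc[common]
    h = hap_status.loc[common]
    bad = set(h.unique()) - set(HAP_STATUSES)
    if bad:
        raise ValueError(f"unknown haplotype statuses: {sorted(bad)}")
    table = pd.crosstab(h, g).reindex(index=list(HAP_STATUSES),
                                      columns=list(GENOTYPE_CLASSES),
                                      fill_value=0)
    table.index.name, table.columns.name = "hap_status", "genotype"
    cells = []
    discordant = 0
    for status, expected in EXPECTED_GENOTYPE.items():
        for cls in GENOTYPE_CLASSES:
            n = int(table.loc[status, cls])
            if cls != expected and n > 0:
                cells.append((status, cls, n))
                discordant += n
    return CrossTab(table, discordant, cells)


def expected_homozygous_births(q: float, n_births: int) -> float:
    """Random-mating Hardy–Weinberg expectation q²·N of affected births."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    return q * q * n_births


@dataclass
class TrendPoint:
    group: tuple
    cohort_size: int
    carrier_copies: int
    frequency: float


def frequency_trend(hap_status: pd.Series, metadata: pd.DataFrame,
                    by: list[str] = ("birth_year",)) -> list[TrendPoint]:
    """Carrier-haplotype frequency per metadata group (year and/or sex).

    Frequency = carrier copies / (2 × group size); heterozygous carriers
    contribute one copy, homozygotes two, unknown-status individuals are
    excluded.  Empty groups are omitted with a warning.
    """
    copies_map = {"non-carrier": 0, "carrier": 1, "homozygous": 2}
    common = hap_status.index.intersection(metadata.index)
    df = metadata.loc[common, list(by)].copy()
    df["status"] = hap_status.loc[common]
    df = df[df["status"] != "unknown"]
    dropped = df[list(by)].isna().any(axis=1)
    if dropped.any():
        warnings.warn(f"{int(dropped.sum())} individuals lack grouping "
                      "metadata and were omitted", UserWarning)
        df = df[~dropped]
    points = []
    for key, grp in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        size = len(grp)
        copies = int(grp["status"].map(copies_map).sum())
        points.append(TrendPoint(key, size, copies, copies / (2 * size)))
    return points
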