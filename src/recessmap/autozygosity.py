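"""Runs of homozygosity and the case-shared autozygous segment.

ROH are maximal runs of consecutive markers containing at most
``max_het`` heterozygous and ``max_missing`` missing calls; the shared
segment is the interval contained in at least one ROH of every case.
Detection is genotype-based, so it works on unphased data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable


@dataclass
class RohConfig:
    min_markers: int = 20
    max_het: int = 1
    max_missing: int = 2

    def __post_init__(self):
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("max_het and max_missing must be >= 0")


@dataclass
class RohSegment:
    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    n_het: int
    n_missing: int


def _maximal_runs(het: np.ndarray, miss: np.ndarray, max_het: int,
                  max_missing: int) -> list[tuple[int, int]]:
    """Maximal index intervals with at most max_het hets and max_missing missing.

    Two-pointer sweep: L(r) is the smallest valid left end for right end r;
    [L(r), r] is maximal iff r is the last index or L(r+1) > L(r).
    """
    m = het.size
    runs = []
    l = 0
    n_het = n_miss = 0
    prev_l = None
    for r in range(m):
        n_het += het[r]
        n_miss += miss[r]
        while n_het > max_het or n_miss > max_missing:
            n_het -= het[l]
            n_miss -= miss[l]
            l += 1
        if prev_l is not None and l > prev_l:
            runs.append((prev_l, r - 1))
        prev_l = l
    if prev_l is not None:
        runs.append((prev_l, m - 1))
    return runs


def detect_roh(genotypes: GenotypeMatrix, individual: str, mmap: MarkerMap,
               config: RohConfig | None = None) -> list[RohSegment]:
    """All maximal ROH of one individual, in map order, per chromosome."""
    config = config or RohConfig()
    i = genotypes.individual_index(individual)   # raises if absent
    g = genotypes.genotypes()[i]
    pos = mmap.positions()
    segments = []
    for chrom in mmap.chromosomes:
        idx = mmap.chrom_indices(chrom)
        gc = g[idx]
        het = (gc == 1).astype(np.int64)
        miss = (gc == MISSING).astype(np.int64)
        for l, r in _maximal_runs(het, miss, config.max_het, config.max_missing):
            if r - l + 1 < config.min_markers:
                continue
            segments.append(RohSegment(
                individual=individual, chrom=chrom,
                start_bp=int(pos[idx[l]]), end_bp=int(pos[idx[r]]),
                n_markers=int(r - l + 1),
                n_het=int(het[l:r + 1].sum()),
                n_missing=int(miss[l:r + 1].sum())))
    return segments


def _interval_union(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _intersect_unions(a: list[tuple[int, int]],
                      b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


@dataclass
class SharedSegment:
    chrom: str | None
    interval: tuple[int, int] | None     # longest shared component, bp inclusive
    components: list[tuple[str, int, int]]
    n_cases: int

    @property
    def empty(self) -> bool:
        return self.interval is None


def shared_case_segment(rohs_per_case: dict[str, list[RohSegment]],
                        region_hint: tuple[str, int, int] | None = None
                        ) -> SharedSegment:
    """Intersect every case's ROH coverage; report all shared components and
    the longest one.  ``region_hint`` = (chrom, start, end) restricts the
    search.  An empty intersection is a valid (explicit) outcome.
    """
    if not rohs_per_case:
        raise ValueError("no cases provided")
    chroms = sorted({seg.chrom for segs in rohs_per_case.values()
                     for seg in segs})
    if region_hint is not None:
        chroms = [c for c in chroms if c == str(region_hint[0])]
    components: list[tuple[str, int, int]] = []
    for chrom in chroms:
        shared = None
        for case, segs in rohs_per_case.items():
            ivals = _interval_union([(s.start_bp, s.end_bp) for s in segs
                                     if s.chrom == chrom])
            if region_hint is not None:
                ivals = _intersect_unions(
                    ivals, [(region_hint[1], region_hint[2])])
            shared = ivals if shared is None else _intersect_unions(shared, ivals)
            if not shared:
                break
        components.extend((chrom, s, e) for s, e in (shared or []))
    if not components:
        return SharedSegment(None, None, [], len(rohs_per_case))
    best = max(components, key=lambda c: (c[2] - c[1], -c[1]))
    return SharedSegment(best[0], (best[1], best[2]), components,
                         len(rohs_per_case))


@dataclass
class CarrierStats:
    n_het: int
    n_hom: int
    n_noncarrier: int
    n_copies: int
    total_copies: int
    frequency: float


def haplotype_carrier_stats(haps: GenotypeMatrix, marker_indices: np.ndarray,
                            allele_string: np.ndarray,
                            phenos: PhenotypeTable | None = None,
                            cohort: list[str] | None = None) -> CarrierStats:
    """Carrier counts for one segment haplotype among a cohort.

    A haplotype copy is a carrier copy iff it matches ``allele_string``
    at every marker of the segment (missing ⇒ no match).  Frequency is
    carrier copies / total copies in the cohort.
    """
    if not haps.phased:
        raise ValueError("carrier stats require phased input")
    if cohort is None:
        cohort = (phenos.control_ids if phenos is not None
                  else list(haps.individuals))
    sub = haps.subset_individuals(cohort)
    block = sub.haplotypes[:, np.asarray(marker_indices)]
    match = (block == np.asarray(allele_string, dtype=block.dtype)).all(axis=1)
    per_ind = match[0::2].astype(int) + match[1::2].astype(int)
    n_het = int((per_ind == 1).sum())
    n_hom = int((per_ind == 2).sum())
    n_non = int((per_ind == 0).sum())
    total = 2 * len(cohort)
    copies = n_het + 2 * n_hom
    return CarrierStats(n_het, n_hom, n_non, copies, total,
                        copies / total if total else float("nan"))
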