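"""Sliding-window haplotype association scan.

Windows of W contiguous markers are shifted along each chromosome in
steps of s; within each window every haplotype above a frequency floor
is tested for allelic association (carriers of that haplotype vs all
other haplotype copies, cases vs controls) with a two-sided Fisher exact
test computed in log space, and a Bonferroni threshold is derived from
the total number of haplotypes actually tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable

LOG10E = np.log10(np.e)


@dataclass
class ScanConfig:
    window_size: int = 25
    step: int = 2
    hap_freq_min: float = 0.005
    alpha: float = 0.05

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 1 <= self.step <= self.window_size:
            raise ValueError("step must satisfy 1 <= step <= window_size")
        if not 0.0 <= self.hap_freq_min <= 1.0:
            raise ValueError("hap_freq_min outside [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha outside (0, 1]")


@dataclass
class Window:
    chrom: str
    first: int       # global marker index of first marker
    last: int        # global marker index of last marker (inclusive)
    start_bp: int
    end_bp: int


@dataclass
class AssociationResult:
    chrom: str
    start_bp: int
    end_bp: int
    haplotype: str
    case_carrier: int
    case_noncarrier: int
    control_carrier: int
    control_noncarrier: int
    p_value: float
    log10_p: float
    significant: bool = False


def enumerate_windows(mmap: MarkerMap, config: ScanConfig) -> list[Window]:
    """Windows per chromosome; trailing markers without a full window are skipped."""
    windows = []
    pos = mmap.positions()
    for chrom in mmap.chromosomes:
        idx = mmap.chrom_indices(chrom)
        m = idx.size
        w, s = config.window_size, config.step
        if m < w:
            warnings.warn(f"chromosome {chrom} has {m} < {w} markers; "
                          "no windows placed", UserWarning)
            continue
        for k in range(0, m - w + 1, s):
            first, last = idx[k], idx[k + w - 1]
            windows.append(Window(chrom, int(first), int(last),
                                  int(pos[first]), int(pos[last])))
    return windows


@dataclass
class HaplotypeCounts:
    allele_string: str
    frequency: float
    total_copies: int
    case_carrier: int
    case_noncarrier: int
    control_carrier: int
    control_noncarrier: int


def _status_array(haps: GenotypeMatrix, phenos: PhenotypeTable) -> np.ndarray:
    lookup = dict(zip(phenos.table["individual"], phenos.table["status"]))
    return np.array([lookup.get(ind, "unknown") for ind in haps.individuals])


def tabulate_window_haplotypes(haps: GenotypeMatrix, window: Window,
                               phenos: PhenotypeTable, hap_freq_min: float,
                               _status: np.ndarray | None = None
                               ) -> list[HaplotypeCounts]:
    """Count haplotype copies in a window and build the per-haplotype 2×2 margins.

    A haplotype copy with any missing allele inside the window is
    excluded from tabulation.  Frequency is estimated over every
    non-missing copy (cases + controls + unknowns); only haplotypes with
    frequency strictly above ``hap_freq_min`` are returned.  Copies of
    unknown-status individuals enter frequency estimation but not the
    case/control margins.
    """
    if not haps.phased:
        raise ValueError("haplotype tabulation requires phased input")
    block = haps.haplotypes[:, window.first:window.last + 1]
    complete = (block != MISSING).all(axis=1)

    status = _status if _status is not None else _status_array(haps, phenos)
    hap_status = np.repeat(status, 2)
    is_case = (hap_status == "affected") & complete
    is_control = (hap_status == "unaffected") & complete

    kept = block[complete]
    if kept.shape[0] == 0:
        return []
    w = kept.shape[1]
    if w <= 63:
        # 0/1 alleles pack into one integer per row: much faster than
        # lexicographic row-unique
        codes = kept.astype(np.int64) @ (np.int64(1) << np.arange(w, dtype=np.int64))
        ucodes, inverse = np.unique(codes, return_inverse=True)
        uniq = ((ucodes[:, None] >> np.arange(w, dtype=np.int64)) & 1
                ).astype(np.int8)
    else:
        uniq, inverse = np.unique(kept, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=uniq.shape[0])
    total = int(complete.sum())

    case_rows = np.flatnonzero(is_case[complete])
    control_rows = np.flatnonzero(is_control[complete])
    n_case = case_rows.size
    n_control = control_rows.size
    case_counts = np.bincount(inverse[case_rows], minlength=uniq.shape[0])
    control_counts = np.bincount(inverse[control_rows], minlength=uniq.shape[0])

    out = []
    for h in range(uniq.shape[0]):
        freq = counts[h] / total
        if freq <= hap_freq_min:
            continue
        out.append(HaplotypeCounts(
            allele_string="".join(map(str, uniq[h])),
            frequency=float(freq),
            total_copies=int(counts[h]),
            case_carrier=int(case_counts[h]),
            case_noncarrier=int(n_case - case_counts[h]),
            control_carrier=int(control_counts[h]),
            control_noncarrier=int(n_control - control_counts[h])))
    return out


def fisher_allelic_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of the 2×2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities not exceeding the observed
    one, entirely in log space, so P values far below the double
    underflow limit keep an exact log10.  Returns ``(p, log10_p)``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0, 0.0                       # a zero margin: degenerate

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    logpmf = (gammaln(r1 + 1) + gammaln(n - r1 + 1) + gammaln(c1 + 1)
              + gammaln(n - c1 + 1) - gammaln(n + 1)
              - gammaln(xs + 1) - gammaln(r1 - xs + 1)
              - gammaln(c1 - xs + 1) - gammaln(n - r1 - c1 + xs + 1))
    obs = logpmf[a - lo]
    take = logpmf <= obs + 1e-7               # relative tolerance for ties
    if take.all():
        return 1.0, 0.0
    logp = logsumexp(logpmf[take])
    logp = min(logp, 0.0)
    return float(np.exp(logp)), float(logp * LOG10E)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ScanResult:
    results: list[AssociationResult]
    threshold: float
    n_tests: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chrom": r.chrom, "window_start_bp": r.start_bp,
            "window_end_bp": r.end_bp, "haplotype": r.haplotype,
            "a": r.case_carrier, "b": r.case_noncarrier,
            "c": r.control_carrier, "d": r.control_noncarrier,
            "p": r.p_value, "log10p": r.log10_p,
            "significant": r.significant} for r in self.results])

    def significant_windows(self) -> list[tuple[str, int, int]]:
        seen, out = set(), []
        for r in self.results:
            if r.significant and (r.chrom, r.start_bp, r.end_bp) not in seen:
                seen.add((r.chrom, r.start_bp, r.end_bp))
                out.append((r.chrom, r.start_bp, r.end_bp))
        return out


def scan_genome(haps: GenotypeMatrix, mmap: MarkerMap, phenos: PhenotypeTable,
                config: ScanConfig | None = None) -> ScanResult:
    """One Fisher test per (window, retained haplotype); Bonferroni over all tests.

    Results are sorted by p value (ties by chromosome, then window start);
    ``significant`` means strictly below ``alpha / n_tests``.
    """
    config = config or ScanConfig()
    status = _status_array(haps, phenos)
    tests: list[AssociationResult] = []
    for window in enumerate_windows(mmap, config):
        for hc in tabulate_window_haplotypes(haps, window, phenos,
                                             config.hap_freq_min,
                                             _status=status):
            p, logp = fisher_allelic_test(hc.case_carrier, hc.case_noncarrier,
                                          hc.control_carrier,
                                          hc.control_noncarrier)
            tests.append(AssociationResult(
                window.chrom, window.start_bp, window.end_bp,
                hc.allele_string, hc.case_carrier, hc.case_noncarrier,
                hc.control_carrier, hc.control_noncarrier, p, logp))
    if not tests:
        raise ValueError("no haplotypes passed the frequency filter; "
                         "nothing to test")
    threshold = bonferroni_threshold(config.alpha, len(tests))
    log_thresh = np.log10(threshold)
    for t in tests:
        t.significant = t.log10_p < log_thresh
    tests.sort(key=lambda t: (t.log10_p, t.chrom, t.start_bp))
    return ScanResult(tests, threshold, len(tests))
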