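"""Array quality control: per-marker/per-individual statistics and filters.

Filters mirror standard array practice: minor allele frequency, exact
Hardy–Weinberg test and call rate per marker, call rate per individual.
All thresholds are pass-if-strictly-greater (a marker with MAF exactly
equal to the minimum fails).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable


@dataclass
class QcConfig:
    maf_min: float = 0.005
    hwe_p_min: float = 0.0001
    marker_call_rate_min: float = 0.95
    individual_call_rate_min: float = 0.95
    include_cases_in_hwe: bool = False

    def __post_init__(self):
        for name in ("maf_min", "hwe_p_min", "marker_call_rate_min",
                     "individual_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class MarkerStats:
    marker: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int
    maf: float          # NaN when no calls
    call_rate: float
    hwe_p: float        # NaN when no calls or monomorphic input of size 0

    @property
    def n_called(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact conditional Hardy–Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table.  Computed in log space via log-factorials.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        return float("nan")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    ks = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - ks) // 2
    hom_common = n - ks - hom_rare
    # log P(n_het = k | allele counts), unnormalized:
    #   n! / (hom_r! k! hom_c!) * 2^k ; normalizer is constant over k
    logp = (ks * np.log(2.0) - gammaln(hom_rare + 1) - gammaln(ks + 1)
            - gammaln(hom_common + 1))
    logp -= logsumexp(logp)
    obs = logp[np.searchsorted(ks, n_het)]
    take = logp <= obs + 1e-12
    if take.all():
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logp[take]))))


def compute_marker_stats(genotypes: GenotypeMatrix, marker: int | str,
                         hwe_individuals: np.ndarray | None = None,
                         mmap: MarkerMap | None = None) -> MarkerStats:
    """Per-marker allele/genotype summary.

    ``marker`` is a column index, or a marker id when ``mmap`` is given.
    ``hwe_individuals`` is an optional boolean mask selecting which
    individuals enter the Hardy–Weinberg test (MAF and call rate always
    use everyone).
    """
    name = ""
    if isinstance(marker, str):
        if mmap is None:
            raise ValueError("marker id lookup requires a MarkerMap")
        name, marker = marker, mmap.marker_index(marker)
    g = genotypes.genotypes()[:, marker]
    n_missing = int((g == MISSING).sum())
    n0, n1, n2 = (int((g == k).sum()) for k in (0, 1, 2))
    n_called = n0 + n1 + n2
    call_rate = n_called / len(g) if len(g) else 0.0
    if n_called == 0:
        return MarkerStats(name, n0, n1, n2, n_missing, float("nan"),
                           call_rate, float("nan"))
    alt_freq = (n1 + 2 * n2) / (2 * n_called)
    maf = min(alt_freq, 1.0 - alt_freq)
    gh = g if hwe_individuals is None else g[hwe_individuals]
    h0, h1, h2 = (int((gh == k).sum()) for k in (0, 1, 2))
    hwe = hwe_exact_p(h0, h1, h2)
    return MarkerStats(name, n0, n1, n2, n_missing, maf, call_rate, hwe)


def individual_call_rates(genotypes: GenotypeMatrix) -> np.ndarray:
    g = genotypes.genotypes()
    return (g != MISSING).mean(axis=1)


def apply_qc(genotypes: GenotypeMatrix, mmap: MarkerMap,
             config: QcConfig | None = None,
             phenotypes: PhenotypeTable | None = None
             ) -> tuple[GenotypeMatrix, MarkerMap, pd.DataFrame]:
    """Apply individual-then-marker filters; return survivors plus a report.

    Individuals failing the call-rate threshold are removed first; marker
    statistics are then recomputed on the surviving individuals.  By
    default affected individuals are excluded from the Hardy–Weinberg
    test (a recessive-enriched case set violates HWE at the mapped locus
    by design); set ``include_cases_in_hwe`` to override.
    """
    config = config or QcConfig()
    report_rows = []

    rates = individual_call_rates(genotypes)
    keep_ind = rates > config.individual_call_rate_min
    for ind, rate, ok in zip(genotypes.individuals, rates, keep_ind):
        if not ok:
            report_rows.append(("individual", ind, "call_rate", float(rate),
                                False, "call_rate"))
    surv = genotypes.subset_individuals(
        [ind for ind, ok in zip(genotypes.individuals, keep_ind) if ok])
    if surv.n_individuals == 0:
        raise ValueError(
            f"no individuals survive QC ({len(genotypes.individuals)} removed "
            f"for call rate <= {config.individual_call_rate_min})")

    hwe_mask = None
    if not config.include_cases_in_hwe and phenotypes is not None:
        affected = set(phenotypes.case_ids)
        hwe_mask = np.array([ind not in affected for ind in surv.individuals])
        if not hwe_mask.any():
            hwe_mask = None

    g = surv.genotypes()
    n0 = (g == 0).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    n_called = n0 + n1 + n2
    call_rate = n_called / surv.n_individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (n1 + 2 * n2) / (2 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    gh = g if hwe_mask is None else g[hwe_mask]
    h0 = (gh == 0).sum(axis=0)
    h1 = (gh == 1).sum(axis=0)
    h2 = (gh == 2).sum(axis=0)

    keep_marker = np.ones(surv.n_markers, dtype=bool)
    for j in range(surv.n_markers):
        name = mmap.table["marker"].iloc[j]
        reason = None
        if call_rate[j] <= config.marker_call_rate_min:
            reason, value = "call_rate", call_rate[j]
        elif not maf[j] > config.maf_min:          # NaN fails too
            reason, value = "MAF", maf[j]
        else:
            hwe = hwe_exact_p(int(h0[j]), int(h1[j]), int(h2[j]))
            if not hwe > config.hwe_p_min:
                reason, value = "HWE", hwe
        if reason is not None:
            keep_marker[j] = False
            report_rows.append(("marker", name, reason, float(value),
                                False, reason))
    if not keep_marker.any():
        raise ValueError(
            f"no markers survive QC ({(~keep_marker).sum()} of "
            f"{surv.n_markers} removed)")

    report = pd.DataFrame(report_rows, columns=[
        "entity_type", "entity", "statistic", "value", "pass", "reason"])
    return surv.subset_markers(keep_marker), mmap.subset(keep_marker), report
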