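"""Shared fixtures: a small simulated cohort, the default gene fixture,
and independent brute-force oracles used by the property tests."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest

from recessmap.core import GenotypeMatrix, MarkerMap, PhenotypeTable
from recessmap.simdata import (GeneFixtureSpec, SimulationConfig,
                               make_gene_fixture, simulate_population,
                               simulate_sequence_cohort)


def small_sim_config(**overrides) -> SimulationConfig:
    base = dict(seed=7, n_cases=10, n_controls=300, n_markers_per_chrom=120,
                n_chromosomes=2, causal_chrom="2", causal_pos=3_000_000,
                disease_hap_span=(2_000_000, 4_100_000),
                carrier_hap_freq=0.01, n_sequenced_controls=20,
                n_panel_individuals=15)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_sim_config()
    gm, mmap, phenos, truth = simulate_population(cfg)
    return cfg, gm, mmap, phenos, truth


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    cfg, _, _, _, truth = small_cohort
    return simulate_sequence_cohort(cfg, truth)


@pytest.fixture(scope="session")
def default_fixture():
    return make_gene_fixture(GeneFixtureSpec())


def genotypes_from_classes(classes: str) -> GenotypeMatrix:
    """One individual from a string of h(om-ref)/H(om-alt)/e(het)/m(issing)."""
    mapping = {"h": (0, 0), "H": (1, 1), "e": (0, 1), "m": (-1, -1)}
    pairs = [mapping[c] for c in classes]
    haps = np.array(pairs, dtype=np.int8).T
    return GenotypeMatrix(["IND"], haps, phased=False)


def uniform_map(n: int, chrom: str = "1", spacing: int = 1000) -> MarkerMap:
    return MarkerMap(pd.DataFrame({
        "marker": [f"m{i}" for i in range(n)], "chrom": chrom,
        "pos": spacing * (np.arange(n) + 1), "ref": "A", "alt": "C"}))


def simple_phenos(case_ids, control_ids, unknown_ids=()) -> PhenotypeTable:
    rows = ([{"individual": i, "status": "affected", "role": "case"}
             for i in case_ids]
            + [{"individual": i, "status": "unaffected", "role": "control"}
               for i in control_ids]
            + [{"individual": i, "status": "unknown", "role": "control"}
               for i in unknown_ids])
    return PhenotypeTable(pd.DataFrame(rows))


# ------------------------------------------------------------------ oracles


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact P by exact-rational enumeration of the
    hypergeometric support (independent of the package implementation)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = {x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
             for x in range(lo, hi + 1)}
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs)


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact conditional HWE P by rational enumeration over all heterozygote
    counts compatible with the observed allele totals."""
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return Fraction(1)

    def weight(k: int) -> Fraction:
        hom_rare = (n_rare - k) // 2
        hom_common = n - k - hom_rare
        return Fraction(2 ** k,
                        factorial(hom_rare) * factorial(k) * factorial(hom_common))

    ks = range(n_rare % 2, n_rare + 1, 2)
    weights = {k: weight(k) for k in ks}
    total = sum(weights.values())
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / total


def roh_oracle(classes: str, min_markers: int, max_het: int,
               max_missing: int) -> list[tuple[int, int]]:
    """All maximal valid subintervals by exhaustive enumeration.

    ``classes`` uses h/H (homozygous), e (het), m (missing).
    """
    m = len(classes)
    valid = []
    for l in range(m):
        for r in range(l, m):
            seg = classes[l:r + 1]
            if seg.count("e") <= max_het and seg.count("m") <= max_missing:
                valid.append((l, r))
    maximal = [(l, r) for (l, r) in valid
               if not any(L <= l and r <= R and (L, R) != (l, r)
                          for (L, R) in valid)]
    return [(l, r) for (l, r) in maximal if r - l + 1 >= min_markers]
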