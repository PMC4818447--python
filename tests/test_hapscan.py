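import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from recessmap.core import GenotypeMatrix, MarkerMap
from recessmap.genoqc import apply_qc
from recessmap.hapscan import (ScanConfig, Window, bonferroni_threshold,
                               enumerate_windows, fisher_allelic_test,
                               scan_genome, tabulate_window_haplotypes)

from conftest import fisher_oracle, simple_phenos, uniform_map


def phased_matrix(rows: list[str]) -> GenotypeMatrix:
    """Haplotype rows as allele strings, two consecutive rows per individual."""
    haps = np.array([[{-1: -1}.get(c, int(c)) if c != "." else -1
                      for c in row] for row in rows], dtype=np.int8)
    inds = [f"I{i}" for i in range(len(rows) // 2)]
    return GenotypeMatrix(inds, haps, phased=True)


class TestEnumerateWindows:
    @pytest.mark.parametrize("m,w,s,expected", [
        (25, 25, 2, 1),
        (27, 25, 2, 2),
        (26, 25, 2, 1),
        (44672, 25, 2, 22324),
    ])
    def test_window_counts(self, m, w, s, expected):
        cfg = ScanConfig(window_size=w, step=s)
        assert len(enumerate_windows(uniform_map(m), cfg)) == expected

    def test_windows_do_not_span_chromosomes(self):
        t1 = uniform_map(30, chrom="1").table
        t2 = uniform_map(30, chrom="2").table
        t2["marker"] = [f"n{i}" for i in range(30)]
        mmap = MarkerMap(pd.concat([t1, t2], ignore_index=True))
        windows = enumerate_windows(mmap, ScanConfig(window_size=25, step=2))
        assert len(windows) == 6
        for w in windows:
            chroms = set(mmap.table["chrom"].iloc[w.first:w.last + 1])
            assert len(chroms) == 1

    def test_short_chromosome_warns(self):
        with pytest.warns(UserWarning, match="no windows"):
            windows = enumerate_windows(uniform_map(10),
                                        ScanConfig(window_size=25))
        assert windows == []

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(window_size=0)
        with pytest.raises(ValueError):
            ScanConfig(window_size=5, step=6)


class TestTabulate:
    def window(self, n):
        return Window("1", 0, n - 1, 1000, 1000 * n)

    def test_identical_homozygous_strings(self):
        gm = phased_matrix(["000", "000"] * 4)
        phenos = simple_phenos(["I0"], ["I1", "I2", "I3"])
        out = tabulate_window_haplotypes(gm, self.window(3), phenos, 0.0)
        assert len(out) == 1
        assert out[0].frequency == 1.0

    def test_single_differing_copy_frequency(self):
        rows = ["000", "000"] * 10
        rows[3] = "001"
        gm = phased_matrix(rows)
        phenos = simple_phenos(["I0"], [f"I{i}" for i in range(1, 10)])
        out = tabulate_window_haplotypes(gm, self.window(3), phenos, 0.0)
        minor = min(out, key=lambda h: h.frequency)
        assert minor.frequency == pytest.approx(1 / 20)
        assert len(out) == 2

    def test_rare_haplotype_excluded_at_threshold(self):
        rows = ["000", "000"] * 125
        rows[0] = "111"   # frequency 1/250 = 0.004
        gm = phased_matrix(rows)
        phenos = simple_phenos([], [f"I{i}" for i in range(125)])
        out = tabulate_window_haplotypes(gm, self.window(3), phenos, 0.005)
        assert [h.allele_string for h in out] == ["000"]

    def test_missing_copy_dropped(self):
        rows = ["000", "0.0", "000", "000"]
        gm = phased_matrix(rows)
        phenos = simple_phenos(["I0"], ["I1"])
        out = tabulate_window_haplotypes(gm, self.window(3), phenos, 0.0)
        assert out[0].total_copies == 3

    def test_unknown_status_in_frequency_not_in_test(self):
        rows = ["000", "000", "000", "000", "111", "111"]
        gm = phased_matrix(rows)
        phenos = simple_phenos(["I0"], ["I1"], unknown_ids=["I2"])
        out = tabulate_window_haplotypes(gm, self.window(3), phenos, 0.0)
        by_hap = {h.allele_string: h for h in out}
        assert by_hap["111"].frequency == pytest.approx(2 / 6)
        assert by_hap["111"].case_carrier == 0
        assert by_hap["111"].control_carrier == 0

    def test_unphased_rejected(self):
        gm = phased_matrix(["000", "000"])
        gm.phased = False
        with pytest.raises(ValueError, match="phased"):
            tabulate_window_haplotypes(gm, self.window(3),
                                       simple_phenos(["I0"], []), 0.0)


class TestFisher:
    def test_paper_top_signal(self):
        p, log10p = fisher_allelic_test(54, 0, 81, 20827)
        assert f"{p:.2e}" == "2.18e-124"
        assert log10p == pytest.approx(np.log10(p), rel=1e-9)

    def test_symmetric_unit_table(self):
        assert fisher_allelic_test(1, 1, 1, 1) == (1.0, 0.0)

    def test_zero_margin_degenerate(self):
        assert fisher_allelic_test(0, 0, 5, 7) == (1.0, 0.0)

    def test_row_column_transpose_invariance(self):
        for table in [(5, 3, 2, 8), (1, 9, 7, 2), (10, 0, 3, 5)]:
            a, b, c, d = table
            assert fisher_allelic_test(a, b, c, d)[0] == pytest.approx(
                fisher_allelic_test(a, c, b, d)[0], rel=1e-12)

    def test_monotonicity_adding_control_carrier(self):
        prev = fisher_allelic_test(20, 0, 0, 100)[0]
        for c in range(1, 20):
            cur = fisher_allelic_test(20, 0, c, 100 - c)[0]
            assert cur >= prev - 1e-18
            prev = cur

    def test_one_and_two_sided_coincide_on_extreme_tables(self):
        # opposite tail contributes nothing for the study's tables
        from scipy.stats import fisher_exact
        for table in [(54, 0, 81, 20827), (54, 0, 93, 7617)]:
            a, b, c, d = table
            two, _ = fisher_allelic_test(a, b, c, d)
            one = fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
            assert two == pytest.approx(one, rel=1e-9)

    def test_log_space_agrees_with_direct_space(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p, log10p = fisher_allelic_test(int(a), int(b), int(c), int(d))
            ref = fisher_exact([[a, b], [c, d]]).pvalue
            assert p == pytest.approx(ref, rel=1e-9)
            assert 10 ** log10p == pytest.approx(p, rel=1e-10)

    def test_extreme_table_no_underflow(self):
        # direct space would underflow: log10 P far below -308
        _, log10p = fisher_allelic_test(2000, 0, 0, 2000)
        assert log10p < -1000

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60),
           st.integers(0, 60))
    @settings(max_examples=300, deadline=None)
    def test_oracle_agreement_small_tables(self, a, b, c, d):
        assume(a + b + c + d > 0)
        assume(a + b + c + d <= 60)
        got, _ = fisher_allelic_test(a, b, c, d)
        assert got == pytest.approx(float(fisher_oracle(a, b, c, d)),
                                    rel=1e-9, abs=1e-15)


class TestScan:
    def test_bonferroni_paper_threshold(self):
        assert f"{bonferroni_threshold(0.05, 787232):.2e}" == "6.35e-08"

    def test_bonferroni_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_top_window_overlaps_planted_span(self, small_cohort):
        cfg, gm, mmap, phenos, truth = small_cohort
        fgm, fmap, _ = apply_qc(gm, mmap, phenotypes=phenos)
        result = scan_genome(fgm, fmap, phenos, ScanConfig())
        top = result.results[0]
        lo, hi = truth.marker_span_bp
        assert top.chrom == truth.causal_chrom
        assert top.start_bp <= hi and top.end_bp >= lo
        assert top.significant

    def test_zero_tests_errors(self):
        gm = phased_matrix(["0" * 25, "0" * 25])   # monomorphic -> 1 hap
        phenos = simple_phenos(["I0"], [])
        with pytest.raises(ValueError, match="nothing to test"):
            # freq filter at 1.0 excludes everything
            scan_genome(gm, uniform_map(25), phenos,
                        ScanConfig(hap_freq_min=1.0))

    def test_results_sorted_and_counts_consistent(self, small_cohort):
        cfg, gm, mmap, phenos, truth = small_cohort
        result = scan_genome(gm, mmap, phenos, ScanConfig())
        ps = [r.log10_p for r in result.results]
        assert ps == sorted(ps)
        n_case_copies = 2 * len(phenos.case_ids)
        for r in result.results[:5]:
            assert r.case_carrier + r.case_noncarrier <= n_case_copies
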