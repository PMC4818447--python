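import numpy as np
import pytest

from recessmap.core import MISSING
from recessmap.recfilter import recessive_compatibility_filter, \
    cross_population_exclusion
from recessmap.simdata import (GeneFixtureSpec, SimulationConfig,
                               make_gene_fixture, sequence_sample_names,
                               simulate_population, simulate_sequence_cohort,
                               _translate_to_stop)

from conftest import small_sim_config


class TestSimulationConfig:
    def test_proportion_validation(self):
        with pytest.raises(ValueError, match="carrier_hap_freq"):
            small_sim_config(carrier_hap_freq=1.5)

    def test_causal_pos_must_be_in_span(self):
        with pytest.raises(ValueError, match="causal_pos"):
            small_sim_config(causal_pos=9_999_999)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"bogus": 1})


class TestSimulatePopulation:
    def test_all_cases_homozygous_for_planted_haplotype(self):
        cfg = small_sim_config(seed=1, n_cases=27, n_controls=100)
        _, _, _, truth = simulate_population(cfg)
        block = truth.clean_haplotypes[:2 * 27, truth.span_marker_indices]
        assert (block == truth.founder_haplotype).all()

    def test_control_carrier_frequency_within_3se(self):
        cfg = small_sim_config(seed=1, carrier_hap_freq=0.004,
                               n_controls=10_000, n_cases=2)
        _, _, _, truth = simulate_population(cfg)
        n_copies = 2 * cfg.n_controls
        observed = len(truth.carrier_ids) / n_copies
        se = np.sqrt(0.004 * 0.996 / n_copies)
        assert abs(observed - 0.004) <= 3 * se

    def test_seed_determinism(self):
        a = simulate_population(small_sim_config(seed=5))
        b = simulate_population(small_sim_config(seed=5))
        assert np.array_equal(a[0].haplotypes, b[0].haplotypes)
        assert a[1].table.equals(b[1].table)
        assert a[2].table.equals(b[2].table)

    def test_affected_iff_homozygous_before_noise(self, small_cohort):
        cfg, gm, mmap, phenos, truth = small_cohort
        clean = truth.clean_haplotypes[:, truth.span_marker_indices]
        match = (clean == truth.founder_haplotype).all(axis=1)
        hom = match[0::2] & match[1::2]
        affected = np.array(
            [phenos.status_of(i) == "affected" for i in gm.individuals])
        assert (hom == affected).all()

    def test_zero_noise_reconstructs_genotypes(self):
        cfg = small_sim_config(genotyping_error_rate=0.0, missing_rate=0.0)
        gm, _, _, truth = simulate_population(cfg)
        assert np.array_equal(gm.haplotypes, truth.clean_haplotypes)
        assert not (gm.genotypes() == MISSING).any()

    def test_zero_carriers_warns(self):
        cfg = small_sim_config(carrier_hap_freq=1e-9, n_controls=10)
        with pytest.warns(UserWarning, match="zero carrier"):
            simulate_population(cfg)

    def test_span_without_markers_errors(self):
        with pytest.raises(ValueError, match="fewer than 2 markers"):
            simulate_population(small_sim_config(
                disease_hap_span=(3_000_000, 3_000_010)))

    def test_noise_rates_are_respected(self):
        cfg = small_sim_config(seed=3, genotyping_error_rate=0.05,
                               missing_rate=0.05, n_controls=500)
        gm, _, _, truth = simulate_population(cfg)
        frac_missing = (gm.haplotypes == MISSING).mean()
        assert 0.03 < frac_missing < 0.07
        changed = (gm.haplotypes != truth.clean_haplotypes) \
            & (gm.haplotypes != MISSING)
        assert 0.01 < changed.mean() < 0.05


class TestSequenceCohort:
    def test_causal_variant_structure(self, small_cohort, small_calls):
        cfg, *_ , truth = small_cohort
        causal = [v for v in small_calls.variants if v.vid == "causal_del"]
        assert len(causal) == 1
        v = causal[0]
        assert v.pos == cfg.causal_pos
        roles = sequence_sample_names(cfg)
        assert tuple(small_calls.genotypes_for(v, roles["case"])[0]) == (1, 1)
        assert tuple(sorted(
            small_calls.genotypes_for(v, roles["obligate_carrier"])[0])) == (0, 1)
        ctrl = small_calls.genotypes_for(v, roles["control"])
        assert (ctrl == 0).all()

    def test_filter_retains_causal(self, small_cohort, small_calls):
        cfg, *_ = small_cohort
        roles = sequence_sample_names(cfg)
        cands = recessive_compatibility_filter(
            small_calls, roles["case"], roles["obligate_carrier"],
            roles["control"])
        assert "causal_del" in {c.variant.vid for c in cands}

    def test_table1_style_survivor_count(self):
        # 9 compatible decoys, 8 panel-polymorphic -> 2 candidates survive
        cfg = small_sim_config(n_background_variants=9,
                               panel_polymorphic_fraction=8 / 9,
                               n_incompatible_variants=5)
        _, _, _, truth = simulate_population(cfg)
        calls = simulate_sequence_cohort(cfg, truth)
        roles = sequence_sample_names(cfg)
        cands = recessive_compatibility_filter(
            calls, roles["case"], roles["obligate_carrier"], roles["control"])
        assert len(cands) == 10
        panel = calls.subset_samples(roles["panel"])
        retained, excluded = cross_population_exclusion(cands, panel)
        assert len(retained) == 2 and len(excluded) == 8
        assert "causal_del" in {c.variant.vid for c in retained}

    def test_no_background_variants(self):
        cfg = small_sim_config(n_background_variants=0,
                               n_incompatible_variants=0)
        _, _, _, truth = simulate_population(cfg)
        calls = simulate_sequence_cohort(cfg, truth)
        assert len(calls) == 1
        roles = sequence_sample_names(cfg)
        cands = recessive_compatibility_filter(
            calls, roles["case"], roles["obligate_carrier"], roles["control"])
        assert [c.variant.vid for c in cands] == ["causal_del"]

    def test_positions_unique_and_in_span(self, small_cohort, small_calls):
        cfg, *_ = small_cohort
        positions = [v.pos for v in small_calls.variants]
        assert len(set(positions)) == len(positions)
        lo, hi = cfg.disease_hap_span
        assert all(lo <= p <= hi + 50 for p in positions)

    def test_determinism(self, small_cohort, small_calls):
        cfg, *_, truth = small_cohort
        again = simulate_sequence_cohort(cfg, truth)
        assert [v.key() for v in again.variants] == \
            [v.key() for v in small_calls.variants]
        for a, b in zip(again.variants, small_calls.variants):
            assert np.array_equal(a.gts, b.gts)


class TestGeneFixture:
    def test_wild_type_translation(self, default_fixture):
        fx = default_fixture
        assert len(fx.wild_protein) == 2239
        assert "*" not in fx.wild_protein
        assert fx.gene.n_exons == 31

    def test_mutant_protein_length(self, default_fixture):
        fx = default_fixture
        cds = fx.gene.cds(fx.genome)
        mutant = cds[:fx.deletion_tpos - 1] + cds[fx.deletion_tpos:]
        prot, stopped = _translate_to_stop(mutant)
        assert stopped
        assert len(prot) == 1494
        assert len(fx.wild_protein) - len(prot) == 745

    def test_splice_roundtrip(self, default_fixture):
        fx = default_fixture
        tx = fx.gene.splice(fx.genome)
        prot, stopped = _translate_to_stop(
            tx[fx.gene.cds_start - 1:fx.gene.cds_end])
        assert prot == fx.wild_protein

    def test_in_frame_intron_retention_extends_protein(self):
        spec = GeneFixtureSpec(deletion_codon=None,
                               retained_intron_stop_residue=None,
                               retained_intron_length=1140)
        fx = make_gene_fixture(spec)
        tx = fx.gene.splice(fx.genome, retain_intron=spec.retained_intron_index)
        prot, stopped = _translate_to_stop(tx)
        assert stopped
        assert len(prot) == 2239 + 1140 // 3

    def test_unsatisfiable_stop_offset_errors(self):
        with pytest.raises(ValueError, match="beyond the CDS"):
            make_gene_fixture(GeneFixtureSpec(deletion_codon=2230,
                                              shifted_frame_stop_offset=66))

    def test_deletion_in_declared_exon(self, default_fixture):
        fx = default_fixture
        gpos = fx.gene.transcript_to_genomic(fx.deletion_tpos)
        assert fx.gene.exon_of(gpos) == fx.spec.deletion_exon

    def test_deletion_vcf_is_left_aligned(self, default_fixture):
        pos, ref, alt = default_fixture.deletion_vcf
        assert len(ref) == 2 and len(alt) == 1
        assert ref[0] == alt
        g = default_fixture.genome
        assert g.fetch(pos, pos + 1) == ref

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="deletion_codon"):
            GeneFixtureSpec(deletion_codon=2239)
        with pytest.raises(ValueError, match="retained_intron_length"):
            GeneFixtureSpec(retained_intron_length=0)
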