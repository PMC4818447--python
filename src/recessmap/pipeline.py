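"""End-to-end orchestration: simulate → QC → scan → ROH → filter →
consequence → population stats, with a deterministic machine-readable
report plus per-stage plain-text artifacts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .autozygosity import RohConfig, detect_roh, haplotype_carrier_stats, \
    shared_case_segment
from .consequence import apply_variant_and_translate, insilico_rtpcr, \
    retained_intron_translate
from .core import ROLE_CASE, ROLE_CARRIER, ROLE_CONTROL, ROLE_PANEL, Variant
from .genoqc import QcConfig, apply_qc
from .hapscan import ScanConfig, scan_genome
from .popstats import frequency_trend, genotype_haplotype_crosstab, ld_r2
from .recfilter import (SPLICE_DISTANCE_THRESHOLD, candidates_to_frame,
                        classify_variant_region, cross_population_exclusion,
                        recessive_compatibility_filter)
from .simdata import (GeneFixtureSpec, SimulationConfig, make_gene_fixture,
                      sequence_sample_names, simulate_population,
                      simulate_sequence_cohort)

STAGES = ("simulate", "qc", "scan", "roh", "filter", "annotate", "stats")


@dataclass
class PipelineConfig:
    seed: int = 42
    outdir: str = "recessmap_run"
    verbosity: int = 1
    skip_stages: list = field(default_factory=list)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    roh: RohConfig = field(default_factory=RohConfig)
    fixture: GeneFixtureSpec = field(default_factory=GeneFixtureSpec)
    splice_distance_threshold: int = SPLICE_DISTANCE_THRESHOLD
    strict_missing: bool = True

    def __post_init__(self):
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in skip_stages: {sorted(unknown)}")
        for required in ("simulate", "filter"):
            if required in self.skip_stages:
                raise ValueError(f"stage {required!r} cannot be skipped")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        sections = {"simulation": SimulationConfig.from_dict,
                    "qc": lambda d: QcConfig(**d),
                    "scan": lambda d: ScanConfig(**d),
                    "roh": lambda d: RohConfig(**d)}
        for key, builder in sections.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = builder(kwargs[key])
        if "fixture" in kwargs and isinstance(kwargs["fixture"], dict):
            d = kwargs["fixture"]
            unknown = set(d) - set(GeneFixtureSpec.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown fixture config keys: {sorted(unknown)}")
            for tup in ("primer_exons",):
                if tup in d:
                    d[tup] = tuple(d[tup])
            kwargs["fixture"] = GeneFixtureSpec(**d)
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_end_to_end(config: PipelineConfig) -> dict:
    """Execute all stages on a synthetic cohort; return the run report.

    The report body is a pure function of (config, seed) — timings go to
    ``run.log`` only, so re-running an identical config reproduces
    ``report.json`` byte for byte.  ``report["success"]`` is False when
    the filter stage yields zero candidates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.monotonic()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.monotonic() - t0:8.2f}s] {msg}")
        if config.verbosity > 1:
            print(log_lines[-1])

    report: dict = {"seed": config.seed, "stages": {}, "success": True}
    sim = config.simulation
    sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})

    def stage(name):
        def wrap(fn):
            if name in config.skip_stages:
                log(f"stage {name}: skipped")
                report["stages"][name] = "skipped"
                return None
            log(f"stage {name}: start")
            try:
                result = fn()
            except Exception as exc:      # preserve partial outputs
                _write_log(out, log_lines + [f"stage {name}: FAILED: {exc}"])
                raise StageError(name, exc) from exc
            log(f"stage {name}: done")
            return result
        return wrap

    # ---- simulate ----------------------------------------------------------
    def _simulate():
        fspec0 = config.fixture
        probe = make_gene_fixture(fspec0)
        offset = sim.causal_pos - probe.deletion_vcf[0]
        fspec = GeneFixtureSpec(**{**asdict(fspec0),
                                   "contig": sim.causal_chrom,
                                   "contig_offset": offset})
        fixture = make_gene_fixture(fspec)
        gm, mmap, phenos, truth = simulate_population(sim)
        dpos, dref, dalt = fixture.deletion_vcf
        calls = simulate_sequence_cohort(sim, truth, causal_ref=dref,
                                         causal_alt=dalt,
                                         causal_id="rs_causal_del")
        io.write_haplotypes(gm, out / "haplotypes.tsv")
        io.write_marker_map(mmap, out / "markers.tsv")
        io.write_phenotypes(phenos, out / "phenotypes.tsv")
        io.write_json(truth.to_json(), out / "truth.json")
        io.write_vcf(calls, out / "cohort.vcf")
        io.write_gff3(fixture.gene, out / "gene.gff3")
        io.write_fasta(fixture.genome, out / "gene.fasta")
        report["stages"]["simulate"] = {
            "n_individuals": gm.n_individuals, "n_markers": gm.n_markers,
            "n_sequence_variants": len(calls),
            "n_array_carriers": len(truth.carrier_ids),
            "causal": {"chrom": truth.causal_chrom, "pos": dpos,
                       "ref": dref, "alt": dalt},
        }
        return fixture, gm, mmap, phenos, truth, calls

    fixture, gm, mmap, phenos, truth, calls = stage("simulate")(_simulate)

    # ---- qc ----------------------------------------------------------------
    def _qc():
        fgm, fmap, qreport = apply_qc(gm, mmap, config.qc, phenos)
        qreport.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        report["stages"]["qc"] = {
            "individuals_removed": int((qreport["entity_type"] == "individual").sum()),
            "markers_removed": int((qreport["entity_type"] == "marker").sum()),
            "n_markers_after": fgm.n_markers,
        }
        return fgm, fmap

    qc_result = stage("qc")(_qc)
    fgm, fmap = qc_result if qc_result is not None else (gm, mmap)

    # ---- scan --------------------------------------------------------------
    def _scan():
        result = scan_genome(fgm, fmap, phenos, config.scan)
        result.to_frame().to_csv(out / "scan.tsv", sep="\t", index=False)
        io.write_bed([(c, s, e, "significant_window")
                      for c, s, e in result.significant_windows()],
                     out / "significant_windows.bed")
        top = result.results[0]
        report["stages"]["scan"] = {
            "n_tests": result.n_tests,
            "bonferroni_threshold": result.threshold,
            "n_significant": sum(r.significant for r in result.results),
            "top_window": {"chrom": top.chrom, "start_bp": top.start_bp,
                           "end_bp": top.end_bp, "log10_p": top.log10_p},
        }
        return result

    scan_result = stage("scan")(_scan)

    # ---- roh ---------------------------------------------------------------
    def _roh():
        rohs = {case: detect_roh(fgm, case, fmap, config.roh)
                for case in phenos.case_ids}
        hint = None
        if scan_result is not None:
            top = scan_result.results[0]
            hint = (top.chrom, 0, 10**10)   # restrict to the top chromosome
        shared = shared_case_segment(rohs, region_hint=hint)
        bed = [(s.chrom, s.start_bp, s.end_bp, s.individual)
               for segs in rohs.values() for s in segs]
        io.write_bed(bed, out / "roh.bed")
        if not shared.empty:
            io.write_bed([(shared.chrom, *shared.interval, "shared_segment")],
                         out / "shared_segment.bed")
        report["stages"]["roh"] = {
            "n_cases": shared.n_cases,
            "shared_segment": (None if shared.empty else
                               {"chrom": shared.chrom,
                                "start_bp": shared.interval[0],
                                "end_bp": shared.interval[1]}),
        }
        return shared

    shared = stage("roh")(_roh)

    # ---- filter ------------------------------------------------------------
    def _filter():
        roles = sequence_sample_names(sim)
        study = calls.subset_samples(roles[ROLE_CASE] + roles[ROLE_CARRIER]
                                     + roles[ROLE_CONTROL])
        panel = (calls.subset_samples(roles[ROLE_PANEL])
                 if roles[ROLE_PANEL] else None)
        candidates = recessive_compatibility_filter(
            study, roles[ROLE_CASE], roles[ROLE_CARRIER], roles[ROLE_CONTROL],
            strict_missing=config.strict_missing)
        retained, excluded = cross_population_exclusion(candidates, panel)
        for cand in retained:
            cls = classify_variant_region(cand.variant, fixture.gene,
                                          config.splice_distance_threshold)
            cand.region, cand.gene_id = cls.region, cls.gene_id
            cand.splice_distance, cand.priority = cls.splice_distance, cls.priority
        candidates_to_frame(candidates).to_csv(out / "candidates.tsv",
                                               sep="\t", index=False)
        candidates_to_frame(retained).to_csv(out / "candidates_retained.tsv",
                                             sep="\t", index=False)
        report["stages"]["filter"] = {
            "n_compatible": len(candidates),
            "n_excluded_by_panel": len(excluded),
            "n_retained": len(retained),
            "retained": [{"chrom": c.variant.chrom, "pos": c.variant.pos,
                          "id": c.variant.vid, "region": c.region,
                          "priority": c.priority} for c in retained],
        }
        if not candidates:
            report["success"] = False
        return retained

    retained = stage("filter")(_filter)

    # ---- annotate ----------------------------------------------------------
    def _annotate():
        records = []
        exonic = [c for c in retained if c.region == "exonic"]
        for cand in exonic:
            rec = apply_variant_and_translate(fixture.gene, fixture.genome,
                                              cand.variant)
            records.append((cand.variant.vid, rec))
        rt = None
        if exonic:
            causal = exonic[0].variant
            ri = fixture.spec.retained_intron_index
            rec_ri, retained_tx = retained_intron_translate(
                fixture.gene, fixture.genome, ri, upstream_variant=causal)
            wild_tx = fixture.gene.splice(fixture.genome)
            amps = insilico_rtpcr([wild_tx, retained_tx],
                                  fixture.spec.forward_primer,
                                  fixture.spec.reverse_primer)
            rt = {"intron_index": ri,
                  "stop_residue": rec_ri.stop_residue,
                  "wild_amplicons": amps[0], "mutant_amplicons": amps[1]}
            records.append((f"retained_intron_{ri}", rec_ri))
        frame = pd.DataFrame([{
            "variant": vid, "transcript": r.transcript_id,
            "cdna": r.cdna_description, "protein": r.protein_description,
            "first_altered": r.first_altered_residue,
            "stop_residue": r.stop_residue, "mutant_length": r.mutant_length,
            "residues_removed": r.residues_removed,
            "truncation_fraction": r.truncation_fraction,
            "runoff": r.runoff} for vid, r in records])
        frame.to_csv(out / "consequences.tsv", sep="\t", index=False)
        report["stages"]["annotate"] = {
            "records": frame.drop(columns=[]).to_dict(orient="records"),
            "rtpcr": rt,
        }
        return records

    stage("annotate")(_annotate)

    # ---- stats -------------------------------------------------------------
    def _stats():
        carrier = haplotype_carrier_stats(
            gm, truth.span_marker_indices, truth.founder_haplotype,
            phenos=phenos)
        founder_match = (
            gm.haplotypes[:, truth.span_marker_indices]
            == truth.founder_haplotype).all(axis=1).astype(np.int8)
        r2 = ld_r2(founder_match, truth.causal_alleles)
        status = np.array(["non-carrier"] * gm.n_individuals, dtype=object)
        per_ind = founder_match[0::2] + founder_match[1::2]
        status[per_ind == 1] = "carrier"
        status[per_ind == 2] = "homozygous"
        s = pd.Series(status, index=pd.Index(gm.individuals))
        meta = phenos.table.set_index("individual")
        trend = frequency_trend(s, meta, by=["birth_year"])
        pd.DataFrame([{"group": "/".join(map(str, t.group)),
                       "n": t.cohort_size, "copies": t.carrier_copies,
                       "frequency": t.frequency} for t in trend]
                     ).to_csv(out / "trend.tsv", sep="\t", index=False)
        report["stages"]["stats"] = {
            "control_carrier_frequency": carrier.frequency,
            "control_het_carriers": carrier.n_het,
            "control_hom_carriers": carrier.n_hom,
            "ld_r2_variant_vs_haplotype": (None if np.isnan(r2) else r2),
            "n_trend_groups": len(trend),
        }
        return carrier

    stage("stats")(_stats)

    io.write_json(report, out / "report.json")
    _write_log(out, log_lines)
    return report


def _write_log(outdir: Path, lines: list[str]) -> None:
    (Path(outdir) / "run.log").write_text("\n".join(lines) + "\n")
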