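"""Synthetic cohorts, variant calls and an engineered disease-gene fixture.

The simulator plants a founder haplotype in a case/control array cohort
(affected ⇔ homozygous for the planted haplotype), emits a matching
sequence-level call set (one causal 1-bp deletion, compatible decoys,
incompatible background, a multi-breed exclusion panel) and builds a
fully engineered gene model whose wild-type, frameshifted and
intron-retained translations hit exact, pre-declared residue positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

from .core import (MISSING, GeneModel, GenomeSequence, GenotypeMatrix,
                   MarkerMap, PhenotypeTable, Variant, VariantCallSet,
                   ROLE_CASE, ROLE_CARRIER, ROLE_CONTROL, ROLE_PANEL,
                   STATUS_AFFECTED, STATUS_UNAFFECTED, STATUS_UNKNOWN,
                   revcomp)

import pandas as pd

SAMPLE_CASE_SEQ = "DW_hom"
SAMPLE_CARRIER_SEQ = "DW_het"


# ------------------------------------------------------------ configuration


@dataclass
class SimulationConfig:
    """Knobs for the array + sequence cohort simulator."""

    seed: int = 1
    n_cases: int = 27
    n_controls: int = 2000
    n_markers_per_chrom: int = 400
    n_chromosomes: int = 3
    causal_chrom: str = "3"
    causal_pos: int = 15_079_217
    disease_hap_span: tuple[int, int] = (14_000_000, 16_800_000)
    carrier_hap_freq: float = 0.004
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.001
    n_background_variants: int = 9
    n_panel_individuals: int = 40
    panel_polymorphic_fraction: float = 1.0
    n_incompatible_variants: int = 30
    n_sequenced_controls: int = 60
    marker_spacing: int = 50_000

    def __post_init__(self):
        props = {
            "carrier_hap_freq": self.carrier_hap_freq,
            "genotyping_error_rate": self.genotyping_error_rate,
            "missing_rate": self.missing_rate,
            "panel_polymorphic_fraction": self.panel_polymorphic_fraction,
        }
        for name, p in props.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        lo, hi = self.background_maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("background_maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        s, e = self.disease_hap_span
        if not s <= self.causal_pos <= e:
            raise ValueError("causal_pos must lie inside disease_hap_span")
        self.causal_chrom = str(self.causal_chrom)
        if self.causal_chrom not in self.chromosome_names:
            raise ValueError(
                f"causal_chrom {self.causal_chrom!r} not among simulated "
                f"chromosomes {self.chromosome_names}")

    @property
    def chromosome_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chromosome_length(self) -> int:
        return self.n_markers_per_chrom * self.marker_spacing + self.marker_spacing

    def to_dict(self) -> dict:
        d = asdict(self)
        d["disease_hap_span"] = list(self.disease_hap_span)
        d["background_maf_range"] = list(self.background_maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("disease_hap_span", "background_maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth captured before genotyping error/missingness injection."""

    causal_chrom: str
    causal_pos: int
    span: tuple[int, int]
    marker_span_bp: tuple[int, int]
    span_marker_indices: np.ndarray
    founder_haplotype: np.ndarray
    case_ids: list[str]
    carrier_ids: list[str]
    clean_haplotypes: np.ndarray
    causal_alleles_clean: np.ndarray
    causal_alleles: np.ndarray

    def to_json(self) -> dict:
        return {
            "causal_chrom": self.causal_chrom,
            "causal_pos": int(self.causal_pos),
            "span": [int(x) for x in self.span],
            "marker_span_bp": [int(x) for x in self.marker_span_bp],
            "span_marker_indices": [int(i) for i in self.span_marker_indices],
            "founder_haplotype": "".join(map(str, self.founder_haplotype)),
            "case_ids": self.case_ids,
            "carrier_ids": self.carrier_ids,
        }


# ------------------------------------------------------------ array cohort


def simulate_population(config: SimulationConfig
                        ) -> tuple[GenotypeMatrix, MarkerMap, PhenotypeTable,
                                   TruthRecord]:
    """Simulate a phased case/control array cohort with a planted founder haplotype.

    Every case is homozygous for the founder haplotype across the disease
    span; each control haplotype copies it independently with probability
    ``carrier_hap_freq`` (capped at one copy per control so that no
    control is affected).  Background markers are drawn independently per
    locus.  Genotyping error and missingness are injected after the truth
    phase is captured.
    """
    rng = np.random.default_rng(config.seed)
    m_per = config.n_markers_per_chrom
    spacing = config.marker_spacing

    chroms, positions, names = [], [], []
    for chrom in config.chromosome_names:
        base = (np.arange(1, m_per + 1, dtype=np.int64)) * spacing
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=m_per)
        pos = base + jitter           # jitter < spacing/2 keeps order strict
        chroms.extend([chrom] * m_per)
        positions.append(pos)
        names.extend(f"chr{chrom}_m{i:05d}" for i in range(m_per))
    positions = np.concatenate(positions)
    m_total = len(positions)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, m_total)
    alt_idx = (ref_idx + rng.integers(1, 4, m_total)) % 4
    mmap = MarkerMap(pd.DataFrame({
        "marker": names, "chrom": chroms, "pos": positions,
        "ref": bases[ref_idx], "alt": bases[alt_idx]}))

    span_lo, span_hi = config.disease_hap_span
    on_chrom = mmap.chrom_indices(config.causal_chrom)
    chrom_pos = positions[on_chrom]
    span_idx = on_chrom[(chrom_pos >= span_lo) & (chrom_pos <= span_hi)]
    if span_idx.size < 2:
        raise ValueError(
            "disease_hap_span contains fewer than 2 markers; increase "
            "n_markers_per_chrom or shrink the span")

    n = config.n_cases + config.n_controls
    maf_lo, maf_hi = config.background_maf_range
    freqs = rng.uniform(maf_lo, maf_hi, m_total)
    haps = (rng.random((2 * n, m_total)) < freqs).astype(np.int8)

    founder = (rng.random(span_idx.size) < 0.5).astype(np.int8)
    case_rows = np.arange(2 * config.n_cases)
    haps[np.ix_(case_rows, span_idx)] = founder

    ctrl_copy = rng.random(2 * config.n_controls) < config.carrier_hap_freq
    both = ctrl_copy[0::2] & ctrl_copy[1::2]
    ctrl_copy[1::2][both] = False     # controls carry at most one copy
    ctrl_rows = 2 * config.n_cases + np.flatnonzero(ctrl_copy)
    haps[np.ix_(ctrl_rows, span_idx)] = founder
    if ctrl_copy.sum() == 0 and config.carrier_hap_freq > 0:
        warnings.warn("carrier_hap_freq so low that zero carrier controls "
                      "were drawn", UserWarning)

    case_ids = [f"CASE_{i + 1:04d}" for i in range(config.n_cases)]
    ctrl_ids = [f"CTRL_{i + 1:05d}" for i in range(config.n_controls)]
    individuals = case_ids + ctrl_ids
    carrier_ids = [ctrl_ids[i] for i in
                   np.flatnonzero(ctrl_copy[0::2] | ctrl_copy[1::2])]

    causal_clean = np.zeros(2 * n, dtype=np.int8)
    causal_clean[case_rows] = 1
    causal_clean[ctrl_rows] = 1

    clean = haps.copy()

    err = rng.random((n, m_total)) < config.genotyping_error_rate
    which = rng.integers(0, 2, (n, m_total))
    ii, jj = np.nonzero(err)
    rows = 2 * ii + which[ii, jj]
    haps[rows, jj] = 1 - haps[rows, jj]

    miss = rng.random((n, m_total)) < config.missing_rate
    ii, jj = np.nonzero(miss)
    haps[2 * ii, jj] = MISSING
    haps[2 * ii + 1, jj] = MISSING

    causal_flip = rng.random(2 * n) < config.genotyping_error_rate
    causal_obs = np.where(causal_flip, 1 - causal_clean, causal_clean)

    phenos = PhenotypeTable(pd.DataFrame({
        "individual": individuals,
        "status": [STATUS_AFFECTED] * config.n_cases
                  + [STATUS_UNAFFECTED] * config.n_controls,
        "role": [ROLE_CASE] * config.n_cases + [ROLE_CONTROL] * config.n_controls,
        "breed": "FV",
        "sex": rng.choice(["M", "F"], size=n),
        "birth_year": rng.integers(2000, 2013, size=n),
    }))

    truth = TruthRecord(
        causal_chrom=config.causal_chrom,
        causal_pos=config.causal_pos,
        span=(span_lo, span_hi),
        marker_span_bp=(int(positions[span_idx[0]]), int(positions[span_idx[-1]])),
        span_marker_indices=span_idx,
        founder_haplotype=founder,
        case_ids=case_ids,
        carrier_ids=carrier_ids,
        clean_haplotypes=clean,
        causal_alleles_clean=causal_clean,
        causal_alleles=causal_obs,
    )
    return GenotypeMatrix(individuals, haps, phased=True), mmap, phenos, truth


# ---------------------------------------------------------- sequence cohort


def sequence_sample_names(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        ROLE_CASE: [SAMPLE_CASE_SEQ],
        ROLE_CARRIER: [SAMPLE_CARRIER_SEQ],
        ROLE_CONTROL: [f"SEQCTRL_{i + 1:04d}"
                       for i in range(config.n_sequenced_controls)],
        ROLE_PANEL: [f"PANEL_{i + 1:04d}"
                     for i in range(config.n_panel_individuals)],
    }


def sequence_phenotypes(config: SimulationConfig) -> PhenotypeTable:
    roles = sequence_sample_names(config)
    rows = []
    status = {ROLE_CASE: STATUS_AFFECTED, ROLE_CARRIER: STATUS_UNAFFECTED,
              ROLE_CONTROL: STATUS_UNAFFECTED, ROLE_PANEL: STATUS_UNKNOWN}
    for role, ids in roles.items():
        for s in ids:
            rows.append({"individual": s, "status": status[role], "role": role,
                         "breed": "FV" if role != ROLE_PANEL else "other",
                         "sex": pd.NA, "birth_year": pd.NA})
    return PhenotypeTable(pd.DataFrame(rows))


def simulate_sequence_cohort(config: SimulationConfig, truth: TruthRecord,
                             causal_ref: str = "AC", causal_alt: str = "A",
                             causal_id: str = "causal_del") -> VariantCallSet:
    """Variant calls for the mapped interval: one case, one obligate carrier,
    sequenced controls and a multi-breed exclusion panel.

    Exactly one causal 1-bp deletion is planted (hom-alt case, het carrier,
    hom-ref controls).  ``n_background_variants`` recessive-compatible decoys
    are added, of which ``round(panel_polymorphic_fraction * n)`` segregate in
    the panel; ``n_incompatible_variants`` further variants each violate at
    least one compatibility condition.
    """
    rng = np.random.default_rng(config.seed + 104729)   # independent stream
    roles = sequence_sample_names(config)
    samples = (roles[ROLE_CASE] + roles[ROLE_CARRIER]
               + roles[ROLE_CONTROL] + roles[ROLE_PANEL])
    n_s = len(samples)
    i_case, i_carrier = 0, 1
    ctrl_sl = slice(2, 2 + config.n_sequenced_controls)
    panel_sl = slice(2 + config.n_sequenced_controls, n_s)
    n_panel = config.n_panel_individuals

    span_lo, span_hi = truth.span
    used: set[int] = set(range(config.causal_pos - 1, config.causal_pos + 3))

    def fresh_position() -> int:
        pos = int(rng.integers(span_lo, span_hi + 1))
        while pos in used:
            pos += 1              # deterministic collision resolution
        used.update(range(pos - 1, pos + 2))
        return pos

    bases = "ACGT"

    def snv_alleles() -> tuple[str, str]:
        r = bases[rng.integers(0, 4)]
        a = bases[(bases.index(r) + int(rng.integers(1, 4))) % 4]
        return r, a

    def base_gts() -> np.ndarray:
        return np.zeros((n_s, 2), dtype=np.int8)

    variants: list[Variant] = []

    causal_gts = base_gts()
    causal_gts[i_case] = (1, 1)
    causal_gts[i_carrier] = (0, 1)
    variants.append(Variant(truth.causal_chrom, config.causal_pos,
                            causal_ref, causal_alt, causal_id, causal_gts))

    n_bg = config.n_background_variants
    n_poly = int(round(config.panel_polymorphic_fraction * n_bg))
    poly_flags = np.zeros(n_bg, dtype=bool)
    poly_flags[rng.permutation(n_bg)[:n_poly]] = True
    for k in range(n_bg):
        pos = fresh_position()
        if k % 4 == 3:                       # some decoys are indels
            ref, alt = snv_alleles()
            ref = ref + alt
        else:
            ref, alt = snv_alleles()
        gts = base_gts()
        gts[i_case] = (1, 1)
        gts[i_carrier] = (0, 1)
        if poly_flags[k] and n_panel > 0:
            n_hit = int(rng.integers(1, min(4, n_panel) + 1))
            hit = rng.choice(n_panel, size=n_hit, replace=False)
            for h in hit:
                gts[panel_sl][h] = (0, 1)
        variants.append(Variant(truth.causal_chrom, pos, ref, alt,
                                f"decoy_{k + 1:03d}", gts))

    n_ctrl = config.n_sequenced_controls
    for k in range(config.n_incompatible_variants):
        pos = fresh_position()
        ref, alt = snv_alleles()
        gts = base_gts()
        mode = k % 3
        if mode == 0:                        # case not hom-alt
            gts[i_case] = (0, 1)
            gts[i_carrier] = (0, 1)
        elif mode == 1:                      # carrier not het
            gts[i_case] = (1, 1)
            gts[i_carrier] = (0, 0)
        else:                                # a control carries the allele
            gts[i_case] = (1, 1)
            gts[i_carrier] = (0, 1)
            if n_ctrl > 0:
                gts[ctrl_sl][int(rng.integers(0, n_ctrl))] = (0, 1)
            else:
                gts[i_carrier] = (1, 1)
        variants.append(Variant(truth.causal_chrom, pos, ref, alt,
                                f"bg_{k + 1:03d}", gts))

    return VariantCallSet(samples, variants)


# ------------------------------------------------------------- gene fixture


@dataclass
class GeneFixtureSpec:
    """Declarative constraints for the engineered disease gene."""

    n_exons: int = 31
    protein_length: int = 2239
    deletion_exon: int = 20
    deletion_codon: int = 1430            # first altered residue
    shifted_frame_stop_offset: int = 66   # fsTer offset (first changed residue = 1)
    retained_intron_index: int = 20
    retained_intron_stop_residue: int | None = 1492
    retained_intron_length: int = 1140
    primer_exons: tuple[int, int] = (20, 21)
    spliced_amplicon_length: int = 348
    forward_primer: str = "GAGTCAAGCAGCTCAAACCC"
    reverse_primer: str = "AGCCAAGTCAGTTTCTCCATT"
    contig: str = "3"
    contig_offset: int = 0
    flank: int = 2000
    default_intron_length: int = 300
    long_intron_index: int | None = 5
    long_intron_length: int = 10_000
    gene_id: str = "FIXGENE"
    transcript_id: str = "FIXGENE.t1"

    def __post_init__(self):
        if self.deletion_codon is not None and \
                self.deletion_codon >= self.protein_length:
            raise ValueError("deletion_codon must be < protein_length")
        if self.retained_intron_length <= 0:
            raise ValueError("retained_intron_length must be > 0")
        if not 1 <= self.retained_intron_index < self.n_exons:
            raise ValueError("retained_intron_index out of range")
        if len(self.forward_primer) < 15 or len(self.reverse_primer) < 15:
            raise ValueError("primers must be at least 15 nt")


@dataclass
class GeneFixture:
    """The engineered gene plus everything tests and stages need from it."""

    spec: GeneFixtureSpec
    gene: GeneModel
    genome: GenomeSequence
    wild_protein: str
    deletion_vcf: tuple[int, str, str] | None   # (pos, ref, alt) left-aligned
    deletion_tpos: int | None                   # transcript coord of deleted base

    def __iter__(self):
        return iter((self.gene, self.genome))


def _gc_fill(n: int) -> str:
    if n < 0:
        raise ValueError("negative fill length")
    return ("GC" * (n // 2 + 1))[:n]


def _translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate from base 1; return (protein before first stop, stop_found)."""
    usable = len(seq) - len(seq) % 3
    prot = str(Seq(seq[:usable]).translate())
    if "*" in prot:
        return prot[:prot.index("*")], True
    return prot, False


def make_gene_fixture(spec: GeneFixtureSpec | None = None) -> GeneFixture:
    """Construct a gene satisfying the declared frameshift / intron-retention /
    amplicon constraints exactly, verifying each one at build time.

    The CDS backbone is a ``GCA`` repeat (stop-free in every reading frame);
    specific codons are overwritten to realize the requested deletion,
    shifted-frame stop, retained-intron stop and primer sites, and the
    assembled sequences are re-translated to prove every constraint before
    the fixture is returned.
    """
    spec = spec or GeneFixtureSpec()
    P = spec.protein_length
    T = 3 * (P + 1)                       # CDS including terminal stop codon
    cds = list("GCA" * (P + 1))

    def set_codon(i: int, codon: str) -> None:
        cds[3 * i - 3:3 * i] = list(codon)

    set_codon(P + 1, "TAA")

    D = spec.deletion_codon
    if D is not None:
        if D < 2:
            raise ValueError("deletion_codon must be >= 2 (needs an upstream codon)")
        M = D + spec.shifted_frame_stop_offset - 1
        if M + 1 > P:
            raise ValueError(
                "shifted_frame_stop_offset places the new stop beyond the CDS")
        # codon D-1 = Pro(CCC); deleting its third base leaves CCG (still Pro)
        # and shifts codon D from Glu(GAA) to Lys(AA + G of the GCA filler).
        set_codon(D - 1, "CCC")
        set_codon(D, "GAA")
        # plant TAA straddling codons M / M+1 in the shifted (+1) frame
        set_codon(M, "CTA")
        set_codon(M + 1, "ACA")
        del_t = 3 * (D - 1)               # transcript coord of deleted base
    else:
        M = None
        del_t = None

    # --- exon layout in transcript coordinates -----------------------------
    R = spec.retained_intron_index
    S = spec.retained_intron_stop_residue
    shift = 1 if (D is not None) else 0
    if S is not None:
        E = 3 * S - 6 + shift             # last transcript base of exon R
        if not (S - 1) * 3 < T:
            raise ValueError("retained_intron_stop_residue beyond the transcript")
    else:
        E = 3 * min(P - 50, max(R + 1, (2 * P) // 3))
    if D is not None and E <= del_t:
        raise ValueError("retained intron boundary must lie downstream of the deletion")
    if E >= T - (spec.n_exons - R):
        raise ValueError("retained intron boundary leaves no room for later exons")

    if D is not None:
        b_r = 3 * D - 3 - 150
    else:
        b_r = E - 300
    b_r = max(b_r, R)                     # at least 1 bp per earlier exon
    if b_r >= E:
        raise ValueError("exon hosting the deletion would be empty")

    A = spec.spliced_amplicon_length
    fwd = spec.forward_primer.upper()
    rev_rc = revcomp(spec.reverse_primer.upper())

    bounds: list[tuple[int, int]] = []
    cuts = np.linspace(0, b_r - 1, R, dtype=int)
    for i in range(R - 1):
        bounds.append((int(cuts[i]) + 1, int(cuts[i + 1])))
    bounds.append((b_r, E))
    er1_end = E + A - 101 + 30
    if er1_end >= T - (spec.n_exons - R - 1):
        raise ValueError("amplicon does not fit before the remaining exons")
    bounds.append((E + 1, er1_end))
    n_rest = spec.n_exons - R - 1
    cuts = np.linspace(er1_end, T, n_rest + 1, dtype=int)
    for i in range(n_rest):
        bounds.append((int(cuts[i]) + 1, int(cuts[i + 1])))
    if any(s > e for s, e in bounds):
        raise ValueError("exon layout produced an empty exon; adjust spec")

    # --- retained intron sequence -----------------------------------------
    I = spec.retained_intron_length
    if S is not None:
        if I < 8:
            raise ValueError("retained_intron_length too short to host a stop")
        intron_r = "GTATAA" + _gc_fill(I - 8) + "AG"
    else:
        if I < 4:
            raise ValueError("retained_intron_length must be >= 4")
        intron_r = "GT" + _gc_fill(I - 4) + "AG"

    def intron_seq(i: int) -> str:
        if i == R:
            return intron_r
        if spec.long_intron_index is not None and i == spec.long_intron_index:
            return "GT" + _gc_fill(spec.long_intron_length - 4) + "AG"
        return "GT" + _gc_fill(spec.default_intron_length - 4) + "AG"

    # --- place primers and verify everything -------------------------------
    planted: set[int] = {T - 2, T - 1, T}
    if D is not None:
        planted |= set(range(3 * D - 6, 3 * D + 1))
        planted |= set(range(3 * M - 3, 3 * (M + 1) + 1))

    def verify(seq: list[str]) -> str | None:
        """Return an error message or None if all constraints hold."""
        s = "".join(seq)
        wt, stopped = _translate_to_stop(s)
        if not stopped or len(wt) != P:
            return (f"wild-type translation length {len(wt)} != {P} "
                    f"(internal stop or missing terminator)")
        if D is not None:
            mut = s[:del_t - 1] + s[del_t:]
            mp, stopped = _translate_to_stop(mut)
            if not stopped or len(mp) != M - 1:
                return (f"frameshift translation stops at {len(mp) + 1}, "
                        f"required {M}")
            if mp[:D - 1] != wt[:D - 1] or mp[D - 1] == wt[D - 1]:
                return "frameshift does not diverge exactly at deletion_codon"
            exonic = mut[:E - shift]
        else:
            exonic = s[:E]
        retained = exonic + intron_r + s[E:]
        rp, stopped = _translate_to_stop(retained)
        if S is not None and (not stopped or len(rp) != S - 1):
            return (f"retained-intron translation stops at {len(rp) + 1}, "
                    f"required {S}")
        if S is None and D is None and I % 3 == 0:
            # stop-free in-frame intron must simply extend the protein
            if not stopped or len(rp) != P + I // 3:
                return "in-frame retained intron does not extend the protein"
        return None

    placed = None
    if A is not None and fwd:
        lo = max(b_r, E - 200)
        for p_f in range(E - 118, lo - 1, -1):
            if p_f + len(fwd) - 1 > E:
                continue
            p_r = p_f + A - len(rev_rc)
            if p_r <= E or p_f + A - 1 > er1_end:
                continue
            covered = set(range(p_f, p_f + len(fwd))) | set(range(p_r, p_f + A))
            if covered & planted:
                continue
            trial = list(cds)
            trial[p_f - 1:p_f - 1 + len(fwd)] = list(fwd)
            trial[p_r - 1:p_r - 1 + len(rev_rc)] = list(rev_rc)
            if verify(trial) is None:
                cds = trial
                placed = (p_f, p_r)
                break
        if placed is None:
            raise ValueError("could not place primers without violating a "
                             "translation constraint (spliced_amplicon_length "
                             "or primer_exons unsatisfiable)")

    err = verify(cds)
    if err:
        raise ValueError(f"gene fixture constraint violated: {err}")

    cds_str = "".join(cds)

    # --- assemble genome ----------------------------------------------------
    flank5 = _gc_fill(spec.flank)
    flank3 = _gc_fill(spec.flank)
    pieces = [flank5]
    genomic_exons: list[tuple[int, int]] = []
    cursor = spec.flank
    for i, (ts, te) in enumerate(bounds, start=1):
        pieces.append(cds_str[ts - 1:te])
        genomic_exons.append((spec.contig_offset + cursor + 1,
                              spec.contig_offset + cursor + (te - ts + 1)))
        cursor += te - ts + 1
        if i < spec.n_exons:
            iseq = intron_seq(i)
            pieces.append(iseq)
            cursor += len(iseq)
    pieces.append(flank3)
    genome = GenomeSequence(spec.contig, "".join(pieces),
                            offset=spec.contig_offset)

    gene = GeneModel(spec.gene_id, spec.transcript_id, spec.contig, "+",
                     genomic_exons, cds_start=1, cds_end=T)

    if D is not None and \
            gene.exon_of(gene.transcript_to_genomic(del_t)) != spec.deletion_exon:
        raise ValueError("deletion does not fall in the requested exon")
    pe_f, pe_r = spec.primer_exons
    if placed is not None:
        g_f = gene.transcript_to_genomic(placed[0])
        g_r = gene.transcript_to_genomic(placed[1])
        if gene.exon_of(g_f) != pe_f or gene.exon_of(g_r) != pe_r:
            raise ValueError("primer_exons incompatible with derived exon layout")

    deletion_vcf = None
    if D is not None:
        run_start = del_t
        while run_start > 1 and cds_str[run_start - 2] == cds_str[del_t - 1]:
            run_start -= 1
        anchor = run_start - 1
        g_anchor = gene.transcript_to_genomic(anchor)
        ref = cds_str[anchor - 1] + cds_str[run_start - 1]
        alt = cds_str[anchor - 1]
        deletion_vcf = (g_anchor, ref, alt)

    wt, _ = _translate_to_stop(cds_str)
    return GeneFixture(spec=spec, gene=gene, genome=genome, wild_protein=wt,
                       deletion_vcf=deletion_vcf, deletion_tpos=del_t)
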