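# recessmap

A tested, reusable pipeline for mapping recessive defects from SNP-array
and sequence data: array quality control, sliding-window haplotype
association with log-space Fisher exact tests and Bonferroni control,
autozygosity (ROH) mapping of the case-shared segment,
recessive-compatibility variant filtering with multi-breed panel
exclusion and genic region classification, coding-consequence prediction
(frameshift translation, HGVS naming, intron-retention transcripts,
in-silico RT-PCR), and supporting population statistics (LD r²,
genotype–haplotype concordance, carrier-frequency trends,
Hardy–Weinberg expectations).

Every stage is exercised end to end on synthetic cohorts generated by
the package itself: the simulator plants a founder haplotype
(affected ⇔ homozygous), emits matching sequence calls with one causal
1-bp deletion plus decoys and an exclusion panel, and engineers a
31-exon gene fixture whose wild-type, frameshifted and intron-retained
translations hit exact pre-declared residue positions.

## Layout

| module | role |
| --- | --- |
| `recessmap.simdata` | cohort/sequence simulation and the engineered gene fixture |
| `recessmap.genoqc` | MAF / exact-HWE / call-rate filters |
| `recessmap.hapscan` | sliding-window haplotype association scan |
| `recessmap.autozygosity` | ROH detection and the case-shared segment |
| `recessmap.recfilter` | recessive-compatibility + panel-exclusion filtering |
| `recessmap.consequence` | frameshift / intron-retention translation, in-silico PCR |
| `recessmap.popstats` | LD r², cross-tabs, frequency trends, HWE expectations |
| `recessmap.pipeline` / `recessmap.cli` | end-to-end orchestration and the CLI |
| `recessmap.datasets` | published candidate-variant and validation-genotype tables |

## CLI

```bash
recessmap run --seed 42 --out run/              # full synthetic pipeline
recessmap simulate --seed 1 --out sim/
recessmap qc   --geno sim/haplotypes.tsv --map sim/markers.tsv \
               --pheno sim/phenotypes.tsv --out qc/
recessmap scan --haps qc/haplotypes.tsv --map qc/markers.tsv \
               --pheno sim/phenotypes.tsv --out scan/
recessmap roh  --geno sim/haplotypes.tsv --map sim/markers.tsv \
               --pheno sim/phenotypes.tsv --out roh/
recessmap filter --vcf sim/cohort.vcf --roles roles.tsv \
               --gff sim/gene.gff3 --out filt/
recessmap annotate --gff sim/gene.gff3 --fasta sim/gene.fasta \
               --vcf sim/cohort.vcf --retain-intron 20 \
               --primers GAGTCAAGCAGCTCAAACCC,AGCCAAGTCAGTTTCTCCATT --out ann/
```

`recessmap run` accepts a YAML config with `simulation`, `qc`, `scan`,
`roh` and `fixture` sections (unknown keys are rejected); the report
body in `report.json` is a pure function of config and seed.

All interchange formats are plain text: TSV haplotype matrix / marker
map / phenotypes, VCF v4.2, GFF3 + FASTA, BED, JSON.

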