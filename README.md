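# asdtriage

Rule-based variant triage for **essential autism spectrum disorder (ASD)**
trio cohorts combining whole-exome sequencing (WES) and array-CGH.

Essential ASD denotes autism without dysmorphism, epilepsy, intellectual
disability or other syndromic features. In such cohorts the diagnostic signal
is carried by rare sequence variants in neurodevelopmental genes and by copy
number variants (CNVs), and clinical laboratories triage them with explicit,
auditable rules rather than black-box scores. `asdtriage` implements that
triage end to end for trio data:

- **Sequence-variant cascade** — coverage/GQ/frequency QC (coverage ≥ 10×,
  GQ ≥ 15, gnomAD MAF < 5 %), trio inheritance assignment, compound-heterozygote
  pairing by parental origin, SFARI-panel gene filtering (non-SFARI genes are
  considered only for de novo, compound-het, or rare truncating/splicing
  variants with MAF < 1 %), and retention of hemizygous / homozygous /
  compound-heterozygous / de novo variants with ≤ 10 gnomAD homozygotes.
- **Five-tier classifier** (P / LP / VOUS / LB / B) over four criteria:
  CADD ≥ 20 (criterion 1), prior ACMG class P or LP (criterion 2), ≤ 1 gnomAD
  homozygote (criterion 3), and neurodevelopmental gene function (criterion 4).
  SFARI genes can reach P; non-SFARI genes are capped at LP. Compound-het
  pairs receive a pair-level class from a fixed combination matrix, and a
  proband whose *only* candidate is an LP variant in a SFARI gene is upgraded
  to P.
- **CNV triage** — array QC gate (SD < 1.0, DLR spread < 0.3), exclusion of
  benign-tier and common (DGV > 1 %) calls, per-gene rearrangement typing
  (DELETED / DUPLICATED / INTRAGENIC / INT START / INT END), genes-of-interest
  ranking, and ISCN-style labels such as `14q31.1(79388339_79657573)x1 de novo`.
- **Cohort summaries** — per-proband best finding across both platforms,
  detection rates by tier and platform, CNV composition, recurrence and
  private-variant tables, sex-stratified positivity, gene-family tables.
- **Synthetic cohort generator** — a seeded simulator that plants trios,
  variants and CNVs exercising every rule branch, with a truth table the
  pipeline must recover exactly.

## Worked example

```bash
asdtriage simulate --seed 1 --out cohort/
asdtriage summarize --variants cohort/variants.tsv --cnvs cohort/cnvs.tsv \
    --genes cohort/genes.tsv --qc cohort/arrayqc.tsv --ped cohort/trios.ped \
    --out results/
```

prints

```
n=122 (104M/18F, ratio 5.8:1)
  P: 4 (3.3%)
  LP: 34 (27.9%)
  VOUS: 70 (57.4%)
  none: 14 (11.5%)
overall P+LP detection rate: 31.1%
```

Reading: of 122 probands, 4 carry a pathogenic finding (3.3 %), 34 a likely
pathogenic one (27.9 %), 70 only variants of uncertain significance, and 14
nothing reportable; the combined-platform diagnostic yield (P + LP) is 31.1 %.
`results/` contains the classified-variant table with per-variant rule traces,
per-patient findings, the drop log (one primary reason per excluded record)
and the cohort summary.

The same pipeline is available as a library:

```python
from asdtriage import SimConfig, generate_cohort, run_pipeline

cohort = generate_cohort(SimConfig(seed=1))
result = run_pipeline(cohort.variants, cohort.cnvs, cohort.genes,
                      cohort.array_qc, cohort.members)
print(result.summary.category_rates)
```

## Input formats

Tab-separated tables with a header row (`variants.tsv`, `cnvs.tsv`,
`genes.tsv`, `arrayqc.tsv`; columns documented in `asdtriage/io.py`) plus a
standard 6-column PED pedigree. Coordinates are 1-based inclusive throughout.
Empty cells mean *not annotated* — in particular an absent gnomAD homozygote
count is a distinct state from zero and passes the retention filter. An
optional pysam-backed adapter (`asdtriage.vcf`) maps trio VCFs onto the same
model.

See `docs/methods.md` for the full statement of the rules, the design
decisions behind ambiguous corners, and known limitations.
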