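# Methods

## Scope and model

`asdtriage` implements a rule-based diagnostic triage for trio-based genetic
testing of essential ASD: probands with both parents sequenced (WES) and
array-CGH performed. The package consumes *annotated* inputs — per-variant
CADD scores, prior five-tier ACMG classes, gnomAD frequencies and homozygote
counts, per-CNV prior classes and DGV frequencies — and applies deterministic
filtering and classification rules. It deliberately does **not** implement
variant calling, CADD computation, the ACMG/AMP evidence-code engine or the
ACMG/ClinGen CNV point-scoring system: those classes enter as annotations,
exactly as a diagnostic laboratory consumes them from its annotation stack.

## Sequence-variant cascade

Order: QC → inheritance → compound-het pairing → gene filter → provisional
classification → retention → final classification.

1. **QC** (strict exclusions below threshold; equality passes): coverage
   < 10×, GQ < 15, or gnomAD MAF ≥ 5 % exclude a variant. The frequency rule
   is stated in the source material as excluding variants with "MAF lower
   than 5 %", which read literally would discard every rare variant; it is
   implemented as *exclude common variants* (MAF ≥ 5 %), the only reading
   consistent with the rest of the analysis. An absent MAF annotation passes.
2. **Inheritance** from trio genotypes: de novo iff the allele is absent in
   both parents; maternal/paternal by carrier parent; biparental when both
   carry; hemizygous X variants in males resolve against the mother's
   genotype. Mendelian-impossible configurations (e.g. a homozygous proband
   with a non-carrier parent) yield `unknown` plus an inconsistency flag.
   Tables may also supply zygosity/inheritance directly.
3. **Compound-het pairing** precedes the inherited-het exclusion, because
   each pair member is individually an inherited heterozygous variant. Two
   heterozygous variants in the same gene pair when their origins differ
   among {maternal, paternal, de novo} — trio phasing is the only phase
   evidence available, so unphased same-parent couples never pair, and a de
   novo het counts as its own origin. Synonymous variants never pair (they
   are unconditionally excluded, so they cannot rescue a partner).
4. **Gene filter**: SFARI-panel genes are examined for every variant. Other
   genes qualify only via de novo status, compound-het membership, or a
   truncating consequence (frameshift, stop-gained, start-lost, splicing)
   with MAF < 1 % or unannotated. The MAF bound is attached to the
   truncating clause; de novo and compound-het candidates in non-SFARI genes
   are not additionally frequency-filtered (their trio evidence is the
   qualification). Genes absent from the metadata table follow the
   non-SFARI branch with no function tags (logged).
5. **Provisional classification** of every candidate (below) — needed before
   retention because the compound-het retention exception reads both
   members' classes.
6. **Retention**: synonymous variants are dropped; inherited heterozygous
   variants survive only inside a pair; all other candidates (de novo,
   homozygous, hemizygous, paired) require ≤ 10 gnomAD homozygotes or no
   annotation. Exception: a pair combining an LP member with a VOUS/LP/P
   member is retained regardless of homozygote count. Retention runs as a
   small fixed-point loop: dropping one pair member on homozygote count can
   orphan its partner, which then falls to the inherited-het exclusion on
   the next sweep. Each dropped record carries exactly one primary reason.

With more than two pair-eligible variants in one gene, partner links are
assigned by a greedy mutual matching (by pair-class severity, then key) so
that `compound_partner` is always symmetric; an unmatched but pair-eligible
variant stays retained without a recorded partner.

## Classifier

Severity order P > LP > VOUS > LB > B.

SFARI branch: **P** iff CADD ≥ 20 ∧ ACMG ∈ {P, LP} ∧ (homozygotes absent or
≤ 1); else **LP** iff homozygotes ∈ [2, 10] ∧ CADD ≥ 20 ∧ ACMG ∈ {P, LP,
VOUS} ∧ the gene has a neurodevelopment / nervous-system-function /
synaptic-transmission / epigenetic-transcription-regulation tag; else **LB**
iff CADD < 15 ∧ ACMG = LB; else **VOUS**.

Non-SFARI branch: **LP** iff CADD ≥ 20 ∧ ACMG ∈ {P, LP} ∧ criterion-4 tag;
else **LB** iff CADD < 15 ∧ ACMG ∈ {B, LB, VOUS}; else **VOUS**. Non-SFARI
variants are conservatively never P (configurable via
`allow_non_sfari_pathogenic`).

Notes on deliberate readings:

- The LP rule literally requires 2–10 homozygotes; a variant with 0–1
  homozygotes, CADD ≥ 20, ACMG VOUS and a criterion-4 gene therefore falls
  to VOUS. This is implemented literally; `lp_allow_low_hom` offers the
  lenient reading (default off).
- "LB or B" outputs collapse to LB; the two tiers are never distinguished
  downstream.
- The classifier is total and monotone in CADD (raising CADD with all else
  fixed never lowers severity); both properties are tested, the former
  against an independently written brute-force decision table over the full
  720-cell discrete feature grid.

**Compound-het combination matrix** (pair normalised to (more-severe,
less-severe)): (P,P)→P, (P,LP)→P, (LP,LP)→LP, (LP,VOUS)→LP, (VOUS,VOUS)→VOUS,
(VOUS,LB)→VOUS, (LB,LP)→VOUS, (LB,P)→VOUS, (LB,LB)→LB. The (P,VOUS) pair is
not covered by the published table; the default resolution is **LP**, lying
between the adjacent (P,LP)→P and (LP,VOUS)→LP rows, and is overridable via
`combination_matrix`. B members are pre-excluded and are an error.

**Unique-candidate upgrade**: a proband whose sole retained finding across
both platforms is a single unpaired LP variant in a SFARI gene is upgraded
to P (recorded in the rule trace; `unique_candidate_upgrade` flag).

**Incomplete penetrance** is carried as a boolean annotation (variant
inherited from an unaffected parent); it affects nothing numerically.

## CNV triage

Arrays must pass SD < 1.0 and DLR spread < 0.3 (strict); failing patients
have all calls excluded. Calls with prior class B/LB, or DGV frequency
strictly above 1 %, are excluded (exactly 1 % is retained; absent frequency
passes). Gene overlap uses closed 1-based intervals (one shared base is an
overlap) over an interval tree. Rearrangement typing: gene ⊆ CNV → DELETED
or DUPLICATED by copy state (exact coincidence counts as whole-gene);
CNV ⊂ gene → INTRAGENIC; partial overlaps are INT START / INT END according
to which transcriptional terminus of the gene lies inside the CNV,
strand-aware with unknown strand treated as +. A CNV is *intragenic* when it
overlaps at least one gene and every overlap is INTRAGENIC.

Genes of interest: a monogenic CNV nominates its gene; multi-gene CNVs are
ranked by a fixed lexicographic priority — SFARI score tier (1<2<3<S<none),
criterion-4 tag, dosage-sensitivity flag matching the copy state
(haploinsufficiency for losses, triplosensitivity for gains), brain
expression percentile descending, then symbol. The published criteria state
no weights; this fixed priority makes the ranking total and deterministic
and is config-overridable.

ISCN-style labels render `band(start_end)xN` with a `pat`/`mat`/`de novo`
suffix; in two-band spans the chromosome number is not repeated
(`13q14.13q14.2(...)`).

## Summaries

Per-proband best finding: maximum-severity retained finding capped at
{P, LP, VOUS} (pair-level classes for compound-het members; LB-only patients
have no reportable finding), with source `sequence` / `cnv` / `both` (both
when the two platforms independently reach the best tier). Detection rate =
(P + LP patients)/n. A variant key (gene, HGVS c.) is *private* when carried
by exactly one proband and *recurrent* at ≥ 2 carriers, siblings counted
separately. Array positivity counts probands carrying ≥ 1 retained CNV of
any class. Gene families group observed genes by annotated family name; the
size filter applies to genome-wide family sizes when supplied, else to
observed counts (`min_family_size`, default 2).

All percentages are rounded half-away-from-zero at `rate_decimals` (default
1; patient-level pathogenic-CNV rates at 2, the intragenic share at 0). The
cohort this package models mixes rounding conventions in places (printing
28.9 % for 30/104 where consistent rounding gives 28.8, and an overall
"30.8 % (32 cases)" that conflicts with its own 4 + 34 = 38); the
implementation is uniformly consistent and computes the overall rate as
(P + LP)/n. These divergences are documented rather than matched.

## Synthetic cohort generator

The generator emulates the *statistical structure* the rules see, not
biology: each planted record satisfies exactly its branch's predicates
(e.g. a `seq_P` variant draws CADD from [20.5, 44.5], ACMG from {P, LP} and
0–1 homozygotes), trio inheritance is consistent with the planted zygosity,
and noise records violate exactly one retention predicate each (synonymous,
inherited-het singleton, low coverage, low GQ, common MAF, > 10 homozygotes,
non-SFARI gene-filter failure; plus benign-class and common-DGV CNVs). Gene
metadata is synthesized — no real SFARI content is shipped — and
`read_gene_metadata` accepts a real table with the same columns.

The default plan is the modelled study's composition: 122 trios, 104 male /
18 female probands, tiers {P: 4 (3 sequence + 1 CNV), LP: 34 (24/8/2),
VOUS: 70 (54/3/13), none: 14}, 46 retained CNVs (16 losses / 30 gains, 11
intragenic, one de novo pathogenic intragenic deletion, 12 P/LP-CNV
carriers, 35 CNV-positive patients: 30 male, 5 female). CADD draws stay
clear of rule boundaries (e.g. [20.5, 44.5] for deleterious, [15.1, 19.4]
for uncertain) so planted classes are forced by construction; boundary
behaviour itself is unit-tested directly. A single RNG stream drives all
draws; the seed appears in every output header, the same seed yields
byte-identical files, and different seeds change identifiers and values but
never branch counts.

What the generator does **not** emulate: realistic allele-frequency spectra,
linkage, annotation noise or mosaicism. Passing the recovery test therefore
demonstrates that the deterministic rules are implemented exactly as
specified — not that the rules are clinically optimal on real data.

## Numerical and degenerate-input choices

- Rounding is decimal-exact (`decimal` module), half away from zero.
- Zero denominators raise rather than return 0 (empty cohort, zero CNVs are
  explicit empty results where meaningful).
- Parsers fail loudly with file/row/column context; there is no silent
  coercion. Missing optional annotations are `None`, never 0.
- Copy-state/copy-number consistency is enforced on autosomes only; expected
  ploidy on X/Y is sex-dependent and the CNV table does not carry sex.
- The problem sizes used in the test suite and the acceptance script are the
  cohort's own (122 trios, ~140 variants, ~50 CNVs), which run in seconds.

## Known limitations

- Phase is inferred solely from parental origin; cis configurations that
  trio phasing cannot see are treated as trans.
- Non-coding variants are out of scope, as in the modelled analysis.
- The classifier consumes ACMG classes as ground truth; disagreements
  between the prior class and the other annotations are not arbitrated.
- Band labels are consumed, not computed from coordinates; no liftover.
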