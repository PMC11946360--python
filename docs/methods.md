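# Methods

## Scope and data model

The pipeline treats a targeted screen as four sequential questions over a
fixed variant panel and a fixed cohort:

1. **Which catalogue entries are usable?** (curation)
2. **Which panel loci were reliably sequenced in which samples?** (depth
   qualification)
3. **Which panel variants does each sample carry, and in what zygosity?**
   (screening)
4. **How does the carrier fraction grow with panel size?** (accumulation)

It consumes caller output — a filtered multi-sample VCF and per-base depth
tables — and never touches reads or performs alignment or variant calling.

## Curation

Four criteria, applied in order, each record excluded with its first failing
criterion as the primary reason:

| criterion | reason code | stage |
|---|---|---|
| location is `g.<digits>` / `m.<digits>` (with a chromosome for `g.`) | `NO_GENOMIC_LOCATION` | 1 |
| build tag equals the accepted build (default `CanFam3.1`) | `WRONG_BUILD` | 1 |
| gene symbol present, alphanumeric-token form | `BAD_GENE_SYMBOL` | 1 |
| alleles parseable (ACGT, not both empty, ref ≠ alt) | `BAD_ALLELES` | 1 |
| max(len(ref), len(alt)) ≤ 20 bp | `SIZE_GT_MAX` | 2 |

Stage 1 collects annotation problems, stage 2 the size cutoff, so the report
mirrors the two-pass narrative of catalogue cleaning. The gene-symbol check
is purely syntactic by design: no external gene list is consulted, which
keeps curation deterministic and testable offline. Counts always reconcile
(`n_input = stage1 + stage2 + retained`, asserted at construction) and
curation is idempotent on its own output.

Categories: size 1 + CDS → coding SNV; size 1 + intron/UTR/promoter →
non-coding (one group, because off-target capture behaviour is what
distinguishes them, not their sub-annotation); size 2–20 → larger variant
regardless of location. The disease/non-disease flag is a catalogue column,
never inferred from the phene text.

## Allele representation

Catalogue descriptions and caller records are matched on a minimal key
obtained by trimming the shared suffix, then the shared prefix, of the
ref/alt pair (advancing the position per prefix base). Conventions after
trimming:

* deletion: ref = deleted bases, alt empty, position = first deleted base;
* pure insertion: ref empty, position = the base immediately **right** of
  the insertion point;
* delins: both alleles non-empty with differing first and last bases.

Trimming is reference-sequence-free. Representations that differ by a shift
through a repeat run (left-alignment proper) are **not** unified — that
requires the reference genome, which this package deliberately does not
load. The synthetic generator therefore chooses anchor bases that never
extend a trimmable run, and real-world inputs should be pre-normalized
(e.g. `bcftools norm`) when repeat-context indels matter.

## Depth qualification

A variant qualifies at threshold *T* in a sample iff every base of its span
has depth ≥ *T* (inclusive). Spans: SNV → its position; deletion of *k*
bases → all *k* positions; insertion → both flanking anchor bases, because
inserted bases have no reference coordinate (a convention, configurable in
principle, recorded here as the package default); delins → the replaced
reference positions. Spans are computed on the normalized form, so anchored
catalogue entries behave identically to their minimal form.

Positions absent from a depth file are depth 0 — fully uncovered loci need
no sentinel. Thresholds are evaluated from the span's minimum depth, which
makes monotonicity (≥30 ⇒ ≥20 ⇒ ≥10) structural rather than incidental.

Per-sample qualified counts are summarized per category as min / max /
median / mean. The median uses the standard midpoint rule for even cohort
sizes (a 49-sample cohort uses the single order statistic). Percentages are
`100 · statistic / n_variants`, rounded half-up to 2 decimals; the mean is
first rounded to 2 decimals so printed tables are self-consistent.

## Screening and zygosity

VCF records are indexed by normalized key after splitting multi-allelic
sites; duplicate keys keep the first record in file order with a warning.
For each sample × panel variant:

* matched, FILTER `PASS`/`.`, genotype called → dosage = count of the
  matched alternate allele index in GT;
* matched but hard-filter-failed, or any missing GT allele (`./1`) →
  **not assessable**;
* unmatched → **wild-type** iff the span qualified at the reporting depth
  threshold (default ≥10x), else **not assessable**. Callers emit variant
  sites only, so absence of a record is evidence of the reference genotype
  only where there was coverage to call it.

Interpretation: autosomal (and complex/unknown) 0/1/2 → wild-type /
carrier / homozygous; X-linked males: any alternate → hemizygous (a diploid
male-X dosage of 2 is logged as a data inconsistency and still reported
hemizygous); X-linked females follow the autosomal mapping; mitochondrial
variants are present/absent under a homoplasmy assumption — heteroplasmy
fractions are out of scope. Pseudoautosomal regions are ignored.

Per-dog summaries count **distinct** detected panel records (dosage ≥ 1),
deliberately zygosity-agnostic; the disease-only restriction uses the
catalogue flag.

## Accumulation

For subset sizes 50, 100, … up to the panel (the full panel always
appended), the proportion of samples with ≥1 detection is averaged over
replicates. Default: nested draws (each subset extends the previous inside
a replicate, making every replicate curve monotone), 100 replicates, seed 0
— all three configurable, since nothing forces a particular choice.
Independent mode additionally offers an exact evaluation using
`P(miss | k of n) = C(n−d, k)/C(n, k)` per sample, equivalent to enumerating
all subsets. The full-panel point is computed as an exact count ratio and is
invariant to seed, mode and replicate count. Uncertainty is reported as the
replicate min/max envelope only; no confidence bands.

## Reporting

Per sample at the reporting threshold (default ≥10x, configurable because
no consensus minimal depth exists for veterinary germline screening): the
reportable range = qualified panel fraction; an explicit unassessable-loci
list (`LOW_DEPTH`, `FILTER_FAIL`, `GENOTYPE_MISSING`) — shallow loci are
listed, never silently dropped; findings grouped by inheritance mode, since
the breeding consequences of recessive carriership differ from dominant or
X-linked findings. No advice text is generated. The panel always
reconciles: |panel| = |qualified| + |low-depth loci|.

## Synthetic study generator

The generator emulates the screen's input structure on an artificial
mini-genome (chr1–chr4, X, MT; kilobase scale, loci 100 bp apart) so no
reference download is ever needed. Defaults define the study conditions:

* **Cohort**: 49 samples, 22 male / 27 female, breed labels cycled from a
  fixed list.
* **Catalogue**: 251 coding SNVs + 7 non-coding 1 bp + 94 larger (2–20 bp)
  variants = 352 valid records; 323 disease-flagged; 118/6/46 per category
  published after the 2014 design year (170 total); 3 planted invalid
  records per curation reason (15 total). X-linked variants sit on X,
  mitochondrial ones on MT with `m.` locations.
* **Depth**: per-base negative binomial (dispersion 5) with marginal means
  35x (coding), 37x (larger), 5x (non-coding) and per-locus capture-dropout
  masses 0.02 / 0.02 / 0.30 — the NB mean is inflated by 1/(1−dropout) so
  the recorded marginal means are exact targets. Bases are drawn
  independently; real coverage is autocorrelated along the genome, so
  qualification of long spans is somewhat harsher here than in real data.
* **Genotypes**: carrier probability per sample 0.00437 for autosomal
  disease variants — chosen so the expected fraction of samples with ≥1
  disease-panel hit is ≈ 0.84, the saturation regime the screen operates
  in — 0.08 for non-disease (coat-colour-type) variants, and observed-scale
  rates for the X-linked (0.10) and mitochondrial (0.06) plants so such
  findings actually occur in a 49-sample cohort. Allele frequency is
  derived as q = 1 − √(1−c); males are haploid on X, everyone on MT (GTs
  emitted haploid there, so planted dosages round-trip exactly).
* **Adversarial structure**: ~2 % of emitted sites fail the hard filter;
  ~10 % of SNV sites are emitted multi-allelic with a decoy allele carried
  by a dosage-0 sample; all indels are emitted anchored (30 % additionally
  suffix-padded), differing from the catalogue's minimal representation.

Every plant is recorded in a truth JSON, and all generators are
seed-deterministic (child seed streams from one master seed).

**What passing synthetic tests does and does not show.** Recovery tests
prove the bookkeeping — curation logic, allele matching, depth gating,
inheritance interpretation — is exact under the stated representations.
They do not validate performance on real exomes: real capture efficiency,
batch effects, repeat-context indel ambiguity, caller-specific genotype
errors and breed population structure are all outside the generator.
Absolute depth-qualification percentages on synthetic data depend entirely
on the chosen coverage model and should not be read as predictions for any
real design.

## Problem sizes and numerics

The default study (49 samples × 352 variants, ~25 depth positions per
locus) runs the full pipeline in a few seconds; tests share one
session-scoped study at a fixed seed. Percentages use decimal half-up
rounding to 2 places. Exact-count ratios are kept as true integer divisions
where seed-invariance is asserted (full-panel accumulation point). Degenerate
inputs fail loudly: empty sample sets, empty count vectors, non-positive
thresholds and unknown samples raise typed errors rather than returning
NaNs.

## Known limitations

* No structural-variant or CNV logic; the panel is point/short-indel only.
* No HGVS parsing beyond `g.`/`m.` + integer; no liftover between builds.
* Reference-free normalization cannot unify repeat-shifted indel
  representations (pre-normalize inputs when this matters).
* Mitochondrial heteroplasmy and X pseudoautosomal regions are ignored.
* The gene-symbol criterion is syntactic; a wrong-but-well-formed symbol
  passes curation.
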