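# Methods

This note documents the models, parameters and numerical choices behind
`snparray`, and what the synthetic-data generator does and does not
emulate.

## Filtering model

Calls are invalidated per sample at DP < 10, DP > 100 or GQ < 20. The
depth/quality conditions combine with OR semantics: any single failing
condition invalidates the call. Defaults are the pipeline's published
thresholds; all three are configurable.

The per-site missing rate counts invalidated plus absent genotypes over
all cohort samples. MAF is computed over valid calls only (each
contributing two alleles; a heterozygote contributes one alternate
allele). Removal criteria are strict — MAF < 0.05, missing rate > 0.1 —
so sites exactly at a boundary are kept. Indel proximity uses only the
indel's VCF anchor position with an inclusive 20-bp radius; indel length
is deliberately ignored because no length-aware rule is defined for the
workflow, and anchor distance is the conservative, reproducible choice.

## Effect classification

One effect per SNP. For coding positions, the reference and alternate
codons are rebuilt from the gene's CDS segments in transcription order
(phase-adjusted, strand-aware) and translated under the standard genetic
code. Class resolution:

* first codon ATG altered → `start_lost` (or `initiator_codon` if the
  change preserved Met — unreachable for single-base changes under the
  standard code, since ATG is the only Met codon, but kept so the class
  vocabulary is total);
* reference codon is a stop → `stop_retained` / `stop_lost`;
* alternate codon is a stop → `stop_gained`;
* otherwise `synonymous` / `missense` by amino-acid identity.

Splice distances follow the common effect-predictor convention, which the
category vocabulary implies but does not quantify: the first/last 2 bp of
an intron are `splice_donor`/`splice_acceptor` (by the gene's strand),
3–8 bp into the intron or 1–3 bp into a non-coding exon edge is
`splice_region`. Genic non-coding positions otherwise fold into `intron`
(the gene models carry no UTR class). Within 2,000 bp of a gene span the
SNP is `upstream2k`/`downstream2k` by strand; otherwise `intergenic`.

When a SNP hits several genes, the highest-priority effect wins; ties go
to the lexicographically first gene id. Unresolvable codons (broken
frame, reference mismatch) demote to `intron` with a warning rather than
failing the pipeline.

Priorities: 4 = {missense, stop_gained, start_lost, stop_lost,
initiator_codon, splice_donor, splice_acceptor}, 3 = {synonymous,
stop_retained}, 2 = {intron, splice_region, upstream2k, downstream2k},
1 = intergenic. Large-effect = {stop_gained, start_lost, stop_lost,
splice_donor, splice_acceptor}.

## Window selection

The "sliding window" is implemented as a non-overlapping tiling anchored
at position 1 — windows [1, w], [w+1, 2w], … — because exactly one marker
is taken per window; an overlapping slide would re-select the same best
candidate repeatedly. Ties inside a window break by priority, then MAF
(more informative markers first), then smallest position; this makes the
design a pure function of its inputs, and designs are byte-identical
across runs.

The expected marker count of a scaffold is ⌊length / target spacing⌋ with
a minimum of 1; the floor keeps the genome-wide sum at or below the
nominal capacity. The 1-kb fill-in pass runs only for deficit scaffolds,
considers only windows holding no selected marker, and consumes windows
in order of their best candidate's rank (a left-to-right order is
available via `SelectionConfig.fillin_by_quality=False`). Over capacity,
non-must-include markers are dropped in ascending (priority, MAF) order;
must-include markers are never dropped.

Probe templates are plus-strand sequences of 35 bp flank on each side
with the variant written `[ref/alt]`, truncated without padding at
scaffold edges.

## Post-genotyping QC

Sample gating: call rate ≥ 0.970 and, where a DQC value is supplied,
DQC ≥ 0.82 (both platform defaults; DQC is intensity-derived and is
consumed, never computed).

Marker categories are assigned from calls over passing samples: a marker
call rate below 0.970 dominates; otherwise all three genotype classes →
PolyHighResolution; one homozygote class plus heterozygotes → NoMinorHom;
a single homozygote class → MonoHighResolution; anything else (both
homozygotes with no heterozygote, or heterozygotes only) → Other. The
reference platform derives these categories from intensity-space cluster
fitting; a call-based classifier cannot see cluster geometry and cannot
detect OTV at all, so externally supplied labels (e.g. from SNPolisher)
override the call-based assignment when available. "Converted" =
PolyHighResolution + NoMinorHom.

Summary conventions: percentages round half-up to the printed precision
(1 decimal for shares, 2 for conversion rates). Allele-pair types are
unordered ref/alt pairs printed alphabetically with no strand collapsing
(A/G and C/T stay separate; transitions = A/G + C/T). Spacing intervals
are consecutive same-scaffold position differences, so k markers on a
scaffold contribute k−1 intervals and the percentage denominator is
n_markers − n_scaffolds. Two average-spacing readings are reported —
total spanned length over total intervals, and the unweighted mean of
per-scaffold means — because a single published average is not
recoverable from either definition alone. Gene coverage counts markers
with any non-intergenic effect toward their assigned gene.

## Concordance

Per marker, only samples called on both platforms enter the comparison;
the rate is the matching fraction, undefined when no sample is
comparable. Means are reported over converted markers (undefined rates
excluded) and over all on-chip markers, where designed markers that never
produced a comparable call count as rate 0 — a marker that cannot be
called is a failed assay, and this treatment reproduces the expected gap
between the two means.

## Family-based error model

Markers are grouped by the parents' genotype combination; same-homozygote
pairs fold into one canonical class (AA×AA covers BB×BB) while hom×het
orientations stay separate (AA×AB vs AB×AA). Markers with an uncalled
parent are excluded entirely. An offspring call outside the Mendelian set
of the actual parental genotypes is "unexpected"; the error-call rate is
unexpected calls over non-missing offspring calls, and an error marker
has at least one unexpected call.

Detectability varies by design: under a uniform miscall model (a wrong
call becomes either other genotype with equal probability) the expected
detectable fraction per call is e for AA×AA and AA×BB, e/2 for hom×het
(a miscall onto the other permitted genotype is invisible), and 0 for
AB×AB, where every genotype is permitted. Per-offspring accuracy is
1 − unexpected/typed. The sample-pass-rate comparison uses the two-sided
Fisher exact test (sum of hypergeometric point probabilities not
exceeding the observed table's).

## Synthetic data

The generator emulates the study design the toolkit targets: a
multi-scaffold draft genome with compact multi-exon genes (CDS starts
ATG, ends at a stop, no internal stops, frame-consistent phases; exons
equal CDS segments — no UTRs), a re-sequenced cohort of 472 samples at
~20-fold mean depth with Hardy–Weinberg genotypes over a configurable
MAF spectrum, per-call Poisson depth with GQ a noisy increasing function
of depth (so quality degrades exactly where coverage does), interspersed
indels, array call matrices with independent per-call miscall/no-call
noise, and a full-sib family of 24 offspring with independent Mendelian
transmission per marker and an exported mask of injected errors.

Defaults not fixed by the study design were chosen once at desk scale:
10 scaffolds × 100 kb, 10 genes per scaffold, 0.005 SNPs/bp (a scaled-
down stand-in for the very high natural polymorphism of the target
genome), uniform MAF on (0.01, 0.5), indel rate 2×10⁻⁴/bp, 1% per-call
miscall and 0.5% no-call rates. Every generator draws from its own
seed-derived child stream, so outputs are bit-reproducible and
independently regenerable.

What passing tests on synthetic data do **not** show: the generator has
no linkage disequilibrium, population structure, probe cross-
hybridization, intensity space, or locus-specific error correlation, so
conversion rates and concordance on real arrays will be lower and
structured in ways these simulations cannot predict. Category
classification is exercised by forcing designated marker subsets
monomorphic, heterozygote-free or low-call-rate.

## Problem sizes and numerical notes

The test suite's end-to-end run uses a 5-Mb genome (10 × 500 kb) with
472 samples; the acceptance script's seeded run uses 1.5 Mb with 200
samples and a 10,000-marker family — sizes chosen so the full pipeline
exercises every stage at desk scale. Oracle-equivalence suites run the
window scan against exhaustive per-window argmax on ≤50-kb scaffolds,
effect classes against a translate-and-compare oracle over all
substitutions of a codon, the exact test against full table enumeration
for margins ≤ 12, and the filters against a scalar per-site reference on
1,000 random sites.

Degenerate inputs: sites with no valid call get missing rate 1 and
undefined MAF and always fail; empty designs write header-only files;
markers absent from a concordance comparison are excluded (converted
mean) or zero-scored (all-chip mean); an empty call vector or call
matrix is an error, not a silent zero.

## Known limitations

* Cluster categories are call-based approximations of intensity-based
  clustering; OTV requires external labels.
* p-convert scores are carried through, never computed (proprietary).
* One transcript per gene (longest CDS); no multi-transcript consequence
  ranking.
* Indel handling is anchor-position only.
* No linkage-disequilibrium pruning, Hardy–Weinberg filtering or
  population-structure analysis.
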