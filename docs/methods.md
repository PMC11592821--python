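# Methods

## Model and assumptions

`covasym` treats fusion detection as a two-sample location problem on
per-exon expression. A fusion that replaces a kinase gene's 5′ portion while
retaining the kinase domain produces transcripts covering only the 3′ exons,
so the normalized coverage of a 5′ control exon group should be
stochastically smaller than that of the kinase-domain (TK) exon group. The
method assumes:

* a single transcript model per run (no isoform mixing, no UTR trimming);
* a strand-specific library, so transcript-sense reads can be separated from
  antisense reads (read-through transcription from an opposite-strand
  neighbour would otherwise contaminate the 3′ exons);
* breakpoints upstream of the TK group (for ALK, intron 19 is the common
  breakpoint, so exons 20–24 — the first half of the TK domain — sit just
  downstream and also certify that the kinase domain is intact);
* exon 1 is excluded from the control group because poly-dT-primed cDNA
  protocols under-represent the transcript's 5′ extremity regardless of
  fusion status.

## The statistic

Let c₁..c₅ and t₁..t₅ be the normalized sense coverages of the control and
TK exons. The mid-rank Mann–Whitney statistic is

U = Σᵢⱼ [ 1(tⱼ > cᵢ) + ½·1(tⱼ = cᵢ) ],

and the one-sided p-value is the exact permutation tail

p = #{reassignments of the pooled 10 values with U* ≥ U} / C(10,5).

Exact enumeration (supported up to a pooled size of 12) was chosen over the
normal approximation because the group sizes are tiny and fusion profiles are
saturated with zero ties, where asymptotic tie corrections are at their
worst. The achievable p-values are k/252; complete separation gives 1/252 ≈
0.00397 (displayed as 0.004), and a fully tied pool (e.g. an unexpressed
gene) gives p = 1. The implementation is cross-checked in the tests against
an independent rational-arithmetic enumeration oracle (rank-sum formulation,
`fractions.Fraction`) and, on tie-free inputs, against the exact
Mann–Whitney distribution in scipy to 1e-12.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| control_exons | 2–6 | exon numbers | 5′ group; exon 1 excluded (priming artefact) |
| tk_exons | 20–24 | exon numbers | first half of the TK domain; certifies intact kinase |
| alpha | 0.05 | probability | one-sided screening threshold; 5v5 groups make p = 1/252 reachable |
| min_mapq | 101 | Phred-like MAPQ | strict "MQ > 100": selects STAR unique mappers (255) |
| min_aln_len | 10 | bp | discards near-empty alignments after clipping/splicing |
| min_library_reads | 2,500,000 | unique reads | library QC floor (inclusive) |
| min_tk_depth | 0.7 | bases/position | reliability gate calibrated by subsampling (below) |
| expression_floor | 0.01 | norm. coverage | separates wild-type expression from a silent gene |
| library_strandedness | reverse | — | dUTP-style protocols; forward/unstranded supported |

The expression floor deserves a note: the wild-type-vs-silent distinction in
the published screen was described qualitatively ("all exons transcribed")
without a numeric threshold, so the floor here is an explicit, configurable
stand-in. It only routes non-significant samples between the
`WILD_TYPE_EXPRESSION` and `NOT_EXPRESSED` verdicts; it never affects the
fusion call itself.

Two definitional choices that the protocol leaves open are resolved as
follows and recorded in every JSON report: "total number of reads" for
normalization means primary, mapped, non-duplicate records genome-wide
(without the MAPQ/length filters, which are coverage-step filters); and TK
depth uses transcript-sense bases only by default (`depth_both_strands`
flips this), since antisense read-through is a QC signal, not kinase
expression.

## Coverage counting

Aligned length and per-exon base counts both use only reference-consuming
match operations (cigar M/=/X). Deletions and splice gaps (D/N) advance the
reference without contributing coverage, so a spliced read whose N gap spans
an exon contributes nothing to it. Counting is exact interval intersection,
not per-position pileup, but the two agree by construction; the test suite
enforces equality against a per-position brute-force oracle on small SAM
fixtures. Contig-name mismatches (chr2 vs 2) raise immediately with a
remediation hint instead of silently returning zero coverage. Paired-end
input is supported by flipping read-2 to its fragment's strand before
orientation is assigned; single-end is the tested default.

## The simulator

The generator emulates exactly the features the method consumes:

* on-target reads placed uniformly **within single exons**, drawn per exon
  proportionally to weight × length — no splice-junction reads, no sequencing
  errors, no GC or degradation bias. Junction reads are irrelevant to the
  statistic, and single-exon placement keeps brute-force oracle counts exact;
* truth profiles: FUSION (weights 0 before the breakpoint exon, `fold` after;
  an optional leak models residual wild-type expression), WILD_TYPE
  (uniform), SILENT (zero);
* an `antisense_fraction` that flips reads to the antisense orientation,
  emulating read-through transcription;
* background reads on a decoy contig, which set the library size
  independently of on-target coverage;
* MAPQ 255 and clean flags throughout, with deterministic output for a given
  seed.

Consequently, passing tests demonstrate the statistical machinery and the
counting semantics, not robustness to alignment artefacts, multimapping,
FFPE degradation or annotation errors in real data.

## The depth-reliability (subsampling) experiment

The published calibration subsampled 1/2/5/10/20 million reads in triplicate
from real libraries and located the depth below which fusion calls become
unstable at a TK depth of 0.7. The packaged experiment reproduces that
design's *shape* at desk scale: a 200,000-read master library per replicate
(on-target fraction 0.002), subsampled to 5k/10k/20k/50k/100k reads in
triplicate, each subsample pushed through the full coverage → exact-test
pipeline. Problem sizes were chosen so the grid straddles the 0.7 gate and a
full run takes seconds.

Reads in this experiment are 25 bp (elsewhere the default is 50 bp). At a
fixed depth d the expected read count in an exon of length L is d·L/r for
read length r, and with 5v5 groups and an all-zero control the call only
becomes non-significant when **two or more** TK-group exons are empty (one
empty exon still gives p = 6/252 < 0.05; two give 21/252). Shorter reads
therefore sharpen the empty-exon transition around the gate, which is what
makes the qualitative pattern — every replicate at depth ≥ 0.7 significant,
instability confined below — reproducible at 10⁴-scale read counts rather
than the original 10⁶–10⁷ scale. Subsampling acts on alignments rather than
FASTQ records; per read the alignment is deterministic, so the statistic is
unaffected by this deviation from the original pipeline.

## Numerical and degenerate-input choices

* U comparisons in the enumeration use a 1e-9 guard; U is a multiple of 0.5,
  so this cannot misclassify a split.
* Normalizing against an empty library raises instead of returning NaN;
  counting an empty file yields an all-zero profile plus a warning.
* An unexpressed gene (all ties) is reported as p = 1, verdict
  `NOT_EXPRESSED`, with the low-coverage flag attached (depth 0 < 0.7).
* The low-coverage annotation never changes a verdict; it coexists with it,
  so a significant call at depth 0.3 is reported as
  `FUSION_PREDICTED` + `LOW_COVERAGE_UNRELIABLE`.
* p-values are printed to three decimals in human-readable output and at
  full precision in JSON/TSV.
* In batch mode, alpha is applied per sample without multiplicity adjustment
  (one gene per run); an optional Benjamini–Hochberg q-value column is
  available for cohort screening, off by default.

## Packaged data

* `alk_exons_synthetic.tsv` — the built-in ALK model keyed to
  ENST00000389048.8: 29 exons, chromosome 2, minus strand, hg38-like span.
  The per-exon coordinates are a synthetic stand-in with realistic exon and
  intron lengths (offline generation; no network access at runtime); exon
  count, chromosome and strand match the reference transcript. Analyses of
  real BAMs should supply real annotation via `--gene-model` (GTF/BED12 or
  the exon-table format).
* `validation_cohort.tsv` — the 50-sample targeted-NGS validation cohort of
  the published screen: 19 individually reported samples transcribed
  verbatim as predicted/confirmed flags, plus 31 synthetic negative/negative
  rows standing in for controls that were only reported in aggregate
  (TP=11, FP=2, TN=37, FN=0).

## Known limitations

* One transcript model per run; a fusion joining mid-exon, or a gene whose
  wild-type expression is itself 3′-biased, can confound the call.
* The method cannot identify the 5′ partner or the exact breakpoint beyond
  the exon-group pattern.
* The exact test is limited to pooled group sizes ≤ 12 by design; larger
  exon groups would need a different enumeration strategy.
* The wild-type/silent distinction rests on the heuristic expression floor.
* The synthetic ALK coordinates make the built-in model suitable for
  simulation and testing, not for quantifying real ALK BAMs.
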