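# covasym — kinase-fusion prediction from RNA-seq exon coverage asymmetry

Oncogenic kinase fusions (the classic example being *EML4::ALK* in lung
adenocarcinoma) put the 3′ portion of a kinase gene — the exons encoding the
tyrosine-kinase (TK) domain — under the control of a partner gene's promoter.
In whole-transcriptome RNA-seq this leaves a footprint that does not depend on
sequencing the fusion junction at all: exons downstream of the breakpoint are
highly covered while the gene's own 5′ exons are nearly silent. `covasym`
detects that footprint directly from aligned reads, for molecular-pathology
and cancer-genomics users who have RNA-seq BAMs and want a fusion call that
does not require junction (chimeric) reads.

## The method

For a target gene with exons numbered 1..N in transcription order:

1. **Filtered, strand-aware coverage.** Only primary, non-duplicate, mapped
   reads with mapping quality > 100 (STAR unique mappers are MAPQ 255) and at
   least 10 bp of aligned reference length are counted. Each read's aligned
   (M/=/X) blocks are intersected with the exon intervals, and each base is
   attributed to the transcript-sense or antisense strand according to the
   library protocol (dUTP/"reverse" by default). Antisense coverage — e.g.
   read-through transcription from a tail-to-tail neighbour gene — is kept
   for QC but excluded from the test.
2. **RPKM-like per-exon normalization.** For exon *e*,

   ```
   norm(e) = bases(e) / length(e) / library_total_reads × 10⁶
   ```

   where `library_total_reads` is the genome-wide count of unique (primary,
   mapped, non-duplicate) reads. Libraries under 2.5 million unique reads
   fail QC.
3. **Exact one-sided rank test.** The normalized sense coverages of a 5′
   control group (ALK exons 2–6) and the TK group (exons 20–24, the first
   half of the kinase domain) are compared with a one-sided Mann–Whitney U
   test, alternative "TK coverage larger". With n₁ = n₂ = 5 the p-value is
   computed by exact enumeration of all C(10,5) = 252 reassignments of the
   pooled values using the mid-rank U (ties score ½), so the smallest
   achievable p is 1/252 ≈ 0.004 and the test is exact under the heavy zero
   ties typical of fusion profiles.
4. **Verdict.** p < 0.05 predicts a fusion; otherwise expressed-but-uniform
   coverage indicates the wild-type gene and absent coverage a silent gene.
   A TK-domain depth (aligned bases per position over exons 20–24) below 0.7
   flags any verdict as low-coverage-unreliable.

A synthetic read simulator (fusion / wild-type / silent truth profiles,
configurable antisense fraction, decoy-contig background reads) and a
subsampling experiment driver make the whole method testable end to end
without any external data.

## Worked example

Simulate an ALK fusion sample (300 on-target reads over exons 20–29, 2,000
background reads) and run the assay:

```python
import covasym as cv

cfg = cv.AssayConfig(min_library_reads=1000)   # desk-scale library floor
prof = cv.make_profile("FUSION", on_target_reads=300, background_reads=2000, seed=7)
cv.simulate_alignments(prof, "demo.sam")

model = cv.CoverageAsymmetry.from_alignments("demo.sam", config=cfg, sample_id="demo")
res = model.fit()
print(res.summary())
```

```
=======================================================
             Exon Coverage Asymmetry Test
=======================================================
Sample                     demo
Gene / transcript          ALK / ENST00000389048.8
Exons in model             29
Library reads (unique)     2,300
Library QC (>= 1,000)      pass
Control exons              2,3,4,5,6
TK exons                   20,21,22,23,24
Control mean coverage      0.0000
TK mean coverage           2060.1802
TK depth (gate 0.70)       4.786
U statistic                25
p-value (one-sided exact)  0.004
Verdict                    FUSION_PREDICTED
Flags                      none
=======================================================
```

The control exons received no reads while all five TK exons are covered, so
U hits its maximum (25) and the p-value its floor (1/252, shown as 0.004):
the sample is called a predicted fusion, and the TK depth of 4.79 is well
above the 0.7 reliability gate. `res.plot("demo.png")` draws the per-exon
coverage with sense bars up, antisense bars down and the TK group
highlighted.

The packaged targeted-NGS validation cohort gives the assay's headline
performance:

```python
from covasym import confusion_metrics, load_validation_table
print(confusion_metrics(load_validation_table()))
# TP=11 FP=2 TN=37 FN=0 | accuracy 96.0% sensitivity 100.0% specificity 94.9%
```

The same functionality is available from the shell via the `covasym` command
(`run`, `batch`, `simulate`, `subsample-experiment`, `validate-metrics`).

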