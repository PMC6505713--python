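# tilescope

Analysis toolkit for bacterial genome-tiling microarray experiments that
compare a reference and a treated condition (e.g. a DNA-damage challenge in
*E. coli*) with several replicates per condition.  Tiling arrays probe the
whole replicon — including intergenic space — so transcripts can be detected
and quantified without trusting the annotation, which is what makes them
useful for finding novel ncRNAs, UTRs and operon structure.

`tilescope` implements the full downstream analysis, starting from a log2
probe-intensity table:

1. **Annotation-based differential expression** — for each annotated gene,
   all probe × replicate log2 values of the probes targeting it (probe
   midpoint inside the gene, same strand) are pooled per condition and
   compared with a Welch two-sample t-test.  The reported *P score* is
   `1 − p` (probability of differential expression) and the log2 fold
   change is `mean(treated) − mean(reference)`.  A gene is *present* in a
   condition when its pooled mean is at or above the 9.0 log2 detection
   floor; genes present in exactly one condition count as repressed or
   induced accordingly.
2. **Annotation-independent segmentation** — each strand's probe series is
   split at untiled gaps (>60 nt between probe starts), then partitioned by
   an exact change-point dynamic programme minimising
   `Σ_segments (RSS_ref + RSS_treated) + λ · #segments`.  Segments are
   scored like genes; regions are called *differential*
   (P > 0.95, |log2FC| > 0.5, ≥ 25 nt) or *similarly expressed* (present in
   ≥ 1 condition, > 35 nt).
3. **Region classification** — each region is mapped to the annotation as
   `touching` (≥ 1 nt same-strand overlap), `operon_element` (same-strand
   gene within < 100 nt on both sides), `utr5`/`utr3` (one same-strand gene
   end within < 100 nt, side strand-aware), `antisense` (opposite-strand
   overlap only; filtered out as unverifiable) or `novel`.
4. **Ada-box promoter scan** — searches the 200 nt upstream of transcript
   start sites for the methylated-Ada recognition elements box A (`AAT`) and
   box B (`GCAA`) at 5–7 nt spacers, and compares occurrence rates between
   gene groups with Fisher's exact test.
5. **Prediction-set meta-comparison** — candidate-level intersection/union
   between interval sets, integer-percent overlap fractions, and
   nucleotide-level coverage comparison between two transcript maps.

A first-class synthetic-data generator builds an artificial replicon,
annotation, selective tiling layout (19 probes per gene, 14 nt intergenic
step) and five replicates per condition with a known truth set, so the whole
pipeline is testable end to end without any download.

## Worked example

```sh
tilescope simulate --outdir demo --seed 7 --genome-length 50000 --n-genes 15 --n-novel 6
tilescope run --config demo/config.yaml
```

prints

```
fixture written to demo (21 transcripts)
differential regions: 11, similar regions: 8
```

and `demo/results/summary.json` contains (excerpt):

```
DE genes up/down: 5 3
expressed nt: {'reference': 8245, 'treated': 8184} ratio 0.993
classification diff: {'novel': 3, 'touching': 8, 'operon_element': 0, 'utr5': 0, 'utr3': 0, 'antisense': 0}
motif: fisher_p 1.0, differential 1/8 with a box A/B match, similar 0/5
```

Reading: of the 15 simulated genes, 5 were induced and 3 repressed
(including genes dropping below the detection floor in one condition); the
segmentation found 11 differential regions — 8 touching annotated genes and
3 recovering the spiked novel intervals — and the total expressed sequence
shrank by ~0.7% in the treated condition.  The ada-box scan found one
box A/spacer/box B promoter among the differential genes; the rate does not
differ significantly from the similarly expressed group (Fisher p = 1.0),
as expected on random sequence.

Every stage is also available separately (`tilescope annotate-de`,
`segment`, `classify`, `adabox`, `compare`, `convert`) and as library
functions (`tilescope.annotation_de`, `tilescope.segmentation`, …).

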