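# Methods

## Scope and data model

`tilescope` analyses two-condition (reference vs treated) tiling-microarray
experiments on a single bacterial replicon.  Input is a log2
probe-intensity table (probes × samples, ≥ 2 replicates per condition), a
probe layout (1-based inclusive coordinates, strand), a genome FASTA and a
gene annotation (GFF3 or BED6).  All internal coordinates are 1-based
inclusive; BED's 0-based half-open convention is converted exactly at the
I/O boundary, so `bed_end − bed_start == end − start + 1` always holds.
Anything upstream of the log2 table (scanning, normalisation,
between-array calibration) is out of scope.

## Differential-expression score

For a gene or region, all probe × replicate values per condition are pooled
and compared with a Welch (unequal-variance) two-sample two-sided t-test;
probes are treated as exchangeable measurements of the same transcript.

* `P = 1 − p_value` — the probability-of-differential-expression score,
  thresholded at P > 0.95;
* `log2FC = mean(treated) − mean(reference)`, thresholded at |log2FC| > 0.5.

Welch rather than pooled-variance t is the default because probe pools from
the two conditions need not share a variance; the choice is isolated in
`tilescope.stats.welch_de`.  Degenerate inputs are defined, not NaN: zero
variance in both groups gives P = 0 for equal means and P = 1 otherwise.
Label swap negates log2FC and leaves P unchanged (tested).  No
multiple-testing correction is applied; the P > 0.95 rule is a per-feature
decision threshold, and the observed false-positive rate among truly null
genes is checked empirically (~5%) in the test suite.

## Presence calls

A probe set (gene or region) is *present* in a condition when its pooled
mean is at or above the detection floor of 9.0 log2 — intensities below 9.0
are inseparable from background.  The floor is applied to the pooled mean
rather than per probe: per-probe presence voting adds a tuning parameter
(what fraction of probes must pass) without changing the decisions on
well-measured transcripts.  A gene present only in the reference is called
`absent_treated_only` and counted with the down-regulated genes (and
symmetrically for induction).

## Change-point segmentation

Per strand, probes sorted by start are first split into runs wherever
consecutive probe starts are more than `max_gap = 60` nt apart: with a
14 nt intergenic tiling step and ≤ ~55 nt genic probe spacing, a larger gap
implies untiled sequence that a transcript call must not bridge.  Within a
run the exact minimiser of

    total cost = Σ_segments (RSS_ref + RSS_treated) + λ · #segments

is found by dynamic programming (O(n²) with prefix sums; the inner
minimisation is vectorised), where RSS_c is the residual sum of squares of
all probe × replicate values of condition c around the segment's condition
mean.  Fitting both condition means per segment makes a boundary profitable
wherever *either* condition changes level, so the segmentation
simultaneously performs the reference-vs-treated comparison.  The DP is
verified against exhaustive search over all 2^(n−1) partitions for n ≤ 12.

**Penalty λ.**  λ is in squared-log2 units and trades resolution against
false splits.  The shipped calibration (`scripts/calibrate_penalty.py`)
simulates pure-noise series (sd 0.3, 5+5 replicates) and reports the
fraction left unsplit; λ ≥ 2 already keeps ≥ 99% of 60-probe noise series
in one segment, and the default λ = 6 keeps that margin on genome-length
runs with thousands of candidate split points.  Expression steps are ≥ 1.5
log2 over ≥ 4 probes × 10 values, i.e. RSS gains of ≳ 90 ≫ λ, so the
default costs essentially no sensitivity.

**Region extent and calls.**  A segment's genomic extent is its first probe
start to its last probe end (probe spans, not midpoints).  Scored segments
are called *differential* (P > 0.95, |log2FC| > 0.5, length ≥ 25 nt,
expressed in ≥ 1 condition) or *similarly expressed* (not differential,
expressed in ≥ 1 condition, length > 35 nt); a region meeting both criteria
appears only in the differential list, and sub-length regions are dropped
with a logged count.  Parts of one annotated gene may legitimately surface
in both lists (no deduplication across lists).  Expressed-nucleotide totals
per condition are strand-wise union lengths of the present regions.

## Region classification

Precedence: `touching` → `operon_element` → `utr5`/`utr3` → `antisense` →
`novel`.  The precedence is a package decision: the most
annotation-anchored label wins, and the operon rule (same-strand gene
within < 100 nt on *both* sides) is strictly stronger than the UTR rule
(one side), so it is tested first.  Distances are gap nucleotide counts
exclusive of both ends, with "< 100 nt" a strict inequality.  UTR side is
strand-aware: a region genomically before a + gene (or after a − gene) is
its 5′ UTR.  The documented tie-break for an equally distant upstream and
downstream gene (prefer the utr5-yielding gene) is implemented but
unreachable under this precedence, since two near genes already imply
`operon_element`.  Antisense regions (opposite-strand overlap only) are
filtered out of downstream summaries because reverse-transcription
artefacts cannot be excluded without strand-specific labelling controls.
A touching region spanning k ≥ 2 same-strand genes additionally contributes
k − 1 operon-element parts to the summary table (it identifies a potential
operon).  The classifier is verified against a per-nucleotide brute-force
scan on random fixtures and is invariant under coordinate translation.

## Ada-box promoter scan

Box A is `AAT`, box B `GCAA`; the scanner reports every (position, spacer)
pair with spacer 5–7 nt within the 200 nt upstream window of a start site
(annotated starts by default; a detected region's start is its 5′-most base
on its strand).  Windows are truncated and logged at replicon ends; `N`
never matches; overlapping matches are all reported (the matcher equals an
overlap-enumerating regex oracle on random sequence).  `upstream_distance`
counts the nucleotides between the last base of box B and the start site
(0 = abutting); the anchor is a documented convention and can be switched
to box A.  Group occurrence rates (fraction of genes with ≥ 1 match) are
compared with a two-sided Fisher exact test, reported but never
thresholded.

## Prediction-set comparison

Candidate-level intersection counts an A-candidate as "present in both"
when it overlaps ≥ 1 nt (configurable) with any B-candidate, strand-aware
only when both sets carry strand; one-to-many overlaps are collapsed by
candidate, and union = |A| + |B| − intersection.  Overlap fractions are
integer percents of the region length, rounded half away from zero.
Nucleotide-level comparison works on the merged per-nucleotide union of
each set (strand-collapsed) and returns only-A / only-B / shared counts
that sum to the coverage of A ∪ B.  A prediction may count in both the
"similarly" and "differentially" expressed columns; the presence columns
are not exclusive.

## Synthetic data: what it emulates and what it does not

The generator packs non-overlapping genes (default U(300, 1000) nt; the cap
keeps 19 evenly spaced genic probes within the 60 nt `max_gap`) and truly
novel intervals (U(60, 250) nt) onto a random replicon with ≥ 150 nt gaps
— large enough that novel intervals stay beyond the 100 nt UTR cutoff and
classify as `novel`, keeping truth bookkeeping exact.  The tiling design
mirrors the selective-tiling idea: 19 probes per gene, 25 nt probes, 14 nt
intergenic step on both strands.  Each transcript draws a status
(differential / similar / single-condition / silent) and per-condition
levels: expressed levels U(10, 14) log2, background 7.5 (below the 9.0
floor), spiked |shifts| U(1.5, 2.5) log2 — clearing the 0.5 fold-change
threshold by ≥ 1.0 so that recovery failures indicate bugs, not borderline
effects.  Probe membership in a transcript is decided by the probe
midpoint.  Intensities are transcript level (or background) plus i.i.d.
Gaussian probe noise (sd 0.3); five replicates per condition.

Deliberately not modelled: sequence-dependent probe affinity (GC bias),
cross-hybridisation, spatial array artefacts, and non-Gaussian background —
real background distributions are unknown here and the Gaussian choice is a
stand-in.  Passing recovery tests therefore demonstrate the correctness of
the segmentation/calling logic under the stated noise model, not
performance on raw array data; systematic probe effects would first hit the
per-probe exchangeability assumption of the pooled t-test.

Everything is deterministic given the seed (NumPy `default_rng`); fixture
files are byte-identical across runs.

## Problem sizes used in the shipped checks

Unit and property tests run on replicons of 12–40 kb; the end-to-end
recovery check uses a 120 kb replicon with 40 genes and 20 novel intervals
(~27 detectable truly differential transcripts) and a separate 140 kb,
150-gene all-null replicon for the false-positive-rate check.  At these
sizes the whole suite runs in well under a minute; the DP scales as O(n²)
per run and handles thousands of probes per strand comfortably.

## Known limitations

* Single replicon only; multi-record FASTA is rejected.
* The segmentation cost is a least-squares instantiation of t-test-guided
  change-point detection; it is this package's own concrete choice and
  other penalties (BIC-style, variance-normalised) would shift boundaries
  slightly.
* The P score inherits the usual caveat of `1 − p`: it is not a posterior
  probability.
* No between-array normalisation: the intensity table is taken as already
  comparable across samples.
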