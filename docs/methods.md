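# Methods

This note documents the models, conventions and design choices behind
`scm6a`, in the order data flows through the pipeline.  All genomic
intervals are 0-based half-open (BED convention); GTF input is converted on
read.  Every stochastic routine takes an explicit seed and is byte-stable
under it.

## Read structure and demultiplexing

A library read pair carries, on read 1, a cell barcode, a short random
stretch (default 4 nt), and a constant `GGG` anchor left by template
switching, followed by cDNA payload; read 2 is payload (optionally prefixed
by a second-round cell barcode), and a sample index may live in the FASTQ
header comment.  Before decoding, constant sequences are trimmed:

* 5′ — up to five rounds of exact-prefix removal of the template-switch
  oligo `TCCGATCT` and the auxiliary `CACGTCTC`, read 1 only (these are
  first-strand-synthesis artifacts and do not occur on read 2);
* 3′ — the adapters `NNNNNNNAGATCGGA` and `TCGGAAGAGCACAC` on both mates,
  where `N` matches any base, a match needs at least 8 exact non-N
  agreements, and partial occurrences running off the 3′ end are allowed.
  Pairs with either mate shorter than 28 nt afterwards are rejected.

Decoding checks components in the order sample index → barcode 1 → anchor →
barcode 2 and reports the first failure; a read too short for the structure
is an anchor failure, not an exception.  Barcode matching is exact by
default.  An optional Hamming-1 rescue accepts a barcode within distance 1
of exactly one table entry; distance-1 ties stay rejected, because a
one-error read equidistant from two cells carries no usable cell identity.

PCR duplicates are collapsed per cell on a molecular key, keeping the first
occurrence.  Two key constructions are provided because the informative
read-1 bases differ between library formats: `UMI_NNNN_READ2` (the 4
random bases plus the first 7 payload bases of read 2) and
`PAYLOAD7_READ1_READ2` (the first 7 payload bases of each mate).  The
payload interpretation is deliberate: the pre-structure read-1 bases are
constant within a cell and cannot identify molecules.

## Peak calling

The internal caller is a deliberately simple, fully specified enrichment
test — not a reimplementation of any external caller — so the pipeline is
self-contained and auditable; externally produced narrowPeak files can be
substituted anywhere downstream.

Windows of 100 bp every 50 bp are scored by the exact Poisson upper tail
P(X ≥ k) of the IP fragment-overlap count k against
λ = max(λ_min, c · N_IP/N_ctrl), where c is the control count in the same
window and λ_min (default 1.0) floors the expectation so control dropout
cannot yield infinite enrichment.  Only windows with at least one IP
fragment are tested; empty windows carry no evidence and would only inflate
the Benjamini–Hochberg family, so q-values are computed across the tested
windows of one caller run.  Windows with q < 0.05 are merged when separated
by at most 50 bp.  Per merged peak: the fold enrichment is k_peak/λ_peak
with λ_peak floored at λ_min scaled by peak length over window length, the
p-value is recomputed on the merged interval, the q-value is the minimum
window q inside the peak, and the summit is the leftmost position of
maximal IP coverage.

The high-confidence filter keeps peaks with fold_enrichment > 2 **and**
−log₁₀(q) > 10, strict inequalities exactly as printed in the rule it
implements.  The dual-control consensus retains a peak when some peak of
the other control's set covers ≥51% of it and it covers ≥51% of that peak
(reciprocal-minimum-fraction semantics, `≥` as in the interval tools the
convention comes from).  Peak–peak overlap ignores strand — IP enrichment
in this protocol is unstranded — while gene annotation reports strand as an
attribute.  Peaks are annotated to the gene with the largest exonic
overlap, requiring at least 50% of the peak length; exact ties report all
tied genes.  Writer-dependent peaks are control peaks with no reciprocal
match in the knockout peak set, restricted to genes expressed at FPKM ≥ 1
in the control; peaks whose gene lacks an expression entry are excluded
with a warning rather than silently kept.

## Quantification

Fragment counting follows the unique-assignment convention: a fragment
increments the single gene whose exons it overlaps; fragments touching
exons of two or more genes are discarded as ambiguous (not fractionally
split), and fragments touching none are unassigned.  FPKM divides counts
by gene length in kb and library size in millions, where the library size
is the column's uniquely assigned fragment total; CPM omits the length
term; TPM rescales per-kb rates to sum to 10⁶ per cell.

The per-cell relative m6A level is `log2(N_IP / (N_IP + N_RNA + N_SUP))`
over deduplicated fragment counts of the three fractions.  It is
scale-invariant, always ≤ 0, equals 0 only when the cell has no control
fragments, and is undefined (the cell is flagged and excluded from
level-based clustering) when N_IP = 0.

Commonly modified transcripts are those ranking within the top 5000
enrichment scores per cell — a transcript's score is its best peak's fold
enrichment — in at least 6 cells.  Ranking ties are broken by transcript
identifier so the rule is deterministic; with continuous scores the
tie-break never fires.

## Metagene and saturation profiles

Coverage of each library is CPM-scaled (fragment-overlap depth ×
10⁶/library size), binned at 5 bp in transcript orientation around the
anchor — TSS with a −50/+500 window, stop codon with ±500 — and
minus-strand rows are reversed.  The per-bin curve is the across-region
mean of the per-region (IP + pseudocount)/(input + pseudocount) ratio
(mean of ratios; ratio of means is available behind a flag).  The
pseudocount (default 1, in CPM units) guards empty bins.  Note that the
mean-of-ratios estimator carries an upward bias of order 1/λ, λ being the
expected input fragment count per bin, so quantitative read-outs of planted
enrichments are made at depths where λ ≳ 30.  Regions whose window crosses
a chromosome edge are dropped, keeping bin semantics uniform; real
chromosome bounds are enforced when supplied and otherwise inferred from
the data with a one-window margin.

Saturation curves draw reads without replacement at each requested depth
with a seeded generator (mirroring shell-level shuffling), count genes with
at least one sampled read (threshold configurable), and report mean ± sd
over replicates.

## Clustering

Expression is z-scored per gene before any embedding.  PCA is the default
reduction because it is fully deterministic; sign ambiguity is fixed by
making each component's largest-magnitude loading positive, and an
all-constant matrix maps every cell to the origin (the degenerate-case
rule).  A seeded UMAP embedding is available where non-linear structure
matters; nothing downstream depends on its geometry beyond separability.

m6A-augmented clustering joins the 2-D embedding with the per-cell m6A
level as a third column, standardizes each column to unit variance (so the
heterogeneous components weigh equally — the design is open here and the
flag is exposed), and applies agglomerative Ward clustering on Euclidean
distances, cut at k clusters or at a height.  Labels are renumbered by
decreasing cluster size so they are stable across cell orderings.  A
caveat follows directly from the standardization: when the embedding is
pure sampling noise, z-scoring amplifies it to the same unit variance as a
genuine level signal, and greedy agglomeration can misplace a few boundary
cells; a clean separation is guaranteed only when expression carries no
variation at all, which is the regime the level-only simulation
(`simulate_level_contrast`) constructs.

Gene-trend clustering is Lloyd K-means (up to 10,000 iterations, seeded
initialization from k distinct rows).  An iteration that empties a cluster
reseeds that centroid from the point farthest from its assigned centroid.
The within-cluster sum of squares is non-increasing across iterations, and
identical seeds give identical labels.

## Gene categories and reader distances

Stage logic for the oocyte-to-embryo transition: **maternal** genes have
FPKM ≥ 1 in the MII oocyte; **maternal-decay** genes are maternal genes
significantly higher in MII than in the zygote (log₂FC > 0.5, adjusted
p < 0.05) — the contrast orientation is an explicit configuration field
because "decay" could be read in either direction, and MII-over-zygote
(transcripts high in the oocyte that drop afterwards) is the default;
**minor-ZGA** genes come up in the early or mid 2-cell embryo against the
previous stage, **major-ZGA** genes in the late 2-cell or 4-cell embryo,
at the same thresholds.  Differential-expression tables are pluggable
inputs; the built-in stand-in (mean-CPM log-ratio with a rank-sum test and
BH correction) exists so synthetic runs need no external fitter and is not
a substitute for a dispersion-modelling DE method on real data.

Peak-to-reader-target distances use the closest-interval convention: 0 for
overlap, 1 for bookended intervals, gap+1 otherwise, ties going to the
smaller start.  The null model relocates each target uniformly within its
own chromosome, preserving length and chromosome assignment (a flag could
relax the latter; the default matches the convention of the standard
shuffling tool), with a seeded generator.

## Synthetic data

The generator emulates the data model the pipeline targets, not any real
genome.  Single-exon (optionally multi-exon) genes are laid out without
overlap across a configurable number of chromosomes (defaults: 2
chromosomes of 100 kb, 60 genes of 600–1200 bp — sizes chosen so a full
simulate–demultiplex–call–cluster cycle runs in seconds while every gene
still receives tens of fragments).  Per-cell counts are negative binomial
(dispersion 5, mean 10 scaled by a per-gene log-normal with σ = 0.5),
matching single-cell overdispersion in form.  Each population fixes a
methylated gene fraction; methylated genes carry a planted peak of ±100 bp
around the stop codon, emulating the canonical 3′-biased m6A distribution.
Molecules of methylated genes are routed to the IP fraction with the
pull-down efficiency (default 0.8), unmethylated molecules with the
background rate (default 0.05), and the remainder split evenly between the
RNA-seq and supernatant fractions; IP molecules of methylated genes are
placed inside the planted peak, everything else uniformly over exons.  PCR
duplication is geometric per molecule, and barcode corruption flips one
barcode base at the configured rate (generated barcode sets keep pairwise
Hamming distance ≥ 3, so one flip can never alias another cell under exact
matching).  Payload sequences are random DNA drawn to be unique per
molecule under both dedup key constructions and free of chance adapter
lookalikes, so trimming and deduplication are exact by construction.

What the generator does **not** emulate — isoform structure, sequencing
base errors inside payloads, quality-score variation, mappability, or
chromatin-driven coverage biases — bounds what passing tests show: they
validate the computational contracts of the pipeline (decoding grammar,
counting rules, statistical calibration, rule thresholds, determinism), not
robustness to alignment artifacts or biological confounders in real
libraries.

## Numerical conventions

Poisson tails use the exact survival function; −log₁₀ values are capped at
323 (the double-precision underflow boundary).  BH correction is the
standard step-up procedure.  Empty peak sets propagate as empty tables, not
errors.  Tests at fixed seeds cover every determinism contract; problem
sizes in the test suite (≈20–500 regions, 4–50 cells, 10⁴ reads) were
chosen as the smallest scales at which the statistical properties under
test are stable.
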