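# Methods

## Coordinate model

All intervals are 0-based half-open on named contigs; 1-based closed GTF
spans are converted at the I/O boundary and nowhere else. A `SplicedRegion`
is an ordered list of non-overlapping exonic blocks (ascending genomic
start) plus a strand; transcript position 0 is the 5'-most base of the
mature RNA — the leftmost genomic base on `+`, the rightmost on `-`.
Transcript→genome mapping of an interval returns genomic blocks in
ascending order whose lengths sum to the interval length; a motif crossing
an exon junction therefore occupies more than one block. Genome→transcript
mapping is the exact inverse on exonic bases and rejects intronic ones.

`interval_gap` counts the bases strictly between two intervals: overlap
and book-ended adjacency are both distance 0. This makes the proximity
rule unambiguous: "fewer than 20 nt" means 0–19 intervening bases.

## 3'UTR model

Explicit `three_prime_utr` features are used verbatim when present;
otherwise the UTR is the exonic territory strictly 3' of the annotated CDS
end in transcript orientation (genomic right of the CDS on `+`, genomic
left on `-`). The CDS end is taken exactly as annotated, with no ±3
stop-codon adjustment — fixtures and annotations are interpreted the same
way. Transcripts with neither UTR features nor a CDS are skipped with a
logged warning. Every isoform is scanned independently and results carry
`transcript_id`; gene-level summaries take the union across isoforms,
which is the conservative choice when no canonical-isoform policy exists.

Spliced RNA is produced by concatenating block sequences in genomic order,
reverse-complementing for `-`, transcribing T→U, and mapping any
non-ACGT base to N (N never matches a motif).

## QRE scanning

The core `ACUAA` is matched exactly; every occurrence is reported,
including overlapping ones, because the count is a plain 5-mer count with
no exclusion rule. The `UAAY` half-site is annotated as the nearest match
starting within `half_site_max_gap` nt (default 20 — a deliberate choice,
exposed as a flag, since no canonical gap is defined) downstream of the
core, but it is metadata only: validation and proximity key on the core.

## miRNA site filter

A site survives when (a) its miRNA's expression is at or above the
`1 − top_fraction` quantile (default: the median, i.e. top 50%) of **all**
expression values in the supplied miRNA table — ties at the threshold are
kept, which also makes the all-equal table pass everything — and (b) its
mirSVR score is **strictly** below the cutoff (default −1.0; a score of
exactly −1.0 fails). The reference population for the quantile is the
whole table, not just miRNAs with sites, because that is reproducible from
the expression file alone; the quantile uses linear interpolation, so with
2n distinct values and top fraction 0.5 exactly the n highest-expressed
miRNAs pass. miRNAs absent from the table fail the expression criterion
(logged), rather than raising. When the table has several sample columns
the per-miRNA value is the row mean unless `expression_column` picks one.

Clustering of sites is single linkage with gap ≤ `max_gap` (default 0,
i.e. touching or overlapping), per contig.

## eCLIP validation

A hit is supported by a replicate when any genomic block overlaps any peak
of that replicate by ≥ 1 bp, ignoring strand (narrowPeak strand is usually
'.'). Default `min_replicates` is 1; support in both duplicates is
reported per replicate as columns rather than enforced, so the stricter
view is one flag away.

## Proximity scan

Pairs are restricted to features annotated to the same gene: cross-gene
genomic coincidences are noise for the masking question. The distance is
the minimum `interval_gap` between any QRE block and the site interval
(genomic mode, default) or the gap in transcript coordinates (spliced
mode, available when the site lies fully within the same spliced UTR —
otherwise the pair is skipped with a logged reason). Within one UTR exon
the two measures coincide, which the test suite asserts on the synthetic
fixture. The threshold is strict: distance 20 is excluded.

## Regulation calls

`log2_fold_change(a, b, pc) = log2((a + pc) / (b + pc))` with pseudocount
default 1 for count data (0 is allowed for intensity data; both-zero with
pc = 0 is an error). Direction calls use an inclusive threshold:
Up when log2FC ≥ 0.4, Down when ≤ −0.4. The ±0.4 default is the
conventional arbitrary threshold for n = 1 comparisons where no test
statistic is available; it is read as a symmetric bound on the log2 scale.
Consensus over one gene's per-dataset calls is the direction reaching
`min_support` (default 2 of 3); the conflict flag is set whenever both
directions appear. If both directions independently reach support
(possible at `min_support` = 1) no consensus is declared. A significance
marker per call is carried as metadata but never used by the consensus
rule, which is direction-only. Detectability is a strictly positive value
in at least one sample.

The packaged worked example (`data/ngc_call_matrix.tsv`) is a 17-gene NGC
panel with calls from one RNA-seq and two microarray differentiation
datasets; the consensus caller yields 9 Up and 8 Down genes from it, and
both the test suite and the acceptance script recompute that.

`qki_correlation` is a plain Pearson correlation with two-sided p
(scipy), guarded against n < 3 and constant vectors.

## Synthetic fixtures

The generator emulates the structure the analysis assumes, not raw reads
or realistic eCLIP signal shapes. Defaults (the study conditions used by
tests and the acceptance script): 20 genes tiled on one contig with 500 nt
spacing, 2–4 exons each, about half on the minus strand, 300 nt CDS,
3'UTRs of roughly 200–380 nt split across all exons; 3 planted proximal
genes whose validated QRE lies 4–19 nt (uniform) from a strong site
(mirSVR in [−2.5, −1.3], miRNA drawn from the top expression half), the
first of them with the QRE straddling an exon junction (2|3 split); one
decoy gene per failure class — distance 25–40 nt, miRNA from the bottom
expression half, mirSVR in [−0.9, −0.3], and no peak; 3 extra peak-less
QREs and 3 extra far sites in background genes; 30 miRNAs with distinct
log-normal expression values; 2 eCLIP replicates covering each
to-be-validated QRE (coverage probability 1.0 by default, flanks 8–25 nt)
plus 4 intergenic noise peaks per replicate.

UTRs of genes that carry planted QREs are sanitised: accidental `ACUAA`
occurrences are destroyed by mutating one base to G (which can never
create a new core), so the truth for engineered genes is exact by
construction — without this, a chance background motif inside a decoy
gene's peak could form a legitimate-but-unplanted pair and break the
planted-recovery guarantee. Background genes keep their natural sequence;
their occurrences are recorded in the truth table by an independent regex
scan, so scanner tests can distinguish "planted" from "correct".

Expression tables: three pseudo-datasets (one RNA-seq-like with n = 1
integer counts, two microarray-like with n = 3 intensities) built as
baseline × 2^(planted log2FC) with multiplicative log-normal noise
(σ = 0.1 by default); `fc_effects` accepts per-gene scalars or
per-dataset dicts so partial-support consensus scenarios are expressible.
The patient/sibling pair plants a half-expression deficit on the proximal
genes and on a QKI row in both cell states.

Identical configurations produce byte-identical files; all randomness
flows from a single integer seed.

## What passing tests show — and what they do not

The fixtures exercise coordinate arithmetic, junction handling, every
filter boundary and every rejection stage with known truth, but they are
idealised: peaks are planted exactly over QREs, sites sit in single exons,
expression noise is mild and log-normal, and there is no mapping error,
batch effect or annotation ambiguity. Recovery of planted features at
precision = recall = 1.0 therefore validates the logic, not performance on
real eCLIP/microarray data, where peak calling noise and isoform
uncertainty dominate. The tool never downloads public accessions; real
datasets are supplied as local files in the documented formats.

## Numerical and interface choices

Quantiles use numpy's linear interpolation; ties at thresholds are
inclusive where documented above. Reports are TSV with `#` metadata lines
(tool version, parameters); the run manifest echoes every parameter
verbatim and records SHA-256 checksums of all inputs and per-stage feature
counts. The CLI (click) exposes each stage as a subcommand with YAML
config files; precedence is CLI flag > file > default. Output ordering is
deterministic everywhere (gene symbol, transcript, coordinates), so
re-running a configuration reproduces reports byte for byte; only the
manifest carries a timestamp.

## Problem sizes

The default test and acceptance runs use 20-gene fixtures, 1000-case
oracle sweeps for the scanner and the coordinate mapper, and 50-pair
correlation samples — sizes at which every quantity is recomputed from
scratch in seconds while still covering both strands, junctions and every
decoy class.
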