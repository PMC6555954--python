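# Methods

This note documents the models, procedures and numerical choices behind
`ribocodon`, what the synthetic-data generators do and do not emulate, and
the limitations a user should keep in mind.

## Coordinates and genetic-code conventions

All coordinates are 0-based half-open (BED convention), in transcript space.
DNA alphabet (T, not U) is used throughout, including tRNA references, to
match sequencing reads. The standard genetic code is taken from the NCBI
table; "degeneracy" of a codon is the size of its synonymous family sharing
the first two bases (4 for GCN-Ala, 2 for AAY-Asn, 1 for ATG/TGG). The
hetADAT codon sets are the nnC, nnT and nnA codon boxes of the eight
inosine-modified isotypes (Ala, Arg, Ile, Leu, Pro, Ser, Thr, Val); the
eight nnC codons are the inosine-dependent set used for the
translation-efficiency analysis.

Stop codons are counted in the 64-entry codon vector by default because the
ribosome-site analysis needs them (termination pausing is the built-in
positive control); `include_stops=False` gives amino-acid-level summaries
over the 61 sense codons. Codons containing N are skipped, never imputed, so
frequency denominators stay unbiased.

## Ribosome-site occupancy

A ribosome protects at least nine codons; we number them −5…+3 with 0 the
A-site, −1 the P-site, −2 the E-site. On an in-frame read the P-site codon
occupies read nt 12–14 and the A-site nt 15–17 (0-based). These two facts
are mutually consistent only with 0-based indexing, which fixed the
convention.

**Frame calibration.** 5′-end frames differ between read lengths within one
library, so each length is calibrated independently: 5′ ends falling in
codon positions −7…+32 around the TIS are tallied per frame, both in total
and as per-codon majorities. A length is *selected* when a single frame wins
both tallies and is at least five-fold above the runner-up in each;
otherwise it is excluded (mixed periodicity). The winning frame g implies a
5′ trim of (3 − g) mod 3 nt that restores the P-site to read nt 12–14.
Per-codon majority ties break to the lowest frame (they occur only at
negligible counts). Human-type data can bypass detection with forced
lengths 27–29, frame 0, matching the canonical 12-nt P-site offset.

**Extraction.** A read is used when its length was selected, mapping
quality ≥ 20, CDS overlap ≥ 50% of the read, and its 5′-end frame matches
the expected frame for its length; after trimming, read nt [0, 27) are split
into the nine codons. Each used read contributes exactly one codon per
position — reads too short after trimming, or containing ambiguous bases in
the window, are discarded (tallied), keeping column sums identical across
positions. The overlap filter is applied before the frame filter. Codons
beyond the CDS boundary (UTR triplets near start/stop) are counted as read:
they are part of the protected window.

**Normalization.** Per position, counts become fractions; each codon's
fraction is divided by its mean fraction across the nine positions. By
construction each codon's nine normalized values average exactly 1; codons
never observed are reported missing (NaN), not zero. Flank positions
(−5…−3, +1…+3) are not tRNA-bound and act as a negative control: their codon
fractions track the expression-weighted codon distribution of the
transcriptome (weighting genes by expression only — footprints per gene
scale with expression, so gene length does not enter). Two boundary effects
are inherent and reproduced exactly by the closed-form oracle: the start
codon is enriched at negative positions (every CDS begins ATG, and A-site-
at-start reads fail the 50% overlap filter), and 3′-flank concordance is
slightly diluted by UTR triplets entering the +1…+3 window for reads near
the stop.

**Differential codon usage.** Per (codon, position), normalized values are
compared between conditions across biological replicates with Welch's
unequal-variance two-sided t-test (a pooled-variance switch exists;
Welch is the default as the more conservative choice for 4v4 replicate
designs), followed by Benjamini–Hochberg step-up across all tested pairs.
Degenerate inputs are handled explicitly: both groups constant and equal →
p = 1; both constant but unequal → smallest positive p, flagged. The log2
fold change is condition B over condition A. Pooled-replicate matrices are
available for display, but tests always use per-replicate matrices.

## Wobble-inosine quantification

Inosine pairs most strongly with C and is read as G by reverse
transcriptase, so the A34I level of a tRNA is the G fraction at the
anticodon wobble position in aligned reads. The wobble position is located
through the annotated anticodon offset — recomputed after intron splicing
and verified against the annotated anticodon — rather than a fixed absolute
coordinate, because tRNA lengths vary. Mature references are built by
splicing annotated introns and appending the CCA tail when absent.

The per-tRNA estimate is G/(A+C+G+T) at the wobble base; tRNAs at or below
the depth cutoff (10 reads) are excluded from the reported per-tRNA
distribution but still contribute to the sample aggregate, which is total G
over total depth across hetADAT-substrate tRNAs — identically the
read-weighted mean of per-tRNA fractions. No background-error subtraction
is applied; under a uniform per-base error ε the estimator is inflated by at
most ε/3 (each erroneous base turns into G with probability 1/3), which the
simulator-based tests characterize at ε = 0.01. Condition comparisons report
per-tRNA and per-isotype deltas of replicate-mean fractions and, when both
conditions have ≥ 2 replicates, a two-sided t-test on per-sample aggregates.

## Enrichment and GO PCA

Gene-set summaries are unweighted means of per-gene relative-frequency
vectors (a pooled, codon-count-weighted variant is available behind a
flag). Amino-acid-level enrichment sums synonymous codon frequencies per
gene before averaging. Stability-class enrichment takes an external codon →
class map (the published zebrafish-derived classification is an input file,
not reproduced here; tests use a synthetic map) and compares per-gene class
frequencies between gene sets with a two-sided rank-sum test, BH-adjusted
across classes — chosen for robustness since per-gene class frequencies are
bounded and skewed.

GO profiles average codon frequencies per term (default minimum 40 genes
per term after dropping genes without vectors). The PCA standardizes codon
columns to zero mean and unit variance — equivalent to eigen-decomposition
of the correlation matrix — dropping zero-variance columns; the first
component's sign is oriented so its scores correlate positively with
term-mean AT3 (1 − GC3), and later components get a deterministic
largest-loading-positive orientation. Under a GC3 gradient, PC1 separates
terms by third-base GC and the eight nnC codons load together with the
four-fold-degenerate nnG codons, whose usage rises with GC3 the same way.

## nnC translation-efficiency classes

The per-gene nnC fraction is thresholded at a percentile of the gene
universe (default 99th, linear-interpolation percentile; membership is
strict `>`). Ribosome-occupancy change independent of mRNA level is
δ = ribo log2FC − RNA log2FC; genes are classed higher (δ > log2 fold),
lower (δ < −log2 fold) or similar, with fold = 2 by default. The class
distribution of the nnC-high set is compared to the remaining genes
(disjoint comparison by default; a flag includes the high set in the
background) with a chi-square test on the 2×3 table, plus per-class
two-proportion follow-ups, BH-adjusted; a Fisher-style exact variant exists
for small sets. Classification is invariant to adding a constant to both
fold-change columns.

## Synthetic data: what it emulates

All generators are deterministic functions of (config, seed); identical
inputs give byte-identical outputs.

**Transcriptome.** Each gene is ATG + sense codons + one stop, flanked by
random UTRs (5′ 20–50 nt, 3′ 15–40 nt — long enough that any nine-codon
window fits on the transcript). Synonymous choice follows a per-gene
planted GC3 parameter: codons are drawn from the 61 sense codons with
third-base weight gc3 for G/C-ending versus 1 − gc3 for A/T-ending, so
realized GC3 tracks the planted value (r ≈ 0.98 at n = 500). Gene lengths
are uniform over 100–400 codons by default.

**Footprints.** Reads are placed positionally, not kinetically: a gene is
drawn proportional to expression, the A-site codon within the gene
proportional to the planted per-codon A-site dwell weight (times the P-site
weight of the preceding codon when configured) — occupancy ∝ dwell is
exactly the assumption the site statistic tests, so recovery is directly
interpretable. Read length and 5′ frame offset follow a configurable table
(defaults: 27/28/29 nt at 30/50/20%, frame 0; stop codons dwell 4×). The
P-site dwell knob exists because differential-usage validation plants
P-site shifts. A closed-form oracle (`expected_site_fractions`) computes
the exact expected positional codon fractions under the model, including
the overlap-filter pass probability per (A-site, length, frame) combination
and UTR codons entering the window — the reference for recovery tests.

**tRNA reads.** A compact gene set (two isodecoders per hetADAT isotype
with wobble A, two G34 controls, two genes carrying short introns) is built
into mature references; each read copies its reference, flips the wobble A
to G with the planted per-tRNA rate θ, then applies uniform per-base error.
Planted θ defaults to Uniform(0.6, 0.9), the biologically observed range.

**DE and TE tables.** Differential-expression tables are simulated directly
(gene, log2FC, adjusted p) with a configurable DE fraction and effect-size
range, optionally coupling log2FC to GC3 to plant the GC–expression
association. TE tables plant exactly 1% nnC-high genes and a configurable
odds multiplier for the "higher" class among them; baseline two-fold TE
shift rates are 14% per direction, set by a power analysis of the intended
detection task (a 2×3 chi-square on ~50 nnC-high genes at 3× odds needs
baseline rates of this order for reliable detection; such rates are
plausible for a strong differentiation contrast with unshrunk fold
changes).

**What is not emulated.** Base-quality models, PCR duplicates, multimapping,
genome-space alignment and splicing, kinetic elongation (no ribosome
traffic/collisions), tRNA charging, and isoform structure (one CDS per
gene). UTR base composition is uniform, which slightly dilutes 3′-flank
concordance relative to real isochore-correlated UTRs. Passing tests
therefore demonstrate correctness of the statistics under the positional
occupancy model, not robustness to alignment artefacts or library-prep
biases.

## Problem sizes in the validation suite

The recovery tests run at desk scale, chosen to give comfortable
statistical margins: 2,000 genes / 500k footprints for dwell recovery (all
well-measured codons within ±0.15 log2 of the oracle), 800k footprints for
the uniform-dwell normalization checks (≥500 counts per position for
included codons), 4v4 replicates of 100k footprints for the planted P-site
shift (depth chosen so the planted ×1.3 shift clears BH decisively while
the small renormalization-induced counter-shifts, real properties of the
model at ~−0.05 log2, stay below threshold), 20 repetitions of 4v4 null
comparisons at 15k footprints for the false-positive rate, and 4 replicates
of 500 reads/tRNA for inosine recovery (replicate-mean per-tRNA error
< 0.03, ~3 binomial SD).

## Known limitations

- The five-fold frame rule needs adequate TIS-window coverage; sparse
  libraries mark lengths "no data" rather than guessing.
- The inosine estimator does not separate true A34I from other A→G sources
  (e.g. misincorporation at neighbouring modified bases); it counts only
  the annotated wobble position, and sequencing error adds a small known
  upward bias.
- The chi-square TE enrichment test is approximate for very small nnC-high
  sets; the exact variant is preferable below ~30 genes.
- Normalized occupancy values for boundary-constrained codons (ATG at
  negative positions; stops at positive positions) reflect CDS geometry as
  well as dwell, and should be interpreted against the positional oracle,
  not against 1.
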