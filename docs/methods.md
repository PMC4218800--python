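# Methods

This note records the models, conventions and numerical choices behind
mirforge, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Read cleaning

The cascade order is fixed: 3′ adapter removal → junk screen → length
filter → collapse to unique tags → contaminant triage. Adapter removal
takes the insert upstream of the leftmost full adapter occurrence, falling
back to the longest suffix–prefix overlap of at least 6 exact bases
(configurable); reads with neither are removed ("3′ adapter not found").
The junk screen fires on ≥ 2 ambiguous bases, a homopolymer run of ≥ 7 A /
≥ 8 C / ≥ 6 G / ≥ 7 T, or a tandem repeat of a fixed 2-mer ≥ 10 units,
3-mer ≥ 6, or 4-mer ≥ 5. Whether the homopolymer thresholds count
consecutive or total occurrences is genuinely ambiguous in the upstream
convention; we count maximal consecutive runs by default and expose
`JunkRules(consecutive=False)` for the total-count reading. Clean inserts
are 18–25 nt inclusive.

Triage matches each unique tag as an exact substring (both strands)
against the reference sets rRNA, tRNA, snoRNA, snRNA, other RNA families
and repeats. A tag matching several classes is counted once under the
highest-priority class (family classes before repeats, in the order
above), but every matching class is retained on the tag for overlap
bookkeeping. In the filter report the "Rfam" row is the sum of the five
family rows — the same arithmetic the standard library-distribution table
uses — and "clean = raw − removals" holds exactly whenever the contaminant
classes are disjoint, which the generator guarantees and the tests assert.

## Folding engine and free energy

The default engine maximizes the number of nested base pairs (Watson–Crick
plus G:U, minimum hairpin loop 3 nt) by a Nussinov dynamic program,
vectorized per diagonal. The traceback is deterministic; ties prefer
leaving the 3′ base unpaired before pairing the outer ends, so a stem
embedded before a non-contributing flank folds identically with or without
the flank — a property the flank-window screen depends on, and one that a
"prefer pairing" tie-break violates by swallowing the flank into a
count-neutral long-range pair.

Free energy is assigned post hoc on the predicted pairs: Watson–Crick
nearest-neighbor stacking terms (37 °C values), a single softened constant
(−0.5 kcal/mol) for any stack involving a wobble pair, and coarse
loop-initiation penalties (+5 hairpin loop, +3 internal loop/bulge, +4
multiloop). The loop penalties matter: maximum-pairing structures of
random sequence are chains of short helices separated by small bulges, and
with stacking terms alone such chains routinely reach −15 kcal/mol,
making random 140-nt windows pass the energy criterion. With the
penalties, random background windows essentially never do, while genuine
contiguous stems lose only the one hairpin-loop term. The `fold()`
contract (sequence in, dot-bracket and kcal/mol out) is the only interface
downstream code uses, so a thermodynamic folder can replace the engine
wholesale.

## Hairpin metrics and the 11 criteria

The stem is the helix chain that closes the terminal loop nearest the
candidate mature (walking outward until a multiloop or the exterior).
Between consecutive chain pairs, an internal loop has `g5` unpaired bases
on the 5′ side and `g3` on the 3′ side; the largest of either side over
all loops is the stem-bulge size. For mature-region metrics, `gm` is the
loop's unpaired overlap with the mature span and `go` the opposite side:
`min(gm, go)` bases are *errors* (opposed mismatches); a loop with
`gm > go` is a mature-*biased bulge* of `gm` bases, and the errors inside
such a loop are the "biased errors in one bulge". Mature pairs counts
paired mature nucleotides; percent-in-stem is the mature fraction lying
within the stem arms (the terminal loop excluded). These operational
definitions are one coherent reading of the upstream tool's terse
criterion names; they are exercised by a constructed suite in which each
criterion is violated in isolation.

Thresholds (defaults, all configurable): stem bulge ≤ 12; stem pairs ≥ 16;
ΔG ≤ −15 kcal/mol; hairpin length (up stem + loop + down stem) ≥ 50; loop
≤ 200; mature bulge ≤ 4; biased errors in one bulge ≤ 2; biased bulges
≤ 2; mature errors ≤ 4; mature pairs ≥ 12; mature in stem ≥ 80%. The
energy criterion's printed form ("kcal/mol ≤ 15") is sign-ambiguous; we
read it as a stability cutoff ΔG ≤ −15 and expose the threshold.

When both flank windows of a genomic hit pass, the lower free energy wins;
ties keep the downstream window. Tags hitting more than 20 loci are set
aside as repetitive. The maximum end shift in known-miRNA mapping defaults
to 4 per end — the largest offset observed in published variant names —
with one internal substitution; extensions are validated against the
precursor sequence when available.

## Expression

Normalization is counts per million of clean reads per library (constant
and base configurable). Without replicates, differential expression per
miRNA is a chi-squared goodness-of-fit of its counts against expectations
proportional to library totals; with replicate columns a one-way ANOVA on
log2(CPM+1) — counts without replicates cannot support ANOVA, which is how
we resolve "selectively using chi-squared and ANOVA". The Z-value is the
row-standardized normalized count, (x − mean)/sd with sd on n−1 degrees of
freedom (this reproduces the 1.5/−0.5 pattern of a single-library row);
the source analysis never defines its Z, so this is a documented
interpretation, not a claim about the original. Calls require p ≤ 0.01
and |Z| > 1. No multiple-testing correction is applied by default (an
optional Benjamini–Hochberg flag exists). Tissue partitioning assigns each
miRNA to the exact set of tissues with raw count ≥ 1 (threshold
configurable; exclusivity at one raw count is noise-sensitive on real
data).

## Degradome

Reads must begin with the `CAGCAG` 5′ adaptor; the insert is trimmed to
20 nt (the raw reads are 36 nt; the mapped tag length is our choice).
Tags map exactly, sense strand, to transcripts; each tag increments its
5′-most match position on every matching transcript (no fractional
multi-mapping). Complementarity scoring is gapless with penalties mismatch
1.0 and G:U 0.5, doubled at miRNA positions 2–13, cutoff 7.0 — the
convention of the standard plant degradome tool family, every penalty
configurable. The cleavage position is the transcript base paired to
miRNA position 10, the canonical plant slicing register. The category
median is computed over occupied positions only, matching T-plot peak
semantics. Scoring is invariant under reading the duplex from the other
strand for Watson–Crick and mismatch columns; G:U wobble is chemically
asymmetric under complementation, so exact reversal symmetry holds only
for wobble-free alignments.

## qPCR

2^−ΔΔCt with replicate Cts averaged per (sample, gene) before
differencing, an *actin7* reference gene by default, and the calibrator
fixed to 1 by construction. The simulator writes Ct as
`ct_ref − log2(fold) + gene offset + N(0, sd)`, so the noise-free table
inverts exactly.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a four-tissue plant small-RNA
study: per-tissue 36-nt FASTQ libraries of exact configured depth, planted
known and novel miRNAs at multinomial abundance (log-normal weights; a
configurable fraction tissue-exclusive, default 0.3), contaminant reads
drawn as exact substrings of generated reference sets, junk reads covering
all eight low-complexity rules, adapter-less reads, genomic contigs whose
planted loci fold into criteria-passing hairpins, a degradome with
per-category count profiles at planted cleavage positions, and Ct tables
with known fold changes. Defaults: 30 known miRNAs, 6 novel loci, 10,000
reads per library, contaminant/junk/no-adapter background ≈ 32% of each
library — proportions of the same order as the published library
distribution table, scaled to desk size.

Planted reads are made unambiguous under the pipeline's own rules: miRNA
inserts are rejection-sampled to pass the junk screen, avoid adapter
seeds, and be unreachable from any other reference under the
end-shift/1-mismatch mapping; precursors are verified at construction to
fold into exactly the intended structure under the package engine (the
hairpin contract explicitly defines "folds" by the module's engine); and
planted novel loci are re-verified through the actual flank-window
discovery path before being accepted into the genome. Flanks around
planted precursors are drawn from a two-letter (A/C) alphabet, which
cannot pair with itself and therefore cannot out-compete the planted
hairpin; background contigs are i.i.d. uniform ACGT. Degradome category
plans co-plant multiple sites per transcript only where the rules admit it
(shared maxima for category 1, sub-maximal peaks for 2/3, singletons for
4); a truncated plan stores its realized category instead. FASTQ qualities
are constant maximal — the pipeline filters on sequence content only.

What passing tests on this material do **not** show: robustness to
sequencing error or quality artifacts (none are simulated), to
heterogeneous real contaminant families (matching is exact by default,
configurable to 1 mismatch), to genome-scale multi-mapping, or to the
shallow, dispersed degradome signal of real tissue; and the folding engine
is a maximum-pairing approximation, not a thermodynamic model, so
criteria decisions near the energy threshold can differ from an MFE
folder on real loci.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 10,000-read
libraries (the published study's libraries are ~10⁷), 20–30 planted
miRNAs, 50 degradome sites on ~22 synthetic 300-nt transcripts, 1,000-row
null simulations, 2,000 length-9 sequences against the exhaustive folding
oracle, and 20 seeds for plant/recover properties. Headline counts of the
original study (hundreds of miRNAs) depend on its deposited sequencing
data and a specific miRNA reference release and are not reproducible at
these sizes; the package's claims are therefore plant/recover and
calibration properties plus the bundled curated target table.
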