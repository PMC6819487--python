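# Methods

## Problem and model

The package answers a localization question for a protein of interest
(POI) assayed by ChIP-seq on a contig-based genome: does the POI's
immunoprecipitated DNA accumulate in annotated genes or in the
intergenic space between them? The model is a per-region
ratio-and-threshold scheme, not a statistical peak model. For a region
*r* and a sample pair (INPUT, IP):

```
norm_input(r) = input_count(r) / clusters_pf_input
norm_ip(r)    = ip_count(r)    / clusters_pf_ip
E(r)          = norm_ip(r) / norm_input(r)          (undefined if norm_input = 0)
final(r)      = mean over replicates of [ E(r) − mean_untagged_E(r) ]
call:  final(r) ≥ threshold  (default 1.5, inclusive)
```

`clusters_pf` is the per-sample sequencing depth: the number of clusters
passing Illumina's Chastity filter, or interchangeably a total-sequences
count from the FASTQ or the number of primary mapped alignment records.
Because enrichment is a ratio of two normalized values, any common
rescaling of counts and depth totals cancels exactly (this invariance is
property-tested).

There is deliberately no significance model — no Poisson/negative
binomial test and no FDR. The mock-control subtraction (Filter 1) plays
the role of the background model; the fixed fold-change cutoff (Filter 2)
plays the role of the significance cutoff. The consequence is the
low-count caveat: a region with 2 INPUT and 10 IP reads yields E = 5 and
clears the cutoff while carrying almost no information. The
`min_input_reads` option attaches an advisory `low_input` flag to such
regions; it never removes them.

## Region derivation

Genic regions are GFF3 records selected by a *definition profile*:
`filter1` matches the feature type (column 3), `filter2` optionally
requires a substring of the attribute column, and `delim1/delim2/delim3`
cut the identifier and description out of the attributes. Profiles are
plain `key=value` files so the same machinery targets `gene`, `mRNA`, or
any other specifier in any organism's annotation; two editable examples
ship under `profiles/`. No parent/child hierarchy resolution is done and
strand is ignored — counting is strand-agnostic. A record whose
attributes resist the delimiters falls back to a positional
`contig:start-end` identifier with a warning rather than aborting a
whole-genome run.

All coordinates are 1-based inclusive throughout (the GFF3 convention);
only the BED writer and pysam call sites convert to 0-based half-open.

Intergenic regions (IGRs) are derived per contig from the genes sorted by
start position:

- raw gap of an adjacent pair = `next_start − prev_end`;
- pairs with raw gap ≥ 0 emit `[prev_end+1, next_start−1]` (the
  *exclusive* convention, so an IGR never shares a base with its
  bounding genes); gaps of 0 or 1 emit *degenerate* zero-base regions,
  kept by default so the inventory matches the gap rule, removable with
  `drop_empty`;
- pairs with raw gap < 0 (overlapping annotations) emit nothing and are
  collected into the negative-gap report — overlaps are deliberately not
  merged first, so annotation pathologies stay visible;
- a leading region `[1, first_start−1]` is emitted when the first gene
  starts at position ≥ 2, a trailing region `[last_end+1, contig_len]`
  when the last gene ends early, and a gene-less contig yields one
  whole-contig region.

A `bounds="touching"` compatibility mode emits `[prev_end, next_start]`
instead, for comparing against inventories produced under the
boundary-sharing reading of "starts at the end of a gene". On
non-overlapping annotations the exclusive convention makes genic plus
non-degenerate intergenic bases an exact partition of every contig,
which is tested against a brute-force boolean-mask complement. IGRs are
recomputed from the annotation on every run (never cached) so annotation
updates propagate immediately.

One caveat discovered while testing: "adding a gene never increases
intergenic bases" holds only for genes that do not overlap existing
ones. Under the no-merge rule, a gene nested inside another can move a
flank inward and enlarge a boundary region; the property test therefore
restricts insertions to annotation gaps.

## Counting

A region's count is the number of mapped alignment records whose
reference span (CIGAR-derived; soft clips do not extend it) overlaps the
region by at least one base. Defaults are intentionally naive — every
mapped record counts, including secondary, supplementary and duplicate
records — mirroring plain region-query record counting; `primary_only`,
`exclude_duplicates`, `min_mapq` and `count_unit="template"` (count
distinct read names, for paired-end data) tighten this. A read
straddling two adjacent regions counts once in each. Degenerate regions
always count 0. BAM files must be coordinate-sorted and indexed; plain
SAM is supported through a one-pass in-memory scan meant for small files
and fixtures. Counting can be threaded over region chunks with one file
handle per worker; outputs are identical for any worker count.

## Filters and summary

Filter order is fixed: enrichment → untagged subtraction → replicate
averaging → threshold. Since subtraction is linear, subtract-then-average
equals average-then-subtract (asserted by a test). The untagged
background of a region is the mean of its defined enrichments across
untagged replicates, 0 when none defines it; with no untagged samples at
all the pipeline runs in "arbitrary cutoff" mode where Filter 1 is
skipped. A region undefined (zero normalized INPUT) in any tagged
replicate stays undefined and fails both filters; the `pseudocount`
option adds ε to both normalized values instead, making every ratio
defined. `pass_filter1` records that the averaged enrichment is defined
and survives the background subtraction with a positive value;
`pass_filter2` that the final value clears the threshold. For any
positive threshold, passing Filter 2 implies passing Filter 1.

The compartment summary reports, per compartment (genic, intergenic),
the regions passing both filters and the summed mean normalized IP
signal over those passing regions, with cross-compartment fractions of
each (the localization readout). The sum over *all* regions is reported
in a separate column (`norm_ip_total`) because the source spreadsheet
convention is ambiguous on this point; the fractions use the
passing-region sums.

## Comparison panel

`paired_comparison` reproduces the spreadsheet "paired two sample for
means" panel for two matched percentage vectors: sample (n−1) variances,
Pearson r, t = mean(d)/(sd(d)/√n) with df = n−1, one/two-tailed p-values
and critical values at α (default 0.05) from the t distribution
(scipy). Zero-variance differences give t = 0 (zero mean) or a signed
infinity marker. The implementation is the closed-form formulas;
`scipy.stats.ttest_rel` serves as an independent cross-check in the
tests, not as the implementation.

## Synthetic data generator

The fixture module emulates the experimental design the pipeline
targets: single-end fixed-length reads (default 66 bp), an INPUT and an
IP sample per strain, optional untagged INPUT/IP pairs, and per-region
planted read counts — fixed integers for exact end-to-end checks or
Poisson rates for statistical ones (sampled once, at generation time;
the truth table records the sampled counts). Reads are placed uniformly
at random wholly inside their target interval and written directly as
sorted, indexed BAM plus SAM and gzipped FASTQ; a target shorter than
the read length with a nonzero planned count is a plan error.
`make_untagged_background` extends a plan with an untagged pair that
mirrors the tagged INPUT everywhere and shares the elevated IP rate at
designated "sticky" (nonspecifically binding) targets, so the mock
subtraction removes them downstream while targets enriched only in the
tagged sample survive.

What the generator does **not** emulate: sequencing errors, GC/fragment
biases, mappability structure, multi-mapping ambiguity, or a real
aligner round-trip (coordinates are written directly, and sequence
content is i.i.d. uniform ACGT). Passing tests therefore demonstrate the
correctness of region derivation, counting arithmetic and filter logic —
not robustness to alignment artifacts in real libraries.

Default study conditions in the shipped plans: depth denominators of
10⁶ (minimal/edge-case plans) or 2×10⁷ (the low-count worked example,
a realistic clusters-PF magnitude for a HiSeq lane share), baseline
planted counts of ~50 reads per kilobase-scale region, 10× elevation
for bound or sticky regions, and Poisson checks at an expected INPUT
depth of 5,000 reads per region over 200 regions and three seeds — a
size at which the ratio estimator's relative error is below 10% for at
least 95% of regions, while the whole suite stays interactive
(~3 seconds).

## Numerical and design choices

- Undefined enrichment is NaN end-to-end; flags treat NaN as fail.
  No silent pseudocounts.
- The threshold comparison is `>=` (boundary inclusive): 1.5 passes.
- Averaging replicates propagates NaN (a region undefined in any
  replicate is undefined in the mean) and logs how many regions this
  affected.
- Duplicate region identifiers are tolerated and logged; regions are
  keyed by (contig, start, end, id) internally.
- Output CSVs carry `#`-prefixed header lines with the package version
  and a hash of the fully resolved configuration; reruns with the same
  inputs are byte-identical.
- CLI exit codes: 0 success, 1 usage error, 2 data/configuration error.

## Limitations

- No peak calling, coverage profiles or per-base pileups; the unit of
  inference is the annotated region.
- Counting paired-end data as records double-counts proper pairs unless
  `count_unit="template"` is chosen.
- The 1.5 cutoff is a convention, not a fitted quantity; sensitivity to
  it should be explored with `--threshold`.
- Published region inventories for full-size genomes can depend on the
  boundary convention and degenerate-region handling; the
  `--igr-bounds`/`--drop-empty` flags exist to probe exactly that
  (see `scripts/external_validation.py`).
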