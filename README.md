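# chipcompart

ChIP-seq localization analysis for contig-based genomes: where does a
protein of interest (POI) sit — inside annotated genes, or in the
intergenic space between them?

Peak callers assume reasonably contiguous assemblies and well-behaved
background models. For organisms whose genomes exist only as thousands of
contigs/scaffolds with a flat gene annotation (ciliates such as
*Tetrahymena thermophila* or *Oxytricha trifallax* are the motivating
cases), a simpler and more transparent question is often the right one:
for every annotated gene, and for every gap between genes, how many
immunoprecipitated reads accumulate relative to the input DNA? This
package implements that analysis as a tested library plus a command-line
tool.

## The method

For each region *r* (an annotated gene, or a derived intergenic region)
and each sample pair:

- normalized count = raw reads overlapping *r* divided by the sample's
  sequencing depth ("clusters PF", the clusters passing Illumina's
  Chastity filter, or an equivalent total-sequences value);
- enrichment  E(r) = normalized IP / normalized INPUT;
- **Filter 1**: subtract the mean enrichment of *r* across untagged
  (mock-control) samples, removing nonspecific pull-down;
- replicate enrichments are averaged;
- **Filter 2**: keep regions whose final value is **≥ 1.5** (inclusive).

Intergenic regions are recomputed from the annotation on every run: for
consecutive genes on a contig the raw gap is `next_start − prev_end`;
only gaps ≥ 0 yield a region (overlapping gene pairs are excluded and
reported), and contig ends contribute leading/trailing regions when no
gene touches them. Finally the passing regions and their normalized IP
signal are summarized per compartment (genic vs intergenic), which is the
localization readout.

## Worked example

Generate a small synthetic dataset (two contigs, three genes, planted
read counts, plus an untagged control pair) and run the whole pipeline:

```sh
chipcompart fixtures --seed 21 --preset minimal --outdir fx
chipcompart run \
  --gff3 fx/annotation.gff3 --genome fx/genome.fasta \
  --profile profiles/tetrahymena_thermophila.defn \
  --input fx/tag_input.bam --ip fx/tag_ip.bam \
  --clusters-pf tag_input=1000000 --clusters-pf tag_ip=1000000 \
  --outdir out
```

The `regions` stage reports (also logged into `out/run_metadata.txt`):

```
n_genic_regions=3
n_intergenic_regions=5
n_negative_gap_exclusions=0
```

and `out/genic_enrichment.csv` contains, per region, the normalized
counts, enrichment and filter flags. In this fixture gene `G1` carries
50 INPUT and 250 IP planted reads at equal depth, so its row shows
`enrichment = 5.0` and `pass_filter2 = True`, while `G2` (50 INPUT / 40
IP, enrichment 0.8) fails the 1.5 cutoff. `out/compartment_summary.csv`
then splits passing regions and normalized IP signal between the genic
and intergenic compartments.

A note on small counts: a region with 2 INPUT and 10 IP reads also
returns an enrichment of 5 and clears the threshold, while carrying
almost no information. The `--min-input-reads N` option adds an advisory
`low_input` flag for such regions (it never drops them).

The `compare` subcommand reproduces the spreadsheet-style paired
comparison of two localization-percentage vectors:

```sh
chipcompart compare 51,6,16,27 54,16,14,16
```

prints means (25, 25), sample variances (374, 374.6667), Pearson
correlation 0.89581514, paired t statistic 0 with df 3, and the 5%
critical values 2.35336343 (one-tail) / 3.18244631 (two-tail) — i.e. the
two vectors are strongly correlated with no mean difference.

## Layout

- `chipcompart.annotation` — definition profiles, contig tables, genic
  regions from GFF3
- `chipcompart.intergenic` — intergenic derivation + negative-gap report
- `chipcompart.counting` — per-region INPUT/IP read counting (pysam)
- `chipcompart.enrichment` — normalization, filters, compartment summary
- `chipcompart.stats` — paired t-test / Pearson comparison panel
- `chipcompart.fixtures` — synthetic genomes/alignments with ground truth
- `chipcompart.pipeline`, `chipcompart.cli` — orchestration and CLI

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations.
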