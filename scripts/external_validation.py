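#!/usr/bin/env python
"""Region-inventory validation against full-size public annotations.

This check is deliberately separate from the test suite: it needs the
published assembly/annotation files, which must be downloaded first (they
are not redistributed here).

Expected inventories:

- T_thermophila_June2014: 26,996 genic regions ("gene" profile) and
  27,780 intergenic regions, with 92 overlapping gene pairs excluded as
  negative gaps.
- Oxytricha_trifallax_022112: 24,885 genes and 43,326 intergenic regions.

Coordinate-convention flags may matter when matching published numbers
exactly: try ``--igr-bounds touching`` and/or ``--drop-empty`` if the
default exclusive-bounds inventory is off by the degenerate-region count.

Usage:
    python scripts/external_validation.py --gff3 T_thermophila_June2014.gff3 \
        --genome T_thermophila_June2014.assembly.fasta \
        --profile profiles/tetrahymena_thermophila.defn \
        [--igr-bounds exclusive|touching] [--drop-empty]
"""

from __future__ import annotations

import argparse

from chipcompart.annotation import (
    extract_genic_regions,
    load_definition_profile,
    read_contig_table,
)
from chipcompart.intergenic import derive_intergenic


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--gff3", required=True)
    parser.add_argument("--genome", required=True, help="FASTA or .fai")
    parser.add_argument("--profile", required=True)
    parser.add_argument("--igr-bounds", choices=["exclusive", "touching"],
                        default="exclusive")
    parser.add_argument("--drop-empty", action="store_true")
    args = parser.parse_args()

    profile = load_definition_profile(args.profile)
    contigs = read_contig_table(args.genome)
    genes = extract_genic_regions(args.gff3, profile, contigs)
    igrs, negatives = derive_intergenic(
        genes, contigs, bounds=args.igr_bounds, drop_empty=args.drop_empty
    )
    print(f"contigs:             {len(contigs)}")
    print(f"genic regions:       {len(genes)}")
    print(f"intergenic regions:  {len(igrs)}")
    print(f"negative-gap pairs:  {len(negatives)}")


if __name__ == "__main__":
    main()
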