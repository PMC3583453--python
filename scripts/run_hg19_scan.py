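#!/usr/bin/env python
"""Optional reproduction of the reference-genome (hg19) dinucleotide census.

This script is NOT part of the test suite: it needs a locally downloaded
hg19 FASTA (e.g. from the UCSC Genome Browser) plus, for the genic/exonic
partition, gene and exon BED files derived from UCSC annotations.  Expected
headline numbers for hg19 with the default configuration (threshold 5 units,
mature >= 10 units): 83,840 mature dinucleotide loci genome-wide, of which
823 are exonic, across 385 genes.

Usage:
    python scripts/run_hg19_scan.py --fasta hg19.fa --out-prefix scratch/hg19 \
        [--genes genes.bed --exons exons.bed]
"""

from __future__ import annotations

import argparse
from collections import Counter

from maturems import MATURE, ScannerConfig, annotate_loci, scan_pure_repeats
from maturems.io import read_fasta, read_genes_exons_bed, write_loci_bed, write_loci_tsv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fasta", required=True)
    parser.add_argument("--out-prefix", required=True)
    parser.add_argument("--genes")
    parser.add_argument("--exons")
    args = parser.parse_args()

    config = ScannerConfig()
    loci = []
    for seq_id, seq in read_fasta(args.fasta).items():
        loci.extend(scan_pure_repeats(seq, config, sequence_id=seq_id))
    mature = [l for l in loci if l.lifecycle == MATURE]
    write_loci_bed(mature, f"{args.out_prefix}.mature.bed")
    write_loci_tsv(mature, f"{args.out_prefix}.mature.tsv")
    print(f"{len(mature)} mature dinucleotide loci (>= 10 units)")
    print("by family:", dict(Counter(l.family for l in mature)))

    if args.genes and args.exons:
        features = read_genes_exons_bed(args.genes, args.exons)
        _, summary = annotate_loci(mature, features)
        print(
            f"genic {summary.n_genic}: {summary.n_intronic} intronic "
            f"({summary.pct_intronic_of_genic}%), {summary.n_exonic} exonic "
            f"({summary.pct_exonic_of_genic}%); "
            f"{len(summary.exonic_gene_ids)} genes carry exonic mature loci"
        )


if __name__ == "__main__":
    main()
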