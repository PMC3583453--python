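# maturems

Mature dinucleotide microsatellites — pure 2-bp tandem repeats of ≥ 10 units,
long enough that no single observed mutational event (≤ 4 unit deletion) can
push them back to or below the 5-unit threshold for microsatellite mutational
behaviour — are abundant in genomes, sit inside the exons of hundreds of
human genes, and mutate with a striking directional bias: in mismatch-repair
(MMR)-proficient somatic cells, expansions outnumber deletions, even though
DNA polymerases make mostly deletion errors.

`maturems` is a Python library for analysing this biology end to end:

* **Repeat scanning** (`maturems.scanner`) — detect maximal pure dinucleotide
  repeats in any FASTA, canonicalize motifs into the four rotation/
  reverse-complement families (GT/CA, TC/AG, AT/TA, GC/CG), and classify loci
  by lifecycle stage (`below_threshold` / `young_adult` / `mature`).
* **Genic context and enrichment** (`maturems.annotation`) — exonic /
  intronic / intergenic assignment against BED or GFF3 features, mapping of
  exonic loci to genes, and exact hypergeometric gene-set
  over-representation.
* **Forward-assay calculus** (`maturems.assay`) — the HSV-*tk*
  shuttle-vector arithmetic: mutant frequency `MF = mutants / total
  colonies`, mutation rate `MF / doublings`, microsatellite-specific rates,
  expansion/deletion class frequencies with zero-count bounds, Fisher-exact
  bias tests, rank tests over per-clone rates, polymerase error frequencies
  (background-subtracted, strand-summed) and the exponential error-rate vs
  length fit `EF(n) = a·e^{bn}`.
* **Slippage + MMR model** (`maturems.mmr`) — polymerase slippage creates
  insertion/deletion loops (nascent strand → expansion, template strand →
  deletion); (MutS, MutL) repair channels remove them per genotype; the
  expected surviving frequency is `e_class(n)·Π(1 − r_channel)`. Includes a
  seeded Monte Carlo twin and a convex bounded-least-squares fitter for the
  per-channel repair efficiencies, with the published [GT/CA]19
  genotype-panel data shipped as package data.
* **Synthetic data** (`maturems.synthetic`) — seeded generators for every
  input the pipeline consumes (genomes with certified planted repeats,
  gene/exon/term structure with planted enrichment, clone-level assay
  tables, MMR panels), each with an exact truth record.

A thin CLI (`maturems scan|annotate|enrich|rates|polfit|simulate|fit-mmr|
synth-*`) wraps the library for shell pipelines; `examples/` contains one
narrative script per capability.

## Worked example

Fitting the MMR channel model to the published [GT/CA]19 genotype panel
(`python examples/mmr_model_fit.py`):

```
polymerase anchor at n=19: expansion 0.0056, deletion 0.012 (deletion-biased in vitro)
fitted repair efficiencies (channel -> probability an IDL is removed):
  MutSa.MutLa  expansion r = 0.857
  MutSa.MutLg  deletion  r = 0.592
  MutSa.MutLg  expansion r = 0.000
  MutSb.MutLa  deletion  r = 0.986
  MutSb.MutLa  expansion r = 0.995
  MutSb.MutLg  deletion  r = 0.975
predicted expansion:deletion ratio by genotype (observed side of 1 in parentheses):
  LCL721          2.588  (>1)
  LCL1261        46.031  (>1)
  HCT116+chr3     0.163  (<1)
  HCT116          0.467  (<1)
```

Reading this: purified polymerase makes ~2× more deletion than expansion
errors at 19 units, yet the fitted channel model shows why repair-proficient
cells (LCL721) end up expansion-biased (2.6:1): template-strand IDLs
(deletion precursors) are removed with near-complete efficiency through
MutSβ- and MutLγ-containing channels, while nascent-strand IDLs escape more
often. Removing MutLα (LCL1261) lifts expansion repair and the bias explodes
(> 55:1); removing every MutL (HCT116) switches off all channels and the
cellular spectrum collapses onto the polymerase's deletion bias (ratio < 1).

The assay-calculus worked example (`python examples/mutation_rates_and_bias.py`)
prints, among other things:

```
median MS rate over 10 clones: 4.63e-06 (planted 5e-06; relative error 7.4%)
expansion MF 0.0072, deletion MF < 0.00013 (one-event bound), bias >55:1: ...
```

i.e. the frequency/doublings estimator recovers a planted microsatellite
mutation rate from simulated colony counts, and a spectrum of 55 sequenced
mutants with zero deletions yields the one-event deletion bound MF/55 and a
`>55:1` expansion bias.

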