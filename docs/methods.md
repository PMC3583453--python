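# Methods

`maturems` implements an analysis pipeline for *mature* dinucleotide
microsatellites: pure 2-bp tandem repeats long enough that no single observed
mutational event can drag them back below the length threshold at which
microsatellite mutational behaviour begins. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
data generators do and do not emulate.

## Repeat model and scanner

A dinucleotide microsatellite is a maximal *pure* run of a two-base motif
with distinct bases. Purity is absolute: one interrupting base terminates a
run (there is no interruption-tolerance parameter), and `N` or any other
non-ACGT character is a hard run breaker. Only complete units count: a
74-bp pure tract is 37 units, and a dangling single base extends neither the
unit count nor the reported interval. Coordinates are 0-based half-open
everywhere in the library and in BED output; GFF3 output converts to 1-based
inclusive.

Motifs are equivalence classes under cyclic rotation and reverse complement,
giving exactly four families — GT/CA and TC/AG (four motifs each), AT/TA and
GC/CG (two each, being self-reverse-complementary). Identical-base "motifs"
are mononucleotide runs and are rejected.

The scanner walks maximal period-2 tracts in linear time. A tract of odd
base length supports two phases with equal unit counts (e.g. `CACACAC` as
(CA)3 from offset 0 or (AC)3 from offset 1). Such a run is reported once, at
the phase whose motif is lexicographically smaller. This tie-break was
chosen over "leftmost phase" deliberately: complementation is
order-reversing on the ACGT alphabet, which makes the lexicographic rule the
unique simple rule under which scanning the reverse complement returns
exactly the same loci after coordinate mapping. Strand symmetry of reported
coordinates is asserted as a property test.

Lifecycle classification uses two parameters: the threshold `T = 5` units at
which dinucleotide tracts acquire microsatellite mutational behaviour, and
the largest single-event deletion `D_max = 4` units observed for
dinucleotide repeats. A locus is `below_threshold` if `units < T`, `mature`
if `units − D_max > T` (no single event can kill it), otherwise
`young_adult`. With the defaults, mature is exactly `units ≥ 10`.

The scanner is verified against a brute-force oracle that tests every
(position, motif) pair for purity and maximality directly; equivalence is
exact on random sequences and on generated genomes.

## Genic context and enrichment

A locus is *exonic* if it overlaps any exon by at least one base, *genic* if
it overlaps a gene span, *intronic* if genic but not exonic, *intergenic*
otherwise. Loci that overlap an exon boundary are counted as exonic and
additionally reported as straddlers. Context assignment uses interval trees
and is verified against a per-base membership-array oracle.

Term over-representation uses the exact upper-tail hypergeometric
probability `P(X ≥ observed)` (no normal approximation), with the expected
count `n_selected · K / N`. P-values are raw: the source analyses report
unadjusted hypergeometric p-values at a 0.01 cutoff, so no multiplicity
correction is applied. The universe is the full gene set of the provided
annotation; per-term conditional universes and ontology-graph-aware testing
are out of scope. Null behaviour (uniform p-values under label permutation)
is tested via the randomized probability integral transform, which handles
the discreteness of the hypergeometric exactly.

## Forward-assay calculus

For a clonal population, the mutant frequency is
`MF = mutant colonies / total colonies`, the mutation rate per cell
generation is `MF / doublings`, and the microsatellite-specific rate scales
the rate by the MS-indel share of the sequenced mutant spectrum. Across
clones, rates are summarized by the median (per-clone rate distributions are
heavily skewed). A multi-unit indel counts once toward directional-bias
proportions; its magnitude is kept for the deletion-size analysis.

Class frequencies decompose the MF by the spectrum:
`class_MF = MF · (class count / n_sequenced)`. A class with zero observed
mutants among `n` sequenced is reported as the standard one-event upper
bound `MF / n`, and the expansion:deletion ratio becomes a one-sided bound
(rendered `>55:1`). Ratios are presented with one decimal below 10 and as
integers at or above 10. Worked-example arithmetic on the published
[GT/CA]19 genotype panel (shipped as package data) reproduces the printed
ratios 2.6:1, >55:1, 1:6, 1:1.5 and 1:2 at that presentation precision.

Statistics: directional-bias comparisons use the two-sided Fisher exact test
with the probability-mass summation convention (all tables at fixed margins
with probability ≤ the observed table's), verified exhaustively against a
table-enumeration oracle for totals ≤ 30. Rate-distribution comparisons use
Mann-Whitney (two groups; exact when untied samples permit, tie-corrected
normal approximation without continuity correction otherwise — so identical
groups give p = 1) or Kruskal-Wallis (more groups). Deletion sizes are
binned into {1, 2, 3–4, ≥5} units and compared across alleles with a
chi-square homogeneity test (no continuity correction) on the non-empty
classes, flagging expected cells below 5.

Polymerase error frequencies subtract the single-stranded-DNA background MF
from the observed reaction MF, floored at zero with a warning; an allele's
MS error rate is the sum of its two complementary strand values and is
symmetric in strand order. Pooling across a strand's independent reactions
is by summed counts. The length dependence is fitted as
`EF(n) = a·exp(b·n)` by ordinary least squares of `ln EF` on `n`; `r²` is
computed on the log scale (the scale on which the model is linear and the
noise approximately multiplicative). Two distinct points determine the line
exactly (`r² = 1`); noiseless model data are recovered to numerical
precision.

## Slippage + MMR channel model

Polymerase slippage produces insertion/deletion loops (IDLs):
nascent-strand IDLs mature into expansions, template-strand IDLs into
deletions. Per-replication event probabilities are exponential in allele
length per class (`a·exp(b·n)`), with a deletion-size distribution over the
four size classes; at the frequencies involved (≪ 1) at most one event per
replication is assumed.

Mismatch repair is modeled as *channels*: (MutS, MutL) heterodimer pairings
with per-channel, per-class repair probabilities `r ∈ [0, 1]`. A channel
acts only when both heterodimers are functional in the genotype — hence a
genotype with MutSα protein but no functional MutL complex applies no repair
at all. Channels escape independently, so the expected surviving frequency
is `e_class(n) · Π (1 − r[channel, class])` over functional channels.
Whether the deletion-protective complexes act multiplicatively or
exclusively is not established; the independent-escape product is this
package's choice, being the least-assumption encoding of partial redundancy
between the MutL homologs.

The Monte Carlo simulator is the distributional twin of the closed form
(verified within exact 99.73% binomial bands across random parameter
sweeps at 10^6 replications; the exact band is used because a random sweep
can produce expected surviving counts of order one, where a ±3·SE normal
band is mis-calibrated). It is seeded, bit-reproducible, and conserves
replications across surviving / repaired / error-free outcomes.

### Fitting repair efficiencies

The fitter minimizes squared log10-frequency residuals over channel
efficiencies with box constraints, working internally on escape exponents
`x = −ln(1 − r) ≥ 0`, in which the model is log-linear and the problem
convex (solved with bounded least squares). Bound observations ("< f",
from zero observed mutants) are censored: they contribute loss only when
the prediction exceeds the bound.

A four-genotype panel cannot identify all four pairings per class — the
log-linear design has rank 3. The default estimated channel sets follow the
repair biology and are exactly the largest identifiable subsets for the
standard genotype panel: expansion repair through pairings containing MutSα
or MutLα (SαLα, SαLγ, SβLα), deletion repair through pairings containing
MutSβ or MutLγ (SαLγ, SβLα, SβLγ). Callers can override the channel sets;
channels functional in no supplied genotype are frozen at zero and flagged,
and rank deficiency of the supplied design is reported. Starting values
concentrate expansion repair in SαLα and spread deletion repair over the
MutSβ/MutLγ channels; the optimizer may move them freely, and with the
convex parameterization the fit is initialization-independent on
identifiable designs.

On noiseless generated panels the fitter recovers planted efficiencies
within 0.02. On the published [GT/CA]19 panel the fitted model places every
genotype's predicted expansion:deletion ratio on the observed side of 1 —
expansion-biased for the MutLα-proficient lymphoblastoid lines,
deletion-biased (polymerase-like) for both HCT116 lines. This sign-pattern
check, not a frequency-level match, is the acceptance property: whether
cellular and purified-polymerase event frequencies are quantitatively
commensurable is itself open, which is why an optional genotype-independent
scale factor on the polymerase deletion rate exists (off by default).

## Synthetic data generators

Every generator is a pure function of its parameters and one integer seed,
and emits a truth record sufficient to score pipeline output exactly.

* **Genomes.** Planted repeats are placed with ≥ 2 bp spacers; spacer bases
  are rejection-sampled so no unplanned alternating tract reaches the
  scanner's reporting floor and no spacer base extends a planted run or
  shifts its phase. Generated negatives are therefore certified negatives,
  and scanning reproduces the truth exactly (tested over many packings).
* **Annotations.** Genes with evenly spaced exons on a synthetic
  chromosome; terms draw member genes uniformly; the selected gene set is
  drawn without replacement with weight `factor` for planted-term members.
  At the default study-scale design (universe 400, term size 30, 60
  selected, factor 5) the planted term is detected at p < 0.01 in ≥ 90% of
  seeds.
* **Assay data.** Mutant colony counts are binomial at
  `MF = rate × doublings` and sequenced spectra multinomial — the sampling
  model of the frequency/doublings estimator itself. Jackpot
  (Luria-Delbrück) fluctuations are deliberately not modeled: the pipeline's
  estimator is the frequency estimator, and the generator matches its
  assumptions. This is a simplification relative to real clone-to-clone
  variance. Default regime: rate 5e-6 per generation, 25 doublings, 10^6
  colonies, 25 sequenced mutants, 10 clones — the scale of the source
  assays, where the median-of-clones rate lands within 25% of truth.
* **Deletion-size spectra.** The emulated contrast gives short alleles
  deletions that are almost exclusively single-unit (none ≥ 5 units) and
  long alleles a broader spectrum with ~25% ≥ 5-unit deletions — the
  observed regime; at ~25 deletions per allele the 3-dof chi-square detects
  this in ≈ 90% of simulations.
* **MMR panels.** Class frequencies from the closed form (noiseless) or the
  seeded simulator; a simulated class with zero survivors is emitted as the
  one-event bound `1/n_replications`, censored, mirroring real panels.

What passing these tests shows — and does not show. The generators match
the estimators' own sampling assumptions, so recovery tests validate the
calculus and its implementation, not robustness to real-data pathologies
(jackpot mutations, sequencing misclassification, impure or compound
repeats, chromatin context). The scanner handles any FASTA; reproducing the
reference-genome census requires only a local genome download (see
`scripts/run_hg19_scan.py`) and is not part of the test suite.

## Numerical and interface conventions

* TSV dialect: UTF-8, tab-separated, `#`-prefixed header, `.` for missing.
* All randomness flows through explicit integer seeds; no global RNG state.
* Efficiency cap in the fitter: escape exponents are bounded at 40
  (`1 − r ≥ e^{−40}`), indistinguishable from complete repair at double
  precision.
* Problem sizes in tests and in the acceptance script (10–20 kb scan
  sequences, 10^6 simulator replications, 50-seed power sweeps, Fisher
  enumeration to totals of 30) were chosen as the smallest sizes at which
  each property is statistically decisive.

## Known limitations

* Interrupted and compound microsatellites, and motif sizes other than 2,
  are out of scope (the tract walker generalizes, but only dinucleotides
  are specified and tested).
* Flat term sets only; no ontology-graph propagation or conditional tests.
* The MMR channel model ignores strand-discrimination signals (nick
  positioning) and replication-fork stalling/template-switch mechanics; it
  is a steady-state escape model, not a fork-dynamics model.
* Cross-system (cellular vs purified polymerase) frequency anchoring is an
  assumption, softened only by the optional deletion-scale factor.
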