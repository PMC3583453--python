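"""Ground-truth synthetic data generators for every pipeline input.

Each generator is a pure function of its parameters and an integer seed, and
returns both the dataset and a truth record sufficient to score any pipeline
stage exactly: genomes with planted pure dinucleotide repeats at known
positions (spacer sequence is rejection-sampled so that no unplanned run
reaches the scanner's reporting floor — generated negatives are certified
negatives), gene/exon structure with planted enriched term sets, clone-level
forward-assay colony counts drawn from the estimator's own sampling model
(binomial colony counts, multinomial sequenced spectra — deliberately not
jackpot-distributed, since the frequency/doublings estimator assumes the
binomial regime), and genotype-panel class frequencies drawn from the
slippage + MMR simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import Feature, TermAnnotation
from .assay import CloneAssay, MutantSpectrum
from .mmr import (
    DELETION,
    EXPANSION,
    MMRGenotype,
    PanelObservation,
    PolSlippageModel,
    RepairEfficiencies,
    expected_class_frequencies,
    simulate_replications,
)
from .scanner import (
    FAMILY_MEMBERS,
    RepeatLocus,
    ScannerConfig,
    classify_lifecycle,
)

__all__ = [
    "PlantedLocus",
    "EnrichmentSpec",
    "BiasSpec",
    "synth_genome",
    "synth_annotations",
    "plant_loci_in_exons",
    "build_sequence",
    "synth_assay_data",
    "synth_mmr_panel",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedLocus:
    """A repeat to embed: exact phase motif, unit count, fixed start."""

    start: int
    motif: str
    units: int


def build_sequence(
    length: int,
    placements: Sequence[PlantedLocus],
    rng: np.random.Generator,
    config: ScannerConfig | None = None,
) -> str:
    """Fill a sequence of ``length`` with the given repeats at fixed positions.

    Spacer bases are sampled one at a time with rejection so that (a) no
    unplanned alternating run reaches the scanner's ``min_units_report`` and
    (b) no spacer base extends a planted run or shifts its phase: the base
    before a planted ``(XY)u`` must not be Y and the base after must not be X.
    Placements need >= 2 bp of spacer between them and at least 1 bp from the
    sequence ends.  Raises on an infeasible packing.
    """
    config = config or ScannerConfig()
    cap = 2 * config.min_units_report - 2  # longest tolerated alternating tract (bases)
    ordered = sorted(placements, key=lambda p: p.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start - (prev.start + 2 * prev.units) < 2:
            raise ValueError("placements need >= 2 bp spacers between repeats")
    if ordered and (ordered[0].start < 1 or ordered[-1].start + 2 * ordered[-1].units > length - 1):
        raise ValueError("placements must leave >= 1 bp at the sequence ends")

    chars: list[str] = []
    # (prev2, prev1, run) where run = length of the alternating (period-2)
    # tract ending at the last appended base.
    prev2 = prev1 = ""
    run = 0

    def append_spacer(n_bases: int, forbidden_last: str | None) -> None:
        nonlocal prev2, prev1, run
        for t in range(n_bases):
            while True:
                c = _BASES[rng.integers(4)]
                if t == n_bases - 1 and c == forbidden_last:
                    continue
                if c == prev2 and c != prev1 and run + 1 > cap:
                    continue
                break
            new_run = run + 1 if c == prev2 else 2
            prev2, prev1, run = prev1, c, new_run
            chars.append(c)

    cursor = 0
    for placement in ordered:
        gap = placement.start - cursor
        if gap < 1:
            raise ValueError("infeasible packing: overlapping placements")
        append_spacer(gap, forbidden_last=placement.motif[1])
        chars.append(placement.motif * placement.units)
        prev2, prev1 = placement.motif[0], placement.motif[1]
        run = 2 * placement.units
        cursor = placement.start + 2 * placement.units
    append_spacer(length - cursor, forbidden_last=None)
    return "".join(chars)


def synth_genome(
    n_sequences: int,
    length: int,
    locus_spec: Sequence[tuple[str, int, int]],
    seed: int,
    config: ScannerConfig | None = None,
    min_gap: int = 6,
) -> tuple[dict[str, str], list[RepeatLocus]]:
    """Random genome with planted pure dinucleotide repeats of known truth.

    ``locus_spec`` lists (family, units, count) triples; each planted repeat
    gets a uniformly chosen member motif of its family and a random position.
    Returns (records, truth loci); scanning the records with the same config
    reproduces the truth exactly.
    """
    config = config or ScannerConfig()
    rng = np.random.default_rng(seed)
    todo: list[tuple[str, int]] = []
    for family, units, count in locus_spec:
        if family not in FAMILY_MEMBERS:
            raise ValueError(f"unknown family {family!r}")
        if units < config.min_units_report:
            raise ValueError(
                f"planted repeats must reach min_units_report={config.min_units_report}"
            )
        todo.extend([(family, units)] * count)
    assignment = rng.integers(n_sequences, size=len(todo))

    records: dict[str, str] = {}
    truth: list[RepeatLocus] = []
    for idx in range(n_sequences):
        seq_id = f"synth{idx}"
        mine = [todo[k] for k in np.flatnonzero(assignment == idx)]
        order = rng.permutation(len(mine))
        mine = [mine[k] for k in order]
        repeat_bases = sum(2 * units for _, units in mine)
        slack = length - repeat_bases - (len(mine) + 1) * min_gap
        if slack < 0:
            raise ValueError(
                f"infeasible packing: {repeat_bases} repeat bases + spacers exceed "
                f"sequence length {length}"
            )
        extra = (
            rng.multinomial(slack, np.full(len(mine) + 1, 1.0 / (len(mine) + 1)))
            if mine
            else np.array([slack])
        )
        placements: list[PlantedLocus] = []
        cursor = 0
        for k, (family, units) in enumerate(mine):
            cursor += min_gap + int(extra[k])
            members = sorted(FAMILY_MEMBERS[family])
            motif = members[rng.integers(len(members))]
            placements.append(PlantedLocus(start=cursor, motif=motif, units=units))
            cursor += 2 * units
        records[seq_id] = build_sequence(length, placements, rng, config)
        for placement in placements:
            truth.append(
                RepeatLocus(
                    sequence_id=seq_id,
                    start=placement.start,
                    end=placement.start + 2 * placement.units,
                    family=[f for f, m in FAMILY_MEMBERS.items() if placement.motif in m][0],
                    phase_motif=placement.motif,
                    units=placement.units,
                    lifecycle=classify_lifecycle(placement.units, config),
                )
            )
    truth.sort(key=lambda l: (l.sequence_id, l.start))
    return records, truth


@dataclass(frozen=True)
class EnrichmentSpec:
    """How strongly planted terms are over-represented in the selected set.

    ``factor`` multiplies a gene's selection weight when it belongs to a
    planted term; factor 1 is the null.
    """

    factor: float = 5.0
    n_planted_terms: int = 2
    term_size: int = 30
    n_selected: int = 60


def synth_annotations(
    n_genes: int,
    n_terms: int,
    spec: EnrichmentSpec,
    seed: int,
    sequence_id: str = "synth0",
    gene_length: int = 1200,
    n_exons: int = 3,
    exon_length: int = 150,
    intergenic: int = 300,
) -> tuple[list[Feature], list[TermAnnotation], frozenset[str], dict]:
    """Gene/exon features, term annotations and a selected gene set.

    Genes are laid head to tail on one synthetic chromosome, each with
    ``n_exons`` evenly spaced exons.  Every term draws ``term_size`` genes
    uniformly; the selected set of ``n_selected`` genes is drawn without
    replacement with weight ``factor`` for members of the planted terms, so
    planted terms are over-represented at the chosen factor.  Returns
    (features, terms, selected_genes, truth).
    """
    if spec.term_size > n_genes or spec.n_selected > n_genes:
        raise ValueError("term_size and n_selected must not exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{idx:04d}" for idx in range(n_genes)]

    features: list[Feature] = []
    step = (gene_length - n_exons * exon_length) // (n_exons + 1)
    for idx, gene in enumerate(genes):
        gstart = idx * (gene_length + intergenic) + intergenic
        features.append(Feature(sequence_id, gstart, gstart + gene_length, "gene", gene))
        for e in range(n_exons):
            estart = gstart + step + e * (exon_length + step)
            features.append(Feature(sequence_id, estart, estart + exon_length, "exon", gene))

    terms: list[TermAnnotation] = []
    for t in range(n_terms):
        members = rng.choice(n_genes, size=spec.term_size, replace=False)
        terms.append(
            TermAnnotation(
                term_id=f"T{t:03d}",
                term_name=f"synthetic term {t}",
                genes=frozenset(genes[g] for g in members),
            )
        )
    planted_ids = [f"T{t:03d}" for t in rng.choice(n_terms, size=spec.n_planted_terms, replace=False)]
    planted_genes: set[str] = set()
    for term in terms:
        if term.term_id in planted_ids:
            planted_genes |= term.genes

    weights = np.array([spec.factor if g in planted_genes else 1.0 for g in genes])
    weights /= weights.sum()
    selected = frozenset(
        genes[g] for g in rng.choice(n_genes, size=spec.n_selected, replace=False, p=weights)
    )
    truth = {
        "planted_terms": planted_ids,
        "factor": spec.factor,
        "n_selected": spec.n_selected,
        "universe": genes,
    }
    return features, terms, selected, truth


def plant_loci_in_exons(
    features: Sequence[Feature],
    selected_genes: frozenset[str],
    units: int,
    family: str,
    rng: np.random.Generator,
) -> list[tuple[PlantedLocus, str]]:
    """One mature repeat placement inside the first exon of each selected gene.

    Positions leave >= 3 bp of exon on both sides so the planted locus is
    unambiguously exonic.  Returns (placement, gene_id) pairs.
    """
    placements: list[tuple[PlantedLocus, str]] = []
    members = sorted(FAMILY_MEMBERS[family])
    done: set[str] = set()
    for feat in features:
        if feat.kind != "exon" or feat.gene_id not in selected_genes or feat.gene_id in done:
            continue
        span = feat.end - feat.start - 2 * units - 6
        if span < 1:
            raise ValueError("exon too short for the requested repeat length")
        start = feat.start + 3 + int(rng.integers(span))
        motif = members[int(rng.integers(len(members)))]
        placements.append((PlantedLocus(start=start, motif=motif, units=units), feat.gene_id))
        done.add(feat.gene_id)
    return placements


@dataclass(frozen=True)
class BiasSpec:
    """Sampling parameters of the sequenced-mutant classification."""

    p_expansion: float = 0.8
    deletion_size_probs: tuple[float, float, float, float] = (0.55, 0.20, 0.15, 0.10)
    non_ms_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_expansion <= 1.0:
            raise ValueError("p_expansion must be in [0, 1]")
        if not 0.0 <= self.non_ms_fraction < 1.0:
            raise ValueError("non_ms_fraction must be in [0, 1)")
        probs = np.asarray(self.deletion_size_probs)
        if probs.shape != (4,) or np.any(probs < 0) or not math.isclose(probs.sum(), 1.0):
            raise ValueError("deletion_size_probs must be 4 nonnegative values summing to 1")


def synth_assay_data(
    true_ms_rate: float,
    doublings: float,
    n_cm: int,
    bias: BiasSpec,
    n_clones: int,
    n_sequenced: int,
    seed: int,
) -> tuple[list[CloneAssay], dict]:
    """Clone-level forward-assay data at a planted microsatellite rate.

    The total mutation rate is the MS rate divided by the MS share
    (1 - non_ms_fraction); mutant colony counts are binomial at
    MF = rate x doublings, and each clone's sequenced spectrum is multinomial
    over (non-MS, expansion, deletion-by-size-class) with representative sizes
    3 or 4 for the '3-4' class and 5-8 for the '5+' class.
    """
    if true_ms_rate < 0 or true_ms_rate >= 1e-2:
        raise ValueError("true_ms_rate must be in [0, 1e-2) per generation")
    rng = np.random.default_rng(seed)
    ms_share = 1.0 - bias.non_ms_fraction
    total_rate = true_ms_rate / ms_share if true_ms_rate > 0 else 0.0
    mf = total_rate * doublings
    if mf >= 1:
        raise ValueError("implied mutant frequency >= 1")
    probs = np.concatenate(
        (
            [bias.non_ms_fraction, ms_share * bias.p_expansion],
            ms_share * (1 - bias.p_expansion) * np.asarray(bias.deletion_size_probs),
        )
    )
    assays: list[CloneAssay] = []
    for c in range(n_clones):
        n_mut = int(rng.binomial(n_cm, mf))
        counts = rng.multinomial(n_sequenced, probs)
        changes: list[int] = [1] * int(counts[1])
        for cls_idx, size_draw in ((2, lambda: 1), (3, lambda: 2),
                                   (4, lambda: int(rng.integers(3, 5))),
                                   (5, lambda: int(rng.integers(5, 9)))):
            changes.extend(-size_draw() for _ in range(int(counts[cls_idx])))
        assays.append(
            CloneAssay(
                clone_id=f"clone{c:02d}",
                n_fudr_cm=n_mut,
                n_cm=n_cm,
                doublings=doublings,
                spectrum=MutantSpectrum(tuple(changes), n_non_ms=int(counts[0])),
            )
        )
    truth = {
        "true_ms_rate": true_ms_rate,
        "total_rate": total_rate,
        "mf": mf,
        "p_expansion": bias.p_expansion,
        "non_ms_fraction": bias.non_ms_fraction,
    }
    return assays, truth


def synth_mmr_panel(
    pol: PolSlippageModel,
    efficiencies: RepairEfficiencies,
    genotypes: Mapping[str, MMRGenotype],
    n: int,
    seed: int,
    n_replications: int | None = None,
) -> tuple[list[PanelObservation], dict]:
    """Genotype x class frequency panel from the slippage + MMR model.

    With ``n_replications`` None the panel holds noiseless closed-form
    expectations; otherwise frequencies come from seeded Monte Carlo
    replication, and a class with zero surviving mutants is reported as the
    one-event upper bound 1/n_replications (censored), mirroring how a real
    panel reports an empty mutant class.
    """
    rng = np.random.default_rng(seed)
    panel: list[PanelObservation] = []
    for label, genotype in genotypes.items():
        if n_replications is None:
            e_exp, e_del = expected_class_frequencies(pol, genotype, efficiencies, n)
            freqs = {EXPANSION: (e_exp, False), DELETION: (e_del, False)}
        else:
            sim = simulate_replications(
                pol, genotype, efficiencies, n, n_replications, int(rng.integers(2**31))
            )
            freqs = {}
            for cls, count in ((EXPANSION, sim.n_expansions), (DELETION, sim.n_deletions)):
                if count == 0:
                    freqs[cls] = (1.0 / n_replications, True)
                else:
                    freqs[cls] = (count / n_replications, False)
        for cls, (freq, bound) in freqs.items():
            panel.append(
                PanelObservation(
                    genotype_label=label,
                    idl_class=cls,
                    frequency=freq,
                    is_bound=bound,
                    genotype_override=genotype,
                )
            )
    truth = {"efficiencies": efficiencies.as_dict(), "n": n}
    return panel, truth
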