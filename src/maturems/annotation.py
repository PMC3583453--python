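"""Genic context of repeat loci and hypergeometric gene-set enrichment.

Repeat loci are assigned to exonic / intronic / intergenic context by interval
intersection against gene and exon features, exonic loci are mapped to the
genes that harbour them, and the resulting gene set is tested for functional
term over-representation with an exact upper-tail hypergeometric test (the
classical gene-set over-representation analysis; raw p-values, no
multiple-testing adjustment, flat term sets without ontology-graph
propagation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .scanner import RepeatLocus

__all__ = [
    "Feature",
    "TermAnnotation",
    "LocusContext",
    "AnnotationSummary",
    "annotate_loci",
    "hypergeom_test",
    "enrich_terms",
]


@dataclass(frozen=True)
class Feature:
    """A gene span or exon, 0-based half-open, tied to a gene id."""

    sequence_id: str
    start: int
    end: int
    kind: str  # "gene" or "exon"
    gene_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature interval [{self.start}, {self.end}) on "
                f"{self.sequence_id} has end <= start"
            )
        if self.kind not in ("gene", "exon"):
            raise ValueError(f"feature kind must be 'gene' or 'exon', got {self.kind!r}")
        if not self.gene_id:
            raise ValueError("every feature must carry a gene_id")


@dataclass(frozen=True)
class TermAnnotation:
    """A functional term and the genes annotated to it (genes may recur
    across terms)."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id} has no genes")


@dataclass(frozen=True)
class LocusContext:
    """Per-locus context call: exonic / intronic / intergenic plus the genes
    whose exons the locus overlaps."""

    locus: RepeatLocus
    context: str
    gene_ids: frozenset[str]
    straddles_exon_boundary: bool


@dataclass(frozen=True)
class AnnotationSummary:
    n_loci: int
    n_genic: int
    n_exonic: int
    n_intronic: int
    n_intergenic: int
    pct_exonic_of_genic: float
    pct_intronic_of_genic: float
    exonic_gene_ids: frozenset[str]
    n_exon_intron_straddlers: int


def _trees(features: Iterable[Feature], kind: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for feat in features:
        if feat.kind != kind:
            continue
        trees.setdefault(feat.sequence_id, IntervalTree()).addi(
            feat.start, feat.end, feat.gene_id
        )
    return trees


def annotate_loci(
    loci: Sequence[RepeatLocus], features: Sequence[Feature]
) -> tuple[list[LocusContext], AnnotationSummary]:
    """Assign each locus a genic context label.

    A locus is *exonic* if it overlaps at least one exon by >= 1 bp, *genic*
    if it overlaps at least one gene span, *intronic* if genic but not exonic,
    and *intergenic* otherwise.  Loci that overlap an exon while also covering
    genic sequence outside every exon straddle an exon boundary; they are
    counted as exonic, and their count is reported separately.
    """
    gene_trees = _trees(features, "gene")
    exon_trees = _trees(features, "exon")

    contexts: list[LocusContext] = []
    exonic_genes: set[str] = set()
    n_exonic = n_intronic = n_intergenic = n_straddle = 0
    for locus in loci:
        genes_hit = gene_trees.get(locus.sequence_id, IntervalTree()).overlap(
            locus.start, locus.end
        )
        exons_hit = exon_trees.get(locus.sequence_id, IntervalTree()).overlap(
            locus.start, locus.end
        )
        straddle = False
        if exons_hit:
            context = "exonic"
            gene_ids = frozenset(iv.data for iv in exons_hit)
            exonic_genes.update(gene_ids)
            n_exonic += 1
            straddle = _straddles(locus, genes_hit, exons_hit)
            n_straddle += straddle
        elif genes_hit:
            context = "intronic"
            gene_ids = frozenset()
            n_intronic += 1
        else:
            context = "intergenic"
            gene_ids = frozenset()
            n_intergenic += 1
        contexts.append(LocusContext(locus, context, gene_ids, straddle))

    n_genic = n_exonic + n_intronic
    summary = AnnotationSummary(
        n_loci=len(contexts),
        n_genic=n_genic,
        n_exonic=n_exonic,
        n_intronic=n_intronic,
        n_intergenic=n_intergenic,
        pct_exonic_of_genic=round(100.0 * n_exonic / n_genic, 1) if n_genic else 0.0,
        pct_intronic_of_genic=round(100.0 * n_intronic / n_genic, 1) if n_genic else 0.0,
        exonic_gene_ids=frozenset(exonic_genes),
        n_exon_intron_straddlers=n_straddle,
    )
    return contexts, summary


def _straddles(locus: RepeatLocus, genes_hit, exons_hit) -> bool:
    # True when some genic base of the locus is not covered by any exon.
    genic = _merged_overlap(locus, genes_hit)
    exonic = _merged_overlap(locus, exons_hit)
    return genic > exonic


def _merged_overlap(locus: RepeatLocus, intervals) -> int:
    spans = sorted(
        (max(iv.begin, locus.start), min(iv.end, locus.end)) for iv in intervals
    )
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for start, end in spans:
        if cur_start is None or start > cur_end:
            if cur_start is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        covered += cur_end - cur_start
    return covered


def hypergeom_test(observed: int, K: int, n_selected: int, N_universe: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= observed).

    X counts term genes among ``n_selected`` genes drawn without replacement
    from a universe of ``N_universe`` genes of which ``K`` belong to the term.
    No normal approximation is used.
    """
    if not (0 <= observed <= min(K, n_selected) <= N_universe):
        raise ValueError(
            f"impossible counts: observed={observed}, K={K}, "
            f"n_selected={n_selected}, N_universe={N_universe}"
        )
    if K > N_universe or n_selected > N_universe:
        raise ValueError("K and n_selected must not exceed N_universe")
    return float(hypergeom.sf(observed - 1, N_universe, K, n_selected))


def enrich_terms(
    selected_genes: Iterable[str],
    annotations: Sequence[TermAnnotation],
    universe_genes: Iterable[str],
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Term over-representation among ``selected_genes``.

    One row per term intersecting the universe, sorted ascending by p-value.
    ``expected`` is the chance expectation n_selected * K / N_universe; the
    p-value is the raw exact upper tail (no multiplicity adjustment).
    """
    universe = frozenset(universe_genes)
    if not universe:
        raise ValueError("universe_genes must be nonempty")
    selected = frozenset(selected_genes)
    if not selected <= universe:
        raise ValueError("selected_genes must be a subset of universe_genes")

    n_sel, n_uni = len(selected), len(universe)
    rows = []
    for term in annotations:
        term_genes = term.genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        observed = len(term_genes & selected)
        p = hypergeom_test(observed, K, n_sel, n_uni)
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "term_size": K,
                "expected": n_sel * K / n_uni,
                "observed": observed,
                "p_value": p,
                "significant": p < p_cutoff,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "term_size",
            "expected",
            "observed",
            "p_value",
            "significant",
        ],
    )
    return frame.sort_values("p_value", kind="mergesort").reset_index(drop=True)
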