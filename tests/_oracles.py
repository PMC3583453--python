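"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive everything from first principles (direct
definition checks, exhaustive enumeration with math.comb / itertools,
per-base membership arrays) and share no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

# --- independent motif-family map (closure under rotation + revcomp) -------

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(motif: str) -> str:
    return _RC[motif[1]] + _RC[motif[0]]


def oracle_family(motif: str) -> str:
    for name in ("GT/CA", "TC/AG", "AT/TA", "GC/CG"):
        base = name[:2]
        rot = base[1] + base[0]
        if motif in {base, rot, _rc(base), _rc(rot)}:
            return name
    raise ValueError(motif)


def brute_force_scan(seq: str, min_units: int) -> list[tuple[int, int, str, str, int]]:
    """All maximal pure dinucleotide runs, by definition.

    Tests every (position, motif) pair for purity and unit-maximality, then
    resolves dual-phase (same-family overlapping) candidates by larger unit
    count, then lexicographically smaller phase motif.  Returns sorted
    (start, end, family, phase_motif, units) tuples.
    """
    seq = seq.upper()
    n = len(seq)
    candidates = []
    for start in range(n - 1):
        motif = seq[start : start + 2]
        if motif[0] == motif[1] or any(b not in "ACGT" for b in motif):
            continue
        if start >= 2 and seq[start - 2 : start] == motif:
            continue  # not left-maximal: a whole unit extends to the left
        units = 1
        while seq[start + 2 * units : start + 2 * units + 2] == motif:
            units += 1
        if units >= min_units:
            candidates.append((start, units, motif))

    chosen: list[tuple[int, int, str, str, int]] = []
    for start, units, motif in sorted(candidates, key=lambda c: (-c[1], c[2], c[0])):
        family = oracle_family(motif)
        end = start + 2 * units
        if any(f == family and start < e and s < end for s, e, f, _, _ in chosen):
            continue
        chosen.append((start, end, family, motif, units))
    return sorted(chosen)


# --- hypergeometric upper tail by exhaustive draw enumeration --------------

def hypergeom_upper_tail_enum(observed: int, K: int, n_selected: int, N: int) -> float:
    """P(X >= observed) by enumerating every C(N, n_selected) draw."""
    items = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n_selected):
        total += 1
        if sum(items[i] for i in draw) >= observed:
            hits += 1
    return hits / total


# --- Fisher exact two-sided by table enumeration ---------------------------

def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Probability-mass summation over all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    total = r1 + r2

    def prob(x: int) -> float:
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(total, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


# --- per-base membership annotation oracle ---------------------------------

def per_base_context(
    length: int,
    genes: list[tuple[int, int]],
    exons: list[tuple[int, int]],
    loci: list[tuple[int, int]],
) -> list[str]:
    """Context of each locus interval via explicit per-base membership arrays."""
    in_gene = bytearray(length)
    in_exon = bytearray(length)
    for s, e in genes:
        for i in range(s, e):
            in_gene[i] = 1
    for s, e in exons:
        for i in range(s, e):
            in_exon[i] = 1
    out = []
    for s, e in loci:
        if any(in_exon[i] for i in range(s, e)):
            out.append("exonic")
        elif any(in_gene[i] for i in range(s, e)):
            out.append("intronic")
        else:
            out.append("intergenic")
    return out
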