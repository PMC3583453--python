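"""Detection and lifecycle classification of pure dinucleotide microsatellites.

A dinucleotide microsatellite is a head-to-tail tandem repeat of a 2-bp motif
(e.g. ``GTGTGTGTGT`` = (GT)5).  This module finds every *maximal pure* run in a
DNA sequence: the repeated tract contains no interruptions, and extending it by
one unit on either side breaks purity.  Motifs are canonicalised into the four
strand/rotation equivalence families (GT/CA, TC/AG, AT/TA, GC/CG), so the same
physical locus is reported identically no matter which strand or phase it is
read from.

Loci are classified by microsatellite "lifecycle" stage.  Dinucleotide repeats
acquire microsatellite mutational behaviour at a threshold of five units; an
adult locus is *mature* once no single observed mutational event (deletions of
at most four units have been observed for dinucleotides) can drag it back to or
below the threshold.  With the default threshold T=5 and maximum single-event
deletion D_max=4 this makes loci of >= 10 units mature.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "BELOW_THRESHOLD",
    "YOUNG_ADULT",
    "MATURE",
    "LIFECYCLE_STAGES",
    "FAMILY_NAMES",
    "FAMILY_MEMBERS",
    "MOTIF_TO_FAMILY",
    "reverse_complement",
    "canonical_family",
    "ScannerConfig",
    "RepeatLocus",
    "classify_lifecycle",
    "scan_pure_repeats",
    "scan_sequences",
    "length_distribution",
]

BELOW_THRESHOLD = "below_threshold"
YOUNG_ADULT = "young_adult"
MATURE = "mature"
LIFECYCLE_STAGES = (BELOW_THRESHOLD, YOUNG_ADULT, MATURE)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (uppercase in, uppercase out)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _closure(motif: str) -> frozenset[str]:
    rot = motif[1] + motif[0]
    return frozenset({motif, rot, reverse_complement(motif), reverse_complement(rot)})


#: The four motif families, named as in the field's convention.
FAMILY_NAMES = ("GT/CA", "TC/AG", "AT/TA", "GC/CG")

#: Family name -> set of 2-bp motifs (closed under rotation and reverse
#: complement).  GT/CA and TC/AG contain four motifs each; the palindromic
#: families AT/TA and GC/CG contain two.
FAMILY_MEMBERS: Mapping[str, frozenset[str]] = {
    name: _closure(name[:2]) for name in FAMILY_NAMES
}

MOTIF_TO_FAMILY: Mapping[str, str] = {
    motif: name for name, members in FAMILY_MEMBERS.items() for motif in members
}


def canonical_family(motif: str) -> str:
    """Map a 2-bp motif to its family name.

    The family is the equivalence class of the motif under cyclic rotation and
    reverse complement, so ``TG``, ``GT``, ``CA`` and ``AC`` all map to
    ``"GT/CA"``.

    Raises
    ------
    ValueError
        If the motif is not two ACGT characters, or if both bases are
        identical (a mononucleotide run, not a dinucleotide repeat).
    """
    if not isinstance(motif, str) or len(motif) != 2:
        raise ValueError(f"motif must be a 2-base string, got {motif!r}")
    m = motif.upper()
    if any(base not in "ACGT" for base in m):
        raise ValueError(f"motif {motif!r} contains a non-ACGT character")
    if m[0] == m[1]:
        raise ValueError(
            f"motif {motif!r} is a mononucleotide run; dinucleotide motifs "
            "must have two distinct bases"
        )
    return MOTIF_TO_FAMILY[m]


@dataclass(frozen=True)
class ScannerConfig:
    """Scanner and lifecycle parameters.

    Parameters
    ----------
    min_units_report:
        Smallest complete-unit count reported by the scanner.
    threshold_units:
        Unit count T at which a tandem repeat acquires microsatellite
        mutational behaviour (5 for dinucleotides).
    max_single_event_deletion:
        Largest single-event deletion D_max (in units) observed for
        dinucleotide microsatellites; a locus is mature when even a D_max-unit
        deletion leaves it above threshold.
    """

    min_units_report: int = 5
    threshold_units: int = 5
    max_single_event_deletion: int = 4

    def __post_init__(self) -> None:
        if self.threshold_units < 1:
            raise ValueError("threshold_units must be >= 1")
        if self.max_single_event_deletion < 0:
            raise ValueError("max_single_event_deletion must be >= 0")
        if self.min_units_report < 1:
            raise ValueError("min_units_report must be >= 1")


@dataclass(frozen=True)
class RepeatLocus:
    """A maximal pure dinucleotide repeat.

    Coordinates are 0-based, half-open; ``end - start == 2 * units`` and the
    subsequence ``[start, end)`` is an exact concatenation of ``phase_motif``.
    A dangling single base never extends ``units`` or the interval.
    """

    sequence_id: str
    start: int
    end: int
    family: str
    phase_motif: str
    units: int
    lifecycle: str

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("units must be >= 1")
        if self.end - self.start != 2 * self.units:
            raise ValueError("end - start must equal 2 * units")


def classify_lifecycle(units: int, config: ScannerConfig | None = None) -> str:
    """Classify a repeat of ``units`` complete units by lifecycle stage.

    ``below_threshold`` if units < T; ``mature`` if units - D_max > T (no
    single observed deletion event can kill the locus); ``young_adult``
    otherwise.  With defaults, mature <=> units >= 10.
    """
    config = config or ScannerConfig()
    if units < 1:
        raise ValueError("units must be >= 1")
    if units < config.threshold_units:
        return BELOW_THRESHOLD
    if units - config.max_single_event_deletion > config.threshold_units:
        return MATURE
    return YOUNG_ADULT


_ACGT_CHUNK = re.compile(r"[ACGT]+")


def scan_pure_repeats(
    sequence: str,
    config: ScannerConfig | None = None,
    sequence_id: str = "seq",
) -> list[RepeatLocus]:
    """Find all maximal pure dinucleotide repeats in ``sequence``.

    The sequence is uppercased; ``N`` and any other non-ACGT character act as
    hard run breakers.  Each maximal alternating tract is reported once: a
    tract scannable in two phases (odd base length, e.g. ``CACACAC``) is
    reported at the phase giving the larger complete-unit count, with ties
    broken by the lexicographically smaller phase motif (this tie-break makes
    reported coordinates exactly strand-symmetric).  Trailing partial units are
    excluded from the interval.
    """
    config = config or ScannerConfig()
    seq = sequence.upper()
    loci: list[RepeatLocus] = []
    for match in _ACGT_CHUNK.finditer(seq):
        loci.extend(_scan_chunk(match.group(), match.start(), sequence_id, config))
    return loci


def _scan_chunk(
    chunk: str, offset: int, sequence_id: str, config: ScannerConfig
) -> list[RepeatLocus]:
    # Walk maximal period-2 tracts: [i, j) such that chunk[k] == chunk[k-2]
    # for all k in [i+2, j).  Adjacent tracts may share one base, so the next
    # candidate start is j - 1.
    n = len(chunk)
    out: list[RepeatLocus] = []
    i = 0
    while i < n - 1:
        j = i + 2
        while j < n and chunk[j] == chunk[j - 2]:
            j += 1
        if chunk[i] != chunk[i + 1]:  # identical bases -> mononucleotide run
            length = j - i
            units = length // 2
            if units >= config.min_units_report:
                if length % 2 == 0:
                    start, motif = i, chunk[i : i + 2]
                else:
                    m0, m1 = chunk[i : i + 2], chunk[i + 1 : i + 3]
                    start, motif = (i, m0) if m0 < m1 else (i + 1, m1)
                out.append(
                    RepeatLocus(
                        sequence_id=sequence_id,
                        start=offset + start,
                        end=offset + start + 2 * units,
                        family=MOTIF_TO_FAMILY[motif],
                        phase_motif=motif,
                        units=units,
                        lifecycle=classify_lifecycle(units, config),
                    )
                )
        i = j - 1
    return out


def scan_sequences(
    records: Mapping[str, str], config: ScannerConfig | None = None
) -> list[RepeatLocus]:
    """Scan a mapping of ``sequence_id -> sequence`` (e.g. a parsed FASTA)."""
    loci: list[RepeatLocus] = []
    for seq_id, seq in records.items():
        loci.extend(scan_pure_repeats(seq, config, sequence_id=seq_id))
    return loci


def length_distribution(loci: Iterable[RepeatLocus]) -> dict[str, Counter]:
    """Per-family histogram of complete-unit counts.

    Returns ``{family: Counter({units: count})}`` with all four families
    present (empty counters when a family has no loci).
    """
    hist: dict[str, Counter] = {name: Counter() for name in FAMILY_NAMES}
    for locus in loci:
        hist[locus.family][locus.units] += 1
    return hist
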