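"""Mutant-frequency / mutation-rate calculus for HSV-tk forward mutation assays.

The forward assay reports, per clonal population, the number of reporter-
inactivating mutant colonies (FUdR-resistant + Cm-resistant) out of all
vector-bearing colonies (Cm-resistant).  The mutant frequency MF is their
ratio; dividing by the number of cell population doublings between cloning and
vector extraction gives the mutation rate per cell generation.  Sequencing a
sample of independent mutants classifies each as a microsatellite indel (a
signed whole-unit change of the artificial repeat) or a coding-region (non-MS)
mutation; the microsatellite-specific rate scales the rate by the MS-indel
share of the sequenced spectrum.

The same calculus applies to in vitro polymerase reactions: the polymerase
error frequency (Pol EF) is the observed reaction MF minus the single-stranded
DNA background MF, the MS-specific Pol EF scales by the MS-indel share, and an
allele's error rate is the sum over its two complementary template strands
(e.g. GT_10 + CA_10).

Directional-bias statistics (expansion vs deletion counts) use the two-sided
Fisher exact test with the probability-mass summation convention; per-clone
rate distributions are compared with rank tests (Mann-Whitney for two groups,
Kruskal-Wallis for more); deletion-size spectra are compared with a chi-square
homogeneity test over the size classes {1, 2, 3-4, >=5} units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MutantSpectrum",
    "CloneAssay",
    "RateResult",
    "ClassFrequencies",
    "FoldRatio",
    "PolReaction",
    "PolEFResult",
    "ExpFit",
    "DeletionSizeResult",
    "DELETION_SIZE_CLASSES",
    "mutant_frequency",
    "clone_rates",
    "class_frequencies",
    "fold_ratio",
    "format_fold",
    "bias_test",
    "rate_distribution_test",
    "pol_ef",
    "fit_exponential",
    "deletion_size_classes",
    "summarize_clone_rates",
]

#: Deletion magnitude classes, in repeat units.
DELETION_SIZE_CLASSES = ("1", "2", "3-4", "5+")


def deletion_size_class(units_deleted: int) -> str:
    if units_deleted < 1:
        raise ValueError("deletion size must be >= 1 unit")
    if units_deleted <= 2:
        return str(units_deleted)
    if units_deleted <= 4:
        return "3-4"
    return "5+"


@dataclass(frozen=True)
class MutantSpectrum:
    """Classified sequenced mutants from one assay.

    ``ms_unit_changes`` holds one signed entry per microsatellite indel mutant
    (d > 0 expansion, d < 0 deletion, in repeat units; a multi-unit event
    counts once).  ``n_non_ms`` counts sequenced mutants that mapped to the
    reporter coding region instead of the repeat.
    """

    ms_unit_changes: tuple[int, ...]
    n_non_ms: int = 0

    def __post_init__(self) -> None:
        if any(d == 0 for d in self.ms_unit_changes):
            raise ValueError("microsatellite indels must have nonzero unit change")
        if self.n_non_ms < 0:
            raise ValueError("n_non_ms must be >= 0")

    @classmethod
    def from_counts(
        cls,
        n_expansions: int,
        n_deletions: int,
        n_non_ms: int = 0,
        expansion_units: int = 1,
        deletion_units: int = 1,
    ) -> "MutantSpectrum":
        return cls(
            tuple([expansion_units] * n_expansions + [-deletion_units] * n_deletions),
            n_non_ms,
        )

    @property
    def n_sequenced(self) -> int:
        return len(self.ms_unit_changes) + self.n_non_ms

    @property
    def n_ms(self) -> int:
        return len(self.ms_unit_changes)

    @property
    def n_expansions(self) -> int:
        return sum(1 for d in self.ms_unit_changes if d > 0)

    @property
    def n_deletions(self) -> int:
        return sum(1 for d in self.ms_unit_changes if d < 0)

    @property
    def deletion_sizes(self) -> tuple[int, ...]:
        return tuple(-d for d in self.ms_unit_changes if d < 0)


def mutant_frequency(n_fudr_cm: int, n_cm: int) -> float:
    """Mutant frequency: mutant (FUdR^R + Cm^R) colonies / total Cm^R colonies."""
    if n_cm <= 0:
        raise ValueError("mutant frequency undefined: total colony count is zero")
    if not 0 <= n_fudr_cm <= n_cm:
        raise ValueError("need 0 <= n_fudr_cm <= n_cm")
    return n_fudr_cm / n_cm


@dataclass(frozen=True)
class CloneAssay:
    """One clonal population: colony counts, population doublings, and the
    classified spectrum of its sequenced mutants."""

    clone_id: str
    n_fudr_cm: int
    n_cm: int
    doublings: float
    spectrum: MutantSpectrum = field(default_factory=lambda: MutantSpectrum(()))

    def __post_init__(self) -> None:
        if self.doublings <= 0:
            raise ValueError("doublings must be > 0")
        if not 0 <= self.n_fudr_cm <= self.n_cm:
            raise ValueError("need 0 <= n_fudr_cm <= n_cm")


@dataclass(frozen=True)
class RateResult:
    mf: float
    rate: float  # mutations per cell generation
    ms_rate: float | None  # microsatellite-specific rate; None when no spectrum


def clone_rates(assay: CloneAssay) -> RateResult:
    """Per-clone mutation rate and microsatellite-specific rate.

    rate = MF / doublings; ms_rate = rate * (MS-indel mutants / sequenced
    mutants).  With an empty spectrum the ms_rate is unavailable (None).
    """
    mf = mutant_frequency(assay.n_fudr_cm, assay.n_cm)
    rate = mf / assay.doublings
    spectrum = assay.spectrum
    if spectrum.n_sequenced == 0:
        return RateResult(mf=mf, rate=rate, ms_rate=None)
    return RateResult(mf=mf, rate=rate, ms_rate=rate * spectrum.n_ms / spectrum.n_sequenced)


def format_fold(fold: float) -> str:
    """Fold presentation convention: one decimal below 10, integer at >= 10."""
    return f"{fold:.1f}" if fold < 10 else f"{fold:.0f}"


@dataclass(frozen=True)
class FoldRatio:
    """Expansion:deletion bias as a larger:smaller fold with orientation.

    ``orientation`` names the larger class.  When one class frequency is an
    upper bound (zero observed mutants), the fold is a lower bound and
    ``is_bound`` is set; ``label`` renders the field's ``2.6:1`` / ``>55:1`` /
    ``1:6`` style.
    """

    fold: float
    orientation: str  # "expansion" or "deletion"
    is_bound: bool
    label: str


def fold_ratio(
    expansion_mf: float,
    deletion_mf: float,
    expansion_is_bound: bool = False,
    deletion_is_bound: bool = False,
) -> FoldRatio:
    if expansion_mf <= 0 or deletion_mf <= 0:
        raise ValueError("class frequencies must be positive (use a bound for zero counts)")
    if expansion_mf >= deletion_mf:
        fold = expansion_mf / deletion_mf
        orientation = "expansion"
        is_bound = deletion_is_bound
        label = f"{format_fold(fold)}:1"
    else:
        fold = deletion_mf / expansion_mf
        orientation = "deletion"
        is_bound = expansion_is_bound
        label = f"1:{format_fold(fold)}"
    if is_bound:
        label = ">" + label
    return FoldRatio(fold=fold, orientation=orientation, is_bound=is_bound, label=label)


@dataclass(frozen=True)
class ClassFrequencies:
    """Decomposition of a mutant frequency into expansion and deletion parts."""

    mf: float
    expansion_mf: float
    deletion_mf: float
    expansion_is_bound: bool
    deletion_is_bound: bool
    ratio: FoldRatio


def class_frequencies(mf: float, spectrum: MutantSpectrum) -> ClassFrequencies:
    """Split an MF into expansion and deletion class frequencies.

    class_MF = MF * (class mutant count / sequenced mutants).  A class with
    zero observed mutants is reported as the single-event upper bound
    MF * (1 / n_sequenced), and the bias ratio becomes a '>' lower bound.
    """
    if mf < 0:
        raise ValueError("mutant frequency must be >= 0")
    n = spectrum.n_sequenced
    if n == 0:
        raise ValueError("class frequencies need a nonempty spectrum")
    exp_mf = mf * spectrum.n_expansions / n
    del_mf = mf * spectrum.n_deletions / n
    exp_bound = spectrum.n_expansions == 0
    del_bound = spectrum.n_deletions == 0
    if exp_bound:
        exp_mf = mf / n
    if del_bound:
        del_mf = mf / n
    return ClassFrequencies(
        mf=mf,
        expansion_mf=exp_mf,
        deletion_mf=del_mf,
        expansion_is_bound=exp_bound,
        deletion_is_bound=del_bound,
        ratio=fold_ratio(exp_mf, del_mf, exp_bound, del_bound),
    )


def bias_test(spectrum_a: MutantSpectrum, spectrum_b: MutantSpectrum) -> float:
    """Two-sided Fisher exact p-value comparing expansion/deletion counts.

    The two-sided p sums, at fixed margins, the probabilities of every 2x2
    table no more probable than the observed one (probability-mass summation,
    not tail doubling).
    """
    for name, s in (("first", spectrum_a), ("second", spectrum_b)):
        if s.n_ms < 1:
            raise ValueError(f"{name} spectrum has no microsatellite indels")
    table = [
        [spectrum_a.n_expansions, spectrum_a.n_deletions],
        [spectrum_b.n_expansions, spectrum_b.n_deletions],
    ]
    if any(sum(row) == 0 for row in table) or any(sum(col) == 0 for col in zip(*table)):
        warnings.warn("degenerate 2x2 table with a zero margin; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def rate_distribution_test(groups: Sequence[Sequence[float]]) -> float:
    """Compare per-clone rate distributions across vectors or cell lines.

    Two groups: two-sided Mann-Whitney U (exact when sample sizes permit and
    there are no ties; tie-corrected normal approximation otherwise, without
    continuity correction so identical groups give p = 1).  More than two
    groups: Kruskal-Wallis with tie correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two values")
    if len(groups) == 2:
        return float(
            stats.mannwhitneyu(
                groups[0], groups[1], alternative="two-sided", use_continuity=False
            )[1]
        )
    return float(stats.kruskal(*groups)[1])


@dataclass(frozen=True)
class PolReaction:
    """Pooled in vitro reactions for one template strand of one allele."""

    strand_label: str
    observed_mf: float
    background_mf: float
    spectrum: MutantSpectrum
    allele_units: int

    def __post_init__(self) -> None:
        if self.observed_mf < 0 or self.background_mf < 0:
            raise ValueError("mutant frequencies must be >= 0")
        if self.allele_units < 1:
            raise ValueError("allele_units must be >= 1")


@dataclass(frozen=True)
class PolEFResult:
    allele_units: int
    strand_ef: Mapping[str, float]
    strand_ms_ef: Mapping[str, float]
    allele_ms_ef: float


def pol_ef(reactions: Sequence[PolReaction]) -> PolEFResult:
    """Polymerase error frequencies for the two complementary strands.

    Per strand: Pol EF = observed MF - ssDNA background MF, floored at zero
    (with a warning when the background exceeds the observation); MS Pol EF
    scales by the strand's MS-indel share.  The allele value sums the two
    strand MS Pol EFs and is symmetric in strand order.
    """
    if len(reactions) != 2:
        raise ValueError("pol_ef needs exactly two strands of one allele")
    if reactions[0].strand_label == reactions[1].strand_label:
        raise ValueError("the two reactions must be complementary strands")
    if reactions[0].allele_units != reactions[1].allele_units:
        raise ValueError("strand reactions have mismatched allele_units")
    strand_ef: dict[str, float] = {}
    strand_ms_ef: dict[str, float] = {}
    for rxn in reactions:
        ef = rxn.observed_mf - rxn.background_mf
        if ef < 0:
            warnings.warn(
                f"strand {rxn.strand_label}: background MF exceeds observed MF; "
                "Pol EF floored at 0",
                stacklevel=2,
            )
            ef = 0.0
        n = rxn.spectrum.n_sequenced
        if n == 0:
            raise ValueError(f"strand {rxn.strand_label} has no sequenced mutants")
        strand_ef[rxn.strand_label] = ef
        strand_ms_ef[rxn.strand_label] = ef * rxn.spectrum.n_ms / n
    return PolEFResult(
        allele_units=reactions[0].allele_units,
        strand_ef=strand_ef,
        strand_ms_ef=strand_ms_ef,
        allele_ms_ef=sum(strand_ms_ef.values()),
    )


@dataclass(frozen=True)
class ExpFit:
    """Exponential error-rate model f(n) = a * exp(b * n) fitted on the log
    scale; r_squared is the log-scale coefficient of determination."""

    a: float
    b: float
    r_squared: float

    def predict(self, n: float) -> float:
        return self.a * math.exp(self.b * n)


def fit_exponential(points: Sequence[tuple[float, float]]) -> ExpFit:
    """Ordinary least squares of ln(frequency) on allele units.

    Requires >= 2 points with positive frequencies (a caller may floor zeros
    at a pseudo-frequency before fitting).  Two distinct points give an exact
    fit with r_squared = 1.
    """
    if len(points) < 2:
        raise ValueError("need at least two (units, frequency) points")
    n = np.asarray([p[0] for p in points], dtype=float)
    f = np.asarray([p[1] for p in points], dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive for a log-linear fit")
    if np.ptp(n) == 0:
        raise ValueError("points must span more than one allele length")
    y = np.log(f)
    slope, intercept = np.polyfit(n, y, 1)
    resid = y - (intercept + slope * n)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ExpFit(a=float(np.exp(intercept)), b=float(slope), r_squared=max(0.0, min(1.0, r_squared)))


@dataclass(frozen=True)
class DeletionSizeResult:
    counts: pd.DataFrame  # alleles x size classes
    proportions: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    low_expected_counts: bool


def deletion_size_classes(
    spectra_by_allele: Mapping[str, MutantSpectrum]
) -> DeletionSizeResult:
    """Deletion-size class table across alleles with a chi-square homogeneity test.

    Sizes are binned into {1, 2, 3-4, >=5} units.  The chi-square statistic is
    computed on the alleles x (nonzero) classes contingency table without
    continuity correction; a warning flag is set when any expected cell count
    is below 5.  Every allele must contribute at least one deletion event.
    """
    rows = {}
    for allele, spectrum in spectra_by_allele.items():
        sizes = spectrum.deletion_sizes
        if not sizes:
            raise ValueError(f"allele {allele} has no deletion events")
        counts = {cls: 0 for cls in DELETION_SIZE_CLASSES}
        for size in sizes:
            counts[deletion_size_class(size)] += 1
        rows[allele] = counts
    counts = pd.DataFrame.from_dict(rows, orient="index")[list(DELETION_SIZE_CLASSES)]
    if counts.to_numpy().sum() == 0:
        raise ValueError("all-zero deletion table")
    proportions = counts.div(counts.sum(axis=1), axis=0)

    nonzero = counts.loc[:, counts.sum(axis=0) > 0]
    if nonzero.shape[1] < 2 or nonzero.shape[0] < 2:
        return DeletionSizeResult(counts, proportions, 0.0, 0, 1.0, False)
    chi2, p, dof, expected = stats.chi2_contingency(nonzero.to_numpy(), correction=False)
    return DeletionSizeResult(
        counts=counts,
        proportions=proportions,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        low_expected_counts=bool((expected < 5).any()),
    )


def summarize_clone_rates(assays: Iterable[CloneAssay]) -> pd.DataFrame:
    """Per-clone MF, rate and MS-specific rate as a tidy table.

    Across-clone summaries should use the median MS rate (the field's
    convention for these skewed per-clone distributions).
    """
    rows = []
    for assay in assays:
        result = clone_rates(assay)
        rows.append(
            {
                "clone_id": assay.clone_id,
                "n_fudr_cm": assay.n_fudr_cm,
                "n_cm": assay.n_cm,
                "doublings": assay.doublings,
                "mf": result.mf,
                "rate": result.rate,
                "ms_rate": result.ms_rate,
            }
        )
    return pd.DataFrame(rows)
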