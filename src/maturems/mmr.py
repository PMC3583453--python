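"""Strand-slippage + mismatch-repair model of dinucleotide mutational bias.

During replication of a tandem repeat, polymerase slippage produces
insertion/deletion loops (IDLs): looped-out units on the *nascent* strand
mature into expansions, looped-out units on the *template* strand mature into
deletions.  The polymerase-level event rates are length-dependent (an
exponential in allele units, as measured in vitro) and strongly biased toward
deletions.  Post-replication mismatch repair (MMR) can remove an IDL before it
becomes a mutation: recognition requires a functional MutS heterodimer (MutSα
= MSH2·MSH6 or MutSβ = MSH2·MSH3) and execution a functional MutL heterodimer
(MutLα = MLH1·PMS2 or MutLγ = MLH1·MLH3).  A repair *channel* is a (MutS,
MutL) pairing; a channel acts only in genotypes where both of its heterodimers
are functional, and channels escape independently, so the expected surviving
frequency of an IDL class is the polymerase-level rate times the product of
the channels' escape probabilities.

This structure reproduces the observed genotype pattern: in cells with no
functional MutL complex (e.g. MLH1-deficient HCT116) no channel acts and the
surviving spectrum equals the polymerase spectrum (deletion-biased); channels
containing MutSα or MutLα preferentially remove nascent-strand IDLs, creating
the expansion bias of repair-proficient cells; template-strand IDLs are
efficiently removed through MutSβ- or MutLγ-containing channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .assay import DELETION_SIZE_CLASSES, fold_ratio

__all__ = [
    "MUTS_COMPLEXES",
    "MUTL_COMPLEXES",
    "IDL_CLASSES",
    "EXPANSION",
    "DELETION",
    "MMRGenotype",
    "GENOTYPE_PRESETS",
    "PolSlippageModel",
    "RepairEfficiencies",
    "SimResult",
    "PanelObservation",
    "MMRFitResult",
    "DEFAULT_EXPANSION_CHANNELS",
    "DEFAULT_DELETION_CHANNELS",
    "expected_class_frequencies",
    "simulate_replications",
    "fit_repair_efficiencies",
    "load_gtca19_panel",
]

MUTS_COMPLEXES = ("MutSa", "MutSb")
MUTL_COMPLEXES = ("MutLa", "MutLg")
EXPANSION = "expansion"
DELETION = "deletion"
IDL_CLASSES = (EXPANSION, DELETION)


@dataclass(frozen=True)
class MMRGenotype:
    """Which MutS/MutL heterodimers are functional.

    A MutS complex with no functional MutL partner contributes nothing: repair
    channels are (MutS, MutL) pairings and both members must be present.  The
    HCT116 preset therefore behaves as fully MMR-deficient even though MutSα
    subunits are expressed.
    """

    muts_alpha: bool
    muts_beta: bool
    mutl_alpha: bool
    mutl_gamma: bool

    @property
    def functional_pairings(self) -> tuple[tuple[str, str], ...]:
        muts = [s for s, ok in zip(MUTS_COMPLEXES, (self.muts_alpha, self.muts_beta)) if ok]
        mutl = [l for l, ok in zip(MUTL_COMPLEXES, (self.mutl_alpha, self.mutl_gamma)) if ok]
        return tuple((s, l) for s in muts for l in mutl)


#: Cell-line genotype presets: a repair-proficient lymphoblastoid line
#: (LCL721), a PMS2-deficient line lacking MutLα (LCL1261), an MSH3-deficient
#: chromosome-3-complemented colorectal line lacking MutSβ (HCT116+chr3), and
#: the MLH1/MSH3-deficient parental line with no functional MutL at all
#: (HCT116).
GENOTYPE_PRESETS: Mapping[str, MMRGenotype] = {
    "LCL721": MMRGenotype(True, True, True, True),
    "LCL1261": MMRGenotype(True, True, False, True),
    "HCT116+chr3": MMRGenotype(True, False, True, True),
    "HCT116": MMRGenotype(True, False, False, False),
}


@dataclass(frozen=True)
class PolSlippageModel:
    """Polymerase-level slippage event rates.

    Per-replication probabilities of an (unrepaired-if-no-MMR) expansion or
    deletion event at allele length n units, each an exponential
    a * exp(b * n) as measured for purified polymerases, plus a deletion-size
    distribution over the {1, 2, 3-4, >=5}-unit classes.
    """

    a_exp: float
    b_exp: float
    a_del: float
    b_del: float
    deletion_size_probs: tuple[float, float, float, float] = (0.55, 0.20, 0.15, 0.10)

    def __post_init__(self) -> None:
        if self.a_exp <= 0 or self.a_del <= 0:
            raise ValueError("rate intercepts must be positive")
        probs = np.asarray(self.deletion_size_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or not math.isclose(probs.sum(), 1.0):
            raise ValueError("deletion_size_probs must be 4 nonnegative values summing to 1")

    @classmethod
    def from_point(
        cls,
        e_exp: float,
        e_del: float,
        deletion_size_probs: tuple[float, float, float, float] = (0.55, 0.20, 0.15, 0.10),
    ) -> "PolSlippageModel":
        """Length-independent model pinned to one allele's measured rates."""
        return cls(e_exp, 0.0, e_del, 0.0, deletion_size_probs)

    def e_exp(self, n: int) -> float:
        return self.a_exp * math.exp(self.b_exp * n)

    def e_del(self, n: int) -> float:
        return self.a_del * math.exp(self.b_del * n)

    def p_expansion(self, n: int) -> float:
        e, d = self.e_exp(n), self.e_del(n)
        return e / (e + d)


class RepairEfficiencies:
    """Per-channel IDL repair probabilities r[(MutS, MutL, idl_class)].

    Missing entries default to 0 (the channel does not repair that class).
    Expansion-precursor IDLs sit on the nascent strand, deletion-precursor
    IDLs on the template strand.
    """

    def __init__(self, values: Mapping[tuple[str, str, str], float] | None = None):
        self._r: dict[tuple[str, str, str], float] = {}
        if values:
            for key, value in values.items():
                self[key] = value

    def __setitem__(self, key: tuple[str, str, str], value: float) -> None:
        s, l, cls = key
        if s not in MUTS_COMPLEXES or l not in MUTL_COMPLEXES or cls not in IDL_CLASSES:
            raise KeyError(f"bad repair-efficiency key {key!r}")
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"repair efficiency must be in [0, 1], got {value}")
        self._r[key] = float(value)

    def __getitem__(self, key: tuple[str, str, str]) -> float:
        return self._r.get(key, 0.0)

    def get(self, muts: str, mutl: str, idl_class: str) -> float:
        return self[(muts, mutl, idl_class)]

    def as_dict(self) -> dict[tuple[str, str, str], float]:
        return dict(self._r)

    def survival(self, genotype: MMRGenotype, idl_class: str) -> float:
        """Probability an IDL of this class escapes every functional channel."""
        product = 1.0
        for s, l in genotype.functional_pairings:
            product *= 1.0 - self[(s, l, idl_class)]
        return product

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RepairEfficiencies({self._r!r})"


def expected_class_frequencies(
    pol: PolSlippageModel,
    genotype: MMRGenotype,
    r: RepairEfficiencies,
    n: int,
) -> tuple[float, float]:
    """Closed-form expected surviving (expansion, deletion) frequencies.

    E[class] = e_class(n) * prod over functional (MutS, MutL) pairings of
    (1 - r[pairing, class]).  A genotype with no functional MutL (or no
    functional MutS) has no pairings and applies no repair.
    """
    return (
        pol.e_exp(n) * r.survival(genotype, EXPANSION),
        pol.e_del(n) * r.survival(genotype, DELETION),
    )


@dataclass(frozen=True)
class SimResult:
    """Outcome counts of a seeded replication simulation."""

    n_replications: int
    n_expansions: int
    n_deletions: int
    n_repaired: int
    n_error_free: int
    deletion_size_counts: Mapping[str, int]

    @property
    def expansion_freq(self) -> float:
        return self.n_expansions / self.n_replications

    @property
    def deletion_freq(self) -> float:
        return self.n_deletions / self.n_replications


def simulate_replications(
    pol: PolSlippageModel,
    genotype: MMRGenotype,
    r: RepairEfficiencies,
    n: int,
    n_replications: int,
    seed: int,
) -> SimResult:
    """Monte Carlo twin of :func:`expected_class_frequencies`.

    Each replication independently draws slippage occurrence, IDL class (which
    fixes the strand: expansion-precursors on the nascent strand,
    deletion-precursors on the template strand), deletion size, and escape
    from every functional repair channel.  At most one event per replication
    (event rates are << 1).  The same seed gives a bit-identical result.
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    rng = np.random.default_rng(seed)
    p_exp, p_del = pol.e_exp(n), pol.e_del(n)
    if p_exp + p_del >= 1:
        raise ValueError("per-replication event probability must be < 1")
    n_exp_err, n_del_err, n_clean = rng.multinomial(
        n_replications, (p_exp, p_del, 1.0 - p_exp - p_del)
    )
    surviving_exp = rng.binomial(n_exp_err, r.survival(genotype, EXPANSION))
    surviving_del = rng.binomial(n_del_err, r.survival(genotype, DELETION))
    size_counts = rng.multinomial(surviving_del, pol.deletion_size_probs)
    return SimResult(
        n_replications=n_replications,
        n_expansions=int(surviving_exp),
        n_deletions=int(surviving_del),
        n_repaired=int(n_exp_err - surviving_exp + n_del_err - surviving_del),
        n_error_free=int(n_clean),
        deletion_size_counts=dict(zip(DELETION_SIZE_CLASSES, (int(c) for c in size_counts))),
    )


@dataclass(frozen=True)
class PanelObservation:
    """One observed class frequency (or upper bound) for one genotype.

    ``genotype_label`` is normally a preset name; an explicit
    ``genotype_override`` supports panels of arbitrary genotypes.
    """

    genotype_label: str
    idl_class: str
    frequency: float
    is_bound: bool = False  # frequency is an upper bound (zero observed mutants)
    genotype_override: MMRGenotype | None = None

    def __post_init__(self) -> None:
        if self.idl_class not in IDL_CLASSES:
            raise ValueError(f"idl_class must be one of {IDL_CLASSES}")
        if self.frequency <= 0:
            raise ValueError("observed frequency (or bound) must be positive")

    def genotype(self) -> MMRGenotype:
        if self.genotype_override is not None:
            return self.genotype_override
        try:
            return GENOTYPE_PRESETS[self.genotype_label]
        except KeyError:
            raise ValueError(
                f"unknown genotype preset {self.genotype_label!r}; "
                f"known: {sorted(GENOTYPE_PRESETS)}"
            ) from None


# Channel subsets the fitter estimates, chosen from the repair biology:
# expansion (nascent-strand) IDL removal runs through pairings containing
# MutSα or MutLα; deletion (template-strand) IDL removal through pairings
# containing MutSβ or MutLγ.  Each subset is also the largest one
# identifiable from a four-genotype panel of the presets above.
DEFAULT_EXPANSION_CHANNELS: tuple[tuple[str, str], ...] = (
    ("MutSa", "MutLa"),
    ("MutSa", "MutLg"),
    ("MutSb", "MutLa"),
)
DEFAULT_DELETION_CHANNELS: tuple[tuple[str, str], ...] = (
    ("MutSa", "MutLg"),
    ("MutSb", "MutLa"),
    ("MutSb", "MutLg"),
)

_X_MAX = 40.0  # -ln(1 - r) cap; exp(-40) ~ 4e-18 is indistinguishable from r = 1


@dataclass(frozen=True)
class MMRFitResult:
    efficiencies: RepairEfficiencies
    residuals_log10: Mapping[tuple[str, str], float]
    predicted: Mapping[tuple[str, str], float]
    predicted_ratio: Mapping[str, float]  # expansion/deletion per genotype
    non_identifiable: tuple[tuple[str, str, str], ...]
    rank_deficient: bool
    deletion_scale: float


def fit_repair_efficiencies(
    panel: Sequence[PanelObservation],
    pol: PolSlippageModel,
    n: int,
    expansion_channels: Sequence[tuple[str, str]] = DEFAULT_EXPANSION_CHANNELS,
    deletion_channels: Sequence[tuple[str, str]] = DEFAULT_DELETION_CHANNELS,
    fit_deletion_scale: bool = False,
) -> MMRFitResult:
    """Fit per-channel repair efficiencies to an observed genotype panel.

    Minimizes squared log10-frequency residuals over the requested channel
    efficiencies with box constraints r in [0, 1]; internally the fit works on
    the escape exponents x = -ln(1 - r) >= 0, in which the model is log-linear
    and the problem convex.  Bound observations ("< f") are censored: they
    contribute loss only when the prediction exceeds the bound.  Channels that
    are functional in no supplied genotype are structurally non-identifiable:
    they are frozen at 0 and flagged.  ``rank_deficient`` flags a design whose
    non-censored observations cannot separate the requested channels (some
    linear combination of escape exponents is unconstrained).

    ``fit_deletion_scale`` adds one genotype-independent multiplicative factor
    on the polymerase deletion rate, for panels where the cellular and in
    vitro polymerase-level frequencies are not commensurable; off by default.
    """
    labels = {obs.genotype_label for obs in panel}
    if len(labels) < 2:
        raise ValueError(
            "repair efficiencies are non-identifiable from a single genotype"
        )
    channels = {EXPANSION: tuple(expansion_channels), DELETION: tuple(deletion_channels)}
    genotypes = {obs.genotype_label: obs.genotype() for obs in panel}

    # Parameter layout: one escape exponent per (channel, class), skipping
    # structurally inactive channels; optionally the log deletion scale.
    params: list[tuple[str, str, str]] = []
    non_identifiable: list[tuple[str, str, str]] = []
    for cls in IDL_CLASSES:
        for s, l in channels[cls]:
            active = any(
                (s, l) in genotypes[obs.genotype_label].functional_pairings
                for obs in panel
                if obs.idl_class == cls
            )
            if active:
                params.append((s, l, cls))
            else:
                non_identifiable.append((s, l, cls))

    e_class = {EXPANSION: pol.e_exp(n), DELETION: pol.e_del(n)}
    log10e = math.log10(math.e)

    def design_row(obs: PanelObservation) -> np.ndarray:
        pairings = genotypes[obs.genotype_label].functional_pairings
        return np.array(
            [
                1.0 if (cls == obs.idl_class and (s, l) in pairings) else 0.0
                for (s, l, cls) in params
            ]
        )

    rows = [design_row(obs) for obs in panel]
    obs_log10 = [math.log10(obs.frequency) for obs in panel]

    design = np.array([row for row, obs in zip(rows, panel) if not obs.is_bound])
    rank_deficient = bool(
        design.size == 0 or np.linalg.matrix_rank(design) < len(params)
    )

    n_x = len(params)

    def predict_log10(theta: np.ndarray, i: int) -> float:
        obs = panel[i]
        value = math.log10(e_class[obs.idl_class]) - log10e * float(rows[i] @ theta[:n_x])
        if fit_deletion_scale and obs.idl_class == DELETION:
            value += theta[n_x] * log10e
        return value

    def residuals(theta: np.ndarray) -> np.ndarray:
        res = np.empty(len(panel))
        for i, obs in enumerate(panel):
            diff = predict_log10(theta, i) - obs_log10[i]
            res[i] = max(0.0, diff) if obs.is_bound else diff
        return res

    x0 = np.full(n_x, 0.5)
    for i, (s, l, cls) in enumerate(params):
        if cls == EXPANSION and (s, l) == ("MutSa", "MutLa"):
            x0[i] = 3.0  # prior: expansion repair concentrated in MutSα·MutLα
        if cls == DELETION:
            x0[i] = 2.0  # prior: template-strand IDLs repaired via MutSβ / MutLγ
    lower = np.zeros(n_x)
    upper = np.full(n_x, _X_MAX)
    if fit_deletion_scale:
        x0 = np.append(x0, 0.0)
        lower = np.append(lower, -10.0)
        upper = np.append(upper, 10.0)

    solution = least_squares(residuals, x0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    theta = solution.x

    r = RepairEfficiencies()
    for (s, l, cls), x in zip(params, theta[:n_x]):
        r[(s, l, cls)] = 1.0 - math.exp(-float(x))
    scale = math.exp(float(theta[n_x])) if fit_deletion_scale else 1.0

    predicted: dict[tuple[str, str], float] = {}
    resids: dict[tuple[str, str], float] = {}
    for i, obs in enumerate(panel):
        pred = 10.0 ** predict_log10(theta, i)
        predicted[(obs.genotype_label, obs.idl_class)] = pred
        diff = predict_log10(theta, i) - obs_log10[i]
        resids[(obs.genotype_label, obs.idl_class)] = max(0.0, diff) if obs.is_bound else diff

    predicted_ratio: dict[str, float] = {}
    for label in labels:
        genotype = genotypes[label]
        e_pred = e_class[EXPANSION] * r.survival(genotype, EXPANSION)
        d_pred = e_class[DELETION] * scale * r.survival(genotype, DELETION)
        predicted_ratio[label] = e_pred / d_pred

    return MMRFitResult(
        efficiencies=r,
        residuals_log10=resids,
        predicted=predicted,
        predicted_ratio=predicted_ratio,
        non_identifiable=tuple(non_identifiable),
        rank_deficient=rank_deficient,
        deletion_scale=scale,
    )


def load_gtca19_panel() -> tuple[list[PanelObservation], PolSlippageModel, int]:
    """Published [GT/CA]19 mutant-frequency panel across MMR genotypes.

    Returns the four cell-line observations (expansion and deletion class
    frequencies; the repair-proficient-background deletion cell of LCL1261 is
    an upper bound), a polymerase slippage model anchored at the purified-
    polymerase (in vitro) frequencies for the same allele, and the allele
    length in units.
    """
    with resources.files("maturems.data").joinpath("gtca19_panel.tsv").open() as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        frame = pd.read_csv(fh, sep="\t", names=header)
    anchor = frame[frame["assay"] == "polymerase"].set_index("idl_class")["frequency"]
    pol = PolSlippageModel.from_point(
        e_exp=float(anchor[EXPANSION]), e_del=float(anchor[DELETION])
    )
    cells = frame[frame["assay"] == "ex_vivo"]
    panel = [
        PanelObservation(
            genotype_label=row.genotype,
            idl_class=row.idl_class,
            frequency=float(row.frequency),
            is_bound=bool(row.is_bound),
        )
        for row in cells.itertuples()
    ]
    return panel, pol, 19
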