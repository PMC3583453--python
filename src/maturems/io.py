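"""File-format readers and writers.

Dialects: FASTA (multi-record, wrapped or unwrapped, via Biopython); BED6
(0-based half-open, natively matching the package's coordinates); GFF3
(1-based inclusive — converted on read/write); tab-separated tables with a
'#'-prefixed header line, '.' for missing values, and scientific notation for
frequencies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Feature, TermAnnotation
from .assay import CloneAssay, MutantSpectrum, PolReaction
from .mmr import GENOTYPE_PRESETS, MMRGenotype, PanelObservation
from .scanner import RepeatLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_tsv",
    "read_tsv",
    "loci_to_frame",
    "frame_to_loci",
    "write_loci_tsv",
    "read_loci_tsv",
    "write_loci_bed",
    "read_loci_bed",
    "read_genes_exons_bed",
    "write_features_bed",
    "read_features_gff3",
    "write_features_gff3",
    "read_terms_tsv",
    "write_terms_tsv",
    "write_clone_assays",
    "read_clone_assays",
    "write_pol_reactions",
    "read_pol_reactions",
    "write_panel_tsv",
    "read_panel_tsv",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------- generic TSV

def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated with a '#'-prefixed header and '.' for missing values."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False, na_rep=".")


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
    return pd.read_csv(path, sep="\t", names=header, skiprows=1, na_values=".")


# ---------------------------------------------------------------- repeat loci

_LOCUS_COLUMNS = ["sequence_id", "start", "end", "family", "phase_motif", "units", "lifecycle"]


def loci_to_frame(loci: Iterable[RepeatLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (l.sequence_id, l.start, l.end, l.family, l.phase_motif, l.units, l.lifecycle)
            for l in loci
        ],
        columns=_LOCUS_COLUMNS,
    )


def frame_to_loci(frame: pd.DataFrame) -> list[RepeatLocus]:
    return [
        RepeatLocus(
            sequence_id=str(row.sequence_id),
            start=int(row.start),
            end=int(row.end),
            family=str(row.family),
            phase_motif=str(row.phase_motif),
            units=int(row.units),
            lifecycle=str(row.lifecycle),
        )
        for row in frame.itertuples()
    ]


def write_loci_tsv(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    write_tsv(loci_to_frame(loci), path)


def read_loci_tsv(path: str | Path) -> list[RepeatLocus]:
    return frame_to_loci(read_tsv(path))


def write_loci_bed(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    """BED6; name = family:phase_motif:units:lifecycle, score = units."""
    with open(path, "w") as fh:
        for l in loci:
            name = f"{l.family}:{l.phase_motif}:{l.units}:{l.lifecycle}"
            fh.write(f"{l.sequence_id}\t{l.start}\t{l.end}\t{name}\t{l.units}\t+\n")


def read_loci_bed(path: str | Path) -> list[RepeatLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, _strand = line.rstrip("\n").split("\t")[:6]
            family, phase, units, lifecycle = name.rsplit(":", 3)
            loci.append(
                RepeatLocus(chrom, int(start), int(end), family, phase, int(units), lifecycle)
            )
    return loci


# ---------------------------------------------------------------- features

def read_genes_exons_bed(genes_path: str | Path, exons_path: str | Path) -> list[Feature]:
    """Gene spans and exons from two BED files; BED name column = gene_id."""
    features: list[Feature] = []
    for path, kind in ((genes_path, "gene"), (exons_path, "exon")):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                features.append(
                    Feature(fields[0], int(fields[1]), int(fields[2]), kind, fields[3])
                )
    return features


def write_features_bed(
    features: Iterable[Feature], genes_path: str | Path, exons_path: str | Path
) -> None:
    with open(genes_path, "w") as gfh, open(exons_path, "w") as efh:
        for feat in features:
            fh = gfh if feat.kind == "gene" else efh
            fh.write(f"{feat.sequence_id}\t{feat.start}\t{feat.end}\t{feat.gene_id}\t0\t+\n")


def _gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_features_gff3(path: str | Path) -> list[Feature]:
    """Genes and exons from GFF3 (1-based inclusive -> 0-based half-open).

    gene_id comes from the ``gene_id`` attribute when present, else ``ID``
    for genes and ``Parent`` for exons.  Other feature types are ignored.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in ("gene", "exon"):
                continue
            attrs = _gff3_attributes(fields[8])
            gene_id = attrs.get(
                "gene_id", attrs.get("ID" if fields[2] == "gene" else "Parent", "")
            )
            features.append(
                Feature(fields[0], int(fields[3]) - 1, int(fields[4]), fields[2], gene_id)
            )
    return features


def write_features_gff3(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = (
                f"ID={feat.gene_id};gene_id={feat.gene_id}"
                if feat.kind == "gene"
                else f"Parent={feat.gene_id};gene_id={feat.gene_id}"
            )
            fh.write(
                f"{feat.sequence_id}\tmaturems\t{feat.kind}\t{feat.start + 1}\t"
                f"{feat.end}\t.\t+\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------- terms

def read_terms_tsv(path: str | Path, names_path: str | Path | None = None) -> list[TermAnnotation]:
    """Two-column gene_id<TAB>term_id mapping plus an optional term-name TSV."""
    frame = read_tsv(path)
    names: dict[str, str] = {}
    if names_path is not None:
        name_frame = read_tsv(names_path)
        names = dict(zip(name_frame["term_id"], name_frame["term_name"]))
    terms = []
    for term_id, group in frame.groupby("term_id"):
        terms.append(
            TermAnnotation(
                term_id=str(term_id),
                term_name=names.get(term_id, str(term_id)),
                genes=frozenset(group["gene_id"].astype(str)),
            )
        )
    return terms


def write_terms_tsv(
    terms: Iterable[TermAnnotation],
    path: str | Path,
    names_path: str | Path | None = None,
) -> None:
    rows = [(gene, term.term_id) for term in terms for gene in sorted(term.genes)]
    write_tsv(pd.DataFrame(rows, columns=["gene_id", "term_id"]), path)
    if names_path is not None:
        write_tsv(
            pd.DataFrame(
                [(t.term_id, t.term_name) for t in terms], columns=["term_id", "term_name"]
            ),
            names_path,
        )


# ---------------------------------------------------------------- clone assays

def write_clone_assays(
    assays: Sequence[CloneAssay], clones_path: str | Path, mutants_path: str | Path
) -> None:
    clones = pd.DataFrame(
        [(a.clone_id, a.n_fudr_cm, a.n_cm, a.doublings) for a in assays],
        columns=["clone_id", "n_fudr_cm", "n_cm", "doublings"],
    )
    write_tsv(clones, clones_path)
    rows = []
    for a in assays:
        idx = 0
        for d in a.spectrum.ms_unit_changes:
            rows.append((a.clone_id, f"{a.clone_id}.m{idx:03d}", "ms_indel", d))
            idx += 1
        for _ in range(a.spectrum.n_non_ms):
            rows.append((a.clone_id, f"{a.clone_id}.m{idx:03d}", "non_ms", None))
            idx += 1
    write_tsv(
        pd.DataFrame(rows, columns=["clone_id", "mutant_id", "class", "unit_change"]),
        mutants_path,
    )


def read_clone_assays(clones_path: str | Path, mutants_path: str | Path) -> list[CloneAssay]:
    clones = read_tsv(clones_path)
    required = {"clone_id", "n_fudr_cm", "n_cm", "doublings"}
    if not required <= set(clones.columns):
        raise ValueError(f"clones table is missing columns: {sorted(required - set(clones.columns))}")
    mutants = read_tsv(mutants_path)
    spectra: dict[str, MutantSpectrum] = {}
    for clone_id, group in mutants.groupby("clone_id"):
        changes = tuple(
            int(change)
            for cls, change in zip(group["class"], group["unit_change"])
            if cls == "ms_indel"
        )
        n_non_ms = int((group["class"] == "non_ms").sum())
        spectra[str(clone_id)] = MutantSpectrum(changes, n_non_ms)
    return [
        CloneAssay(
            clone_id=str(row.clone_id),
            n_fudr_cm=int(row.n_fudr_cm),
            n_cm=int(row.n_cm),
            doublings=float(row.doublings),
            spectrum=spectra.get(str(row.clone_id), MutantSpectrum(())),
        )
        for row in clones.itertuples()
    ]


# ---------------------------------------------------------------- pol reactions

def write_pol_reactions(
    reactions: Sequence[PolReaction],
    reactions_path: str | Path,
    reaction_mutants_path: str | Path,
) -> None:
    frame = pd.DataFrame(
        [
            (r.strand_label, r.allele_units, r.observed_mf, r.background_mf)
            for r in reactions
        ],
        columns=["strand", "allele_units", "observed_mf", "background_mf"],
    )
    write_tsv(frame, reactions_path)
    rows = []
    for r in reactions:
        idx = 0
        for d in r.spectrum.ms_unit_changes:
            rows.append((r.strand_label, f"{r.strand_label}.m{idx:03d}", "ms_indel", d))
            idx += 1
        for _ in range(r.spectrum.n_non_ms):
            rows.append((r.strand_label, f"{r.strand_label}.m{idx:03d}", "non_ms", None))
            idx += 1
    write_tsv(
        pd.DataFrame(rows, columns=["strand", "mutant_id", "class", "unit_change"]),
        reaction_mutants_path,
    )


def read_pol_reactions(
    reactions_path: str | Path, reaction_mutants_path: str | Path
) -> list[PolReaction]:
    frame = read_tsv(reactions_path)
    mutants = read_tsv(reaction_mutants_path)
    spectra: dict[str, MutantSpectrum] = {}
    for strand, group in mutants.groupby("strand"):
        changes = tuple(
            int(change)
            for cls, change in zip(group["class"], group["unit_change"])
            if cls == "ms_indel"
        )
        spectra[str(strand)] = MutantSpectrum(changes, int((group["class"] == "non_ms").sum()))
    return [
        PolReaction(
            strand_label=str(row.strand),
            observed_mf=float(row.observed_mf),
            background_mf=float(row.background_mf),
            spectrum=spectra.get(str(row.strand), MutantSpectrum(())),
            allele_units=int(row.allele_units),
        )
        for row in frame.itertuples()
    ]


# ---------------------------------------------------------------- MMR panel

def write_panel_tsv(panel: Sequence[PanelObservation], path: str | Path) -> None:
    rows = []
    for obs in panel:
        g = obs.genotype()
        rows.append(
            (
                obs.genotype_label,
                int(g.muts_alpha),
                int(g.muts_beta),
                int(g.mutl_alpha),
                int(g.mutl_gamma),
                obs.idl_class,
                obs.frequency,
                int(obs.is_bound),
            )
        )
    write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "genotype",
                "muts_alpha",
                "muts_beta",
                "mutl_alpha",
                "mutl_gamma",
                "idl_class",
                "frequency",
                "is_bound",
            ],
        ),
        path,
    )


def read_panel_tsv(path: str | Path) -> list[PanelObservation]:
    frame = read_tsv(path)
    panel = []
    for row in frame.itertuples():
        if {"muts_alpha", "muts_beta", "mutl_alpha", "mutl_gamma"} <= set(frame.columns):
            genotype = MMRGenotype(
                bool(row.muts_alpha),
                bool(row.muts_beta),
                bool(row.mutl_alpha),
                bool(row.mutl_gamma),
            )
        else:
            genotype = GENOTYPE_PRESETS[str(row.genotype)]
        panel.append(
            PanelObservation(
                genotype_label=str(row.genotype),
                idl_class=str(row.idl_class),
                frequency=float(row.frequency),
                is_bound=bool(row.is_bound),
                genotype_override=genotype,
            )
        )
    return panel
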