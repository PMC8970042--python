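"""Core record types and readers for the standard input formats.

The pipeline consumes per-species proteomes (FASTA, primary transcripts
only), gene models (GFF3 or a BED-like gene-order table), and a
species-lineage annotation table. Everything downstream works on the
plain dataclasses defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: lineage classes recognised by the community typology
LINEAGES = (
    "eudicot",
    "monocot",
    "basal_angiosperm",
    "moss",
    "lycophyte",
    "liverwort",
    "green_alga",
    "red_alga",
)

ALGAE_LINEAGES = frozenset({"green_alga", "red_alga"})


class DataError(ValueError):
    """Malformed input data (exit code 1 at the CLI)."""


class ConfigError(ValueError):
    """Invalid configuration or parameters (exit code 2 at the CLI)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate family member: one primary-transcript protein."""

    gene_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().rstrip("*")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise DataError(f"{self.gene_id}: empty protein sequence")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise DataError(
                f"{self.gene_id}: invalid residues {sorted(bad)} "
                "(expected 20-letter amino-acid alphabet plus X)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Genomic location and exon count of a gene's primary transcript."""

    gene_id: str
    species_id: str
    chromosome: str
    start: int  # 1-based bp
    end: int  # 1-based inclusive
    strand: str
    exon_count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise DataError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise DataError(f"{self.gene_id}: invalid coordinates {self.start}..{self.end}")
        if self.exon_count < 1:
            raise DataError(f"{self.gene_id}: exon_count must be >= 1")


@dataclass(frozen=True)
class SpeciesLineage:
    """Lineage annotation of one species (user-supplied configuration)."""

    species_id: str
    lineage: str
    order: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ConfigError(
                f"{self.species_id}: unknown lineage {self.lineage!r}; "
                f"expected one of {', '.join(LINEAGES)}"
            )


def read_proteome_fasta(path: str | Path, species_id: str) -> list[ProteinRecord]:
    """Read one species' primary-transcript proteome.

    Gene ids must be unique within the species; duplicates raise
    :class:`DataError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"{path}: duplicate gene id {rec.id}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, species_id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                header_of=None) -> None:
    """Write records as FASTA; ``header_of(record)`` overrides the id line."""
    seqs = [
        SeqRecord(Seq(r.sequence),
                  id=header_of(r) if header_of else r.gene_id,
                  description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_gene_order_tsv(path: str | Path) -> list[GeneModel]:
    """Read a BED-like gene-order table.

    Columns (tab-separated, ``#`` lines ignored):
    species, chromosome, start, end, strand, gene_id[, exon_count].
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise DataError(f"{path}:{lineno}: expected >=6 tab-separated columns")
            species, chrom, start, end, strand, gene_id = parts[:6]
            exon_count = int(parts[6]) if len(parts) > 6 and parts[6] else 1
            try:
                models.append(GeneModel(gene_id, species, chrom,
                                        int(start), int(end), strand, exon_count))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_gene_order_tsv(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#species\tchromosome\tstart\tend\tstrand\tgene_id\texon_count\n")
        for m in models:
            fh.write(f"{m.species_id}\t{m.chromosome}\t{m.start}\t{m.end}\t"
                     f"{m.strand}\t{m.gene_id}\t{m.exon_count}\n")


_PRIMARY_ATTRS = ("primary", "canonical", "longest")


def read_gene_models_gff3(path: str | Path, species_id: str) -> list[GeneModel]:
    """Extract one primary-transcript :class:`GeneModel` per gene from GFF3.

    The primary transcript is the mRNA flagged with a ``primary=1`` /
    ``canonical=1`` attribute; absent such a flag, the mRNA with the
    longest summed CDS (ties: lexicographically smallest transcript id).
    Genes whose primary mRNA has no exon features are reported with
    ``exon_count=1`` only if CDS features exist; otherwise they are
    skipped (flagged via the returned list simply not containing them).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            flagged = any(
                str(mrna.attributes.get(a, ["0"])[0]).lower() in {"1", "true", "yes"}
                for a in _PRIMARY_ATTRS
            )
            cds_len = sum(c.end - c.start + 1
                          for c in db.children(mrna, featuretype="CDS"))
            candidates.append((not flagged, -cds_len, mrna.id, mrna))
        if not candidates:
            continue
        mrna = min(candidates)[3]
        exons = list(db.children(mrna, featuretype="exon"))
        if not exons:
            exons = list(db.children(mrna, featuretype="CDS"))
        if not exons:
            continue
        models.append(GeneModel(gene.id, species_id, gene.seqid,
                                gene.start, gene.end, gene.strand or "+",
                                exon_count=len(exons)))
    return models


def read_lineage_table(path: str | Path) -> dict[str, SpeciesLineage]:
    """Read the species-lineage table (species_id, lineage, order, family)."""
    out: dict[str, SpeciesLineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\t", line)
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected at least species and lineage")
            sp = SpeciesLineage(parts[0], parts[1],
                                parts[2] if len(parts) > 2 else "",
                                parts[3] if len(parts) > 3 else "")
            out[sp.species_id] = sp
    return out


def write_lineage_table(lineages: Iterable[SpeciesLineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#species_id\tlineage\torder\tfamily\n")
        for sp in lineages:
            fh.write(f"{sp.species_id}\t{sp.lineage}\t{sp.order}\t{sp.family}\n")
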