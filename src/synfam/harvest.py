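"""Candidate harvesting: domain-hit tables, architectures, length filters.

Profile-HMM searching itself is delegated to external tools; this module
consumes their tabular outputs (hmmsearch ``--domtblout`` or InterProScan
TSV), composes per-protein domain architectures for a designated family
domain (e.g. the MatE Pfam domain for MATE transporters), and selects the
clean candidates that feed the identity-clustering stage. Everything else
lands in the ambiguous pool handled by the later classification steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import DataError, ConfigError, GeneModel, ProteinRecord

CATEGORIES = (
    "standard_two",
    "standard_one",
    "multiple_family",
    "with_nonspecific",
    "no_family_domain",
)

#: architecture categories admissible for the clustering stage
STANDARD_CATEGORIES = frozenset({"standard_one", "standard_two"})


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein; coordinates 1-based inclusive."""

    gene_id: str
    domain_id: str
    start: int
    end: int
    score: float = 0.0
    evalue: float = 0.0
    in_proteome: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"{self.gene_id}/{self.domain_id}: invalid coordinates "
                f"{self.start}..{self.end}"
            )
        if self.evalue < 0 or math.isnan(self.evalue):
            raise DataError(f"{self.gene_id}/{self.domain_id}: negative e-value")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain composition of one protein for a given family domain."""

    gene_id: str
    ordered_domains: tuple[str, ...]
    family_domain_count: int
    family_domain_total_len: int
    category: str


def parse_domain_table(path: str | Path, dialect: str) -> list[DomainHit]:
    """Parse a domain-hit table into :class:`DomainHit` rows.

    Parameters
    ----------
    dialect:
        ``"hmmsearch_domtbl"`` (hmmsearch ``--domtblout``; envelope
        coordinates are used) or ``"interproscan_tsv"``.

    Rows for genes not present in the proteome are *retained*; call
    :func:`flag_missing_genes` to mark them.
    """
    path = Path(path)
    if dialect == "hmmsearch_domtbl":
        return _parse_domtbl(path)
    if dialect == "interproscan_tsv":
        return _parse_interproscan(path)
    raise ConfigError(f"unknown domain-table dialect {dialect!r}")


def _parse_domtbl(path: Path) -> list[DomainHit]:
    from Bio import SearchIO

    hits: list[DomainHit] = []
    with open(path) as fh:
        if not fh.read().strip():
            return hits
    try:
        for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
            for hit in qresult:
                for hsp in hit:
                    # SearchIO uses 0-based half-open coordinates; the
                    # source format is 1-based inclusive envelope coords.
                    hits.append(DomainHit(
                        gene_id=hit.id,
                        domain_id=qresult.accession or qresult.id,
                        start=hsp.env_start + 1,
                        end=hsp.env_end,
                        score=float(hsp.bitscore),
                        evalue=float(hsp.evalue),
                    ))
    except Exception as exc:  # parser reports its own line context poorly
        raise DataError(f"{path}: malformed hmmsearch domain table ({exc})") from exc
    return hits


def _parse_interproscan(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise DataError(
                    f"{path}:{lineno}: expected >=9 tab-separated InterProScan columns"
                )
            try:
                score = parts[8]
                hits.append(DomainHit(
                    gene_id=parts[0],
                    domain_id=parts[4],
                    start=int(parts[6]),
                    end=int(parts[7]),
                    score=0.0,
                    evalue=float(score) if score not in {"-", ""} else 0.0,
                ))
            except (ValueError, DataError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return hits


def flag_missing_genes(hits: Sequence[DomainHit],
                       records: Iterable[ProteinRecord]) -> list[DomainHit]:
    """Return hits with ``in_proteome`` set from the given proteome."""
    known = {r.gene_id for r in records}
    return [
        hit if (hit.gene_id in known) == hit.in_proteome
        else DomainHit(hit.gene_id, hit.domain_id, hit.start, hit.end,
                       hit.score, hit.evalue, in_proteome=hit.gene_id in known)
        for hit in hits
    ]


def merge_family_hits(hits: Sequence[DomainHit],
                      min_overlap_fraction: float = 0.5) -> list[DomainHit]:
    """Merge family-domain hits overlapping by more than the given fraction
    of the shorter hit (split envelope reports are common)."""
    merged: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.start, h.end)):
        if merged:
            prev = merged[-1]
            overlap = min(prev.end, hit.end) - max(prev.start, hit.start) + 1
            if overlap > min_overlap_fraction * min(prev.span, hit.span):
                merged[-1] = DomainHit(
                    prev.gene_id, prev.domain_id,
                    min(prev.start, hit.start), max(prev.end, hit.end),
                    max(prev.score, hit.score), min(prev.evalue, hit.evalue),
                    prev.in_proteome,
                )
                continue
        merged.append(hit)
    return merged


def compose_architecture(hits: Sequence[DomainHit], protein: ProteinRecord,
                         family_domain: str) -> DomainArchitecture:
    """Order a protein's hits and categorise its domain architecture.

    Categories: exactly two family domains and nothing else →
    ``standard_two``; exactly one → ``standard_one``; more than two →
    ``multiple_family``; any non-family domain present (alongside at least
    one family domain) → ``with_nonspecific``; no family domain at all →
    ``no_family_domain``. Overlapping family hits are merged first (see
    :func:`merge_family_hits`), never raised as errors.
    """
    own = [h for h in hits if h.gene_id == protein.gene_id]
    if len(own) != len(hits):
        raise DataError(
            f"{protein.gene_id}: hits for other genes passed to compose_architecture"
        )
    family = merge_family_hits([h for h in own if h.domain_id == family_domain])
    other = sorted((h for h in own if h.domain_id != family_domain),
                   key=lambda h: (h.start, h.end))
    ordered = tuple(h.domain_id for h in sorted(family + other,
                                                key=lambda h: (h.start, h.end)))
    total_len = min(sum(h.span for h in family), protein.length)

    if not family:
        category = "no_family_domain"
    elif other:
        category = "with_nonspecific"
    elif len(family) == 1:
        category = "standard_one"
    elif len(family) == 2:
        category = "standard_two"
    else:
        category = "multiple_family"

    return DomainArchitecture(protein.gene_id, ordered, len(family),
                              total_len, category)


def count_introns(model: GeneModel) -> int:
    """Intron count of the primary transcript: ``exon_count - 1``."""
    return model.exon_count - 1


def select_clustering_candidates(
    records: Sequence[ProteinRecord],
    architectures: Mapping[str, DomainArchitecture],
    full_len_range: tuple[int, int] = (350, 650),
    domain_len_range: tuple[int, int] = (140, 340),
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split the harvest into clustering candidates and the ambiguous pool.

    A record is a candidate iff its full length and summed family-domain
    length fall inside the given inclusive ranges and its architecture is
    standard (one or two family domains, nothing else). Everything else —
    fragments, fusions, extra non-family domains, proteins with no family
    domain — goes to the ambiguous pool for the later rescue steps. The
    two sets always partition the input.
    """
    lo, hi = full_len_range
    dlo, dhi = domain_len_range
    candidates: list[ProteinRecord] = []
    ambiguous: list[ProteinRecord] = []
    for rec in records:
        try:
            arch = architectures[rec.gene_id]
        except KeyError:
            raise DataError(f"{rec.gene_id}: no architecture composed") from None
        ok = (
            arch.category in STANDARD_CATEGORIES
            and lo <= rec.length <= hi
            and dlo <= arch.family_domain_total_len <= dhi
        )
        (candidates if ok else ambiguous).append(rec)
    return candidates, ambiguous


def harvest_table(records: Sequence[ProteinRecord],
                  architectures: Mapping[str, DomainArchitecture],
                  models: Mapping[str, GeneModel] | None = None) -> pd.DataFrame:
    """Tabular harvest summary (one row per protein)."""
    models = models or {}
    rows = []
    for rec in records:
        arch = architectures.get(rec.gene_id)
        model = models.get(rec.gene_id)
        rows.append({
            "gene_id": rec.gene_id,
            "species": rec.species_id,
            "length": rec.length,
            "architecture": "-".join(arch.ordered_domains) if arch else "",
            "category": arch.category if arch else "no_family_domain",
            "family_domain_len": arch.family_domain_total_len if arch else 0,
            "intron_count": count_introns(model) if model else pd.NA,
        })
    return pd.DataFrame(rows)
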