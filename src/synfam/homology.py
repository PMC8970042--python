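"""Homology rules, the four-step classifier, and the reference dataset.

The assignment machinery behind classification steps 2 and 4: a strict
subgroup rule (>= 60% identity, E <= 1e-5, alignment covering >= 60% of
the query or >= 150 aa), a relaxed group-level rule (>= 40%, >= 40% or
>= 100 aa), a reference-database classifier usable on new species, the
four-step orchestrator combining cluster, homology and synteny evidence,
and export/import of the pipe-delimited classified reference FASTA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from sklearn.base import BaseEstimator, ClassifierMixin

from .align import AlignmentParams, SearchHit, search_database
from .records import ConfigError, DataError, ProteinRecord

ASSIGNMENT_LEVELS = ("subgroup", "group_only", "unclassified", "non_family")
STEPS = ("step1_cluster", "step2_homology", "step3_synteny", "step4_rescue",
         "group_pass")


@dataclass(frozen=True)
class AssignmentRule:
    """Threshold rule deciding whether a search hit supports assignment.

    Satisfied iff identity >= ``min_identity`` AND evalue <= ``max_evalue``
    AND (align_len >= ``min_cov_fraction`` * query_len OR
    align_len >= ``min_abs_len``).
    """

    min_identity: float
    max_evalue: float
    min_cov_fraction: float
    min_abs_len: int

    def __post_init__(self) -> None:
        if min(self.min_identity, self.max_evalue,
               self.min_cov_fraction, self.min_abs_len) <= 0:
            raise ConfigError("all rule thresholds must be positive")

    def satisfied_by(self, hit: SearchHit, query_len: int) -> bool:
        return (
            hit.pct_identity >= self.min_identity
            and hit.evalue <= self.max_evalue
            and (hit.align_len >= self.min_cov_fraction * query_len
                 or hit.align_len >= self.min_abs_len)
        )


#: strict subgroup-assignment rule
STRICT_SUBGROUP_RULE = AssignmentRule(60.0, 1e-5, 0.60, 150)
#: relaxed group-assignment rule
RELAXED_GROUP_RULE = AssignmentRule(40.0, 1e-5, 0.40, 100)


@dataclass(frozen=True)
class Assignment:
    """Final classification of one gene, with its provenance step."""

    gene_id: str
    level: str
    label: str | None
    step: str | None
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.level not in ASSIGNMENT_LEVELS:
            raise DataError(f"{self.gene_id}: unknown level {self.level!r}")
        if self.level in {"subgroup", "group_only"} and not self.label:
            raise DataError(f"{self.gene_id}: {self.level} assignment needs a label")


def apply_assignment_rule(
    query: ProteinRecord,
    hits: Sequence[SearchHit],
    rule: AssignmentRule,
    label_of: Mapping[str, str] | Callable[[str], str | None],
    step: str = "step2_homology",
    level: str = "subgroup",
) -> Assignment | None:
    """Label the query from its highest-bitscore qualifying hit.

    ``hits`` must be sorted by decreasing bitscore (as returned by the
    search). Hits whose subject lacks a label are skipped with a warning;
    if no hit qualifies, returns ``None``.
    """
    get = label_of.get if isinstance(label_of, Mapping) else label_of
    for hit in hits:
        if not rule.satisfied_by(hit, query.length):
            continue
        label = get(hit.subject_id)
        if label is None:
            warnings.warn(f"{query.gene_id}: qualifying subject "
                          f"{hit.subject_id} has no label; skipped")
            continue
        evidence = (f"subject={hit.subject_id} identity={hit.pct_identity:.1f} "
                    f"alen={hit.align_len} evalue={hit.evalue:.2e}")
        return Assignment(query.gene_id, level, label, step, evidence)
    return None


def apply_group_rule(query, hits, rule, group_of, step="group_pass"):
    """Relaxed group-level counterpart of :func:`apply_assignment_rule`."""
    return apply_assignment_rule(query, hits, rule, group_of,
                                 step=step, level="group_only")


class ReferenceHomologyClassifier(ClassifierMixin, BaseEstimator):
    """Classify proteins against a labelled reference set (sklearn-style).

    ``fit`` stores the reference records and their subgroup labels;
    ``predict`` searches each query against the reference (top-``k``
    local-alignment hits) and applies the assignment rule. Queries with
    no qualifying hit predict ``None``.

    Parameters
    ----------
    rule : AssignmentRule, default strict subgroup rule
    k : int, default 5
        Number of hits retained per query.
    """

    def __init__(self, rule: AssignmentRule = STRICT_SUBGROUP_RULE, k: int = 5,
                 params: AlignmentParams = AlignmentParams()):
        self.rule = rule
        self.k = k
        self.params = params

    def fit(self, X: Sequence[ProteinRecord], y: Sequence[str]):
        if len(X) != len(y):
            raise ConfigError("reference records and labels differ in length")
        if not len(X):
            raise ConfigError("reference database is empty")
        self.reference_ = list(X)
        self.label_of_ = {r.gene_id: lab for r, lab in zip(X, y)}
        self.classes_ = sorted(set(y))
        self.db_residues_ = sum(r.length for r in X)
        return self

    def search(self, query: ProteinRecord) -> list[SearchHit]:
        return search_database(query, self.reference_, k=self.k,
                               params=self.params, db_residues=self.db_residues_)

    def assign(self, query: ProteinRecord, step: str = "step2_homology",
               level: str = "subgroup") -> Assignment | None:
        return apply_assignment_rule(query, self.search(query), self.rule,
                                     self.label_of_, step=step, level=level)

    def predict(self, X: Sequence[ProteinRecord]) -> list[str | None]:
        a = [self.assign(q) for q in X]
        return [x.label if x else None for x in a]


def run_four_step_classification(
    candidates: Sequence[ProteinRecord],
    ambiguous: Sequence[ProteinRecord],
    subgroups,
    architectures: Mapping[str, "DomainArchitecture"] | None = None,
    synteny_context=None,
    strict_rule: AssignmentRule = STRICT_SUBGROUP_RULE,
    relaxed_rule: AssignmentRule = RELAXED_GROUP_RULE,
    k: int = 5,
    min_same_subgroup: int = 4,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[dict[str, Assignment], pd.DataFrame]:
    """Run classification steps 1-4 plus the relaxed group pass.

    Step 1 labels the members of the subgroup-defining clusters. Step 2
    searches every still-unclassified protein against the step-1 database
    under the strict rule. Step 3 applies the synteny vote (an
    unclassified gene syntenic to at least ``min_same_subgroup``
    classified genes of a single subgroup inherits that subgroup). Step 4
    repeats the strict homology rule against the enlarged database of
    everything classified so far. A final relaxed pass assigns group-only
    labels; remaining genes with no family domain become ``non_family``,
    all others ``unclassified``.

    Returns the per-gene assignments and a per-step audit table.
    """
    from .synteny import synteny_assign  # local import; no module cycle at import time

    records = {r.gene_id: r for r in list(candidates) + list(ambiguous)}
    assignments: dict[str, Assignment] = {}
    audit_rows = []

    # step 1: cluster membership
    label_of: dict[str, str] = {}
    group_of_subgroup: dict[str, str] = {}
    for s in subgroups:
        group_of_subgroup[s.label] = s.group or s.label
        for g in s.member_ids:
            label_of[g] = s.label
            assignments[g] = Assignment(g, "subgroup", s.label, "step1_cluster",
                                        evidence=f"cluster={s.label} size={s.size}")
    audit_rows.append(("step1_cluster", len(records), len(assignments)))

    def unassigned() -> list[ProteinRecord]:
        return [records[g] for g in sorted(records) if g not in assignments]

    # step 2: strict homology vs the step-1 database
    step1_db = [records[g] for g in sorted(label_of) if g in records]
    n_before = len(assignments)
    pool = unassigned()
    if step1_db:
        clf = ReferenceHomologyClassifier(strict_rule, k, params).fit(
            step1_db, [label_of[r.gene_id] for r in step1_db])
        for query in pool:
            a = clf.assign(query, step="step2_homology")
            if a:
                assignments[query.gene_id] = a
    audit_rows.append(("step2_homology", len(pool), len(assignments) - n_before))

    # step 3: synteny vote
    n_before = len(assignments)
    pool = unassigned()
    if synteny_context is not None and pool:
        new = synteny_assign([r.gene_id for r in pool], synteny_context,
                             assignments, min_same_subgroup=min_same_subgroup)
        assignments.update(new)
    audit_rows.append(("step3_synteny", len(pool), len(assignments) - n_before))

    # step 4: strict homology vs everything classified in steps 1-3
    n_before = len(assignments)
    pool = unassigned()
    classified = {g: a.label for g, a in assignments.items()
                  if a.level == "subgroup" and g in records}
    if classified and pool:
        db = [records[g] for g in sorted(classified)]
        clf = ReferenceHomologyClassifier(strict_rule, k, params).fit(
            db, [classified[r.gene_id] for r in db])
        for query in pool:
            a = clf.assign(query, step="step4_rescue")
            if a:
                assignments[query.gene_id] = a
    audit_rows.append(("step4_rescue", len(pool), len(assignments) - n_before))

    # relaxed pass: group-only labels for whatever remains
    n_before = len(assignments)
    pool = unassigned()
    classified = {g: a.label for g, a in assignments.items()
                  if a.level == "subgroup" and g in records}
    if classified and pool:
        db = [records[g] for g in sorted(classified)]
        group_labels = [group_of_subgroup.get(classified[r.gene_id],
                                              classified[r.gene_id]) for r in db]
        clf = ReferenceHomologyClassifier(relaxed_rule, k, params).fit(db, group_labels)
        for query in pool:
            a = clf.assign(query, step="group_pass", level="group_only")
            if a:
                assignments[query.gene_id] = a
    audit_rows.append(("group_pass", len(pool), len(assignments) - n_before))

    # terminal states
    architectures = architectures or {}
    for query in unassigned():
        arch = architectures.get(query.gene_id)
        if arch is not None and arch.category == "no_family_domain":
            assignments[query.gene_id] = Assignment(
                query.gene_id, "non_family", None, None,
                evidence="no family domain and no qualifying evidence")
        else:
            assignments[query.gene_id] = Assignment(
                query.gene_id, "unclassified", None, None)

    audit = pd.DataFrame(audit_rows, columns=["stage", "n_input", "n_assigned"])
    totals = pd.DataFrame([
        ("subgroup_total", len(records),
         sum(a.level == "subgroup" for a in assignments.values())),
        ("group_only_total", len(records),
         sum(a.level == "group_only" for a in assignments.values())),
        ("unclassified_total", len(records),
         sum(a.level == "unclassified" for a in assignments.values())),
        ("non_family_total", len(records),
         sum(a.level == "non_family" for a in assignments.values())),
    ], columns=["stage", "n_input", "n_assigned"])
    return assignments, pd.concat([audit, totals], ignore_index=True)


def assignments_table(assignments: Mapping[str, Assignment],
                      records: Mapping[str, ProteinRecord]) -> pd.DataFrame:
    rows = []
    for gene_id in sorted(assignments):
        a = assignments[gene_id]
        rec = records.get(gene_id)
        rows.append({
            "gene_id": gene_id,
            "species": rec.species_id if rec else "",
            "level": a.level,
            "label": a.label or "",
            "step": a.step or "",
            "evidence": a.evidence,
        })
    return pd.DataFrame(rows)


def build_reference_dataset(
    assignments: Mapping[str, Assignment],
    records: Mapping[str, ProteinRecord],
    architectures: Mapping[str, "DomainArchitecture"] | None = None,
    path: str | Path | None = None,
    full_len_range: tuple[int, int] = (351, 650),
    domain_len_range: tuple[int, int] = (79, 342),
) -> list[tuple[ProteinRecord, str, str]]:
    """Export subgroup-classified members as the reference FASTA.

    Headers carry five pipe-delimited attributes:
    ``gene_id|species|subgroup|length|step``. Members are filtered to the
    reference length envelope (full length and, when architectures are
    supplied, summed family-domain length). Returns the retained
    ``(record, subgroup, step)`` triples; writes FASTA when ``path`` is
    given. Duplicate gene ids raise an error.
    """
    lo, hi = full_len_range
    dlo, dhi = domain_len_range
    kept: list[tuple[ProteinRecord, str, str]] = []
    seen: set[str] = set()
    for gene_id in sorted(assignments):
        a = assignments[gene_id]
        if a.level != "subgroup":
            continue
        if gene_id in seen:
            raise DataError(f"duplicate gene id {gene_id} in reference export")
        seen.add(gene_id)
        rec = records.get(gene_id)
        if rec is None:
            continue
        if not (lo <= rec.length <= hi):
            continue
        if architectures is not None:
            arch = architectures.get(gene_id)
            if arch is None or not (dlo <= arch.family_domain_total_len <= dhi):
                continue
        kept.append((rec, a.label, a.step or ""))
    if path is not None:
        with open(path, "w") as fh:
            for rec, label, step in kept:
                fh.write(f">{rec.gene_id}|{rec.species_id}|{label}|{rec.length}|{step}\n")
                for i in range(0, rec.length, 60):
                    fh.write(rec.sequence[i:i + 60] + "\n")
    return kept


def parse_reference_fasta(path: str | Path) -> list[tuple[ProteinRecord, str, str]]:
    """Parse a reference FASTA with ``id|species|subgroup|length|step`` headers."""
    out: list[tuple[ProteinRecord, str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        parts = header.split("|")
        if len(parts) != 5:
            raise DataError(f"{path}: header {header!r} does not have 5 "
                            "pipe-delimited attributes")
        gene_id, species, subgroup, length, step = parts
        record = ProteinRecord(gene_id, species, str(rec.seq))
        if int(length) != record.length:
            raise DataError(f"{path}: header length {length} != sequence "
                            f"length {record.length} for {gene_id}")
        out.append((record, subgroup, step))
    if not out:
        raise ConfigError(f"{path}: reference dataset is empty")
    return out


def classify_new_species(
    proteome: Sequence[ProteinRecord],
    reference: str | Path | Sequence[tuple[ProteinRecord, str, str]],
    rule: AssignmentRule = STRICT_SUBGROUP_RULE,
    k: int = 5,
    relaxed_rule: AssignmentRule | None = None,
    group_of: Mapping[str, str] | None = None,
    params: AlignmentParams = AlignmentParams(),
) -> dict[str, Assignment]:
    """One-pass classification of a new species against the reference set.

    Each query receives the subgroup of its best qualifying hit under the
    strict rule; when ``relaxed_rule`` is given, queries that fail it are
    retried at group level (``group_of`` maps subgroup → group; defaults
    to the subgroup's leading Roman-numeral prefix).
    """
    if isinstance(reference, (str, Path)):
        reference = parse_reference_fasta(reference)
    if not reference:
        raise ConfigError("reference dataset is empty")
    refs = [r for r, _, _ in reference]
    labels = [label for _, label, _ in reference]
    clf = ReferenceHomologyClassifier(rule, k, params).fit(refs, labels)
    if group_of is None:
        group_of = {lab: _group_prefix(lab) for lab in set(labels)}

    out: dict[str, Assignment] = {}
    for query in proteome:
        a = clf.assign(query, step="step2_homology")
        if a is None and relaxed_rule is not None:
            hits = clf.search(query)
            a = apply_group_rule(query, hits, relaxed_rule,
                                 lambda s: group_of.get(clf.label_of_[s]))
        out[query.gene_id] = a or Assignment(query.gene_id, "unclassified",
                                             None, None)
    return out


def _group_prefix(subgroup: str) -> str:
    prefix = ""
    for ch in subgroup:
        if ch in "IVXLCDM":
            prefix += ch
        else:
            break
    return prefix or subgroup
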