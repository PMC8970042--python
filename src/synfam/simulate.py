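"""Seeded synthetic plant genomes with planted family structure.

The generator emulates the statistical structure the classification
pipeline assumes: a gene family of several subgroups separated by a wide
identity gap (within-subgroup identity near a target, between-subgroup
identity at random-sequence background), family genes embedded in
chromosomes inside conserved loci whose shared flanking background genes
form collinear blocks, lineage-specific translocations and losses that
reshape the synteny communities, and degenerate proteins (fragments,
domain fusions, non-specific-domain carriers, heavily diverged copies)
of the kinds the rescue steps exist for.

Sequence evolution is a star phylogeny per subgroup under uniform random
substitution with no indels: each descendant site mutates with a
per-branch probability solved numerically so the expected pairwise
identity between two descendants matches the configured target
(expected identity (1-q)^2 + q^2/19 for substitution probability q).
All randomness flows from the single mandatory seed.

Ground truth (subgroups, communities and their typology, planted blocks,
degenerate defects) is recorded in a :class:`PlantedTruth` serialised
alongside the outputs, enabling exact recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .harvest import DomainHit
from .records import (ConfigError, GeneModel, ProteinRecord, SpeciesLineage,
                      write_fasta, write_gene_order_tsv, write_lineage_table)

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

DEGENERATE_KINDS = ("truncation", "fusion", "nonspecific_insert",
                    "diverged", "late_fragment", "orphan_diverged")


def default_species_panel() -> list[SpeciesLineage]:
    """Six-species angiosperm panel: three eudicots (two Brassicaceae,
    one Solanaceae), two Poaceae monocots, one basal angiosperm."""
    return [
        SpeciesLineage("Ath", "eudicot", "Brassicales", "Brassicaceae"),
        SpeciesLineage("Aly", "eudicot", "Brassicales", "Brassicaceae"),
        SpeciesLineage("Sly", "eudicot", "Solanales", "Solanaceae"),
        SpeciesLineage("Osa", "monocot", "Poales", "Poaceae"),
        SpeciesLineage("Zma", "monocot", "Poales", "Poaceae"),
        SpeciesLineage("Atr", "basal_angiosperm", "Amborellales", "Amborellaceae"),
    ]


def typology_species_panel() -> list[SpeciesLineage]:
    """Twelve-species panel covering every lineage the community
    typology distinguishes."""
    return [
        SpeciesLineage("EudA1", "eudicot", "Brassicales", "Brassicaceae"),
        SpeciesLineage("EudA2", "eudicot", "Brassicales", "Brassicaceae"),
        SpeciesLineage("EudB1", "eudicot", "Solanales", "Solanaceae"),
        SpeciesLineage("MonA1", "monocot", "Poales", "Poaceae"),
        SpeciesLineage("MonA2", "monocot", "Poales", "Poaceae"),
        SpeciesLineage("MonB1", "monocot", "Zingiberales", "Musaceae"),
        SpeciesLineage("Bas1", "basal_angiosperm", "Amborellales", "Amborellaceae"),
        SpeciesLineage("Bas2", "basal_angiosperm", "Nymphaeales", "Nymphaeaceae"),
        SpeciesLineage("Alg1", "green_alga", "Chlamydomonadales", "Chlamydomonadaceae"),
        SpeciesLineage("Alg2", "green_alga", "Chlamydomonadales", "Chlamydomonadaceae"),
        SpeciesLineage("Mos1", "moss", "Funariales", "Funariaceae"),
        SpeciesLineage("Lyc1", "lycophyte", "Selaginellales", "Selaginellaceae"),
    ]


@dataclass(frozen=True)
class CommunitySpec:
    """One planted community: an orthogroup spanning the listed species
    (repeats plant multiple copies in one species)."""

    species: tuple[str, ...]
    subgroup: int = 0
    expected_type: str | None = None


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic run. ``seed`` is mandatory."""

    seed: int
    n_subgroups: int = 4
    genes_per_subgroup: int = 60
    species: list[SpeciesLineage] = field(default_factory=default_species_panel)
    within_subgroup_identity_target: float = 75.0
    between_subgroup_identity_ceiling: float = 40.0
    family_protein_length: int = 400
    family_domain_id: str = "MatE"
    genes_per_chromosome: int = 600
    block_flank_size: int = 10
    spacer_genes: int = 30
    translocation_rate: float = 0.0
    translocation_lineage: str = "monocot"
    loss_rate: float = 0.0
    degenerate_fraction: float = 0.20
    degenerate_kinds: tuple[str, ...] = (
        "truncation", "fusion", "nonspecific_insert", "diverged", "late_fragment")
    diverged_identity_target: float = 48.0
    n_decoys: int = 2
    community_plan: list[CommunitySpec] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        t, c = self.within_subgroup_identity_target, self.between_subgroup_identity_ceiling
        if not c < t:
            raise ConfigError(
                f"infeasible identity targets: ceiling {c} must be below target {t}")
        for rate in (self.translocation_rate, self.loss_rate,
                     self.degenerate_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.family_protein_length < 395:
            raise ConfigError("family_protein_length must be >= 395 to hold "
                              "two 161-residue family domains")
        unknown = set(self.degenerate_kinds) - set(DEGENERATE_KINDS)
        if unknown:
            raise ConfigError(f"unknown degenerate kinds {sorted(unknown)}")
        if self.spacer_genes <= 25:
            raise ConfigError("spacer_genes must exceed the 25-gene block gap "
                              "so neighbouring loci stay in separate blocks")


@dataclass
class PlantedTruth:
    """Serializable ground truth of one synthetic run."""

    subgroup_of: dict[str, str] = field(default_factory=dict)
    community_of: dict[str, str] = field(default_factory=dict)
    community_type: dict[str, str] = field(default_factory=dict)
    blocks: list[list[list[str]]] = field(default_factory=list)
    degenerates: dict[str, str] = field(default_factory=dict)
    decoys: list[str] = field(default_factory=list)
    losses: list[list[str]] = field(default_factory=list)
    translocated: list[str] = field(default_factory=list)

    def community_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, cid in self.community_of.items():
            out.setdefault(cid, set()).add(gene)
        return out

    def block_keys(self) -> set[frozenset]:
        return {frozenset(frozenset(pair) for pair in block)
                for block in self.blocks}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    """In-memory result of one generator run."""

    config: SyntheticConfig
    records: list[ProteinRecord]
    gene_models: list[GeneModel]
    domain_hits: list[DomainHit]
    homology_pairs: list[tuple[str, str]]
    lineages: dict[str, SpeciesLineage]
    truth: PlantedTruth

    def records_by_id(self) -> dict[str, ProteinRecord]:
        return {r.gene_id: r for r in self.records}

    def species_of(self) -> dict[str, str]:
        return {r.gene_id: r.species_id for r in self.records}

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA per species, gene order, domain table (InterProScan
        TSV dialect), homology pairs (blast tabular), lineage table and
        truth JSON under one directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_species: dict[str, list[ProteinRecord]] = {}
        for r in self.records:
            by_species.setdefault(r.species_id, []).append(r)
        for sp in sorted(by_species):
            write_fasta(sorted(by_species[sp], key=lambda r: r.gene_id),
                        outdir / f"{sp}.faa")
        write_gene_order_tsv(
            sorted(self.gene_models,
                   key=lambda m: (m.species_id, m.chromosome, m.start, m.gene_id)),
            outdir / "gene_order.tsv")
        lengths = {r.gene_id: r.length for r in self.records}
        with open(outdir / "domain_hits.tsv", "w") as fh:
            for h in sorted(self.domain_hits,
                            key=lambda h: (h.gene_id, h.start, h.domain_id)):
                fh.write("\t".join([
                    h.gene_id, "-", str(lengths.get(h.gene_id, h.end)), "Pfam",
                    h.domain_id, "synthetic domain hit",
                    str(h.start), str(h.end), f"{h.evalue:.3g}", "T", "-",
                ]) + "\n")
        with open(outdir / "homology_pairs.tsv", "w") as fh:
            for a, b in sorted(self.homology_pairs):
                la = lengths.get(a, 500)
                fh.write(f"{a}\t{b}\t90.0\t{la}\t0\t0\t1\t{la}\t1\t{la}"
                         f"\t1e-100\t500.0\n")
        write_lineage_table([self.lineages[s] for s in sorted(self.lineages)],
                            outdir / "lineages.tsv")
        self.truth.to_json(outdir / "truth.json")


def solve_substitution_probability(target_identity_pct: float) -> float:
    """Per-branch substitution probability whose star-tree expected
    pairwise identity equals the target (two branches per pair)."""
    t = target_identity_pct / 100.0

    def expected(q: float) -> float:
        return (1 - q) ** 2 + q ** 2 / 19.0

    return float(brentq(lambda q: expected(q) - t, 0.0, 0.95))


def _single_branch_probability(target_identity_pct: float) -> float:
    """Substitution probability for one branch at the target identity to
    the unmutated source: identity = (1-q) + q/19."""
    t = target_identity_pct / 100.0
    return (1.0 - t) / (1.0 - 1.0 / 19.0)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length, dtype=np.uint8)


def _mutate(seq: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < q
    n = int(hit.sum())
    if n:
        # uniform over the 19 other residues
        out[hit] = (out[hit] + 1 + rng.integers(0, 19, size=n, dtype=np.uint8)) % 20
    return out


def _to_str(seq: np.ndarray) -> str:
    return _AA[seq].tobytes().decode()


def mutate_sequence(sequence: str, q: float, rng: np.random.Generator) -> str:
    """Point-substitute each site with probability ``q`` (uniform over
    the 19 other residues); the building block of the generator, exposed
    for constructing derived test sequences."""
    lookup = np.full(256, 0, dtype=np.uint8)
    for i, aa in enumerate(_AA):
        lookup[aa] = i
    arr = lookup[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    return _to_str(_mutate(arr, q, rng))


def _domain_coords(length: int) -> tuple[tuple[int, int], tuple[int, int]]:
    return (21, 181), (length - 179, length - 19)


def generate_family(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic dataset with planted ground truth.

    See the module docstring for the model; reruns with the same config
    are byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    lineages = {s.species_id: s for s in config.species}
    species_ids = [s.species_id for s in config.species]
    q = solve_substitution_probability(config.within_subgroup_identity_target)
    L = config.family_protein_length
    (d1s, d1e), (d2s, d2e) = _domain_coords(L)
    fam = config.family_domain_id

    plan = config.community_plan
    if plan is None:
        if config.genes_per_subgroup % len(species_ids):
            raise ConfigError("genes_per_subgroup must be a multiple of the "
                              "species panel size for the default community plan")
        per = config.genes_per_subgroup // len(species_ids)
        plan = [CommunitySpec(tuple(species_ids), sg)
                for sg in range(config.n_subgroups) for _ in range(per)]
    for spec in plan:
        for sp in spec.species:
            if sp not in lineages:
                raise ConfigError(f"community plan references unknown species {sp}")

    truth = PlantedTruth()
    records: list[ProteinRecord] = []
    domain_hits: list[DomainHit] = []
    homology_pairs: list[tuple[str, str]] = []

    ancestors = {sg: _random_seq(rng, L)
                 for sg in range(config.n_subgroups)}

    # --- orthogroups (one per planted community) -------------------------
    # ortho_instances[og] = list of (gene_id, species, flank_context)
    # flank_context names the background-gene orthogroup set a locus uses;
    # loci sharing a context become collinear blocks.
    ortho_ids: list[str] = []
    ortho_instances: dict[str, list[tuple[str, str, str]]] = {}
    ortho_subgroup: dict[str, str] = {}
    seqs: dict[str, np.ndarray] = {}
    counters: dict[str, int] = {}

    trans_species = {s.species_id for s in config.species
                     if s.lineage == config.translocation_lineage}

    for idx, spec in enumerate(plan):
        sg_label = f"SG{spec.subgroup + 1}"
        og = f"{sg_label}og{idx + 1:03d}"
        ortho_ids.append(og)
        ortho_subgroup[og] = sg_label
        translocate = (config.translocation_rate > 0
                       and rng.random() < config.translocation_rate
                       and any(sp in trans_species for sp in spec.species))
        if translocate:
            truth.translocated.append(og)
        instances: list[tuple[str, str, str]] = []
        for sp in spec.species:
            if config.loss_rate > 0 and rng.random() < config.loss_rate:
                truth.losses.append([og, sp])
                continue
            copy = counters[(og, sp)] = counters.get((og, sp), 0) + 1
            gene_id = f"{sp}_{og}" + (f"_c{copy}" if copy > 1 else "")
            seqs[gene_id] = _mutate(ancestors[spec.subgroup], q, rng)
            context = (f"{og}T" if translocate and sp in trans_species else og)
            instances.append((gene_id, sp, context))
            truth.subgroup_of[gene_id] = sg_label
        ortho_instances[og] = instances
        expected = spec.expected_type
        cid_main = og
        for gene_id, sp, context in instances:
            cid = f"{og}.t" if context.endswith("T") else og
            truth.community_of[gene_id] = cid
        for cid in sorted({truth.community_of[g] for g, _, _ in instances}):
            if expected is not None:
                truth.community_type[cid] = expected

    core_ids = sorted(truth.subgroup_of)

    # --- degenerates ------------------------------------------------------
    n_deg = int(round(config.degenerate_fraction * len(core_ids)))
    kinds = [config.degenerate_kinds[i % len(config.degenerate_kinds)]
             for i in range(n_deg)]
    kind_counts = {k: kinds.count(k) for k in config.degenerate_kinds}
    sources = list(rng.choice(core_ids, size=n_deg, replace=False)) if n_deg else []
    q_div = _single_branch_probability(config.diverged_identity_target)

    degenerate_records: list[tuple[str, str, np.ndarray, list[DomainHit], str]] = []
    # (gene_id, kind, seq, hits, placement) placement: "tandem:<src>" | "dup:<src>"
    diverged_ids: list[str] = []
    src_iter = iter(sources)

    def next_src() -> str:
        return str(next(src_iter))

    for kind in ("diverged", "orphan_diverged", "truncation", "fusion",
                 "nonspecific_insert", "late_fragment"):
        for k in range(kind_counts.get(kind, 0)):
            if kind == "late_fragment":
                if not diverged_ids:
                    raise ConfigError("late_fragment degenerates require "
                                      "diverged degenerates in the mix")
                src = str(diverged_ids[int(rng.integers(len(diverged_ids)))])
                base = seqs[src]
            else:
                src = next_src()
                base = seqs[src]
            gene_id = f"{src}_{kind}{k + 1}"
            if kind in {"diverged", "orphan_diverged"}:
                seq = _mutate(base, q_div, rng)
                hits = [DomainHit(gene_id, fam, d1s, d1e, 250.0, 1e-50),
                        DomainHit(gene_id, fam, d2s, d2e, 250.0, 1e-50)]
                placement = "dup" if kind == "diverged" else "tandem"
                if kind == "diverged":
                    diverged_ids.append(gene_id)
            elif kind == "truncation":
                t_len = int(rng.integers(150, 350))
                seq = base[:t_len]
                hits = []
                for ds, de in ((d1s, d1e), (d2s, d2e)):
                    if ds <= t_len - 30:
                        hits.append(DomainHit(gene_id, fam, ds, min(de, t_len),
                                              200.0, 1e-30))
                placement = "tandem"
            elif kind == "fusion":
                seq = np.concatenate([base, base[d2s - 1:d2e]])
                hits = [DomainHit(gene_id, fam, d1s, d1e, 250.0, 1e-50),
                        DomainHit(gene_id, fam, d2s, d2e, 250.0, 1e-50),
                        DomainHit(gene_id, fam, L + 1, L + (d2e - d2s + 1),
                                  200.0, 1e-30)]
                placement = "tandem"
            else:  # nonspecific_insert
                seq = np.concatenate([base, _random_seq(rng, 60)])
                hits = [DomainHit(gene_id, fam, d1s, d1e, 250.0, 1e-50),
                        DomainHit(gene_id, fam, d2s, d2e, 250.0, 1e-50),
                        DomainHit(gene_id, "PF99999", L + 1, L + 60, 40.0, 1e-8)]
                placement = "tandem"
            seqs[gene_id] = seq
            truth.degenerates[gene_id] = kind
            truth.subgroup_of[gene_id] = truth.subgroup_of[src]
            degenerate_records.append((gene_id, kind, seq, hits,
                                       f"{placement}:{src}"))

    # --- genome layout ----------------------------------------------------
    gene_models: list[GeneModel] = []
    spacer_counter: dict[str, int] = {}
    chrom_fill: dict[tuple[str, str], int] = {}
    chrom_index: dict[tuple[str, str], int] = {}
    tandems: dict[str, list[str]] = {}
    dups: dict[str, list[str]] = {}
    for gene_id, kind, _seq, _hits, placement in degenerate_records:
        mode, src = placement.split(":", 1)
        (tandems if mode == "tandem" else dups).setdefault(src, []).append(gene_id)

    def emit_gene(sp: str, chrom: str, gene_id: str, exons: int) -> None:
        pos = chrom_fill[(sp, chrom)] = chrom_fill.get((sp, chrom), 0) + 1
        gene_models.append(GeneModel(gene_id, sp, chrom,
                                     1000 * pos + 1, 1000 * pos + 501, "+", exons))

    def current_chrom(sp: str, kind: str) -> str:
        key = (sp, kind)
        idx = chrom_index.get(key, 1)
        chrom = f"{kind}{idx}"
        if chrom_fill.get((sp, chrom), 0) >= config.genes_per_chromosome:
            chrom_index[key] = idx = idx + 1
            chrom = f"{kind}{idx}"
        return chrom

    def emit_spacers(sp: str, chrom: str) -> None:
        for _ in range(config.spacer_genes):
            n = spacer_counter[sp] = spacer_counter.get(sp, 0) + 1
            emit_gene(sp, chrom, f"{sp}_spc{n:05d}", int(rng.integers(1, 9)))

    bg_instances: dict[tuple[str, int], list[str]] = {}

    def emit_locus(sp: str, chrom: str, gene_id: str, context: str,
                   copy_tag: str) -> None:
        f = config.block_flank_size
        for i in range(f):
            bg = f"{sp}_bg_{context}_L{i:02d}{copy_tag}"
            bg_instances.setdefault((context, i), []).append(bg)
            emit_gene(sp, chrom, bg, int(rng.integers(1, 9)))
        emit_gene(sp, chrom, gene_id, int(rng.integers(6, 13)))
        for extra in tandems.get(gene_id, []):
            emit_gene(sp, chrom, extra, int(rng.integers(2, 6)))
        for i in range(f):
            bg = f"{sp}_bg_{context}_R{i:02d}{copy_tag}"
            bg_instances.setdefault((context, f + i), []).append(bg)
            emit_gene(sp, chrom, bg, int(rng.integers(1, 9)))
        emit_spacers(sp, chrom)

    copy_serial: dict[tuple[str, str], int] = {}
    for og in ortho_ids:
        for gene_id, sp, context in ortho_instances[og]:
            serial = copy_serial[(context, sp)] = copy_serial.get((context, sp), 0) + 1
            copy_tag = f"_x{serial}" if serial > 1 else ""
            kind = "chrT" if context.endswith("T") else "chr"
            chrom = current_chrom(sp, kind)
            emit_locus(sp, chrom, gene_id, context, copy_tag)
            # duplicated loci for diverged copies of this gene
            for dup_gene in dups.get(gene_id, []):
                serial2 = copy_serial[(context, sp)] = copy_serial[(context, sp)] + 1
                emit_locus(sp, current_chrom(sp, "chrD"), dup_gene, context,
                           f"_x{serial2}")

    # decoys and orphan tandems already covered; decoys appended at the end
    decoy_species = species_ids
    for k in range(config.n_decoys):
        sp = decoy_species[k % len(decoy_species)]
        gene_id = f"{sp}_decoy{k + 1}"
        seqs[gene_id] = _random_seq(rng, 300)
        truth.decoys.append(gene_id)
        if k % 2 == 0:
            domain_hits.append(DomainHit(gene_id, "PF00612", 40, 200, 35.0, 1e-6))
        emit_gene(sp, current_chrom(sp, "chr"), gene_id, int(rng.integers(1, 9)))

    # --- homology pairs ---------------------------------------------------
    for og in ortho_ids:
        members = [g for g, _, _ in ortho_instances[og]]
        members += [d for g in members for d in dups.get(g, [])]
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                homology_pairs.append((members[i], members[j]))
    for (_context, _i), genes in sorted(bg_instances.items()):
        genes = sorted(genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                homology_pairs.append((genes[i], genes[j]))

    # --- planted blocks ---------------------------------------------------
    # loci sharing a flank context pair off into one block each
    loci_by_context: dict[str, list[tuple[str, str, str]]] = {}
    #   context -> ordered list of (family gene, species, copy_tag)
    copy_serial2: dict[tuple[str, str], int] = {}
    for og in ortho_ids:
        for gene_id, sp, context in ortho_instances[og]:
            serial = copy_serial2[(context, sp)] = copy_serial2.get((context, sp), 0) + 1
            tag = f"_x{serial}" if serial > 1 else ""
            loci_by_context.setdefault(context, []).append((gene_id, sp, tag))
            for dup_gene in dups.get(gene_id, []):
                serial2 = copy_serial2[(context, sp)] = copy_serial2[(context, sp)] + 1
                loci_by_context.setdefault(context, []).append(
                    (dup_gene, sp, f"_x{serial2}"))
    f = config.block_flank_size
    for context, loci in sorted(loci_by_context.items()):
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                (ga, sa, ta), (gb, sb, tb) = loci[i], loci[j]
                anchors = (
                    [[f"{sa}_bg_{context}_L{k:02d}{ta}",
                      f"{sb}_bg_{context}_L{k:02d}{tb}"] for k in range(f)]
                    + [[ga, gb]]
                    + [[f"{sa}_bg_{context}_R{k:02d}{ta}",
                        f"{sb}_bg_{context}_R{k:02d}{tb}"] for k in range(f)]
                )
                truth.blocks.append(anchors)

    # --- assemble records -------------------------------------------------
    species_lookup = {m.gene_id: m.species_id for m in gene_models}
    for gene_id in sorted(seqs):
        sp = species_lookup.get(gene_id, gene_id.split("_", 1)[0])
        records.append(ProteinRecord(gene_id, sp, _to_str(seqs[gene_id])))
    for gene_id in sorted(truth.subgroup_of):
        if gene_id not in truth.degenerates:
            domain_hits.append(DomainHit(gene_id, fam, d1s, d1e, 250.0, 1e-50))
            domain_hits.append(DomainHit(gene_id, fam, d2s, d2e, 250.0, 1e-50))
    for _gene_id, _kind, _seq, hits, _placement in degenerate_records:
        domain_hits.extend(hits)

    # derive community types where the plan left them implicit
    from .profiles import categorize_community
    members = truth.community_members()
    for cid, genes in sorted(members.items()):
        if cid not in truth.community_type:
            sps = [species_lookup.get(g, g.split("_", 1)[0]) for g in genes]
            truth.community_type[cid] = categorize_community(
                sps, lineages).community_type

    return SyntheticDataset(config, records, gene_models, domain_hits,
                            sorted(set(homology_pairs)), lineages, truth)


def generate_typology_fixture(seed: int) -> SyntheticDataset:
    """A dataset planting exactly one community per each of the 13
    lineage-composition types."""
    panel = typology_species_panel()
    plan = [
        CommunitySpec(("EudA1", "MonA1"), 0, "angiosperm_wide"),
        CommunitySpec(("Bas1", "EudA1"), 0, "BE_specific"),
        CommunitySpec(("Bas1", "MonA1"), 0, "BM_specific"),
        CommunitySpec(("EudA1", "EudB1"), 0, "eudicot_wide"),
        CommunitySpec(("MonA1", "MonB1"), 0, "monocot_wide"),
        CommunitySpec(("EudA1", "EudA2"), 1, "EFO_specific"),
        CommunitySpec(("MonA1", "MonA2"), 1, "MFO_specific"),
        CommunitySpec(("EudA1", "EudA1"), 1, "ES_specific"),
        CommunitySpec(("MonA1", "MonA1"), 1, "MS_specific"),
        CommunitySpec(("Bas1", "Bas2"), 1, "basal_specific"),
        CommunitySpec(("Alg1", "Alg2"), 2, "AFO_specific"),
        CommunitySpec(("Mos1", "Mos1"), 2, "MoS_specific"),
        CommunitySpec(("Lyc1", "Lyc1"), 2, "LS_specific"),
    ]
    config = SyntheticConfig(seed=seed, n_subgroups=3, species=panel,
                             community_plan=plan, degenerate_fraction=0.0,
                             n_decoys=0)
    return generate_family(config)
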