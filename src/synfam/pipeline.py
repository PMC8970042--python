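"""End-to-end orchestration of the classification pipeline.

``run_full_pipeline`` chains the stages — harvest, identity clustering,
subgroup labelling, synteny network, four-step classification, community
profiling, reference export — over one in-memory input bundle, producing
a result object plus a machine-readable audit table. The CLI stage
commands are thin wrappers that load/store the same artefacts on disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
import pandas as pd

from . import __version__
from .align import AlignmentParams
from .clustering import (IdentityMatrix, SubgroupDefinition, assign_labels,
                         build_distance_matrix, cluster_min_linkage,
                         select_subgroup_clusters)
from .harvest import (DomainHit, compose_architecture, parse_domain_table,
                      harvest_table, select_clustering_candidates)
from .homology import (Assignment, AssignmentRule, assignments_table,
                       build_reference_dataset, run_four_step_classification)
from .profiles import ProfileMatrix, build_profile_matrix, summarize_category_counts, write_profile
from .records import (ConfigError, DataError, GeneModel, ProteinRecord,
                      SpeciesLineage, read_gene_order_tsv, read_lineage_table,
                      read_proteome_fasta)
from .report import classification_summary, syntenic_fraction_pct
from .synteny import (SyntenyNetwork, classify_edges, detect_collinear_blocks,
                      detect_communities, extract_family_subnetwork, rank_genes,
                      write_blocks, write_communities, write_edges)


@dataclass
class PipelineConfig:
    """All pipeline thresholds; the defaults are the published ones."""

    family_domain: str = "MatE"
    psi_threshold: float = 60.0
    min_subgroup_size: int = 50
    full_len_range: tuple[int, int] = (350, 650)
    domain_len_range: tuple[int, int] = (140, 340)
    ref_full_len_range: tuple[int, int] = (351, 650)
    ref_domain_len_range: tuple[int, int] = (79, 342)
    strict_min_identity: float = 60.0
    strict_min_cov: float = 0.60
    strict_min_abs_len: int = 150
    relaxed_min_identity: float = 40.0
    relaxed_min_cov: float = 0.40
    relaxed_min_abs_len: int = 100
    max_evalue: float = 1e-5
    k: int = 5
    min_anchors: int = 5
    max_gap: int = 25
    min_same_subgroup: int = 4
    community_method: str = "modularity_greedy"
    group_threshold_psi: float = 40.0
    group_anchors: dict | None = None
    seed: int = 0

    @property
    def strict_rule(self) -> AssignmentRule:
        return AssignmentRule(self.strict_min_identity, self.max_evalue,
                              self.strict_min_cov, self.strict_min_abs_len)

    @property
    def relaxed_rule(self) -> AssignmentRule:
        return AssignmentRule(self.relaxed_min_identity, self.max_evalue,
                              self.relaxed_min_cov, self.relaxed_min_abs_len)

    def resolved(self) -> dict:
        out = asdict(self)
        out["version"] = __version__
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Plain key=value config file; CLI overrides take precedence."""
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                values[key.strip()] = _coerce(value.strip())
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("full_len_range", "domain_len_range",
                    "ref_full_len_range", "ref_domain_len_range"):
            if key in values and isinstance(values[key], str):
                lo, _, hi = values[key].partition(",")
                values[key] = (int(lo), int(hi))
        return cls(**values)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


@dataclass
class PipelineInputs:
    """The input bundle every stage consumes."""

    records: list[ProteinRecord]
    gene_models: list[GeneModel]
    domain_hits: list[DomainHit]
    homology_pairs: list[tuple[str, str]]
    lineages: dict[str, SpeciesLineage]


@dataclass
class PipelineResult:
    harvest: pd.DataFrame
    architectures: dict
    candidates: list[ProteinRecord]
    ambiguous: list[ProteinRecord]
    matrix: IdentityMatrix
    clusters: object
    subgroups: list[SubgroupDefinition]
    medoid_tree_newick: str
    blocks: list
    network: SyntenyNetwork
    communities: list[set[str]]
    assignments: dict[str, Assignment]
    audit: pd.DataFrame
    edge_summary: dict
    profile: ProfileMatrix | None
    category_summary: pd.DataFrame | None
    reference: list
    summary: dict


def inputs_from_dataset(dataset) -> PipelineInputs:
    """Adapt a synthetic dataset (or any duck-typed bundle) to inputs."""
    return PipelineInputs(
        records=list(dataset.records),
        gene_models=list(dataset.gene_models),
        domain_hits=list(dataset.domain_hits),
        homology_pairs=list(dataset.homology_pairs),
        lineages=dict(dataset.lineages),
    )


def load_inputs(data_dir: str | Path) -> PipelineInputs:
    """Load an input bundle from a directory (the simulator's layout):
    ``<species>.faa`` proteomes, ``gene_order.tsv``, ``domain_hits.tsv``
    (InterProScan TSV dialect), ``homology_pairs.tsv`` (12-column blast
    tabular) and ``lineages.tsv``."""
    data_dir = Path(data_dir)
    records: list[ProteinRecord] = []
    for fasta in sorted(data_dir.glob("*.faa")):
        records.extend(read_proteome_fasta(fasta, fasta.stem))
    if not records:
        raise DataError(f"{data_dir}: no <species>.faa proteomes found")
    gene_models = read_gene_order_tsv(data_dir / "gene_order.tsv")
    domain_hits = parse_domain_table(data_dir / "domain_hits.tsv",
                                     "interproscan_tsv")
    pairs: list[tuple[str, str]] = []
    pairs_path = data_dir / "homology_pairs.tsv"
    if pairs_path.exists():
        with open(pairs_path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and not line.startswith("#"):
                    pairs.append((parts[0], parts[1]))
    lineages = read_lineage_table(data_dir / "lineages.tsv") \
        if (data_dir / "lineages.tsv").exists() else {}
    return PipelineInputs(records, gene_models, domain_hits, pairs, lineages)


def compose_all_architectures(inputs: PipelineInputs, family_domain: str) -> dict:
    hits_by_gene: dict[str, list[DomainHit]] = {}
    for h in inputs.domain_hits:
        hits_by_gene.setdefault(h.gene_id, []).append(h)
    return {
        r.gene_id: compose_architecture(hits_by_gene.get(r.gene_id, []), r,
                                        family_domain)
        for r in inputs.records
    }


def run_full_pipeline(inputs: PipelineInputs,
                      config: PipelineConfig = PipelineConfig(),
                      params: AlignmentParams = AlignmentParams()) -> PipelineResult:
    """Run every stage over one input bundle. See the module docstring."""
    architectures = compose_all_architectures(inputs, config.family_domain)
    models = {m.gene_id: m for m in inputs.gene_models}
    harvest = harvest_table(inputs.records, architectures, models)
    candidates, ambiguous = select_clustering_candidates(
        inputs.records, architectures,
        config.full_len_range, config.domain_len_range)

    matrix = build_distance_matrix(candidates, params)
    clusters = cluster_min_linkage(matrix, config.psi_threshold)
    raw_subgroups, _leftover = select_subgroup_clusters(
        clusters, matrix, config.min_subgroup_size)
    if raw_subgroups:
        subgroups, newick = assign_labels(raw_subgroups, matrix,
                                          config.group_anchors,
                                          config.group_threshold_psi)
    else:
        subgroups, newick = [], ""

    positions = rank_genes(inputs.gene_models)
    blocks = detect_collinear_blocks(inputs.homology_pairs, positions,
                                     config.min_anchors, config.max_gap)
    family_ids = {r.gene_id for r in inputs.records}
    network = extract_family_subnetwork(blocks, family_ids)
    communities = detect_communities(network, config.community_method,
                                     config.seed)

    assignments, audit = run_four_step_classification(
        candidates, ambiguous, subgroups,
        architectures=architectures, synteny_context=network,
        strict_rule=config.strict_rule, relaxed_rule=config.relaxed_rule,
        k=config.k, min_same_subgroup=config.min_same_subgroup, params=params)

    group_of = {s.label: s.group for s in subgroups if s.group}
    edge_summary = classify_edges(network, assignments, group_of)

    profile = category_summary = None
    if inputs.lineages and communities:
        species_of = {r.gene_id: r.species_id for r in inputs.records}
        profile = build_profile_matrix(communities, species_of, inputs.lineages)
        category_summary = summarize_category_counts(profile)

    records_by_id = {r.gene_id: r for r in inputs.records}
    reference = build_reference_dataset(
        assignments, records_by_id, architectures,
        full_len_range=config.ref_full_len_range,
        domain_len_range=config.ref_domain_len_range)

    step_counts = {
        step: sum(1 for a in assignments.values()
                  if a.level == "subgroup" and a.step == step)
        for step in ("step1_cluster", "step2_homology",
                     "step3_synteny", "step4_rescue")
    }
    n_non_family = sum(a.level == "non_family" for a in assignments.values())
    n_group_only = sum(a.level == "group_only" for a in assignments.values())
    summary_obj = classification_summary(step_counts, n_group_only,
                                         n_hits=len(inputs.records),
                                         n_non_family=n_non_family)
    n_family = summary_obj.n_family
    summary = {
        "n_hits": len(inputs.records),
        "n_family": n_family,
        "n_candidates": len(candidates),
        "n_ambiguous": len(ambiguous),
        "n_clusters": len(clusters.clusters),
        "n_subgroups": len(subgroups),
        "subgroup_by_step": step_counts,
        "n_subgroup_assigned": summary_obj.n_subgroup,
        "n_group_only": n_group_only,
        "n_unclassified": summary_obj.n_unclassified,
        "n_non_family": n_non_family,
        "subgroup_rate_pct": summary_obj.subgroup_rate_pct,
        "group_rate_pct": summary_obj.group_rate_pct,
        "n_blocks": len(blocks),
        "n_nodes": network.graph.number_of_nodes(),
        "n_edges": network.graph.number_of_edges(),
        "n_communities": len(communities),
        "syntenic_fraction_pct": syntenic_fraction_pct(
            network.graph.number_of_nodes(), n_family),
        "edge_type_counts": edge_summary["counts"],
        "edge_type_pct": edge_summary["percentages"],
        "n_reference": len(reference),
    }
    return PipelineResult(harvest, architectures, candidates, ambiguous,
                          matrix, clusters, subgroups, newick, blocks, network,
                          communities, assignments, audit, edge_summary,
                          profile, category_summary, reference, summary)


def _header(config: PipelineConfig) -> str:
    return f"# synfam {__version__} config={config.config_hash()}\n"


def write_result(result: PipelineResult, outdir: str | Path,
                 config: PipelineConfig, write_matrix: bool = False) -> None:
    """Write every stage artefact (TSV/FASTA/JSON) under ``outdir``.

    Every tabular output carries a header comment with the tool version
    and the resolved-config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = _header(config)

    def tsv(df: pd.DataFrame, name: str, **kwargs) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(head)
            df.to_csv(fh, sep="\t", index=False, **kwargs)

    with open(outdir / "config_resolved.json", "w") as fh:
        json.dump(config.resolved(), fh, indent=1, sort_keys=True, default=str)
    tsv(result.harvest, "harvest.tsv")
    if write_matrix:
        result.matrix.to_tsv(outdir / "matrix.tsv")
    result.clusters.to_tsv(outdir / "clusters.tsv")
    sub_rows = [{"label": s.label, "group": s.group or "", "size": s.size,
                 "medoid": s.medoid_id, "members": ",".join(s.member_ids)}
                for s in result.subgroups]
    tsv(pd.DataFrame(sub_rows,
                     columns=["label", "group", "size", "medoid", "members"]),
        "subgroups.tsv")
    (outdir / "medoid_tree.nwk").write_text(result.medoid_tree_newick + "\n")
    write_blocks(result.blocks, outdir / "blocks.txt")
    write_edges(result.network, outdir / "edges.tsv")
    write_communities(result.communities, outdir / "communities.tsv")
    records_by_id = {r.gene_id: r for r in result.candidates + result.ambiguous}
    tsv(assignments_table(result.assignments, records_by_id), "assignments.tsv")
    tsv(result.audit, "audit.tsv")
    if result.profile is not None:
        write_profile(result.profile, outdir / "profile.tsv")
        tsv(result.category_summary, "category_summary.tsv")
    build_reference_dataset(
        result.assignments, records_by_id,
        result.architectures, path=outdir / "reference.faa",
        full_len_range=config.ref_full_len_range,
        domain_len_range=config.ref_domain_len_range)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
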