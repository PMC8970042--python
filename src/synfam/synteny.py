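"""Collinear-block detection and the family synteny network.

Blocks are chains of homologous gene pairs (anchors) whose gene-order
ranks are strictly monotonic on both chromosomes, with at most
``max_gap`` intervening genes between consecutive anchors on either
side; chains shorter than ``min_anchors`` are discarded (defaults 25 and
5, the conventional collinearity parameters). Chaining maximises anchor
count by dynamic programming, separately per chromosome pair and
orientation; intra-genome (self) chromosome pairs are included.

The family sub-network keeps only anchors whose genes are BOTH family
members (pairs with exactly one family gene are curation artefacts and
dropped); duplicate edges collapse to multiplicity one. Communities of
the sub-network are the unit of conservation profiled downstream, and
the network also powers the step-3 synteny vote of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .homology import Assignment
from .records import ConfigError, DataError, GeneModel

EDGE_TYPES = ("intra_subgroup", "inter_subgroup", "inter_group", "unlabeled")


@dataclass(frozen=True)
class GenePosition:
    """Rank of a gene along its chromosome (0-based, by start coordinate)."""

    species_id: str
    chromosome: str
    rank: int
    gene_id: str

    @property
    def chrom_key(self) -> tuple[str, str]:
        return (self.species_id, self.chromosome)


@dataclass
class SyntenyBlock:
    """A collinear chain of anchors between two chromosomes."""

    chrom_a: tuple[str, str]
    chrom_b: tuple[str, str]
    anchors: list[tuple[str, str]]
    orientation: str  # "same" | "inverted"

    @property
    def score(self) -> int:
        return len(self.anchors)


@dataclass
class SyntenyNetwork:
    """The family synteny sub-network with optional communities."""

    graph: nx.Graph
    communities: list[set[str]] | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def rank_genes(models: Sequence[GeneModel]) -> dict[str, GenePosition]:
    """Assign consecutive 0-based ranks along each chromosome.

    Genes are ordered by start coordinate, ties broken by end coordinate
    then gene id; a duplicate gene id raises an error.
    """
    positions: dict[str, GenePosition] = {}
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        if m.gene_id in positions:
            raise DataError(f"duplicate gene id {m.gene_id} in gene order")
        positions[m.gene_id] = None  # type: ignore[assignment]
        by_chrom.setdefault((m.species_id, m.chromosome), []).append(m)
    for (species, chrom), genes in by_chrom.items():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(genes):
            positions[g.gene_id] = GenePosition(species, chrom, rank, g.gene_id)
    return positions


def _collapse_tandem(anchors: list[tuple[int, int, str, str]],
                     ) -> list[tuple[int, int, str, str]]:
    """Collapse tandem arrays: runs of consecutive ranks on one side all
    hitting the same gene on the other side keep only the lowest rank."""
    def collapse(items, rank_idx, partner_idx):
        by_partner: dict[str, list] = {}
        for a in items:
            by_partner.setdefault(a[partner_idx], []).append(a)
        kept = []
        for group in by_partner.values():
            group.sort(key=lambda a: a[rank_idx])
            prev_rank = None
            for a in group:
                if prev_rank is not None and a[rank_idx] == prev_rank + 1:
                    prev_rank = a[rank_idx]  # extend the run, drop the anchor
                    continue
                kept.append(a)
                prev_rank = a[rank_idx]
        return kept

    anchors = collapse(anchors, 0, 3)  # runs on side A hitting one B gene
    anchors = collapse(anchors, 1, 2)  # runs on side B hitting one A gene
    return anchors


def _chain_once(anchors: list[tuple[int, int, str, str]], max_gap: int,
                inverted: bool) -> list[int]:
    """Best chain (max anchor count) over the anchor list; returns indices.

    Ranks must be strictly increasing on side A and strictly increasing
    (or strictly decreasing when ``inverted``) on side B, with rank gaps
    of at most ``max_gap`` intervening genes on both sides.
    """
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i][0],
                                  -anchors[i][1] if inverted else anchors[i][1]))
    best_len = [1] * len(order)
    prev = [-1] * len(order)
    for oi, i in enumerate(order):
        ra, rb = anchors[i][0], anchors[i][1]
        for oj in range(oi):
            j = order[oj]
            qa, qb = anchors[j][0], anchors[j][1]
            if qa >= ra or (qa < ra and ra - qa - 1 > max_gap):
                continue
            if inverted:
                if qb <= rb or qb - rb - 1 > max_gap:
                    continue
            else:
                if qb >= rb or rb - qb - 1 > max_gap:
                    continue
            if best_len[oj] + 1 > best_len[oi]:
                best_len[oi] = best_len[oj] + 1
                prev[oi] = oj
    if not order:
        return []
    end = max(range(len(order)), key=lambda oi: (best_len[oi], -oi))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def detect_collinear_blocks(
    pairs: Iterable[tuple[str, str]],
    positions: Mapping[str, GenePosition],
    min_anchors: int = 5,
    max_gap: int = 25,
    collapse_tandem: bool = True,
) -> list[SyntenyBlock]:
    """Chain homology pairs into collinear blocks.

    ``pairs`` are (top-k) homologous gene-id pairs; both genes of a pair
    must be ranked in ``positions`` (pairs with an unranked gene raise an
    error, self-pairs are ignored). For every chromosome pair — including
    a chromosome against itself — and each orientation, maximal chains
    are peeled off greedily (best chain first, its anchors removed, until
    no chain reaches ``min_anchors``), so each anchor belongs to at most
    one reported block per orientation.
    """
    by_chrompair: dict[tuple, list[tuple[int, int, str, str]]] = {}
    for a, b in pairs:
        if a == b:
            continue
        pa, pb = positions.get(a), positions.get(b)
        if pa is None or pb is None:
            missing = a if pa is None else b
            raise DataError(f"gene {missing} in homology pairs has no position")
        ka, kb = pa.chrom_key, pb.chrom_key
        if (kb, pb.rank) < (ka, pa.rank):
            pa, pb = pb, pa
            ka, kb = kb, ka
        by_chrompair.setdefault((ka, kb), []).append(
            (pa.rank, pb.rank, pa.gene_id, pb.gene_id))

    blocks: list[SyntenyBlock] = []
    for (ka, kb) in sorted(by_chrompair):
        anchors = sorted(set(by_chrompair[(ka, kb)]))
        if collapse_tandem:
            anchors = sorted(_collapse_tandem(anchors))
        for orientation in ("same", "inverted"):
            remaining = list(anchors)
            while True:
                chain = _chain_once(remaining, max_gap, orientation == "inverted")
                if len(chain) < min_anchors:
                    break
                chosen = [remaining[i] for i in chain]
                blocks.append(SyntenyBlock(
                    ka, kb, [(a[2], a[3]) for a in chosen], orientation))
                chosen_set = set(chain)
                remaining = [a for i, a in enumerate(remaining)
                             if i not in chosen_set]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.orientation,
                               b.anchors[0]))
    return blocks


def extract_family_subnetwork(blocks: Sequence[SyntenyBlock],
                              family_ids: Iterable[str]) -> SyntenyNetwork:
    """Keep anchors whose genes are both family members as network edges.

    Anchor pairs with exactly one family member are curation artefacts
    and dropped; the same family pair seen in several blocks collapses
    to one edge. Family genes with no retained edge are not nodes.
    """
    family = set(family_ids)
    g = nx.Graph()
    for block in blocks:
        for a, b in block.anchors:
            if a in family and b in family and a != b:
                g.add_edge(*sorted((a, b)))
    return SyntenyNetwork(g)


def detect_communities(network: SyntenyNetwork, method: str = "modularity_greedy",
                       seed: int = 0) -> list[set[str]]:
    """Partition the network nodes into communities.

    ``method`` is one of ``components`` (connected components),
    ``modularity_greedy`` (greedy modularity maximisation) or
    ``label_propagation`` (seeded asynchronous label propagation). The
    result is deterministic given method and seed, ordered by decreasing
    size then smallest member id, and is stored on the network.
    """
    g = network.graph
    if method == "components":
        parts = [set(c) for c in nx.connected_components(g)]
    elif method == "modularity_greedy":
        parts = ([set(c) for c in
                  nx.community.greedy_modularity_communities(g)]
                 if g.number_of_edges() else
                 [set(c) for c in nx.connected_components(g)])
    elif method == "label_propagation":
        parts = [set(c) for c in
                 nx.community.asyn_lpa_communities(g, seed=seed)]
    else:
        raise ConfigError(f"unknown community method {method!r}")
    parts.sort(key=lambda c: (-len(c), min(c)))
    network.communities = parts
    return parts


class SyntenyVoteResult(dict):
    """dict of new Assignments; ``flagged`` lists quorum-ambiguous genes."""

    def __init__(self, *args, flagged: list[str] | None = None, **kwargs):
        super().__init__(*args, **kwargs)
        self.flagged: list[str] = flagged or []


def synteny_assign(
    unclassified_ids: Iterable[str],
    network: SyntenyNetwork,
    assignments: Mapping[str, Assignment],
    min_same_subgroup: int = 4,
) -> SyntenyVoteResult:
    """The step-3 synteny vote.

    An unclassified gene whose syntenic neighbours include at least
    ``min_same_subgroup`` subgroup-classified genes of exactly one
    subgroup inherits that subgroup. If two or more subgroups reach the
    quorum the gene is left unassigned and listed in the result's
    ``flagged`` attribute.
    """
    g = network.graph
    result = SyntenyVoteResult()
    for gene_id in sorted(set(unclassified_ids)):
        if gene_id not in g:
            continue
        votes: dict[str, int] = {}
        for nb in g.neighbors(gene_id):
            a = assignments.get(nb)
            if a is not None and a.level == "subgroup":
                votes[a.label] = votes.get(a.label, 0) + 1
        quorum = sorted(lab for lab, n in votes.items() if n >= min_same_subgroup)
        if len(quorum) == 1:
            label = quorum[0]
            result[gene_id] = Assignment(
                gene_id, "subgroup", label, "step3_synteny",
                evidence=f"syntenic neighbours in {label}: {votes[label]}")
        elif len(quorum) > 1:
            result.flagged.append(gene_id)
    return result


def classify_edges(network: SyntenyNetwork,
                   assignments: Mapping[str, Assignment],
                   group_of: Mapping[str, str] | None = None) -> dict:
    """Type every edge from its endpoints' labels and report percentages.

    Same subgroup → ``intra_subgroup``; same group, different subgroup →
    ``inter_subgroup``; different groups → ``inter_group``; any endpoint
    without a subgroup label → ``unlabeled``. Percentages are over all
    edges, truncated to three decimals (as conventionally printed).
    """
    def group(label: str) -> str:
        if group_of and label in group_of:
            return group_of[label]
        from .homology import _group_prefix
        return _group_prefix(label)

    counts = {t: 0 for t in EDGE_TYPES}
    typed: dict[tuple[str, str], str] = {}
    for a, b in network.edges:
        aa, ab = assignments.get(a), assignments.get(b)
        if not aa or not ab or aa.level != "subgroup" or ab.level != "subgroup":
            t = "unlabeled"
        elif aa.label == ab.label:
            t = "intra_subgroup"
        elif group(aa.label) == group(ab.label):
            t = "inter_subgroup"
        else:
            t = "inter_group"
        counts[t] += 1
        typed[(a, b)] = t
    total = sum(counts.values())
    percentages = {t: truncate_pct(100.0 * n / total) if total else 0.0
                   for t, n in counts.items()}
    return {"counts": counts, "percentages": percentages, "total": total,
            "edge_types": typed}


def truncate_pct(value: float, decimals: int = 3) -> float:
    """Truncate (not round) a percentage to the given decimals."""
    factor = 10 ** decimals
    return int(value * factor) / factor


def write_blocks(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    """Write blocks in a collinearity-style text format."""
    with open(path, "w") as fh:
        for k, b in enumerate(blocks):
            fh.write(f"## block {k}: {b.chrom_a[0]}:{b.chrom_a[1]} vs "
                     f"{b.chrom_b[0]}:{b.chrom_b[1]} orientation={b.orientation} "
                     f"anchors={b.score}\n")
            for a, bb in b.anchors:
                fh.write(f"{k}\t{a}\t{bb}\n")


def write_edges(network: SyntenyNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\n")
        for a, b in network.edges:
            fh.write(f"{a}\t{b}\n")


def write_communities(communities: Sequence[set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#community_id\tgene_id\n")
        for k, comm in enumerate(communities, 1):
            for g in sorted(comm):
                fh.write(f"K{k:03d}\t{g}\n")
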