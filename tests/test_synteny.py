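"""Gene ranking, collinear-block chaining, network, communities, vote."""

import itertools

import numpy as np
import pytest

from synfam.homology import Assignment
from synfam.records import ConfigError, DataError, GeneModel
from synfam.synteny import (SyntenyNetwork, classify_edges,
                            detect_collinear_blocks, detect_communities,
                            extract_family_subnetwork, rank_genes,
                            synteny_assign, truncate_pct)


def chromosome(species, chrom, gene_ids, start_step=1000):
    return [GeneModel(g, species, chrom, (i + 1) * start_step,
                      (i + 1) * start_step + 500, "+")
            for i, g in enumerate(gene_ids)]


def positions_for(*chromosomes):
    models = [m for chrom in chromosomes for m in chrom]
    return rank_genes(models)


class TestRankGenes:
    def test_ranks_follow_start_coordinates(self):
        models = [GeneModel("a", "sp", "c1", 100, 200, "+"),
                  GeneModel("b", "sp", "c1", 500, 600, "+"),
                  GeneModel("c", "sp", "c1", 900, 950, "+")]
        pos = rank_genes(models)
        assert [pos[g].rank for g in "abc"] == [0, 1, 2]

    def test_input_order_is_irrelevant(self):
        models = [GeneModel("a", "sp", "c1", 100, 200, "+"),
                  GeneModel("b", "sp", "c1", 500, 600, "+")]
        assert ({g: p.rank for g, p in rank_genes(models).items()}
                == {g: p.rank for g, p in rank_genes(models[::-1]).items()})

    def test_tied_starts_break_by_end_coordinate(self):
        models = [GeneModel("long", "sp", "c1", 100, 900, "+"),
                  GeneModel("short", "sp", "c1", 100, 300, "+")]
        pos = rank_genes(models)
        assert pos["short"].rank == 0 and pos["long"].rank == 1

    def test_duplicate_gene_id_is_error(self):
        models = [GeneModel("a", "sp", "c1", 100, 200, "+"),
                  GeneModel("a", "sp", "c2", 100, 200, "+")]
        with pytest.raises(DataError):
            rank_genes(models)


def brute_force_max_chain(anchors, max_gap, inverted):
    """Exhaustive DFS over anchor chains honouring strict monotonicity
    and the per-side gap bound; returns the maximum chain length."""
    order = sorted(anchors)
    best = 0

    def extend(last, count):
        nonlocal best
        best = max(best, count)
        for nxt in order:
            if last is not None:
                if nxt[0] <= last[0] or nxt[0] - last[0] - 1 > max_gap:
                    continue
                if inverted:
                    if nxt[1] >= last[1] or last[1] - nxt[1] - 1 > max_gap:
                        continue
                else:
                    if nxt[1] <= last[1] or nxt[1] - last[1] - 1 > max_gap:
                        continue
            extend(nxt, count + 1)

    extend(None, 0)
    return best


class TestCollinearBlocks:
    def shared(self, n, order=None, gap_positions=()):
        """Two chromosomes sharing n genes (optionally reordered on B),
        with runs of species-B-private genes inserted."""
        a_genes = [f"A{i}" for i in range(n)]
        order = order if order is not None else list(range(n))
        b_genes = []
        for slot, idx in enumerate(order):
            if slot in gap_positions:
                b_genes.extend(f"Bpad{slot}_{k}" for k in range(26))
            b_genes.append(f"B{idx}")
        pos = positions_for(chromosome("spA", "c1", a_genes),
                            chromosome("spB", "c1", b_genes))
        pairs = [(f"A{i}", f"B{i}") for i in range(n)]
        return pairs, pos

    def test_six_shared_genes_form_one_block(self):
        pairs, pos = self.shared(6)
        (block,) = detect_collinear_blocks(pairs, pos)
        assert block.score == 6 and block.orientation == "same"

    def test_four_shared_genes_are_below_minimum(self):
        pairs, pos = self.shared(4)
        assert detect_collinear_blocks(pairs, pos) == []

    def test_26_gene_insertion_splits_chain_below_minimum(self):
        pairs, pos = self.shared(6, gap_positions={3})
        assert detect_collinear_blocks(pairs, pos) == []

    def test_reversed_order_gives_inverted_block(self):
        pairs, pos = self.shared(6, order=[5, 4, 3, 2, 1, 0])
        (block,) = detect_collinear_blocks(pairs, pos)
        assert block.orientation == "inverted" and block.score == 6

    def test_block_invariants_hold_on_random_fixtures(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            n = int(rng.integers(6, 13))
            perm = rng.permutation(n).tolist()
            pairs, pos = self.shared(n, order=perm)
            for block in detect_collinear_blocks(pairs, pos, min_anchors=3):
                ra = [pos[a].rank for a, _ in block.anchors]
                rb = [pos[b].rank for _, b in block.anchors]
                assert ra == sorted(ra) and len(set(ra)) == len(ra)
                rb_sorted = sorted(rb, reverse=block.orientation == "inverted")
                assert rb == rb_sorted and len(set(rb)) == len(rb)
                for (g1, g2) in zip(ra, ra[1:]):
                    assert g2 - g1 - 1 <= 25
                for (g1, g2) in zip(rb, rb[1:]):
                    assert abs(g2 - g1) - 1 <= 25

    def test_reported_chains_are_optimal_vs_brute_force(self):
        """Every reported block has the exhaustively-verified maximum
        anchor count given the anchors still available."""
        rng = np.random.default_rng(31)
        for trial in range(20):
            n = int(rng.integers(6, 12))
            perm = rng.permutation(n).tolist()
            pairs, pos = self.shared(n, order=perm)
            rank_pairs = [(pos[a].rank, pos[b].rank) for a, b in pairs]
            blocks = detect_collinear_blocks(pairs, pos, min_anchors=3,
                                             max_gap=25)
            for orientation in ("same", "inverted"):
                remaining = sorted(rank_pairs)
                # peeling reports best chains first: replay by score
                for block in sorted(blocks, key=lambda b: -b.score):
                    if block.orientation != orientation:
                        continue
                    oracle = brute_force_max_chain(remaining, 25,
                                                   orientation == "inverted")
                    assert block.score == oracle
                    used = {(pos[a].rank, pos[b].rank) for a, b in block.anchors}
                    remaining = [x for x in remaining if x not in used]
                assert brute_force_max_chain(remaining, 25,
                                             orientation == "inverted") < 3

    def test_self_pairs_ignored_and_unranked_gene_is_error(self):
        pairs, pos = self.shared(6)
        assert detect_collinear_blocks(pairs + [("A0", "A0")], pos)
        with pytest.raises(DataError):
            detect_collinear_blocks([("A0", "nowhere")], pos)

    def test_tandem_arrays_collapse_to_lowest_rank(self):
        a_genes = [f"A{i}" for i in range(6)] + ["A2b"]
        b_genes = [f"B{i}" for i in range(6)]
        models = chromosome("spA", "c1", a_genes[:3] + ["A2b"] + a_genes[3:6])
        pos = positions_for(models, chromosome("spB", "c1", b_genes))
        pairs = [(f"A{i}", f"B{i}") for i in range(6)] + [("A2b", "B2")]
        (block,) = detect_collinear_blocks(pairs, pos)
        names = [a for a, _ in block.anchors]
        assert "A2b" not in names and "A2" in names


class TestFamilySubnetwork:
    def test_curation_keeps_only_family_family_anchors(self):
        pairs, pos = TestCollinearBlocks().shared(6)
        blocks = detect_collinear_blocks(pairs, pos)
        network = extract_family_subnetwork(blocks, {"A0", "B0", "A3", "B3",
                                                     "A5", "Bx"})
        assert network.edges == [("A0", "B0"), ("A3", "B3")]

    def test_duplicate_edges_collapse(self):
        import networkx as nx
        blocks = detect_collinear_blocks(
            *TestCollinearBlocks().shared(6))
        doubled = blocks + blocks
        network = extract_family_subnetwork(doubled, {"A0", "B0"})
        assert network.edges == [("A0", "B0")]


def clique_network(*cliques):
    import networkx as nx
    g = nx.Graph()
    for members in cliques:
        for a, b in itertools.combinations(members, 2):
            g.add_edge(a, b)
    return SyntenyNetwork(g)


class TestCommunities:
    @pytest.mark.parametrize("method", ["components", "modularity_greedy",
                                        "label_propagation"])
    def test_two_disjoint_cliques(self, method):
        net = clique_network([f"a{i}" for i in range(5)],
                             [f"b{i}" for i in range(5)])
        parts = detect_communities(net, method, seed=1)
        assert {frozenset(p) for p in parts} == \
            {frozenset(f"a{i}" for i in range(5)),
             frozenset(f"b{i}" for i in range(5))}

    def test_planted_three_communities_recovered(self):
        net = clique_network([f"x{i}" for i in range(6)],
                             [f"y{i}" for i in range(4)],
                             [f"z{i}" for i in range(3)])
        parts = detect_communities(net, "modularity_greedy", seed=0)
        assert sorted(len(p) for p in parts) == [3, 4, 6]

    def test_same_seed_is_deterministic(self):
        net = clique_network([f"x{i}" for i in range(6)],
                             [f"y{i}" for i in range(6)])
        first = detect_communities(net, "label_propagation", seed=5)
        second = detect_communities(net, "label_propagation", seed=5)
        assert first == second

    def test_unknown_method_is_config_error(self):
        with pytest.raises(ConfigError):
            detect_communities(clique_network(["a", "b"]), "walktrap", 0)

    def test_translocation_splits_community_under_components(self):
        """Moving a planted locus to a new chromosome context in one
        lineage severs its synteny to the other lineages."""
        from synfam.pipeline import PipelineConfig, inputs_from_dataset, run_full_pipeline
        from synfam.simulate import SyntheticConfig, generate_family

        ds = generate_family(SyntheticConfig(
            seed=41, n_subgroups=1, genes_per_subgroup=12,
            degenerate_fraction=0.0, n_decoys=0, translocation_rate=1.0))
        assert ds.truth.translocated  # every orthogroup hit at rate 1.0
        inputs = inputs_from_dataset(ds)
        result = run_full_pipeline(inputs, PipelineConfig(
            min_subgroup_size=10, community_method="components"))
        truth_parts = {frozenset(m)
                       for m in ds.truth.community_members().values()}
        assert {frozenset(c) for c in result.communities} == truth_parts
        # each translocated orthogroup contributes two communities
        assert len(result.communities) == 2 * len(ds.truth.translocated)


def assignments_for(labels):
    return {g: Assignment(g, "subgroup", lab, "step1_cluster")
            for g, lab in labels.items()}


class TestSyntenyVote:
    def star(self, centre, neighbours):
        import networkx as nx
        g = nx.Graph()
        for n in neighbours:
            g.add_edge(centre, n)
        return SyntenyNetwork(g)

    def test_quorum_of_four_assigns(self):
        net = self.star("u", [f"n{i}" for i in range(4)])
        labels = assignments_for({f"n{i}": "IIA" for i in range(4)})
        out = synteny_assign(["u"], net, labels, min_same_subgroup=4)
        assert out["u"].label == "IIA" and out["u"].step == "step3_synteny"

    def test_three_neighbours_miss_default_quorum(self):
        net = self.star("u", [f"n{i}" for i in range(3)])
        labels = assignments_for({f"n{i}": "IIA" for i in range(3)})
        assert synteny_assign(["u"], net, labels, min_same_subgroup=4) == {}
        relaxed = synteny_assign(["u"], net, labels, min_same_subgroup=3)
        assert relaxed["u"].label == "IIA"

    def test_competing_quorums_flagged_not_assigned(self):
        neighbours = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        net = self.star("u", neighbours)
        labels = assignments_for(
            {**{f"a{i}": "IIA" for i in range(4)},
             **{f"b{i}": "IVC" for i in range(4)}})
        out = synteny_assign(["u"], net, labels, min_same_subgroup=4)
        assert out == {} and out.flagged == ["u"]

    def test_gene_absent_from_network_is_skipped(self):
        net = self.star("u", ["n0"])
        assert synteny_assign(["ghost"], net, {}, 4) == {}


class TestEdgeTyping:
    def test_all_intra(self):
        net = clique_network([f"g{i}" for i in range(5)])
        out = classify_edges(net, assignments_for(
            {f"g{i}": "IIA" for i in range(5)}))
        assert out["counts"]["intra_subgroup"] == 10
        assert out["percentages"]["intra_subgroup"] == 100.0

    def test_type_partition_and_percentage_truncation(self):
        import networkx as nx
        g = nx.Graph()
        g.add_edge("a", "b")  # IIA-IIA intra
        g.add_edge("a", "c")  # IIA-IIE inter subgroup
        g.add_edge("a", "d")  # IIA-IVC inter group
        g.add_edge("a", "e")  # unlabeled endpoint
        net = SyntenyNetwork(g)
        labels = assignments_for({"a": "IIA", "b": "IIA", "c": "IIE",
                                  "d": "IVC"})
        out = classify_edges(net, labels)
        assert out["counts"] == {"intra_subgroup": 1, "inter_subgroup": 1,
                                 "inter_group": 1, "unlabeled": 1}
        assert sum(out["counts"].values()) == out["total"] == 4
        assert out["percentages"]["intra_subgroup"] == 25.0
        assert out["edge_types"][("a", "c")] == "inter_subgroup"

    def test_truncation_not_rounding(self):
        assert truncate_pct(100 * 348 / 55276) == 0.629
        assert truncate_pct(100 * 4 / 55276) == 0.007
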