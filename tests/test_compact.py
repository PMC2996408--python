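"""List-ranking transform, pruning, chain ranking and graph compaction."""

import math
import random

import networkx as nx
import pytest

from bidbg.build import BiGraph, CanonicalEdge, Head, build_graph
from bidbg.codec import reverse_complement_str
from bidbg.compact import (
    MINUS,
    PLUS,
    compact,
    list_ranking_transform,
    prune_branches,
    rank_chains_external,
    rank_chains_memory,
    scomp,
    smol,
    snode,
    spell_chain,
    ssign,
    write_rank_tuples,
)
from bidbg.seqio import ReadSet, simulate_genome_unique_kmers, tiling_reads
from bidbg.sorting import SortConfig
from bidbg.walks import bidirected_reachable, read_is_spelled

from conftest import random_bigraph


def _mk_graph(labels, edge_rows, k=3):
    """Graph with an explicit vertex order (names = list positions)."""
    from bidbg.codec import KMolecule, encode, reverse_complement

    mols = []
    for i, lab in enumerate(labels):
        seq = encode(lab)
        mols.append(KMolecule(seq, reverse_complement(seq), i))
    edges = sorted(
        (CanonicalEdge(u, v, h1, h2, 1) for u, v, h1, h2 in edge_rows),
        key=CanonicalEdge.key,
    )
    return BiGraph(k=k, vertices=mols, edges=edges)


F, R = Head.FWD, Head.REV


class TestTransform:
    def test_fwd_fwd_edge(self):
        g = _mk_graph(["AAC", "AAG"], [(0, 1, F, F)])
        dg = list_ranking_transform(g)
        assert dg.arcs == {(snode(0, PLUS), snode(1, PLUS)),
                           (snode(1, MINUS), snode(0, MINUS))}

    def test_rev_fwd_edge(self):
        g = _mk_graph(["AAC", "AAG"], [(0, 1, R, F)])
        dg = list_ranking_transform(g)
        assert dg.arcs == {(snode(0, MINUS), snode(1, PLUS)),
                           (snode(1, MINUS), snode(0, PLUS))}

    def test_self_loop_fwd_rev_single_arc(self):
        g = _mk_graph(["ACG"], [(0, 0, F, R)])
        dg = list_ranking_transform(g)
        assert dg.arcs == {(snode(0, PLUS), snode(0, MINUS))}

    def test_arc_symmetry_random(self):
        rng = random.Random(2)
        for _ in range(50):
            g = random_bigraph(rng)
            arcs = list_ranking_transform(g).arcs
            for a, b in arcs:
                assert (scomp(b), scomp(a)) in arcs

    def test_arc_count_accounting(self):
        rng = random.Random(3)
        for _ in range(50):
            g = random_bigraph(rng)
            arcs = list_ranking_transform(g).arcs
            self_comp = sum(1 for a, b in arcs if (scomp(b), scomp(a)) == (a, b))
            assert len(arcs) == 2 * g.n_edges - self_comp


class TestLemma1:
    """Bi-directed reachability equals directed reachability after the
    transform, checked on random graphs against a networkx BFS oracle."""

    def _check(self, g):
        arcs = list_ranking_transform(g).arcs
        dig = nx.DiGraph()
        nodes = [snode(v, s) for v in range(g.n_vertices) for s in (PLUS, MINUS)]
        dig.add_nodes_from(nodes)
        dig.add_edges_from(arcs)
        for a in nodes:
            reach = nx.descendants(dig, a) | {a}
            for b in nodes:
                expected = b in reach
                got = bidirected_reachable(
                    g, (smol(a), ssign(a)), (smol(b), ssign(b))
                )
                assert got == expected, (a, b, sorted(arcs))

    def test_single_edge_cases(self):
        g = _mk_graph(["AAC", "AAG"], [(0, 1, F, F)])
        assert bidirected_reachable(g, (0, PLUS), (1, PLUS))
        assert not bidirected_reachable(g, (0, PLUS), (1, MINUS))
        assert bidirected_reachable(g, (1, MINUS), (0, MINUS))
        self._check(g)

    def test_random_graphs_agree(self):
        rng = random.Random(17)
        for _ in range(120):
            self._check(random_bigraph(rng))

    def test_walks_may_revisit_nodes(self):
        # A-B-E plus a B-C-D-B detour, all FWD: both walks valid
        g = _mk_graph(
            ["AAA", "AAC", "AAG", "AAT", "ACC"],
            [(0, 1, F, F), (1, 2, F, F), (2, 3, F, F), (3, 1, F, F), (1, 4, F, F)],
        )
        assert bidirected_reachable(g, (0, PLUS), (4, PLUS))


class TestPrune:
    def test_simple_path_nothing_pruned(self):
        g = _mk_graph(["AAC", "AAG", "ACC"], [(0, 1, F, F), (1, 2, F, F)])
        pr = prune_branches(list_ranking_transform(g))
        assert pr.vp == set() and pr.ep == set()

    def test_branching_node_and_complement_enter_vp(self):
        g = _mk_graph(
            ["AAC", "AAG", "ACC"], [(0, 1, F, F), (0, 2, F, F)]
        )  # two out-arcs from 0+
        pr = prune_branches(list_ranking_transform(g))
        assert snode(0, PLUS) in pr.vp and snode(0, MINUS) in pr.vp

    def test_pruned_components_are_paths_or_cycles(self):
        rng = random.Random(19)
        for _ in range(100):
            g = random_bigraph(rng)
            pr = prune_branches(list_ranking_transform(g))
            d_in, d_out = pr.pruned.degrees()
            for s in pr.pruned.nodes:
                assert d_in.get(s, 0) <= 1 and d_out.get(s, 0) <= 1

    def test_vp_closed_under_complement(self):
        rng = random.Random(20)
        for _ in range(100):
            pr = prune_branches(list_ranking_transform(random_bigraph(rng)))
            assert {scomp(s) for s in pr.vp} == pr.vp


class TestRankChains:
    def _pruned_from_succ(self, succ):
        from bidbg.compact import DoubledGraph

        nodes = set(succ) | set(succ.values())
        return DoubledGraph(nodes, {(a, b) for a, b in succ.items()},
                            {(a, b): 0 for a, b in succ.items()})

    def test_path_chain_and_round_bound(self):
        pruned = self._pruned_from_succ({0: 2, 2: 4, 4: 6})
        chains, rep = rank_chains_memory(pruned)
        assert chains == [[0, 2, 4, 6]]
        assert rep.rounds <= 3

    def test_isolated_nodes_are_singleton_chains(self):
        from bidbg.compact import DoubledGraph

        pruned = DoubledGraph({2, 3, 8}, set(), {})
        chains, rep = rank_chains_memory(pruned)
        assert chains == [[2], [3], [8]] and not rep.cycles

    @pytest.mark.parametrize("n", [3, 4, 8])  # includes power-of-two lengths
    def test_cycles_detected_memory(self, n):
        succ = {2 * i: 2 * ((i + 1) % n) for i in range(n)}
        chains, rep = rank_chains_memory(self._pruned_from_succ(succ))
        assert chains == []
        assert len(rep.cycles) == 1 and len(rep.cycles[0]) == n

    def test_external_path_example(self, tmp_path):
        # (1,2),(2,3),(3,4): first phase joins to (1,3),(2,4); J: 2 then 0
        cfg = SortConfig(memory_budget_bytes=4096, block_bytes=512, tmp_dir=tmp_path)
        tf = write_rank_tuples({1: 2, 2: 3, 3: 4}, tmp_path / "t.bin")
        chains, rep = rank_chains_external(tf, cfg)
        assert chains == [[1, 2, 3, 4]]
        assert rep.join_counts == [2, 0]
        assert not rep.cycles

    def test_external_cycle_join_count_constant(self, tmp_path):
        cfg = SortConfig(memory_budget_bytes=4096, block_bytes=512, tmp_dir=tmp_path)
        tf = write_rank_tuples({1: 2, 2: 3, 3: 1}, tmp_path / "t.bin")
        chains, rep = rank_chains_external(tf, cfg)
        assert chains == []
        assert rep.join_counts[-1] == rep.join_counts[-2] == 3
        assert rep.cycles == [[1, 2, 3]]

    def test_external_phase_bound_power_of_two(self, tmp_path):
        m = 5
        n = 2 ** m
        cfg = SortConfig(memory_budget_bytes=4096, block_bytes=512, tmp_dir=tmp_path)
        tf = write_rank_tuples({i: i + 1 for i in range(n)}, tmp_path / "t.bin")
        chains, rep = rank_chains_external(tf, cfg)
        assert chains == [list(range(n + 1))]
        assert rep.phases <= m + 1
        # acyclic: J strictly decreases to 0
        assert rep.join_counts[-1] == 0
        assert all(a > b for a, b in zip(rep.join_counts, rep.join_counts[1:]))

    def test_memory_external_equivalence_random(self, tmp_path):
        rng = random.Random(29)
        cfg = SortConfig(memory_budget_bytes=4096, block_bytes=512, tmp_dir=tmp_path)
        for trial in range(20):
            g = random_bigraph(rng)
            pr = prune_branches(list_ranking_transform(g))
            chains_m, rep_m = rank_chains_memory(pr.pruned)
            succ = {a: b for a, b in pr.pruned.arcs}
            linked = set(succ) | set(succ.values())
            if succ:
                tf = write_rank_tuples(succ, tmp_path / f"t{trial}.bin")
                chains_e, rep_e = rank_chains_external(tf, cfg)
            else:
                chains_e, rep_e = [], None
            singles = [[s] for s in sorted(pr.pruned.nodes - linked)]
            assert sorted(chains_e + singles) == sorted(chains_m)
            if rep_e is not None:
                assert sorted(map(sorted, rep_e.cycles)) == sorted(
                    map(sorted, rep_m.cycles)
                )


class TestSpellChain:
    def test_singleton_spells_oriented_kmer(self):
        g = _mk_graph(["ACG"], [])
        assert spell_chain([snode(0, PLUS)], g) == "ACG"
        assert spell_chain([snode(0, MINUS)], g) == "CGT"

    def test_tagg_ccta_pairing(self):
        # Y2=(AGG,CCT), Y3=(CTA,TAG): (Y2-,Y3+) spells CCTA, (Y3-,Y2+) TAGG
        g = _mk_graph(["AGG", "CTA"], [(0, 1, R, F)])
        fwd = spell_chain([snode(0, MINUS), snode(1, PLUS)], g)
        rev = spell_chain([snode(1, MINUS), snode(0, PLUS)], g)
        assert (fwd, rev) == ("CCTA", "TAGG")
        assert reverse_complement_str(fwd) == rev

    def test_broken_adjacency_raises(self):
        g = _mk_graph(["AAC", "GGA"], [])
        with pytest.raises(ValueError, match="overlap"):
            spell_chain([snode(0, PLUS), snode(1, PLUS)], g)


def _fig3_graph():
    """A graph realising the Figure-3 legend: Y2-Y3 and X1-X2-X3 chains
    between branching context nodes Y1, Y4, Z, Z2."""
    labels = ["AAC", "AGG", "CTA", "AAG", "ATA", "ATC", "AGA", "ACA", "ACT"]
    #          Y1=0   Y2=1   Y3=2   Y4=3   X1=4   X2=5   X3=6   Z=7    Z2=8
    rows = [
        (0, 1, F, R),  # Y1+ -> Y2-
        (1, 2, R, F),  # chain arc Y2- -> Y3+
        (2, 3, F, F),  # Y3+ -> Y4+
        (0, 4, R, R),  # arc Y1- -> X1-, comp X1+ -> Y1+
        (4, 5, R, F),  # chain arc X1- -> X2+
        (5, 6, F, R),  # chain arc X2+ -> X3-
        (3, 7, F, F),  # Y4 context
        (3, 8, F, R),  # Y4 branching
        (7, 8, F, F),  # Z/Z2 interconnect
        (7, 8, R, F),
        (0, 7, R, R),  # arc Z+ -> Y1+ ... makes Z branching
    ]
    return _mk_graph(labels, rows)


class TestFigure3:
    def test_four_maximal_chains(self):
        g = _fig3_graph()
        pr = prune_branches(list_ranking_transform(g))
        chains, rep = rank_chains_memory(pr.pruned)
        assert not rep.cycles
        Y2, Y3, X1, X2, X3 = 1, 2, 4, 5, 6
        expected = {
            (snode(Y2, MINUS), snode(Y3, PLUS)),
            (snode(Y3, MINUS), snode(Y2, PLUS)),
            (snode(X1, MINUS), snode(X2, PLUS), snode(X3, MINUS)),
            (snode(X3, PLUS), snode(X2, MINUS), snode(X1, PLUS)),
        }
        assert {tuple(c) for c in chains} == expected

    def test_chain_labels_reverse_complementary(self):
        g = _fig3_graph()
        pr = prune_branches(list_ranking_transform(g))
        chains, _ = rank_chains_memory(pr.pruned)
        by_key = {tuple(c): spell_chain(c, g) for c in chains}
        y_fwd = by_key[(snode(1, MINUS), snode(2, PLUS))]
        y_rev = by_key[(snode(2, MINUS), snode(1, PLUS))]
        assert (y_fwd, y_rev) == ("CCTA", "TAGG")
        x_fwd = by_key[(snode(4, MINUS), snode(5, PLUS), snode(6, MINUS))]
        x_rev = by_key[(snode(6, PLUS), snode(5, MINUS), snode(4, PLUS))]
        assert x_rev == reverse_complement_str(x_fwd)

    def test_compaction_min_id_names_and_boundary_edges(self):
        g = _fig3_graph()
        cg = compact(g)
        # chains Y2/Y3 -> named 1 (=Y2); X1..X3 -> named 4 (=X1);
        # branching molecules keep their names
        assert cg.names == [0, 1, 3, 4, 7, 8]
        wy = cg.names.index(1)
        assert cg.label(wy) == "CCTA"
        wx = cg.names.index(4)
        assert cg.label(wx) in ("AGATA", "TATCT")
        assert cg.label(wx) == min(
            cg.label(wx), reverse_complement_str(cg.label(wx))
        )
        # the Y3-Y4 boundary edge was re-targeted onto the merged Y2 node
        y4 = cg.names.index(3)
        assert any({e.u, e.v} == {wy, y4} for e in cg.edges)
        # and the Y1-Y2 boundary edge onto the same node from the other side
        y1 = cg.names.index(0)
        assert any({e.u, e.v} == {wy, y1} for e in cg.edges)


class TestCompact:
    def test_unique_kmer_genome_single_node(self):
        k = 15
        genome = simulate_genome_unique_kmers(400, k - 1, seed=2)
        g = build_graph(tiling_reads(genome, 60, 40), k)
        cg = compact(g)
        assert cg.n_vertices == 1 and cg.n_edges == 0
        assert cg.label(0) in (genome, reverse_complement_str(genome))

    def test_recompaction_is_identity(self):
        k = 9
        genome = simulate_genome_unique_kmers(150, k - 1, seed=4)
        g = build_graph(tiling_reads(genome, 40, 25), k)
        cg = compact(g)
        cg2 = compact(cg)
        assert [cg2.label(i) for i in range(cg2.n_vertices)] == [
            cg.label(i) for i in range(cg.n_vertices)
        ]
        assert [e.key() for e in cg2.edges] == [e.key() for e in cg.edges]
        assert cg2.names == cg.names

    def test_fully_branching_graph_unchanged(self):
        g = _mk_graph(
            ["AAC", "AAG"],
            [(0, 1, F, F), (0, 1, R, R), (0, 1, F, R), (0, 1, R, F)],
        )
        cg = compact(g)
        assert [cg.label(i) for i in range(2)] == ["AAC", "AAG"]
        assert [e.key() for e in cg.edges] == [e.key() for e in g.edges]

    @staticmethod
    def _random_read_graph(rng):
        from conftest import random_read_set

        seqs = random_read_set(rng, max_reads=12, min_len=15, max_len=40)
        k = rng.choice([5, 7, 9])
        return build_graph(ReadSet.from_sequences(seqs), k)

    def test_node_count_monotone_and_maximal(self):
        rng = random.Random(41)
        for _ in range(25):
            g = self._random_read_graph(rng)
            cg = compact(g)
            assert cg.n_vertices <= g.n_vertices
            # maximality: recompaction changes nothing
            cg2 = compact(cg)
            assert cg2.n_vertices == cg.n_vertices
            assert [e.key() for e in cg2.edges] == [e.key() for e in cg.edges]

    def test_symmetry_preserved_after_compaction(self):
        rng = random.Random(43)
        for _ in range(25):
            cg = compact(self._random_read_graph(rng))
            arcs = list_ranking_transform(cg).arcs
            assert {(scomp(b), scomp(a)) for a, b in arcs} == arcs

    def test_reads_still_spelled_after_compaction(self):
        k = 9
        genome = simulate_genome_unique_kmers(200, k - 1, seed=6)
        rs = tiling_reads(genome, 50, 30)
        cg = compact(build_graph(rs, k))
        for r in rs.reads:
            assert read_is_spelled(cg, r.sequence)

    def test_circular_genome_cycle_detected_and_broken(self):
        k = 13
        genome = simulate_genome_unique_kmers(150, k - 1, seed=8)
        rs = tiling_reads(genome, 50, 30, circular=True)
        g = build_graph(rs, k)
        cg = compact(g)
        rep = cg.cycle_report
        assert rep.has_cycles and len(rep.broken_arcs) == len(rep.cycles)
        assert cg.n_vertices == 1 and cg.n_edges == 0
        # the opened cycle spells the circular genome plus the k-1 wrap
        lab = cg.label(0)
        assert len(lab) == len(genome) + k - 1
        assert lab[: k - 1] == lab[-(k - 1):]
        doubled = genome + genome
        assert lab[: len(genome)] in doubled or (
            reverse_complement_str(lab)[: len(genome)] in doubled
        )

    def test_memory_external_compaction_equal(self, tmp_path):
        cfg = SortConfig(memory_budget_bytes=4096, block_bytes=512, tmp_dir=tmp_path)
        rng = random.Random(47)
        for _ in range(10):
            g = self._random_read_graph(rng)
            cm = compact(g, mode="memory")
            ce = compact(g, cfg=cfg, mode="external")
            assert [cm.label(i) for i in range(cm.n_vertices)] == [
                ce.label(i) for i in range(ce.n_vertices)
            ]
            assert [e.key() for e in cm.edges] == [e.key() for e in ce.edges]
            assert cm.names == ce.names
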