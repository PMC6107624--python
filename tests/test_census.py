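import networkx as nx
import numpy as np
import pytest

from ganet import (MotifSpectrum, brute_force_census, build_class_table,
                   graphlet_census, triad_census)
from ganet.census import (GRAPHLET_SIZES, N_GRAPHLET_CLASSES, N_TRIAD_CLASSES,
                          graphlet_class_info)


class TestClassTables:
    @pytest.mark.parametrize("size,n_classes", [(3, 2), (4, 6), (5, 21)])
    def test_undirected_connected_class_counts(self, size, n_classes):
        table = build_class_table(size)
        assert len(table) == n_classes
        assert all(table.connected)

    def test_total_graphlet_classes(self):
        assert sum(len(build_class_table(s)) for s in GRAPHLET_SIZES) == \
            N_GRAPHLET_CLASSES

    def test_directed_triad_classes(self):
        table = build_class_table(3, directed=True)
        assert len(table) == N_TRIAD_CLASSES
        assert sum(table.connected) == 13

    def test_representatives_are_canonical_and_distinct(self):
        table = build_class_table(4)
        assert len(set(table.representatives)) == len(table)
        assert list(table.representatives) == sorted(table.representatives)

    def test_representative_graphs_are_nonisomorphic(self):
        reps = [build_class_table(4).representative_graph(i)
                for i in range(6)]
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert not nx.is_isomorphic(reps[i], reps[j])

    def test_unsupported_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_class_table(6)
        with pytest.raises(ValueError):
            build_class_table(4, directed=True)


class TestGraphletCensus:
    def test_complete_graph_k5(self):
        spec = graphlet_census(nx.complete_graph(5))
        info = graphlet_class_info()
        by_class = dict(zip(info, spec.counts))
        # triangles, K4s and the K5 itself; nothing else is induced
        expect = {3: 10, 4: 5, 5: 1}
        for (size, rep), c in by_class.items():
            full = rep == max(r for s, r in info if s == size)
            assert c == (expect[size] if full else 0)

    def test_five_cycle(self):
        spec = graphlet_census(nx.cycle_graph(5))
        sizes = np.array([s for s, _ in graphlet_class_info()])
        assert spec.counts[sizes == 3].sum() == 5  # 5 induced paths
        assert spec.counts[sizes == 5].sum() == 1  # the cycle itself
        assert spec.total == 5 + 5 + 1  # plus the 5 induced 4-paths

    def test_triangle_free_graph_has_no_triangle_class(self):
        g = nx.bipartite.random_graph(8, 8, 0.5, seed=0)
        spec = graphlet_census(g, max_size=3)
        # triangle is the larger canonical mask among size-3 classes
        assert spec.counts[1] == 0
        assert spec.counts[0] > 0

    def test_directed_input_redirected(self):
        with pytest.raises(TypeError, match="triad_census"):
            graphlet_census(nx.gnp_random_graph(10, 0.3, seed=0,
                                                directed=True))

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            graphlet_census(nx.path_graph(3), max_size=5)

    def test_node_guard_trips_and_can_be_lifted(self):
        g = nx.empty_graph(2500)
        nx.add_path(g, range(2500))
        with pytest.raises(ValueError, match="guard"):
            graphlet_census(g, max_size=5)
        spec = graphlet_census(g, max_size=3, node_guard=True)  # under guard
        assert spec.counts[0] == 2498


class TestTriadCensus:
    def test_directed_three_cycle(self):
        spec = triad_census(nx.DiGraph([(0, 1), (1, 2), (2, 0)]))
        assert spec.counts.sum() == 1
        cyc = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        table = build_class_table(3, directed=True)
        hit = int(np.flatnonzero(spec.counts)[0])
        assert nx.is_isomorphic(table.representative_graph(hit), cyc)

    def test_out_star(self):
        spec = triad_census(nx.DiGraph([(0, 1), (0, 2)]))
        assert spec.counts.sum() == 1
        hit = int(np.flatnonzero(spec.counts)[0])
        table = build_class_table(3, directed=True)
        assert nx.is_isomorphic(table.representative_graph(hit),
                                nx.DiGraph([(0, 1), (0, 2)]))

    def test_edgeless_digraph_counts_nothing(self):
        spec = triad_census(nx.empty_graph(6, create_using=nx.DiGraph))
        assert spec.counts.sum() == 0

    def test_disconnected_classes_zeroed(self):
        d = nx.gnp_random_graph(12, 0.2, seed=5, directed=True)
        spec = triad_census(d)
        assert (spec.counts[~spec.connected] == 0).all()

    def test_undirected_input_redirected(self):
        with pytest.raises(TypeError, match="graphlet_census"):
            triad_census(nx.path_graph(5))


class TestOracleEquivalence:
    def test_esu_matches_brute_force(self, random_graphs):
        for g in random_graphs:
            esu = graphlet_census(g)
            brute = sum(brute_force_census(g, s).counts
                        for s in GRAPHLET_SIZES)
            assert (esu.counts == brute).all(), nx.to_dict_of_lists(g)

    def test_triads_match_brute_force(self, random_digraphs):
        for d in random_digraphs:
            fast = triad_census(d)
            brute = brute_force_census(d, 3)
            conn = fast.connected
            assert (fast.counts[conn] == brute.counts[conn]).all()
            # brute force keeps the disconnected classes; totals must
            # cover every 3-subset
            n = d.number_of_nodes()
            assert brute.counts.sum() == n * (n - 1) * (n - 2) // 6

    def test_census_totals_count_connected_subsets(self):
        g = nx.gnp_random_graph(12, 0.35, seed=3)
        spec = graphlet_census(g)
        from itertools import combinations
        for k in GRAPHLET_SIZES:
            n_connected = sum(
                1 for sub in combinations(g.nodes, k)
                if nx.is_connected(g.subgraph(sub)))
            sizes = np.array([s for s, _ in graphlet_class_info()])
            assert spec.counts[sizes == k].sum() == n_connected

    def test_invariant_under_relabelling(self):
        g = nx.gnp_random_graph(12, 0.4, seed=11)
        perm = np.random.default_rng(2).permutation(12)
        h = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(12)})
        assert (graphlet_census(g).counts == graphlet_census(h).counts).all()

    def test_brute_force_guard(self):
        with pytest.raises(ValueError):
            brute_force_census(nx.path_graph(20), 3)

    def test_k4_lands_in_complete_class(self):
        spec = brute_force_census(nx.complete_graph(4), 4)
        info = graphlet_class_info()
        nonzero = np.flatnonzero(spec.counts)
        assert len(nonzero) == 1
        size, rep = info[nonzero[0]]
        assert size == 4 and rep == max(r for s, r in info if s == 4)


class TestIndependentIgraphCrossCheck:
    """igraph's RAND-ESU with full sampling is an independent motif
    counter; totals per size must agree with ours."""

    def test_undirected_counts_match_igraph(self, random_graphs):
        igraph = pytest.importorskip("igraph")
        sizes = np.array([s for s, _ in graphlet_class_info()])
        for g in random_graphs[::5]:
            ig = igraph.Graph(n=10, edges=list(g.edges))
            spec = graphlet_census(g)
            for k in (3, 4, 5):
                theirs = np.nansum(ig.motifs_randesu(size=k))
                assert spec.counts[sizes == k].sum() == int(theirs)

    def test_directed_triads_match_igraph(self, random_digraphs):
        igraph = pytest.importorskip("igraph")
        for d in random_digraphs[::5]:
            ig = igraph.Graph(n=10, edges=list(d.edges), directed=True)
            ours = triad_census(d)
            theirs = np.array(ig.motifs_randesu(size=3))
            assert ours.counts[ours.connected].sum() == int(np.nansum(theirs))


class TestSpectrumSerialization:
    def test_tsv_round_trip(self, tmp_path):
        spec = graphlet_census(nx.gnp_random_graph(12, 0.4, seed=1))
        path = tmp_path / "spec.tsv"
        spec.to_tsv(path)
        back = MotifSpectrum.from_tsv(path)
        assert back.kind == spec.kind
        assert (back.counts == spec.counts).all()

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            MotifSpectrum(kind="undirected-graphlet", counts=np.zeros(5))
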