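import logging

import numpy as np
import pytest

from orthoclust.graph_core import (
    Labeling,
    SpeciesNetwork,
    build_multilayer,
    compute_ortholog_weights,
    dump_network,
    find_triplets,
    load_network,
)


class TestOrthologWeights:
    def test_one_to_one_pair_has_weight_one(self):
        om = compute_ortholog_weights(("a", "b"), [("x", "y")])
        assert om.weights[0] == 1.0

    def test_one_to_many_splits_by_partner_counts(self):
        # gene x with 2 partners, each partner exclusive to x: w = (1/2 + 1)/2
        om = compute_ortholog_weights(("a", "b"), [("x", "y1"), ("x", "y2")])
        assert np.allclose(om.weights, 0.75)

    def test_complete_bipartite_clique_damped(self):
        pairs = [(f"x{i}", f"y{j}") for i in range(3) for j in range(3)]
        om = compute_ortholog_weights(("a", "b"), pairs)
        assert np.allclose(om.weights, 1.0 / 3.0)
        # per-node attached weight sums to 1 in the 3x3 clique
        for g in ("x0", "x1", "x2"):
            total = sum(w for (a, _), w in zip(om.pairs, om.weights) if a == g)
            assert total == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "scheme,expected", [("product", 1 / 6), ("geometric", 1 / 6**0.5), ("uniform", 1.0)]
    )
    def test_alternative_schemes(self, scheme, expected):
        # gene x has 2 partners; y1 has 3 partners -> a=2, b=3 for pair (x, y1)
        pairs = [("x", "y1"), ("x", "y2"), ("u", "y1"), ("v", "y1")]
        om = compute_ortholog_weights(("a", "b"), pairs, scheme=scheme)
        w = dict(zip(om.pairs, om.weights))
        assert w[("x", "y1")] == pytest.approx(expected)

    def test_weight_conservation_exclusive_partners(self):
        # a partners each exclusive to x: total = a*(1/a + 1)/2
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = int(rng.integers(1, 8))
            pairs = [("x", f"y{i}") for i in range(a)]
            om = compute_ortholog_weights(("s1", "s2"), pairs)
            assert om.weights.sum() == pytest.approx(a * (1 / a + 1) / 2)

    def test_duplicates_deduplicated(self, caplog):
        with caplog.at_level(logging.WARNING):
            om = compute_ortholog_weights(("a", "b"), [("x", "y"), ("x", "y")])
        assert len(om) == 1
        assert om.weights[0] == 1.0

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_ortholog_weights(("a", "b"), [])


class TestSpeciesNetwork:
    def test_degree_and_edge_count_consistent(self):
        net = SpeciesNetwork.from_edges(
            "sp", ["a", "b", "c"], [("a", "b"), ("b", "c", -1)]
        )
        k = net.degrees()
        assert k.sum() == 2 * net.edge_count()
        assert net.edge_count(sign=1) == 1 and net.edge_count(sign=-1) == 1
        assert net.degrees(sign=1).tolist() == [1, 1, 0]

    def test_self_loop_rejected(self):
        net = SpeciesNetwork("sp", ["a", "b"])
        with pytest.raises(ValueError, match="self-loop"):
            net.add_edge("a", "a")

    def test_invalid_sign_rejected(self):
        net = SpeciesNetwork("sp", ["a", "b"])
        with pytest.raises(ValueError, match="sign"):
            net.add_edge("a", "b", 2)

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SpeciesNetwork("sp", ["a", "a"])


class TestBuildMultilayer:
    def test_minimal_assembly(self):
        l1 = SpeciesNetwork.from_edges("A", ["a1", "a2", "a3"], [("a1", "a2")])
        l2 = SpeciesNetwork.from_edges("B", ["b1", "b2", "b3"], [("b1", "b2")])
        mln = build_multilayer([l1, l2], [("A", "a1", "B", "b1")])
        assert mln.M == 6
        ii, jj, ww = mln.ortholog_edges_global()
        assert len(ii) == 1 and ww[0] == 1.0
        assert mln.global_index("B", "b1") == 3

    def test_unknown_gene_dropped_with_warning(self, caplog):
        l1 = SpeciesNetwork.from_edges("A", ["a1", "a2"], [("a1", "a2")])
        l2 = SpeciesNetwork.from_edges("B", ["b1", "b2"], [("b1", "b2")])
        with caplog.at_level(logging.WARNING):
            mln = build_multilayer(
                [l1, l2], [("A", "a1", "B", "b1"), ("A", "missing", "B", "b1")]
            )
        assert sum(len(o) for o in mln.orthologies.values()) == 1
        assert "dropped 1" in caplog.text

    def test_duplicate_species_rejected(self):
        l1 = SpeciesNetwork.from_edges("A", ["a1", "a2"], [("a1", "a2")])
        l2 = SpeciesNetwork.from_edges("A", ["b1", "b2"], [("b1", "b2")])
        with pytest.raises(ValueError, match="duplicate species_id"):
            build_multilayer([l1, l2])

    def test_empty_layer_rejected(self):
        l1 = SpeciesNetwork.from_edges("A", ["a1", "a2"], [("a1", "a2")])
        l2 = SpeciesNetwork("B", [])
        with pytest.raises(ValueError, match="'B'"):
            build_multilayer([l1, l2])


class TestTriplets:
    @staticmethod
    def _brute_force_triplets(layers, orthologies):
        """Independent scan over all cross-species gene combinations."""
        import itertools

        def partners(om, gene, side):
            if side == 0:
                return [b for a, b in om.pairs if a == gene]
            return [a for a, b in om.pairs if b == gene]

        found = set()
        ids = [l.species_id for l in layers]
        for s1, s2, s3 in itertools.combinations(ids, 3):
            def omap(x, y):
                if (x, y) in orthologies:
                    return orthologies[(x, y)], 0
                return orthologies.get((y, x)), 1

            o12, f12 = omap(s1, s2)
            o13, f13 = omap(s1, s3)
            o23, f23 = omap(s2, s3)
            if not (o12 and o13 and o23):
                continue
            l = dict(zip(ids, layers))
            for g1 in l[s1].nodes:
                for g2 in l[s2].nodes:
                    for g3 in l[s3].nodes:
                        p12 = partners(o12, g1, f12)
                        p21 = partners(o12, g2, 1 - f12)
                        p13 = partners(o13, g1, f13)
                        p31 = partners(o13, g3, 1 - f13)
                        p23 = partners(o23, g2, f23)
                        p32 = partners(o23, g3, 1 - f23)
                        if (
                            p12 == [g2] and p21 == [g1]
                            and p13 == [g3] and p31 == [g1]
                            and p23 == [g3] and p32 == [g2]
                        ):
                            found.add((g1, g2, g3))
        return found

    def test_mutual_one_to_one_triplet_detected(self):
        layers = [
            SpeciesNetwork.from_edges("A", ["a", "a2"], [("a", "a2")]),
            SpeciesNetwork.from_edges("B", ["b", "b2"], [("b", "b2")]),
            SpeciesNetwork.from_edges("C", ["c", "c2"], [("c", "c2")]),
        ]
        rows = [("A", "a", "B", "b"), ("A", "a", "C", "c"), ("B", "b", "C", "c")]
        mln = build_multilayer(layers, rows, triplet_detection=True)
        assert len(mln.triplets) == 1
        assert mln.triplets[0].genes == ("a", "b", "c")

    def test_competing_partner_blocks_triplet(self):
        layers = [
            SpeciesNetwork.from_edges("A", ["a", "a2"], [("a", "a2")]),
            SpeciesNetwork.from_edges("B", ["b", "b2"], [("b", "b2")]),
            SpeciesNetwork.from_edges("C", ["c", "c2"], [("c", "c2")]),
        ]
        rows = [
            ("A", "a", "B", "b"),
            ("A", "a", "C", "c"),
            ("B", "b", "C", "c"),
            ("A", "a2", "B", "b"),  # b now has two partners in A
        ]
        mln = build_multilayer(layers, rows, triplet_detection=True)
        assert len(mln.triplets) == 0

    def test_triplets_match_brute_force_on_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            layers = []
            for sp in ("A", "B", "C"):
                nodes = [f"{sp.lower()}{i}" for i in range(4)]
                net = SpeciesNetwork(sp, nodes)
                net.add_edge(nodes[0], nodes[1])
                layers.append(net)
            rows = []
            for la, lb in (("A", "B"), ("A", "C"), ("B", "C")):
                for ga in range(4):
                    for gb in range(4):
                        if rng.random() < 0.25:
                            rows.append(
                                (la, f"{la.lower()}{ga}", lb, f"{lb.lower()}{gb}")
                            )
            if not rows:
                continue
            mln = build_multilayer(layers, rows, triplet_detection=True)
            expected = self._brute_force_triplets(mln.layers, mln.orthologies)
            got = {t.genes for t in mln.triplets}
            assert got == expected


class TestRoundTrip:
    def test_dump_load_identical(self, tmp_path):
        l1 = SpeciesNetwork.from_edges(
            "A", ["a1", "a2", "a3"], [("a1", "a2", -1), ("a2", "a3", 1)]
        )
        l2 = SpeciesNetwork.from_edges("B", ["b1", "b2"], [("b1", "b2")])
        mln = build_multilayer([l1, l2], [("A", "a1", "B", "b1"), ("A", "a2", "B", "b1")])
        dump_network(mln, tmp_path)
        back = load_network(tmp_path)
        assert [l.nodes for l in back.layers] == [l.nodes for l in mln.layers]
        assert [l.edges() for l in back.layers] == [l.edges() for l in mln.layers]
        for key in mln.orthologies:
            assert back.orthologies[key].pairs == mln.orthologies[key].pairs
            assert np.allclose(back.orthologies[key].weights, mln.orthologies[key].weights)


class TestLabeling:
    def test_validation(self):
        with pytest.raises(ValueError):
            Labeling(np.array([0, 1]), q=2)  # labels are 1-based
        with pytest.raises(ValueError):
            Labeling(np.array([1, 3]), q=2)
        lab = Labeling(np.array([1, 2, 2]), q=2)
        assert len(lab) == 3
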