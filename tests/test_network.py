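import numpy as np
import pytest

from cernet.core import Config, GenomicInterval
from cernet.network import (
    NetworkGraph,
    build_network,
    classify_lncrna_roles,
    enrich_categories,
    find_bridges,
    qtl_colocalize,
)
from cernet.targets import BindingSite, CorrelationEdge

from _oracles import hypergeom_tail_oracle
from conftest import make_matrix, make_record


def site(mir, target):
    return BindingSite(mir, target, 0, 22, 150.0, -20.0)


def _expr(profiles, ids):
    return make_matrix(np.array(profiles), feature_ids=ids, kind="transformed")


BASE = np.array([1.0, 1.2, 0.8, 5.0, 5.2, 4.8, 1.1, 0.9, 1.0, 5.1, 4.9, 5.0])


class TestClassifyRoles:
    def test_target_rule(self, cfg):
        lnc = _expr([-BASE], ["lnc1"])  # r(lnc, mir) = -1
        mir = _expr([BASE], ["mir1"])
        mrna = _expr([np.random.default_rng(0).normal(size=12)], ["g1"])
        roles, edges = classify_lncrna_roles(
            [site("mir1", "lnc1")], lnc, mir, mrna, [], cfg
        )
        assert roles == {"lnc1": "target"}
        assert edges[0].edge_class == "lnc_mir"
        assert edges[0].r == pytest.approx(-1.0)

    def test_decoy_rule(self, cfg, rng):
        noise = rng.normal(size=12)
        lnc = _expr([BASE], ["lnc1"])  # follows the mRNA, not anti-mir
        mir = _expr([noise], ["mir1"])  # uncorrelated with lnc
        mrna = _expr([BASE], ["g1"])  # r(lnc, g1) = +1
        mm_edge = CorrelationEdge("mir1", "g1", 0.85, 12, "mir_mrna")
        roles, edges = classify_lncrna_roles(
            [site("mir1", "lnc1")], lnc, mir, mrna, [mm_edge], cfg
        )
        assert roles == {"lnc1": "decoy"}

    def test_no_site_no_edge(self, cfg):
        lnc = _expr([-BASE], ["lnc1"])
        mir = _expr([BASE], ["mir1"])
        mrna = _expr([BASE], ["g1"])
        roles, edges = classify_lncrna_roles([], lnc, mir, mrna, [], cfg)
        assert roles == {} and edges == []

    def test_weak_correlation_no_edge(self, cfg, rng):
        lnc = _expr([rng.normal(size=12)], ["lnc1"])
        mir = _expr([rng.normal(size=12)], ["mir1"])
        mrna = _expr([rng.normal(size=12)], ["g1"])
        roles, edges = classify_lncrna_roles(
            [site("mir1", "lnc1")], lnc, mir, mrna, [], cfg
        )
        assert roles == {} and edges == []


class TestBuildNetwork:
    def test_single_admitted_edge(self, cfg):
        net = build_network(
            {"mir1", "g1"}, {}, [], [("mir1", "g1", 0.9, True)], cfg
        )
        assert net.nodes() == {"mir1", "g1"}
        assert len(net.edges) == 1
        net.validate()

    def test_non_de_endpoint_drops_edge(self, cfg):
        with pytest.warns(UserWarning):
            net = build_network({"mir1"} - {"mir1"}, {}, [], [("mir1", "g1", 0.9, True)], cfg)
        assert net.nodes() == set()
        net2 = build_network({"mir1"}, {}, [], [("mir1", "g1", 0.9, True)], cfg)
        assert net2.nodes() == set()

    def test_requires_site_and_correlation(self, cfg):
        de = {"mir1", "g1"}
        assert build_network(de, {}, [], [("mir1", "g1", 0.9, False)], cfg).nodes() == set()
        assert build_network(de, {}, [], [("mir1", "g1", 0.5, True)], cfg).nodes() == set()
        assert build_network(de, {}, [], [("mir1", "g1", -0.9, True)], cfg).nodes() == {"mir1", "g1"}

    def test_lnc_edges_need_de(self, cfg):
        lnc_edge = [CorrelationEdge("lnc1", "mir1", -0.9, 12, "lnc_mir")]
        roles = {"lnc1": "target"}
        net = build_network({"lnc1", "mir1"}, roles, lnc_edge, [], cfg)
        assert len(net.edges) == 1
        assert net.node_role["lnc1"] == "mir_target_lnc"
        net_nolnc = build_network({"mir1"}, roles, lnc_edge, [], cfg)
        assert net_nolnc.nodes() == set()

    def test_membership_rule_and_idempotence(self, cfg):
        de = {"mir1", "mir2", "g1", "lnc1"}
        roles = {"lnc1": "decoy"}
        lnc_edges = [CorrelationEdge("lnc1", "mir1", 0.9, 12, "lnc_mir")]
        cands = [("mir1", "g1", 0.92, True), ("mir2", "g1", -0.85, True)]
        net = build_network(de, roles, lnc_edges, cands, cfg)
        net.validate()
        rebuilt = build_network(de, roles, lnc_edges, cands, cfg)
        assert rebuilt.edges == net.edges
        assert rebuilt.node_type == net.node_type

    def test_monotone_in_r_pair(self, cfg, rng):
        de = {f"mir{i}" for i in range(10)} | {f"g{i}" for i in range(10)}
        cands = [
            (f"mir{i}", f"g{j}", float(rng.uniform(-1, 1)), True)
            for i in range(10)
            for j in range(10)
        ]
        loose = build_network(de, {}, [], cands, cfg.replace(r_pair=0.5))
        tight = build_network(de, {}, [], cands, cfg.replace(r_pair=0.9))
        assert set(tight.edges) <= set(loose.edges)


class TestBridges:
    def _star(self):
        net = NetworkGraph()
        net.set_node("g1", "mRNA")
        for i in range(3):
            net.set_node(f"mir{i}", "miRNA")
            net.add_edge(f"mir{i}", "g1", "mir_mrna", 0.9, True)
        return net

    def test_star(self):
        assert find_bridges(self._star()) == [("g1", 3)]

    def test_degree_one_only(self):
        net = NetworkGraph()
        for i in range(3):
            net.set_node(f"g{i}", "mRNA")
            net.set_node(f"mir{i}", "miRNA")
            net.add_edge(f"mir{i}", f"g{i}", "mir_mrna", 0.9, True)
        assert find_bridges(net) == []

    def test_matches_brute_force(self, rng):
        net = NetworkGraph()
        mirs = [f"mir{i}" for i in range(20)]
        genes = [f"g{i}" for i in range(30)]
        for _ in range(100):
            m = mirs[rng.integers(0, 20)]
            g = genes[rng.integers(0, 30)]
            net.set_node(m, "miRNA")
            net.set_node(g, "mRNA")
            net.add_edge(m, g, "mir_mrna", 0.9, True)
        got = find_bridges(net, min_mirna_degree=2)
        counts = {}
        for (a, b), _meta in net.edges.items():
            g = a if a.startswith("g") else b
            m = b if a.startswith("g") else a
            counts.setdefault(g, set()).add(m)
        expected = sorted(
            ((g, len(ms)) for g, ms in counts.items() if len(ms) >= 2),
            key=lambda t: (-t[1], t[0]),
        )
        assert got == expected


class TestQTL:
    INTERVAL = GenomicInterval("chr11", 8_900_000, 12_200_000)

    def test_contained_gene_included(self, cfg):
        rec = make_record("g1", chrom="chr11", exon_spans=((9_000_000, 9_010_000),), biotype="known_mRNA")
        out = qtl_colocalize([rec], {"g1"}, self.INTERVAL, cfg)
        assert out.genes == {"g1"}

    def test_other_chromosome_excluded(self, cfg):
        recs = [
            make_record("g1", chrom="chr10", exon_spans=((9_000_000, 9_010_000),), biotype="known_mRNA"),
            make_record("g2", chrom="chr11", exon_spans=((9_000_000, 9_010_000),), biotype="known_mRNA"),
        ]
        out = qtl_colocalize(recs, {"g1", "g2"}, self.INTERVAL, cfg)
        assert out.genes == {"g2"}

    def test_straddling_boundary_semantics(self, cfg):
        rec = make_record("g1", chrom="chr11", exon_spans=((8_850_000, 8_950_000),), biotype="known_mRNA")
        contained = qtl_colocalize([rec], {"g1"}, self.INTERVAL, cfg)
        assert contained.genes == set()
        overlap = qtl_colocalize([rec], {"g1"}, self.INTERVAL, cfg.replace(qtl_overlap=True))
        assert overlap.genes == {"g1"}

    def test_non_de_excluded(self, cfg):
        rec = make_record("g1", chrom="chr11", exon_spans=((9_000_000, 9_010_000),), biotype="known_mRNA")
        out = qtl_colocalize([rec], set(), self.INTERVAL, cfg)
        assert out.genes == set()

    def test_lncrna_split(self, cfg):
        recs = [
            make_record("l1", chrom="chr11", exon_spans=((9_000_000, 9_001_000),), biotype="known_lncRNA"),
            make_record("g1", chrom="chr11", exon_spans=((9_100_000, 9_110_000),), biotype="known_mRNA"),
        ]
        out = qtl_colocalize(recs, {"l1", "g1"}, self.INTERVAL, cfg)
        assert out.lncrnas == {"l1"} and out.genes == {"g1"}

    def test_missing_chromosome_errors(self, cfg):
        rec = make_record("g1", chrom="chr3", biotype="known_mRNA")
        with pytest.raises(ValueError, match="absent"):
            qtl_colocalize([rec], {"g1"}, self.INTERVAL, cfg)

    def test_random_spans_match_brute_force(self, cfg, rng):
        recs, de = [], set()
        for i in range(2000):
            start = int(rng.integers(0, 14_000_000))
            length = int(rng.integers(1000, 500_000))
            rec = make_record(
                f"g{i}", chrom="chr11", exon_spans=((start, start + length),),
                biotype="known_mRNA",
            )
            recs.append(rec)
            de.add(f"g{i}")
        for mode in (False, True):
            c = cfg.replace(qtl_overlap=mode)
            got = qtl_colocalize(recs, de, self.INTERVAL, c).genes
            expected = set()
            for rec in recs:
                s, e = rec.interval.start, rec.interval.end
                if mode:
                    hit = s < self.INTERVAL.end and self.INTERVAL.start < e
                else:
                    hit = self.INTERVAL.start <= s and e <= self.INTERVAL.end
                if hit:
                    expected.add(rec.transcript_id)
            assert got == expected


class TestEnrichment:
    def test_query_equals_universe(self):
        universe = {f"g{i}" for i in range(10)}
        rows = enrich_categories(universe, universe, {"cat": set(list(universe)[:5])})
        assert all(p == pytest.approx(1.0) for _c, _o, p, _q in rows)

    def test_hand_hypergeometric(self):
        universe = {f"g{i}" for i in range(10)}
        category = {f"g{i}" for i in range(5)}
        query = {f"g{i}" for i in range(4)}  # overlap 4
        rows = enrich_categories(query, universe, {"cat": category})
        # P[X >= 4] = [C(5,4)C(5,0) + C(5,5)C(5,-)] / C(10,4) = (5 + 0)/210
        assert rows[0][2] == pytest.approx(5 / 210)

    def test_query_outside_universe_errors(self):
        with pytest.raises(ValueError):
            enrich_categories({"x"}, {"a"}, {})

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n_univ = int(rng.integers(5, 21))
            universe = {f"g{i}" for i in range(n_univ)}
            ids = sorted(universe)
            cat = set(rng.choice(ids, size=rng.integers(1, n_univ + 1), replace=False))
            query = set(rng.choice(ids, size=rng.integers(1, n_univ + 1), replace=False))
            rows = enrich_categories(query, universe, {"c": cat})
            overlap = len(cat & query)
            expected = hypergeom_tail_oracle(overlap, n_univ, len(cat), len(query))
            assert rows[0][1] == overlap
            assert rows[0][2] == pytest.approx(expected, abs=1e-12)


class TestNetworkGraphInvariants:
    def test_no_self_edges(self):
        net = NetworkGraph()
        net.set_node("a", "miRNA")
        with pytest.raises(ValueError):
            net.add_edge("a", "a", "mir_mrna", 0.9, True)

    def test_type_compatibility_checked(self):
        net = NetworkGraph()
        net.set_node("g1", "mRNA")
        net.set_node("g2", "mRNA")
        net.add_edge("g1", "g2", "mir_mrna", 0.9, True)
        with pytest.raises(ValueError, match="miRNA"):
            net.validate()

    def test_orphan_node_detected(self):
        net = NetworkGraph()
        net.set_node("g1", "mRNA")
        with pytest.raises(ValueError, match="pair"):
            net.validate()

    def test_duplicate_edges_collapsed(self):
        net = NetworkGraph()
        net.set_node("m", "miRNA")
        net.set_node("g", "mRNA")
        net.add_edge("m", "g", "mir_mrna", 0.9, True)
        net.add_edge("g", "m", "mir_mrna", 0.9, True)
        assert len(net.edges) == 1
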