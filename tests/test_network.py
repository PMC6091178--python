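import itertools

import numpy as np
import pytest

from guidecoex.correlation import ThresholdSpec, correlate_guides
from guidecoex.io import GuideGeneSet, TFFamilyAnnotation
from guidecoex.network import (
    build_network,
    count_edge_signs,
    export_graphml,
    export_sif,
    read_sif,
    select_negative_candidates,
)

from conftest import make_matrix, make_table


@pytest.fixture
def toy_net():
    """r(G1,t1)=0.7, r(G1,t2)=-0.65, r(G2,t2)=-0.61, r(G2,t3)=0.2 at tau 0.6."""
    table = make_table(
        {
            "G1": {"G1": 1.0, "G2": 0.5, "t1": 0.7, "t2": -0.65, "t3": 0.1},
            "G2": {"G1": 0.5, "G2": 1.0, "t1": 0.3, "t2": -0.61, "t3": 0.2},
        }
    )
    ann = TFFamilyAnnotation({"t1": "G2-like", "t2": "G2-like", "t3": "G2-like"})
    return build_network(table, ann, family="all", spec=ThresholdSpec(0.6))


class TestBuildNetwork:
    def test_toy_edges(self, toy_net):
        assert set(toy_net.tf_ids) == {"t1", "t2"}
        got = {(e.guide_id, e.tf_id, e.sign) for e in toy_net.edges}
        assert got == {
            ("G1", "t1", "positive"),
            ("G1", "t2", "negative"),
            ("G2", "t2", "negative"),
        }

    def test_high_tau_leaves_guides_only(self):
        table = make_table({"G1": {"G1": 1.0, "t1": 0.5}})
        ann = TFFamilyAnnotation({"t1": "MYB"})
        net = build_network(table, ann, spec=ThresholdSpec(0.99))
        assert net.edges == [] and net.tf_ids == [] and net.guide_ids == ["G1"]

    def test_unknown_family_lists_available(self):
        table = make_table({"G1": {"G1": 1.0, "t1": 0.9}})
        ann = TFFamilyAnnotation({"t1": "MYB"})
        with pytest.raises(ValueError, match="MYB"):
            build_network(table, ann, family="G2like-typo")

    def test_family_filter_restricts_pool(self):
        table = make_table({"G1": {"G1": 1.0, "t1": 0.9, "t2": 0.9}})
        ann = TFFamilyAnnotation({"t1": "MYB", "t2": "G2-like"})
        net = build_network(table, ann, family="G2-like", spec=ThresholdSpec(0.6))
        assert net.tf_ids == ["t2"]

    def test_guides_never_appear_as_tfs(self):
        table = make_table({"G1": {"G1": 1.0, "G2": 0.95}, "G2": {"G1": 0.95, "G2": 1.0}})
        ann = TFFamilyAnnotation({"G2": "G2-like"})  # a guide that is also a TF
        net = build_network(table, ann, spec=ThresholdSpec(0.6))
        assert net.edges == []

    def test_matches_bruteforce_enumeration_on_random_toys(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_guides = int(rng.integers(1, 6))
            n_genes = int(rng.integers(5, 51))
            genes = [f"x{i}" for i in range(n_genes)]
            guides = [f"G{i}" for i in range(n_guides)]
            r = {
                g: {**{x: float(rng.uniform(-1, 1)) for x in genes},
                    **{h: 1.0 if h == g else 0.0 for h in guides}}
                for g in guides
            }
            table = make_table(r)
            ann = TFFamilyAnnotation({x: "F" for x in genes})
            tau = float(rng.uniform(0.2, 0.9))
            net = build_network(table, ann, spec=ThresholdSpec(tau))
            expected = {
                (g, x)
                for g, x in itertools.product(guides, genes)
                if abs(r[g][x]) > tau
            }
            assert {(e.guide_id, e.tf_id) for e in net.edges} == expected

    def test_raising_tau_never_adds_edges(self):
        rng = np.random.default_rng(11)
        genes = [f"x{i}" for i in range(30)]
        r = {"G": {"G": 1.0, **{x: float(rng.uniform(-1, 1)) for x in genes}}}
        table = make_table(r)
        ann = TFFamilyAnnotation({x: "F" for x in genes})
        previous = None
        for tau in [0.2, 0.4, 0.6, 0.8, 0.95]:
            edges = {(e.guide_id, e.tf_id) for e in build_network(table, ann, spec=ThresholdSpec(tau)).edges}
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_reflecting_tf_rows_flips_all_signs(self):
        """Mapping each TF profile x -> max(x) - x flips every edge sign."""
        rows = {
            "G": [1.0, 2.0, 3.0, 5.0, 8.0, 9.0, 11.0, 12.0, 14.0, 17.0, 20.0],
            "t1": [2.0, 3.0, 3.5, 6.0, 7.5, 10.0, 10.5, 13.0, 15.0, 16.0, 19.0],
            "t2": [20.0, 18.0, 17.0, 15.0, 12.0, 11.0, 9.0, 7.0, 6.0, 3.0, 1.0],
        }
        reflected = {
            g: (v if g == "G" else list(max(v) - np.asarray(v))) for g, v in rows.items()
        }
        ann = TFFamilyAnnotation({"t1": "F", "t2": "F"})
        guides = GuideGeneSet([("G", "G")])
        spec = ThresholdSpec(0.6)
        net = build_network(correlate_guides(make_matrix(rows), guides), ann, spec=spec)
        net_ref = build_network(correlate_guides(make_matrix(reflected), guides), ann, spec=spec)
        signs = {e.tf_id: e.sign for e in net.edges}
        signs_ref = {e.tf_id: e.sign for e in net_ref.edges}
        assert set(signs) == set(signs_ref) == {"t1", "t2"}
        flip = {"positive": "negative", "negative": "positive"}
        assert signs_ref == {tf: flip[s] for tf, s in signs.items()}
        c, c_ref = count_edge_signs(net).counts, count_edge_signs(net_ref).counts
        assert (c["positive"], c["negative"]) == (c_ref["negative"], c_ref["positive"])


class TestSignSummary:
    def test_toy_counts(self, toy_net):
        s = count_edge_signs(toy_net)
        assert s.per_tf == {"t1": "positive", "t2": "negative"}
        assert s.counts == {"positive": 1, "negative": 1, "mixed": 0}

    def test_empty_network(self):
        table = make_table({"G": {"G": 1.0, "t": 0.1}})
        net = build_network(table, TFFamilyAnnotation({"t": "F"}), spec=ThresholdSpec(0.6))
        assert count_edge_signs(net).counts == {"positive": 0, "negative": 0, "mixed": 0}

    def test_sign_tie_is_mixed(self):
        table = make_table({"G1": {"G1": 1.0, "G2": 0.0, "t": 0.8}, "G2": {"G1": 0.0, "G2": 1.0, "t": -0.8}})
        net = build_network(table, TFFamilyAnnotation({"t": "F"}), spec=ThresholdSpec(0.6))
        s = count_edge_signs(net)
        assert s.per_tf == {"t": "mixed"}
        assert s.counts["mixed"] == 1


class TestCandidates:
    def test_toy_candidate(self, toy_net):
        reports = select_negative_candidates(toy_net, min_negative_partners=2)
        assert len(reports) == 1
        c = reports[0]
        assert c.tf_id == "t2"
        assert c.negative_partner_guides == ["G1", "G2"]
        assert c.positive_partner_guides == []
        assert c.n_negative == 2

    def test_empty_network(self):
        table = make_table({"G": {"G": 1.0, "t": 0.1}})
        net = build_network(table, TFFamilyAnnotation({"t": "F"}), spec=ThresholdSpec(0.6))
        assert select_negative_candidates(net, 1) == []

    def test_sort_order(self):
        table = make_table(
            {
                "G1": {"G1": 1.0, "G2": 0.0, "a": -0.9, "b": -0.9},
                "G2": {"G1": 0.0, "G2": 1.0, "a": -0.9, "b": 0.1},
            }
        )
        net = build_network(table, TFFamilyAnnotation({"a": "F", "b": "F"}), spec=ThresholdSpec(0.6))
        reports = select_negative_candidates(net, 1)
        assert [c.tf_id for c in reports] == ["a", "b"]


class TestExports:
    def test_sif_content_and_order(self, toy_net, tmp_path):
        p = tmp_path / "net.sif"
        export_sif(toy_net, p)
        lines = p.read_text().splitlines()
        assert lines == ["G1\tpos\tt1", "G1\tneg\tt2", "G2\tneg\tt2"]

    def test_sif_round_trip(self, toy_net, tmp_path):
        p = tmp_path / "net.sif"
        export_sif(toy_net, p)
        triples = read_sif(p)
        expected = {
            (e.guide_id, "pos" if e.sign == "positive" else "neg", e.tf_id)
            for e in toy_net.edges
        }
        assert set(triples) == expected

    def test_empty_sif(self, tmp_path):
        table = make_table({"G": {"G": 1.0, "t": 0.1}})
        net = build_network(table, TFFamilyAnnotation({"t": "F"}), spec=ThresholdSpec(0.6))
        p = tmp_path / "empty.sif"
        export_sif(net, p)
        assert p.read_text() == ""

    def test_exports_are_byte_deterministic(self, toy_net, tmp_path):
        a, b = tmp_path / "a.graphml", tmp_path / "b.graphml"
        export_graphml(toy_net, a)
        export_graphml(toy_net, b)
        assert a.read_bytes() == b.read_bytes()
        s1, s2 = tmp_path / "a.sif", tmp_path / "b.sif"
        export_sif(toy_net, s1)
        export_sif(toy_net, s2)
        assert s1.read_bytes() == s2.read_bytes()

    def test_graphml_parses_and_matches_sif_edges(self, toy_net, tmp_path):
        import networkx as nx

        p = tmp_path / "net.graphml"
        export_graphml(toy_net, p)
        g = nx.read_graphml(p)
        assert len(g.nodes) == 4
        assert len(g.edges) == 3
        assert g.nodes["t2"]["type"] == "tf"
        assert g.nodes["G1"]["type"] == "guide"
        assert g.edges["G1", "t1"]["r"] == pytest.approx(0.7)
        assert g.edges["G1", "t1"]["sign"] == "positive"
        sif = tmp_path / "net.sif"
        export_sif(toy_net, sif)
        sif_edges = {(s, t) for s, _, t in read_sif(sif)}
        assert sif_edges == {(u, v) for u, v in g.edges}

    def test_graphml_r_has_six_decimals(self, toy_net, tmp_path):
        p = tmp_path / "net.graphml"
        export_graphml(toy_net, p)
        assert "0.700000" in p.read_text()

    def test_empty_graphml_is_valid(self, tmp_path):
        import networkx as nx

        table = make_table({"G": {"G": 1.0, "t": 0.1}})
        net = build_network(table, TFFamilyAnnotation({"t": "F"}), spec=ThresholdSpec(0.6))
        p = tmp_path / "empty.graphml"
        export_graphml(net, p)
        g = nx.read_graphml(p)
        assert len(g.edges) == 0 and len(g.nodes) == 1
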