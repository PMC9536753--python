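import numpy as np
import pandas as pd
import pytest

from regnetrank.io import ExpressionMatrix, GeneAnnotation
from regnetrank.motifs import BindingSite
from regnetrank import network as gn


def site(contig="c1", start=100, end=112, tfs=("T1",), motif="m1", pv=1e-5, peak_p=5.0, strand="+"):
    return BindingSite(motif, tuple(tfs), contig, start, end, strand, pv, peak_p)


def annotation(rows):
    """rows: list of (symbol, contig, tss, strand)"""
    t = pd.DataFrame(rows, columns=["symbol", "contig", "tss", "strand"]).set_index("symbol")
    return GeneAnnotation(t)


class TestZscore:
    def test_constant_gene_gets_zero(self):
        expr = ExpressionMatrix(pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}, index=["g"]))
        z = gn.zscore_expression(expr)
        assert (z.loc["g"] == 0).all()

    def test_two_point_sample_sd(self):
        expr = ExpressionMatrix(pd.DataFrame({"a": [0.0], "b": [2.0]}, index=["g"]))
        z = gn.zscore_expression(expr, log_transform=False)
        assert z.loc["g", "a"] == pytest.approx(-np.sqrt(0.5))
        assert z.loc["g", "b"] == pytest.approx(np.sqrt(0.5))

    def test_column_permutation_equivariance(self, rng):
        data = pd.DataFrame(rng.uniform(0, 50, size=(6, 5)), index=list("abcdef"),
                            columns=[f"c{i}" for i in range(5)])
        z = gn.zscore_expression(ExpressionMatrix(data))
        perm = ["c3", "c0", "c4", "c1", "c2"]
        z_perm = gn.zscore_expression(ExpressionMatrix(data[perm]))
        assert np.allclose(z[perm].to_numpy(), z_perm.to_numpy())

    def test_single_cell_type_is_error(self):
        expr = ExpressionMatrix(pd.DataFrame({"a": [1.0]}, index=["g"]))
        with pytest.raises(ValueError, match="2 cell types"):
            gn.zscore_expression(expr)


class TestWeights:
    def test_node_weight_exponential(self):
        assert gn.node_weight(0.0) == 1.0
        assert gn.node_weight(1.0) == pytest.approx(np.e)
        assert gn.node_weight(1.0) > gn.node_weight(0.5)

    def test_sigmoid_midpoint_and_limits(self):
        assert gn.sigmoid_rescale(5.0) == 0.5
        assert gn.sigmoid_rescale(0.0) == pytest.approx(1 / (1 + np.exp(5)))
        assert gn.sigmoid_rescale(50.0) == pytest.approx(1.0, abs=1e-12)
        xs = np.linspace(0, 20, 50)
        assert (np.diff(gn.sigmoid_rescale(xs)) > 0).all()

    def test_edge_weight_midpoint_arithmetic(self):
        # one site at the sigmoid midpoint for both terms: 2 * 0.5 * 0.5
        w = gn.edge_weight(2.0, [site(pv=1e-5, peak_p=5.0)])
        assert w == pytest.approx(0.5)

    def test_edge_weight_zero_expression(self):
        assert gn.edge_weight(0.0, [site(), site(pv=1e-9)]) == 0.0

    def test_edge_weight_additive_over_sites(self):
        one = gn.edge_weight(1.5, [site()])
        two = gn.edge_weight(1.5, [site(), site()])
        assert two == pytest.approx(2 * one)

    def test_perfect_match_pvalue_capped(self):
        w = gn.edge_weight(1.0, [site(pv=0.0, peak_p=5.0)])
        assert np.isfinite(w)
        assert w == pytest.approx(0.5 * gn.sigmoid_rescale(gn.MOTIF_NEG_LOG10_CAP))


class TestAssignSites:
    def test_upstream_site_in_window(self):
        ann = annotation([("g1", "c1", 1000, "+")])
        rule = gn.LinkageRule(upstream=5000, downstream=1000)
        out = gn.assign_sites([site(start=800, end=812)], ann, rule)
        assert list(out) == ["g1"]

    def test_narrow_window_excludes(self):
        ann = annotation([("g1", "c1", 1000, "+")])
        rule = gn.LinkageRule(upstream=100, downstream=100)
        out = gn.assign_sites([site(start=800, end=812)], ann, rule)
        assert out == {}

    def test_minus_strand_window_is_mirrored(self):
        ann = annotation([("g1", "c1", 1000, "-")])
        rule = gn.LinkageRule(upstream=500, downstream=10)
        # 200 bp downstream in genome coordinates = upstream of a '-' gene
        assert list(gn.assign_sites([site(start=1200, end=1212)], ann, rule)) == ["g1"]
        assert gn.assign_sites([site(start=700, end=712)], ann, rule) == {}

    def test_enhancer_link_table_cross_contig(self):
        ann = annotation([("g1", "c1", 1000, "+")])
        rule = gn.LinkageRule(upstream=10, downstream=10, links=[("c9", 500, 600, "g1")])
        out = gn.assign_sites([site(contig="c9", start=520, end=532)], ann, rule)
        assert list(out) == ["g1"]

    def test_unknown_link_gene_is_error(self):
        ann = annotation([("g1", "c1", 1000, "+")])
        rule = gn.LinkageRule(links=[("c1", 0, 10, "nope")])
        with pytest.raises(ValueError, match="nope"):
            gn.assign_sites([site()], ann, rule)


@pytest.fixture
def simple_setup():
    """One TF (T1) whose motif sits in the promoters of three genes."""
    ann = annotation(
        [
            ("T1", "cT", 100, "+"),
            ("g1", "c1", 2000, "+"),
            ("g2", "c2", 2000, "+"),
            ("g3", "c3", 2000, "+"),
        ]
    )
    ann.flag_tfs(["T1"])
    expr = ExpressionMatrix(
        pd.DataFrame(
            {"ctA": [3.0, 1.0, 2.0, 4.0], "ctB": [1.0, 2.0, 2.0, 8.0]},
            index=["T1", "g1", "g2", "g3"],
        )
    )
    sites = [site(contig=f"c{i}", start=1500, end=1512, tfs=("T1",)) for i in (1, 2, 3)]
    return ann, expr, sites


class TestBuildNetwork:
    def test_planted_sites_give_three_edges(self, simple_setup):
        ann, expr, sites = simple_setup
        net = gn.build_network("ctA", sites, ann, expr)
        assert len(net.edges) == 3
        assert set(net.edges["target"]) == {"g1", "g2", "g3"}
        assert (net.edges["tf"] == "T1").all()
        assert net.audit_weights()

    def test_shared_motif_scales_by_own_expression(self, simple_setup):
        ann, expr, sites = simple_setup
        ann2 = annotation(
            [(s, r["contig"], r["tss"], r["strand"]) for s, r in ann.table.iterrows()]
            + [("T2", "cT2", 100, "+")]
        )
        ann2.flag_tfs(["T1", "T2"])
        expr2 = ExpressionMatrix(
            pd.concat([expr.data, pd.DataFrame({"ctA": [7.0], "ctB": [2.0]}, index=["T2"])])
        )
        shared = [
            site(contig=f"c{i}", start=1500, end=1512, tfs=("T1", "T2")) for i in (1, 2, 3)
        ]
        net = gn.build_network("ctA", shared, ann2, expr2)
        w1 = net.edges.set_index(["tf", "target"])["weight"]
        g1, g2 = np.log2(3.0 + 1), np.log2(7.0 + 1)
        for t in ("g1", "g2", "g3"):
            assert w1[("T1", t)] / w1[("T2", t)] == pytest.approx(g1 / g2)

    def test_no_sites_gives_edgeless_network(self, simple_setup, caplog):
        ann, expr, _ = simple_setup
        with caplog.at_level("WARNING"):
            net = gn.build_network("ctA", [], ann, expr)
        assert len(net.edges) == 0
        assert len(net.nodes) == 4

    def test_doubling_expression_doubles_edge_weights(self, simple_setup):
        ann, expr, sites = simple_setup
        net = gn.build_network("ctA", sites, ann, expr, log_transform=False)
        data2 = expr.data.copy()
        data2.loc["T1"] *= 2
        net2 = gn.build_network("ctA", sites, ann, ExpressionMatrix(data2), log_transform=False)
        assert np.allclose(net2.edges["weight"], 2 * net.edges["weight"])

    def test_unknown_tf_skipped_with_warning(self, simple_setup, caplog):
        ann, expr, _ = simple_setup
        orphan = [site(contig="c1", start=1500, end=1512, tfs=("Tghost",))]
        with caplog.at_level("WARNING"):
            net = gn.build_network("ctA", orphan, ann, expr)
        assert len(net.edges) == 0
        assert any("Tghost" in r.message for r in caplog.records)


class TestSubsample:
    def _network(self, n_tf=10, n_non=30):
        regulatees = [f"t{i}" for i in range(n_tf)] + [f"g{i}" for i in range(n_non)]
        nodes = pd.DataFrame(
            {
                "is_tf": [True] * (n_tf + 1) + [False] * n_non,
                "node_weight": 1.0,
            },
            index=pd.Index(["F"] + regulatees, name="gene"),
        )
        edges = pd.DataFrame(
            [("F", r, 2.0, 1) for r in regulatees],
            columns=["tf", "target", "weight", "n_sites"],
        )
        return gn.RegulatoryNetwork("ct", nodes, edges)

    def test_ratio_preserved(self):
        net = self._network()
        out = gn.subsample_for_visualization(
            net, "F", n_regulatees=20, edge_fraction=1.0, seed=3
        )
        sampled = set(out["target"])
        n_tf = sum(t.startswith("t") for t in sampled)
        assert len(sampled) == 20
        assert n_tf == 5  # 10:30 ratio preserved at 20 regulatees

    def test_deterministic_under_seed(self):
        net = self._network()
        a = gn.subsample_for_visualization(net, "F", seed=11)
        b = gn.subsample_for_visualization(net, "F", seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_min_weight_above_all_gives_empty(self, caplog):
        net = self._network()
        with caplog.at_level("WARNING"):
            out = gn.subsample_for_visualization(net, "F", min_weight=99.0)
        assert out.empty
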