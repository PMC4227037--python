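"""Node grammar, graph I/O round-trips, merging and annotation statistics."""

import warnings

import pytest
from hypothesis import given, strategies as st

from rcrnet import (
    ActivityTag,
    CausalEdge,
    Evidence,
    NodeRef,
    Species,
    Subnetwork,
    context_edge_proportion,
    format_node_label,
    make_chimeric,
    merge_subnetworks,
    node_overlap_matrix,
    parse_node_label,
    read_edge_table,
    read_xgmml,
    write_edge_table,
    write_xgmml,
)
from rcrnet.kbase import NodeLabelError

from conftest import build_graph, random_graph


# ---------------------------------------------------------------------------
# node grammar
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "label, symbol, tag, site",
    [
        ("taof(STAT1)", "STAT1", ActivityTag.TRANSCRIPTIONAL_ACTIVITY, None),
        ("kaof(Chuk)", "Chuk", ActivityTag.KINASE_ACTIVITY, None),
        ("exp(CXCL1)", "CXCL1", ActivityTag.RNA_EXPRESSION, None),
        ("gtpof(RHOA)", "RHOA", ActivityTag.GTP_BOUND, None),
        ("paof(PTPN1)", "PTPN1", ActivityTag.PHOSPHATASE_ACTIVITY, None),
        ("catof(MMP9)", "MMP9", ActivityTag.CATALYTIC_ACTIVITY, None),
        ("bp(macrophage activation)", "macrophage activation",
         ActivityTag.BIOLOGICAL_PROCESS, None),
        ("AKT1 P@S473", "AKT1", ActivityTag.PHOSPHO_FORM, "S473"),
        ("CCL5", "CCL5", ActivityTag.ABUNDANCE, None),
        ("Ox-LDL", "Ox-LDL", ActivityTag.ABUNDANCE, None),
    ],
)
def test_parse_node_label(label, symbol, tag, site):
    node = parse_node_label(label)
    assert node.entity_symbol == symbol
    assert node.activity_tag is tag
    assert node.phospho_site == site
    assert format_node_label(node) == label


@pytest.mark.parametrize(
    "bad", ["", "taof(", "taof()", "foo(X)", "A(B)C", "taof(X))", "(X)"]
)
def test_parse_node_label_rejects_malformed(bad):
    with pytest.raises(NodeLabelError):
        parse_node_label(bad)


_symbols = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters="-_."),
    min_size=1,
    max_size=10,
)


@given(
    symbol=_symbols,
    tag=st.sampled_from([t for t in ActivityTag if t is not ActivityTag.PHOSPHO_FORM]),
)
def test_format_parse_roundtrip(symbol, tag):
    node = NodeRef(symbol, tag)
    assert parse_node_label(format_node_label(node)) == node


@given(symbol=_symbols, site=_symbols)
def test_format_parse_roundtrip_phospho(symbol, site):
    node = NodeRef(symbol, ActivityTag.PHOSPHO_FORM, phospho_site=site)
    assert parse_node_label(format_node_label(node)) == node


def test_phospho_site_requires_phospho_tag():
    with pytest.raises(NodeLabelError):
        NodeRef("AKT1", ActivityTag.ABUNDANCE, phospho_site="S473")
    with pytest.raises(NodeLabelError):
        NodeRef("AKT1", ActivityTag.PHOSPHO_FORM)


# ---------------------------------------------------------------------------
# graph normalization
# ---------------------------------------------------------------------------


def test_self_loops_dropped_with_warning():
    with pytest.warns(UserWarning, match="self-loop"):
        g = build_graph("g", [("taof(X)", 1, "taof(X)")])
    assert g.n_edges == 0


def test_conflicting_signs_collapse_to_ambiguous():
    with pytest.warns(UserWarning, match="conflicting"):
        g = build_graph("g", [("taof(X)", 1, "exp(Y)"), ("taof(X)", -1, "exp(Y)")])
    assert g.n_edges == 1
    assert g.edges[0].sign == 0


# ---------------------------------------------------------------------------
# XGMML / edge-table I/O
# ---------------------------------------------------------------------------


def test_xgmml_nodes_only(tmp_path):
    g = build_graph("empty_edges", [])
    for lab in ("taof(A)", "exp(B)", "C"):
        g.add_node(parse_node_label(lab))
    sn = Subnetwork("empty_edges", g)
    path = tmp_path / "g.xgmml"
    write_xgmml(sn, path)
    back = read_xgmml(path)
    assert back.graph.n_nodes == 3
    assert back.graph.n_edges == 0
    assert back == sn


def test_xgmml_known_edge_count(tmp_path):
    # fixture generator emits a controlled number of edges
    edges = [
        (f"kaof(U{i})", 1 if (i + j) % 3 else -1, f"exp(G{i}_{j})")
        for i in range(10)
        for j in range(18)
    ][:179]
    g = build_graph("smc_scale", edges)
    assert g.n_edges == 179
    path = tmp_path / "g.xgmml"
    write_xgmml(Subnetwork("smc_scale", g), path)
    assert read_xgmml(path).graph.n_edges == 179


@pytest.mark.parametrize("seed", range(100))
def test_xgmml_roundtrip_random_graphs(tmp_path, seed):
    g = random_graph(seed)
    sn = Subnetwork(g.name, g)
    path = tmp_path / f"g{seed}.xgmml"
    write_xgmml(sn, path)
    assert read_xgmml(path) == sn


@pytest.mark.parametrize("seed", range(30))
def test_edge_table_roundtrip_random_graphs(tmp_path, seed):
    g = random_graph(seed + 1000)
    sn = Subnetwork(g.name, g)
    path = tmp_path / f"g{seed}.tsv"
    write_edge_table(sn, path)
    assert read_edge_table(path, name=sn.name) == sn


def test_edge_table_single_line(tmp_path):
    path = tmp_path / "one.tsv"
    path.write_text(
        "# comment line\n\n"
        "taof(NFKB1)\tincreases\texp(CXCL1)\t16414985\thuman\tHeLa\n"
    )
    sn = read_edge_table(path)
    assert sn.graph.n_edges == 1
    edge = sn.graph.edges[0]
    assert edge.sign == 1
    assert edge.source.label == "taof(NFKB1)"
    assert edge.target.label == "exp(CXCL1)"
    (ev,) = edge.evidences
    assert ev.citation_id == "16414985"
    assert ev.species is Species.HUMAN
    assert ev.context_keywords == frozenset({"HeLa"})


def test_unknown_relationship_policy(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("taof(A)\tsubset\texp(B)\n")
    with pytest.raises(IOError, match="subset"):
        read_edge_table(path)
    sn = read_edge_table(path, on_unknown_relationship="ambiguous")
    assert sn.graph.edges[0].sign == 0


def test_read_xgmml_rejects_malformed_xml(tmp_path):
    path = tmp_path / "broken.xgmml"
    path.write_text("<graph><node")
    with pytest.raises(IOError):
        read_xgmml(path)


def test_xgmml_preserves_unknown_attributes(tmp_path):
    g = build_graph("g", [])
    g.add_edge(
        CausalEdge(
            parse_node_label("taof(A)"), 1, parse_node_label("exp(B)"),
            attrs=(("curator", "jd"), ("confidence", "0.9")),
        )
    )
    path = tmp_path / "g.xgmml"
    write_xgmml(Subnetwork("g", g), path)
    back = read_xgmml(path)
    assert dict(back.graph.edges[0].attrs) == {"curator": "jd", "confidence": "0.9"}


# ---------------------------------------------------------------------------
# merge / overlap
# ---------------------------------------------------------------------------


def test_merge_unifies_shared_nodes():
    a = build_graph("a", [("taof(NFKB1)", 1, "exp(CXCL1)")])
    b = build_graph("b", [("taof(NFKB1)", 1, "exp(IL6)")])
    merged = merge_subnetworks([Subnetwork("a", a), Subnetwork("b", b)])
    assert sorted(merged.node_labels()) == ["exp(CXCL1)", "exp(IL6)", "taof(NFKB1)"]
    assert merged.n_edges == 2


def test_merge_identity_and_union_oracle():
    graphs = [random_graph(s) for s in (5, 6, 7)]
    single = merge_subnetworks([Subnetwork("x", graphs[0])])
    assert single == graphs[0]
    merged = merge_subnetworks([Subnetwork(g.name, g) for g in graphs])
    assert merged.node_labels() == set().union(*(g.node_labels() for g in graphs))


def test_merge_order_insensitive():
    graphs = [Subnetwork(f"s{i}", random_graph(i + 50)) for i in range(3)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forward = merge_subnetworks(graphs)
        backward = merge_subnetworks(graphs[::-1])
        nested = merge_subnetworks(
            [Subnetwork("ab", merge_subnetworks(graphs[:2])), graphs[2]]
        )
    assert forward == backward == nested


def test_node_overlap_matrix_against_bruteforce():
    subnets = [Subnetwork(f"s{i}", random_graph(i + 20)) for i in range(4)]
    counts, pct = node_overlap_matrix(subnets)
    for i in subnets:
        for j in subnets:
            expect = len(i.graph.node_labels() & j.graph.node_labels())
            assert counts.loc[i.name, j.name] == expect
            assert pct.loc[i.name, j.name] == pytest.approx(
                100 * expect / i.graph.n_nodes
            )
    assert (counts.values == counts.values.T).all()
    for sn in subnets:
        assert counts.loc[sn.name, sn.name] == sn.graph.n_nodes
        assert pct.loc[sn.name, sn.name] == pytest.approx(100.0)


def test_node_overlap_matrix_disjoint_and_identical():
    a = build_graph("a", [("taof(A)", 1, "exp(B)")])
    b = build_graph("b", [("taof(C)", 1, "exp(D)")])
    counts, _ = node_overlap_matrix([Subnetwork("a", a), Subnetwork("b", b)])
    assert counts.loc["a", "b"] == 0
    twin = build_graph("a2", [("taof(A)", 1, "exp(B)")])
    counts, pct = node_overlap_matrix([Subnetwork("a", a), Subnetwork("a2", twin)])
    assert (counts.values == 2).all()
    assert (pct.values == 100.0).all()


# ---------------------------------------------------------------------------
# context proportions
# ---------------------------------------------------------------------------


def _context_fixture(n_total: int, n_vascular: int) -> Subnetwork:
    vascular = Evidence("11111111", Species.HUMAN, frozenset({"endothelial cells"}))
    other = Evidence("22222222", Species.HUMAN, frozenset({"hepatocytes"}))
    edges, evmap = [], {}
    for i in range(n_total):
        src, tgt = f"kaof(U{i})", f"exp(G{i})"
        edges.append((src, 1, tgt))
        evmap[(src, tgt)] = [vascular if i < n_vascular else other]
    return Subnetwork("ctx", build_graph("ctx", edges, evmap))


@pytest.mark.parametrize(
    "n_total, n_match, percent",
    [(407, 238, 58), (179, 10, 6), (179, 78, 44), (50, 0, 0)],
)
def test_context_edge_proportion(n_total, n_match, percent):
    sn = _context_fixture(n_total, n_match)
    result = context_edge_proportion(sn, {"endothelial"})
    assert result["n_total"] == n_total
    assert result["n_context"] == n_match
    assert result["percent"] == percent
    assert 0.0 <= result["fraction"] <= 1.0


def test_context_proportion_monotone_in_keywords():
    sn = Subnetwork("r", random_graph(3))
    base = context_edge_proportion(sn, {"endothelial"})["fraction"]
    wider = context_edge_proportion(sn, {"endothelial", "aorta"})["fraction"]
    assert wider >= base


def test_context_proportion_empty_subnetwork_signalled():
    sn = Subnetwork("empty", build_graph("empty", []))
    with pytest.raises(ValueError, match="undefined"):
        context_edge_proportion(sn, {"aorta"})
    with pytest.raises(ValueError):
        context_edge_proportion(_context_fixture(3, 1), set())


def test_context_proportion_min_evidence():
    ev = Evidence("1", Species.HUMAN, frozenset({"aorta"}))
    sn = Subnetwork(
        "m",
        build_graph("m", [("kaof(U)", 1, "exp(G)")], {("kaof(U)", "exp(G)"): [ev]}),
    )
    assert context_edge_proportion(sn, {"aorta"}, min_evidence=1)["n_context"] == 1
    assert context_edge_proportion(sn, {"aorta"}, min_evidence=2)["n_context"] == 0


# ---------------------------------------------------------------------------
# chimeric unification
# ---------------------------------------------------------------------------


def test_make_chimeric_unifies_orthologs():
    g = build_graph(
        "g",
        [("taof(Stat1)", 1, "exp(Gbp2)"), ("taof(STAT1)", 1, "exp(GBP2)")],
    )
    chim = make_chimeric(g, {"Stat1": "STAT1", "Gbp2": "GBP2"})
    assert sorted(chim.node_labels()) == ["exp(GBP2)", "taof(STAT1)"]
    assert chim.n_edges == 1
    assert chim.nodes["taof(STAT1)"].species_context is Species.CHIMERIC


def test_make_chimeric_empty_map_is_identity():
    g = random_graph(9)
    assert make_chimeric(g, {}) == g


def test_make_chimeric_idempotent():
    g = build_graph(
        "g", [("taof(Stat1)", 1, "exp(Gbp2)"), ("kaof(Stat1)", -1, "exp(Il6)")]
    )
    amap = {"Stat1": "STAT1"}
    once = make_chimeric(g, amap)
    assert make_chimeric(once, amap) == once


def test_make_chimeric_rejects_chained_renames():
    g = build_graph("g", [("taof(A)", 1, "exp(B)")])
    with pytest.raises(ValueError, match="chained"):
        make_chimeric(g, {"A": "B", "B": "C"})
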