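"""Data model and I/O for signed causal knowledge graphs.

A causal knowledge graph encodes experimentally supported statements of the
form *"increased activity of X increases the RNA expression of Y"* as signed,
directed edges between typed biological entities.  Node labels follow the
compact activity grammar used by curated causal knowledgebases::

    taof(STAT1)      transcriptional activity of STAT1
    kaof(Chuk)       kinase activity of Chuk
    exp(CXCL1)       RNA expression of CXCL1
    gtpof(RHOA)      GTP-bound activity of RHOA
    paof(PTPN1)      phosphatase activity of PTPN1
    catof(MMP9)      catalytic activity of MMP9
    bp(angiogenesis) a biological process
    AKT1 P@S473      abundance of AKT1 phosphorylated at serine 473
    CCL5             protein abundance of CCL5

Graphs are exchanged either as XGMML (the XML dialect consumed by Cytoscape)
or as a 6-column tab-separated edge table.  Modular subnetworks — named
slices of one agglomerated model — are the unit of evaluation downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from lxml import etree

__all__ = [
    "ActivityTag",
    "Species",
    "NodeRef",
    "Evidence",
    "CausalEdge",
    "CausalGraph",
    "Subnetwork",
    "NodeLabelError",
    "parse_node_label",
    "format_node_label",
    "read_xgmml",
    "write_xgmml",
    "read_edge_table",
    "write_edge_table",
    "merge_subnetworks",
    "node_overlap_matrix",
    "context_edge_proportion",
    "make_chimeric",
]


class ActivityTag(str, Enum):
    """Activity-function tag qualifying what aspect of an entity a node denotes."""

    ABUNDANCE = "abundance"
    TRANSCRIPTIONAL_ACTIVITY = "transcriptional_activity"
    KINASE_ACTIVITY = "kinase_activity"
    PHOSPHATASE_ACTIVITY = "phosphatase_activity"
    CATALYTIC_ACTIVITY = "catalytic_activity"
    GTP_BOUND = "gtp_bound"
    RNA_EXPRESSION = "rna_expression"
    PHOSPHO_FORM = "phospho_form"
    BIOLOGICAL_PROCESS = "biological_process"


class Species(str, Enum):
    HUMAN = "human"
    MOUSE = "mouse"
    RAT = "rat"
    CHIMERIC = "chimeric"
    UNSPECIFIED = "unspecified"


#: label prefix <-> tag, for every tag written in functional form
_PREFIX_TO_TAG = {
    "taof": ActivityTag.TRANSCRIPTIONAL_ACTIVITY,
    "kaof": ActivityTag.KINASE_ACTIVITY,
    "paof": ActivityTag.PHOSPHATASE_ACTIVITY,
    "catof": ActivityTag.CATALYTIC_ACTIVITY,
    "gtpof": ActivityTag.GTP_BOUND,
    "exp": ActivityTag.RNA_EXPRESSION,
    "bp": ActivityTag.BIOLOGICAL_PROCESS,
}
_TAG_TO_PREFIX = {v: k for k, v in _PREFIX_TO_TAG.items()}

_FUNC_RE = re.compile(r"^([A-Za-z]+)\((.*)\)$")
_PHOSPHO_RE = re.compile(r"^(.+?)\s+P@(\S+)$")
# symbols may contain word chars, dash, dot, colon, slash and internal spaces
# (biological processes such as "macrophage activation"); no tabs or parens.
_SYMBOL_RE = re.compile(r"^[^()\t\n]+$")


class NodeLabelError(ValueError):
    """Raised when a node label does not match the activity grammar."""


@dataclass(frozen=True)
class NodeRef:
    """A typed biological entity — the vertex type of the causal graph.

    Node identity is the canonical label (tag + symbol + optional phospho
    site), case-sensitive.  ``species_context`` is annotation only and does
    not participate in equality; cross-species unification happens solely
    through :func:`make_chimeric`.
    """

    entity_symbol: str
    activity_tag: ActivityTag = ActivityTag.ABUNDANCE
    phospho_site: str | None = None
    species_context: Species = field(default=Species.UNSPECIFIED, compare=False)

    def __post_init__(self) -> None:
        if not self.entity_symbol or not _SYMBOL_RE.match(self.entity_symbol):
            raise NodeLabelError(f"invalid entity symbol: {self.entity_symbol!r}")
        if (self.phospho_site is not None) != (
            self.activity_tag is ActivityTag.PHOSPHO_FORM
        ):
            raise NodeLabelError(
                "phospho_site must be present exactly when activity_tag is "
                f"phospho_form (got {self.entity_symbol!r})"
            )

    @property
    def label(self) -> str:
        return format_node_label(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_node_label(label: str, species: Species = Species.UNSPECIFIED) -> NodeRef:
    """Parse a canonical node label into a :class:`NodeRef`.

    Accepted forms: ``TAG(SYMBOL)`` with a known tag prefix, ``SYMBOL P@SITE``
    for a phosphorylated form, and a bare ``SYMBOL`` (protein abundance).
    ``format_node_label(parse_node_label(s)) == s`` for canonical labels.
    """
    if not isinstance(label, str) or not label.strip():
        raise NodeLabelError(f"empty or non-string node label: {label!r}")
    label = label.strip()
    m = _FUNC_RE.match(label)
    if m:
        prefix, symbol = m.groups()
        if prefix not in _PREFIX_TO_TAG:
            raise NodeLabelError(f"unknown activity tag {prefix!r} in label {label!r}")
        if not symbol:
            raise NodeLabelError(f"empty symbol in label {label!r}")
        return NodeRef(symbol, _PREFIX_TO_TAG[prefix], species_context=species)
    if "(" in label or ")" in label:
        raise NodeLabelError(f"unbalanced or misplaced parentheses in label {label!r}")
    m = _PHOSPHO_RE.match(label)
    if m:
        symbol, site = m.groups()
        return NodeRef(
            symbol, ActivityTag.PHOSPHO_FORM, phospho_site=site, species_context=species
        )
    return NodeRef(label, ActivityTag.ABUNDANCE, species_context=species)


def format_node_label(node: NodeRef) -> str:
    """Canonical text form of a node; inverse of :func:`parse_node_label`."""
    tag = node.activity_tag
    if tag is ActivityTag.ABUNDANCE:
        return node.entity_symbol
    if tag is ActivityTag.PHOSPHO_FORM:
        return f"{node.entity_symbol} P@{node.phospho_site}"
    return f"{_TAG_TO_PREFIX[tag]}({node.entity_symbol})"


@dataclass(frozen=True)
class Evidence:
    """A single literature (or synthetic) support for a causal edge."""

    citation_id: str = ""
    species: Species = Species.UNSPECIFIED
    context_keywords: frozenset[str] = frozenset()

    def sort_key(self) -> tuple:
        return (self.citation_id, self.species.value, tuple(sorted(self.context_keywords)))


_SIGN_TO_REL = {1: "increases", -1: "decreases", 0: "ambiguous"}
_REL_TO_SIGN = {v: k for k, v in _SIGN_TO_REL.items()}


@dataclass(frozen=True)
class CausalEdge:
    """Signed, directed causal relation between two nodes.

    ``sign`` is +1 (increases), -1 (decreases) or 0 (ambiguous).  Evidence
    annotations do not participate in edge equality.
    """

    source: NodeRef
    sign: int
    target: NodeRef
    evidences: tuple[Evidence, ...] = field(default=(), compare=False)
    attrs: tuple[tuple[str, str], ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"edge sign must be -1, 0 or +1; got {self.sign!r}")

    @property
    def relationship(self) -> str:
        return _SIGN_TO_REL[self.sign]


class CausalGraph:
    """A normalized signed causal graph.

    Normalization on insertion: endpoints are registered as nodes, self-loops
    are dropped with a warning, duplicate ``(source, target)`` pairs are
    merged (evidences concatenated) and conflicting signs collapse to
    ambiguous with a warning.  The depth-1 hypothesis model downstream needs
    exactly one expected sign per (controller, transcript) pair, which these
    rules guarantee.
    """

    def __init__(self, name: str = "graph") -> None:
        self.name = name
        self._nodes: dict[str, NodeRef] = {}
        self._edges: dict[tuple[str, str], CausalEdge] = {}

    # -- construction ------------------------------------------------------
    def add_node(self, node: NodeRef) -> NodeRef:
        return self._nodes.setdefault(node.label, node)

    def add_edge(self, edge: CausalEdge) -> None:
        src = self.add_node(edge.source)
        tgt = self.add_node(edge.target)
        if src.label == tgt.label:
            warnings.warn(
                f"dropping self-loop on {src.label!r} during normalization",
                stacklevel=2,
            )
            return
        key = (src.label, tgt.label)
        prev = self._edges.get(key)
        if prev is None:
            self._edges[key] = CausalEdge(src, edge.sign, tgt, edge.evidences, edge.attrs)
            return
        sign = prev.sign
        if prev.sign != edge.sign:
            # any disagreement collapses to ambiguous; this keeps the merge
            # associative and order-insensitive
            sign = 0
            if {prev.sign, edge.sign} == {1, -1}:
                warnings.warn(
                    f"conflicting signs for edge {key[0]!r} -> {key[1]!r}; "
                    "collapsing to ambiguous",
                    stacklevel=2,
                )
        self._edges[key] = CausalEdge(
            src, sign, tgt, prev.evidences + edge.evidences, prev.attrs + edge.attrs
        )

    # -- access ------------------------------------------------------------
    @property
    def nodes(self) -> dict[str, NodeRef]:
        return dict(self._nodes)

    @property
    def edges(self) -> list[CausalEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node_labels(self) -> set[str]:
        return set(self._nodes)

    def out_edges(self, label: str) -> list[CausalEdge]:
        return [e for (s, _), e in self._edges.items() if s == label]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        if self.node_labels() != other.node_labels():
            return False
        if set(self._edges) != set(other._edges):
            return False
        for key, e in self._edges.items():
            o = other._edges[key]
            if e.sign != o.sign:
                return False
            if sorted(ev.sort_key() for ev in e.evidences) != sorted(
                ev.sort_key() for ev in o.evidences
            ):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        return f"CausalGraph({self.name!r}, {self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class Subnetwork:
    """A named module of an agglomerated causal model."""

    name: str
    graph: CausalGraph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Subnetwork):
            return NotImplemented
        return self.name == other.name and self.graph == other.graph


# ---------------------------------------------------------------------------
# XGMML I/O
# ---------------------------------------------------------------------------

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _localname(el) -> str:
    return etree.QName(el).localname


def read_xgmml(path, on_unknown_relationship: str = "reject") -> Subnetwork:
    """Read a subnetwork from an XGMML file.

    Node ``label`` attributes must parse under the activity grammar; each
    edge must carry a ``relationship`` att (increases/decreases/ambiguous).
    Unknown node and edge atts are preserved opaquely and round-tripped.
    ``on_unknown_relationship`` is ``"reject"`` (default) or ``"ambiguous"``.
    """
    if on_unknown_relationship not in ("reject", "ambiguous"):
        raise ValueError("on_unknown_relationship must be 'reject' or 'ambiguous'")
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise IOError(f"cannot read XGMML file {path}: {exc}") from exc
    root = tree.getroot()
    if _localname(root) != "graph":
        raise IOError(f"{path}: root element is not <graph>")
    graph = CausalGraph(root.get("label", "graph"))
    id_to_node: dict[str, NodeRef] = {}
    for el in root:
        if not isinstance(el.tag, str):
            continue
        kind = _localname(el)
        if kind == "node":
            label = el.get("label")
            if label is None:
                raise IOError(f"{path}: node without label attribute")
            species = Species.UNSPECIFIED
            attrs = []
            for att in el:
                if isinstance(att.tag, str) and _localname(att) == "att":
                    name, value = att.get("name", ""), att.get("value", "")
                    if name == "species":
                        species = Species(value)
                    else:
                        attrs.append((name, value))
            node = parse_node_label(label, species=species)
            id_to_node[el.get("id", label)] = node
            graph.add_node(node)
        elif kind == "edge":
            src_id, tgt_id = el.get("source"), el.get("target")
            if src_id not in id_to_node or tgt_id not in id_to_node:
                raise IOError(f"{path}: edge references unknown node id")
            relationship = None
            evidences: list[Evidence] = []
            attrs = []
            for att in el:
                if not (isinstance(att.tag, str) and _localname(att) == "att"):
                    continue
                name, value = att.get("name", ""), att.get("value", "")
                if name == "relationship":
                    relationship = value
                elif name == "evidence":
                    evidences.append(_evidence_from_string(value))
                else:
                    attrs.append((name, value))
            if relationship not in _REL_TO_SIGN:
                if on_unknown_relationship == "ambiguous":
                    relationship = "ambiguous"
                else:
                    raise IOError(
                        f"{path}: unmappable relationship {relationship!r} on edge "
                        f"{src_id} -> {tgt_id}"
                    )
            graph.add_edge(
                CausalEdge(
                    id_to_node[src_id],
                    _REL_TO_SIGN[relationship],
                    id_to_node[tgt_id],
                    tuple(evidences),
                    tuple(attrs),
                )
            )
    return Subnetwork(graph.name, graph)


def write_xgmml(subnetwork: Subnetwork, path) -> None:
    """Write a subnetwork as XGMML, re-readable by :func:`read_xgmml`."""
    graph = subnetwork.graph
    root = etree.Element(f"{{{_XGMML_NS}}}graph", nsmap={None: _XGMML_NS})
    root.set("label", subnetwork.name)
    root.set("directed", "1")
    ids = {label: str(i) for i, label in enumerate(sorted(graph.nodes))}
    for label, node_id in ids.items():
        node = graph.nodes[label]
        el = etree.SubElement(root, f"{{{_XGMML_NS}}}node", id=node_id, label=label)
        if node.species_context is not Species.UNSPECIFIED:
            etree.SubElement(
                el, f"{{{_XGMML_NS}}}att", name="species", value=node.species_context.value
            )
    for edge in graph.edges:
        el = etree.SubElement(
            root,
            f"{{{_XGMML_NS}}}edge",
            source=ids[edge.source.label],
            target=ids[edge.target.label],
            label=f"{edge.source.label} {edge.relationship} {edge.target.label}",
        )
        etree.SubElement(
            el, f"{{{_XGMML_NS}}}att", name="relationship", value=edge.relationship
        )
        for ev in edge.evidences:
            etree.SubElement(
                el, f"{{{_XGMML_NS}}}att", name="evidence", value=_evidence_to_string(ev)
            )
        for name, value in edge.attrs:
            etree.SubElement(el, f"{{{_XGMML_NS}}}att", name=name, value=value)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _evidence_to_string(ev: Evidence) -> str:
    return "|".join(
        [ev.citation_id, ev.species.value, ";".join(sorted(ev.context_keywords))]
    )


def _evidence_from_string(s: str) -> Evidence:
    parts = (s.split("|") + ["", "", ""])[:3]
    citation, species, keywords = parts
    return Evidence(
        citation,
        Species(species) if species else Species.UNSPECIFIED,
        frozenset(k for k in keywords.split(";") if k),
    )


# ---------------------------------------------------------------------------
# Edge-table I/O
# ---------------------------------------------------------------------------
# Tab-separated, '#' comments.  Columns:
#   source-label  relationship  target-label  citation  species  keywords
# One line per evidence; an edge without evidence writes a single line with
# the last three columns empty.


def read_edge_table(path, name: str | None = None,
                    on_unknown_relationship: str = "reject") -> Subnetwork:
    """Read a subnetwork from the tab-separated edge-table dialect."""
    graph = CausalGraph(name or _stem(path))
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise IOError(f"{path}:{lineno}: expected at least 3 columns")
            cols += [""] * (6 - len(cols))
            src_l, rel, tgt_l, citation, species, keywords = cols[:6]
            if rel not in _REL_TO_SIGN:
                if on_unknown_relationship == "ambiguous":
                    rel = "ambiguous"
                else:
                    raise IOError(f"{path}:{lineno}: unmappable relationship {rel!r}")
            evidences: tuple[Evidence, ...] = ()
            if citation or species or keywords:
                evidences = (
                    Evidence(
                        citation,
                        Species(species) if species else Species.UNSPECIFIED,
                        frozenset(k for k in keywords.split(";") if k),
                    ),
                )
            graph.add_edge(
                CausalEdge(
                    parse_node_label(src_l), _REL_TO_SIGN[rel], parse_node_label(tgt_l),
                    evidences,
                )
            )
    return Subnetwork(graph.name, graph)


def write_edge_table(subnetwork: Subnetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# causal edge table: {subnetwork.name}\n")
        fh.write("# source\trelationship\ttarget\tcitation\tspecies\tkeywords\n")
        for edge in subnetwork.graph.edges:
            base = f"{edge.source.label}\t{edge.relationship}\t{edge.target.label}"
            if not edge.evidences:
                fh.write(base + "\t\t\t\n")
                continue
            for ev in sorted(edge.evidences, key=Evidence.sort_key):
                fh.write(
                    base
                    + f"\t{ev.citation_id}\t{ev.species.value}"
                    + "\t" + ";".join(sorted(ev.context_keywords)) + "\n"
                )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# Topology / annotation statistics
# ---------------------------------------------------------------------------


def merge_subnetworks(
    subnetworks: Sequence[Subnetwork | CausalGraph], name: str = "merged"
) -> CausalGraph:
    """Agglomerate subnetworks into one graph.

    Nodes unify by canonical label; duplicate (source, target) edges merge
    with concatenated evidences, and conflicting signs collapse to ambiguous
    (warning emitted).  Associative and order-insensitive up to evidence
    ordering.
    """
    if not subnetworks:
        raise ValueError("merge_subnetworks requires at least one subnetwork")
    merged = CausalGraph(name)
    for sn in subnetworks:
        graph = sn.graph if isinstance(sn, Subnetwork) else sn
        for node in graph.nodes.values():
            merged.add_node(node)
        for edge in graph.edges:
            merged.add_edge(edge)
    return merged


def node_overlap_matrix(subnetworks: Sequence[Subnetwork]):
    """Pairwise node-overlap counts and row-normalized percentages.

    Returns ``(counts, percent)`` DataFrames indexed by subnetwork name.
    ``counts`` is symmetric with subnetwork sizes on the diagonal;
    ``percent[i, j] = 100 * counts[i, j] / |i|``.
    """
    import pandas as pd

    if len(subnetworks) < 2:
        raise ValueError("node_overlap_matrix requires at least two subnetworks")
    names = [sn.name for sn in subnetworks]
    if len(set(names)) != len(names):
        raise ValueError("subnetwork names must be unique")
    sets = {sn.name: sn.graph.node_labels() for sn in subnetworks}
    counts = pd.DataFrame(
        [[len(sets[i] & sets[j]) for j in names] for i in names],
        index=names,
        columns=names,
        dtype=int,
    )
    sizes = pd.Series({n: len(sets[n]) for n in names})
    percent = counts.div(sizes, axis=0) * 100.0
    return counts, percent


def context_edge_proportion(
    subnetwork: Subnetwork, keywords: Iterable[str], min_evidence: int = 1
) -> dict:
    """Fraction of edges supported by evidence from a given tissue context.

    An evidence matches when any of its context keywords contains (case-
    insensitive substring) any query keyword; an edge counts when at least
    ``min_evidence`` of its evidences match.  Returns
    ``{"n_total", "n_context", "fraction", "percent"}`` with ``percent``
    rounded to an integer for reporting.
    """
    kws = [k.lower() for k in keywords]
    if not kws:
        raise ValueError("keywords must be non-empty")
    edges = subnetwork.graph.edges
    if not edges:
        raise ValueError(f"subnetwork {subnetwork.name!r} has no edges; "
                         "context proportion is undefined")
    n_context = 0
    for edge in edges:
        n_match = sum(
            1
            for ev in edge.evidences
            if any(q in ckw.lower() for ckw in ev.context_keywords for q in kws)
        )
        if n_match >= min_evidence:
            n_context += 1
    fraction = n_context / len(edges)
    return {
        "n_total": len(edges),
        "n_context": n_context,
        "fraction": fraction,
        "percent": round(100 * fraction),
    }


def make_chimeric(graph: CausalGraph, ortholog_map: Mapping[str, str]) -> CausalGraph:
    """Unify orthologous nodes under a symbol map, producing a chimeric graph.

    Every node whose entity symbol is a key of ``ortholog_map`` is renamed to
    the mapped symbol (same activity tag and phospho site) with
    ``species_context`` set to chimeric; edges are re-targeted and duplicates
    merged under the standard rules.  Idempotent: chained renames (a map
    value that is itself a key with a different target) are rejected.
    """
    collisions = sorted(
        v for k, v in ortholog_map.items()
        if v in ortholog_map and ortholog_map[v] != v
    )
    if collisions:
        raise ValueError(
            "ortholog_map contains chained renames through: " + ", ".join(collisions)
        )

    def remap(node: NodeRef) -> NodeRef:
        if node.entity_symbol not in ortholog_map:
            return node
        return NodeRef(
            ortholog_map[node.entity_symbol],
            node.activity_tag,
            node.phospho_site,
            Species.CHIMERIC,
        )

    out = CausalGraph(graph.name)
    for node in graph.nodes.values():
        out.add_node(remap(node))
    for edge in graph.edges:
        out.add_edge(
            CausalEdge(remap(edge.source), edge.sign, remap(edge.target),
                       edge.evidences, edge.attrs)
        )
    return out
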