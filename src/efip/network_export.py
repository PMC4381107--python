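"""Phospho-interaction networks and Cytoscape-compatible XGMML export.

Tuples merged across documents become a typed graph: each distinct
site-set of a substrate is a separate *phosphoform* node (site-less
tuples get the "phosphoX" phosphoform), linked to its base protein node
by a ``phosphoform_of`` edge; kinases point at the phosphoform they
produce with ``phosphorylates`` edges; and ``association`` /
``dissociation`` edges connect phosphoforms to their interactants,
carrying polarity ("+", "-" or ""), a dashed flag for dissociations,
a support count and the supporting document ids.  Styling (the green
kinase pentagons and so on of an interactive viewer) is emitted as
attributes only; rendering belongs to Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from ._text import norm_name
from .impact_relations import EFIPTuple

NODE_TYPES = ("kinase", "protein", "phosphoform", "interactant")
EDGE_TYPES = ("phosphorylates", "phosphoform_of", "association",
              "dissociation")

_POL_SYMBOL = {"increase": "+", "decrease": "-", "unspecified": ""}


@dataclass
class Node:
    id: str
    label: str
    node_type: str
    sites: tuple[str, ...] = ()


@dataclass
class Edge:
    source: str
    target: str
    edge_type: str
    polarity: str = ""  # "+", "-" or ""
    support_count: int = 0
    doc_refs: list[str] = field(default_factory=list)

    @property
    def dashed(self) -> bool:
        return self.edge_type == "dissociation"


@dataclass
class PhosphoNetwork:
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: dict[tuple, Edge] = field(default_factory=dict)

    def sorted_nodes(self) -> list[Node]:
        return [self.nodes[k] for k in sorted(self.nodes)]

    def sorted_edges(self) -> list[Edge]:
        return [self.edges[k] for k in sorted(self.edges)]


def _key_of(name: str | None, acc: str) -> str:
    if acc:
        return acc
    return norm_name(name or "")


def build_network(tuples: list[EFIPTuple]) -> PhosphoNetwork:
    """Merge tuples into a typed phospho-interaction graph.

    Node identity keys on accession when available, else normalized
    surface name.  Identical tuples from different documents increment
    the supporting edge's ``support_count`` and extend its ``doc_refs``.
    """
    net = PhosphoNetwork()

    def ensure_node(key: str, label: str, node_type: str,
                    sites: tuple[str, ...] = ()) -> str:
        node = net.nodes.get(key)
        if node is None:
            net.nodes[key] = Node(id=key, label=label, node_type=node_type,
                                  sites=sites)
        elif node.node_type == "interactant" and node_type == "kinase":
            node.node_type = "kinase"
        return key

    def bump(source: str, target: str, edge_type: str, polarity: str,
             doc_id: str) -> None:
        key = (source, target, edge_type, polarity)
        edge = net.edges.get(key)
        if edge is None:
            edge = net.edges[key] = Edge(source=source, target=target,
                                         edge_type=edge_type,
                                         polarity=polarity)
        edge.support_count += 1
        if doc_id and doc_id not in edge.doc_refs:
            edge.doc_refs.append(doc_id)

    for tup in tuples:
        base_key = _key_of(tup.substrate, tup.substrate_acc)
        sites = tuple(sorted(tup.sites)) or ("phosphoX",)
        form_key = base_key + "@" + "+".join(sites)
        ensure_node(base_key, tup.substrate, "protein")
        ensure_node(form_key, f"{tup.substrate} {' '.join(sites)}",
                    "phosphoform", sites)
        pf_edge = (form_key, base_key, "phosphoform_of", "")
        if pf_edge not in net.edges:
            net.edges[pf_edge] = Edge(source=form_key, target=base_key,
                                      edge_type="phosphoform_of")
        inter_key = _key_of(tup.interactant, tup.interactant_acc)
        ensure_node(inter_key, tup.interactant, "interactant")
        edge_type = "dissociation" if tup.ppi_type == "dissociation" \
            else "association"
        bump(form_key, inter_key, edge_type,
             _POL_SYMBOL.get(tup.polarity, ""), tup.doc_id)
        if tup.kinase:
            kin_key = _key_of(tup.kinase, tup.kinase_acc)
            ensure_node(kin_key, tup.kinase, "kinase")
            net.nodes[kin_key].node_type = "kinase"
            bump(kin_key, form_key, "phosphorylates", "", tup.doc_id)
    return net


# --- XGMML -----------------------------------------------------------------

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _att(parent, name, value, att_type="string"):
    etree.SubElement(parent, "att",
                     name=name, value=str(value), type=att_type)


def export_xgmml(network: PhosphoNetwork, label: str = "phospho-network") -> str:
    """Serialize a network to Cytoscape-compatible XGMML text.

    Element order is deterministic (sorted by id) and the output
    re-imports losslessly via :func:`parse_xgmml`.
    """
    graph = etree.Element("graph", label=label, directed="1",
                          xmlns=_XGMML_NS)
    for node in network.sorted_nodes():
        el = etree.SubElement(graph, "node", id=node.id, label=node.label)
        _att(el, "node_type", node.node_type)
        _att(el, "sites", " ".join(node.sites))
    for edge in network.sorted_edges():
        el = etree.SubElement(graph, "edge", source=edge.source,
                              target=edge.target,
                              label=f"{edge.source} ({edge.edge_type}) "
                                    f"{edge.target}")
        _att(el, "edge_type", edge.edge_type)
        _att(el, "polarity", edge.polarity)
        _att(el, "dashed", "true" if edge.dashed else "false")
        _att(el, "support_count", edge.support_count, "integer")
        _att(el, "doc_refs", " ".join(edge.doc_refs))
    return etree.tostring(graph, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def parse_xgmml(text: str | bytes) -> PhosphoNetwork:
    """Read XGMML produced by :func:`export_xgmml` back into a network."""
    if isinstance(text, str):
        text = text.encode("utf-8")
    root = etree.fromstring(text)
    net = PhosphoNetwork()

    def atts(el):
        return {a.get("name"): a.get("value")
                for a in el if etree.QName(a).localname == "att"}

    for el in root:
        tag = etree.QName(el).localname
        if tag == "node":
            a = atts(el)
            net.nodes[el.get("id")] = Node(
                id=el.get("id"), label=el.get("label"),
                node_type=a.get("node_type", "protein"),
                sites=tuple(a.get("sites", "").split()) or (),
            )
        elif tag == "edge":
            a = atts(el)
            edge = Edge(
                source=el.get("source"), target=el.get("target"),
                edge_type=a.get("edge_type", "association"),
                polarity=a.get("polarity", ""),
                support_count=int(a.get("support_count", 0)),
                doc_refs=a.get("doc_refs", "").split(),
            )
            net.edges[(edge.source, edge.target, edge.edge_type,
                       edge.polarity)] = edge
    return net


def edge_list_csv(network: PhosphoNetwork) -> str:
    """Flat CSV edge list: source,target,edge_type,polarity,support,docs."""
    lines = ["source,target,edge_type,polarity,support,docs"]
    for e in network.sorted_edges():
        docs = ";".join(e.doc_refs)
        lines.append(f"{e.source},{e.target},{e.edge_type},{e.polarity},"
                     f"{e.support_count},{docs}")
    return "\n".join(lines) + "\n"
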